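"""Library construct modelling: primers, in-silico PCR, barcodes.

The SELEX library architecture is a constant 5' flank, a random insert,
and a constant 3' flank. PCR is modelled as exact annealing of each
primer's 3'-terminal suffix (template N acts as a wildcard), which is
what the construct arithmetic needs: primer extensions add their 5'
overhangs, so product length is fully determined by the printed
sequences. Barcode handling covers extraction from barcoded reverse
primers, design validation (pairwise Hamming distance, per-position base
composition), and read demultiplexing. Coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

from selexkit.errors import PCRError, ValidationError
from selexkit.seqio import Read, write_sequences

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class Primer:
    """A PCR primer, written 5'->3'. N is not allowed in primers."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"primer {self.name!r}: empty sequence")
        if not set(self.seq) <= set("ACGT"):
            raise ValidationError(
                f"primer {self.name!r}: only A/C/G/T allowed in primers"
            )


@dataclass(frozen=True, slots=True)
class LibraryConstruct:
    """Fixed-flank / random-insert architecture of a SELEX library."""

    five_prime_flank: str
    insert_length: int
    three_prime_flank: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.insert_length <= 0:
            raise ValidationError("insert_length must be positive")
        if not self.five_prime_flank or not self.three_prime_flank:
            raise ValidationError("construct flanks must be non-empty")

    @property
    def template(self) -> str:
        """Single-stranded template with the insert as an N run."""
        return self.five_prime_flank + "N" * self.insert_length + self.three_prime_flank


@dataclass(slots=True)
class BarcodeTable:
    """Ordered sample_name -> barcode map; barcodes uniform-length and unique."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        barcodes = list(self.entries.values())
        if barcodes:
            length = len(barcodes[0])
            if any(len(b) != length for b in barcodes):
                raise ValidationError("barcodes must all have the same length")
            if len(set(barcodes)) != len(barcodes):
                raise ValidationError("barcodes must be unique")
            for name, bc in self.entries.items():
                if not bc or not set(bc) <= set("ACGT"):
                    raise ValidationError(
                        f"barcode for {name!r} must be non-empty A/C/G/T"
                    )

    @property
    def length(self) -> int:
        if not self.entries:
            raise ValidationError("empty barcode table")
        return len(next(iter(self.entries.values())))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        entries = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValidationError(
                        f"{path}: barcode table rows need 2 tab-separated columns"
                    )
                entries[fields[0]] = fields[1].upper()
        return cls(entries)


def _match_pairing(template: str, probe: str, start: int) -> int:
    """Base pairings of probe at template[start:]; -1 on mismatch.

    N in the template is a wildcard (it pairs with anything but
    contributes no specific base pairing); the returned count is the
    number of non-N matched positions.
    """
    paired = 0
    for offset, base in enumerate(probe):
        t = template[start + offset]
        if t == "N":
            continue
        if t != base:
            return -1
        paired += 1
    return paired


def _find_sites(template: str, probe: str, min_pairing: int) -> list[int]:
    """Sites where probe matches with at least min_pairing real pairings.

    The pairing floor keeps a primer from 'annealing' inside a random
    (all-N) insert, where nothing would hold it in place.
    """
    return [
        i
        for i in range(len(template) - len(probe) + 1)
        if _match_pairing(template, probe, i) >= min_pairing
    ]


def _anneal(template: str, primer: Primer, min_anneal: int, revcomp: bool) -> tuple[int, int]:
    """Longest annealing 3'-terminal suffix of the primer on the template.

    Returns (template start of the annealed region, suffix length).
    For a reverse primer (revcomp=True) the reverse complement of the
    suffix is matched against the top strand.
    """
    max_len = min(len(primer.seq), len(template))
    for length in range(max_len, min_anneal - 1, -1):
        suffix = primer.seq[-length:]
        probe = reverse_complement(suffix) if revcomp else suffix
        sites = _find_sites(template, probe, min_anneal)
        if len(sites) > 1:
            raise PCRError(
                f"primer {primer.name!r}: ambiguous annealing "
                f"({len(sites)} sites of length {length})"
            )
        if len(sites) == 1:
            return sites[0], length
    raise PCRError(
        f"primer {primer.name!r} does not anneal "
        f"(no exact 3'-suffix match of length >= {min_anneal})"
    )


def in_silico_pcr(template: str, fw: Primer, rv: Primer, min_anneal: int = 15) -> str:
    """Top strand of the PCR product of a template with two primers.

    The longest 3'-terminal suffix of the forward primer annealing
    exactly to the template (N wild) and the longest suffix of the
    reverse primer whose reverse complement anneals define the product
    span; primer 5' overhangs are appended on either side. Template N
    between the primer sites is preserved, so design checks run directly
    on the printed N-containing templates.
    """
    if min_anneal < 10:
        raise ValidationError("min_anneal must be >= 10")
    template = template.upper()
    if not set(template) <= set("ACGTN"):
        raise ValidationError("template must be over A/C/G/T/N")
    fw_start, fw_len = _anneal(template, fw, min_anneal, revcomp=False)
    rv_start, rv_len = _anneal(template, rv, min_anneal, revcomp=True)
    fw_end = fw_start + fw_len
    rv_end = rv_start + rv_len
    if fw_start > rv_start or fw_end > rv_end:
        raise PCRError(
            f"orientation error: forward site [{fw_start},{fw_end}) is not "
            f"5' of reverse site [{rv_start},{rv_end})"
        )
    middle = template[fw_end:rv_start] if rv_start >= fw_end else ""
    if rv_start < fw_end:
        raise PCRError("primer annealing sites overlap; product undefined")
    return fw.seq + middle + reverse_complement(rv.seq)


def extract_barcode(primer: Primer, five_flank: str, three_flank: str) -> str:
    """Barcode embedded in a primer between two stated constant flanks."""
    seq = primer.seq
    if not seq.startswith(five_flank) or not seq.endswith(three_flank):
        raise ValidationError(
            f"primer {primer.name!r} does not match the stated flank structure"
        )
    barcode = seq[len(five_flank) : len(seq) - len(three_flank)]
    if not barcode:
        raise ValidationError(f"primer {primer.name!r}: no barcode between flanks")
    return barcode


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValidationError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_set(table: BarcodeTable) -> dict:
    """Design report for a barcode set.

    Reports the minimum pairwise Hamming distance (a well-separated set
    has >= 2 so single sequencing errors cannot silently reassign a
    sample) and per-position base counts for the composition-homogeneity
    check. Composition is reported, not thresholded.
    """
    if len(table) < 2:
        raise ValidationError("barcode validation needs at least 2 entries")
    barcodes = list(table.entries.values())
    length = table.length
    min_dist = min(hamming(a, b) for a, b in combinations(barcodes, 2))
    counts = [
        {base: sum(bc[pos] == base for bc in barcodes) for base in "ACGT"}
        for pos in range(length)
    ]
    return {
        "n": len(barcodes),
        "length": length,
        "min_pairwise_hamming": min_dist,
        "per_position_base_counts": counts,
    }


def _read_barcode(read: Read, length: int, mode: str) -> str | None:
    if mode == "tag":
        return read.tags.get("BC")
    if len(read.seq) < length:
        return None
    return read.seq[-length:]


def demultiplex(
    reads: Iterable[Read],
    table: BarcodeTable,
    max_mismatch: int = 0,
    mode: str = "tag",
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Partition reads by sample barcode.

    The barcode is taken from the read's ``BC`` tag (mode="tag") or from
    its last L bases (mode="suffix"). A read is assigned iff exactly one
    barcode lies within max_mismatch; otherwise it is unassigned. With
    the default max_mismatch=0 and a minimum pairwise distance of 2,
    assignment is always unambiguous.
    """
    if max_mismatch not in (0, 1):
        raise ValidationError("max_mismatch must be 0 or 1")
    if mode not in ("tag", "suffix"):
        raise ValidationError("mode must be 'tag' or 'suffix'")
    length = table.length
    exact = {bc: name for name, bc in table.entries.items()}
    assigned: dict[str, list[Read]] = {name: [] for name in table.entries}
    unassigned: list[Read] = []
    for read in reads:
        observed = _read_barcode(read, length, mode)
        if observed is None or len(observed) != length:
            unassigned.append(read)
            continue
        if max_mismatch == 0:
            name = exact.get(observed)
            if name is None:
                unassigned.append(read)
            else:
                assigned[name].append(read)
            continue
        hits = [
            name
            for name, bc in table.entries.items()
            if sum(x != y for x, y in zip(observed, bc)) <= max_mismatch
        ]
        if len(hits) == 1:
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


def demultiplex_to_files(
    reads: Iterable[Read],
    table: BarcodeTable,
    out_dir: str | Path,
    max_mismatch: int = 0,
    mode: str = "tag",
    format: str = "fastq",
) -> dict[str, int]:
    """Demultiplex and write one file per sample plus unassigned."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "fastq" if format == "fastq" else "fasta"
    assigned, unassigned = demultiplex(reads, table, max_mismatch, mode)
    counts = {}
    for name, sample_reads in assigned.items():
        counts[name] = write_sequences(sample_reads, out_dir / f"{name}.{ext}", format)
    counts["unassigned"] = write_sequences(
        unassigned, out_dir / f"unassigned.{ext}", format
    )
    return counts


def load_primers(path: str | Path) -> list[Primer]:
    """Load primers from a 2-column TSV (name, sequence) or FASTA file."""
    path = Path(path)
    primers = []
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        with open(path) as handle:
            for header, seq in SimpleFastaParser(handle):
                primers.append(Primer(header.split()[0], seq.upper()))
    else:
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, seq = line.partition("\t")
                primers.append(Primer(name, seq.strip().upper()))
    return primers
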