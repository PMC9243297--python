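"""Sequence file and sample-sheet I/O.

FASTA/FASTQ parsing is delegated to Biopython's low-level iterators
(fast, no per-record object overhead); records are wrapped in the
lightweight :class:`Read` type that all downstream modules consume.
Gzip compression is handled transparently by file extension. Sample
metadata is a tab-separated sheet with the header
``Samplename  library  protein  cycle``; the protein value ``None``
marks the no-protein negative control.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from selexkit.errors import ParseError, ValidationError

#: protein value marking a no-protein negative control in sample sheets
NO_PROTEIN = "None"

_ALPHABET = set("ACGTN")
_REQUIRED_COLUMNS = ("samplename", "library", "protein", "cycle")


@dataclass(slots=True)
class Read:
    """A single sequencing read.

    qual holds per-base Phred scores (Phred+33 on disk) and must match
    the sequence length; FASTA reads carry no qualities. tags holds
    opaque key=value annotations from the header comment (for example
    the sample barcode written by the simulator).
    """

    id: str
    seq: str
    qual: list[int] | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValidationError(
                f"read {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class SampleMeta:
    """One row of the HT-SELEX sample sheet."""

    sample_name: str
    library: str
    protein: str
    cycle: int
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def is_control(self) -> bool:
        """True for the no-protein negative control."""
        return self.protein == NO_PROTEIN

    def __post_init__(self) -> None:
        if self.cycle < 0:
            raise ValidationError(
                f"sample {self.sample_name!r}: cycle must be >= 0, got {self.cycle}"
            )
        # normalize the control marker case-insensitively
        if self.protein.lower() == NO_PROTEIN.lower():
            self.protein = NO_PROTEIN


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _infer_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if not suffixes:
        raise ValidationError(f"cannot infer sequence format from {path.name!r}")
    ext = suffixes[-1]
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ValidationError(f"cannot infer sequence format from extension {ext!r}")


def _check_seq(seq: str, index: int, rec_id: str) -> str:
    seq = seq.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ParseError(
            f"record {index} ({rec_id!r}): invalid characters {bad} "
            "(alphabet is A/C/G/T/N)"
        )
    return seq


def _split_header(header: str) -> tuple[str, dict[str, str]]:
    parts = header.split()
    if not parts:
        return "", {}
    tags = {}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return parts[0], tags


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[Read]:
    """Stream reads from a FASTA/FASTQ file (optionally gzip-compressed).

    Yields reads in file order; FASTA reads have no qualities; sequences
    are uppercased and validated against the A/C/G/T/N alphabet.
    Malformed records raise :class:`ParseError` naming the record index.
    """
    path = Path(path)
    fmt = _infer_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ValidationError(f"unknown sequence format {fmt!r}")
    with _open_text(path) as handle:
        if fmt == "fasta":
            for index, (header, seq) in enumerate(SimpleFastaParser(handle)):
                rec_id, tags = _split_header(header)
                yield Read(rec_id, _check_seq(seq, index, rec_id), None, tags)
        else:
            iterator = FastqGeneralIterator(handle)
            index = 0
            while True:
                try:
                    header, seq, qual_str = next(iterator)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ParseError(f"record {index}: {exc}") from exc
                rec_id, tags = _split_header(header)
                if len(qual_str) != len(seq):
                    raise ParseError(
                        f"record {index} ({rec_id!r}): quality length "
                        f"{len(qual_str)} != sequence length {len(seq)}"
                    )
                qual = [ord(c) - 33 for c in qual_str]
                if qual and min(qual) < 0:
                    raise ParseError(
                        f"record {index} ({rec_id!r}): quality below Phred+33 range"
                    )
                yield Read(rec_id, _check_seq(seq, index, rec_id), qual, tags)
                index += 1


def _format_header(read: Read) -> str:
    if read.tags:
        return read.id + " " + " ".join(f"{k}={v}" for k, v in read.tags.items())
    return read.id


def write_sequences(reads: Iterable[Read], path: str | Path, format: str) -> int:
    """Write reads as 2-line FASTA or 4-line FASTQ records; returns the count.

    FASTQ requires qualities on every read (Phred+33 encoding).
    """
    if format not in ("fasta", "fastq"):
        raise ValidationError(f"unknown sequence format {format!r}")
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            if format == "fasta":
                handle.write(f">{_format_header(read)}\n{read.seq}\n")
            else:
                if read.qual is None:
                    raise ValidationError(
                        f"read {read.id!r}: FASTQ output requires qualities"
                    )
                qual_str = "".join(chr(q + 33) for q in read.qual)
                handle.write(f"@{_format_header(read)}\n{read.seq}\n+\n{qual_str}\n")
            n += 1
    return n


def parse_metadata(path: str | Path) -> list[SampleMeta]:
    """Parse the tab-separated HT-SELEX sample sheet.

    The header must contain the columns Samplename/library/protein/cycle
    (case-insensitive, any order); extra columns are preserved as opaque
    annotations. Rows with a non-integer or negative cycle, or duplicate
    sample names, raise :class:`ValidationError` naming the row.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty metadata sheet (missing header)") from exc
    colmap = {c.lower(): c for c in df.columns}
    missing = [c for c in _REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c.lower() not in _REQUIRED_COLUMNS]

    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        record = dict(zip(df.columns, row))
        name = record[colmap["samplename"]].strip()
        if not name:
            raise ValidationError(f"{path}: row {i}: empty sample name")
        if name in seen:
            raise ValidationError(f"{path}: row {i}: duplicate sample name {name!r}")
        seen.add(name)
        raw_cycle = record[colmap["cycle"]].strip()
        try:
            cycle = int(raw_cycle)
        except ValueError:
            raise ValidationError(
                f"{path}: row {i}: cycle must be an integer, got {raw_cycle!r}"
            ) from None
        try:
            meta = SampleMeta(
                sample_name=name,
                library=record[colmap["library"]].strip(),
                protein=record[colmap["protein"]].strip(),
                cycle=cycle,
                extra={c: record[c] for c in extra_cols},
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        samples.append(meta)
    return samples


def write_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    """Write a sample sheet in the canonical four-column layout."""
    with open(path, "w") as handle:
        handle.write("Samplename\tlibrary\tprotein\tcycle\n")
        for s in samples:
            handle.write(f"{s.sample_name}\t{s.library}\t{s.protein}\t{s.cycle}\n")
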