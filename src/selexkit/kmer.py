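"""Exhaustive k-mer quantification over the full 4^k alphabet.

Every sample is summarized by a :class:`KmerTable` holding, for each of
the 4^k k-mers, the total occurrence count over all reads and the
read-presence count (number of reads containing the k-mer at least
once). The per-read presence *fraction* (presence / n_reads) is the
abundance statistic used downstream: it is bounded in [0, 1] and robust
to within-read repeats. A per-position base-frequency matrix
(:class:`PositionalModel`) is produced alongside as a composition-bias
QC object, so one call yields the familiar counts / fractions / models
triple.

k-mers are 2-bit encoded (A=0, C=1, G=2, T=3, leftmost base most
significant) and counting is vectorized with numpy: all reads are
concatenated with ``N`` separators, so windows crossing read boundaries
or containing N are invalid and simply skipped. k is capped at 10
(4^10 ≈ 1.05 M k-mers); larger k is rejected as a capability error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from selexkit.errors import KmerLimitError, ValidationError
from selexkit.seqio import Read, read_sequences

MAX_K = 10

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def _check_k(k: int) -> None:
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise KmerLimitError(
            f"k={k} exceeds the supported maximum of {MAX_K}; exhaustive "
            f"quantification of 4^{k} k-mers is not supported"
        )


def encode_kmer(s: str) -> int:
    """2-bit code of a k-mer (A=0, C=1, G=2, T=3, leftmost most significant)."""
    code = 0
    for base in s:
        value = _CODE[ord(base)]
        if value < 0:
            raise ValidationError(f"k-mer {s!r} contains a non-A/C/G/T symbol")
        code = (code << 2) | int(value)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_k(k)
    if not 0 <= code < 4**k:
        raise ValidationError(f"code {code} out of range for k={k}")
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in encoding order."""
    _check_k(k)
    return [decode_kmer(c, k) for c in range(4**k)]


@lru_cache(maxsize=4)
def _revcomp_table(k: int) -> np.ndarray:
    """code -> code of the reverse complement, for all 4^k codes."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    for i in range(k):
        digit = (codes >> (2 * (k - 1 - i))) & 3
        rc |= (3 - digit) << (2 * i)
    return rc


@dataclass(slots=True)
class KmerTable:
    """Exhaustive per-sample k-mer abundance."""

    k: int
    occurrence: np.ndarray  # int64, length 4^k: total occurrences
    presence: np.ndarray  # int64, length 4^k: reads containing >= 1 occurrence
    n_reads: int
    n_windows: int  # valid (N-free, within-read) windows scanned
    canonical: bool = False

    def fractions(self) -> np.ndarray:
        return kmer_fractions(self)


def count_kmers(
    reads: Iterable[Read] | Sequence[str], k: int, canonical: bool = False
) -> KmerTable:
    """Count all 4^k k-mers over a read stream.

    Windows containing N are skipped and excluded from n_windows. With
    canonical=True each window is collapsed onto min(code, code of its
    reverse complement) before tallying, merging the two strands of the
    duplex ligand.
    """
    _check_k(k)
    seqs = [r.seq if isinstance(r, Read) else str(r) for r in reads]
    n_reads = len(seqs)
    size = 4**k
    if n_reads == 0:
        return KmerTable(
            k, np.zeros(size, np.int64), np.zeros(size, np.int64), 0, 0, canonical
        )
    # 'N' separators make windows spanning read boundaries invalid.
    cat = "N".join(seqs)
    arr = np.frombuffer(cat.encode("ascii"), dtype=np.uint8)
    codes4 = _CODE[arr].astype(np.int64)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n_reads)
    char_read = np.repeat(np.arange(n_reads, dtype=np.int64), lengths + 1)[: len(arr)]

    m = len(arr) - k + 1
    if m <= 0:
        return KmerTable(
            k, np.zeros(size, np.int64), np.zeros(size, np.int64), n_reads, 0, canonical
        )
    code = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        seg = codes4[j : j + m]
        ok &= seg >= 0
        code = (code << 2) | (seg & 3)
    valid = code[ok]
    read_ids = char_read[:m][ok]
    if canonical:
        valid = np.minimum(valid, _revcomp_table(k)[valid])
    occurrence = np.bincount(valid, minlength=size)
    # unique (read, k-mer) pairs give the presence counts
    pairs = np.unique(read_ids * size + valid)
    presence = np.bincount(pairs % size, minlength=size)
    return KmerTable(k, occurrence, presence, n_reads, int(ok.sum()), canonical)


def kmer_fractions(table: KmerTable) -> np.ndarray:
    """Per-read presence fraction for every k-mer: presence / n_reads."""
    if table.n_reads == 0:
        raise ValidationError("cannot compute fractions for an empty sample")
    return table.presence / table.n_reads


@dataclass(slots=True)
class PositionalModel:
    """Per-position base composition of uniform-length reads.

    base_freq[i, j] is the frequency of base j (A/C/G/T order) among the
    counted (non-N) bases at position i; rows with no counted base are
    flagged in empty_positions and left at zero.
    """

    length: int
    base_freq: np.ndarray  # (length, 4) float
    empty_positions: list[int]


def positional_model(reads: Iterable[Read] | Sequence[str]) -> PositionalModel:
    """Column-wise base frequencies; requires uniform read length."""
    seqs = [r.seq if isinstance(r, Read) else str(r) for r in reads]
    if not seqs:
        raise ValidationError("cannot build a positional model from zero reads")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValidationError(
            "positional model requires uniform read length; trim reads first"
        )
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), length
    )
    codes = _CODE[arr].astype(np.int64)
    freq = np.zeros((length, 4), dtype=float)
    empty = []
    for pos in range(length):
        col = codes[:, pos]
        counts = np.bincount(col[col >= 0], minlength=4).astype(float)
        total = counts.sum()
        if total == 0:
            empty.append(pos)
        else:
            freq[pos] = counts / total
    return PositionalModel(length, freq, empty)


def top_kmers(fractions: np.ndarray, m: int, k: int | None = None) -> list[tuple[str, float]]:
    """Top-m k-mers by fraction, ties broken by ascending encoded integer."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    fractions = np.asarray(fractions)
    if k is None:
        k = round(np.log2(len(fractions)) / 2)
    if 4**k != len(fractions):
        raise ValidationError("fraction vector length is not a power of 4")
    order = np.argsort(-fractions, kind="stable")[:m]
    return [(decode_kmer(int(c), k), float(fractions[c])) for c in order]


def quantify(
    reads: Iterable[Read] | Sequence[str], k: int, canonical: bool = False
) -> tuple[KmerTable, np.ndarray, PositionalModel]:
    """Counts / fractions / positional-model triple for one sample."""
    seqs = [r.seq if isinstance(r, Read) else str(r) for r in reads]
    table = count_kmers(seqs, k, canonical)
    return table, kmer_fractions(table), positional_model(seqs)


def quantify_file(
    path: str | Path, k: int, canonical: bool = False
) -> tuple[KmerTable, np.ndarray, PositionalModel]:
    """:func:`quantify` on a FASTA/FASTQ(.gz) file of trimmed reads."""
    return quantify(list(read_sequences(path)), k, canonical)


def write_kmer_table(table: KmerTable, path: str | Path, comment: str = "") -> None:
    """Write a per-sample TSV: kmer, occurrence, presence, fraction."""
    fractions = kmer_fractions(table)
    with open(path, "w") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        handle.write("kmer\toccurrence\tpresence\tfraction\n")
        for code in range(4**table.k):
            handle.write(
                f"{decode_kmer(code, table.k)}\t{table.occurrence[code]}\t"
                f"{table.presence[code]}\t{fractions[code]:.8g}\n"
            )
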