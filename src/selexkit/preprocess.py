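"""Read pre-processing: quality trimming and hard trim to the insert size.

Reproduces the fixed trimming recipe used for HT-SELEX reads: trim the
low-quality 3' tail (TAIL semantics — the insert sits at the 5' end, so
only 3' trimming is safe), optionally clip a known constant 5' prefix,
keep the first ``post_trim_length`` bases, and drop reads shorter than
``min_read_length``. With the defaults (threshold 30, both lengths
20 bp) every surviving read is exactly the 20 bp random insert.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from selexkit.errors import ValidationError
from selexkit.seqio import Read, read_sequences, write_sequences


@dataclass(frozen=True, slots=True)
class TrimConfig:
    """Trimming parameters (defaults match the 20 bp-insert workflow)."""

    qtrim_threshold: int = 30
    post_trim_length: int = 20
    min_read_length: int = 20
    prefix_clip: str | None = None

    def __post_init__(self) -> None:
        if self.min_read_length < 1:
            raise ValidationError("min_read_length must be >= 1")
        if self.post_trim_length < self.min_read_length:
            raise ValidationError("post_trim_length must be >= min_read_length")
        if self.qtrim_threshold < 0:
            raise ValidationError("qtrim_threshold must be >= 0")


def quality_trim_tail(read: Read, threshold: int) -> Read:
    """Remove the maximal 3' run of bases with quality < threshold.

    No-op for quality-less (FASTA) reads; the 5' end is never touched.
    """
    if read.qual is None:
        return read
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < threshold:
        end -= 1
    if end == len(read.qual):
        return read
    return Read(read.id, read.seq[:end], read.qual[:end], dict(read.tags))


def trim_to_insert(read: Read, cfg: TrimConfig) -> Read | None:
    """Trim one read to the insert; returns None if it fails the length filter.

    Order of operations: optional exact 5'-prefix clip, 3' quality trim,
    hard trim keeping the 5'-most ``post_trim_length`` bases, then the
    ``min_read_length`` filter.
    """
    if cfg.prefix_clip and read.seq.startswith(cfg.prefix_clip):
        n = len(cfg.prefix_clip)
        read = Read(
            read.id,
            read.seq[n:],
            read.qual[n:] if read.qual is not None else None,
            dict(read.tags),
        )
    read = quality_trim_tail(read, cfg.qtrim_threshold)
    if len(read.seq) > cfg.post_trim_length:
        read = Read(
            read.id,
            read.seq[: cfg.post_trim_length],
            read.qual[: cfg.post_trim_length] if read.qual is not None else None,
            dict(read.tags),
        )
    if len(read.seq) < cfg.min_read_length:
        return None
    return read


def trim_reads(reads: Iterable[Read], cfg: TrimConfig) -> Iterator[Read]:
    """Lazy trim of a read stream, dropping rejected reads."""
    for read in reads:
        trimmed = trim_to_insert(read, cfg)
        if trimmed is not None:
            yield trimmed


def preprocess_file(
    in_path: str | Path,
    out_path: str | Path,
    cfg: TrimConfig | None = None,
    out_format: str = "fasta",
) -> dict[str, int]:
    """Trim a FASTA/FASTQ file; write survivors; return the count summary.

    The default output is FASTA (qualities dropped after trimming, as in
    the downstream k-mer counting workflow); the summary satisfies
    input == passed + rejected.
    """
    cfg = cfg or TrimConfig()
    counts = {"input": 0, "passed": 0, "rejected": 0}

    def survivors() -> Iterator[Read]:
        for read in read_sequences(in_path):
            counts["input"] += 1
            trimmed = trim_to_insert(read, cfg)
            if trimmed is None:
                counts["rejected"] += 1
                continue
            if out_format == "fasta" and trimmed.qual is not None:
                trimmed = Read(trimmed.id, trimmed.seq, None, dict(trimmed.tags))
            counts["passed"] += 1
            yield trimmed

    write_sequences(survivors(), out_path, out_format)
    return counts
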