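"""Sequencing-depth sufficiency by sub-sampling rank concordance.

To decide how deep an HT-SELEX sample must be sequenced, the full-depth
read set is sub-sampled (without replacement, simulating a shallower
run of the same pool), k-mer presence fractions are recomputed at each
depth, and the squared Spearman rank correlation against the full-depth
fractions is reported per (depth, k). Short k-mers (5-6 bp) keep high
concordance down to ~10,000 reads; long k-mers (up to 10 bp) need far
deeper sequencing because the 4^k table outgrows the window count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from selexkit.errors import CoverageError
from selexkit.kmer import count_kmers, kmer_fractions, top_kmers
from selexkit.seqio import Read


def subsample_reads(reads: Sequence[Read], depth: int, seed: int) -> list[Read]:
    """Uniform sample of `depth` reads without replacement, input order kept."""
    if depth > len(reads):
        raise CoverageError(
            f"requested depth {depth} exceeds available reads ({len(reads)})"
        )
    if depth < 1:
        raise CoverageError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(len(reads), size=depth, replace=False))
    return [reads[i] for i in indices]


def spearman_r2(x: np.ndarray, y: np.ndarray, squared: bool = True) -> float:
    """Squared Spearman rank correlation (average ranks for ties).

    Squaring discards the sign; pass squared=False to inspect raw rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise CoverageError("inputs must be equal-length 1-D vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CoverageError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho**2) if squared else float(rho)


@dataclass(slots=True)
class CoverageReport:
    """Rank-concordance matrix across sub-sampling depths and k values."""

    depths: list[int]
    k_values: list[int]
    r2: np.ndarray  # (len(depths), len(k_values)) in [0, 1]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.r2,
            index=pd.Index(self.depths, name="depth"),
            columns=pd.Index(self.k_values, name="k"),
        )
        return frame

    def write_tsv(self, path: str | Path, comment: str = "") -> None:
        with open(path, "w") as handle:
            if comment:
                handle.write(f"# {comment}\n")
            handle.write(f"# seed={self.seed}\n")
            self.to_frame().to_csv(handle, sep="\t")


def coverage_analysis(
    reads: Sequence[Read],
    depths: Sequence[int],
    k_values: Sequence[int],
    seed: int,
) -> CoverageReport:
    """Sub-sample at each depth and correlate k-mer fractions with full depth.

    Each depth uses its own deterministic sub-stream derived from the
    seed, so the report is reproducible bit-for-bit.
    """
    reads = list(reads)
    if not reads:
        raise CoverageError("no reads supplied")
    if any(d > len(reads) or d < 1 for d in depths):
        raise CoverageError("all depths must lie in [1, number of reads]")
    full = {
        k: kmer_fractions(count_kmers(reads, k)) for k in k_values
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(len(depths))
    r2 = np.zeros((len(depths), len(k_values)))
    for i, depth in enumerate(depths):
        if depth == len(reads):
            # no sampling: the vectors are identical, concordance is exact
            r2[i, :] = 1.0
            continue
        sub = subsample_reads(reads, depth, int(child_seeds[i] % 2**31))
        for j, k in enumerate(k_values):
            sub_frac = kmer_fractions(count_kmers(sub, k))
            r2[i, j] = spearman_r2(sub_frac, full[k])
    return CoverageReport(list(depths), list(k_values), r2, seed)


def top_overlap(x: np.ndarray, y: np.ndarray, m: int) -> float:
    """Fraction of the top-m k-mers shared between two abundance vectors.

    Uses the deterministic ranking of :func:`selexkit.kmer.top_kmers`
    (fraction descending, ties by ascending code).
    """
    top_x = {kmer for kmer, _ in top_kmers(np.asarray(x), m)}
    top_y = {kmer for kmer, _ in top_kmers(np.asarray(y), m)}
    return len(top_x & top_y) / m
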