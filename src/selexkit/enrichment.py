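"""Cycle-0-normalized enrichment and the A/T-content category summary.

Enrichment of a k-mer w in a selected sample s against its cycle-0
reference r is the pseudocounted ratio of presence fractions

    FC(w) = ((p_s(w) + a) / (n_s + a)) / ((p_r(w) + a) / (n_r + a))

with a Laplace-style pseudocount a (default 1) so k-mers absent from
either sample yield finite, symmetric fold changes. Each selected
sample is normalized by default to the cycle-0 sample of its own
replicate library (each starting library has a slightly different
sequence distribution); no-protein negative controls are carried
through as their own rows, compared side by side and never subtracted.
The A/T summary groups the 4^k k-mers into k+1 categories by their
number of A/T letters (six categories at k=5) and reports, per
(protein, cycle, category), the mean fold change with the standard
deviation across replicate libraries as the technical-variability bar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from selexkit.errors import ValidationError
from selexkit.kmer import KmerTable, all_kmers, kmer_fractions
from selexkit.seqio import SampleMeta

_AT = set("AT")


def at_category(kmer: str) -> int:
    """Number of A/T letters in a k-mer (0..k)."""
    if not set(kmer) <= set("ACGT"):
        raise ValidationError(f"k-mer {kmer!r} must be over A/C/G/T")
    return sum(base in _AT for base in kmer)


@lru_cache(maxsize=4)
def _at_categories(k: int) -> np.ndarray:
    """A/T category of every k-mer in encoding order (A=0, T=3 are A/T)."""
    codes = np.arange(4**k, dtype=np.int64)
    cats = np.zeros(4**k, dtype=np.int64)
    for i in range(k):
        digit = (codes >> (2 * i)) & 3
        cats += (digit == 0) | (digit == 3)
    return cats


@dataclass(frozen=True, slots=True)
class EnrichmentConfig:
    """Zero-handling and reference-pairing policy."""

    pseudocount: float = 1.0
    pairing: str = "matched_library"  # or "pooled_cycle0"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.pairing not in ("matched_library", "pooled_cycle0"):
            raise ValidationError(f"unknown pairing {self.pairing!r}")


@dataclass(slots=True)
class EnrichmentTable:
    """Long-format per-(k-mer, sample) enrichment records.

    data columns: kmer, sample, protein, cycle, library, fraction,
    fold_change, at_category, reference_sample.
    """

    k: int
    data: pd.DataFrame


def fold_change(
    sample: KmerTable, reference: KmerTable, cfg: EnrichmentConfig | None = None
) -> np.ndarray:
    """Pseudocounted presence-fraction fold change for every k-mer."""
    cfg = cfg or EnrichmentConfig()
    if sample.k != reference.k:
        raise ValidationError(
            f"k mismatch: sample k={sample.k}, reference k={reference.k}"
        )
    if sample.canonical != reference.canonical:
        raise ValidationError("sample and reference differ in canonical collapsing")
    a = cfg.pseudocount
    if a == 0 and (reference.presence == 0).any():
        raise ValidationError(
            "pseudocount 0 with zero reference presence counts; set "
            "pseudocount > 0 to obtain finite fold changes"
        )
    num = (sample.presence + a) / (sample.n_reads + a)
    den = (reference.presence + a) / (reference.n_reads + a)
    return num / den


def _pool_cycle0(tables: Sequence[KmerTable]) -> KmerTable:
    k = tables[0].k
    canonical = tables[0].canonical
    return KmerTable(
        k,
        sum(t.occurrence for t in tables),
        sum(t.presence for t in tables),
        sum(t.n_reads for t in tables),
        sum(t.n_windows for t in tables),
        canonical,
    )


def enrich_dataset(
    tables: Mapping[str, KmerTable],
    meta: Sequence[SampleMeta],
    cfg: EnrichmentConfig | None = None,
) -> EnrichmentTable:
    """Fold changes vs cycle 0 for every selected and control sample.

    Under matched_library pairing each cycle > 0 sample is referenced to
    the cycle-0 sample of the same replicate library; a missing
    reference is an error naming the orphan sample. Cycle-0 samples
    define the references and do not appear as enriched rows.
    """
    cfg = cfg or EnrichmentConfig()
    meta_by_name = {m.sample_name: m for m in meta}
    for name in tables:
        if name not in meta_by_name:
            raise ValidationError(f"sample {name!r} has counts but no metadata row")

    cycle0 = [m for m in meta if m.cycle == 0 and m.sample_name in tables]
    refs_by_library = {m.library: m.sample_name for m in cycle0}
    pooled = (
        _pool_cycle0([tables[m.sample_name] for m in cycle0]) if cycle0 else None
    )

    frames = []
    k = next(iter(tables.values())).k if tables else 0
    kmers = all_kmers(k) if tables else []
    cats = _at_categories(k) if tables else None
    for m in meta:
        if m.cycle == 0 or m.sample_name not in tables:
            continue
        if cfg.pairing == "matched_library":
            ref_name = refs_by_library.get(m.library)
            if ref_name is None:
                raise ValidationError(
                    f"sample {m.sample_name!r} (library {m.library!r}) has no "
                    "cycle-0 reference under matched_library pairing"
                )
            reference = tables[ref_name]
        else:
            if pooled is None:
                raise ValidationError(
                    f"sample {m.sample_name!r}: no cycle-0 samples to pool"
                )
            ref_name = "pooled_cycle0"
            reference = pooled
        table = tables[m.sample_name]
        frames.append(
            pd.DataFrame(
                {
                    "kmer": kmers,
                    "sample": m.sample_name,
                    "protein": m.protein,
                    "cycle": m.cycle,
                    "library": m.library,
                    "fraction": kmer_fractions(table),
                    "fold_change": fold_change(table, reference, cfg),
                    "at_category": cats,
                    "reference_sample": ref_name,
                }
            )
        )
    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(
            columns=[
                "kmer",
                "sample",
                "protein",
                "cycle",
                "library",
                "fraction",
                "fold_change",
                "at_category",
                "reference_sample",
            ]
        )
    return EnrichmentTable(k, data)


def summarize_by_category(table: EnrichmentTable) -> pd.DataFrame:
    """Per-(protein, cycle, A/T category) fold-change summary.

    For each replicate library the fold change is first averaged over
    the k-mers of the category; the reported value is the mean of these
    per-replicate means and the dispersion is their standard deviation
    (ddof=1; reported as 0 with a warning when only one replicate is
    present).
    """
    df = table.data
    if df.empty:
        return pd.DataFrame(
            columns=[
                "protein",
                "cycle",
                "at_category",
                "mean_fold_change",
                "sd_fold_change",
                "n_libraries",
                "n_kmers",
            ]
        )
    per_replicate = (
        df.groupby(["protein", "cycle", "at_category", "library"], sort=True)
        .agg(mean_fc=("fold_change", "mean"), n_kmers=("kmer", "size"))
        .reset_index()
    )
    rows = []
    single_replicate = False
    for (protein, cycle, cat), group in per_replicate.groupby(
        ["protein", "cycle", "at_category"], sort=True
    ):
        values = group["mean_fc"].to_numpy()
        if len(values) == 1:
            single_replicate = True
            sd = 0.0
        else:
            sd = float(np.std(values, ddof=1))
        rows.append(
            {
                "protein": protein,
                "cycle": cycle,
                "at_category": cat,
                "mean_fold_change": float(values.mean()),
                "sd_fold_change": sd,
                "n_libraries": len(values),
                "n_kmers": int(group["n_kmers"].iloc[0]),
            }
        )
    if single_replicate:
        warnings.warn(
            "single replicate library in at least one group; dispersion "
            "reported as 0",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def write_enrichment(
    table: EnrichmentTable, path: str | Path, comment: str = ""
) -> None:
    """Write the long-format enrichment TSV."""
    with open(path, "w") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        table.data.to_csv(handle, sep="\t", index=False)
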