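"""Seeded multi-cycle HT-SELEX simulator.

Generates the full experimental design this toolkit analyses: replicate
random libraries (cycle 0), iterative selection rounds for a
DNA-binding protein, matched no-protein negative controls, and
sequencing output in the library construct layout (read = 20 bp random
insert followed by the constant 3' flank, constant quality 40, an 8 bp
sample barcode attached as a tag).

Selection is a single-site occupancy model: a read carrying windows w
is retained with probability

    p = b + (1 - b) * s * max_w affinity(w)

where b is the wash-resistant background capture the negative control
measures, s the overall selection strength, and affinity in (0, 1]
comes from either a consensus model (lambda ** HammingDistance to a
consensus motif) or an A/T-content model ((n_AT / k) ** gamma, floored
at a small epsilon so all-G/C windows stay selectable). PCR
amplification between rounds is uniform resampling with replacement
back to the per-sample read count. All randomness flows from one seed
through spawned, per-replicate sub-streams, so identical configurations
reproduce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from selexkit.construct import BarcodeTable, LibraryConstruct
from selexkit.errors import SimulationError, ValidationError
from selexkit.seqio import NO_PROTEIN, Read, SampleMeta, write_metadata, write_sequences

AFFINITY_FLOOR = 1e-6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode_seq(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValidationError(f"sequence {seq!r} must be over A/C/G/T")
    return codes.astype(np.uint8)


def _decode_rows(codes: np.ndarray) -> list[str]:
    chars = _BASES[codes]
    return [row.tobytes().decode("ascii") for row in chars]


@dataclass(frozen=True, slots=True)
class AffinityModel:
    """Window affinity of the simulated protein, in (0, 1].

    kind="consensus": affinity = mismatch_factor ** HammingDistance(w,
    consensus), a specific binder with exponentially penalized
    mismatches. kind="at_content": affinity = (n_AT(w)/window)**
    at_exponent, a promiscuous A/T-rich binder. Both are floored at
    AFFINITY_FLOOR.
    """

    kind: str = "at_content"
    consensus: str = ""
    mismatch_factor: float = 0.1
    at_exponent: float = 1.0
    window: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("consensus", "at_content"):
            raise ValidationError(f"unknown affinity kind {self.kind!r}")
        if self.kind == "consensus":
            if not self.consensus:
                raise ValidationError("consensus model requires a consensus motif")
            if not 0 < self.mismatch_factor < 1:
                raise ValidationError("mismatch_factor must lie in (0, 1)")
            object.__setattr__(self, "window", len(self.consensus))
        else:
            if self.at_exponent <= 0:
                raise ValidationError("at_exponent must be positive")
            if self.window < 1:
                raise ValidationError("window must be >= 1")

    def read_affinity(self, pool: np.ndarray) -> np.ndarray:
        """Max window affinity per read for a (n_reads, L) code matrix."""
        n, length = pool.shape
        w = self.window
        if length < w:
            raise ValidationError(
                f"insert length {length} shorter than affinity window {w}"
            )
        if self.kind == "consensus":
            motif = _encode_seq(self.consensus)
            min_dist = np.full(n, w, dtype=np.int64)
            for start in range(length - w + 1):
                dist = (pool[:, start : start + w] != motif).sum(axis=1)
                np.minimum(min_dist, dist, out=min_dist)
            affinity = self.mismatch_factor ** min_dist.astype(float)
        else:
            at = (pool == 0) | (pool == 3)  # A or T
            window_sums = np.lib.stride_tricks.sliding_window_view(
                at, w, axis=1
            ).sum(axis=2)
            max_at = window_sums.max(axis=1)
            affinity = (max_at / w) ** self.at_exponent
        return np.maximum(affinity, AFFINITY_FLOOR)


def _default_construct() -> LibraryConstruct:
    from selexkit.oligos import RANDOM_LIBRARY_CONSTRUCT

    return RANDOM_LIBRARY_CONSTRUCT


def _default_barcodes() -> BarcodeTable:
    from selexkit.oligos import seqlib_barcode_table

    return seqlib_barcode_table()


@dataclass(slots=True)
class SimulationConfig:
    """Full parameterization of a multi-cycle SELEX simulation.

    Defaults reproduce the study design the toolkit targets: 20 bp
    inserts, 3 replicate libraries, 6 selection cycles with cycles
    0/1/3/6 sequenced (21 samples), 20,000 reads per sample (the
    recommended 10,000-50,000 depth band), an A/T-content affinity
    model, and the printed construct and 21-barcode table.
    """

    insert_length: int = 20
    n_cycles: int = 6
    emit_cycles: tuple[int, ...] = (0, 1, 3, 6)
    reads_per_sample: int = 20_000
    n_replicates: int = 3
    selection_strength: float = 0.5
    background_capture: float = 0.05
    affinity: AffinityModel = field(default_factory=AffinityModel)
    sequencing_error_rate: float = 0.001
    read_length: int = 40
    protein_name: str = "ZFC4"
    construct: LibraryConstruct = field(default_factory=_default_construct)
    barcode_table: BarcodeTable = field(default_factory=_default_barcodes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_length < 1 or self.reads_per_sample < 1:
            raise ValidationError("insert_length and reads_per_sample must be >= 1")
        if self.n_cycles < 0:
            raise ValidationError("n_cycles must be >= 0")
        if not all(0 <= c <= self.n_cycles for c in self.emit_cycles):
            raise ValidationError("emit_cycles must lie in [0, n_cycles]")
        if not 0 <= self.selection_strength <= 1:
            raise ValidationError("selection_strength must lie in [0, 1]")
        if not 0 <= self.background_capture <= 1:
            raise ValidationError("background_capture must lie in [0, 1]")
        if not 0 <= self.sequencing_error_rate < 1:
            raise ValidationError("sequencing_error_rate must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.read_length < self.insert_length:
            raise ValidationError("read_length must cover the insert")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "affinity" in raw:
            raw["affinity"] = AffinityModel(**raw["affinity"])
        if "emit_cycles" in raw:
            raw["emit_cycles"] = tuple(raw["emit_cycles"])
        if "construct" in raw:
            raw["construct"] = LibraryConstruct(**raw["construct"])
        if "barcode_table" in raw:
            raw["barcode_table"] = BarcodeTable(dict(raw["barcode_table"]))
        return cls(**raw)

    def describe(self) -> dict:
        desc = asdict(self)
        desc["construct"] = asdict(self.construct)
        desc["barcode_table"] = dict(self.barcode_table.entries)
        desc["affinity"] = asdict(self.affinity)
        desc["emit_cycles"] = list(self.emit_cycles)
        desc["retention_model"] = (
            "p = b + (1-b) * s * max_window_affinity; PCR = uniform "
            "resampling with replacement"
        )
        return desc


def simulate_cycle0(cfg: SimulationConfig) -> list[np.ndarray]:
    """Independent uniform-random insert pools, one per replicate library.

    Each replicate draws from its own spawned sub-stream, so pools are
    distinct but individually reproducible from the master seed.
    """
    pools = []
    for rep_ss in np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates):
        rng = np.random.default_rng(rep_ss)
        pools.append(
            rng.integers(
                0, 4, size=(cfg.reads_per_sample, cfg.insert_length), dtype=np.uint8
            )
        )
    return pools


def select_round(
    pool: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    selective: bool = True,
) -> np.ndarray:
    """One bind-wash-amplify round; returns a pool of the original size.

    selective=False models the no-protein control: retention is the
    affinity-blind background capture b alone, followed by the same
    amplification resampling.
    """
    if pool.shape[0] == 0:
        raise SimulationError("empty input pool")
    b = cfg.background_capture
    s = cfg.selection_strength
    if selective and s > 0:
        affinity = cfg.affinity.read_affinity(pool)
        p = b + (1.0 - b) * s * affinity
    else:
        p = np.full(pool.shape[0], b)
    keep = rng.random(pool.shape[0]) < p
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise SimulationError(
            "no reads retained in this round; increase background_capture "
            "(b > 0 guarantees a wash-resistant floor)"
        )
    amplified = rng.choice(kept, size=cfg.reads_per_sample, replace=True)
    return pool[amplified]


def _assemble_reads(
    pool: np.ndarray,
    cfg: SimulationConfig,
    sample_name: str,
    barcode: str,
    rng: np.random.Generator,
) -> list[Read]:
    """Insert + 3' constant flank, truncated to read_length, with errors."""
    n, insert_len = pool.shape
    flank = _encode_seq(cfg.construct.three_prime_flank)
    tail_len = min(len(flank), cfg.read_length - insert_len)
    reads_codes = np.concatenate(
        [pool, np.tile(flank[:tail_len], (n, 1))], axis=1
    )
    if cfg.sequencing_error_rate > 0:
        errors = rng.random(reads_codes.shape) < cfg.sequencing_error_rate
        shifts = rng.integers(1, 4, size=reads_codes.shape, dtype=np.uint8)
        reads_codes = np.where(
            errors, (reads_codes + shifts) % 4, reads_codes
        ).astype(np.uint8)
    qual = [40] * reads_codes.shape[1]
    return [
        Read(f"{sample_name}.{i}", seq, list(qual), {"BC": barcode})
        for i, seq in enumerate(_decode_rows(reads_codes))
    ]


def simulate_samples(
    cfg: SimulationConfig,
) -> Iterator[tuple[SampleMeta, list[Read]]]:
    """Yield (metadata, reads) for every sample of the simulated design.

    Samples follow the study listing order: all cycle-0 libraries, then
    for each later sequenced cycle the protein replicates followed by
    the no-protein control replicates. Sample names and barcodes are
    taken from the barcode table in order.
    """
    names = list(cfg.barcode_table.entries)
    order: list[tuple[int, int, bool]] = []  # (cycle, replicate, is_protein)
    emit = sorted(set(cfg.emit_cycles))
    if 0 in emit:
        order.extend((0, rep, False) for rep in range(cfg.n_replicates))
    for cycle in emit:
        if cycle == 0:
            continue
        order.extend((cycle, rep, True) for rep in range(cfg.n_replicates))
        order.extend((cycle, rep, False) for rep in range(cfg.n_replicates))
    if len(order) > len(names):
        raise SimulationError(
            f"design needs {len(order)} samples but the barcode table has "
            f"only {len(names)}"
        )

    # evolve all lineages first, snapshotting emitted cycles
    root = np.random.SeedSequence(cfg.seed)
    rep_seeds = root.spawn(cfg.n_replicates)
    snapshots: dict[tuple[int, int, bool], np.ndarray] = {}
    error_rngs: list[np.random.Generator] = []
    for rep in range(cfg.n_replicates):
        gen0_ss, protein_ss, control_ss, error_ss = rep_seeds[rep].spawn(4)
        rng0 = np.random.default_rng(gen0_ss)
        pool0 = rng0.integers(
            0, 4, size=(cfg.reads_per_sample, cfg.insert_length), dtype=np.uint8
        )
        error_rngs.append(np.random.default_rng(error_ss))
        protein_rng = np.random.default_rng(protein_ss)
        control_rng = np.random.default_rng(control_ss)
        snapshots[(0, rep, False)] = pool0
        protein_pool = pool0
        control_pool = pool0
        for cycle in range(1, cfg.n_cycles + 1):
            protein_pool = select_round(protein_pool, cfg, protein_rng, selective=True)
            control_pool = select_round(control_pool, cfg, control_rng, selective=False)
            if cycle in emit:
                snapshots[(cycle, rep, True)] = protein_pool
                snapshots[(cycle, rep, False)] = control_pool

    for index, (cycle, rep, is_protein) in enumerate(order):
        name = names[index]
        barcode = cfg.barcode_table.entries[name]
        protein = cfg.protein_name if is_protein else NO_PROTEIN
        meta = SampleMeta(
            sample_name=name,
            library=f"lib{rep + 1}",
            protein=protein,
            cycle=cycle,
        )
        reads = _assemble_reads(
            snapshots[(cycle, rep, is_protein)], cfg, name, barcode, error_rngs[rep]
        )
        yield meta, reads


def simulate_dataset(
    cfg: SimulationConfig, out_dir: str | Path, gzip_output: bool = False
) -> dict:
    """Write the simulated dataset: per-sample FASTQ, sample sheet, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "fastq.gz" if gzip_output else "fastq"
    metas = []
    n_reads = {}
    for meta, reads in simulate_samples(cfg):
        metas.append(meta)
        n_reads[meta.sample_name] = write_sequences(
            reads, out_dir / f"{meta.sample_name}.{ext}", "fastq"
        )
    write_metadata(metas, out_dir / "samples.tsv")
    manifest = {
        "tool": "selexkit simulate",
        "seed": cfg.seed,
        "n_samples": len(metas),
        "reads_per_sample": cfg.reads_per_sample,
        "config": cfg.describe(),
    }
    with open(out_dir / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=False)
    return manifest
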