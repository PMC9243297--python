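"""Multi-cycle SELEX simulator: design layout, selection, reproducibility."""

from __future__ import annotations

import numpy as np
import pytest

from selexkit.enrichment import enrich_dataset
from selexkit.errors import SimulationError, ValidationError
from selexkit.kmer import count_kmers, encode_kmer, kmer_fractions
from selexkit.preprocess import TrimConfig, trim_reads
from selexkit.seqio import NO_PROTEIN, parse_metadata, read_sequences
from selexkit.simulate import (
    AFFINITY_FLOOR,
    AffinityModel,
    SimulationConfig,
    select_round,
    simulate_cycle0,
    simulate_dataset,
    simulate_samples,
)


def small_cfg(**kwargs) -> SimulationConfig:
    defaults = dict(
        n_cycles=1,
        emit_cycles=(0, 1),
        reads_per_sample=2000,
        n_replicates=2,
        sequencing_error_rate=0.0,
        seed=42,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestAffinityModel:
    def test_consensus_affinity_is_lambda_to_the_distance(self):
        model = AffinityModel(kind="consensus", consensus="TATTA", mismatch_factor=0.1)
        pool = np.array(
            [
                [3, 0, 3, 3, 0],  # TATTA: distance 0
                [3, 0, 3, 3, 3],  # TATTT: distance 1
                [2, 2, 2, 2, 2],  # GGGGG: distance 5
            ],
            dtype=np.uint8,
        )
        affinity = model.read_affinity(pool)
        assert affinity[0] == pytest.approx(1.0)
        assert affinity[1] == pytest.approx(0.1)
        assert affinity[2] == pytest.approx(max(0.1**5, AFFINITY_FLOOR))

    def test_consensus_uses_best_window(self):
        model = AffinityModel(kind="consensus", consensus="TAT", mismatch_factor=0.2)
        # GGTATG contains TAT at offset 2
        pool = np.array([[2, 2, 3, 0, 3, 2]], dtype=np.uint8)
        assert model.read_affinity(pool)[0] == pytest.approx(1.0)

    def test_at_content_affinity(self):
        model = AffinityModel(kind="at_content", at_exponent=2.0, window=4)
        pool = np.array(
            [
                [0, 3, 0, 3],  # ATAT: (4/4)^2 = 1
                [0, 1, 2, 3],  # ACGT: best window is the whole read, 2/4
                [1, 2, 1, 2],  # CGCG: floored
            ],
            dtype=np.uint8,
        )
        affinity = model.read_affinity(pool)
        assert affinity[0] == pytest.approx(1.0)
        assert affinity[1] == pytest.approx(0.25)
        assert affinity[2] == pytest.approx(AFFINITY_FLOOR)

    def test_affinity_bounded_in_unit_interval(self, rng):
        pool = rng.integers(0, 4, (500, 20), dtype=np.uint8)
        for model in (
            AffinityModel(kind="consensus", consensus="TATTA"),
            AffinityModel(kind="at_content", at_exponent=1.0, window=5),
        ):
            affinity = model.read_affinity(pool)
            assert np.all((affinity > 0) & (affinity <= 1.0))

    def test_invalid_models_rejected(self):
        with pytest.raises(ValidationError):
            AffinityModel(kind="consensus", consensus="")
        with pytest.raises(ValidationError):
            AffinityModel(kind="at_content", at_exponent=0)
        with pytest.raises(ValidationError):
            AffinityModel(kind="magic")


class TestCycle0:
    def test_insert_dimensions(self):
        pools = simulate_cycle0(small_cfg())
        assert len(pools) == 2
        assert all(p.shape == (2000, 20) for p in pools)

    def test_replicates_differ_but_reproduce(self):
        a = simulate_cycle0(small_cfg())
        b = simulate_cycle0(small_cfg())
        assert not np.array_equal(a[0], a[1])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_base_frequencies_uniform_within_3_sigma(self):
        cfg = small_cfg(reads_per_sample=10000)
        pool = simulate_cycle0(cfg)[0]
        freq = np.array([(pool == b).mean(axis=0) for b in range(4)])
        sigma = np.sqrt(0.25 * 0.75 / 10000)
        assert np.all(np.abs(freq - 0.25) < 3.5 * sigma)


class TestSelectRound:
    def test_null_selection_is_affinity_blind(self):
        cfg = small_cfg(selection_strength=0.0, background_capture=0.1,
                        reads_per_sample=20000)
        pool = simulate_cycle0(cfg)[0]
        rng = np.random.default_rng(1)
        out = select_round(pool, cfg, rng)
        # post-amplification base composition within sampling noise of input
        for b in range(4):
            assert abs((out == b).mean() - (pool == b).mean()) < 0.01

    def test_output_size_restored_by_amplification(self):
        cfg = small_cfg(background_capture=0.05)
        pool = simulate_cycle0(cfg)[0]
        out = select_round(pool, cfg, np.random.default_rng(0))
        assert out.shape == pool.shape

    def test_consensus_fraction_strictly_increases_each_round(self):
        cfg = small_cfg(
            reads_per_sample=50000,
            selection_strength=1.0,
            background_capture=0.01,
            affinity=AffinityModel(kind="consensus", consensus="TATTA", mismatch_factor=0.1),
        )
        motif = encode_kmer("TATTA")

        def motif_fraction(pool):
            seqs = ["".join("ACGT"[b] for b in row) for row in pool]
            table = count_kmers(seqs, 5)
            return kmer_fractions(table)[motif]

        rng = np.random.default_rng(3)
        pool = simulate_cycle0(cfg)[0]
        f0 = motif_fraction(pool)
        pool1 = select_round(pool, cfg, rng)
        f1 = motif_fraction(pool1)
        pool2 = select_round(pool1, cfg, rng)
        f2 = motif_fraction(pool2)
        assert f0 < f1 < f2

    def test_retention_probability_capped_at_one(self):
        cfg = small_cfg(selection_strength=1.0, background_capture=1.0)
        pool = simulate_cycle0(cfg)[0]
        out = select_round(pool, cfg, np.random.default_rng(0))
        assert out.shape == pool.shape  # p == 1 everywhere retains all

    def test_zero_retention_raises_with_guidance(self):
        cfg = small_cfg(selection_strength=0.0, background_capture=0.0)
        pool = simulate_cycle0(cfg)[0]
        with pytest.raises(SimulationError, match="background_capture"):
            select_round(pool, cfg, np.random.default_rng(0))


class TestSimulateDataset:
    def test_cycle0_only_design(self, tmp_path):
        cfg = small_cfg(n_cycles=0, emit_cycles=(0,), n_replicates=3)
        simulate_dataset(cfg, tmp_path)
        meta = parse_metadata(tmp_path / "samples.tsv")
        assert len(meta) == 3
        assert all(m.cycle == 0 and m.is_control for m in meta)

    def test_default_design_has_21_samples(self, tmp_path):
        cfg = SimulationConfig(reads_per_sample=300, seed=1)
        manifest = simulate_dataset(cfg, tmp_path)
        assert manifest["n_samples"] == 21
        meta = parse_metadata(tmp_path / "samples.tsv")
        assert len(meta) == 21
        by_cycle = {}
        for m in meta:
            by_cycle.setdefault(m.cycle, []).append(m)
        assert {c: len(v) for c, v in by_cycle.items()} == {0: 3, 1: 6, 3: 6, 6: 6}
        for cycle in (1, 3, 6):
            assert sum(m.is_control for m in by_cycle[cycle]) == 3
        # last sample of the listing: cycle-6 no-protein control, replicate 3
        assert meta[-1].cycle == 6 and meta[-1].is_control and meta[-1].library == "lib3"

    def test_reads_carry_construct_flank_and_barcode(self, tmp_path):
        cfg = small_cfg(reads_per_sample=50)
        simulate_dataset(cfg, tmp_path)
        meta = parse_metadata(tmp_path / "samples.tsv")
        reads = list(read_sequences(tmp_path / f"{meta[0].sample_name}.fastq"))
        assert len(reads) == 50
        flank = cfg.construct.three_prime_flank
        for read in reads:
            assert len(read.seq) == cfg.read_length
            assert read.seq[20:] == flank[: cfg.read_length - 20]
            assert read.tags["BC"] == cfg.barcode_table.entries[meta[0].sample_name]
            assert read.qual == [40] * cfg.read_length

    def test_byte_identical_reproducibility(self, tmp_path):
        cfg = small_cfg(reads_per_sample=200, sequencing_error_rate=0.01)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(cfg, tmp_path / "b")
        for path_a in sorted((tmp_path / "a").glob("*.fastq")):
            path_b = tmp_path / "b" / path_a.name
            assert path_a.read_bytes() == path_b.read_bytes()

    def test_barcode_table_too_small_is_an_error(self, tmp_path):
        from selexkit.construct import BarcodeTable

        cfg = small_cfg(barcode_table=BarcodeTable({"only": "ACGTACGT"}))
        with pytest.raises(SimulationError, match="barcode table"):
            simulate_dataset(cfg, tmp_path)

    def test_yaml_config_round_trip(self, tmp_path):
        config_text = (
            "reads_per_sample: 500\n"
            "n_cycles: 2\n"
            "emit_cycles: [0, 2]\n"
            "seed: 9\n"
            "affinity:\n  kind: consensus\n  consensus: TATTA\n  mismatch_factor: 0.2\n"
        )
        path = tmp_path / "sim.yaml"
        path.write_text(config_text)
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.reads_per_sample == 500
        assert cfg.emit_cycles == (0, 2)
        assert cfg.affinity.kind == "consensus"
        assert cfg.affinity.window == 5  # derived from the consensus length


class TestEndToEnd:
    def test_planted_motif_recovered_through_the_pipeline(self):
        cfg = SimulationConfig(
            n_cycles=2,
            emit_cycles=(0, 2),
            reads_per_sample=15000,
            n_replicates=1,
            selection_strength=1.0,
            background_capture=0.01,
            affinity=AffinityModel(kind="consensus", consensus="TATTA", mismatch_factor=0.1),
            seed=8,
        )
        tables, metas = {}, []
        for meta, reads in simulate_samples(cfg):
            metas.append(meta)
            trimmed = list(trim_reads(reads, TrimConfig()))
            assert all(len(r.seq) == 20 for r in trimmed)
            tables[meta.sample_name] = count_kmers(trimmed, 5)
        df = enrich_dataset(tables, metas).data
        protein = df[(df.protein != NO_PROTEIN) & (df.cycle == 2)]
        top = protein.sort_values("fold_change", ascending=False).iloc[0]
        assert top["kmer"] == "TATTA"

    def test_null_model_fold_changes_bounded(self):
        cfg = SimulationConfig(
            n_cycles=1,
            emit_cycles=(0, 1),
            reads_per_sample=10000,
            n_replicates=1,
            selection_strength=0.0,
            background_capture=0.2,
            sequencing_error_rate=0.0,
            seed=12,
        )
        tables, metas = {}, []
        for meta, reads in simulate_samples(cfg):
            metas.append(meta)
            tables[meta.sample_name] = count_kmers(
                list(trim_reads(reads, TrimConfig())), 5
            )
        df = enrich_dataset(tables, metas).data
        log_fc = np.log2(df["fold_change"].to_numpy())
        # noise scale: b*n = 2000 retained reads carry ~31 copies of each
        # 5-mer, amplification roughly doubles the variance -> sigma of
        # log2 FC ~ 0.36; no 5-mer should reach a 4-fold change
        assert np.abs(log_fc).max() < 2.0
        assert np.quantile(np.abs(log_fc), 0.99) < 1.0
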