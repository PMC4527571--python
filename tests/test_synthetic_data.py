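"""Generator ground-truth invariants, determinism and noise calibration."""

import dataclasses
import math

import numpy as np
import pytest

from mirmodule import novel_discovery as nd
from mirmodule import synthetic_data as synth
from mirmodule._seq import revcomp


def _tiny(seed=0, **kw):
    defaults = dict(
        seed=seed, n_known=5, n_novel=3, genome_length=20_000,
        depth_A=5_000, depth_B=5_000, n_background_genes=5,
    )
    defaults.update(kw)
    return synth.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_infeasible_genome_rejected(self):
        with pytest.raises(ValueError):
            synth.SimulationConfig(n_known=100, n_novel=100, genome_length=5000).validate()

    def test_fraction_bounds(self):
        cfg = _tiny()
        cfg.fc_distribution.fraction_up = 0.8
        cfg.fc_distribution.fraction_down = 0.5
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_noise_model(self):
        with pytest.raises(ValueError):
            _tiny(noise_model="gamma").validate()


class TestGenomeTruth:
    def test_fixed_seed_is_bit_identical(self):
        d1 = synth.simulate_all(_tiny(seed=42))
        d2 = synth.simulate_all(_tiny(seed=42))
        assert d1.genome == d2.genome
        assert d1.truth_table().equals(d2.truth_table())
        assert d1.libraries == d2.libraries
        assert d1.transcripts == d2.transcripts
        assert d1.gene_de.equals(d2.gene_de)

    def test_different_seeds_differ(self):
        assert synth.simulate_all(_tiny(seed=1)).genome != synth.simulate_all(_tiny(seed=2)).genome

    def test_mature_is_substring_of_stranded_precursor(self):
        genome, truth = synth.simulate_genome(_tiny(seed=3))
        for t in truth:
            window = genome[t.chrom][t.precursor_start : t.precursor_end]
            if t.strand == "-":
                window = revcomp(window)
            assert t.mature_seq in window

    def test_log2fc_bookkeeping_uses_epsilon(self):
        cfg = _tiny(seed=4)
        _, truth = synth.simulate_genome(cfg)
        for t in truth:
            expected = math.log2(
                (t.true_abundance_B + cfg.epsilon) / (t.true_abundance_A + cfg.epsilon)
            )
            assert t.true_log2fc == pytest.approx(expected)

    def test_no_novel_means_no_hairpin_calls(self):
        cfg = _tiny(seed=5, n_known=0, n_novel=0)
        genome, truth = synth.simulate_genome(cfg)
        assert truth == []
        libs = synth.simulate_libraries(truth, cfg)
        novel, _ = nd.discover_novel(list(libs[cfg.library_A]), genome)
        assert novel == []

    def test_planted_precursors_fold_as_hairpins(self):
        """Every planted novel locus passes the hairpin criteria from at
        least one excised window (the generator's design guarantee)."""
        cfg = _tiny(seed=6, n_known=0, n_novel=10, genome_length=40_000)
        genome, truth = synth.simulate_genome(cfg)
        novel, _ = nd.discover_novel([t.mature_seq for t in truth], genome)
        assert len(novel) == 10


class TestLibraries:
    def test_zero_rate_gives_zero_counts(self):
        cfg = _tiny(seed=7, noise_model="poisson")
        _, truth = synth.simulate_genome(cfg)
        truth[0].true_abundance_A = 0.0
        libs = synth.simulate_libraries(truth, cfg)
        assert libs[cfg.library_A][truth[0].mature_seq] == 0

    def test_depth_is_exact(self):
        cfg = _tiny(seed=8)
        _, truth = synth.simulate_genome(cfg)
        libs = synth.simulate_libraries(truth, cfg)
        assert sum(libs[cfg.library_A].values()) == cfg.depth_A
        assert sum(libs[cfg.library_B].values()) == cfg.depth_B

    def test_background_never_collides_with_matures(self):
        """With all miRNA abundances zeroed, no mature sequence appears in
        the libraries: the background pool re-samples collisions."""
        cfg = _tiny(seed=9)
        _, truth = synth.simulate_genome(cfg)
        for t in truth:
            t.true_abundance_A = t.true_abundance_B = 0.0
        libs = synth.simulate_libraries(truth, cfg)
        matures = {t.mature_seq for t in truth}
        for counts in libs.values():
            assert not matures & {s for s, c in counts.items() if c > 0}

    def test_counts_unbiased_over_seeds(self):
        """Mean count over many seeded draws tracks true abundance within 2%."""
        cfg = _tiny(seed=10, noise_model="poisson")
        _, truth = synth.simulate_genome(cfg)
        target = max(truth, key=lambda t: t.true_abundance_A)
        totals = 0.0
        n_seeds = 150
        for s in range(n_seeds):
            cfg_s = dataclasses.replace(cfg, seed=10_000 + s)
            libs = synth.simulate_libraries(truth, cfg_s)
            totals += libs[cfg.library_A][target.mature_seq]
        assert abs(totals / n_seeds - target.true_abundance_A) <= 0.02 * target.true_abundance_A

    def test_high_depth_fold_change_concentrates(self):
        """At high depth an |log2FC|=2 miRNA shows empirical log2FC within
        +-0.5 of truth in nearly all replicates."""
        cfg = _tiny(
            seed=11, n_known=1, n_novel=0, depth_A=50_000, depth_B=50_000,
            noise_model="poisson",
        )
        _, truth = synth.simulate_genome(cfg)
        t = truth[0]
        t.true_abundance_A = 500.0
        t.true_abundance_B = 2000.0
        ok = 0
        reps = 60
        for s in range(reps):
            cfg_s = dataclasses.replace(cfg, seed=20_000 + s)
            libs = synth.simulate_libraries(truth, cfg_s)
            ca = libs[cfg.library_A][t.mature_seq]
            na = libs[cfg.library_B][t.mature_seq]
            if ca > 0 and abs(math.log2(na / ca) - 2.0) <= 0.5:
                ok += 1
        assert ok / reps >= 0.95


class TestMrnaDe:
    def test_inverse_relation_flips_status(self):
        cfg = _tiny(seed=12)
        _, truth = synth.simulate_genome(cfg)
        table = synth.simulate_mrna_de(truth, cfg)
        status = dict(zip(table.gene_id, table.status))
        for t in truth:
            for gene in t.target_gene_ids:
                if t.target_relation == "inverse" and t.direction == "up":
                    assert status[gene] == "down"
                elif t.target_relation == "inverse" and t.direction == "down":
                    assert status[gene] == "up"
                elif t.target_relation == "positive" and t.direction in ("up", "down"):
                    assert status[gene] == t.direction
                elif t.target_relation == "none":
                    assert status[gene] == "unDE"

    def test_duplicate_gene_ids_rejected(self):
        cfg = _tiny(seed=13)
        _, truth = synth.simulate_genome(cfg)
        carriers = [t for t in truth if t.target_gene_ids]
        if len(carriers) < 2:
            pytest.skip("seed produced fewer than two target carriers")
        carriers[1].target_gene_ids = list(carriers[0].target_gene_ids)
        with pytest.raises(ValueError):
            synth.simulate_mrna_de(truth, cfg)

    def test_transcripts_carry_planted_sites(self):
        cfg = _tiny(seed=14)
        _, truth = synth.simulate_genome(cfg)
        transcripts = synth.simulate_transcripts(truth, cfg)
        for t in truth:
            for gene in t.target_gene_ids:
                assert revcomp(t.mature_seq) in transcripts[gene]


def test_write_dataset_round_trips(tmp_path):
    ds = synth.simulate_all(_tiny(seed=15))
    paths = synth.write_dataset(ds, tmp_path)
    assert paths["genome"].exists() and paths["truth"].exists()
    from mirmodule._seq import read_fasta_dict, read_sequences

    assert read_fasta_dict(paths["genome"]) == ds.genome
    lib = ds.config.library_A
    counts = {seq: c for _r, seq, c in read_sequences(paths[f"reads_{lib}"])}
    assert counts == dict(ds.libraries[lib])
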