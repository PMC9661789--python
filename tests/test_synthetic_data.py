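import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from riceeco import synthetic_data as syn
from riceeco.genotype_io import MISSING, read_genes, read_sample_table, read_vcf
from riceeco.popgen_windows import make_windows, pi_windowed

from conftest import build_gm


def tiny_config(**overrides):
    base = dict(
        n_chromosomes=1,
        chrom_length_bp=200_000,
        pop_sizes={"wild": 30, "progenitor": 30, "ecotype": 30},
        split_generations={"wild->progenitor": 30, "progenitor->ecotype": 15},
        bottleneck_size=15,
        bottleneck_duration=5,
        mutation_rate=2e-6,
        recombination_rate=1e-7,
        selfing_rate=0.9,
        missing_rate=0.02,
        seed=0,
        burn_in_factor=5.0,
    )
    base.update(overrides)
    return syn.SimConfig(**base)


def _hash_dataset(G, table, truth):
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(G.calls).tobytes())
    h.update(np.asarray(G.pos).tobytes())
    h.update("".join(G.chrom.tolist()).encode())
    h.update(table.to_csv().encode())
    h.update(truth.sweep_windows.to_csv().encode())
    h.update(truth.new_mutation_sites.to_csv().encode())
    return h.hexdigest()


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(syn.SimConfigError):
            tiny_config(mutation_rate=-1e-8).validate()

    def test_nonfinite_rejected(self):
        with pytest.raises(syn.SimConfigError):
            tiny_config(mutation_rate=float("nan")).validate()

    def test_sweep_outside_chromosome_rejected(self):
        with pytest.raises(syn.SimConfigError):
            tiny_config(sweep_loci=[("chr1", 190_000, 40_000, "ecotype")]).validate()

    def test_split_order_enforced(self):
        with pytest.raises(syn.SimConfigError):
            tiny_config(
                split_generations={"wild->progenitor": 10, "progenitor->ecotype": 20}
            ).validate()


class TestSimulateDataset:
    def test_same_seed_identical_outputs(self):
        cfg = tiny_config(seed=42)
        a = syn.simulate_dataset(cfg)
        b = syn.simulate_dataset(cfg)
        assert _hash_dataset(*a) == _hash_dataset(*b)

    def test_different_seed_differs(self):
        a = syn.simulate_dataset(tiny_config(seed=1))
        b = syn.simulate_dataset(tiny_config(seed=2))
        assert _hash_dataset(*a) != _hash_dataset(*b)

    def test_zero_mutation_rate_empty_new_mutation_truth(self):
        G, table, truth = syn.simulate_dataset(tiny_config(mutation_rate=0.0))
        assert len(truth.new_mutation_sites) == 0
        assert G.n_variants == 0  # nothing ever mutates

    def test_selfing_yields_mostly_homozygous_lines(self):
        G, _, _ = syn.simulate_dataset(tiny_config(selfing_rate=0.99, seed=5))
        called = G.calls[G.calls != MISSING]
        assert (called == 1).mean() < 0.12

    def test_monomorphic_sweep_window_skipped_with_warning(self):
        cfg = tiny_config(
            mutation_rate=0.0,
            sweep_loci=[("chr1", 100_000, 40_000, "ecotype")],
        )
        with pytest.warns(UserWarning, match="sweep"):
            _, _, truth = syn.simulate_dataset(cfg)
        assert truth.sweep_windows["realized"].tolist() == [False]

    def test_truth_new_mutations_exist_in_variants_or_marked_lost(self, small_sim):
        _, G, _, truth = small_sim
        emitted = set(zip(G.chrom.tolist(), G.pos.tolist()))
        nm = truth.new_mutation_sites
        present = nm[nm["present"]]
        assert all(
            (c, p) in emitted for c, p in zip(present["chrom"], present["pos"])
        )

    def test_sample_table_matches_genotypes(self, small_sim):
        _, G, table, _ = small_sim
        assert list(table["sample_id"]) == list(G.samples)


class TestNeutralCalibration:
    def test_mean_pi_matches_theta(self):
        # no sweeps, no bottleneck, no selfing: windowed pi ~ 4*N*mu per bp
        vals = []
        for seed in range(50):
            cfg = tiny_config(
                chrom_length_bp=100_000,
                pop_sizes={"wild": 30, "progenitor": 4, "ecotype": 4},
                split_generations={"wild->progenitor": 4, "progenitor->ecotype": 2},
                bottleneck_size=4,
                bottleneck_duration=0,
                selfing_rate=0.0,
                missing_rate=0.0,
                burn_in_factor=8.0,
                sample_sizes={"wild": 30, "progenitor": 0, "ecotype": 0},
                seed=seed,
            )
            G, table, _ = syn.simulate_dataset(cfg)
            grid = make_windows({"chr1": 100_000}, 100_000, 100_000)
            wild = table.loc[table["group"] == "Or", "sample_id"].tolist()
            vals.append(pi_windowed(G, wild, grid)["value"].iloc[0])
        theta = 4 * 30 * 2e-6
        assert abs(np.mean(vals) - theta) / theta < 0.15

    def test_bottleneck_reduces_progenitor_diversity(self):
        wild_pi, prog_pi = [], []
        for seed in range(20):
            cfg = tiny_config(
                chrom_length_bp=100_000,
                bottleneck_size=6,
                bottleneck_duration=10,
                selfing_rate=0.5,
                missing_rate=0.0,
                seed=100 + seed,
            )
            G, table, _ = syn.simulate_dataset(cfg)
            grid = make_windows({"chr1": 100_000}, 100_000, 100_000)
            for group, sink in (("Or", wild_pi), ("IR-XI", prog_pi)):
                samples = table.loc[table["group"] == group, "sample_id"].tolist()
                sink.append(pi_windowed(G, samples, grid)["value"].iloc[0])
        assert np.mean(prog_pi) < np.mean(wild_pi)


class TestInjectMissing:
    def test_rate_zero_identity(self):
        G = build_gm(np.zeros((5, 10), dtype=np.int8))
        assert syn.inject_missing(G, 0.0, seed=0) is G

    def test_binomial_bound(self):
        rng = np.random.default_rng(0)
        G = build_gm(rng.integers(0, 3, size=(100, 1000)).astype(np.int8))
        out = syn.inject_missing(G, 0.5, seed=1)
        frac = (out.calls == MISSING).mean()
        sd = np.sqrt(0.5 * 0.5 / G.calls.size)
        assert abs(frac - 0.5) <= 3 * sd

    def test_rate_one_rejected(self):
        G = build_gm(np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            syn.inject_missing(G, 1.0, seed=0)
        with pytest.raises(ValueError):
            syn.inject_missing(G, -0.1, seed=0)


class TestSimulateExpression:
    def _genes(self, n=10):
        cfg = tiny_config()
        return syn.make_genes(cfg, n_genes=n, seed=0)

    def test_noise_free_down_gene_exact_ratios(self):
        genes = self._genes()
        truth = syn.SimTruth(de_genes={genes["gene_id"].iloc[0]: "down"})
        expr = syn.simulate_expression(genes, truth, fold_up=3.0, fold_down=0.36,
                                       noise_sd=0.0, seed=0, zero_fraction=0.0)
        row = expr.iloc[0]
        assert row["rpkm_dw_sub"] / row["rpkm_ndw_sub"] == pytest.approx(0.36)
        assert row["rpkm_after"] / row["rpkm_before"] == pytest.approx(0.36)

    def test_zero_fraction_genes_all_zero(self):
        genes = self._genes(20)
        expr = syn.simulate_expression(genes, syn.SimTruth(), noise_sd=0.1,
                                       seed=0, zero_fraction=0.25)
        zero_rows = expr[(expr[["rpkm_dw_sub", "rpkm_ndw_sub",
                                "rpkm_after", "rpkm_before"]] == 0).all(axis=1)]
        assert len(zero_rows) == 5

    def test_planted_up_genes_recovered_downstream(self):
        from riceeco.candidate_screen import label_expression

        genes = self._genes(100)
        truth = syn.SimTruth(de_genes={g: "up" for g in genes["gene_id"]})
        expr = syn.simulate_expression(genes, truth, fold_up=3.0, fold_down=0.3,
                                       noise_sd=0.1, seed=3, zero_fraction=0.0)
        labelled = label_expression(expr)
        assert (labelled["label"] == "up").sum() >= 95

    def test_threshold_violating_folds_rejected(self):
        genes = self._genes()
        with pytest.raises(ValueError):
            syn.simulate_expression(genes, syn.SimTruth(), fold_up=1.2)
        with pytest.raises(ValueError):
            syn.simulate_expression(genes, syn.SimTruth(), fold_down=0.8)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_expression(self._genes().iloc[:0], syn.SimTruth())


class TestWriteFixture:
    def _dataset(self, seed=0):
        cfg = tiny_config(seed=seed)
        G, table, truth = syn.simulate_dataset(cfg)
        genes = syn.make_genes(cfg, n_genes=10, seed=seed)
        truth.de_genes = syn.plant_de_genes(genes, 2, 2, seed=seed)
        expr = syn.simulate_expression(genes, truth, seed=seed)
        return cfg, G, table, genes, expr, truth

    def test_vcf_roundtrip_exact(self, tmp_path):
        cfg, G, table, genes, expr, truth = self._dataset()
        syn.write_fixture(G, table, genes, expr, truth, cfg, tmp_path)
        assert read_vcf(tmp_path / "genotypes.vcf").equals(G)
        pd.testing.assert_frame_equal(
            read_sample_table(tmp_path / "samples.tsv"), table
        )
        pd.testing.assert_frame_equal(read_genes(tmp_path / "genes.bed"), genes)

    def test_manifest_hash_tracks_config(self, tmp_path):
        cfg, G, table, genes, expr, truth = self._dataset()
        m1 = syn.write_fixture(G, table, genes, expr, truth, cfg, tmp_path / "a")
        m2 = syn.write_fixture(G, table, genes, expr, truth, cfg, tmp_path / "b")
        assert m1["config_hash"] == m2["config_hash"]
        cfg2, G2, table2, genes2, expr2, truth2 = self._dataset(seed=9)
        m3 = syn.write_fixture(G2, table2, genes2, expr2, truth2, cfg2, tmp_path / "c")
        assert m3["config_hash"] != m1["config_hash"]

    def test_bed_sorted_half_open(self, tmp_path):
        cfg, G, table, genes, expr, truth = self._dataset()
        syn.write_fixture(G, table, genes, expr, truth, cfg, tmp_path)
        rows = [l.split("\t") for l in (tmp_path / "genes.bed").read_text().splitlines()]
        starts = [(r[0], int(r[1])) for r in rows]
        assert starts == sorted(starts)
        assert all(int(r[1]) < int(r[2]) for r in rows)

    def test_manifest_json_lists_all_files(self, tmp_path):
        cfg, G, table, genes, expr, truth = self._dataset()
        manifest = syn.write_fixture(G, table, genes, expr, truth, cfg, tmp_path)
        with (tmp_path / "manifest.json").open() as fh:
            on_disk = json.load(fh)
        assert on_disk == manifest
        for path in manifest["files"].values():
            assert (tmp_path / path.split("/")[-1]).exists()


class TestPhenotypeHelpers:
    def test_causal_snps_are_common(self, small_sim):
        _, G, _, _ = small_sim
        causal = syn.choose_causal_snps(G, n_causal=3, seed=0, min_maf=0.1)
        assert len(causal) == 3
        from riceeco.genotype_io import variant_maf

        maf = variant_maf(G)
        for _, row in causal.iterrows():
            j = np.flatnonzero((G.chrom == row["chrom"]) & (G.pos == row["pos"]))[0]
            assert maf[j] >= 0.1

    def test_liability_phenotype_case_fraction(self, small_sim):
        _, G, _, _ = small_sim
        causal = syn.choose_causal_snps(G, n_causal=3, seed=0)
        y = syn.liability_phenotype(G, causal, case_fraction=0.3, seed=0)
        assert set(np.unique(y)) <= {0, 1}
        assert abs(y.mean() - 0.3) < 0.1
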