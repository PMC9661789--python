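import numpy as np
import pandas as pd
import pytest

from riceeco.genotype_io import (
    MISSING,
    make_genotype_matrix,
    make_sample_table,
    samples_in_group,
)
from riceeco.popgen_windows import make_windows, pi_windowed, fst_windowed
from riceeco.sweep_detection import (
    call_outlier_regions,
    composite_sweep_scan,
    rod_windowed,
)
from riceeco.synthetic_data import SimConfig, simulate_dataset


def build_gm(calls, chrom=None, pos=None, samples=None):
    """GenotypeMatrix from a (samples x variants) array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 10
    return make_genotype_matrix(samples, chrom, pos, ["A"] * m, ["T"] * m, calls)


@pytest.fixture
def gm_factory():
    return build_gm


# ---------------------------------------------------------------------------
# session-scoped simulation harnesses (shared by module and acceptance tests)
# ---------------------------------------------------------------------------

def _sweep_config(seed):
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        pop_sizes={"wild": 60, "progenitor": 60, "ecotype": 60},
        split_generations={"wild->progenitor": 60, "progenitor->ecotype": 30},
        bottleneck_size=50,
        bottleneck_duration=5,
        mutation_rate=2e-6,
        recombination_rate=1e-7,
        selfing_rate=0.85,
        sweep_loci=[("chr1", 1_000_000, 200_000, "ecotype")],
        sweep_strength=5.0,
        missing_rate=0.02,
        seed=seed,
        burn_in_factor=5.0,
    )


N_SWEEP_REPS = 50
SWEEP_SPAN = ("chr1", 900_000, 1_100_000)


def _overlaps(df, chrom, start, end):
    return df[(df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)]


@pytest.fixture(scope="session")
def sweep_replicates():
    """Per-replicate scan outputs for the planted-sweep recovery harness."""
    results = []
    for rep in range(N_SWEEP_REPS):
        cfg = _sweep_config(1000 + rep)
        G, table, truth = simulate_dataset(cfg)
        wild = samples_in_group(table, "Or")
        eco = samples_in_group(table, "DW")
        prog = samples_in_group(table, "IR-XI")
        lengths = cfg.chrom_lengths()
        grid = make_windows(lengths, 40_000, 20_000)
        pi_w = pi_windowed(G, wild, grid)
        pi_e = pi_windowed(G, eco, grid)
        rod = rod_windowed(pi_w, pi_e)
        rod_regions = call_outlier_regions(rod, 0.99)
        cgrid = make_windows(lengths, 25_000, 25_000)
        comp = composite_sweep_scan(G, eco, cgrid)
        comp_regions = call_outlier_regions(comp, 0.99)
        fst, _ = fst_windowed(G, eco, prog, grid)
        fst.attrs["statistic"] = "fst"
        fst_regions = call_outlier_regions(fst, 0.99)
        results.append(
            {
                "truth": truth,
                "pi_eco": pi_e,
                "rod": rod,
                "rod_regions": rod_regions,
                "composite": comp,
                "comp_regions": comp_regions,
                "fst_regions": fst_regions,
            }
        )
    return results


def recovery_stats(replicates, window_key, region_key):
    """Recall of the planted sweep and window-level false-positive rate."""
    chrom, lo, hi = SWEEP_SPAN
    hits = 0
    fp = 0
    neutral = 0
    for rep in replicates:
        if len(_overlaps(rep[region_key], chrom, lo, hi)):
            hits += 1
        win = rep[window_key]
        ranked = win[(win["flag"] != "undefined") & np.isfinite(win["value"])]
        from riceeco.sweep_detection import outlier_threshold

        thr = outlier_threshold(ranked["value"].to_numpy(dtype=float), 0.99)
        called = ranked["value"].to_numpy(dtype=float) >= thr
        in_sweep = (
            (ranked["chrom"] == chrom) & (ranked["start"] < hi) & (ranked["end"] > lo)
        ).to_numpy()
        fp += int((called & ~in_sweep).sum())
        neutral += int((~in_sweep).sum())
    return hits / len(replicates), fp / neutral, neutral


# ---------------------------------------------------------------------------
# GWAS recovery harness
# ---------------------------------------------------------------------------

N_GWAS_REPS = 20
GWAS_TARGETS = [("chr1", 100_000), ("chr1", 300_000), ("chr2", 200_000)]


def _gwas_config(seed):
    # one large weakly-selfing panel: an "ecotype membership" phenotype built
    # from individual SNPs needs within-panel variance that a deeply
    # structured multi-population design would hand to the kinship/PC terms
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=400_000,
        pop_sizes={"wild": 30, "progenitor": 30, "ecotype": 320},
        split_generations={"wild->progenitor": 60, "progenitor->ecotype": 30},
        bottleneck_size=30,
        bottleneck_duration=0,
        mutation_rate=2e-6,
        recombination_rate=5e-7,
        selfing_rate=0.4,
        missing_rate=0.02,
        seed=seed,
        burn_in_factor=5.0,
        sample_sizes={"wild": 0, "progenitor": 0, "ecotype": 320},
    )


def _nearest_common_snp(G, chrom, pos, lo=0.25, hi=0.5):
    from riceeco.genotype_io import variant_maf

    maf = np.nan_to_num(variant_maf(G), nan=0.0)
    ok = np.flatnonzero((G.chrom == chrom) & (maf >= lo) & (maf <= hi))
    if ok.size == 0:
        return None
    return ok[np.argmin(np.abs(G.pos[ok] - pos))]


@pytest.fixture(scope="session")
def gwas_replicates():
    """Planted-ecotype-loci GWAS replicates: simulate, scan, call QTLs."""
    import riceeco.ecotype_gwas as gw
    from riceeco.genotype_io import filter_variants

    results = []
    for rep in range(N_GWAS_REPS):
        cfg = _gwas_config(2000 + rep)
        G, table, truth = simulate_dataset(cfg)
        G = filter_variants(G, 0.5, 0.05)
        rng = np.random.default_rng(3000 + rep)
        causal = [
            j for t in GWAS_TARGETS
            if (j := _nearest_common_snp(G, *t)) is not None
        ]
        dosage = G.calls.astype(float)
        dosage[dosage == MISSING] = np.nan
        liability = rng.normal(0.0, 0.3, size=G.n_samples)
        for j in causal:
            g = dosage[:, j]
            g = np.where(np.isfinite(g), g, np.nanmean(g))
            liability += 2.0 * g
        y = (liability >= np.quantile(liability, 0.5)).astype(float)
        kept = gw.ld_prune(G, 50, 5, 0.3)
        Gp = G.subset_variants(kept)
        K = gw.grm(Gp)
        pcs = gw.pca_covariates(Gp, 3)
        assoc = gw.lmm_scan(G, y, covariates=pcs, K=K)
        thr = gw.suggestive_threshold(len(kept), 0.01)
        qtls = gw.call_qtls(assoc, thr, merge_distance_bp=100_000)
        results.append(
            {
                "causal": [(G.chrom[j], int(G.pos[j])) for j in causal],
                "assoc": assoc,
                "qtls": qtls,
                "threshold": thr,
                "n_effective": len(kept),
            }
        )
    return results


def qtl_coverage(rep, slack=50_000):
    covered = 0
    for chrom, pos in rep["causal"]:
        hit = rep["qtls"][
            (rep["qtls"]["chrom"] == chrom)
            & (rep["qtls"]["start"] - slack <= pos)
            & (rep["qtls"]["end"] + slack >= pos)
        ]
        if len(hit):
            covered += 1
    return covered, len(rep["causal"])


# ---------------------------------------------------------------------------
# one shared small dataset for miscellaneous tests
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_sim():
    cfg = _sweep_config(7)
    G, table, truth = simulate_dataset(cfg)
    return cfg, G, table, truth
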