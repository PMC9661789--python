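"""Outlier scans for selective sweeps and divergence regions.

Implements the reduction-of-diversity (ROD) ratio scan, empirical top-quantile
region calling with bookend merging, a multi-signature composite sweep score
over non-overlapping windows, gene annotation of called regions, and
genome-fraction reporting.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .popgen_windows import _grids_equal, _window_sums, site_pi

REGION_COLUMNS = ["chrom", "start", "end", "peak_value", "mean_value", "n_windows", "scan"]


def rod_windowed(pi_ancestral: pd.DataFrame, pi_derived: pd.DataFrame) -> pd.DataFrame:
    """Reduction of diversity: per-window ratio ancestral-pi / derived-pi.

    Zero derived-pi windows are floored at epsilon = the 1st percentile of the
    positive derived-pi values (flag ``floored``); windows with zero ancestral
    pi are flagged ``undefined`` and excluded from downstream ranking.
    """
    if not _grids_equal(pi_ancestral, pi_derived):
        raise ValueError("pi window grids do not match")
    anc = pi_ancestral["value"].to_numpy(dtype=float)
    der = pi_derived["value"].to_numpy(dtype=float)
    positive = der[der > 0]
    eps = float(np.percentile(positive, 1)) if positive.size else np.nan
    out = pi_ancestral[["chrom", "start", "end"]].copy()
    out["n_snps"] = pi_derived["n_snps"].to_numpy() + pi_ancestral["n_snps"].to_numpy()
    floored = der <= 0
    denom = np.where(floored, eps, der)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["value"] = anc / denom
    flag = np.where(floored, "floored", "")
    flag = np.where(anc <= 0, "undefined", flag)
    out["flag"] = flag
    out.loc[out["flag"] == "undefined", "value"] = np.nan
    out.attrs["statistic"] = "rod"
    out.attrs["epsilon"] = eps
    return out


def outlier_threshold(values: np.ndarray, quantile: float) -> float:
    """Empirical top-quantile threshold: the order statistic at 0-based index
    ceil(q * M) of the sorted values (ties at the threshold are kept)."""
    v = np.sort(values)
    m = len(v)
    k = min(int(math.ceil(quantile * m)), m - 1)
    return float(v[k])


def call_outlier_regions(stats_df: pd.DataFrame, quantile=0.99, merge=True,
                         scan=None) -> pd.DataFrame:
    """Call regions from windows scoring in the empirical top quantile.

    Windows at or above the threshold whose intervals overlap or bookend are
    merged into one region (unless ``merge`` is false). Windows flagged
    ``undefined``/NaN are excluded from the ranking.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    scan = scan or stats_df.attrs.get("statistic", "scan")
    df = stats_df.copy()
    if "flag" in df.columns:
        df = df[df["flag"] != "undefined"]
    df = df[np.isfinite(df["value"].to_numpy(dtype=float))]
    if len(df) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    if len(df) < 100:
        warnings.warn(
            f"only {len(df)} ranked windows; top-quantile threshold is unstable",
            stacklevel=2,
        )
    values = df["value"].to_numpy(dtype=float)
    if np.all(values == values[0]):
        warnings.warn("all window values identical; no outlier regions called", stacklevel=2)
        return pd.DataFrame(columns=REGION_COLUMNS)
    thr = outlier_threshold(values, quantile)
    hits = df[values >= thr].sort_values(["chrom", "start"], kind="mergesort")
    rows = []
    if not merge:
        for _, w in hits.iterrows():
            rows.append(
                (w["chrom"], int(w["start"]), int(w["end"]), w["value"], w["value"], 1, scan)
            )
    else:
        cur = None
        for _, w in hits.iterrows():
            if cur is not None and w["chrom"] == cur["chrom"] and w["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["values"].append(w["value"])
            else:
                if cur is not None:
                    rows.append(_finish_region(cur, scan))
                cur = {
                    "chrom": w["chrom"],
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "values": [w["value"]],
                }
        if cur is not None:
            rows.append(_finish_region(cur, scan))
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    out.attrs["threshold"] = thr
    return out


def _finish_region(cur, scan):
    vals = cur["values"]
    return (
        cur["chrom"], cur["start"], cur["end"],
        float(max(vals)), float(np.mean(vals)), len(vals), scan,
    )


# ---------------------------------------------------------------------------
# composite multi-signature scan
# ---------------------------------------------------------------------------

def _rank_z(values: np.ndarray) -> np.ndarray:
    """Genome-wide rank-based normal scores; NaNs stay NaN."""
    z = np.full(len(values), np.nan)
    ok = np.isfinite(values)
    if ok.sum() >= 2:
        ranks = stats.rankdata(values[ok])
        z[ok] = stats.norm.ppf(ranks / (ok.sum() + 1.0))
    return z


def _mean_imputed(calls: np.ndarray) -> np.ndarray:
    g = calls.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    inds = np.where(np.isnan(g))
    g[inds] = mu[inds[1]]
    return g


def _ld_ratio(calls: np.ndarray) -> float:
    """(mean within-half r^2 summed over halves) / (mean cross-half r^2 + 0.01)."""
    g = _mean_imputed(calls)
    sd = g.std(axis=0)
    g = g[:, sd > 0]
    k = g.shape[1]
    if k < 4:
        return np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.corrcoef(g, rowvar=False) ** 2
    half = k // 2
    def _mean_tri(block):
        n = block.shape[0]
        iu = np.triu_indices(n, 1)
        return float(np.nanmean(block[iu])) if iu[0].size else np.nan
    within = _mean_tri(r2[:half, :half])
    within_r = _mean_tri(r2[half:, half:])
    cross = float(np.nanmean(r2[:half, half:]))
    if not (np.isfinite(within) and np.isfinite(within_r) and np.isfinite(cross)):
        return np.nan
    return (within + within_r) / (cross + 0.01)


def composite_sweep_scan(G: GenotypeMatrix, samples, grid: pd.DataFrame,
                         min_snps=5) -> pd.DataFrame:
    """Composite sweep score over a non-overlapping grid.

    Per window: S1 = -z(pi) (diversity deficit), S2 = z(fraction of SNPs in
    the SFS tails), S3 = z(within/cross-half LD ratio); z is the genome-wide
    rank normal score and the composite is S1 + S2 + S3. Windows with fewer
    than ``min_snps`` SNPs fall back to S1 alone (flag ``sparse``).
    """
    if len(samples) < 4:
        raise ValueError("composite scan needs >= 4 samples (r^2 unstable below)")
    g = grid.sort_values(["chrom", "start"], kind="mergesort")
    same_chrom = g["chrom"].to_numpy()[1:] == g["chrom"].to_numpy()[:-1]
    if np.any(g["start"].to_numpy()[1:][same_chrom] < g["end"].to_numpy()[:-1][same_chrom]):
        raise ValueError("composite scan requires a non-overlapping window grid")

    idx = G.sample_indices(samples)
    sub = G.calls[idx, :]
    pi, called = site_pi(G, samples)
    alt = np.where(sub == MISSING, 0, sub).sum(axis=0)
    minor = np.minimum(alt, called - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        tail = (minor <= 2) | (p_alt >= 1.0 - 2.0 / np.maximum(called, 1))
    usable = called >= 2

    length = (grid["end"] - grid["start"]).to_numpy()
    sums, n_snps = _window_sums(
        grid, G.chrom, G.pos, [pi, tail.astype(float)], usable
    )
    pi_w = sums[:, 0] / length
    with np.errstate(invalid="ignore", divide="ignore"):
        f_tail = np.where(n_snps > 0, sums[:, 1] / np.maximum(n_snps, 1), np.nan)

    ld = np.full(len(grid), np.nan)
    by_chrom = {c: np.flatnonzero(G.chrom == c) for c in np.unique(G.chrom)}
    for w, (c, start, end) in enumerate(
        zip(grid["chrom"], grid["start"], grid["end"])
    ):
        if n_snps[w] < min_snps:
            continue
        sites = by_chrom.get(c)
        if sites is None:
            continue
        p = G.pos[sites]
        lo = np.searchsorted(p, start + 1)
        hi = np.searchsorted(p, end, side="right")
        ld[w] = _ld_ratio(sub[:, sites[lo:hi]])

    sparse = n_snps < min_snps
    s1 = -_rank_z(pi_w)
    s2 = np.where(sparse, np.nan, _rank_z(np.where(sparse, np.nan, f_tail)))
    s3 = np.where(sparse, np.nan, _rank_z(np.where(sparse, np.nan, ld)))
    composite = np.where(sparse, s1, s1 + np.nan_to_num(s2) + np.nan_to_num(s3))

    out = grid[["chrom", "start", "end"]].copy()
    out["n_snps"] = n_snps
    out["value"] = composite
    out["flag"] = np.where(sparse, "sparse", "")
    out["s1"] = s1
    out["s2"] = s2
    out["s3"] = s3
    out.attrs["statistic"] = "composite"
    return out


# ---------------------------------------------------------------------------
# annotation / reporting
# ---------------------------------------------------------------------------

def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach gene ids overlapping each region by >= 1 bp (half-open)."""
    out = regions.copy()
    assigned = []
    for _, r in out.iterrows():
        hit = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        assigned.append(",".join(hit["gene_id"].tolist()))
    out["genes"] = assigned
    return out


def genome_fraction(regions: pd.DataFrame, chrom_lengths: dict):
    """Total span of (non-overlapping) regions and its genome fraction."""
    if len(regions) == 0:
        return 0, 0.0
    r = regions.sort_values(["chrom", "start"], kind="mergesort")
    same = r["chrom"].to_numpy()[1:] == r["chrom"].to_numpy()[:-1]
    if np.any(r["start"].to_numpy()[1:][same] < r["end"].to_numpy()[:-1][same]):
        raise ValueError("regions overlap; merge before computing genome fraction")
    span = int((r["end"] - r["start"]).sum())
    total = float(sum(chrom_lengths.values()))
    return span, span / total


def intersect_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Interval intersection of two region sets (utility for cross-scan
    comparisons)."""
    rows = []
    for _, x in a.iterrows():
        hit = b[(b["chrom"] == x["chrom"]) & (b["start"] < x["end"]) & (b["end"] > x["start"])]
        for _, y in hit.iterrows():
            rows.append(
                (x["chrom"], max(int(x["start"]), int(y["start"])),
                 min(int(x["end"]), int(y["end"])))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
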