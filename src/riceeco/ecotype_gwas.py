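"""Mixed-model association of SNPs with a binary ecotype phenotype.

The model is y = W alpha + g beta + u + e with u ~ N(0, sg^2 K); K is
eigendecomposed once, the variance ratio delta = se^2/sg^2 is REML-estimated
on the covariate-only null (grid search then bounded refinement), and each
SNP is tested by generalized least squares in the rotated coordinates
(EMMAX-style single global delta). The binary phenotype is treated as
quantitative, as in the source design.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix

ASSOC_COLUMNS = ["chrom", "pos", "beta", "se", "p_value", "neglog10p"]


# ---------------------------------------------------------------------------
# phenotype / genotype preparation
# ---------------------------------------------------------------------------

def encode_phenotype(T: pd.DataFrame, target_group, sample_order=None) -> np.ndarray:
    """0/1 phenotype: 1 for the target ecotype, 0 otherwise, aligned to
    ``sample_order`` (default: the table's order)."""
    groups = dict(zip(T["sample_id"], T["group"]))
    if target_group not in set(T["group"]):
        raise ValueError(f"target group {target_group!r} absent from sample table")
    order = list(T["sample_id"]) if sample_order is None else list(sample_order)
    y = np.array([1 if groups[s] == target_group else 0 for s in order], dtype=float)
    if y.sum() < 5:
        warnings.warn(f"only {int(y.sum())} cases for {target_group!r}; low power",
                      stacklevel=2)
    return y


def _dosage_matrix(G: GenotypeMatrix) -> np.ndarray:
    """float genotype dosages with missing mean-imputed per variant."""
    g = G.calls.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    inds = np.where(np.isnan(g))
    g[inds] = mu[inds[1]]
    return g


def _standardized(G: GenotypeMatrix):
    """Columns centered by 2*p_hat and scaled by sqrt(2 p (1-p)); zero-variance
    columns dropped. Returns (Z, kept_mask)."""
    g = _dosage_matrix(G)
    p = g.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    keep = denom > 0
    Z = (g[:, keep] - 2.0 * p[keep]) / denom[keep]
    return Z, keep


# ---------------------------------------------------------------------------
# LD pruning (PLINK --indep-pairwise semantics)
# ---------------------------------------------------------------------------

def pairwise_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes over samples non-missing
    at both SNPs."""
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = gi[ok].astype(float)
    y = gj[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise-deletion r^2 matrix for a block of SNP columns."""
    masked = np.ma.masked_equal(calls.astype(float), float(MISSING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.ma.corrcoef(masked, rowvar=False)
    r2 = np.asarray(r.filled(0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(G: GenotypeMatrix, window_snps=50, step_snps=5, r2_max=0.3):
    """Return indices of variants kept by sliding-window pairwise pruning.

    Within each window, while any pair exceeds ``r2_max``, the worst pair's
    lower-MAF SNP (tie-break: later position) is removed. Passes repeat until
    no window contains an offending pair, so pruning is a fixed point.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    from .genotype_io import variant_maf

    maf = np.nan_to_num(variant_maf(G), nan=0.0)
    kept = np.ones(G.n_variants, dtype=bool)
    for chrom in np.unique(G.chrom):
        chrom_idx = np.flatnonzero(G.chrom == chrom)
        changed = True
        while changed:
            changed = False
            alive = chrom_idx[kept[chrom_idx]]
            for start in range(0, max(len(alive) - 1, 1), step_snps):
                win = alive[start:start + window_snps]
                win = win[kept[win]]  # may have been pruned by an earlier window
                if len(win) < 2:
                    continue
                r2 = _window_r2(G.calls[:, win])
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    vi, vj = win[i], win[j]
                    if maf[vi] < maf[vj]:
                        drop = i
                    elif maf[vj] < maf[vi]:
                        drop = j
                    else:  # equal MAF: drop the later position
                        drop = i if G.pos[vi] > G.pos[vj] else j
                    kept[win[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
                    changed = True
    return np.flatnonzero(kept)


def suggestive_threshold(n_independent: int, alpha=0.01, mode="exact") -> float:
    """-log10(alpha / n_independent); ``floor`` truncates to an integer."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    value = -math.log10(alpha / n_independent)
    if mode == "floor":
        return float(math.floor(value))
    if mode == "exact":
        return value
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# kinship and covariates
# ---------------------------------------------------------------------------

def grm(G: GenotypeMatrix) -> np.ndarray:
    """Standardized genomic relationship matrix K = Z Z' / m."""
    if G.n_samples < 2 or G.n_variants < 10:
        raise ValueError("grm needs >= 2 samples and >= 10 variants")
    Z, keep = _standardized(G)
    if Z.shape[1] == 0:
        raise ValueError("all variants are monomorphic; cannot build a GRM")
    return Z @ Z.T / Z.shape[1]


def pca_covariates(G: GenotypeMatrix, k=3) -> np.ndarray:
    """Top-k principal component scores of the standardized genotype matrix
    (left singular vectors scaled by singular values; deterministic signs)."""
    if k == 0:
        return np.empty((G.n_samples, 0))
    Z, _ = _standardized(G)
    if k >= min(Z.shape):
        raise ValueError(f"k={k} must be < min(n_samples, n_variants)={min(Z.shape)}")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _reml_neg_loglik(log10_delta, lam, UW, Uy):
    """Negative REML log-likelihood of the covariate-only model at a given
    variance ratio delta (profiled over sg^2)."""
    delta = 10.0 ** log10_delta
    d = lam + delta
    n, p = UW.shape
    Dinv = 1.0 / d
    WtW = (UW * Dinv[:, None]).T @ UW
    Wty = (UW * Dinv[:, None]).T @ Uy
    try:
        beta = np.linalg.solve(WtW, Wty)
    except np.linalg.LinAlgError:
        return np.inf
    r = Uy - UW @ beta
    rss = float(np.sum(r * r * Dinv))
    if rss <= 0:
        return np.inf
    sign, logdet_wtw = np.linalg.slogdet(WtW)
    if sign <= 0:
        return np.inf
    nf = n - p
    ll = -0.5 * (nf * math.log(rss / nf) + np.sum(np.log(d)) + logdet_wtw)
    return -ll


def estimate_delta(lam, UW, Uy, grid_points=64, tol=1e-6):
    """REML estimate of delta via a log10 grid on [-5, 5] plus bounded
    refinement."""
    grid = np.linspace(-5.0, 5.0, grid_points)
    vals = np.array([_reml_neg_loglik(g, lam, UW, Uy) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, UW, Uy),
        method="bounded", options={"xatol": tol},
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    return 10.0 ** float(best)


def lmm_scan(G: GenotypeMatrix, y, covariates=None, K=None, delta=None) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Monomorphic SNPs are skipped. Wald p-values use a t distribution with
    n - rank(W) - 1 degrees of freedom, where W is the intercept+covariate
    block. ``delta`` may be supplied to bypass REML estimation.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match samples")
    W = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        W = np.hstack([W, C])
    rank_w = np.linalg.matrix_rank(W)
    if rank_w < W.shape[1]:
        raise ValueError("singular covariate block: columns are collinear "
                         f"(rank {rank_w} < {W.shape[1]})")
    if K is None:
        K = np.eye(n)
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    Uy = U.T @ y
    UW = U.T @ W
    if delta is None:
        delta = estimate_delta(lam, UW, Uy)
    d = lam + delta
    Dinv = 1.0 / d

    g = _dosage_matrix(G)
    poly = g.std(axis=0) > 0
    cols = np.flatnonzero(poly)
    Xg = U.T @ g[:, cols]

    # GLS with the covariate block projected out (block inversion)
    A = (UW * Dinv[:, None]).T @ UW
    Ainv = np.linalg.inv(A)
    Wty = (UW * Dinv[:, None]).T @ Uy
    yty = float(np.sum(Uy * Uy * Dinv))
    rss0 = yty - float(Wty @ Ainv @ Wty)

    Wtg = (UW * Dinv[:, None]).T @ Xg                     # (p, m)
    gtg = np.einsum("im,i,im->m", Xg, Dinv, Xg)           # (m,)
    gty = Xg.T @ (Dinv * Uy)                              # (m,)
    AiWtg = Ainv @ Wtg
    gtg_adj = gtg - np.einsum("pm,pm->m", Wtg, AiWtg)
    gty_adj = gty - Wty @ AiWtg

    df = n - rank_w - 1
    ok = gtg_adj > 1e-12
    beta = np.full(len(cols), np.nan)
    se = np.full(len(cols), np.nan)
    pv = np.full(len(cols), np.nan)
    beta[ok] = gty_adj[ok] / gtg_adj[ok]
    rss = rss0 - gty_adj[ok] ** 2 / gtg_adj[ok]
    sigma2 = np.maximum(rss, 0.0) / df
    se[ok] = np.sqrt(sigma2 / gtg_adj[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[ok] / se[ok]
    pv[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)

    keep = np.isfinite(pv)
    out = pd.DataFrame(
        {
            "chrom": G.chrom[cols[keep]],
            "pos": G.pos[cols[keep]],
            "beta": beta[keep],
            "se": se[keep],
            "p_value": pv[keep],
            "neglog10p": -np.log10(pv[keep]),
        }
    )
    out.attrs["delta"] = float(delta)
    out.attrs["df"] = int(df)
    return out


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

QTL_COLUMNS = ["chrom", "start", "end", "lead_chrom", "lead_pos", "min_p",
               "n_significant", "genes"]


def call_qtls(assoc: pd.DataFrame, threshold: float, merge_distance_bp=200_000,
              genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cluster significant SNPs (neglog10p >= threshold) within
    ``merge_distance_bp`` on the same chromosome into QTLs."""
    sig = assoc[assoc["neglog10p"] >= threshold].sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        pval = sub["p_value"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_distance_bp) + 1
        for piece in np.split(np.arange(len(pos)), breaks):
            p = pos[piece]
            q = pval[piece]
            order = np.lexsort((p, q))  # min p, tie -> smaller position
            lead_i = piece[order[0]]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(p.min() - 1),
                    "end": int(p.max()),
                    "lead_chrom": chrom,
                    "lead_pos": int(pos[lead_i]),
                    "min_p": float(q.min()),
                    "n_significant": int(len(piece)),
                    "genes": "",
                }
            )
    out = pd.DataFrame(rows, columns=QTL_COLUMNS)
    if genes is not None and len(out):
        annotated = []
        for _, r in out.iterrows():
            lo = r["start"] - merge_distance_bp
            hi = r["end"] + merge_distance_bp
            hit = genes[
                (genes["chrom"] == r["chrom"]) & (genes["start"] < hi) & (genes["end"] > lo)
            ]
            annotated.append(",".join(hit["gene_id"].tolist()))
        out["genes"] = annotated
    return out
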