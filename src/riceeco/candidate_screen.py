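"""Candidate-gene prioritization inside QTL/sweep regions.

Expression genes are classified by the two-ratio rule: up when both the
submerged deepwater/non-deepwater RPKM ratio and the deepwater-variety
after/before ratio exceed 1.5, down when both fall below 0.67 (strict
inequalities; all-zero genes are excluded). Haplotype differentiation across
groups uses a Pearson chi-square with a label-permutation p-value, justified
for unphased data by the near-complete homozygosity of inbred accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def _ratio(num: float, den: float):
    """RPKM ratio; None when undefined (0/0), inf when only the denominator
    is zero."""
    if den > 0:
        return num / den
    return np.inf if num > 0 else None


def classify_expression(rpkm_dw_sub, rpkm_ndw_sub, rpkm_after, rpkm_before,
                        up_cut=1.5, down_cut=0.67) -> str:
    """Label one gene: up / down / unclassified / excluded."""
    values = (rpkm_dw_sub, rpkm_ndw_sub, rpkm_after, rpkm_before)
    if any(v < 0 for v in values):
        raise ValueError("negative RPKM")
    if all(v == 0 for v in values):
        return "excluded"
    r_dw = _ratio(rpkm_dw_sub, rpkm_ndw_sub)
    r_ab = _ratio(rpkm_after, rpkm_before)
    if r_dw is None or r_ab is None:
        return "unclassified"
    if r_dw > up_cut and r_ab > up_cut:
        return "up"
    if r_dw < down_cut and r_ab < down_cut:
        return "down"
    return "unclassified"


def label_expression(expr: pd.DataFrame, up_cut=1.5, down_cut=0.67) -> pd.DataFrame:
    """Vectorized labelling of an expression table; adds ratio columns."""
    out = expr.copy()
    out["label"] = [
        classify_expression(r.rpkm_dw_sub, r.rpkm_ndw_sub, r.rpkm_after, r.rpkm_before,
                            up_cut, down_cut)
        for r in expr.itertuples()
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio_dw"] = np.where(
            expr["rpkm_ndw_sub"] > 0, expr["rpkm_dw_sub"] / expr["rpkm_ndw_sub"], np.nan
        )
        out["ratio_ab"] = np.where(
            expr["rpkm_before"] > 0, expr["rpkm_after"] / expr["rpkm_before"], np.nan
        )
    return out


def screen_candidates(regions: pd.DataFrame, genes: pd.DataFrame,
                      expr: pd.DataFrame, up_cut=1.5, down_cut=0.67) -> pd.DataFrame:
    """Genes overlapping any region, with their expression label.

    Candidates are the rows labelled ``up``/``down``; genes without
    expression data are reported with label ``no-data`` rather than dropped.
    """
    labelled = label_expression(expr, up_cut, down_cut).set_index("gene_id")
    rows = []
    for _, r in regions.iterrows():
        hit = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        for _, g in hit.iterrows():
            gid = g["gene_id"]
            if gid in labelled.index:
                rec = labelled.loc[gid]
                label, rdw, rab = rec["label"], rec["ratio_dw"], rec["ratio_ab"]
            else:
                label, rdw, rab = "no-data", np.nan, np.nan
            rows.append(
                {
                    "chrom": r["chrom"],
                    "region_start": int(r["start"]),
                    "region_end": int(r["end"]),
                    "gene_id": gid,
                    "label": label,
                    "ratio_dw": rdw,
                    "ratio_ab": rab,
                    "is_candidate": label in ("up", "down"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "region_start", "region_end", "gene_id", "label",
                 "ratio_dw", "ratio_ab", "is_candidate"],
    )


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Pseudo-haplotype strings over a region's SNPs, pooled per group."""

    haplotypes: list          # distinct haplotype strings
    counts: pd.DataFrame      # haplotype x group counts
    sample_hap: np.ndarray    # per retained sample: haplotype index
    sample_group: np.ndarray  # per retained sample: group label
    dropped: list             # sample ids dropped by the het/missing filter


def haplotype_table(G: GenotypeMatrix, region, groups: pd.DataFrame,
                    max_missing_frac=0.2) -> HaplotypeTable:
    """Build per-accession pseudo-haplotypes over the SNPs in ``region``
    (``(chrom, start, end)``, 0-based half-open).

    Hom-ref/hom-alt codes map to ref/alt alleles; heterozygous and missing
    codes are filled with the site's major allele when the accession's
    het+missing fraction is within ``max_missing_frac``, otherwise the
    accession is dropped.
    """
    chrom, start, end = region
    in_region = (G.chrom == chrom) & (G.pos - 1 >= start) & (G.pos - 1 < end)
    cols = np.flatnonzero(in_region)
    if cols.size == 0:
        raise ValueError(f"region {chrom}:{start}-{end} contains no SNPs")
    calls = G.calls[:, cols]
    group_of = dict(zip(groups["sample_id"], groups["group"]))

    # per-site major allele (0 or 1) over unambiguous calls
    hom_alt = (calls == 2).sum(axis=0)
    hom_ref = (calls == 0).sum(axis=0)
    major = (hom_alt > hom_ref).astype(np.int8)

    strings, hap_groups, retained, dropped = [], [], [], []
    for i, sid in enumerate(G.samples):
        if sid not in group_of:
            continue
        row = calls[i]
        fuzzy = (row == 1) | (row == MISSING)
        if fuzzy.mean() > max_missing_frac:
            dropped.append(sid)
            continue
        alleles = np.where(row == 2, 1, np.where(row == 0, 0, major)).astype(np.int8)
        strings.append("".join("01"[a] for a in alleles))
        hap_groups.append(group_of[sid])
        retained.append(sid)
    if not strings:
        raise ValueError(
            f"all accessions dropped (het+missing fraction > {max_missing_frac}) "
            f"in region {chrom}:{start}-{end}"
        )
    uniq = sorted(set(strings))
    hap_idx = {h: k for k, h in enumerate(uniq)}
    sample_hap = np.array([hap_idx[s] for s in strings], dtype=np.int64)
    sample_group = np.array(hap_groups, dtype=object)
    counts = pd.crosstab(
        pd.Series(strings, name="haplotype"), pd.Series(hap_groups, name="group")
    ).reindex(uniq)
    return HaplotypeTable(uniq, counts, sample_hap, sample_group, dropped)


def _chi2_stat(table: np.ndarray) -> float:
    """Pearson chi-square without continuity correction; zero-margin cells
    contribute nothing."""
    table = table.astype(float)
    rows = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = rows @ colsum / total
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(contrib.sum())


def haplotype_differentiation(tab: HaplotypeTable, n_perm=10_000, seed=0):
    """Chi-square statistic and label-permutation p-value for haplotype x
    group differentiation."""
    group_labels = sorted(set(tab.sample_group.tolist()))
    if len(group_labels) < 2:
        raise ValueError("need >= 2 groups")
    if len(tab.haplotypes) < 2:
        warnings.warn("single haplotype in region; no differentiation testable",
                      stacklevel=2)
        return 0.0, 1.0
    g_idx = {g: k for k, g in enumerate(group_labels)}
    groups = np.array([g_idx[g] for g in tab.sample_group], dtype=np.int64)
    n_hap = len(tab.haplotypes)
    n_grp = len(group_labels)

    def table_for(grp):
        return np.bincount(
            tab.sample_hap * n_grp + grp, minlength=n_hap * n_grp
        ).reshape(n_hap, n_grp)

    observed = _chi2_stat(table_for(groups))
    rng = np.random.default_rng(seed)
    count = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _chi2_stat(table_for(perm)) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, float(p)
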