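"""Standing / new / lost variant classification between an ecotype and its
immediate ancestral progenitor, with alternative-allele-frequency
differentiation (AFD) summaries.

Presence of a SNP in a population means its alternative-allele count among
non-missing calls reaches ``min_carrier_count`` (default 1). Frequencies are
computed over non-missing alleles; the literal printed alt/ref odds
convention is available behind a flag because it is unbounded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .popgen_windows import _grids_equal

CLASS_COLUMNS = ["chrom", "pos", "label", "p_eco", "p_prog", "afd", "flag"]
LABELS = ("standing", "new", "lost", "absent")


def alt_allele_frequency(G: GenotypeMatrix, samples, convention="fraction") -> np.ndarray:
    """Per-variant alternative-allele frequency for a sample subset.

    ``fraction`` returns alt/(alt+ref); ``odds`` returns the literal alt/ref
    ratio (inf when ref = 0). Variants without calls are NaN.
    """
    idx = G.sample_indices(samples)
    alt, called = G.allele_counts(idx)
    ref = called - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        if convention == "fraction":
            return np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        if convention == "odds":
            out = np.where(called > 0, alt / ref.astype(float), np.nan)
            return np.where((called > 0) & (ref == 0), np.inf, out)
    raise ValueError(f"unknown convention {convention!r}")


def classify_variants(G: GenotypeMatrix, eco_samples, prog_samples,
                      min_carrier_count=1) -> pd.DataFrame:
    """Label every variant standing/new/lost/absent for an ecotype versus its
    progenitor, with both populations' alt frequencies and the AFD."""
    if set(eco_samples) & set(prog_samples):
        raise ValueError("ecotype and progenitor sample sets must be disjoint")
    if len(eco_samples) < 2 or len(prog_samples) < 2:
        raise ValueError("both populations need >= 2 samples")
    ie = G.sample_indices(eco_samples)
    ip = G.sample_indices(prog_samples)
    alt_e, called_e = G.allele_counts(ie)
    alt_p, called_p = G.allele_counts(ip)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_e = np.where(called_e > 0, alt_e / np.maximum(called_e, 1), np.nan)
        p_p = np.where(called_p > 0, alt_p / np.maximum(called_p, 1), np.nan)
    in_e = alt_e >= min_carrier_count
    in_p = alt_p >= min_carrier_count
    label = np.where(
        in_e & in_p, "standing",
        np.where(in_e, "new", np.where(in_p, "lost", "absent")),
    )
    flag = np.where((called_e == 0) | (called_p == 0), "one-sided", "")
    afd = np.abs(np.nan_to_num(p_e) - np.nan_to_num(p_p))
    return pd.DataFrame(
        {
            "chrom": G.chrom,
            "pos": G.pos,
            "label": label,
            "p_eco": p_e,
            "p_prog": p_p,
            "afd": afd,
            "flag": flag,
        }
    )


def afd_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-label counts, fractions (over standing+new+lost), mean AFD and mean
    ecotype alt frequency. Both means are emitted because the headline
    proportions could be either."""
    if len(classes) == 0:
        raise ValueError("empty classification")
    kept = classes[classes["label"] != "absent"]
    total = len(kept)
    rows = []
    for label in ("standing", "new", "lost"):
        sub = kept[kept["label"] == label]
        rows.append(
            {
                "label": label,
                "n_snps": len(sub),
                "fraction": len(sub) / total if total else np.nan,
                "mean_afd": float(sub["afd"].mean()) if len(sub) else np.nan,
                "mean_p_eco": float(sub["p_eco"].mean()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def diversity_test(pi_windows_a: pd.DataFrame, pi_windows_b: pd.DataFrame):
    """Two-sided Mann-Whitney U comparing per-window pi between populations.

    Exact when either group is tiny (with a warning); otherwise the normal
    approximation with tie correction.
    """
    if not _grids_equal(pi_windows_a, pi_windows_b):
        raise ValueError("pi window grids do not match")
    a = pi_windows_a["value"].to_numpy(dtype=float)
    b = pi_windows_b["value"].to_numpy(dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    method = "auto"
    if min(len(a), len(b)) < 5:
        warnings.warn("fewer than 5 windows per group; forcing the exact test",
                      stacklevel=2)
        method = "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
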