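"""Sliding-window nucleotide diversity and Weir & Cockerham (1984) F_ST.

Window statistics are returned as data frames with columns
``chrom, start, end, n_snps, value`` (intervals 0-based half-open) and a
``flag`` column for degenerate windows. The window F_ST estimate is the
weighted ratio-of-sums sum(a) / sum(a+b+c) over in-window sites, matching
the VCFtools default; per-window pi divides by window length in bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "value", "flag"]


def make_windows(chrom_lengths: dict, size=100_000, step=50_000) -> pd.DataFrame:
    """Tile each chromosome from 0 with ``size``-bp windows offset by ``step``.

    The terminal window is truncated at the chromosome end; trailing windows
    fully contained in the previous one are not emitted.
    """
    if step <= 0 or size <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step > size would leave gaps between windows")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        start, prev_end = 0, -1
        while start < length:
            end = min(start + size, length)
            if end > prev_end:
                rows.append((chrom, start, end))
                prev_end = end
            start += step
    grid = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    grid.attrs["window_size"] = size
    grid.attrs["step"] = step
    return grid


def _grids_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    return len(a) == len(b) and (
        (a[["chrom", "start", "end"]].to_numpy() == b[["chrom", "start", "end"]].to_numpy())
        .all()
    )


def _window_sums(grid, chrom, pos, per_site_values, usable):
    """Sum per-site values into (possibly overlapping) windows.

    ``usable`` marks sites that count towards ``n_snps``. Sites are assumed
    coordinate-sorted. Returns (sums, n_snps) arrays aligned with ``grid``.
    """
    stacked = np.column_stack(per_site_values) if per_site_values else None
    n_stats = len(per_site_values)
    sums = np.zeros((len(grid), n_stats))
    n_snps = np.zeros(len(grid), dtype=np.int64)
    by_chrom = {}
    for c in np.unique(chrom):
        mask = chrom == c
        idx = np.flatnonzero(mask)
        by_chrom[c] = idx
    # prefix sums per chromosome for O(log n) window queries
    for w, (c, start, end) in enumerate(zip(grid["chrom"], grid["start"], grid["end"])):
        idx = by_chrom.get(c)
        if idx is None:
            continue
        p = pos[idx]
        lo = np.searchsorted(p, start + 1, side="left")
        hi = np.searchsorted(p, end, side="right")
        if hi <= lo:
            continue
        sel = idx[lo:hi]
        use = sel[usable[sel]]
        n_snps[w] = use.size
        if use.size and stacked is not None:
            sums[w, :] = stacked[use, :].sum(axis=0)
    return sums, n_snps


def site_pi(G: GenotypeMatrix, samples) -> tuple:
    """Per-site pairwise diversity 2*c_ref*c_alt / (n*(n-1)) over called
    alleles; returns (pi, called_alleles)."""
    idx = G.sample_indices(samples)
    alt, called = G.allele_counts(idx)
    ref = called - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(called >= 2, 2.0 * ref * alt / (called * np.maximum(called - 1, 1)), 0.0)
    return pi, called


def pi_windowed(G: GenotypeMatrix, samples, grid: pd.DataFrame) -> pd.DataFrame:
    """Windowed nucleotide diversity: sum of per-site pairwise diversity
    divided by window length in bp."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    pi, called = site_pi(G, samples)
    usable = called >= 2
    sums, n_snps = _window_sums(grid, G.chrom, G.pos, [pi], usable)
    length = (grid["end"] - grid["start"]).to_numpy()
    out = grid[["chrom", "start", "end"]].copy()
    out["n_snps"] = n_snps
    out["value"] = sums[:, 0] / length
    out["flag"] = ""
    out.attrs["statistic"] = "pi"
    return out


def wc_site_components(G: GenotypeMatrix, samplesA, samplesB):
    """Weir & Cockerham (1984) per-site variance components (a, b, c) for two
    populations, plus a usable-site mask.

    Sites monomorphic across both populations, or without called genotypes in
    either population, are flagged unusable.
    """
    iA = G.sample_indices(samplesA)
    iB = G.sample_indices(samplesB)
    comps = []
    for idx in (iA, iB):
        alt, called = G.allele_counts(idx)
        het = G.het_counts(idx)
        n_ind = called / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
            h = np.where(n_ind > 0, het / np.maximum(n_ind, 1), np.nan)
        comps.append((n_ind, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    usable = (n1 > 0) & (n2 > 0)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    # exclude monomorphic-across-both and single-individual-total edge cases
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    usable &= ~((pbar == 0.0) | (pbar == 1.0)) | (np.nan_to_num(hbar) > 0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def hudson_site_components(G: GenotypeMatrix, samplesA, samplesB):
    """Hudson (1992)-style per-site numerator/denominator (sensitivity
    alternative to Weir & Cockerham)."""
    iA = G.sample_indices(samplesA)
    iB = G.sample_indices(samplesB)
    out = []
    for idx in (iA, iB):
        alt, called = G.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        out.append((p, called))
    (p1, n1), (p2, n2) = out
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(
            n2 - 1, 1
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    usable &= np.isfinite(num) & (np.nan_to_num(den) > 0)
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0), usable


def fst_windowed(G: GenotypeMatrix, samplesA, samplesB, grid: pd.DataFrame,
                 estimator="wc"):
    """Windowed F_ST (ratio-of-sums) and the genome-wide mean.

    Returns ``(window_frame, genome_mean)``. Negative estimates are reported
    as-is; windows without usable sites are flagged ``undefined``.
    """
    if len(samplesA) < 2 or len(samplesB) < 2:
        raise ValueError("both populations need >= 2 samples")
    if estimator == "wc":
        a, b, c, usable = wc_site_components(G, samplesA, samplesB)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den, usable = hudson_site_components(G, samplesA, samplesB)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    sums, n_snps = _window_sums(grid, G.chrom, G.pos, [num, den], usable)
    out = grid[["chrom", "start", "end"]].copy()
    out["n_snps"] = n_snps
    with np.errstate(invalid="ignore", divide="ignore"):
        out["value"] = np.where(sums[:, 1] != 0, sums[:, 0] / sums[:, 1], np.nan)
    out["flag"] = np.where(n_snps == 0, "undefined", "")
    out.attrs["statistic"] = "fst"
    total_den = den[usable].sum()
    genome_mean = float(num[usable].sum() / total_den) if total_den != 0 else float("nan")
    return out, genome_mean
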