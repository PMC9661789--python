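"""Reading/writing of the standard formats the pipeline touches and the
sample/variant filters applied before every analysis.

Coordinate conventions: VCF positions are 1-based; BED intervals and every
internal window/region interval are 0-based half-open. Chromosome names are
passed through verbatim (no "chr" normalisation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing diploid genotype call
MISSING: int = -1

#: declared group vocabulary for sample tables
CULTIVATED_GROUPS = frozenset(
    {
        "DW", "SW", "TW", "IR", "RL", "UP", "Aus",
        "DW-XI", "SW-XI", "TW-XI",
        "IR-XI", "IR-GJ", "RL-XI", "RL-GJ", "UP-XI", "UP-GJ",
    }
)
WILD_GROUPS = frozenset({"Or", "OrI", "OrII", "On", "Ob", "Ol", "Om", "Oglu", "Ogla"})

EXPRESSION_COLUMNS = ["gene_id", "rpkm_dw_sub", "rpkm_ndw_sub", "rpkm_after", "rpkm_before"]


class VcfParseError(ValueError):
    """Raised when a VCF record/header cannot be parsed."""


@dataclass(eq=False)
class GenotypeMatrix:
    """samples x biallelic-SNP genotype matrix.

    ``calls[i, j]`` counts alternative alleles of sample ``i`` at variant
    ``j`` (0/1/2) or is :data:`MISSING`. Variants are sorted by
    ``(chrom, pos)`` with no duplicate coordinate.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    skipped_records: int = 0

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_variants):
            raise ValueError("calls shape does not match samples x variants")
        key = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if key != sorted(key):
            raise ValueError("variants not sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) variant")
        codes = np.unique(self.calls)
        bad = set(codes.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return replace(self, samples=list(names), calls=self.calls[idx, :])

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
        )

    def allele_counts(self, sample_idx=None):
        """Return ``(alt_alleles, called_alleles)`` per variant.

        Missing genotypes contribute neither alt nor called alleles.
        """
        calls = self.calls if sample_idx is None else self.calls[sample_idx, :]
        missing = calls == MISSING
        alt = np.where(missing, 0, calls).sum(axis=0)
        called = 2 * (calls.shape[0] - missing.sum(axis=0))
        return alt.astype(np.int64), called.astype(np.int64)

    def het_counts(self, sample_idx=None) -> np.ndarray:
        calls = self.calls if sample_idx is None else self.calls[sample_idx, :]
        return (calls == 1).sum(axis=0).astype(np.int64)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            list(self.samples) == list(other.samples)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


def make_genotype_matrix(samples, chrom, pos, ref, alt, calls, skipped=0) -> GenotypeMatrix:
    """Build a validated, coordinate-sorted :class:`GenotypeMatrix`."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    calls = np.asarray(calls, dtype=np.int8)
    order = np.lexsort((pos, chrom))
    G = GenotypeMatrix(
        samples=list(samples),
        chrom=chrom[order],
        pos=pos[order],
        ref=ref[order],
        alt=alt[order],
        calls=calls[:, order],
        skipped_records=skipped,
    )
    G.validate()
    return G


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def _parse_region(region):
    if region is None:
        return None
    if isinstance(region, (tuple, list)):
        chrom, start, end = region
        return str(chrom), int(start), int(end)
    chrom, _, span = str(region).partition(":")
    if not span:
        return chrom, 0, np.iinfo(np.int64).max
    lo, _, hi = span.partition("-")
    # region strings are 1-based inclusive; convert to 0-based half-open
    return chrom, int(lo) - 1, int(hi)


def read_vcf(path, region=None) -> GenotypeMatrix:
    """Read a VCF with GT into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged and stored on
    ``skipped_records``); half-calls and ``./.`` become :data:`MISSING`.
    ``region`` is ``"chrom:start-end"`` (1-based inclusive) or a 0-based
    half-open ``(chrom, start, end)`` tuple.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    samples = list(vcf.samples)
    reg = _parse_region(region)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    skipped = 0
    recno = 0
    try:
        for rec in vcf:
            recno += 1
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                skipped += 1
                continue
            if rec.REF.upper() not in _BASES or rec.ALT[0].upper() not in _BASES:
                skipped += 1
                continue
            if reg is not None:
                c, lo, hi = reg
                if rec.CHROM != c or not (lo < rec.POS <= hi):
                    continue
            codes = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1] if len(gt) > 2 else -1
                codes[i] = MISSING if (a < 0 or b < 0) else a + b
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            rows.append(codes)
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error at record {recno + 1}: {exc}") from exc
    finally:
        vcf.close()
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic/non-SNP records", path, skipped)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return make_genotype_matrix(samples, chroms, poss, refs, alts, calls, skipped=skipped)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path, chrom_lengths=None) -> None:
    """Write a minimal deterministic VCF v4.2 (GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for c in sorted(chrom_lengths):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for j in range(G.n_variants):
            gts = "\t".join(_GT_STR[int(c)] for c in G.calls[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t.\t{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def variant_missing_rate(G: GenotypeMatrix) -> np.ndarray:
    if G.n_samples == 0:
        return np.zeros(G.n_variants)
    return (G.calls == MISSING).sum(axis=0) / G.n_samples


def variant_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency over non-missing called alleles (NaN if none)."""
    alt, called = G.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return np.fmin(p, 1.0 - p)


def filter_variants(G: GenotypeMatrix, max_missing_rate=0.5, min_maf=0.05) -> GenotypeMatrix:
    """Keep variants with missing fraction <= ``max_missing_rate`` and MAF >=
    ``min_maf`` (both boundaries inclusive, as printed)."""
    for name, v in (("max_missing_rate", max_missing_rate), ("min_maf", min_maf)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    maf = variant_maf(G)
    keep = (variant_missing_rate(G) <= max_missing_rate) & (
        np.nan_to_num(maf, nan=-1.0) >= min_maf
    )
    out = G.subset_variants(keep)
    if out.n_variants == 0:
        warnings.warn("filter_variants removed every variant", stacklevel=2)
    logger.info("filter_variants: %d -> %d variants", G.n_variants, out.n_variants)
    return out


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "group", "q_value"]


def make_sample_table(sample_ids, groups, q_values=None) -> pd.DataFrame:
    q = [np.nan] * len(sample_ids) if q_values is None else list(q_values)
    df = pd.DataFrame({"sample_id": list(sample_ids), "group": list(groups), "q_value": q})
    _check_sample_table(df)
    return df


def _check_sample_table(df: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    _check_sample_table(df)
    df["q_value"] = pd.to_numeric(df["q_value"], errors="coerce")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    _check_sample_table(df)
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS, float_format="%.6g")


def select_core_samples(T: pd.DataFrame, min_q=0.8, keep_missing_q=False) -> pd.DataFrame:
    """Keep samples with ancestry ``q_value`` strictly greater than ``min_q``.

    Samples without a q value (e.g. wild accessions) are dropped unless
    ``keep_missing_q`` is set.
    """
    if not (0.0 <= min_q <= 1.0):
        raise ValueError(f"min_q must be in [0, 1], got {min_q}")
    q = pd.to_numeric(T["q_value"], errors="coerce")
    keep = q > min_q
    if keep_missing_q:
        keep = keep | q.isna()
    return T.loc[keep].reset_index(drop=True)


def samples_in_group(T: pd.DataFrame, groups) -> list:
    if isinstance(groups, str):
        groups = [groups]
    return T.loc[T["group"].isin(groups), "sample_id"].tolist()


def panel_summary(T: pd.DataFrame) -> dict:
    """Per-group counts plus cultivated/wild panel totals from the declared
    group vocabulary."""
    counts = T["group"].value_counts().to_dict()
    cultivated = int(sum(n for g, n in counts.items() if g in CULTIVATED_GROUPS))
    wild = int(sum(n for g, n in counts.items() if g in WILD_GROUPS))
    return {
        "per_group": counts,
        "cultivated_total": cultivated,
        "wild_total": wild,
        "total": int(len(T)),
    }


# ---------------------------------------------------------------------------
# Genes / BED
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def make_gene_set(gene_ids, chroms, starts, ends, strands=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "chrom": list(chroms),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": ["+"] * len(gene_ids) if strands is None else list(strands),
        }
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"gene {bad['gene_id']!r} has start >= end")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def read_genes(path) -> pd.DataFrame:
    """Read a BED6 (or BED4) gene file; intervals are 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene BED needs at least 4 columns (chrom,start,end,name)")
    strands = df[5].tolist() if df.shape[1] >= 6 else None
    return make_gene_set(df[3], df[0].astype(str), df[1], df[2], strands)


def write_bed(df: pd.DataFrame, path, name_col="gene_id", score=".") -> None:
    """Emit sorted BED6 with 0-based half-open intervals."""
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with Path(path).open("w") as fh:
        for _, row in out.iterrows():
            strand = row["strand"] if "strand" in out.columns else "+"
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row[name_col]}\t{score}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression / generic TSV
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
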