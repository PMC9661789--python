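"""Forward Wright-Fisher simulator for a wild -> progenitor -> ecotype
domestication history, plus expression-table and fixture generation.

The simulator is deliberately desk-scale (megabase chromosomes, hundreds of
diploids) and produces the structure the downstream scans assume: reduced
diversity after bottlenecks, planted diversity-reducing sweeps, post-split
new mutations, near-complete homozygosity under high selfing, missing
genotypes, and a four-condition RPKM table with planted up/down genes.

Random numbers come from one master seed; each stage (burn-in/evolution,
missingness, expression, phenotypes) draws from its own child stream so the
streams are reproducible independently.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    make_gene_set,
    make_genotype_matrix,
    make_sample_table,
    write_bed,
    write_sample_table,
    write_tsv,
    write_vcf,
)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    pop_sizes: dict = field(
        default_factory=lambda: {"wild": 200, "progenitor": 200, "ecotype": 200}
    )
    split_generations: dict = field(
        default_factory=lambda: {"wild->progenitor": 400, "progenitor->ecotype": 200}
    )
    bottleneck_size: int = 40
    bottleneck_duration: int = 20
    mutation_rate: float = 2.5e-7
    recombination_rate: float = 1e-7
    selfing_rate: float = 0.99
    sweep_loci: list = field(default_factory=list)  # (chrom, center_bp, width_bp, target_pop)
    sweep_strength: float = 5.0
    missing_rate: float = 0.02
    seed: int = 0
    burn_in_factor: float = 8.0
    sample_sizes: dict | None = None
    group_labels: dict = field(
        default_factory=lambda: {"wild": "Or", "progenitor": "IR-XI", "ecotype": "DW"}
    )

    def validate(self) -> None:
        for name in ("mutation_rate", "recombination_rate", "selfing_rate", "missing_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SimConfigError(f"{name} must be finite and >= 0, got {v}")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise SimConfigError("selfing_rate must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise SimConfigError("chromosome counts/lengths must be positive")
        for pop in ("wild", "progenitor", "ecotype"):
            if self.pop_sizes.get(pop, 0) < 2:
                raise SimConfigError(f"pop_sizes[{pop!r}] must be >= 2")
        if self.bottleneck_size < 2 or self.bottleneck_duration < 0:
            raise SimConfigError("bottleneck_size >= 2 and bottleneck_duration >= 0 required")
        g1 = self.split_generations.get("wild->progenitor")
        g2 = self.split_generations.get("progenitor->ecotype")
        if g1 is None or g2 is None or g1 <= 0 or g2 <= 0 or g1 <= g2:
            raise SimConfigError(
                "split_generations must give wild->progenitor > progenitor->ecotype > 0"
            )
        if self.sweep_strength < 1.0:
            raise SimConfigError("sweep_strength must be >= 1")
        for chrom, center, width, target in self.sweep_loci:
            if target not in self.pop_sizes:
                raise SimConfigError(f"sweep target {target!r} not a population")
            if not (0 <= center - width / 2 and center + width / 2 <= self.chrom_length_bp):
                raise SimConfigError(f"sweep at {chrom}:{center} extends outside chromosome")

    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: SimConfig) -> str:
    """Stable content hash of a configuration (covers the seed)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    sweep_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    new_mutation_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_genes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

class _Pop:
    """Haplotypes of one population over its currently-segregating sites.

    ``gpos`` holds genome-global coordinates (chrom_index * L + offset);
    sites fixed for the alt allele are moved to ``fixed`` (every descendant
    haplotype carries them), lost sites are dropped.
    """

    __slots__ = ("H", "gpos", "fixed")

    def __init__(self, H, gpos, fixed):
        self.H = H          # (2N, S) uint8
        self.gpos = gpos    # (S,) int64
        self.fixed = fixed  # set of int

    @property
    def n_dip(self) -> int:
        return self.H.shape[0] // 2

    def compact(self) -> None:
        if self.H.shape[1] == 0:
            return
        tot = self.H.sum(axis=0)
        lost = tot == 0
        fixed = tot == self.H.shape[0]
        if fixed.any():
            self.fixed.update(self.gpos[fixed].tolist())
        keep = ~(lost | fixed)
        if not keep.all():
            self.H = np.ascontiguousarray(self.H[:, keep])
            self.gpos = self.gpos[keep]


def _reproduce(pop: _Pop, n_off: int, selfing: float, L: int, n_chrom: int,
               r_per_chrom: float, rng: np.random.Generator) -> None:
    """One non-overlapping Wright-Fisher generation with partial selfing."""
    N = pop.n_dip
    p1 = rng.integers(0, N, size=n_off)
    self_mask = rng.random(n_off) < selfing
    p2 = np.where(self_mask, p1, rng.integers(0, N, size=n_off))
    parents = np.empty(2 * n_off, dtype=np.int64)
    parents[0::2] = p1
    parents[1::2] = p2

    S = pop.H.shape[1]
    if S == 0:
        pop.H = np.zeros((2 * n_off, 0), dtype=np.uint8)
        return
    chrom_of = (pop.gpos // L).astype(np.int64)
    start = rng.integers(0, 2, size=(2 * n_off, n_chrom), dtype=np.int8)
    src = start[:, chrom_of]
    n_x = rng.poisson(r_per_chrom, size=(2 * n_off, n_chrom))
    offset = pop.gpos % L
    for g, c in zip(*np.nonzero(n_x)):
        bps = np.sort(rng.integers(0, L, size=n_x[g, c]))
        on_c = chrom_of == c
        src[g, on_c] ^= (np.searchsorted(bps, offset[on_c]) % 2).astype(np.int8)
    rows = 2 * parents[:, None] + src
    pop.H = pop.H[rows, np.arange(S)[None, :]]


def _mutate(pop: _Pop, mu: float, L: int, n_chrom: int, registry: set,
            origins: dict, origin_tag, rng: np.random.Generator) -> None:
    n_hap = pop.H.shape[0]
    lam = n_hap * L * n_chrom * mu
    n_mut = rng.poisson(lam)
    if n_mut == 0:
        return
    new_pos, rows = [], []
    for _ in range(n_mut):
        g = int(rng.integers(0, L * n_chrom))
        if g in registry:
            continue  # infinite-sites: silently drop the rare collision
        registry.add(g)
        origins[g] = origin_tag
        new_pos.append(g)
        rows.append(int(rng.integers(0, n_hap)))
    if not new_pos:
        return
    block = np.zeros((n_hap, len(new_pos)), dtype=np.uint8)
    block[rows, np.arange(len(new_pos))] = 1
    pop.H = np.concatenate([pop.H, block], axis=1)
    pop.gpos = np.concatenate([pop.gpos, np.asarray(new_pos, dtype=np.int64)])


class _Sweep:
    """Deterministic logistic frequency trajectory of a stored haplotype
    segment; enforced by overwriting the window of randomly chosen
    haplotypes each generation."""

    __slots__ = ("chrom_idx", "lo", "hi", "alleles", "f0", "f1", "rate", "t",
                 "duration", "strength", "baseline_pi")

    def __init__(self, chrom_idx, lo, hi, alleles, n_dip, strength, duration,
                 baseline_pi=None):
        self.chrom_idx = chrom_idx
        self.lo = lo
        self.hi = hi
        self.alleles = alleles  # dict gpos -> 0/1 captured at planting
        self.f0 = 1.0 / (2 * n_dip)
        # final frequency chosen so that pairwise diversity drops by ~strength:
        # pi_after/pi_before ~= 1 - p^2  =>  p = sqrt(1 - 1/strength)
        self.f1 = min(math.sqrt(max(1.0 - 1.0 / strength, 0.0)), 1.0 - self.f0)
        self.duration = max(duration, 1)
        # logistic rate so f(duration) == f1 starting from f0
        a0 = self.f0 / (1 - self.f0)
        a1 = self.f1 / (1 - self.f1) if self.f1 < 1 else 1e6
        self.rate = math.log(a1 / a0) / self.duration
        self.t = 0
        self.strength = strength
        self.baseline_pi = baseline_pi

    def frequency(self) -> float:
        a0 = self.f0 / (1 - self.f0)
        a = a0 * math.exp(self.rate * min(self.t, self.duration))
        return a / (1 + a)

    def enforce(self, pop: _Pop, L: int, rng: np.random.Generator) -> None:
        """Top up the carrier frequency to the logistic target.

        Carriers are identified by matching planted alt alleles at marker
        sites near the window centre; only the deficit below the target is
        converted, so non-carrier lineages persist and the final diversity
        reduction tracks 1 - f1^2 rather than collapsing to fixation.
        """
        self.t += 1
        f = self.frequency()
        n_hap = pop.H.shape[0]
        in_win = (pop.gpos // L == self.chrom_idx) & (pop.gpos % L >= self.lo) & (
            pop.gpos % L < self.hi
        )
        cols = np.flatnonzero(in_win)
        if cols.size == 0:
            return
        planted = np.array(
            [self.alleles.get(int(g), -1) for g in pop.gpos[cols]], dtype=np.int16
        )
        pcols = cols[planted >= 0]
        pvals = planted[planted >= 0].astype(np.uint8)
        if pcols.size == 0:
            return  # every planted site fixed or lost; nothing to track
        # markers: planted alt alleles, preferring the rarest (those are the
        # most carrier-specific; common alt alleles would count non-carriers
        # as carriers and stall the trajectory)
        is_alt = pvals == 1
        mcols, mvals = (pcols[is_alt], pvals[is_alt]) if is_alt.any() else (pcols, pvals)
        if mcols.size > 12:
            freq = pop.H[:, mcols].mean(axis=0)
            order = np.argsort(freq, kind="stable")[:12]
            mcols, mvals = mcols[order], mvals[order]
        match = (pop.H[:, mcols] == mvals[None, :]).all(axis=1)
        deficit = int(round(f * n_hap)) - int(match.sum())
        if deficit > 0:
            non_carriers = np.flatnonzero(~match)
            conv = rng.choice(non_carriers, size=min(deficit, non_carriers.size),
                              replace=False)
            pop.H[np.ix_(conv, pcols)] = pvals[None, :]
            match[conv] = True
        # after the trajectory completes, top up conversions until the window
        # diversity actually sits at ~ baseline/strength: under selfing, deep
        # lineage structure can otherwise leave 2p(1-p) x (deep divergence)
        # diversity exceeding the target
        if self.t >= self.duration and self.baseline_pi is not None:
            target_pi = self.baseline_pi / self.strength
            length = self.hi - self.lo
            for _ in range(20):
                freq = pop.H[:, cols].mean(axis=0)
                pi = float(np.sum(2.0 * freq * (1.0 - freq))) * n_hap / (n_hap - 1) / length
                non_carriers = np.flatnonzero(~match)
                if pi <= target_pi or non_carriers.size <= 2:
                    break
                conv = rng.choice(non_carriers,
                                  size=min(max(n_hap // 40, 1), non_carriers.size),
                                  replace=False)
                pop.H[np.ix_(conv, pcols)] = pvals[None, :]
                match[conv] = True


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig):
    """Run the forward simulation.

    Returns ``(G, sample_table, truth)`` where ``G`` includes injected
    missingness at ``config.missing_rate``. Deterministic for a fixed
    config/seed (content-hash stable).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    evo_seed, miss_seed, samp_seed = ss.spawn(3)
    rng = np.random.default_rng(evo_seed)

    L = config.chrom_length_bp
    n_chrom = config.n_chromosomes
    mu = config.mutation_rate
    r_per_chrom = config.recombination_rate * L
    selfing = config.selfing_rate

    registry: set = set()
    origins: dict = {}

    pops = {
        "wild": _Pop(
            np.zeros((2 * config.pop_sizes["wild"], 0), dtype=np.uint8),
            np.empty(0, dtype=np.int64),
            set(),
        )
    }

    g1 = config.split_generations["wild->progenitor"]
    g2 = config.split_generations["progenitor->ecotype"]

    # sweep bookkeeping: start each sweep so it completes at the present
    sweep_specs = []
    realized_rows = []
    for chrom, center, width, target in config.sweep_loci:
        n_dip = config.pop_sizes[target]
        duration = max(int(math.ceil(0.2 * n_dip)), 1)
        # the sweep must fit inside the target population's lifetime
        lifetime = g2 if target == "ecotype" else g1
        duration = min(duration, lifetime)
        start = duration
        sweep_specs.append(
            {
                "chrom": chrom,
                "lo": int(center - width // 2),
                "hi": int(center + width // 2),
                "target": target,
                "start_gen": start,  # generations before present
                "duration": duration,
                "obj": None,
            }
        )

    def step(pop_name, gens_before_present):
        """Advance one generation of one population."""
        pop = pops[pop_name]
        _mutate(pop, mu, L, n_chrom, registry, origins, pop_name, rng)
        _reproduce(pop, pop.n_dip, selfing, L, n_chrom, r_per_chrom, rng)
        for spec in sweep_specs:
            if spec["target"] != pop_name:
                continue
            if gens_before_present == spec["start_gen"] and spec["obj"] is None:
                spec["obj"] = _plant_sweep(pop, spec, config, L, realized_rows, rng)
            if spec["obj"] is not None and gens_before_present <= spec["start_gen"]:
                spec["obj"].enforce(pop, L, rng)
        pop.compact()

    # burn-in of the wild population
    burn = int(math.ceil(config.burn_in_factor * config.pop_sizes["wild"]))
    for _ in range(burn):
        step("wild", g1 + 1)  # sweeps never target this phase

    def fork(parent_name, child_name):
        parent = pops[parent_name]
        founders = rng.choice(parent.n_dip, size=config.bottleneck_size, replace=False)
        rows = np.stack([2 * founders, 2 * founders + 1], axis=1).reshape(-1)
        pops[child_name] = _Pop(
            np.ascontiguousarray(parent.H[rows, :]), parent.gpos.copy(), set(parent.fixed)
        )

    def grow(pop_name):
        pop = pops[pop_name]
        target = config.pop_sizes[pop_name]
        if pop.n_dip == target:
            return
        picks = rng.integers(0, pop.n_dip, size=target)
        rows = np.stack([2 * picks, 2 * picks + 1], axis=1).reshape(-1)
        pop.H = np.ascontiguousarray(pop.H[rows, :])

    # wild -> progenitor split at g1 generations before present
    fork("wild", "progenitor")
    for t in range(g1, g2, -1):  # from g1 down to g2+1 before present
        if t == g1 - config.bottleneck_duration:
            grow("progenitor")
        step("wild", t)
        step("progenitor", t)
    if g1 - config.bottleneck_duration <= g2:
        grow("progenitor")

    # progenitor -> ecotype split at g2 generations before present
    fork("progenitor", "ecotype")
    for t in range(g2, 0, -1):
        if t == g2 - config.bottleneck_duration:
            grow("ecotype")
        step("wild", t)
        step("progenitor", t)
        step("ecotype", t)
    if g2 - config.bottleneck_duration <= 0:
        grow("ecotype")

    G, table = _assemble(pops, config, np.random.default_rng(samp_seed))
    G = inject_missing(G, config.missing_rate, miss_seed)

    truth = SimTruth(
        sweep_windows=pd.DataFrame(
            realized_rows, columns=["population", "chrom", "start", "end", "realized"]
        ),
        new_mutation_sites=_new_mutation_truth(origins, G, L),
        causal_snps=pd.DataFrame(columns=["chrom", "pos", "effect"]),
        de_genes={},
    )
    return G, table, truth


def _plant_sweep(pop: _Pop, spec, config: SimConfig, L, realized_rows, rng):
    chrom_idx = config.chrom_names().index(spec["chrom"])
    in_win = (pop.gpos // L == chrom_idx) & (pop.gpos % L >= spec["lo"]) & (
        pop.gpos % L < spec["hi"]
    )
    cols = np.flatnonzero(in_win)
    row = [spec["target"], spec["chrom"], spec["lo"], spec["hi"], True]
    if cols.size == 0:
        warnings.warn(
            f"sweep window {spec['chrom']}:{spec['lo']}-{spec['hi']} monomorphic at "
            "planting time; sweep skipped",
            stacklevel=2,
        )
        row[-1] = False
        realized_rows.append(row)
        return None
    realized_rows.append(row)
    # backbone = a random haplotype carrying at least one alt allele in the
    # window (a typical haplotype; an atypical one would add back 2p(1-p)
    # carrier/non-carrier diversity and cancel the intended reduction)
    alt_counts = pop.H[:, cols].sum(axis=1)
    candidates = np.flatnonzero(alt_counts > 0)
    hap = int(rng.choice(candidates)) if candidates.size else int(np.argmax(alt_counts))
    alleles = {int(g): int(a) for g, a in zip(pop.gpos[cols], pop.H[hap, cols])}
    n_hap = pop.H.shape[0]
    freq = pop.H[:, cols].mean(axis=0)
    baseline_pi = float(np.sum(2.0 * freq * (1.0 - freq))) * n_hap / (n_hap - 1) / (
        spec["hi"] - spec["lo"]
    )
    return _Sweep(chrom_idx, spec["lo"], spec["hi"], alleles, pop.n_dip,
                  config.sweep_strength, spec["duration"], baseline_pi)


def _new_mutation_truth(origins: dict, G: GenotypeMatrix, L: int) -> pd.DataFrame:
    emitted = set(zip(G.chrom.tolist(), G.pos.tolist()))
    rows = []
    for g, pop_name in sorted(origins.items()):
        if pop_name == "wild":
            continue
        chrom = f"chr{g // L + 1}"
        pos = int(g % L) + 1
        rows.append((pop_name, chrom, pos, (chrom, pos) in emitted))
    return pd.DataFrame(rows, columns=["population", "chrom", "pos", "present"])


def _assemble(pops: dict, config: SimConfig, rng: np.random.Generator):
    L = config.chrom_length_bp
    all_g = set()
    for pop in pops.values():
        all_g.update(pop.gpos.tolist())
        all_g.update(pop.fixed)
    gpos = np.asarray(sorted(all_g), dtype=np.int64)

    sample_sizes = config.sample_sizes or {
        name: min(pops[name].n_dip, 40) for name in pops
    }
    sample_ids, groups, qvals, blocks = [], [], [], []
    for name in ("wild", "progenitor", "ecotype"):
        pop = pops[name]
        k = min(sample_sizes.get(name, 0), pop.n_dip)
        if k == 0:
            continue
        picks = np.sort(rng.choice(pop.n_dip, size=k, replace=False))
        idx = {g: j for j, g in enumerate(pop.gpos.tolist())}
        codes = np.zeros((k, len(gpos)), dtype=np.int8)
        cols_in_pop = np.asarray([idx.get(g, -1) for g in gpos], dtype=np.int64)
        has = cols_in_pop >= 0
        if has.any():
            sub = pop.H[:, cols_in_pop[has]]
            codes[:, has] = (sub[2 * picks, :] + sub[2 * picks + 1, :]).astype(np.int8)
        if pop.fixed:
            fixed_mask = np.isin(gpos, np.asarray(sorted(pop.fixed), dtype=np.int64))
            codes[:, fixed_mask] = 2
        blocks.append(codes)
        label = config.group_labels.get(name, name)
        for i in range(k):
            sample_ids.append(f"{name.upper()}_{i:03d}")
            groups.append(label)
            qvals.append(np.nan if name == "wild" else 1.0)
    calls = np.concatenate(blocks, axis=0) if blocks else np.empty((0, len(gpos)), np.int8)

    # keep only sites carrying at least one alt allele among the samples
    seg = (calls > 0).any(axis=0)
    calls = calls[:, seg]
    gpos = gpos[seg]

    chroms = [f"chr{g // L + 1}" for g in gpos]
    positions = (gpos % L) + 1
    bases = np.array(list("ACGT"))
    ref = bases[gpos % 4]
    alt = bases[(gpos % 4 + 1 + gpos % 3) % 4]
    G = make_genotype_matrix(sample_ids, chroms, positions, ref, alt, calls)
    table = make_sample_table(sample_ids, groups, qvals)
    return G, table


# ---------------------------------------------------------------------------
# missingness / expression / phenotype helpers
# ---------------------------------------------------------------------------

def inject_missing(G: GenotypeMatrix, rate, seed) -> GenotypeMatrix:
    """Set each genotype to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return G
    rng = np.random.default_rng(seed)
    mask = rng.random(G.calls.shape) < rate
    calls = G.calls.copy()
    calls[mask] = MISSING
    import dataclasses

    return dataclasses.replace(G, calls=calls)


def make_genes(config: SimConfig, n_genes=60, gene_length=2000, seed=0) -> pd.DataFrame:
    """Evenly spaced gene models covering the simulated chromosomes."""
    rng = np.random.default_rng(seed)
    ids, chroms, starts, ends, strands = [], [], [], [], []
    per_chrom = max(n_genes // config.n_chromosomes, 1)
    i = 0
    for chrom in config.chrom_names():
        spacing = config.chrom_length_bp // (per_chrom + 1)
        for j in range(per_chrom):
            start = (j + 1) * spacing
            ids.append(f"GENE_{i:04d}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(min(start + gene_length, config.chrom_length_bp))
            strands.append("+" if rng.random() < 0.5 else "-")
            i += 1
    return make_gene_set(ids, chroms, starts, ends, strands)


def plant_de_genes(genes: pd.DataFrame, n_up=3, n_down=3, seed=0) -> dict:
    """Pick up-/down-regulated truth genes from a gene set."""
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(genes), size=min(n_up + n_down, len(genes)), replace=False)
    ids = genes["gene_id"].to_numpy()[picks]
    return {g: ("up" if i < n_up else "down") for i, g in enumerate(ids)}


def simulate_expression(genes: pd.DataFrame, truth: SimTruth, fold_up=3.0,
                        fold_down=0.3, noise_sd=0.2, seed=0,
                        zero_fraction=0.05, baseline_rpkm=20.0) -> pd.DataFrame:
    """Four-condition RPKM table with planted differential genes.

    Planted genes have both the submerged deepwater/non-deepwater ratio and
    the after/before ratio shifted by the fold factor; a ``zero_fraction`` of
    the remaining genes gets all four values exactly 0.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if not fold_up > 1.5:
        raise ValueError("fold_up must exceed the 1.5 detection threshold")
    if not fold_down < 0.67:
        raise ValueError("fold_down must be below the 0.67 detection threshold")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    de = truth.de_genes or {}
    rows = []
    gene_ids = genes["gene_id"].tolist()
    n_zero = int(round(zero_fraction * len(gene_ids)))
    zero_pool = [g for g in gene_ids if g not in de]
    zero_ids = set(
        rng.choice(zero_pool, size=min(n_zero, len(zero_pool)), replace=False).tolist()
    )
    for gid in gene_ids:
        if gid in zero_ids:
            rows.append((gid, 0.0, 0.0, 0.0, 0.0))
            continue
        base = baseline_rpkm * math.exp(rng.normal(0.0, 0.5)) if noise_sd > 0 else baseline_rpkm
        fold = {"up": fold_up, "down": fold_down}.get(de.get(gid), 1.0)
        eps = np.exp(rng.normal(0.0, noise_sd, size=4)) if noise_sd > 0 else np.ones(4)
        rows.append(
            (
                gid,
                base * fold * eps[0],  # deepwater, submerged
                base * eps[1],         # non-deepwater, submerged
                base * fold * eps[2],  # deepwater variety, after submergence
                base * eps[3],         # deepwater variety, before submergence
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "rpkm_dw_sub", "rpkm_ndw_sub", "rpkm_after", "rpkm_before"]
    )


def choose_causal_snps(G: GenotypeMatrix, n_causal=3, effect=1.0, seed=0,
                       min_maf=0.1) -> pd.DataFrame:
    """Pick well-spread common SNPs to act as causal sites for a phenotype."""
    from .genotype_io import variant_maf

    rng = np.random.default_rng(seed)
    ok = np.flatnonzero(np.nan_to_num(variant_maf(G), nan=0.0) >= min_maf)
    if ok.size < n_causal:
        raise ValueError("not enough common SNPs to choose causal sites")
    picks = np.sort(rng.choice(ok, size=n_causal, replace=False))
    return pd.DataFrame(
        {
            "chrom": G.chrom[picks],
            "pos": G.pos[picks],
            "effect": [effect] * n_causal,
        }
    )


def liability_phenotype(G: GenotypeMatrix, causal: pd.DataFrame, noise_sd=0.5,
                        case_fraction=0.3, seed=0) -> np.ndarray:
    """Binary phenotype from a liability threshold over planted SNP effects."""
    rng = np.random.default_rng(seed)
    key = {(c, p): e for c, p, e in zip(causal["chrom"], causal["pos"], causal["effect"])}
    liab = rng.normal(0.0, noise_sd, size=G.n_samples)
    for j in range(G.n_variants):
        e = key.get((G.chrom[j], int(G.pos[j])))
        if e is None:
            continue
        g = G.calls[:, j].astype(float)
        g[g == MISSING] = np.nanmean(np.where(g == MISSING, np.nan, g))
        liab += e * g
    cut = np.quantile(liab, 1.0 - case_fraction)
    return (liab >= cut).astype(np.int8)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(G: GenotypeMatrix, table: pd.DataFrame, genes: pd.DataFrame,
                  expression: pd.DataFrame, truth: SimTruth, config: SimConfig,
                  out_dir) -> dict:
    """Write VCF + TSV/BED fixtures and a manifest (paths, seed, config hash)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "genes": out / "genes.bed",
        "expression": out / "expression.tsv",
        "truth_sweeps": out / "truth_sweeps.tsv",
        "truth_new_mutations": out / "truth_new_mutations.tsv",
        "truth_causal": out / "truth_causal_snps.tsv",
        "truth_de_genes": out / "truth_de_genes.tsv",
    }
    write_vcf(G, paths["vcf"], chrom_lengths=config.chrom_lengths())
    write_sample_table(table, paths["samples"])
    write_bed(genes, paths["genes"])
    write_tsv(expression, paths["expression"])
    write_tsv(truth.sweep_windows, paths["truth_sweeps"])
    write_tsv(truth.new_mutation_sites, paths["truth_new_mutations"])
    write_tsv(truth.causal_snps, paths["truth_causal"])
    de = pd.DataFrame(
        sorted(truth.de_genes.items()), columns=["gene_id", "direction"]
    )
    write_tsv(de, paths["truth_de_genes"])
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "files": {k: v.name for k, v in sorted(paths.items())},  # relative to out_dir
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
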