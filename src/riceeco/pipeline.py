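"""Configuration-driven orchestration of the full analysis DAG.

Stages: simulate -> filter -> windows -> sweeps -> classify -> gwas ->
candidates. Every stage is idempotent (re-running with the same config/seed
rewrites byte-identical outputs); the manifest records the config hash, the
seeds, and every emitted file. Timestamps go to the per-run log, not the
manifest, so manifests from identical runs compare equal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import candidate_screen as cs
from . import ecotype_gwas as gw
from . import genotype_io as gio
from . import sweep_detection as sd
from . import synthetic_data as syn
from . import variation_typing as vt
from . import popgen_windows as pw

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "windows", "sweeps", "classify", "gwas", "candidates"]

_DEPS = {
    "simulate": [],
    "filter": ["simulate"],
    "windows": ["filter"],
    "sweeps": ["windows"],
    "classify": ["filter"],
    "gwas": ["filter"],
    "candidates": ["gwas", "sweeps"],
}


class StageError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {},  # SimConfig overrides
    "filter": {"max_missing_rate": 0.5, "min_maf": 0.05, "min_q": 0.8},
    "windows": {"size": 100_000, "step": 50_000},
    "sweeps": {"quantile": 0.99, "composite_window": 50_000},
    "populations": {
        "ancestral": "Or",
        "pairs": [{"ecotype": "DW", "progenitor": "IR-XI"}],
    },
    "gwas": {
        "target": "DW",
        "alpha": 0.01,
        "prune": [50, 5, 0.3],
        "n_pcs": 3,
        "merge_distance_bp": 200_000,
        "threshold_mode": "exact",
    },
    "expression": {"up_cut": 1.5, "down_cut": 0.67},
}


def load_config(path_or_dict, out_dir=None) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    if "out_dir" not in cfg:
        raise ValueError("config needs an out_dir")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(canon, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class Pipeline:
    cfg: dict
    out: Path = field(init=False)

    def __post_init__(self):
        self.out = Path(self.cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)

    # -- manifest ------------------------------------------------------------
    @property
    def manifest_path(self) -> Path:
        return self.out / "manifest.json"

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with self.manifest_path.open() as fh:
                return json.load(fh)
        return {
            "config_hash": _config_hash(self.cfg),
            "version": __version__,
            "seed": self.cfg["seed"],
            "stages": {},
        }

    def _record(self, stage: str, paths: list) -> dict:
        manifest = self._load_manifest()
        manifest["config_hash"] = _config_hash(self.cfg)
        manifest["stages"][stage] = sorted(str(Path(p).relative_to(self.out)) for p in paths)
        with self.manifest_path.open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with (self.out / "run.log").open("a") as fh:
            import datetime

            fh.write(f"{datetime.datetime.now().isoformat()}\t{stage}\t{len(paths)} files\n")
        return manifest

    def _require(self, stage: str) -> None:
        for dep in _DEPS[stage]:
            if dep not in self._load_manifest()["stages"]:
                raise StageError(
                    f"stage {stage!r} needs outputs of stage {dep!r}; run {dep!r} first"
                )

    # -- stage bodies ---------------------------------------------------------
    def run_stage(self, name: str) -> dict:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
        self._require(name)
        paths = getattr(self, f"_stage_{name}")()
        logger.info("stage %s: %d outputs", name, len(paths))
        return self._record(name, paths)

    def run_all(self) -> dict:
        for name in STAGES:
            self.run_stage(name)
        manifest = self._report()
        return manifest

    def _sim_config(self) -> syn.SimConfig:
        params = dict(self.cfg.get("simulate") or {})
        params.setdefault("seed", self.cfg["seed"])
        sweep_loci = [tuple(s) for s in params.get("sweep_loci", [])]
        params["sweep_loci"] = sweep_loci
        return syn.SimConfig(**params)

    def _stage_simulate(self):
        config = self._sim_config()
        G, table, truth = syn.simulate_dataset(config)
        genes = syn.make_genes(config, seed=config.seed)
        truth.de_genes = syn.plant_de_genes(genes, seed=config.seed)
        expr = syn.simulate_expression(genes, truth, seed=config.seed)
        fix_dir = self.out / "fixture"
        manifest = syn.write_fixture(G, table, genes, expr, truth, config, fix_dir)
        return [fix_dir / Path(p).name for p in manifest["files"].values()] + [
            fix_dir / "manifest.json"
        ]

    def _fixture(self):
        fix = self.out / "fixture"
        G = gio.read_vcf(fix / "genotypes.vcf")
        table = gio.read_sample_table(fix / "samples.tsv")
        genes = gio.read_genes(fix / "genes.bed")
        expr = gio.read_expression(fix / "expression.tsv")
        return G, table, genes, expr

    def _stage_filter(self):
        G, table, _, _ = self._fixture()
        fcfg = self.cfg["filter"]
        core = gio.select_core_samples(table, fcfg.get("min_q", 0.8), keep_missing_q=True)
        G = G.subset_samples([s for s in G.samples if s in set(core["sample_id"])])
        Gf = gio.filter_variants(G, fcfg["max_missing_rate"], fcfg["min_maf"])
        out = self.out / "filtered.vcf"
        gio.write_vcf(Gf, out, chrom_lengths=self._sim_config().chrom_lengths())
        gio.write_sample_table(core, self.out / "core_samples.tsv")
        return [out, self.out / "core_samples.tsv"]

    def _filtered(self):
        G = gio.read_vcf(self.out / "filtered.vcf")
        table = gio.read_sample_table(self.out / "core_samples.tsv")
        return G, table

    def _grid(self):
        lengths = self._sim_config().chrom_lengths()
        wcfg = self.cfg["windows"]
        return pw.make_windows(lengths, wcfg["size"], wcfg["step"])

    def _stage_windows(self):
        G, table = self._filtered()
        grid = self._grid()
        wdir = self.out / "windows"
        wdir.mkdir(exist_ok=True)
        paths = []
        pops = self.cfg["populations"]
        names = {pops["ancestral"]} | {
            p[k] for p in pops["pairs"] for k in ("ecotype", "progenitor")
        }
        for group in sorted(names):
            samples = gio.samples_in_group(table, group)
            if len(samples) < 2:
                continue
            df = pw.pi_windowed(G, samples, grid)
            path = wdir / f"pi_{group}.tsv"
            gio.write_tsv(df, path)
            paths.append(path)
        for pair in pops["pairs"]:
            a = gio.samples_in_group(table, pair["ecotype"])
            b = gio.samples_in_group(table, pair["progenitor"])
            if len(a) < 2 or len(b) < 2:
                continue
            df, mean = pw.fst_windowed(G, a, b, grid)
            df.attrs["genome_mean"] = mean
            path = wdir / f"fst_{pair['ecotype']}_{pair['progenitor']}.tsv"
            gio.write_tsv(df, path)
            paths.append(path)
        return paths

    def _stage_sweeps(self):
        G, table = self._filtered()
        scfg = self.cfg["sweeps"]
        pops = self.cfg["populations"]
        genes = gio.read_genes(self.out / "fixture" / "genes.bed")
        sdir = self.out / "sweeps"
        sdir.mkdir(exist_ok=True)
        paths = []
        anc = pops["ancestral"]
        for pair in pops["pairs"]:
            eco = pair["ecotype"]
            pi_a = gio.read_tsv(self.out / "windows" / f"pi_{anc}.tsv").fillna({"flag": ""})
            pi_d = gio.read_tsv(self.out / "windows" / f"pi_{eco}.tsv").fillna({"flag": ""})
            rod = sd.rod_windowed(pi_a, pi_d)
            regions = sd.annotate_regions(
                sd.call_outlier_regions(rod, scfg["quantile"], scan="rod"), genes
            )
            path = sdir / f"rod_regions_{eco}.tsv"
            gio.write_tsv(regions, path)
            paths.append(path)

            fst = gio.read_tsv(
                self.out / "windows" / f"fst_{eco}_{pair['progenitor']}.tsv"
            ).fillna({"flag": ""})
            fst.attrs["statistic"] = "fst"
            fregions = sd.annotate_regions(
                sd.call_outlier_regions(fst, scfg["quantile"], scan="fst"), genes
            )
            fpath = sdir / f"fst_regions_{eco}_{pair['progenitor']}.tsv"
            gio.write_tsv(fregions, fpath)
            paths.append(fpath)

            samples = gio.samples_in_group(table, eco)
            if len(samples) >= 4:
                lengths = self._sim_config().chrom_lengths()
                cgrid = pw.make_windows(
                    lengths, scfg["composite_window"], scfg["composite_window"]
                )
                comp = sd.composite_sweep_scan(G, samples, cgrid)
                cpath = sdir / f"composite_{eco}.tsv"
                gio.write_tsv(comp, cpath)
                paths.append(cpath)
                cregions = sd.annotate_regions(
                    sd.call_outlier_regions(comp, scfg["quantile"], scan="composite"),
                    genes,
                )
                crpath = sdir / f"composite_regions_{eco}.tsv"
                gio.write_tsv(cregions, crpath)
                paths.append(crpath)
        return paths

    def _stage_classify(self):
        G, table = self._filtered()
        cdir = self.out / "classify"
        cdir.mkdir(exist_ok=True)
        paths = []
        for pair in self.cfg["populations"]["pairs"]:
            eco = gio.samples_in_group(table, pair["ecotype"])
            prog = gio.samples_in_group(table, pair["progenitor"])
            if len(eco) < 2 or len(prog) < 2:
                continue
            classes = vt.classify_variants(G, eco, prog)
            tag = f"{pair['ecotype']}_{pair['progenitor']}"
            path = cdir / f"classes_{tag}.tsv"
            gio.write_tsv(classes, path)
            spath = cdir / f"afd_summary_{tag}.tsv"
            gio.write_tsv(vt.afd_summary(classes), spath)
            paths.extend([path, spath])
        return paths

    def _stage_gwas(self):
        G, table = self._filtered()
        gcfg = self.cfg["gwas"]
        gdir = self.out / "gwas"
        gdir.mkdir(exist_ok=True)
        y = gw.encode_phenotype(table, gcfg["target"], sample_order=G.samples)
        w, s, r2 = gcfg["prune"]
        kept = gw.ld_prune(G, w, s, r2)
        n_eff = len(kept)
        Gp = G.subset_variants(kept)
        K = gw.grm(Gp)
        pcs = gw.pca_covariates(Gp, gcfg["n_pcs"])
        assoc = gw.lmm_scan(G, y, covariates=pcs, K=K)
        thr = gw.suggestive_threshold(n_eff, gcfg["alpha"], gcfg["threshold_mode"])
        genes = gio.read_genes(self.out / "fixture" / "genes.bed")
        qtls = gw.call_qtls(assoc, thr, gcfg["merge_distance_bp"], genes)
        apath = gdir / "assoc.tsv"
        qpath = gdir / "qtls.tsv"
        mpath = gdir / "model.json"
        gio.write_tsv(assoc, apath)
        gio.write_tsv(qtls, qpath)
        with mpath.open("w") as fh:
            json.dump(
                {
                    "n_effective_snps": int(n_eff),
                    "threshold_neglog10p": thr,
                    "delta": assoc.attrs.get("delta"),
                    "n_cases": int(y.sum()),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return [apath, qpath, mpath]

    def _stage_candidates(self):
        _, _, genes, expr = self._fixture()
        ecfg = self.cfg["expression"]
        qtls = gio.read_tsv(self.out / "gwas" / "qtls.tsv")
        frames = [qtls[["chrom", "start", "end"]]] if len(qtls) else []
        sweep_dir = self.out / "sweeps"
        for path in sorted(sweep_dir.glob("rod_regions_*.tsv")):
            df = gio.read_tsv(path)
            if len(df):
                frames.append(df[["chrom", "start", "end"]])
        regions = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        table = cs.screen_candidates(regions, genes, expr, ecfg["up_cut"], ecfg["down_cut"])
        cdir = self.out / "candidates"
        cdir.mkdir(exist_ok=True)
        path = cdir / "candidates.tsv"
        gio.write_tsv(table, path)
        return [path]

    # -- report --------------------------------------------------------------
    def _report(self) -> dict:
        manifest = self._load_manifest()
        rows = [("stage", "n_outputs")]
        for stage in STAGES:
            rows.append((stage, str(len(manifest["stages"].get(stage, [])))))
        truth_path = self.out / "fixture" / "truth_sweeps.tsv"
        report_path = self.out / "report.tsv"
        lines = ["\t".join(r) for r in rows]
        if truth_path.exists():
            truth = gio.read_tsv(truth_path)
            recovered = 0
            planted = truth[truth.get("realized", True) == True]  # noqa: E712
            for _, t in planted.iterrows():
                for path in sorted((self.out / "sweeps").glob("rod_regions_*.tsv")):
                    regions = gio.read_tsv(path)
                    hit = regions[
                        (regions["chrom"] == t["chrom"])
                        & (regions["start"] < t["end"])
                        & (regions["end"] > t["start"])
                    ]
                    if len(hit):
                        recovered += 1
                        break
            lines.append(f"planted_sweeps\t{len(planted)}")
            lines.append(f"recovered_sweeps\t{recovered}")
        report_path.write_text("\n".join(lines) + "\n")
        manifest = self._load_manifest()
        manifest["report"] = "report.tsv"
        with self.manifest_path.open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run_stage(name: str, config) -> dict:
    return Pipeline(load_config(config)).run_stage(name)


def run_all(config) -> dict:
    return Pipeline(load_config(config)).run_all()
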