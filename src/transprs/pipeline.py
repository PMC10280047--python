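"""End-to-end experiment orchestration: simulate -> LD -> train -> score -> evaluate.

A single config drives five stages and produces the cross-panel comparison
tables for a matched-ancestry cohort, a mismatched-ancestry cohort and a
three-way admixed cohort, plus the shareable "site bundle" (weight files +
manifest) that lets a collaborating site score its own cohort locally with
nothing else.
"""

from __future__ import annotations

import hashlib
import json
import tarfile
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from transprs import __version__
from transprs.evaluation import EvaluationResult, compare_panels, evaluate_scores
from transprs.ldpred_core import DEFAULT_FRACTIONS, TrainConfig, WeightSet, train_all
from transprs.ldref import LDReference, compute_ld_windows, pool_trans_ethnic
from transprs.scoring import ScoreTable, score_panel
from transprs.sumstats import (
    DEFAULT_HLA_REGION,
    SummaryStats,
    exclude_region,
    harmonize_alleles,
    restrict_to_panel,
    standardize_effects,
    write_sumstats,
)
from transprs.synthetic_data import (
    GenotypePanel,
    SimulationConfig,
    TraitModel,
    simulate_admixed,
    simulate_frequencies,
    simulate_genotypes,
    simulate_gwas,
    simulate_phenotype,
    variant_table,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "RunManifest", "run_experiment", "export_site_bundle", "score_from_bundle"]


@dataclass(frozen=True)
class ExperimentConfig:
    """One config for the whole experiment (single master seed).

    ``ld_panels`` lists founder-population labels plus the special labels
    ``ADM`` (admixed reference, the desk-scale analogue of an admixed
    American panel) and ``TE`` (pool of all other panels). Target cohorts
    map a cohort name to a founder label or ``ADM``. The first configured
    population is the GWAS training population.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_ld: int = 2500
    n_target: int = 2000
    ld_panels: tuple = ("EUR", "ASN", "AFR", "ADM", "TE")
    target_cohorts: tuple = (("matched", "EUR"), ("mismatched", "AFR"), ("admixed", "ADM"))
    fractions: tuple = DEFAULT_FRACTIONS
    train_h2: float = 0.25
    n_iter: int = 200
    n_burn: int = 40
    shrinkage_lambda: float = 0.01
    window_size: Optional[int] = None
    percentiles: tuple = (1.0, 5.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "populations" in sim_raw:
            sim_raw["populations"] = tuple((str(a), int(b)) for a, b in sim_raw["populations"])
        for key in ("ld_panels", "fractions", "percentiles", "admixture_alpha"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "target_cohorts" in raw:
            raw["target_cohorts"] = tuple((str(a), str(b)) for a, b in raw["target_cohorts"])
        sim = SimulationConfig(**sim_raw)
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: config hash, seed, versions, digests, timings."""

    config_hash: str
    seed: int
    versions: Dict[str, str]
    digests: Dict[str, str] = field(default_factory=dict)
    wallclock: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


@dataclass
class ExperimentResult:
    sumstats: SummaryStats
    std_effects: np.ndarray
    trait: TraitModel
    ld_refs: Dict[str, LDReference]
    weight_sets: Dict[Tuple[str, str], WeightSet]
    score_tables: Dict[str, ScoreTable]
    phenotypes: Dict[str, np.ndarray]
    results: List[EvaluationResult]
    tables: Dict[Tuple[str, float], pd.DataFrame]


def _seed_parts(master: int, stage: int, item: int = 0) -> list:
    return [int(master), int(stage), int(item)]


def _stage(name):
    """Decorator-free stage wrapper: re-raise with stage-scoped context."""

    class _Ctx:
        def __init__(self, label):
            self.label = label
            self.t0 = None

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.elapsed = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{self.label}' failed: {exc}") from exc
            return False

    return _Ctx(name)


def run_experiment(config: ExperimentConfig, out_dir=None) -> Tuple[RunManifest, ExperimentResult]:
    """Execute the five-stage workflow; optionally write all artifacts.

    Stages: (1) simulate GWAS cohort and summary statistics; (2) build LD
    reference panels (population-specific, admixed, pooled trans-ethnic);
    (3) train posterior-mean weights for every panel x fraction; (4) score
    the target cohorts; (5) define extreme-percentile cases and evaluate.
    Any stage error aborts with a stage-scoped message; nothing partial is
    written for later stages.
    """
    sim = config.sim
    master = config.seed
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=master,
        versions={"transprs": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    )
    founders = sim.population_labels
    train_pop = founders[0]

    with _stage("simulate") as st:
        vm = variant_table(sim)
        freqs = simulate_frequencies(sim)
        gwas_panel = simulate_genotypes(
            freqs[0], sim.n_gwas, sim, variant_meta=vm, population=train_pop,
            seed=_seed_parts(master, 10),
        )
        trait = simulate_phenotype(gwas_panel, sim, seed=_seed_parts(master, 11))
        stats = simulate_gwas(gwas_panel)
        del gwas_panel
    manifest.wallclock["simulate"] = st.elapsed

    with _stage("build-ld") as st:
        raw_panels: Dict[str, GenotypePanel] = {}
        # TE pools every founder population (plus ADM when configured), so
        # founder panels are simulated even when only TE weights are requested.
        needed = [lab for lab in config.ld_panels if lab != "TE"]
        if "TE" in config.ld_panels:
            needed += [lab for lab in founders if lab not in needed]
        for i, lab in enumerate(needed):
            if lab == "ADM":
                raw_panels[lab] = simulate_admixed(
                    freqs, config.n_ld, sim.admixture_alpha, sim,
                    variant_meta=vm, population="ADM", seed=_seed_parts(master, 20, i),
                )
            else:
                raw_panels[lab] = simulate_genotypes(
                    freqs[founders.index(lab)], config.n_ld, sim,
                    variant_meta=vm, population=lab, seed=_seed_parts(master, 20, i),
                )
        ld_refs: Dict[str, LDReference] = {}
        for lab, pan in raw_panels.items():
            ld_refs[lab] = compute_ld_windows(
                pan, config.window_size, config.shrinkage_lambda, label=lab
            )
        if "TE" in config.ld_panels:
            pooled = pool_trans_ethnic(list(raw_panels.values()))
            ld_refs["TE"] = compute_ld_windows(
                pooled, config.window_size, config.shrinkage_lambda, label="TE"
            )
            del pooled
        del raw_panels
    manifest.wallclock["build-ld"] = st.elapsed

    with _stage("train") as st:
        stats = exclude_region(stats, *DEFAULT_HLA_REGION)
        ref_meta = ld_refs[next(iter(ld_refs))].variant_meta
        stats = restrict_to_panel(stats, ref_meta["variant_id"])
        stats, _harm = harmonize_alleles(stats, ref_meta)
        stats = stats.usable()  # drop flagged (e.g. monomorphic) variants
        std = standardize_effects(stats)
        # align every LD panel to the harmonized, usable variant list
        idx = pd.Index(ref_meta["variant_id"]).get_indexer(stats.df["variant_id"])
        if (idx < 0).any():
            raise ValueError("harmonized statistics contain variants absent from the LD panels")
        if len(idx) < len(ref_meta):
            for lab in list(ld_refs):
                ld_refs[lab] = ld_refs[lab].subset_variants(idx)
        tcfg = TrainConfig(
            n_gwas=sim.n_gwas,
            h2=config.train_h2,
            fractions=config.fractions,
            n_iter=config.n_iter,
            n_burn=config.n_burn,
            seed=int(np.random.SeedSequence(_seed_parts(master, 40)).generate_state(1)[0] % (2**31 - 1)),
        )
        weight_sets = train_all(std, [ld_refs[lab] for lab in config.ld_panels if lab in ld_refs], tcfg)
    manifest.wallclock["train"] = st.elapsed

    with _stage("score") as st:
        score_tables: Dict[str, ScoreTable] = {}
        phenotypes: Dict[str, np.ndarray] = {}
        for i, (name, kind) in enumerate(config.target_cohorts):
            if kind == "ADM":
                cohort = simulate_admixed(
                    freqs, config.n_target, sim.admixture_alpha, sim,
                    variant_meta=vm, population=name, seed=_seed_parts(master, 50, i),
                )
            else:
                cohort = simulate_genotypes(
                    freqs[founders.index(kind)], config.n_target, sim,
                    variant_meta=vm, population=name, seed=_seed_parts(master, 50, i),
                )
            simulate_phenotype(cohort, sim, trait=trait, seed=_seed_parts(master, 60, i))
            score_tables[name] = score_panel(cohort, weight_sets.values())
            phenotypes[name] = cohort.phenotype
            del cohort
    manifest.wallclock["score"] = st.elapsed

    with _stage("evaluate") as st:
        results: List[EvaluationResult] = []
        tables: Dict[Tuple[str, float], pd.DataFrame] = {}
        for name in score_tables:
            for pct in config.percentiles:
                res = evaluate_scores(
                    score_tables[name], phenotypes[name], cohort=name, percentiles=[pct]
                )
                results.extend(res)
                tables[(name, pct)] = compare_panels(res)
    manifest.wallclock["evaluate"] = st.elapsed

    result = ExperimentResult(
        sumstats=stats,
        std_effects=std,
        trait=trait,
        ld_refs=ld_refs,
        weight_sets=weight_sets,
        score_tables=score_tables,
        phenotypes=phenotypes,
        results=results,
        tables=tables,
    )
    if out_dir is not None:
        _write_outputs(config, manifest, result, Path(out_dir))
    return manifest, result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(config, manifest, result, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    wdir = out_dir / "weights"
    wdir.mkdir(exist_ok=True)
    files = {}
    for (panel, frac), ws in result.weight_sets.items():
        fname = f"weights_{panel}_{frac}.tsv"
        ws.write(wdir / fname)
        files.setdefault(panel, {})[frac] = fname
        manifest.digests[f"weights/{fname}"] = _sha256(wdir / fname)
    with open(wdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "config_hash": manifest.config_hash,
                "seed": manifest.seed,
                "panels": sorted(files),
                "fractions": [("inf" if f == "inf" else f"{float(f):g}") for f in config.fractions],
                "files": files,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    write_sumstats(result.sumstats, out_dir / "sumstats.tsv")
    manifest.digests["sumstats.tsv"] = _sha256(out_dir / "sumstats.tsv")
    sdir = out_dir / "scores"
    sdir.mkdir(exist_ok=True)
    for name, tab in result.score_tables.items():
        tab.write(sdir / f"{name}.tsv")
        manifest.digests[f"scores/{name}.tsv"] = _sha256(sdir / f"{name}.tsv")
    eval_df = pd.DataFrame([r.as_dict() for r in result.results])
    eval_df.to_csv(out_dir / "evaluation.tsv", sep="\t", index=False)
    manifest.digests["evaluation.tsv"] = _sha256(out_dir / "evaluation.tsv")
    tdir = out_dir / "tables"
    tdir.mkdir(exist_ok=True)
    for (name, pct), tab in result.tables.items():
        path = tdir / f"{name}_top{pct:g}pct.tsv"
        tab.to_csv(path, sep="\t")
        manifest.digests[f"tables/{path.name}"] = _sha256(path)
    manifest.to_json(out_dir / "manifest.json")


def export_site_bundle(weights_dir, out_path) -> Path:
    """Archive the shareable artifact: weight TSVs + manifest + instructions.

    A collaborating site needs only this bundle plus its local genotypes and
    phenotypes to reproduce the scoring and evaluation. Missing fraction
    files (relative to the manifest) abort with the list of gaps.
    """
    weights_dir = Path(weights_dir)
    man_path = weights_dir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"no manifest.json in {weights_dir}; nothing to export")
    with open(man_path) as fh:
        man = json.load(fh)
    gaps = []
    for panel, fracs in man["files"].items():
        for frac, fname in fracs.items():
            if not (weights_dir / fname).exists():
                gaps.append(fname)
    if gaps:
        raise FileNotFoundError(f"weight files missing from {weights_dir}: {sorted(gaps)}")
    out_path = Path(out_path)
    instructions = (
        "Site scoring protocol\n"
        "=====================\n"
        "1. Align each weight file's alleles to your cohort's counted alleles\n"
        "   (transprs score does this automatically).\n"
        "2. Compute PRS = sum_j weight_j * dosage_j per individual.\n"
        "3. Define the top 1% and 5% of your BMI distribution as cases and\n"
        "   report ROC AUC per weight file (transprs evaluate).\n"
    )
    with tarfile.open(out_path, "w") as tar:
        tar.add(man_path, arcname="manifest.json")
        for panel, fracs in man["files"].items():
            for fname in fracs.values():
                tar.add(weights_dir / fname, arcname=fname)
        inst = weights_dir / "INSTRUCTIONS.txt"
        inst.write_text(instructions)
        tar.add(inst, arcname="INSTRUCTIONS.txt")
    return out_path


def score_from_bundle(bundle_path, panel: GenotypePanel, extract_dir) -> ScoreTable:
    """Score a cohort using only an exported site bundle (federated step)."""
    extract_dir = Path(extract_dir)
    with tarfile.open(bundle_path) as tar:
        tar.extractall(extract_dir, filter="data")
    with open(extract_dir / "manifest.json") as fh:
        man = json.load(fh)
    weight_sets = []
    for panel_lab, fracs in sorted(man["files"].items()):
        for frac, fname in sorted(fracs.items()):
            weight_sets.append(WeightSet.read(extract_dir / fname, frac, panel_lab))
    return score_panel(panel, weight_sets)
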