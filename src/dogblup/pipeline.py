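"""End-to-end orchestration: simulate -> edit -> evaluate -> trends -> report.

Stages mirror the registry analysis plan: parse and edit the score file,
build and clean the pedigree, estimate variance components by AI-REML,
solve the MME for EBVs, derive PEV/accuracy, and regress genetic trends.
Each stage failure aborts with the stage name; every output carries the
seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, registry, reml, trends
from .model import (ModelSpec, VarianceComponents, assemble_mme,
                    build_design)
from .pedigree import (Pedigree, ainverse_sparse, build_pedigree,
                       read_pedigree_csv, write_inbreeding_csv)
from .registry import ELBOW, HIP, EditConfig
from .simulate import SimConfig, simulate_registry

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    """Single configuration object driving the pipeline."""

    out_dir: str = "dogblup_out"
    registry_path: str | None = None
    pedigree_path: str | None = None
    seed: int = 0
    edit: EditConfig = field(default_factory=EditConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    scenario: SimConfig | None = None
    elbow_transformation: str = "identity"
    apply_edits: bool = True
    reml_tol: float = 1e-6
    reml_max_iter: int = 200
    fixed_components: VarianceComponents | None = None
    solver: str = "auto"
    pev_method: str = "auto"
    elbow_trend_window: tuple[int, int] | None = (1996, 2009)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {f.name for f in dataclasses.fields(cls)} - {
            "edit", "model", "scenario", "fixed_components"}
        for key in simple & set(raw):
            kwargs[key] = raw[key]
        if "elbow_trend_window" in kwargs and kwargs["elbow_trend_window"]:
            kwargs["elbow_trend_window"] = tuple(kwargs["elbow_trend_window"])
        if raw.get("edit"):
            kwargs["edit"] = EditConfig(**raw["edit"])
        if raw.get("model"):
            kwargs["model"] = ModelSpec(**raw["model"])
        if raw.get("scenario"):
            sc = dict(raw["scenario"])
            if "components" in sc:
                comp = sc.pop("components")
                sc["components"] = VarianceComponents(
                    G0=np.array(comp["G0"]), R0=np.array(comp["R0"]),
                    U0=np.array(comp["U0"]) if comp.get("U0") else None)
            kwargs["scenario"] = SimConfig(**sc)
        if raw.get("fixed_components"):
            comp = raw["fixed_components"]
            kwargs["fixed_components"] = VarianceComponents(
                G0=np.array(comp["G0"]), R0=np.array(comp["R0"]),
                U0=np.array(comp["U0"]) if comp.get("U0") else None)
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = repr(self)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                    from exc
        return inner
    return wrap


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: RunConfig) -> dict:
    """Write synthetic registry + pedigree CSVs and a manifest."""
    scenario = config.scenario or SimConfig()
    if scenario.seed != config.seed:
        scenario = dataclasses.replace(scenario, seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, pedigree = simulate_registry(scenario, seed=config.seed)
    reg_path = out / "registry.csv"
    ped_path = out / "pedigree.csv"
    records.to_csv(reg_path, index=False)
    pedigree.write_csv(ped_path)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {p.name: _sha256(p) for p in (reg_path, ped_path)},
        "n_records": int(len(records)),
        "n_pedigree": int(pedigree.n),
        "scenario": {"n_breeds": scenario.n_breeds,
                     "dogs_per_breed": scenario.dogs_per_breed,
                     "generations": scenario.generations,
                     "mating": scenario.mating,
                     "score_scale": scenario.score_scale},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("simulated %d records / %d pedigree entries into %s",
                len(records), pedigree.n, out)
    return manifest


# ---------------------------------------------------------------------------
# evaluate


@dataclass
class ResultsBundle:
    components: reml.REMLResult | None
    used_components: VarianceComponents
    evaluation: evaluation.EvaluationResult
    trend_tables: dict[str, pd.DataFrame]
    datasets: dict[str, registry.TraitDataset]
    pedigree: Pedigree
    out_dir: str


def run_evaluate(config: RunConfig) -> ResultsBundle:
    """Full evaluation: edits -> pedigree -> REML -> BLUP -> accuracy -> trends."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = _stage("parse_registry")(registry.parse_registry)(
        config.registry_path)
    datasets = _stage("edits")(_edit_records)(records, config)
    if config.pedigree_path:
        pedigree = _stage("pedigree")(read_pedigree_csv)(config.pedigree_path)
    else:
        pedigree = _stage("pedigree")(_pedigree_from_records)(records)
    relationship = _stage("relationship")(ainverse_sparse)(pedigree)
    design = _stage("design")(build_design)(datasets, pedigree, config.model)

    if config.fixed_components is not None:
        fit = None
        used = config.fixed_components
    else:
        fit = _stage("reml")(reml.estimate_components)(
            design=design, relationship=relationship,
            tol=config.reml_tol, max_iter=config.reml_max_iter)
        used = fit.components
    system = _stage("assemble")(assemble_mme)(design, relationship, used)
    solution = _stage("solve")(system.solve)(method=config.solver)
    result = _stage("accuracy")(evaluation.evaluate)(
        system, solution, pev_method=config.pev_method, seed=config.seed)

    trend_tables = _stage("trends")(_compute_trends)(result, config)

    _stage("outputs")(_write_bundle)(out, config, fit, used, result,
                                     trend_tables, datasets)
    _stage("outputs")(write_inbreeding_csv)(pedigree, out / "inbreeding.csv",
                                            relationship.inbreeding)
    return ResultsBundle(components=fit, used_components=used,
                         evaluation=result, trend_tables=trend_tables,
                         datasets=datasets, pedigree=pedigree,
                         out_dir=str(out))


def _edit_records(records, config: RunConfig):
    datasets = {}
    hip_ds = registry.apply_hip_edits(records, config.edit)
    if hip_ds.n_records:
        datasets[HIP] = hip_ds
    elbow_ds = registry.apply_elbow_edits(records, config.edit)
    if elbow_ds.n_records:
        datasets[ELBOW] = elbow_ds.with_transformation(
            config.elbow_transformation)
    if not datasets:
        raise ValueError("no records survived editing")
    if not config.apply_edits:
        logger.warning("apply_edits=False is ignored; edits always run")
    return datasets


def _pedigree_from_records(records) -> Pedigree:
    rows = {}
    for r in records:
        rows.setdefault(r.dog_id, (r.dog_id, r.sire_id, r.dam_id, r.sex,
                                   r.breed, float(r.birth_date[0])))
    return build_pedigree(rows.values())


def _compute_trends(result: evaluation.EvaluationResult,
                    config: RunConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for trait in (HIP, ELBOW):
        frame = result.for_trait(trait)
        if frame.empty:
            continue
        window = (config.elbow_trend_window if trait == ELBOW else None)
        try:
            per_breed = trends.genetic_trend(
                frame["ebv"], frame["birth_year"], frame["breed"],
                trait=trait, year_range=window)
        except ValueError:
            if window is None:
                raise
            logger.warning("%s trend window %s too narrow; using all years",
                           trait, window)
            per_breed = trends.genetic_trend(
                frame["ebv"], frame["birth_year"], frame["breed"], trait=trait)
        tables[trait] = trends.trends_to_frame(per_breed)
    return tables


def _components_payload(config, fit, used):
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "G0": used.G0.tolist(),
        "U0": None if used.U0 is None else used.U0.tolist(),
        "R0": used.R0.tolist(),
    }
    for k in range(used.n_traits):
        payload[f"h2_trait{k + 1}"] = reml.heritability(used, k)
        payload[f"phenotypic_variance_trait{k + 1}"] = \
            used.phenotypic_variance(k)
    if used.n_traits == 2:
        rg, re = reml.genetic_correlation(used)
        payload["r_g"] = rg
        payload["r_e"] = re
    if fit is not None:
        payload["loglik"] = fit.loglik
        payload["converged"] = bool(fit.converged)
        payload["iterations"] = int(fit.iterations)
        payload["se"] = fit.se.tolist()
    return payload


def _write_bundle(out: Path, config, fit, used, result, trend_tables,
                  datasets) -> None:
    with open(out / "components.json", "w") as fh:
        json.dump(_components_payload(config, fit, used), fh, indent=2)
    result.write_csv(out / "ebv.csv")
    for trait, table in trend_tables.items():
        table.to_csv(out / f"trends_{trait}.csv", index=False)
    audit = {trait: ds.audit for trait, ds in datasets.items()}
    with open(out / "edit_audit.json", "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
    if fit is not None and fit.trajectory is not None:
        fit.trajectory.to_csv(out / "reml_trajectory.csv", index=False)


# ---------------------------------------------------------------------------
# report


def run_report(out_dir) -> dict[str, pd.DataFrame]:
    """Render the component table and per-breed AGI tables from a bundle."""
    out = Path(out_dir)
    comp_path = out / "components.json"
    if not comp_path.exists():
        raise FileNotFoundError(
            f"incomplete bundle: missing {comp_path.name} in {out}")
    with open(comp_path) as fh:
        comp = json.load(fh)
    rows = []
    labels = {"G0": [("sigma2_a1", 0, 0), ("sigma_a12", 0, 1),
                     ("sigma2_a2", 1, 1)],
              "R0": [("sigma2_e1", 0, 0), ("sigma_e12", 0, 1),
                     ("sigma2_e2", 1, 1)]}
    t = len(comp["G0"])
    for mat_name, entries in labels.items():
        mat = comp[mat_name]
        for name, i, j in entries:
            if i < t and j < t:
                rows.append((name, mat[i][j]))
    if comp.get("U0"):
        for k, v in enumerate(comp["U0"]):
            rows.append((f"sigma2_u{k + 1}", v))
    for k in range(t):
        rows.append((f"sigma2_p{k + 1}", comp[f"phenotypic_variance_trait{k + 1}"]))
        rows.append((f"h2_{k + 1}", comp[f"h2_trait{k + 1}"]))
    if "r_g" in comp:
        rows.append(("r_g", comp["r_g"]))
        rows.append(("r_e", comp["r_e"]))
    tables = {"components": pd.DataFrame(rows, columns=["parameter",
                                                        "estimate"])}
    for trait in (HIP, ELBOW):
        path = out / f"trends_{trait}.csv"
        if path.exists():
            tables[f"agi_{trait}"] = pd.read_csv(path)
        else:
            logger.warning("bundle lacks %s; AGI table skipped", path.name)
    return tables
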