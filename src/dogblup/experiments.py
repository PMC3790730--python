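"""Self-contained validation experiments at the study's conditions.

Each function simulates its own data with the package's generator,
runs the relevant slice of the evaluation pipeline, and returns the
measured quantities.  They are used both by the acceptance test suite
and by ``scripts/acceptance.py``; the scenario sizes are the package's
reference conditions (a four-breed, 3000-dogs-per-breed population bred
over eight generations for parameter recovery, matching the published
bivariate variance components as simulation truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSpec, VarianceComponents, assemble_mme, build_design
from .pedigree import ainverse_sparse
from .registry import (EditConfig, apply_elbow_edits, apply_hip_edits,
                       dichotomize)
from .reml import REMLResult, estimate_components, pack_components
from .simulate import (SimConfig, apply_reporting_bias, simulate_population,
                       simulate_records, simulate_registry)
from .trends import genetic_trend


def split_date_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Expand the ISO birth/test date strings into year/month columns."""
    out = records.copy()
    out[["birth_year", "birth_month"]] = \
        out["birth_date"].str.split("-", expand=True).iloc[:, :2].astype(int)
    out[["test_year", "test_month"]] = \
        out["test_date"].str.split("-", expand=True).iloc[:, :2].astype(int)
    return out


def edited_datasets(records: pd.DataFrame, edit: EditConfig | None = None):
    frame = split_date_columns(records)
    edit = edit or EditConfig()
    datasets = {}
    hip = apply_hip_edits(frame, edit)
    if hip.n_records:
        datasets["hip"] = hip
    elbow = apply_elbow_edits(frame, edit)
    if elbow.n_records:
        datasets["elbow"] = elbow
    return datasets


@dataclass
class RecoveryOutcome:
    fit: REMLResult
    truth: VarianceComponents
    n_records: int

    def z_scores(self) -> np.ndarray:
        est = pack_components(self.fit.components, True)
        tru = pack_components(self.truth, True)
        se = np.where(self.fit.se > 0, self.fit.se, np.inf)
        return (est - tru) / se


def parameter_recovery(seed: int, config: SimConfig | None = None,
                       edit: EditConfig | None = None) -> RecoveryOutcome:
    """Simulate the reference Gaussian-recorded population and re-estimate
    its variance components by AI-REML."""
    config = config or SimConfig.recovery(seed=seed)
    records, pedigree = simulate_registry(config, seed=seed)
    datasets = edited_datasets(records, edit)
    relationship = ainverse_sparse(pedigree)
    design = build_design(datasets, pedigree)
    fit = estimate_components(design=design, relationship=relationship)
    n = sum(ds.n_records for ds in datasets.values())
    return RecoveryOutcome(fit=fit, truth=config.components, n_records=n)


def incidence_calibration(seed: int, n_dogs: int = 50_000) -> dict:
    """Realized dysplasia incidences of the ordinal generator defaults."""
    config = SimConfig(n_breeds=4, dogs_per_breed=n_dogs // 4,
                       generations=1, scoring_prob=(1.0, 1.0), seed=seed)
    pedigree, bv = simulate_population(config, seed=seed)
    records = simulate_records(pedigree, bv, config, seed=seed)
    datasets = edited_datasets(records, EditConfig(min_breed_records=1))
    out = {}
    for trait, ds in datasets.items():
        inc = dichotomize(ds)
        out[trait] = {"incidence": inc.proportion, "n": inc.n_total,
                      "mean_score": float(ds.data["score"].mean()),
                      "sd_score": float(ds.data["score"].std())}
    return out


def blup_calibration(seed: int, config: SimConfig | None = None) -> dict:
    """Regression of true on estimated breeding values at known components
    (BLUP unbiasedness: expected slope 1)."""
    config = config or SimConfig.recovery(n_breeds=2, dogs_per_breed=1000,
                                          generations=6, seed=seed)
    pedigree, bv = simulate_population(config, seed=seed)
    records = simulate_records(pedigree, bv, config, seed=seed)
    datasets = edited_datasets(records, EditConfig(min_breed_records=1))
    relationship = ainverse_sparse(pedigree)
    design = build_design(datasets, pedigree)
    system = assemble_mme(design, relationship, config.components)
    solution = system.solve()
    fit = stats.linregress(solution.ebv[:, 0], bv[:, 0])
    return {"slope": float(fit.slope), "se": float(fit.stderr),
            "n": pedigree.n}


def bias_attenuation(seed: int, n_replicates: int = 20,
                     dogs_per_breed: int = 800) -> pd.DataFrame:
    """Paired biased/unbiased trend estimates under era censoring.

    Each replicate breeds one truncation-selected population with a
    realistic (high) true dysplasia rate, scores it on the ordinal scale,
    and estimates the hip genetic trend twice: from the complete records
    and from the era-censored ones (pre-2000 dysplastic grades withheld).
    Columns: unbiased, biased, true (AGI of the simulated breeding
    values), attenuated (|biased| < |unbiased|).
    """
    rows = []
    rng = np.random.default_rng(seed)
    spec = ModelSpec(fixed_factors={
        "hip": ["breed", "sex", "test_year", "birth_year", "age_group"]})
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        config = SimConfig.bias_study(dogs_per_breed=dogs_per_breed,
                                      seed=rep_seed)
        pedigree, bv = simulate_population(config, seed=rep_seed)
        records = simulate_records(pedigree, bv, config, seed=rep_seed)
        censored = apply_reporting_bias(records, config, seed=rep_seed)
        relationship = ainverse_sparse(pedigree)
        vc_hip = VarianceComponents(
            G0=[[config.components.G0[0, 0]]],
            U0=[config.components.U0[0]],
            R0=[[config.components.R0[0, 0]]])
        agi = {}
        for label, rec in (("unbiased", records), ("biased", censored)):
            datasets = edited_datasets(rec, EditConfig(min_breed_records=1))
            design = build_design({"hip": datasets["hip"]}, pedigree, spec)
            system = assemble_mme(design, relationship, vc_hip)
            solution = system.solve()
            agi[label] = genetic_trend(solution.ebv[:, 0],
                                       pedigree.birth_year)["all"].agi
        agi["true"] = genetic_trend(bv[:, 0], pedigree.birth_year)["all"].agi
        agi["attenuated"] = abs(agi["biased"]) < abs(agi["unbiased"])
        rows.append(agi)
    return pd.DataFrame(rows)
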