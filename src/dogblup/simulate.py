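"""Synthetic pedigrees and registry files with the structure the model assumes.

The generator emulates a voluntary orthopedic registry: closed purebred
populations bred over discrete generations (optionally under truncation or
assortative selection on hip merit), bivariate additive genetics a ~
(0, G0 (x) A) realized founder-by-founder and through Mendelian sampling,
test-year-by-month environmental effects, correlated residuals for dogs
scored on both joints, ordinal scoring through global liability thresholds
calibrated to target incidences, and era-dependent under-reporting of
dysplastic grades (before 2000 essentially only normal scores were
released).

Two recording scales are supported: ``ordinal`` writes registry-style
integer scores (hip 1-7, elbow 1-4); ``liability`` writes the underlying
Gaussian response itself, which is the appropriate scale for exercising
the linear-model estimation machinery under its own assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import VarianceComponents, published_components
from .pedigree import Pedigree, inbreeding_coefficients
from .registry import ELBOW, HIP

logger = logging.getLogger(__name__)

MATING_SCHEMES = ("random", "truncation", "assortative")

#: default ordinal category proportions; the last three hip categories
#: (dysplastic) sum to 0.83% and elbow grades I-III to 2.08%, with means
#: and SDs close to the registry's 2.05/0.63 (hip) and 1.03/0.19 (elbow)
DEFAULT_HIP_PROPS = (0.130, 0.700, 0.158, 0.0037, 0.006, 0.002, 0.0003)
DEFAULT_ELBOW_PROPS = (0.9792, 0.015, 0.004, 0.0018)


@dataclass(frozen=True)
class ReportingEra:
    """Report probabilities by score category for one test-year window."""

    first_test_year: int | None
    last_test_year: int | None
    hip_probs: dict[int, float]
    elbow_probs: dict[int, float]

    def contains(self, year: np.ndarray) -> np.ndarray:
        lo = -np.inf if self.first_test_year is None else self.first_test_year
        hi = np.inf if self.last_test_year is None else self.last_test_year
        return (year >= lo) & (year <= hi)


def default_reporting_eras() -> tuple[ReportingEra, ...]:
    """Pre-2000: only normal hip grades (1-3) and normal elbows released;
    from 2000 every category is reported."""
    return (
        ReportingEra(None, 1999,
                     hip_probs={1: 1.0, 2: 1.0, 3: 1.0},
                     elbow_probs={1: 1.0}),
        ReportingEra(2000, None,
                     hip_probs={k: 1.0 for k in range(1, 8)},
                     elbow_probs={k: 1.0 for k in range(1, 5)}),
    )


@dataclass
class SimConfig:
    """Scenario definition for the synthetic registry."""

    n_breeds: int = 4
    dogs_per_breed: int = 3000
    generations: int = 8
    mating: str = "random"
    selected_proportion: float = 1.0
    components: VarianceComponents = field(default_factory=published_components)
    trait_means: tuple[float, float] = (2.05, 1.03)
    breed_sd: tuple[float, float] = (0.10, 0.03)
    sex_effect: tuple[float, float] = (0.0, 0.0082)
    age_effects: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.0, 0.01, 0.03, 0.03), (0.0, 0.0, 0.0, 0.0))
    test_year_sd: tuple[float, float] = (0.02, 0.01)
    birth_year_sd: tuple[float, float] = (0.02, 0.01)
    age_group_probs: tuple[float, ...] = (0.25, 0.35, 0.20, 0.20)
    scoring_prob: tuple[float, float] = (0.90, 0.25)
    score_scale: str = "ordinal"
    hip_category_props: tuple[float, ...] = DEFAULT_HIP_PROPS
    elbow_category_props: tuple[float, ...] = DEFAULT_ELBOW_PROPS
    reporting_eras: tuple[ReportingEra, ...] = field(
        default_factory=default_reporting_eras)
    founder_year: int = 1970
    generation_interval: float = 4.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mating not in MATING_SCHEMES:
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if self.selected_proportion <= 0 or self.selected_proportion > 1:
            raise ValueError("selected_proportion must lie in (0, 1]")
        if self.score_scale not in ("ordinal", "liability"):
            raise ValueError("score_scale must be 'ordinal' or 'liability'")
        for props in (self.hip_category_props, self.elbow_category_props):
            if abs(sum(props) - 1.0) > 1e-6:
                raise ValueError("category proportions must sum to 1")

    @classmethod
    def recovery(cls, **overrides) -> "SimConfig":
        """The parameter-recovery scenario: default population under random
        mating, recorded on the liability (Gaussian) scale."""
        base = dict(score_scale="liability", mating="random")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def bias_study(cls, **overrides) -> "SimConfig":
        """Reporting-bias scenario: a single selected population with a
        realistic (high) true dysplasia rate so era censoring bites."""
        base = dict(
            n_breeds=1, dogs_per_breed=800, mating="truncation",
            selected_proportion=0.5, score_scale="ordinal",
            hip_category_props=(0.22, 0.33, 0.20, 0.05, 0.12, 0.05, 0.03),
            elbow_category_props=(0.90, 0.06, 0.03, 0.01))
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# pedigree simulation


def _spawn(seed, n):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_pedigree(config: SimConfig, seed: int | None = None) -> Pedigree:
    """Pedigree only (true breeding values discarded)."""
    ped, _ = simulate_population(config, seed=seed)
    return ped


def simulate_population(config: SimConfig,
                        seed: int | None = None) -> tuple[Pedigree, np.ndarray]:
    """Pedigree plus true bivariate breeding values, bred per the scenario.

    Discrete generations within closed breeds; under truncation or
    assortative mating, parents are chosen by a hip-merit criterion
    (true breeding value plus residual-sized noise, lower is better).
    Output order is breed-contiguous and topological.
    """
    seed = config.seed if seed is None else seed
    rng_struct, rng_bv = _spawn(seed, 2)
    G0, R0 = config.components.G0, config.components.R0

    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    breed: list[str] = []
    byear: list[int] = []
    bvs: list[np.ndarray] = []

    n_cohort = max(4, int(round(config.dogs_per_breed / config.generations)))
    for b in range(config.n_breeds):
        breed_name = f"Breed{b + 1:02d}"
        prev_idx: list[int] = []
        prev_f = np.zeros(0)
        for g in range(config.generations):
            cohort: list[int] = []
            if g == 0:
                years = rng_struct.integers(config.founder_year,
                                            config.founder_year + 4,
                                            size=n_cohort)
                founder_bv = rng_bv.multivariate_normal(
                    np.zeros(2), G0, size=n_cohort)
                for j in range(n_cohort):
                    idx = len(ids)
                    ids.append(f"{breed_name}-G0-{j:05d}")
                    sire.append(-1)
                    dam.append(-1)
                    sex.append("male" if j % 2 == 0 else "female")
                    breed.append(breed_name)
                    byear.append(int(years[j]))
                    bvs.append(founder_bv[j])
                    cohort.append(idx)
                cohort_f = np.zeros(n_cohort)
            else:
                sires_pool, dams_pool = _select_parents(
                    config, prev_idx, np.array([bvs[i][0] for i in prev_idx]),
                    np.array([sex[i] == "male" for i in prev_idx]),
                    R0[0, 0], rng_struct)
                year = (config.founder_year
                        + int(round(g * config.generation_interval)))
                jitter = rng_struct.integers(-1, 2, size=n_cohort)
                if config.mating == "assortative":
                    pair_s, pair_d = _assortative_pairs(
                        sires_pool, dams_pool,
                        np.array([bvs[i][0] for i in sires_pool]),
                        np.array([bvs[i][0] for i in dams_pool]))
                    pick = rng_struct.integers(0, len(pair_s), size=n_cohort)
                    s_choice = pair_s[pick]
                    d_choice = pair_d[pick]
                else:
                    s_choice = rng_struct.choice(sires_pool, size=n_cohort)
                    d_choice = rng_struct.choice(dams_pool, size=n_cohort)
                sexes = rng_struct.random(n_cohort) < 0.5
                f_lookup = dict(zip(prev_idx, prev_f))
                mendel_sd = np.array([
                    np.sqrt(0.5 - 0.25 * (f_lookup[s] + f_lookup[d]))
                    for s, d in zip(s_choice, d_choice)])
                noise = rng_bv.multivariate_normal(np.zeros(2), G0,
                                                   size=n_cohort)
                for j in range(n_cohort):
                    idx = len(ids)
                    s, d = int(s_choice[j]), int(d_choice[j])
                    ids.append(f"{breed_name}-G{g}-{j:05d}")
                    sire.append(s)
                    dam.append(d)
                    sex.append("male" if sexes[j] else "female")
                    breed.append(breed_name)
                    byear.append(int(year + jitter[j]))
                    bvs.append(0.5 * (bvs[s] + bvs[d])
                               + mendel_sd[j] * noise[j])
                    cohort.append(idx)
                cohort_f = None
            prev_idx = cohort
            if cohort_f is None:
                # recompute F on the pedigree so far for the next generation
                partial = Pedigree(
                    ids=np.array(ids, dtype=object),
                    sire=np.array(sire), dam=np.array(dam),
                    sex=np.array(sex, dtype=object),
                    breed=np.array(breed, dtype=object),
                    birth_year=np.array(byear, dtype=float))
                full_f = inbreeding_coefficients(partial)
                prev_f = full_f[np.array(cohort)]
            else:
                prev_f = cohort_f

    ped = Pedigree(ids=np.array(ids, dtype=object), sire=np.array(sire),
                   dam=np.array(dam), sex=np.array(sex, dtype=object),
                   breed=np.array(breed, dtype=object),
                   birth_year=np.array(byear, dtype=float))
    return ped, np.array(bvs)


def _select_parents(config, prev_idx, hip_bv, is_male, resid_var, rng):
    """Candidate parents for the next cohort under the mating scheme.

    The selection criterion is always drawn (hip BV + residual noise,
    lower is better) so the random stream is identical across schemes;
    random mating simply ignores it.  Selected sets are returned in
    original (index) order so that proportion 1.0 reproduces random
    mating exactly.
    """
    prev = np.asarray(prev_idx)
    crit = hip_bv + rng.normal(0.0, np.sqrt(resid_var), size=len(prev))
    males = prev[is_male]
    females = prev[~is_male]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("a generation lost one sex entirely; enlarge cohorts")
    if config.mating == "random":
        return males, females

    def top(group_idx, group_crit):
        k = max(1, int(np.ceil(config.selected_proportion * len(group_idx))))
        order = np.argsort(group_crit, kind="stable")[:k]
        return np.sort(group_idx[order])

    return (top(males, crit[is_male]), top(females, crit[~is_male]))


def _assortative_pairs(sires, dams, sire_crit, dam_crit):
    ns = min(len(sires), len(dams))
    s_order = np.argsort(sire_crit, kind="stable")[:ns]
    d_order = np.argsort(dam_crit, kind="stable")[:ns]
    return sires[s_order], dams[d_order]


def simulate_breeding_values(pedigree: Pedigree, G0: np.ndarray,
                             seed: int = 0) -> np.ndarray:
    """True breeding values on an existing pedigree: founders ~ N(0, G0),
    offspring = parent average + Mendelian deviation with covariance
    (1/2 - (F_s + F_d)/4) G0 (3/4 - F_p/4 with one known parent)."""
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    if np.any(np.linalg.eigvalsh(G0) <= 0):
        raise ValueError("G0 must be positive definite")
    t = G0.shape[0]
    rng = np.random.default_rng(seed)
    F = inbreeding_coefficients(pedigree)
    n = pedigree.n
    chol = np.linalg.cholesky(G0)
    z = rng.standard_normal((n, t))
    bv = np.zeros((n, t))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            bv[i] = chol @ z[i]
        elif s < 0 or d < 0:
            p = s if s >= 0 else d
            bv[i] = 0.5 * bv[p] + np.sqrt(0.75 - 0.25 * F[p]) * (chol @ z[i])
        else:
            w = np.sqrt(0.5 - 0.25 * (F[s] + F[d]))
            bv[i] = 0.5 * (bv[s] + bv[d]) + w * (chol @ z[i])
    return bv


# ---------------------------------------------------------------------------
# record simulation


def _fixed_effect_tables(config: SimConfig, pedigree: Pedigree, rng):
    breeds = sorted(pd.unique(pedigree.breed))
    years = np.arange(config.founder_year - 1, 2031)
    tables = {}
    for k in range(2):
        tables[("breed", k)] = dict(zip(
            breeds, rng.normal(0, config.breed_sd[k], size=len(breeds))))
        tables[("test_year", k)] = dict(zip(
            years, rng.normal(0, config.test_year_sd[k], size=len(years))))
        tables[("birth_year", k)] = dict(zip(
            years, rng.normal(0, config.birth_year_sd[k], size=len(years))))
    return breeds, tables


def _liability_sd(config: SimConfig, trait_idx: int) -> float:
    """Marginal residual-plus-random SD around the mixture component mean."""
    vc = config.components
    var = (vc.phenotypic_variance(trait_idx)
           + config.test_year_sd[trait_idx] ** 2
           + config.birth_year_sd[trait_idx] ** 2)
    return float(np.sqrt(var))


def liability_thresholds(config: SimConfig, trait_idx: int,
                         breed_effects: dict) -> np.ndarray:
    """Global cutpoints mapping liabilities onto ordinal categories.

    Solved so the *mixture* over realized breed effects, sexes and age
    groups hits the target cumulative category proportions (the last
    categories' mass is the target dysplasia incidence).
    """
    props = np.asarray(config.hip_category_props if trait_idx == 0
                       else config.elbow_category_props)
    if np.any(props <= 0):
        raise ValueError("category proportions must be strictly positive "
                         "(thresholds would not be strictly increasing)")
    mu0 = config.trait_means[trait_idx]
    sd = _liability_sd(config, trait_idx)
    age = np.asarray(config.age_effects[trait_idx])
    age_p = np.asarray(config.age_group_probs)
    comps = []
    for b_eff in breed_effects.values():
        for sex_w, sex_eff in ((0.5, config.sex_effect[trait_idx]), (0.5, 0.0)):
            for ap, ae in zip(age_p, age):
                comps.append((sex_w * ap / len(breed_effects),
                              mu0 + b_eff + sex_eff + ae))
    weights = np.array([c[0] for c in comps])
    means = np.array([c[1] for c in comps])

    def mixture_cdf(x):
        return float(weights @ stats.norm.cdf((x - means) / sd))

    cum = np.cumsum(props)[:-1]
    cuts = []
    lo, hi = means.min() - 8 * sd, means.max() + 8 * sd
    for target in cum:
        cuts.append(optimize.brentq(
            lambda x, t=target: mixture_cdf(x) - t, lo, hi, xtol=1e-10))
    cuts = np.asarray(cuts)
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("liability thresholds are not strictly increasing")
    return cuts


def simulate_records(pedigree: Pedigree, breeding_values: np.ndarray,
                     config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Registry-style records realized from the liability model.

    Each dog receives at most one visit; its hip and/or elbow is scored
    with the configured per-trait probabilities, residuals for dogs scored
    on both joints are correlated (R0), and liabilities are either written
    directly (``liability`` scale) or discretized through globally
    calibrated thresholds (``ordinal``).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    vc = config.components
    n = pedigree.n
    breeds, tables = _fixed_effect_tables(config, pedigree, rng)

    birth_month = rng.integers(1, 13, size=n)
    group_idx = rng.choice(len(config.age_group_probs), size=n,
                           p=config.age_group_probs)
    bounds = [(24, 24), (25, 29), (30, 36), (37, 60)]
    age_months = np.array([rng.integers(lo, hi + 1)
                           for lo, hi in (bounds[g] for g in group_idx)])
    total_month = ((pedigree.birth_year.astype(int) * 12 + birth_month - 1)
                   + age_months)
    test_year = total_month // 12
    test_month = total_month % 12 + 1

    scored = rng.random((n, 2)) < np.asarray(config.scoring_prob)
    resid = rng.multivariate_normal(np.zeros(2), vc.R0, size=n)

    u_tables = [{}, {}]
    u_vals = np.zeros((n, 2))
    for k in range(2):
        keys = list(zip(test_year, test_month))
        for i, key in enumerate(keys):
            if key not in u_tables[k]:
                u_tables[k][key] = rng.normal(0.0, np.sqrt(vc.U0[k])
                                              if vc.U0 is not None else 0.0)
            u_vals[i, k] = u_tables[k][key]

    is_male = np.array([s == "male" for s in pedigree.sex])
    liability = np.zeros((n, 2))
    for k in range(2):
        b_eff = np.array([tables[("breed", k)][b] for b in pedigree.breed])
        ty_eff = np.array([tables[("test_year", k)].get(y, 0.0)
                           for y in test_year])
        by_eff = np.array([tables[("birth_year", k)].get(int(y), 0.0)
                           for y in pedigree.birth_year.astype(int)])
        age_eff = np.asarray(config.age_effects[k])[group_idx]
        liability[:, k] = (config.trait_means[k] + b_eff
                           + config.sex_effect[k] * is_male + age_eff
                           + ty_eff + by_eff + u_vals[:, k]
                           + breeding_values[:, k] + resid[:, k])

    if config.score_scale == "ordinal":
        scores = np.zeros((n, 2))
        for k in range(2):
            cuts = liability_thresholds(config, k, tables[("breed", k)])
            scores[:, k] = np.searchsorted(cuts, liability[:, k]) + 1
    else:
        scores = liability

    rows = []
    sire_ids = np.where(pedigree.sire >= 0,
                        pedigree.ids[np.maximum(pedigree.sire, 0)], "")
    dam_ids = np.where(pedigree.dam >= 0,
                       pedigree.ids[np.maximum(pedigree.dam, 0)], "")
    for k, trait in enumerate((HIP, ELBOW)):
        idx = np.nonzero(scored[:, k])[0]
        rows.append(pd.DataFrame({
            "dog_id": pedigree.ids[idx],
            "breed": pedigree.breed[idx],
            "sex": np.asarray(pedigree.sex)[idx],
            "birth_date": [f"{int(y)}-{m:02d}" for y, m in
                           zip(pedigree.birth_year[idx], birth_month[idx])],
            "sire_id": sire_ids[idx],
            "dam_id": dam_ids[idx],
            "trait": trait,
            "score": scores[idx, k],
            "test_date": [f"{int(y)}-{m:02d}" for y, m in
                          zip(test_year[idx], test_month[idx])],
        }))
    out = pd.concat(rows, ignore_index=True)
    return out


def apply_reporting_bias(records: pd.DataFrame, config: SimConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Censor records era by era with score-dependent report probabilities.

    Emulates the registry's voluntary-release pattern: essentially no
    dysplastic grades appear before 2000.  Requires ordinal scores; with
    all probabilities 1 the output equals the input.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    test_year = records["test_date"].str.slice(0, 4).astype(int).to_numpy()
    score = np.round(records["score"].to_numpy(float)).astype(int)
    trait = records["trait"].to_numpy()
    prob = np.zeros(len(records))
    for era in config.reporting_eras:
        in_era = era.contains(test_year)
        for tr, table in ((HIP, era.hip_probs), (ELBOW, era.elbow_probs)):
            m = in_era & (trait == tr)
            if m.any():
                prob[m] = np.array([table.get(s, 0.0) for s in score[m]])
    keep = rng.random(len(records)) < prob
    kept = records[keep].reset_index(drop=True)
    logger.info("reporting bias kept %d of %d records", len(kept),
                len(records))
    return kept


def simulate_registry(config: SimConfig,
                      seed: int | None = None) -> tuple[pd.DataFrame, Pedigree]:
    """Pedigree + (bias-censored, when ordinal) registry records."""
    seed = config.seed if seed is None else seed
    ped, bv = simulate_population(config, seed=seed)
    records = simulate_records(ped, bv, config, seed=seed)
    if config.score_scale == "ordinal":
        records = apply_reporting_bias(records, config, seed=seed)
    return records, ped
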