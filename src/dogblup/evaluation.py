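"""Per-dog breeding values, prediction error variances and accuracies.

The accuracy of an EBV follows from its prediction error variance (PEV),
the corresponding diagonal element of the inverse MME coefficient matrix:

    r = sqrt(1 - PEV / sigma2_a)

A dog with no records and no informative relatives has PEV = sigma2_a and
accuracy 0; PEV = 0 gives accuracy 1.  The diagonal is extracted exactly
(chunked solves against unit vectors) below a size threshold and by a
seeded Hutchinson-type Monte Carlo diagonal estimator above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MMESolution, MMESystem
from .pedigree import Pedigree
from .sparsela import SchurFactor

logger = logging.getLogger(__name__)

#: largest system for which the exact (columnwise-solve) PEV path is used
DENSE_PEV_LIMIT = 20_000


@dataclass
class EvaluationResult:
    """Tidy per-(dog, trait) evaluation table.

    Columns: dog_id, breed, birth_year, trait, ebv, pev, accuracy, inbreeding.
    """

    table: pd.DataFrame

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait].reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_pev(system: MMESystem, method: str = "auto",
                n_samples: int = 256, seed: int = 0) -> np.ndarray:
    """PEV per animal per trait: animal-block diagonal of C^-1.

    ``method``: 'selected' reads the diagonal from the block selected
    inverse (exact at any size, when the system was factored in block
    form); 'exact' solves unit vectors in chunks; 'mc' uses the Rademacher
    diagonal estimator z * (C^-1 z) with a reported SE; 'auto' prefers
    selected, then exact below :data:`DENSE_PEV_LIMIT` equations.
    """
    n, q, t = system.n_equations, system.n_animals, system.n_traits
    lu = system.factorize()
    if method == "auto":
        if isinstance(lu, SchurFactor):
            method = "selected"
        else:
            method = "exact" if n <= DENSE_PEV_LIMIT else "mc"
    if method == "selected":
        if not isinstance(lu, SchurFactor):
            raise ValueError("selected PEV needs a block factorization")
        diag = lu.cinv_diagonal(np.arange(system.off_animal, n))
    elif method == "exact":
        diag = np.empty(q * t)
        cols = np.arange(system.off_animal, n)
        chunk = 512
        for start in range(0, len(cols), chunk):
            block = cols[start:start + chunk]
            rhs = np.zeros((n, len(block)))
            rhs[block, np.arange(len(block))] = 1.0
            sol = lu.solve(rhs)
            diag[start:start + len(block)] = sol[block, np.arange(len(block))]
    elif method == "mc":
        rng = np.random.default_rng(seed)
        acc = np.zeros(n)
        acc2 = np.zeros(n)
        for _ in range(n_samples):
            z = rng.choice([-1.0, 1.0], size=n)
            est = z * lu.solve(z)
            acc += est
            acc2 += est ** 2
        diag_full = acc / n_samples
        se = np.sqrt(np.clip(acc2 / n_samples - diag_full ** 2, 0, None)
                     / n_samples)
        logger.info("MC PEV: median relative SE %.3f",
                    float(np.median(se[system.off_animal:]
                                    / np.abs(diag_full[system.off_animal:]))))
        diag = diag_full[system.off_animal:]
    else:
        raise ValueError(f"unknown PEV method {method!r}")
    pev = diag.reshape(t, q).T
    if np.any(pev < -1e-8):
        raise ValueError("negative PEV: coefficient matrix is indefinite")
    return np.clip(pev, 0.0, None)


def accuracy(pev, sigma2_a, inbreeding=None, tolerance: float = 1e-6):
    """r = sqrt(1 - PEV/sigma2_a), clipped to [0, 1].

    PEV above sigma2_a*(1+F) (plus tolerance) indicates a broken system
    and raises.  Tiny numerical excursions are clipped.
    """
    pev = np.asarray(pev, dtype=float)
    if sigma2_a <= 0:
        raise ValueError("additive variance must be positive")
    upper = sigma2_a * (1.0 + (np.zeros_like(pev) if inbreeding is None
                               else np.asarray(inbreeding, dtype=float)))
    if np.any(pev > upper * (1 + tolerance) + tolerance * sigma2_a):
        worst = float(np.max(pev / sigma2_a))
        raise ValueError(f"PEV exceeds sigma2_a*(1+F) (max ratio {worst:.4f}); "
                         "check the assembled system")
    radicand = np.clip(1.0 - pev / sigma2_a, 0.0, 1.0)
    return np.sqrt(radicand)


def evaluate(system: MMESystem, solution: MMESolution,
             pev_method: str = "auto", seed: int = 0) -> EvaluationResult:
    """Full evaluation table: EBV, PEV, accuracy and F for every animal."""
    ped: Pedigree = system.design.pedigree
    ebv = solution.ebv
    pev = compute_pev(system, method=pev_method, seed=seed)
    F = system.rel.inbreeding
    rows = []
    for k, trait in enumerate(system.traits):
        s2a = float(system.components.G0[k, k])
        acc = accuracy(pev[:, k], s2a, inbreeding=F)
        rows.append(pd.DataFrame({
            "dog_id": ped.ids, "breed": ped.breed,
            "birth_year": ped.birth_year, "trait": trait,
            "ebv": ebv[:, k], "pev": pev[:, k], "accuracy": acc,
            "inbreeding": F}))
    return EvaluationResult(table=pd.concat(rows, ignore_index=True))


def ebv_accuracy_correlation(result: EvaluationResult, trait: str,
                             by_breed: bool = False):
    """Pearson correlation between EBVs and their accuracies.

    Returns a float overall, or a {breed: r} dict with ``by_breed``.
    Zero variance in either variable is signalled as an error; groups need
    at least 3 dogs.
    """
    frame = result.for_trait(trait)

    def corr(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            raise ValueError("need at least 3 dogs for a correlation")
        e, a = sub["ebv"].to_numpy(), sub["accuracy"].to_numpy()
        if np.std(e) == 0 or np.std(a) == 0:
            raise ValueError("EBV-accuracy correlation undefined: a variable "
                             "has zero variance")
        return float(stats.pearsonr(e, a)[0])

    if not by_breed:
        return corr(frame)
    return {str(b): corr(sub) for b, sub in frame.groupby("breed")}


def parent_offspring_prediction(phenotypes: pd.DataFrame, pedigree: Pedigree,
                                result: EvaluationResult,
                                trait: str) -> tuple[float, float]:
    """Correlations of offspring with midparent predictions.

    ``phenotypes`` needs columns dog_id and value.  For every trio in
    which both parents are known and all three have phenotypes, the
    phenotype-based prediction is half the sum of the parents' scores;
    the EBV-based prediction is the midparent EBV.  Returns
    (phenotype-based r, EBV-based r); fewer than 3 complete trios is
    signalled.
    """
    pheno = dict(zip(phenotypes["dog_id"], phenotypes["value"]))
    ebv_frame = result.for_trait(trait)
    ebv = dict(zip(ebv_frame["dog_id"], ebv_frame["ebv"]))

    off_p, mid_p, off_e, mid_e = [], [], [], []
    for i in range(pedigree.n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 or d < 0:
            continue
        dog, sire, dam = pedigree.ids[i], pedigree.ids[s], pedigree.ids[d]
        if dog in pheno and sire in pheno and dam in pheno:
            off_p.append(pheno[dog])
            mid_p.append(0.5 * (pheno[sire] + pheno[dam]))
        if dog in ebv and sire in ebv and dam in ebv:
            off_e.append(ebv[dog])
            mid_e.append(0.5 * (ebv[sire] + ebv[dam]))
    if len(off_p) < 3 or len(off_e) < 3:
        raise ValueError("fewer than 3 complete parent-offspring trios")
    r_p = float(stats.pearsonr(off_p, mid_p)[0])
    r_e = float(stats.pearsonr(off_e, mid_e)[0])
    return r_p, r_e
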