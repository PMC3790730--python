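"""Bivariate linear mixed ("animal") model: design matrices and MME.

The evaluation model for hip (trait 1) and elbow (trait 2) scores is

    y_k = X_k b_k + Z_k a_k + W_k u_k + e_k ,   k = 1, 2

with fixed effects b_k (breed, sex, test-year period, test year nested in
period, birth year, age group; the elbow sub-model omits the period), the
additive genetic effect a with var(a) = G0 (x) A, the test-year-by-month
environmental effect u with var(u) = diag(U0) (x) I, and residuals with
2x2 covariance R0 for dogs scored on both traits.  Henderson's mixed model
equations (MME) jointly solve fixed effects and BLUP predictions; dogs
scored for a single trait contribute through the scalar inverse of their
trait's residual variance, dogs with both records through the 2x2 inverse
of R0.

The :class:`MMESystem` keeps the pieces of the coefficient matrix cached
separately (record cross-products by residual pattern, the G0^-1 (x) A^-1
genetic block, the diagonal u block) so REML can rebuild the system for
perturbed variance components at the cost of a few sparse additions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import lapack

from .pedigree import Pedigree, RelationshipStructure
from .registry import HIP, ELBOW, TraitDataset
from .sparsela import SchurFactor, SpluFactor

logger = logging.getLogger(__name__)

#: below this many equations a monolithic sparse LU is used; above it the
#: breed-block Schur factorization (see sparsela) is much faster
MONOLITHIC_FACTOR_LIMIT = 2000

DEFAULT_FIXED_FACTORS = {
    HIP: ["breed", "sex", "test_year_period", "test_year", "birth_year",
          "age_group"],
    ELBOW: ["breed", "sex", "test_year", "birth_year", "age_group"],
}


@dataclass
class ModelSpec:
    """Which effects enter each trait's sub-model."""

    fixed_factors: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_FIXED_FACTORS.items()})
    include_u: bool = True
    #: first test years of the 2nd.. scoring-strategy eras
    period_breaks: tuple[int, ...] = (1986, 2000)
    #: reference-level policy: all factors after the first drop their first
    #: observed level (the first factor plays the per-level intercept role)
    drop_reference: bool = True

    def traits_for(self, datasets: dict[str, TraitDataset]) -> list[str]:
        order = [t for t in (HIP, ELBOW) if t in datasets]
        extra = [t for t in datasets if t not in order]
        return order + extra


@dataclass
class VarianceComponents:
    """G0 (additive, t x t), U0 (year-month variances, length t), R0
    (residual, t x t)."""

    G0: np.ndarray
    R0: np.ndarray
    U0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        if self.U0 is not None:
            self.U0 = np.atleast_1d(np.asarray(self.U0, dtype=float))
        t = self.G0.shape[0]
        if self.R0.shape != (t, t):
            raise ValueError("G0 and R0 must have matching dimensions")
        if self.U0 is not None and self.U0.shape != (t,):
            raise ValueError("U0 must hold one variance per trait")

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G0.copy(), self.R0.copy(),
                                  None if self.U0 is None else self.U0.copy())

    def scaled(self, factor: float) -> "VarianceComponents":
        return VarianceComponents(self.G0 * factor, self.R0 * factor,
                                  None if self.U0 is None else self.U0 * factor)

    def phenotypic_variance(self, trait_index: int) -> float:
        u = 0.0 if self.U0 is None else self.U0[trait_index]
        return float(self.G0[trait_index, trait_index] + u
                     + self.R0[trait_index, trait_index])

    def validate(self) -> None:
        for name, mat in (("G0", self.G0), ("R0", self.R0)):
            if np.any(np.linalg.eigvalsh(mat) <= 0):
                raise ValueError(f"{name} must be positive definite")
        if self.U0 is not None and np.any(self.U0 < 0):
            raise ValueError("U0 variances must be nonnegative")


def published_components() -> VarianceComponents:
    """The published bivariate estimates for original-scale hip and elbow
    scores, used as the generator's default truth."""
    return VarianceComponents(
        G0=np.array([[0.08488, 0.00270], [0.00270, 0.00559]]),
        U0=np.array([0.00057, 0.00002]),
        R0=np.array([[0.28800, 0.00749], [0.00749, 0.02908]]))


# ---------------------------------------------------------------------------
# design construction


@dataclass
class TraitDesign:
    trait: str
    X: sp.csr_matrix
    fixed_labels: list[tuple[str, str]]
    u_index: np.ndarray | None
    u_labels: list[str]
    animal_index: np.ndarray
    y: np.ndarray
    dog_ids: np.ndarray


@dataclass
class DesignLayout:
    traits: list[str]
    per_trait: dict[str, TraitDesign]
    pedigree: Pedigree

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _factor_values(frame: pd.DataFrame, factor: str,
                   spec: ModelSpec) -> np.ndarray:
    if factor == "test_year_period":
        breaks = np.asarray(spec.period_breaks)
        idx = np.searchsorted(breaks, frame["test_year"].to_numpy(),
                              side="right")
        return np.char.add("period", idx.astype(str))
    if factor not in frame.columns:
        raise ValueError(f"dataset lacks column for factor {factor!r}")
    return frame[factor].astype(str).to_numpy()


def _dummy_columns(values: np.ndarray, factor: str, drop_first: bool,
                   nest_in: np.ndarray | None = None):
    """Indicator columns for a factor's observed levels.

    With ``nest_in`` given (nesting factor values), the first observed
    level within each nesting group is the dropped reference.
    """
    if nest_in is not None:
        combo = pd.DataFrame({"g": nest_in, "v": values})
        keep_levels = []
        for g, sub in combo.groupby("g", sort=True):
            levels = sorted(sub["v"].unique())
            keep_levels.extend((g, v) for v in levels[1:])
        key = list(zip(nest_in, values))
        labels = [f"{g}:{v}" for g, v in keep_levels]
        level_map = {lv: j for j, lv in enumerate(keep_levels)}
        col = np.array([level_map.get(k, -1) for k in key])
    else:
        levels = sorted(pd.unique(values))
        if drop_first and len(levels) > 1:
            levels = levels[1:]
        labels = [str(lv) for lv in levels]
        level_map = {lv: j for j, lv in enumerate(levels)}
        col = np.array([level_map.get(v, -1) for v in values])
    n = len(values)
    mask = col >= 0
    X = sp.csr_matrix((np.ones(mask.sum()), (np.nonzero(mask)[0], col[mask])),
                      shape=(n, len(labels)))
    return X, [(factor, lab) for lab in labels]


def _full_rank_repair(X: sp.csr_matrix, labels: list) -> tuple[sp.csr_matrix, list]:
    """Drop linearly dependent fixed-effect columns via pivoted Cholesky of
    the Gram matrix (handles accidental confounding such as birth year vs
    test year vs age group on small datasets)."""
    if X.shape[1] == 0:
        return X, labels
    gram = np.asarray((X.T @ X).todense())
    scale = np.sqrt(np.clip(np.diag(gram), 1e-300, None))
    gramn = gram / scale[:, None] / scale[None, :]
    c, piv, rank, _ = lapack.dpstrf(gramn, lower=1, tol=1e-8)
    keep = np.sort(piv[:rank] - 1)
    if rank < X.shape[1]:
        dropped = [labels[j] for j in range(X.shape[1]) if j not in set(keep)]
        logger.info("dropped %d dependent fixed-effect columns: %s",
                    len(dropped), dropped[:8])
        X = X[:, keep].tocsr()
        labels = [labels[j] for j in keep]
    return X, labels


def build_design(datasets: dict[str, TraitDataset], pedigree: Pedigree,
                 spec: ModelSpec | None = None) -> DesignLayout:
    """Per-trait incidence structures for the MME.

    Every scored dog must exist in the pedigree (hard failure otherwise);
    pedigree animals without records still receive equations and are
    evaluated through their relatives.
    """
    spec = spec or ModelSpec()
    traits = spec.traits_for(datasets)
    per_trait: dict[str, TraitDesign] = {}
    for trait in traits:
        frame = datasets[trait].data
        missing = [d for d in frame["dog_id"] if not pedigree.contains(d)]
        if missing:
            raise ValueError(
                f"{len(missing)} scored {trait} dogs absent from pedigree, "
                f"e.g. {missing[:5]}")
        blocks, labels = [], []
        factors = spec.fixed_factors.get(trait, [])
        period_vals = None
        if "test_year_period" in factors:
            period_vals = _factor_values(frame, "test_year_period", spec)
        for pos, factor in enumerate(factors):
            values = _factor_values(frame, factor, spec)
            nest = (period_vals if factor == "test_year"
                    and period_vals is not None else None)
            Xf, labs = _dummy_columns(
                values, factor,
                drop_first=spec.drop_reference and pos > 0, nest_in=nest)
            blocks.append(Xf)
            labels.extend(labs)
        if blocks:
            X = sp.hstack(blocks, format="csr")
        else:
            X = sp.csr_matrix((len(frame), 0))
        X, labels = _full_rank_repair(X, labels)

        if spec.include_u and {"test_year", "test_month"} <= set(frame.columns):
            key = (frame["test_year"].astype(int).astype(str) + "-"
                   + frame["test_month"].astype(int).astype(str))
            u_labels = sorted(key.unique())
            u_map = {k: j for j, k in enumerate(u_labels)}
            u_index = key.map(u_map).to_numpy(np.int64)
        else:
            u_index, u_labels = None, []

        per_trait[trait] = TraitDesign(
            trait=trait, X=X, fixed_labels=labels, u_index=u_index,
            u_labels=list(u_labels),
            animal_index=pedigree.index_of(frame["dog_id"]),
            y=frame["value"].to_numpy(float),
            dog_ids=frame["dog_id"].to_numpy())
    return DesignLayout(traits=traits, per_trait=per_trait, pedigree=pedigree)


# ---------------------------------------------------------------------------
# mixed model equations


def _inv2(mat: np.ndarray) -> np.ndarray:
    out = np.linalg.inv(mat)
    return 0.5 * (out + out.T)


def sparse_factor(C: sp.csc_matrix):
    """Sparse LU of an SPD coefficient matrix in SuperLU symmetric mode
    (minimum-degree on the symmetric pattern, no diagonal pivoting), which
    keeps fill-in manageable for animal-model equations."""
    return spla.splu(C, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                     options={"SymmetricMode": True})


@dataclass
class MMESolution:
    solution: np.ndarray
    system: "MMESystem"
    method: str
    iterations: int = 0
    residual_norm: float = 0.0

    @property
    def ebv(self) -> np.ndarray:
        """(n_animals, n_traits) matrix of estimated breeding values."""
        sys = self.system
        q, t = sys.n_animals, sys.n_traits
        return self.solution[sys.off_animal:sys.off_animal + q * t] \
            .reshape(t, q).T

    def fixed_effects(self) -> pd.DataFrame:
        sys = self.system
        rows = []
        for k, trait in enumerate(sys.traits):
            sol = self.solution[sys.off_fixed[k]:
                                sys.off_fixed[k] + sys.n_fixed[k]]
            for (factor, level), est in zip(sys.fixed_labels[k], sol):
                rows.append((trait, factor, level, est))
        return pd.DataFrame(rows, columns=["trait", "factor", "level",
                                           "estimate"])

    def u_effects(self) -> pd.DataFrame:
        sys = self.system
        rows = []
        for k, trait in enumerate(sys.traits):
            sol = self.solution[sys.off_u[k]:sys.off_u[k] + sys.n_u[k]]
            for label, est in zip(sys.u_labels[k], sol):
                rows.append((trait, label, est))
        return pd.DataFrame(rows, columns=["trait", "year_month", "estimate"])


class MMESystem:
    """Assembled mixed model equations C s = rhs for given components.

    Equation order: fixed effects per trait, then year-month effects per
    trait, then the animal block (trait-major: all animals for trait 1,
    then trait 2).  The record cross-products are cached per residual
    pattern so the system can be rebuilt for new variance components
    cheaply (the REML estimator relies on this).
    """

    def __init__(self, design: DesignLayout, relationship: RelationshipStructure,
                 components: VarianceComponents):
        if components.n_traits != design.n_traits:
            raise ValueError("components dimension does not match design")
        components.validate()
        self.design = design
        self.rel = relationship
        self.traits = list(design.traits)
        self.n_traits = len(self.traits)
        self.n_animals = design.pedigree.n

        t, q = self.n_traits, self.n_animals
        per = [design.per_trait[tr] for tr in self.traits]
        self.n_fixed = [p.X.shape[1] for p in per]
        self.fixed_labels = [p.fixed_labels for p in per]
        self.n_u = [len(p.u_labels) for p in per]
        self.u_labels = [p.u_labels for p in per]
        self.has_u = any(self.n_u)
        self.off_fixed = list(np.concatenate([[0], np.cumsum(self.n_fixed)[:-1]]))
        base = int(sum(self.n_fixed))
        self.off_u = []
        for m in self.n_u:
            self.off_u.append(base)
            base += m
        self.off_animal = base
        self.n_equations = base + t * q

        # global record incidence matrix M, rows trait-major
        blocks = []
        ys = []
        for k, p in enumerate(per):
            n_k = len(p.y)
            parts = [sp.csr_matrix((n_k, self.off_fixed[k])), p.X]
            pad = self.off_u[k] - (self.off_fixed[k] + self.n_fixed[k])
            parts.append(sp.csr_matrix((n_k, pad)))
            if p.u_index is not None and self.n_u[k]:
                parts.append(sp.csr_matrix(
                    (np.ones(n_k), (np.arange(n_k), p.u_index)),
                    shape=(n_k, self.n_u[k])))
            else:
                parts.append(sp.csr_matrix((n_k, self.n_u[k])))
            pad2 = (self.off_animal - (self.off_u[k] + self.n_u[k])
                    + k * q)
            parts.append(sp.csr_matrix((n_k, pad2)))
            parts.append(sp.csr_matrix(
                (np.ones(n_k), (np.arange(n_k), p.animal_index)),
                shape=(n_k, q)))
            parts.append(sp.csr_matrix((n_k, (t - 1 - k) * q)))
            blocks.append(sp.hstack(parts, format="csr"))
            ys.append(p.y)
        self.M = sp.vstack(blocks, format="csr")
        self.y = np.concatenate(ys)
        self.row_offsets = np.concatenate(
            [[0], np.cumsum([len(p.y) for p in per])])

        self._build_residual_patterns(per)
        self._cache_gram_pieces()
        self._symbolic_cache: dict = {}
        self._ainv_lu = None
        self.set_components(components)

    # -- residual pattern bookkeeping ------------------------------------

    def _build_residual_patterns(self, per) -> None:
        t = self.n_traits
        if t == 1:
            self.pair_rows = (np.array([], int), np.array([], int))
            self.single_rows = [np.arange(len(per[0].y))]
            return
        if t != 2:
            raise NotImplementedError("only 1- or 2-trait systems supported")
        rows1 = {d: i for i, d in enumerate(per[0].dog_ids)}
        both1, both2 = [], []
        for i2, d in enumerate(per[1].dog_ids):
            if d in rows1:
                both1.append(rows1[d])
                both2.append(i2)
        both1 = np.asarray(both1, int)
        both2 = np.asarray(both2, int)
        n1, n2 = len(per[0].y), len(per[1].y)
        s1 = np.setdiff1d(np.arange(n1), both1)
        s2 = np.setdiff1d(np.arange(n2), both2)
        # global row numbers
        self.pair_rows = (both1, both2 + n1)
        self.single_rows = [s1, s2 + n1]

    def _cache_gram_pieces(self) -> None:
        M, y = self.M, self.y
        self._gram = {}
        self._vec = {}
        self._sca = {}
        for k, rows in enumerate(self.single_rows):
            Mk = M[rows]
            yk = y[rows]
            self._gram[f"s{k}"] = (Mk.T @ Mk).tocsc()
            self._vec[f"s{k}"] = Mk.T @ yk
            self._sca[f"s{k}"] = float(yk @ yk)
        r1, r2 = self.pair_rows
        if len(r1):
            M1, M2 = M[r1], M[r2]
            y1, y2 = y[r1], y[r2]
            self._gram["b11"] = (M1.T @ M1).tocsc()
            self._gram["b22"] = (M2.T @ M2).tocsc()
            b12 = (M1.T @ M2).tocsc()
            self._gram["b12"] = (b12 + b12.T).tocsc()
            self._vec["b1"] = M1.T @ y1
            self._vec["b2"] = M2.T @ y2
            self._vec["c1"] = M1.T @ y2
            self._vec["c2"] = M2.T @ y1
            self._sca["b11"] = float(y1 @ y1)
            self._sca["b22"] = float(y2 @ y2)
            self._sca["b12"] = float(y1 @ y2)

    # -- assembly for a given set of components --------------------------

    def _residual_weights(self, R0: np.ndarray):
        if self.n_traits == 1:
            return np.array([[1.0 / R0[0, 0]]])
        return _inv2(R0)

    def data_block(self, R0: np.ndarray) -> tuple[sp.csc_matrix, np.ndarray, float]:
        """M' R^-1 M, M' R^-1 y and y' R^-1 y for residual covariance R0."""
        W = self._residual_weights(R0)
        C = None
        rhs = np.zeros(self.n_equations)
        yry = 0.0

        def acc(mat, coef):
            # keep every structural block in the sum even at coefficient 0
            # so the assembled pattern is invariant across component values
            # (cached symbolic factorizations rely on a stable pattern)
            nonlocal C
            contrib = mat * coef
            contrib.data[contrib.data == 0.0] = 1e-300
            C = contrib if C is None else C + contrib

        for k in range(self.n_traits):
            w = 1.0 / R0[k, k]
            if len(self.single_rows[k]):
                acc(self._gram[f"s{k}"], w)
                rhs += w * self._vec[f"s{k}"]
                yry += w * self._sca[f"s{k}"]
        if len(self.pair_rows[0]):
            w11, w12, w22 = W[0, 0], W[0, 1], W[1, 1]
            acc(self._gram["b11"], w11)
            acc(self._gram["b22"], w22)
            acc(self._gram["b12"], w12)
            rhs += (w11 * self._vec["b1"] + w22 * self._vec["b2"]
                    + w12 * (self._vec["c1"] + self._vec["c2"]))
            yry += (w11 * self._sca["b11"] + w22 * self._sca["b22"]
                    + 2 * w12 * self._sca["b12"])
        if C is None:
            C = sp.csc_matrix((self.n_equations, self.n_equations))
        return C, rhs, yry

    def data_block_derivative(self, R0: np.ndarray, i: int,
                              j: int) -> sp.csc_matrix:
        """d(M' R^-1 M)/dr_ij for the symmetric residual parameter (i, j)."""
        parts = []

        def acc(mat, coef):
            if coef != 0.0:
                parts.append(mat * coef)

        if i == j:
            if len(self.single_rows[i]):
                acc(self._gram[f"s{i}"], -1.0 / R0[i, i] ** 2)
        if self.n_traits == 2 and len(self.pair_rows[0]):
            W = self._residual_weights(R0)
            E = np.zeros((2, 2))
            E[i, j] = E[j, i] = 1.0
            dW = -W @ E @ W
            acc(self._gram["b11"], dW[0, 0])
            acc(self._gram["b22"], dW[1, 1])
            acc(self._gram["b12"], dW[0, 1])
        if not parts:
            return sp.csc_matrix((self.n_equations, self.n_equations))
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out

    def ainv_factor(self):
        """Cached sparse factorization of A^-1 (to apply A as an operator)."""
        if getattr(self, "_ainv_lu", None) is None:
            self._ainv_lu = sparse_factor(self.rel.ainv.tocsc())
        return self._ainv_lu

    def random_blocks(self, components: VarianceComponents) -> sp.csc_matrix:
        """G0^-1 (x) A^-1 on the animal block plus the diagonal u block."""
        t, q = self.n_traits, self.n_animals
        g_inv = _inv2(components.G0)
        # expand G0^-1 (x) A^-1 with every trait-pair block structurally
        # present (zero covariances must not change the sparsity pattern)
        ainv = self.rel.ainv.tocoo()
        data, rr, cc = [], [], []
        for i in range(t):
            for j in range(t):
                coef = g_inv[i, j] if g_inv[i, j] != 0.0 else 1e-300
                rr.append(ainv.row + self.off_animal + i * q)
                cc.append(ainv.col + self.off_animal + j * q)
                data.append(ainv.data * coef)
        if self.has_u:
            if components.U0 is None:
                raise ValueError("system has year-month effects but U0 is None")
            for k in range(t):
                if self.n_u[k] == 0:
                    continue
                idx = np.arange(self.off_u[k], self.off_u[k] + self.n_u[k])
                rr.append(idx)
                cc.append(idx)
                data.append(np.full(self.n_u[k], 1.0 / components.U0[k]))
        return sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rr), np.concatenate(cc))),
            shape=(self.n_equations, self.n_equations)).tocsc()

    def coefficient_matrix(self, components: VarianceComponents | None = None):
        components = components or self.components
        C_data, rhs, yry = self.data_block(components.R0)
        C = (C_data + self.random_blocks(components)).tocsc()
        return C, rhs, yry

    def set_components(self, components: VarianceComponents) -> None:
        self.components = components
        self.C, self.rhs, self.yry = self.coefficient_matrix(components)
        self._lu = None

    # -- determinants ----------------------------------------------------

    def logdet_terms(self, components: VarianceComponents) -> float:
        """log|R| + log|G| + log|U| for the current data structure."""
        t, q = self.n_traits, self.n_animals
        R0, G0 = components.R0, components.G0
        ld = q * float(np.linalg.slogdet(G0)[1]) + t * self.rel.logdet_a
        for k in range(t):
            ld += len(self.single_rows[k]) * np.log(R0[k, k])
        if len(self.pair_rows[0]):
            ld += len(self.pair_rows[0]) * float(np.linalg.slogdet(R0)[1])
        if self.has_u and components.U0 is not None:
            for k in range(t):
                if self.n_u[k]:
                    ld += self.n_u[k] * np.log(components.U0[k])
        return ld

    # -- residual metric -------------------------------------------------

    def residual_inverse(self, R0: np.ndarray | None = None) -> sp.csc_matrix:
        """Sparse R^-1 over record rows (diagonal plus both-trait pairs)."""
        R0 = self.components.R0 if R0 is None else R0
        W = self._residual_weights(R0)
        n = len(self.y)
        rows, cols, vals = [], [], []
        for k in range(self.n_traits):
            s = self.single_rows[k]
            rows.append(s)
            cols.append(s)
            vals.append(np.full(len(s), 1.0 / R0[k, k]))
        r1, r2 = self.pair_rows
        if len(r1):
            rows.extend([r1, r2, r1, r2])
            cols.extend([r1, r2, r2, r1])
            vals.extend([np.full(len(r1), W[0, 0]),
                         np.full(len(r1), W[1, 1]),
                         np.full(len(r1), W[0, 1]),
                         np.full(len(r1), W[0, 1])])
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)).tocsc()

    # -- solving ---------------------------------------------------------

    def equation_partition(self) -> tuple[list[np.ndarray], np.ndarray]:
        """(per-breed animal equation groups, shared fixed+u equations)."""
        q, t = self.n_animals, self.n_traits
        groups = []
        for _, (r0, r1) in self.design.pedigree.breed_ranges.items():
            groups.append(np.concatenate(
                [self.off_animal + k * q + np.arange(r0, r1)
                 for k in range(t)]))
        return groups, np.arange(self.off_animal)

    def factorize(self):
        """Cached factorization of C (SpluFactor or breed-block Schur)."""
        if self._lu is None:
            groups, _ = self.equation_partition()
            if self.n_equations <= MONOLITHIC_FACTOR_LIMIT or len(groups) == 0:
                self._lu = SpluFactor(self.C)
            else:
                self._lu = SchurFactor(self.C, *self.equation_partition(),
                                       symbolic_cache=self._symbolic_cache)
        return self._lu

    def logdet_c(self) -> float:
        return self.factorize().logdet()

    def solve(self, method: str = "auto", tol: float = 1e-10,
              max_iter: int = 5000,
              direct_limit: int = 50_000) -> MMESolution:
        """Solve the MME directly (sparse LU) or by Jacobi-preconditioned CG."""
        if method == "auto":
            method = "direct" if self.n_equations <= direct_limit else "pcg"
        if method == "direct":
            sol = self.factorize().solve(self.rhs)
            res = float(np.linalg.norm(self.C @ sol - self.rhs))
            return MMESolution(sol, self, "direct", 0, res)
        if method != "pcg":
            raise ValueError(f"unknown solver {method!r}")
        diag = self.C.diagonal()
        precond = spla.LinearOperator(
            self.C.shape, matvec=lambda v: v / np.where(diag > 0, diag, 1.0))
        iters = 0

        def count(_):
            nonlocal iters
            iters += 1

        sol, info = spla.cg(self.C, self.rhs, rtol=tol, maxiter=max_iter,
                            M=precond, callback=count)
        res = float(np.linalg.norm(self.C @ sol - self.rhs))
        if info != 0:
            raise RuntimeError(
                f"PCG failed to converge in {max_iter} iterations "
                f"(residual norm {res:.3e})")
        return MMESolution(sol, self, "pcg", iters, res)

    # -- index map -------------------------------------------------------

    def equation_index(self, kind: str, trait: str, key) -> int:
        """Global equation number for (effect kind, trait, level/animal)."""
        k = self.traits.index(trait)
        if kind == "fixed":
            return self.off_fixed[k] + self.fixed_labels[k].index(key)
        if kind == "u":
            return self.off_u[k] + self.u_labels[k].index(key)
        if kind == "animal":
            idx = (key if isinstance(key, (int, np.integer))
                   else self.design.pedigree.index_of([key])[0])
            return self.off_animal + k * self.n_animals + int(idx)
        raise ValueError(f"unknown effect kind {kind!r}")


def assemble_mme(design: DesignLayout, relationship: RelationshipStructure,
                 components: VarianceComponents) -> MMESystem:
    """Build Henderson's MME for the given design and variance components."""
    return MMESystem(design, relationship, components)


def solve_mme(system: MMESystem, method: str = "auto", tol: float = 1e-10,
              max_iter: int = 5000) -> MMESolution:
    return system.solve(method=method, tol=tol, max_iter=max_iter)
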