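"""Restricted maximum likelihood estimation of the variance components.

The restricted log-likelihood of the mixed model is evaluated through the
MME sparse factorization,

    -2 l_R = log|R| + log|G| + log|U| + log|C| + y'Py + const,

where C is the MME coefficient matrix and y'Py = y'R^-1 y - s'rhs with s
the MME solutions.  Updates use the average-information (AI) algorithm:

* the AI matrix is exact, AI_ij = f_i' P f_j / 2 with f_i = dV/dtheta_i
  . Py, each P-application being one solve against the current
  factorization;
* the quadratic part of the score, Py' f_i, is exact;
* the trace part splits into closed forms for the log|R| / log|G| /
  log|U| derivatives plus tr(C^-1 dC/dtheta_i), which is computed exactly
  -- by central finite differences of log|C| on small systems (one
  factorization per perturbation) or through the block selected inverse
  on large ones (see :mod:`dogblup.sparsela`).  A seeded Hutchinson
  estimator reusing the base factorization is available as an option
  (identical probes every iteration keep it deterministic).

When an AI step would leave the parameter space or decrease the
likelihood it is halved repeatedly, with a final scaled-gradient
fallback, so the accepted likelihood never decreases.

Parameter order for two traits: (g11, g21, g22, [u1, u2,] r11, r21, r22);
for one trait (g, [u,] r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import scipy.sparse as sp

from .model import MMESystem, VarianceComponents, DesignLayout, assemble_mme
from .pedigree import RelationshipStructure
from .sparsela import SchurFactor, SpluFactor

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-10
#: systems below this use finite-difference log|C| derivatives; larger
#: ones the exact block selected inverse
_EXACT_TRACE_LIMIT = 2000
_PROBE_SEED = 872031463


# ---------------------------------------------------------------------------
# parameter packing


def _tril_indices(t: int):
    return np.tril_indices(t)


def pack_components(vc: VarianceComponents, has_u: bool) -> np.ndarray:
    t = vc.n_traits
    tril = _tril_indices(t)
    parts = [vc.G0[tril]]
    if has_u:
        parts.append(np.asarray(vc.U0))
    parts.append(vc.R0[tril])
    return np.concatenate(parts)


def unpack_components(theta: np.ndarray, t: int,
                      has_u: bool) -> VarianceComponents:
    tril = _tril_indices(t)
    k = len(tril[0])
    G0 = np.zeros((t, t))
    G0[tril] = theta[:k]
    G0 = G0 + np.tril(G0, -1).T
    pos = k
    U0 = None
    if has_u:
        U0 = np.array(theta[pos:pos + t])
        pos += t
    R0 = np.zeros((t, t))
    R0[tril] = theta[pos:pos + k]
    R0 = R0 + np.tril(R0, -1).T
    return VarianceComponents(G0=G0, R0=R0, U0=U0)


def _clip_pd(mat: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix onto the PD cone by eigenvalue clipping."""
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite covariance matrix")
    vals, vecs = np.linalg.eigh(mat)
    if vals[0] > floor:
        return mat
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def project_components(vc: VarianceComponents,
                       u_floor: float = _EIG_FLOOR) -> VarianceComponents:
    U0 = None if vc.U0 is None else np.clip(vc.U0, u_floor, None)
    return VarianceComponents(G0=_clip_pd(vc.G0), R0=_clip_pd(vc.R0), U0=U0)


def _components_valid(vc: VarianceComponents) -> bool:
    """True when every determinant term of the likelihood is computable."""
    for mat in (vc.G0, vc.R0):
        if not np.all(np.isfinite(mat)) or np.linalg.eigvalsh(mat)[0] <= 0:
            return False
    if vc.U0 is not None and np.any(vc.U0 <= 0):
        return False
    return True


# ---------------------------------------------------------------------------
# likelihood machinery


def restricted_loglik(system: MMESystem,
                      vc: VarianceComponents) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood (up to a constant) and MME solutions."""
    system.set_components(vc)
    sol = system.factorize().solve(system.rhs)
    ld = system.logdet_terms(vc) + system.logdet_c()
    ypy = system.yry - float(sol @ system.rhs)
    return -0.5 * (ld + ypy), sol


def _logdet_c(system: MMESystem, vc: VarianceComponents) -> float:
    C, _, _ = system.coefficient_matrix(vc)
    return SpluFactor(C).logdet()


def _sym_basis(t: int, i: int, j: int) -> np.ndarray:
    """Symmetric elementary matrix for the (i, j) covariance parameter."""
    E = np.zeros((t, t))
    E[i, j] = 1.0
    E[j, i] = 1.0
    return E


class _Gradient:
    """Score and AI matrix at the system's current components."""

    def __init__(self, system: MMESystem, sol: np.ndarray,
                 probes: np.ndarray | None = None):
        self.system = system
        vc = system.components
        self.vc = vc
        self.t = vc.n_traits
        self.has_u = system.has_u
        self.theta = pack_components(vc, self.has_u)
        self.lu = system.factorize()
        self.probes = probes

        rinv = system.residual_inverse()
        resid = system.y - system.M @ sol
        self.Py = rinv @ resid
        self.rinv = rinv
        self.MtPy = system.M.T @ self.Py
        self._ainv_lu = system.ainv_factor()

    # each f_i = dV/dtheta_i . Py lives in record-row space
    def _f_vectors(self) -> list[np.ndarray]:
        sys, t, q = self.system, self.t, self.system.n_animals
        Py = self.Py
        v = self.MtPy[sys.off_animal:].reshape(t, q)
        Av = np.stack([self._ainv_lu.solve(v[k]) for k in range(t)])
        fs: list[np.ndarray] = []
        tril = _tril_indices(t)
        for i, j in zip(*tril):
            w = np.zeros((t, q))
            if i == j:
                w[i] = Av[i]
            else:
                w[i] += Av[j]
                w[j] += Av[i]
            vec = np.zeros(sys.n_equations)
            vec[sys.off_animal:] = w.reshape(-1)
            fs.append(sys.M @ vec)
        if self.has_u:
            for k in range(t):
                vec = np.zeros(sys.n_equations)
                s = slice(sys.off_u[k], sys.off_u[k] + sys.n_u[k])
                vec[s] = self.MtPy[s]
                fs.append(sys.M @ vec)
        rows_by_trait = [np.arange(sys.row_offsets[k], sys.row_offsets[k + 1])
                         for k in range(t)]
        for i, j in zip(*tril):
            f = np.zeros(len(sys.y))
            if i == j:
                rows = rows_by_trait[i]
                f[rows] = Py[rows]
            else:
                r1, r2 = sys.pair_rows
                f[r1] = Py[r2]
                f[r2] = Py[r1]
            fs.append(f)
        return fs

    def _ai_matrix(self, fs: list[np.ndarray]) -> np.ndarray:
        sys = self.system
        F = np.column_stack(fs)
        H = self.rinv @ F
        S = self.lu.solve(sys.M.T @ H)
        PF = H - self.rinv @ (sys.M @ S)
        ai = 0.5 * (F.T @ PF)
        return 0.5 * (ai + ai.T)

    # -- trace terms -----------------------------------------------------

    def _analytic_rgu_derivatives(self) -> np.ndarray:
        """Closed-form d(log|R| + log|G| + log|U|)/dtheta."""
        sys, t, vc = self.system, self.t, self.vc
        q = sys.n_animals
        tril = _tril_indices(t)
        g_inv = np.linalg.inv(vc.G0)
        out = []
        for i, j in zip(*tril):
            out.append(q * (2 - (i == j)) * g_inv[i, j])
        if self.has_u:
            for k in range(t):
                out.append(sys.n_u[k] / vc.U0[k])
        W = np.linalg.inv(vc.R0)
        n_b = len(sys.pair_rows[0])
        for i, j in zip(*tril):
            d = n_b * (2 - (i == j)) * W[i, j]
            if i == j:
                d += len(sys.single_rows[i]) / vc.R0[i, i]
            out.append(d)
        return np.array(out)

    def _trace_mc(self) -> np.ndarray:
        """Hutchinson estimates of tr(C^-1 dC/dtheta_i) from shared probes."""
        sys, t, q = self.system, self.t, self.system.n_animals
        vc = self.vc
        Z = self.probes
        m = Z.shape[1]
        W = self.lu.solve(Z)
        tril = _tril_indices(t)
        traces = []

        g_inv = np.linalg.inv(vc.G0)
        Z_anim = Z[sys.off_animal:].reshape(t, q, m)
        W_anim = W[sys.off_animal:].reshape(t, q, m)
        AinvZ = np.stack([sys.rel.ainv @ Z_anim[k] for k in range(t)])
        for i, j in zip(*tril):
            S = -g_inv @ _sym_basis(t, i, j) @ g_inv
            BZ = np.einsum("ij,jqm->iqm", S, AinvZ)
            traces.append(np.sum(W_anim * BZ) / m)
        if self.has_u:
            for k in range(t):
                s = slice(sys.off_u[k], sys.off_u[k] + sys.n_u[k])
                traces.append(-np.sum(W[s] * Z[s]) / (m * vc.U0[k] ** 2))
        for i, j in zip(*tril):
            dC = sys.data_block_derivative(vc.R0, i, j)
            traces.append(np.sum(W * (dC @ Z)) / m)
        return np.array(traces)

    def _trace_fd(self, fd_rel_step: float = 1e-5) -> np.ndarray:
        """Central-difference d log|C| / dtheta (one-sided at boundaries)."""
        sys = self.system
        scale = np.mean([self.vc.phenotypic_variance(k)
                         for k in range(self.t)])
        n_par = len(self.theta)
        dld = np.empty(n_par)
        ld_base = None
        for i in range(n_par):
            h = fd_rel_step * max(abs(self.theta[i]), 1e-3 * scale)
            up = self.theta.copy()
            up[i] += h
            dn = self.theta.copy()
            dn[i] -= h
            vc_up = unpack_components(up, self.t, self.has_u)
            vc_dn = unpack_components(dn, self.t, self.has_u)
            ld_up = _logdet_c(sys, vc_up)
            if _components_valid(vc_dn):
                dld[i] = (ld_up - _logdet_c(sys, vc_dn)) / (2 * h)
            else:
                # parameter at its boundary: one-sided difference
                if ld_base is None:
                    ld_base = sys.logdet_c()
                dld[i] = (ld_up - ld_base) / h
        return dld

    def _dc_matrices(self):
        """Sparse dC/dtheta_i for every parameter, full equation dims."""
        sys, t, q = self.system, self.t, self.system.n_animals
        vc = self.vc
        tril = _tril_indices(t)
        g_inv = np.linalg.inv(vc.G0)
        n = sys.n_equations
        out = []
        for i, j in zip(*tril):
            S = -g_inv @ _sym_basis(t, i, j) @ g_inv
            kron = sp.kron(sp.csc_matrix(S), sys.rel.ainv, format="coo")
            out.append(sp.coo_matrix(
                (kron.data, (kron.row + sys.off_animal,
                             kron.col + sys.off_animal)),
                shape=(n, n)).tocsr())
        if self.has_u:
            for k in range(t):
                idx = np.arange(sys.off_u[k], sys.off_u[k] + sys.n_u[k])
                vals = np.full(len(idx), -1.0 / vc.U0[k] ** 2)
                out.append(sp.coo_matrix((vals, (idx, idx)),
                                         shape=(n, n)).tocsr())
        for i, j in zip(*tril):
            out.append(sys.data_block_derivative(vc.R0, i, j).tocsr())
        return out

    def _trace_selected(self) -> np.ndarray:
        """Exact tr(C^-1 dC/dtheta_i) via the block selected inverse."""
        if not isinstance(self.lu, SchurFactor):
            raise ValueError("selected traces need a SchurFactor; use "
                             "'exact' for monolithic factorizations")
        return np.array([self.lu.trace_cinv(B) for B in self._dc_matrices()])

    def compute(self, trace_method: str = "exact") -> tuple[np.ndarray,
                                                            np.ndarray]:
        fs = self._f_vectors()
        ai = self._ai_matrix(fs)
        quad = np.array([float(self.Py @ f) for f in fs])
        if trace_method == "mc":
            dld_c = self._trace_mc()
        elif trace_method == "selected":
            dld_c = self._trace_selected()
        else:
            dld_c = self._trace_fd()
        dld = self._analytic_rgu_derivatives() + dld_c
        score = -0.5 * (dld - quad)
        return score, ai


# ---------------------------------------------------------------------------
# estimator


@dataclass
class REMLResult:
    components: VarianceComponents
    loglik: float
    converged: bool
    iterations: int
    ai_matrix: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    trajectory: pd.DataFrame = field(repr=False, default=None)

    @property
    def se_components(self) -> VarianceComponents:
        """SEs arranged like the components (from the inverse AI matrix)."""
        t = self.components.n_traits
        return unpack_components(self.se, t, self.components.U0 is not None)


def default_init(system: MMESystem) -> VarianceComponents:
    """10% / 5% / 85% of each trait's observed phenotypic variance to the
    additive, year-month and residual components; zero covariances."""
    t = system.n_traits
    var_y = np.empty(t)
    for k in range(t):
        rows = np.arange(system.row_offsets[k], system.row_offsets[k + 1])
        var_y[k] = np.var(system.y[rows]) if len(rows) > 1 else 1.0
    var_y = np.clip(var_y, 1e-8, None)
    G0 = np.diag(0.10 * var_y)
    if system.has_u:
        U0 = 0.05 * var_y
        R0 = np.diag(0.85 * var_y)
    else:
        U0 = None
        R0 = np.diag(0.90 * var_y)
    return VarianceComponents(G0=G0, R0=R0, U0=U0)


def estimate_components(system: MMESystem | None = None, *,
                        design: DesignLayout | None = None,
                        relationship: RelationshipStructure | None = None,
                        init: VarianceComponents | None = None,
                        tol: float = 1e-6, max_iter: int = 200,
                        trace_method: str = "auto", n_probes: int = 128,
                        verbose: bool = False) -> REMLResult:
    """AI-REML estimates of G0, U0, R0 with approximate standard errors.

    Either a prebuilt :class:`MMESystem` or (design, relationship) must be
    given.  Convergence is declared when the largest relative parameter
    change falls below ``tol``; a non-converged fit is returned flagged,
    with its trajectory, rather than raised.  ``trace_method`` 'exact'
    differentiates log|C| by central differences; 'selected' computes the
    traces exactly through the block selected inverse (the default for
    block-factored systems above 2000 equations); 'mc' uses seeded
    Hutchinson probes.
    """
    if system is None:
        if design is None or relationship is None:
            raise ValueError("need either a system or design+relationship")
        probe = init or VarianceComponents(
            G0=np.eye(design.n_traits), R0=np.eye(design.n_traits),
            U0=np.ones(design.n_traits))
        system = assemble_mme(design, relationship, probe)
    if trace_method == "auto":
        if system.n_equations <= _EXACT_TRACE_LIMIT:
            trace_method = "exact"
        elif isinstance(system.factorize(), SchurFactor):
            trace_method = "selected"
        else:
            trace_method = "mc"
    probes = None
    if trace_method == "mc":
        prng = np.random.default_rng(_PROBE_SEED)
        probes = prng.choice([-1.0, 1.0],
                             size=(system.n_equations, n_probes))

    vc = project_components((init or default_init(system)).copy())
    has_u = system.has_u
    t = system.n_traits

    scale = np.mean([vc.phenotypic_variance(k) for k in range(t)])
    u_floor = 1e-10 * max(scale, 1.0)

    logL, sol = restricted_loglik(system, vc)
    history = [(0, logL) + tuple(pack_components(vc, has_u))]
    converged = False
    ai = np.eye(len(pack_components(vc, has_u)))
    it = 0
    for it in range(1, max_iter + 1):
        grad = _Gradient(system, sol, probes=probes)
        score, ai = grad.compute(trace_method)
        theta = grad.theta
        if not np.all(np.isfinite(score)):
            logger.warning("REML: zeroing %d non-finite score entries",
                           int(np.sum(~np.isfinite(score))))
            score = np.nan_to_num(score)

        # active set: a variance pinned at its floor whose score pushes it
        # further down is frozen out of the Newton system this iteration
        floors = _floor_mask(theta, t, has_u, u_floor)
        frozen = floors & (score < 0)
        free = ~frozen
        step = np.zeros_like(theta)
        step[free] = _solve_step(ai[np.ix_(free, free)], score[free])
        expected_gain = 0.5 * float(score[free] @ step[free])
        # limit per-parameter changes (a factorization per rejected
        # candidate makes over-shooting expensive on large systems)
        cap = np.maximum(0.8 * np.abs(theta), 0.2 * scale)
        step = np.clip(step, -cap, cap)

        accepted = False
        new_vc, new_logL, new_sol = vc, logL, sol

        def try_step(delta):
            try:
                cand = project_components(
                    unpack_components(theta + delta, t, has_u), u_floor)
                cand_logL, cand_sol = restricted_loglik(system, cand)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                return None
            if np.isfinite(cand_logL) and cand_logL >= logL - 1e-7:
                return cand, cand_logL, cand_sol
            return None

        n_halved = 0
        for n_halved in range(15):
            hit = try_step(step)
            if hit is not None:
                new_vc, new_logL, new_sol = hit
                accepted = True
                break
            step = step * 0.5
        if not accepted:
            # scaled-gradient fallback step
            gstep = score * (1e-3 * scale / max(np.max(np.abs(score)), 1e-30))
            hit = try_step(gstep)
            if hit is not None:
                new_vc, new_logL, new_sol = hit
                accepted = True
                n_halved = 15

        if not accepted:
            logger.warning("REML: no improving step at iteration %d", it)
            restricted_loglik(system, vc)  # leave system at accepted state
            break

        new_theta = pack_components(new_vc, has_u)
        denom = np.maximum(np.abs(theta), 1e-4 * scale)
        delta = np.max(np.abs(new_theta - theta) / denom)
        vc, logL, sol = new_vc, new_logL, new_sol
        history.append((it, logL) + tuple(new_theta))
        if verbose:
            logger.info("REML iter %d logL=%.6f max-rel-change=%.2e",
                        it, logL, delta)
        # a damped (halved) step can be arbitrarily small without being at
        # the optimum: require a full accepted AI step, or a Newton
        # decrement showing the remaining likelihood gain is negligible
        if (delta < tol and n_halved == 0) or expected_gain < 1e-4:
            converged = True
            break

    cov = _safe_inverse(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = _param_names(t, has_u)
    traj = pd.DataFrame(history, columns=["iteration", "loglik"] + names)
    if not converged:
        logger.warning("REML did not converge in %d iterations", it)
    return REMLResult(components=vc, loglik=logL, converged=converged,
                      iterations=it, ai_matrix=ai, covariance=cov, se=se,
                      trajectory=traj)


def _floor_mask(theta: np.ndarray, t: int, has_u: bool,
                u_floor: float) -> np.ndarray:
    """Which parameters sit at their lower boundary (u variances only)."""
    mask = np.zeros(len(theta), dtype=bool)
    if has_u:
        k = len(_tril_indices(t)[0])
        mask[k:k + t] = theta[k:k + t] <= u_floor * 1.5
    return mask


def _param_names(t: int, has_u: bool) -> list[str]:
    tril = _tril_indices(t)
    names = [f"g{i+1}{j+1}" for i, j in zip(*tril)]
    if has_u:
        names += [f"u{k+1}" for k in range(t)]
    names += [f"r{i+1}{j+1}" for i, j in zip(*tril)]
    return names


def _solve_step(ai: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Newton step from the AI matrix, ridge-damped if ill-conditioned."""
    ridge = 0.0
    diag = np.abs(np.diag(ai)).max() or 1.0
    for _ in range(8):
        try:
            step = np.linalg.solve(ai + ridge * np.eye(len(score)), score)
            if np.all(np.isfinite(step)):
                return step
        except np.linalg.LinAlgError:
            pass
        ridge = max(ridge * 10, 1e-8 * diag)
    return score / diag


def _safe_inverse(ai: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(ai)


# ---------------------------------------------------------------------------
# derived genetic parameters


def heritability(vc: VarianceComponents, trait) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_u + sigma2_e) for one trait.

    ``trait`` may be an index or a trait name (hip = 0, elbow = 1 in the
    standard bivariate model).
    """
    k = _trait_index(vc, trait)
    sp2 = vc.phenotypic_variance(k)
    if sp2 <= 0:
        raise ValueError("phenotypic variance must be positive")
    return float(vc.G0[k, k] / sp2)


def genetic_correlation(vc: VarianceComponents) -> tuple[float, float]:
    """(r_g, r_e): additive and residual correlations between the traits."""
    if vc.n_traits != 2:
        raise ValueError("correlations require a two-trait model")
    ga, gb = vc.G0[0, 0], vc.G0[1, 1]
    ra, rb = vc.R0[0, 0], vc.R0[1, 1]
    if min(ga, gb, ra, rb) <= 0:
        raise ValueError("variances must be positive")
    return (float(vc.G0[0, 1] / np.sqrt(ga * gb)),
            float(vc.R0[0, 1] / np.sqrt(ra * rb)))


def _trait_index(vc: VarianceComponents, trait) -> int:
    if isinstance(trait, (int, np.integer)):
        return int(trait)
    order = {"hip": 0, "elbow": 1}
    if trait not in order or order[trait] >= vc.n_traits:
        raise ValueError(f"unknown trait {trait!r}")
    return order[trait]


def derived_parameter_ses(result: REMLResult) -> dict[str, tuple[float, float]]:
    """Delta-method SEs for h2 of each trait and, for two traits, r_g/r_e.

    Returns {name: (value, se)} using the inverse-AI covariance.
    """
    vc = result.components
    t = vc.n_traits
    has_u = vc.U0 is not None
    theta = pack_components(vc, has_u)

    def functions(th):
        v = unpack_components(th, t, has_u)
        out = [heritability(v, k) for k in range(t)]
        if t == 2:
            rg, re = genetic_correlation(v)
            out += [rg, re]
        return np.array(out)

    base = functions(theta)
    jac = np.zeros((len(base), len(theta)))
    for i in range(len(theta)):
        h = 1e-6 * max(abs(theta[i]), 1e-8)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        jac[:, i] = (functions(up) - functions(dn)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", jac, result.covariance, jac)
    se = np.sqrt(np.clip(var, 0.0, None))
    names = [f"h2_{k+1}" for k in range(t)]
    if t == 2:
        names += ["r_g", "r_e"]
    return {n: (float(v), float(s)) for n, v, s in zip(names, base, se)}
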