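"""Block-sparse LDL' factorization and selected inversion for the MME.

The MME coefficient matrix has a characteristic structure: the animal
equations are block diagonal across breeds (closed purebred populations)
apart from their coupling to a modest number of shared columns (fixed
effects and year-month environmental levels).  Factoring each breed's
animal block sparsely and treating the shared columns through a dense
Schur complement is dramatically cheaper than a monolithic sparse
factorization, whose fill explodes on the mixed sparse/dense pattern.

The per-block factorization is an up-looking sparse LDL' (elimination
tree based), with the fill-reducing permutation taken once from SuperLU's
minimum-degree analysis and the symbolic factorization cached across
refactorizations -- REML refactors the same pattern hundreds of times.
Owning the factorization guarantees the stored pattern is the full
chordal fill-in, which the Takahashi selected-inverse recursion requires:
for C = L D L', the entries of C^-1 on the pattern of L follow from a
backward recursion without ever forming the full inverse.  Combined with
the Schur form,

    C^-1 = [[Ablk^-1, 0], [0, 0]] + W S^-1 W',     W = [-Ablk^-1 B; I],

any trace tr(C^-1 B) for sparse symmetric B -- the quantities REML needs
-- and the animal-block diagonal of C^-1 (prediction error variances)
are exact and cheap.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

logger = logging.getLogger(__name__)


def _splu_sym(C: sp.csc_matrix):
    return spla.splu(C, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                     options={"SymmetricMode": True})


# ---------------------------------------------------------------------------
# sparse LDL' (up-looking, elimination tree)


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Elimination tree and column counts for upper-triangular CSC input."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.empty(n, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                flag[i] = k
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + lnz[k]
    return parent, Lp


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):
    """Numeric LDL' of an SPD matrix given in upper-triangular CSC form.

    Returns (Li, Lx, D); L is strictly lower triangular CSC with rows
    ascending within each column (the implicit diagonal is 1).
    """
    Li = np.empty(Lp[n], dtype=np.int64)
    Lx = np.empty(Lp[n])
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        Y[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            depth = 0
            while flag[i] != k:
                stack[depth] = i
                depth += 1
                flag[i] = k
                i = parent[i]
            while depth > 0:
                depth -= 1
                top -= 1
                pattern[top] = stack[depth]
        D[k] = Y[k]
        Y[k] = 0.0
        for pp in range(top, n):
            i = pattern[pp]
            yi = Y[i]
            Y[i] = 0.0
            p_end = Lp[i] + lnz[i]
            if p_end >= Lp[i + 1]:
                # pattern disagrees with the symbolic analysis
                return Li, Lx, D, -(i + 1)
            for p in range(Lp[i], p_end):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[p_end] = k
            Lx[p_end] = l_ki
            lnz[i] += 1
        if D[k] == 0.0:
            return Li, Lx, D, k + 1
    return Li, Lx, D, 0


@njit(cache=True)
def _ldl_solve_many(n, Lp, Li, Lx, D, B):
    """Solve (L D L') X = B in place for a dense (n, m) right-hand side."""
    m = B.shape[1]
    for j in range(n):
        for p in range(Lp[j], Lp[j + 1]):
            i = Li[p]
            l = Lx[p]
            for c in range(m):
                B[i, c] -= l * B[j, c]
    for j in range(n):
        d = D[j]
        for c in range(m):
            B[j, c] /= d
    for j in range(n - 1, -1, -1):
        for p in range(Lp[j], Lp[j + 1]):
            i = Li[p]
            l = Lx[p]
            for c in range(m):
                B[j, c] -= l * B[i, c]
    return B


@njit(cache=True)
def _takahashi(n, Lp, Li, Lx, D):
    """Selected inverse of L D L' on the pattern of L (plus diagonal).

    Returns (Zx aligned with Li, Zdiag).  The pattern produced by
    :func:`_ldl_symbolic` is the exact chordal fill-in, so every entry the
    recursion touches is present by construction.  Gather/scatter
    formulation: each unordered pair of column-j neighbours {r, c} (r > c)
    is visited once, in column c, contributing to both accumulator rows.
    """
    Zx = np.zeros_like(Lx)
    Zd = np.zeros(n)
    acc = np.zeros(n)
    w = np.zeros(n)
    stamp = np.full(n, -1, dtype=np.int64)
    for j in range(n - 1, -1, -1):
        start = Lp[j]
        end = Lp[j + 1]
        if end == start:
            Zd[j] = 1.0 / D[j]
            continue
        for p in range(start, end):
            r = Li[p]
            w[r] = Lx[p]
            stamp[r] = j
            acc[r] = 0.0
        for p in range(start, end):
            c = Li[p]
            wc = Lx[p]
            acc[c] += wc * Zd[c]
            for p2 in range(Lp[c], Lp[c + 1]):
                r = Li[p2]
                if stamp[r] == j:
                    z = Zx[p2]
                    acc[r] += wc * z
                    acc[c] += w[r] * z
        diag = 0.0
        for p in range(start, end):
            r = Li[p]
            Zx[p] = -acc[r]
            diag += Lx[p] * Zx[p]
        Zd[j] = 1.0 / D[j] - diag
    return Zx, Zd


class LDLFactor:
    """Sparse LDL' of an SPD matrix with a reusable symbolic analysis.

    ``symbolic`` is (perm, parent, Lp) from a previous factorization of
    the same pattern; pass it back in to skip the ordering and symbolic
    steps on refactorization.
    """

    def __init__(self, C: sp.csc_matrix, symbolic=None):
        C = C.tocsc()
        self.n = C.shape[0]
        if symbolic is not None:
            # a cached analysis is only valid for an identical pattern
            perm = symbolic[0]
            upper = self._permuted_upper(C, perm)
            if not (np.array_equal(symbolic[3], upper.indptr)
                    and np.array_equal(symbolic[4], upper.indices)):
                logger.info("LDL: pattern changed, redoing symbolic analysis")
                symbolic = None
        if symbolic is None:
            # splu factors C[argsort(perm_c)][:, argsort(perm_c)] = LU
            perm = (np.argsort(_splu_sym(C).perm_c) if self.n > 1
                    else np.zeros(1, dtype=np.int64)).astype(np.int64)
            upper = self._permuted_upper(C, perm)
            parent, Lp = _ldl_symbolic(self.n, upper.indptr.astype(np.int64),
                                       upper.indices.astype(np.int64))
            symbolic = (perm, parent, Lp, upper.indptr.copy(),
                        upper.indices.copy())
        self.symbolic = symbolic
        perm, parent, Lp = symbolic[:3]
        upper = self._permuted_upper(C, perm)
        Li, Lx, D, fail = _ldl_numeric(
            self.n, upper.indptr.astype(np.int64),
            upper.indices.astype(np.int64), upper.data, parent, Lp)
        if fail < 0:
            raise RuntimeError("LDL: numeric pattern overflow at column "
                               f"{-fail - 1}")
        if fail:
            raise RuntimeError(f"LDL: zero pivot at column {fail - 1}")
        if np.any(D <= 0):
            raise RuntimeError("LDL: matrix is not positive definite")
        self.perm = perm
        self.Lp, self.Li, self.Lx, self.D = Lp, Li, Lx, D

    @staticmethod
    def _permuted_upper(C, perm):
        upper = sp.triu(C[perm][:, perm].tocsc(), format="csc")
        upper.sort_indices()
        return upper

    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    def solve(self, b):
        b = np.asarray(b, dtype=float)
        one_d = b.ndim == 1
        B = (b[:, None] if one_d else b)[self.perm].copy()
        _ldl_solve_many(self.n, self.Lp, self.Li, self.Lx, self.D, B)
        out = np.empty_like(B)
        out[self.perm] = B
        return out[:, 0] if one_d else out

    def selected_inverse(self) -> sp.csc_matrix:
        """Symmetric C^-1 on the fill pattern, original numbering."""
        Zx, Zd = _takahashi(self.n, self.Lp, self.Li, self.Lx, self.D)
        # exact-cancellation zeros must stay structurally present (sparse
        # arithmetic prunes stored zeros, which would shrink the pattern)
        Zx[Zx == 0.0] = 1e-300
        Zd[Zd == 0.0] = 1e-300
        lower = sp.csc_matrix((Zx, self.Li.copy(), self.Lp.copy()),
                              shape=(self.n, self.n))
        Z = lower + lower.T + sp.diags(Zd)
        iperm = np.argsort(self.perm)
        return Z.tocsr()[iperm][:, iperm].tocsc()


class SpluFactor:
    """Thin wrapper around a monolithic symmetric-mode SuperLU factor."""

    def __init__(self, C: sp.csc_matrix):
        self._lu = _splu_sym(C)
        self.n = C.shape[0]

    def solve(self, b):
        return self._lu.solve(np.asarray(b, dtype=float))

    def logdet(self) -> float:
        return float(np.sum(np.log(np.abs(self._lu.U.diagonal()))))


class SchurFactor:
    """Block factorization of C over (sparse groups | dense tail).

    ``sparse_groups`` are disjoint index arrays whose blocks of C are
    mutually uncoupled (breed animal blocks); ``dense_idx`` holds the
    remaining equations (fixed effects and year-month levels), handled by
    a dense Cholesky of their Schur complement.  ``symbolic_cache`` (a
    dict) carries the per-group LDL symbolic analyses across repeated
    factorizations of the same pattern.
    """

    def __init__(self, C: sp.csc_matrix, sparse_groups: list[np.ndarray],
                 dense_idx: np.ndarray, symbolic_cache: dict | None = None):
        C = C.tocsr()
        self.n = C.shape[0]
        self.groups = [np.asarray(g, dtype=np.int64) for g in sparse_groups]
        self.dense_idx = np.asarray(dense_idx, dtype=np.int64)
        self.sparse_idx = np.concatenate(self.groups) if self.groups else \
            np.empty(0, dtype=np.int64)
        nd = len(self.dense_idx)
        cache = symbolic_cache if symbolic_cache is not None else {}

        self._lus: list[LDLFactor] = []
        self._B_blocks = []
        self._X_blocks = []
        schur = np.asarray(C[self.dense_idx][:, self.dense_idx].todense())
        self._logdet_sparse = 0.0
        for gi, g in enumerate(self.groups):
            Ab = C[g][:, g].tocsc()
            Bb = C[g][:, self.dense_idx].tocsc()
            lu = LDLFactor(Ab, symbolic=cache.get(gi))
            cache[gi] = lu.symbolic
            self._logdet_sparse += lu.logdet()
            Xb = lu.solve(np.asarray(Bb.todense())) if nd else \
                np.zeros((len(g), 0))
            schur -= np.asarray(Bb.T @ Xb)
            self._lus.append(lu)
            self._B_blocks.append(Bb)
            self._X_blocks.append(Xb)
        if nd:
            self._schur_chol = sla.cho_factor(schur, lower=True)
            self._logdet_dense = 2.0 * float(
                np.sum(np.log(np.abs(np.diag(self._schur_chol[0])))))
        else:
            self._schur_chol = None
            self._logdet_dense = 0.0
        self._m2 = None
        self._zaa = None
        self._zaa_sub = None
        self._zaa_pattern = None

    # -- basics ----------------------------------------------------------

    def logdet(self) -> float:
        return self._logdet_sparse + self._logdet_dense

    def solve(self, b):
        b = np.asarray(b, dtype=float)
        one_d = b.ndim == 1
        if one_d:
            b = b[:, None]
        x = np.empty_like(b)
        ys = []
        rhs_d = b[self.dense_idx].copy()
        for g, lu, Bb in zip(self.groups, self._lus, self._B_blocks):
            yb = lu.solve(b[g])
            ys.append(yb)
            rhs_d -= Bb.T @ yb
        if self._schur_chol is not None:
            xd = sla.cho_solve(self._schur_chol, rhs_d)
            x[self.dense_idx] = xd
        else:
            xd = None
        for g, lu, Bb, yb in zip(self.groups, self._lus, self._B_blocks, ys):
            x[g] = yb if xd is None else yb - lu.solve(np.asarray(Bb @ xd))
        return x[:, 0] if one_d else x

    # -- selected-inverse machinery --------------------------------------

    def _low_rank_term(self) -> np.ndarray:
        """Rows of W Schur^{-T/2} in original equation numbering, where
        C^-1 = blockdiag(Ablk^-1, 0) + W Schur^-1 W'."""
        if self._m2 is None:
            nd = len(self.dense_idx)
            if nd == 0:
                self._m2 = np.zeros((self.n, 0))
                return self._m2
            cinv_half = sla.solve_triangular(
                self._schur_chol[0], np.eye(nd), lower=True).T
            m2 = np.zeros((self.n, nd))
            m2[self.dense_idx] = cinv_half
            for g, Xb in zip(self.groups, self._X_blocks):
                m2[g] = -Xb @ cinv_half
            self._m2 = m2
        return self._m2

    def animal_block_selected_inverse(self) -> sp.csr_matrix:
        """Ablk^-1 on its fill pattern, in full equation numbering."""
        if self._zaa is None:
            rows, cols, vals = [], [], []
            for g, lu in zip(self.groups, self._lus):
                Zb = lu.selected_inverse().tocoo()
                rows.append(g[Zb.row])
                cols.append(g[Zb.col])
                vals.append(Zb.data)
            if rows:
                self._zaa = sp.coo_matrix(
                    (np.concatenate(vals),
                     (np.concatenate(rows), np.concatenate(cols))),
                    shape=(self.n, self.n)).tocsr()
            else:
                self._zaa = sp.csr_matrix((self.n, self.n))
        return self._zaa

    def trace_cinv(self, B: sp.spmatrix, chunk: int = 256) -> float:
        """Exact tr(C^-1 B) for sparse symmetric B.

        The sparse-block part is summed over B's pattern against the
        Takahashi selected inverse; the low-rank Schur part is accumulated
        as sum(M2 * (B M2)) in column chunks.
        """
        B = B.tocsr()
        Baa = B[self.sparse_idx][:, self.sparse_idx]
        if Baa.nnz:
            if self._zaa_sub is None:
                zaa = self.animal_block_selected_inverse()
                self._zaa_sub = zaa[self.sparse_idx][:, self.sparse_idx] \
                    .tocsr()
                ind = self._zaa_sub.copy()
                ind.data = np.ones_like(ind.data)
                self._zaa_pattern = ind
            outside = abs(Baa) - abs(Baa).multiply(self._zaa_pattern)
            if outside.sum() > 1e-300:
                raise RuntimeError("trace target has entries outside the "
                                   "animal-block fill pattern")
            total = float(Baa.multiply(self._zaa_sub).sum())
        else:
            total = 0.0
        m2 = self._low_rank_term()
        nd = m2.shape[1]
        for lo in range(0, nd, chunk):
            block = m2[:, lo:lo + chunk]
            total += float(np.sum(block * (B @ block)))
        return total

    def cinv_diagonal(self, idx: np.ndarray) -> np.ndarray:
        """Exact diagonal entries of C^-1 at the given equations."""
        idx = np.asarray(idx, dtype=np.int64)
        zaa = self.animal_block_selected_inverse()
        base = np.asarray(zaa.diagonal())[idx]
        m2 = self._low_rank_term()
        return base + np.einsum("ij,ij->i", m2[idx], m2[idx])
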