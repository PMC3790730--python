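"""Pedigree construction, inbreeding, and the numerator relationship matrix.

The additive (numerator) relationship matrix A encodes expected additive
genetic relationships among all animals in a pedigree: diag(A) = 1 + F with
F the inbreeding coefficient.  Because only purebred dogs enter the
evaluation, A is block diagonal by breed.  The mixed model equations need
A^-1, which is assembled directly from parent links (Henderson's rules with
Mendelian-sampling variances adjusted for parental inbreeding); F itself is
computed with the Meuwissen & Luo recursion, which scales to registry-sized
pedigrees without ever forming A.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

UNKNOWN = -1


@dataclass
class Pedigree:
    """Topologically ordered individuals with integer parent links.

    ``sire`` / ``dam`` hold positional indices into the same arrays
    (:data:`UNKNOWN` for missing parents).  Parents always precede their
    offspring, and individuals of one breed occupy one contiguous range.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    breed: np.ndarray
    birth_year: np.ndarray
    edit_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {dog: i for i, dog in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, dog_ids) -> np.ndarray:
        """Positional indices for an iterable of dog ids (KeyError if absent)."""
        return np.array([self._index[d] for d in dog_ids], dtype=np.int64)

    def contains(self, dog_id) -> bool:
        return dog_id in self._index

    @property
    def breed_ranges(self) -> dict[str, tuple[int, int]]:
        """Half-open index range occupied by each breed."""
        ranges: dict[str, tuple[int, int]] = {}
        if self.n == 0:
            return ranges
        start = 0
        for i in range(1, self.n + 1):
            if i == self.n or self.breed[i] != self.breed[start]:
                ranges[str(self.breed[start])] = (start, i)
                start = i
        return ranges

    def is_topological(self) -> bool:
        idx = np.arange(self.n)
        ok = True
        for parent in (self.sire, self.dam):
            known = parent >= 0
            ok &= bool(np.all(parent[known] < idx[known]))
        return ok

    def mendelian_variances(self) -> np.ndarray:
        """Per-individual Mendelian-sampling variance multipliers d_i.

        d = 1 for founders, 3/4 - F_known/4 with one known parent, and
        1/2 - (F_s + F_d)/4 with both parents known.
        """
        F = inbreeding_coefficients(self)
        return _mendelian_variances(self.sire, self.dam, F)

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return np.where(idx >= 0, self.ids[np.maximum(idx, 0)], "")
        return pd.DataFrame({
            "id": self.ids, "sire_id": name(self.sire),
            "dam_id": name(self.dam), "sex": self.sex, "breed": self.breed,
            "birth_year": self.birth_year})

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        frame["birth_year"] = frame["birth_year"].astype(object)
        frame.loc[~np.isfinite(self.birth_year), "birth_year"] = ""
        frame.to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    """Read an (id, sire_id, dam_id, sex, breed, birth_year) CSV; empty
    parent fields mean unknown."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = ["id", "sire_id", "dam_id", "sex", "breed", "birth_year"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"pedigree file is missing columns: {missing}")
    year = pd.to_numeric(frame["birth_year"], errors="coerce").to_numpy(float)
    return build_pedigree(zip(frame["id"], frame["sire_id"], frame["dam_id"],
                              frame["sex"].str.lower(), frame["breed"], year))


# ---------------------------------------------------------------------------
# pedigree building


def build_pedigree(raw_links) -> Pedigree:
    """Clean raw parent links into a topologically ordered :class:`Pedigree`.

    ``raw_links`` yields ``(id, sire_id, dam_id, sex, breed, birth_year)``
    tuples (empty/None parent = unknown, birth_year may be NaN).  Rules, in
    order: duplicate ids keep the first row; ids used both as sire and dam
    lose all parent roles; female sires / male dams are severed; a parent
    born in the same year as or later than its offspring is severed; cycles
    are broken by severing the parent links of every individual involved.
    Individuals referenced only as parents are added as unknown-pedigree
    ancestors (sex inferred from role, breed from offspring).
    """
    rows: list[list] = []
    seen: dict[str, int] = {}
    log: dict[str, int] = {"duplicate_ids": 0, "dual_role_parents": 0,
                           "sex_mismatch_links": 0, "birth_order_links": 0,
                           "cycle_links": 0}

    def norm(v):
        v = "" if v is None else str(v).strip()
        return v

    for entry in raw_links:
        dog, sire, dam, sex, breed, year = entry
        dog = norm(dog)
        if not dog:
            continue
        if dog in seen:
            log["duplicate_ids"] += 1
            continue
        seen[dog] = len(rows)
        year = float(year) if year is not None and not _isnan(year) else np.nan
        rows.append([dog, norm(sire), norm(dam), norm(sex).lower(),
                     norm(breed), year])

    # phantom ancestors for parents without their own row
    sires_seen = {r[1] for r in rows if r[1]}
    dams_seen = {r[2] for r in rows if r[2]}
    for r in list(rows):
        for parent, inferred_sex in ((r[1], "male"), (r[2], "female")):
            if parent and parent not in seen:
                seen[parent] = len(rows)
                rows.append([parent, "", "", inferred_sex, r[4], np.nan])

    dual = sires_seen & dams_seen
    if dual:
        log["dual_role_parents"] = len(dual)
        for r in rows:
            if r[1] in dual:
                r[1] = ""
            if r[2] in dual:
                r[2] = ""

    index = {r[0]: i for i, r in enumerate(rows)}
    for r in rows:
        if r[1]:
            s = rows[index[r[1]]]
            if s[3] == "female":
                r[1] = ""
                log["sex_mismatch_links"] += 1
        if r[2]:
            d = rows[index[r[2]]]
            if d[3] == "male":
                r[2] = ""
                log["sex_mismatch_links"] += 1
        for k in (1, 2):
            if r[k]:
                p = rows[index[r[k]]]
                if not _isnan(p[5]) and not _isnan(r[5]) and p[5] >= r[5]:
                    r[k] = ""
                    log["birth_order_links"] += 1

    # Kahn topological ordering; survivors of a cycle lose their parent links
    n = len(rows)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(rows):
        for k in (1, 2):
            if r[k]:
                p = index[r[k]]
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(queue)
    topo: list[int] = []
    while queue:
        i = heapq.heappop(queue)
        topo.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(queue, c)
    if len(topo) < n:
        cyclic = sorted(set(range(n)) - set(topo))
        logger.warning("severing parent links of %d individuals in pedigree "
                       "cycles", len(cyclic))
        for i in cyclic:
            for k in (1, 2):
                if rows[i][k]:
                    rows[i][k] = ""
                    log["cycle_links"] += 1
        topo.extend(cyclic)

    # generation depth for a stable (breed, depth, input-order) arrangement
    depth = np.zeros(n, dtype=np.int64)
    for i in topo:
        r = rows[i]
        for k in (1, 2):
            if r[k]:
                depth[i] = max(depth[i], depth[index[r[k]]] + 1)
    order = sorted(range(n), key=lambda i: (rows[i][4], depth[i], i))
    pos = {i: p for p, i in enumerate(order)}

    ids = np.array([rows[i][0] for i in order], dtype=object)
    sex = np.array([rows[i][3] or "" for i in order], dtype=object)
    breed = np.array([rows[i][4] for i in order], dtype=object)
    year = np.array([rows[i][5] for i in order], dtype=float)
    sire = np.array([pos[index[rows[i][1]]] if rows[i][1] else UNKNOWN
                     for i in order], dtype=np.int64)
    dam = np.array([pos[index[rows[i][2]]] if rows[i][2] else UNKNOWN
                    for i in order], dtype=np.int64)

    for rule, count in log.items():
        if count:
            logger.info("pedigree edit %s: %d", rule, count)
    return Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, breed=breed,
                    birth_year=year, edit_log=log)


def _isnan(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# inbreeding


def _mendelian_variances(sire, dam, F) -> np.ndarray:
    d = np.ones(len(sire))
    s_known, d_known = sire >= 0, dam >= 0
    both = s_known & d_known
    one_s = s_known & ~d_known
    one_d = d_known & ~s_known
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F = diag(A) - 1 by the Meuwissen-Luo recursion.

    Founders (at least one unknown parent) have F = 0.  Requires a
    topologically ordered pedigree.
    """
    if not pedigree.is_topological():
        raise ValueError("pedigree must be topologically ordered "
                         "(parents before offspring)")
    sire, dam = pedigree.sire, pedigree.dam
    n = pedigree.n
    F = np.zeros(n)
    D = np.ones(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            D[i] = 1.0
            continue
        if s == UNKNOWN or d == UNKNOWN:
            p = s if s != UNKNOWN else d
            D[i] = 0.75 - 0.25 * F[p]
            continue
        D[i] = 0.5 - 0.25 * (F[s] + F[d])
        # A_ii = sum over ancestors j of L_ij^2 * D_j, visiting j descending
        coeff = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


# ---------------------------------------------------------------------------
# relationship matrices


def amatrix_dense(pedigree: Pedigree, max_size: int = 5000) -> np.ndarray:
    """Dense A by the tabular method (testing/oracle path).

    A_ii = 1 + A_{s,d}/2 and A_ij = (A_{i,s(j)} + A_{i,d(j)})/2 for i < j;
    unknown parents contribute zero.
    """
    n = pedigree.n
    if n > max_size:
        raise ValueError(f"pedigree of {n} exceeds dense limit {max_size}")
    if not pedigree.is_topological():
        raise ValueError("pedigree must be topologically ordered")
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for j in range(n):
        s, d = sire[j], dam[j]
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        prior = np.arange(j)
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[prior, s]
        if d >= 0:
            row += 0.5 * A[prior, d]
        A[prior, j] = row
        A[j, prior] = row
    return A


@dataclass
class RelationshipStructure:
    """Sparse A^-1 with its breed block index and log-determinant of A."""

    ainv: sp.csc_matrix
    breed_ranges: dict[str, tuple[int, int]]
    logdet_a: float
    inbreeding: np.ndarray


def ainverse_sparse(pedigree: Pedigree,
                    inbreeding: np.ndarray | None = None) -> RelationshipStructure:
    """Sparse A^-1 assembled from parent links (Henderson's rules).

    Each individual contributes alpha_i = 1/d_i to its own diagonal,
    -alpha_i/2 to parent-offspring entries and alpha_i/4 among its known
    parents, where d_i is the Mendelian-sampling variance adjusted for
    parental inbreeding.  Cross-breed parentage is an error: the evaluation
    assumes closed purebred populations, which keeps A block diagonal.
    """
    if not pedigree.is_topological():
        raise ValueError("pedigree must be topologically ordered")
    sire, dam, breed = pedigree.sire, pedigree.dam, pedigree.breed
    for parent in (sire, dam):
        known = parent >= 0
        if np.any(breed[known] != breed[parent[known]]):
            bad = pedigree.ids[known][breed[known] != breed[parent[known]]]
            raise ValueError(
                f"cross-breed parentage for ids {list(bad[:5])}; only "
                "purebred (closed-breed) pedigrees are supported")

    F = (inbreeding if inbreeding is not None
         else inbreeding_coefficients(pedigree))
    d = _mendelian_variances(sire, dam, F)
    alpha = 1.0 / d

    n = pedigree.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, alpha)
    for parent in (sire, dam):
        m = parent >= 0
        add(idx[m], parent[m], -0.5 * alpha[m])
        add(parent[m], idx[m], -0.5 * alpha[m])
        add(parent[m], parent[m], 0.25 * alpha[m])
    both = (sire >= 0) & (dam >= 0)
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])

    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsc()
    ainv.sum_duplicates()
    return RelationshipStructure(ainv=ainv, breed_ranges=pedigree.breed_ranges,
                                 logdet_a=float(np.sum(np.log(d))),
                                 inbreeding=F)


def write_inbreeding_csv(pedigree: Pedigree, path,
                         inbreeding: np.ndarray | None = None) -> None:
    """Export per-individual inbreeding coefficients as (id, F)."""
    F = (inbreeding if inbreeding is not None
         else inbreeding_coefficients(pedigree))
    pd.DataFrame({"id": pedigree.ids, "F": F}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inbreeding trends


@dataclass
class InbreedingTrend:
    group: str
    years: np.ndarray
    mean_f: np.ndarray
    slope: float
    slope_se: float
    intercept: float


def split_breeds_by_size(breeds: np.ndarray,
                         threshold: int = 50_000) -> np.ndarray:
    """Label each individual's breed as 'small' (<= threshold dogs) or
    'large' (> threshold)."""
    breeds = np.asarray(breeds)
    counts = pd.Series(breeds).value_counts()
    large = set(counts.index[counts > threshold])
    return np.where(pd.Series(breeds).isin(large), "large", "small")


def inbreeding_trend(F, birth_years, groups=None) -> dict[str, InbreedingTrend]:
    """Per-group mean F by birth year plus the OLS annual increment.

    ``groups`` labels each individual (e.g. small vs large breed
    populations); a group with fewer than two distinct years is an error.
    """
    F = np.asarray(F, dtype=float)
    years = np.asarray(birth_years, dtype=float)
    groups = (np.asarray(groups) if groups is not None
              else np.repeat("all", len(F)))
    ok = np.isfinite(years)
    out: dict[str, InbreedingTrend] = {}
    for g in pd.unique(groups[ok]):
        m = ok & (groups == g)
        frame = pd.DataFrame({"year": years[m], "F": F[m]})
        means = frame.groupby("year")["F"].mean()
        if len(means) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 distinct birth "
                             "years; annual increment undefined")
        fit = stats.linregress(means.index.to_numpy(), means.to_numpy())
        out[str(g)] = InbreedingTrend(
            group=str(g), years=means.index.to_numpy(),
            mean_f=means.to_numpy(), slope=float(fit.slope),
            slope_se=float(fit.stderr), intercept=float(fit.intercept))
    return out
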