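"""Pedigree containers, validation and deterministic pedigree statistics.

The pedigree is the central data structure of the package: a directed
acyclic parentage graph over individually identified animals, stored in a
canonical ancestors-before-descendants order.  On top of it this module
provides the classical deterministic quantities of pedigree analysis:

* exact inbreeding coefficients ``F`` (Meuwissen–Luo tabular recursion),
* the additive (numerator) relationship matrix ``A`` and its sparse
  inverse built directly from pedigree rules (Henderson),
* complete generation equivalents (CGE), a pedigree-completeness measure,
* expected founder contributions to any cohort,
* the per-generation rate of inbreeding ``ΔF`` and the effective
  population size ``Ne = 1/(2ΔF)``.

"Litter dummies" — one synthetic progeny per unique (dam, sire) mating
pair — let litter-level inbreeding coefficients be computed for litters
whose kits are not individually pedigreed, the standard device for
polytocous species.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = [
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "NeEstimate",
    "read_pedigree",
    "add_dummy_progenies",
    "dummy_id",
    "inbreeding",
    "exact_inbreeding",
    "relationship_matrix",
    "a_inverse",
    "complete_generation_equivalents",
    "complete_generation_equivalent",
    "founder_contributions",
    "estimate_Ne",
    "ne_from_delta_f",
]

#: values interpreted as "unknown parent" in input files
DEFAULT_UNKNOWN_SENTINELS = frozenset({"", "0", "NA", "na", "NaN", "nan", ".", "None"})

DUMMY_SEX = "dummy"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate, missing parent...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row: an individual and its (possibly unknown) parents."""

    id: str
    sire: str | None = None
    dam: str | None = None
    birth_date: pd.Timestamp | None = None
    sex: str | None = None  # "male", "female", "dummy" or None

    def __post_init__(self):
        if not self.id:
            raise PedigreeError("empty individual id")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"individual {self.id!r} listed as its own parent")


def _parse_date(value) -> pd.Timestamp | None:
    """ISO date parser; month-precision dates get day 15 (period splits are
    month-level, so mid-month is an unbiased placeholder)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, pd.Timestamp):
        return value.normalize()
    s = str(value).strip()
    if not s or s in DEFAULT_UNKNOWN_SENTINELS:
        return None
    parts = s.split("-")
    if len(parts) == 2:  # YYYY-MM
        return pd.Timestamp(int(parts[0]), int(parts[1]), 15)
    return pd.Timestamp(s).normalize()


def _norm_sex(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if not s or s in {"na", "nan", "unknown", "?"}:
        return None
    if s == DUMMY_SEX:
        return DUMMY_SEX
    if s in {"m", "male", "sire", "buck", "1"}:
        return "male"
    if s in {"f", "female", "dam", "doe", "2"}:
        return "female"
    raise PedigreeError(f"unrecognised sex code {value!r}")


class Pedigree:
    """Validated pedigree in canonical topological order.

    Validation enforces: unique non-empty ids, no self-parentage, acyclic
    parentage, every referenced parent present (or auto-inserted as a
    founder when ``missing_parents='founder'``), parent sexes compatible
    with their role, and litter dummies never used as parents.

    The topological order is canonical (Kahn's algorithm breaking ties by
    id), so two pedigrees with the same records compare equal regardless
    of input row order.
    """

    def __init__(self, records: Iterable[PedigreeRecord], *, missing_parents: str = "error"):
        records = list(records)
        by_id: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in by_id:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            by_id[rec.id] = rec

        # missing parents: error out or promote to founders
        referenced = {p for r in records for p in (r.sire, r.dam) if p is not None}
        missing = sorted(referenced - by_id.keys())
        if missing:
            if missing_parents == "founder":
                for pid in missing:
                    by_id[pid] = PedigreeRecord(pid)
                records = list(by_id.values())
            else:
                raise PedigreeError(
                    f"parent {missing[0]!r} referenced but has no pedigree record"
                )

        for rec in by_id.values():
            if rec.sire is not None and rec.dam is not None and rec.sire == rec.dam:
                raise PedigreeError(
                    f"individual {rec.id!r} has identical sire and dam {rec.sire!r}"
                )
            for role, pid, bad in (("sire", rec.sire, "female"), ("dam", rec.dam, "male")):
                if pid is None:
                    continue
                parent = by_id[pid]
                if parent.sex == DUMMY_SEX:
                    raise PedigreeError(
                        f"litter dummy {pid!r} used as {role} of {rec.id!r}"
                    )
                if parent.sex == bad:
                    raise PedigreeError(
                        f"{role} {pid!r} of {rec.id!r} is recorded as {bad}"
                    )

        # Kahn topological sort, ties broken by id -> canonical order
        children: dict[str, list[str]] = {i: [] for i in by_id}
        indeg = {i: 0 for i in by_id}
        for rec in by_id.values():
            for pid in (rec.sire, rec.dam):
                if pid is not None:
                    children[pid].append(rec.id)
                    indeg[rec.id] += 1
        ready = [i for i, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        order: list[str] = []
        while ready:
            i = heapq.heappop(ready)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(order) != len(by_id):
            on_cycle = min(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle through {on_cycle!r}")

        self._records = tuple(by_id[i] for i in order)
        self._index = {i: k for k, i in enumerate(order)}
        n = len(order)
        self.sire_idx = np.full(n, -1, dtype=np.int32)
        self.dam_idx = np.full(n, -1, dtype=np.int32)
        for k, rec in enumerate(self._records):
            if rec.sire is not None:
                self.sire_idx[k] = self._index[rec.sire]
            if rec.dam is not None:
                self.dam_idx[k] = self._index[rec.dam]

    # -- basic container API -------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self._records == other._records

    def __repr__(self) -> str:
        return (
            f"Pedigree(n={len(self)}, founders={len(self.founders)}, "
            f"dummies={int(self.is_dummy.sum())})"
        )

    @property
    def records(self) -> tuple[PedigreeRecord, ...]:
        return self._records

    @property
    def ids(self) -> tuple[str, ...]:
        """All ids in topological (ancestors first) order."""
        return tuple(r.id for r in self._records)

    @property
    def topo_order(self) -> tuple[str, ...]:
        return self.ids

    def index(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"individual {individual!r} not in pedigree") from None

    def indices(self, individuals: Iterable[str]) -> np.ndarray:
        return np.array([self.index(i) for i in individuals], dtype=np.int64)

    def record(self, individual: str) -> PedigreeRecord:
        return self._records[self.index(individual)]

    @property
    def founders(self) -> tuple[str, ...]:
        """Individuals with both parents unknown, in topological order."""
        mask = (self.sire_idx < 0) & (self.dam_idx < 0)
        return tuple(r.id for r, m in zip(self._records, mask) if m)

    @property
    def is_dummy(self) -> np.ndarray:
        return np.array([r.sex == DUMMY_SEX for r in self._records], dtype=bool)

    @property
    def birth_dates(self) -> pd.Series:
        return pd.Series(
            [r.birth_date for r in self._records], index=list(self.ids), dtype="object"
        )

    def ancestor_closure(self, individuals: Iterable[str]) -> list[str]:
        """Ids of ``individuals`` plus all their ancestors, topologically ordered."""
        keep = np.zeros(len(self), dtype=bool)
        keep[[self.index(i) for i in individuals]] = True
        for k in range(len(self) - 1, -1, -1):
            if keep[k]:
                for p in (self.sire_idx[k], self.dam_idx[k]):
                    if p >= 0:
                        keep[p] = True
        return [r.id for r, m in zip(self._records, keep) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "sire": [r.sire for r in self._records],
                "dam": [r.dam for r in self._records],
                "birth_date": [r.birth_date for r in self._records],
                "sex": [r.sex for r in self._records],
            }
        )


# -- input / output ---------------------------------------------------------


def read_pedigree(
    path,
    *,
    columns: Mapping[str, str] | None = None,
    unknown: Iterable[str] = DEFAULT_UNKNOWN_SENTINELS,
    missing_parents: str = "error",
) -> Pedigree:
    """Read a pedigree CSV (columns id, sire, dam, birth_date, sex).

    Parameters
    ----------
    columns
        Optional mapping from the canonical names to the file's column
        names, e.g. ``{"id": "animal", "sire": "father"}``.
    unknown
        Sentinel strings encoding an unknown parent.
    missing_parents
        ``"error"`` (default) to reject parents without a record of their
        own, ``"founder"`` to auto-insert them as founders.
    """
    colmap = {"id": "id", "sire": "sire", "dam": "dam", "birth_date": "birth_date", "sex": "sex"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(unknown)

    def parent(v):
        v = v.strip() if isinstance(v, str) else v
        return None if (v is None or v in unknown) else v

    records = []
    for _, row in df.iterrows():
        records.append(
            PedigreeRecord(
                id=row[colmap["id"]].strip(),
                sire=parent(row.get(colmap["sire"])),
                dam=parent(row.get(colmap["dam"])),
                birth_date=_parse_date(row.get(colmap["birth_date"])),
                sex=_norm_sex(row.get(colmap["sex"])),
            )
        )
    return Pedigree(records, missing_parents=missing_parents)


def write_coefficient_table(table: pd.DataFrame, path) -> None:
    """Write a per-individual statistics table as CSV (one row per id)."""
    table.rename_axis("id").to_csv(path)


# -- dummy progenies --------------------------------------------------------


def dummy_id(dam: str, sire: str) -> str:
    """Deterministic id of the litter dummy for a (dam, sire) mating pair."""
    return f"L:{dam}x{sire}"


def add_dummy_progenies(ped: Pedigree, matings: Iterable[tuple[str, str]]) -> Pedigree:
    """Append one litter dummy per unique (dam, sire) pair.

    Repeated kindlings of the same pair map to the same dummy; the returned
    pedigree is re-validated.  Dummy ids are ``L:<dam>x<sire>``, disjoint
    from real ids by construction (a collision raises).
    """
    pairs = sorted({(d, s) for d, s in matings})
    new = []
    for dam, sire in pairs:
        for pid, role in ((dam, "dam"), (sire, "sire")):
            if pid not in ped:
                raise PedigreeError(f"unknown {role} id {pid!r} in mating list")
        did = dummy_id(dam, sire)
        if did in ped:
            raise PedigreeError(f"dummy id {did!r} collides with an existing individual")
        new.append(PedigreeRecord(id=did, sire=sire, dam=dam, sex=DUMMY_SEX))
    if not new:
        return ped
    return Pedigree(list(ped.records) + new)


# -- exact inbreeding (Meuwissen & Luo tabular recursion) --------------------


@njit(cache=True)
def _ml_inbreeding(sire, dam):  # pragma: no cover - exercised through wrapper
    n = sire.size
    F = np.zeros(n)
    D = np.empty(n)
    AN = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # accumulate L_ij over ancestors j of i; F_i = sum L^2 D - 1
        AN[i] = 1.0
        acc = -1.0
        for j in range(i, -1, -1):
            a = AN[j]
            if a == 0.0:
                continue
            acc += a * a * D[j]
            if sire[j] >= 0:
                AN[sire[j]] += 0.5 * a
            if dam[j] >= 0:
                AN[dam[j]] += 0.5 * a
            AN[j] = 0.0
        F[i] = acc
    return F


def inbreeding(ped: Pedigree) -> pd.Series:
    """Classical inbreeding coefficient F per individual (exact, tabular).

    Unknown parents are treated as unique unrelated non-inbred founders.
    """
    return pd.Series(_ml_inbreeding(ped.sire_idx, ped.dam_idx), index=list(ped.ids), name="F")


def exact_inbreeding(ped: Pedigree) -> pd.Series:
    """Alias of :func:`inbreeding` emphasising exactness vs Monte Carlo."""
    return inbreeding(ped)


# -- relationship matrix ----------------------------------------------------


@njit(cache=True)
def _tabular_A(sire, dam):  # pragma: no cover - exercised through wrapper
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = v
            A[j, i] = v
        v = 1.0
        if s >= 0 and d >= 0:
            v += 0.5 * A[s, d]
        A[i, i] = v
    return A


def _sub_pedigree_arrays(ped: Pedigree, closure: Sequence[str]):
    pos = {i: k for k, i in enumerate(closure)}
    n = len(closure)
    sire = np.full(n, -1, dtype=np.int32)
    dam = np.full(n, -1, dtype=np.int32)
    for k, i in enumerate(closure):
        rec = ped.record(i)
        if rec.sire is not None:
            sire[k] = pos[rec.sire]
        if rec.dam is not None:
            dam[k] = pos[rec.dam]
    return sire, dam


def relationship_matrix(ped: Pedigree, subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Additive relationship matrix A for ``subset`` (default: everyone).

    ``A_ii = 1 + F_i``; off-diagonals are twice the kinship.  Computed by
    the tabular method over the ancestor closure of the subset, then cut
    back to the requested individuals (in the requested order).
    """
    subset = list(ped.ids) if subset is None else list(subset)
    closure = ped.ancestor_closure(subset)
    sire, dam = _sub_pedigree_arrays(ped, closure)
    A = _tabular_A(sire, dam)
    pos = {i: k for k, i in enumerate(closure)}
    idx = [pos[i] for i in subset]
    return pd.DataFrame(A[np.ix_(idx, idx)], index=subset, columns=subset)


def a_inverse(ped: Pedigree, subset: Sequence[str] | None = None):
    """Sparse inverse of A over the ancestor closure of ``subset``.

    Built directly from pedigree rules (Henderson, with inbreeding): each
    individual contributes 1/d to its own cell, -1/(2d) to parent cells and
    1/(4d) to parent-pair cells, where d is its Mendelian sampling variance.

    Returns ``(ids, Ainv)`` with ids the closure in topological order and
    Ainv in CSC format.
    """
    closure = ped.ancestor_closure(list(ped.ids) if subset is None else list(subset))
    sire, dam = _sub_pedigree_arrays(ped, closure)
    F = _ml_inbreeding(sire, dam)
    rows, cols, vals = [], [], []
    for i in range(len(closure)):
        s, d = int(sire[i]), int(dam[i])
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            mend = 0.75 - 0.25 * F[max(s, d)]
        else:
            mend = 1.0
        b = 1.0 / mend
        rows.append(i); cols.append(i); vals.append(b)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-b / 2, -b / 2]
        known = [p for p in (s, d) if p >= 0]
        for p in known:
            for q in known:
                rows.append(p); cols.append(q); vals.append(b / 4)
    n = len(closure)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return closure, Ainv


# -- complete generation equivalents ----------------------------------------


def complete_generation_equivalents(ped: Pedigree) -> pd.Series:
    """CGE per individual: sum of (1/2)^n over all known ancestors, one term
    per distinct pedigree path (a fully known depth-g pedigree gives g)."""
    n = len(ped)
    cge = np.zeros(n)
    for i in range(n):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                cge[i] += 0.5 * (1.0 + cge[p])
    return pd.Series(cge, index=list(ped.ids), name="CGE")


def complete_generation_equivalent(ped: Pedigree, individual: str) -> float:
    return float(complete_generation_equivalents(ped).loc[individual])


# -- founder contributions ---------------------------------------------------


def founder_contributions(
    ped: Pedigree, cohort: Sequence[str] | None = None, *, include_dummies: bool = False
) -> pd.Series:
    """Expected genetic contribution of each founder to a cohort.

    Per-individual contributions follow c_f(f)=1 for the founder itself and
    c_f(i) = (c_f(sire)+c_f(dam))/2 (an unknown parent contributes nothing,
    so mass is lost to unrecorded ancestry); the result averages over the
    cohort.  Sums to 1 per individual when the cohort is fully pedigreed
    back to founders.
    """
    if cohort is None:
        mask = ~ped.is_dummy if not include_dummies else np.ones(len(ped), bool)
        cohort = [i for i, m in zip(ped.ids, mask) if m]
    cohort = list(cohort)
    founders = list(ped.founders)
    fpos = {ped.index(f): k for k, f in enumerate(founders)}
    n = len(ped)
    C = np.zeros((n, len(founders)))
    for i in range(n):
        if i in fpos:
            C[i, fpos[i]] = 1.0
            continue
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                C[i] += 0.5 * C[p]
    rows = ped.indices(cohort)
    mean = C[rows].mean(axis=0) if len(rows) else np.zeros(len(founders))
    return pd.Series(mean, index=founders, name="contribution")


# -- effective population size ----------------------------------------------


@dataclass(frozen=True)
class NeEstimate:
    """Rate of inbreeding per generation and the matching Ne = 1/(2ΔF)."""

    delta_f: float
    ne: int
    method: str
    n: int = 0

    def __post_init__(self):
        if not (0.0 < self.delta_f < 1.0):
            raise ValueError(f"delta_F must be in (0, 1), got {self.delta_f}")


def ne_from_delta_f(delta_f: float, method: str = "analytic", n: int = 0) -> NeEstimate:
    """Ne from a per-generation rate of inbreeding, rounded to an integer."""
    if not (0.0 < delta_f < 1.0):
        raise ValueError(f"delta_F must be in (0, 1), got {delta_f}")
    return NeEstimate(delta_f=delta_f, ne=int(round(1.0 / (2.0 * delta_f))), method=method, n=n)


def estimate_Ne(
    ped: Pedigree,
    cohort_window: tuple | None = None,
    method: str = "regression_logF",
    *,
    include_dummies: bool = False,
) -> NeEstimate:
    """Estimate ΔF and Ne from realised inbreeding and pedigree completeness.

    ``method="regression_logF"`` (default) regresses -ln(1-F_i) on the
    equivalent generation number t_i = CGE_i + 1 and converts the slope b
    into ΔF = 1 - exp(-b), following the idealized relation
    F_t = 1 - (1 - ΔF)^t.  ``method="individual_deltaF"`` averages the
    individual rates ΔF_i = 1 - (1 - F_i)^(1/(t_i - 1)).

    ``cohort_window`` restricts the cohort to individuals born within the
    (start, end) date range, both inclusive; dummies are excluded unless
    requested.
    """
    F = inbreeding(ped).to_numpy()
    t = complete_generation_equivalents(ped).to_numpy() + 1.0
    keep = np.ones(len(ped), dtype=bool)
    if not include_dummies:
        keep &= ~ped.is_dummy
    if cohort_window is not None:
        start, end = (pd.Timestamp(b) for b in cohort_window)
        dates = ped.birth_dates
        inside = np.array(
            [(d is not None and start <= d <= end) for d in dates], dtype=bool
        )
        keep &= inside
    F, t = F[keep], t[keep]
    if method == "regression_logF":
        if np.unique(t).size < 2:
            raise ValueError(
                "regression_logF needs at least 2 distinct equivalent-generation values"
            )
        y = -np.log1p(-np.clip(F, 0.0, 1.0 - 1e-12))
        slope = np.polyfit(t, y, 1)[0]
        delta_f = 1.0 - np.exp(-slope)
    elif method == "individual_deltaF":
        ok = t > 1.0
        if not ok.any():
            raise ValueError("no individual with equivalent generations > 1")
        di = 1.0 - (1.0 - F[ok]) ** (1.0 / (t[ok] - 1.0))
        delta_f = float(di.mean())
    else:
        raise ValueError(f"unknown Ne method {method!r}")
    return ne_from_delta_f(float(delta_f), method=method, n=int(keep.sum()))
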