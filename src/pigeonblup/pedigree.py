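"""Pedigree validation, ordering, and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` holds the expected
additive-genetic relationships implied by a pedigree: ``A[i, i] = 1 + F_i``
with ``F_i`` the inbreeding coefficient, and ``A[i, j]`` twice the kinship
between *i* and *j*.  It is the covariance structure of breeding values in
the animal model, ``u ~ N(0, A * sigma2_u)``.

``A`` is built densely by the tabular (recursive) method; its inverse is
assembled directly and sparsely by Henderson's rules, using
Mendelian-sampling variances that account for parental inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = None

_SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parent links, sex, and optional birth year."""

    animal_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = "unknown"
    birth_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.animal_id:
            raise ValueError("animal_id must be non-empty")


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycles, duplicates, sex-role conflicts)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological (parents-before-offspring) order."""

    records: list[PedigreeRecord]
    n_phantom: int = 0
    index: dict[str, int] = field(init=False, repr=False)
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {r.animal_id: i for i, r in enumerate(self.records)}
        self.sire_idx = np.array(
            [self.index[r.sire_id] if r.sire_id is not None else -1 for r in self.records],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [self.index[r.dam_id] if r.dam_id is not None else -1 for r in self.records],
            dtype=np.int64,
        )
        if (self.sire_idx >= np.arange(len(self.records))).any() or (
            self.dam_idx >= np.arange(len(self.records))
        ).any():
            raise PedigreeError("pedigree is not sorted: a parent follows its offspring")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def sexes(self) -> list[str]:
        return [r.sex for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": [r.sire_id or "" for r in self.records],
                "dam_id": [r.dam_id or "" for r in self.records],
                "sex": self.sexes(),
                "birth_year": [r.birth_year for r in self.records],
            }
        )


@dataclass
class RelationshipMatrix:
    """Dense additive relationship matrix with the animal order it refers to."""

    ids: list[str]
    A: np.ndarray

    @property
    def F(self) -> np.ndarray:
        """Inbreeding coefficients (diagonal of A minus one)."""
        return np.diag(self.A) - 1.0


def _check_sex_roles(records: Sequence[PedigreeRecord]) -> None:
    sex_of = {r.animal_id: r.sex for r in records}
    as_sire = {r.sire_id for r in records if r.sire_id is not None}
    as_dam = {r.dam_id for r in records if r.dam_id is not None}
    for aid in as_sire & as_dam:
        if sex_of.get(aid, "unknown") != "unknown":
            raise PedigreeError(f"animal {aid!r} appears both as sire and as dam")
    for aid in as_sire:
        if sex_of.get(aid, "unknown") == "female":
            raise PedigreeError(f"female animal {aid!r} used as sire")
    for aid in as_dam:
        if sex_of.get(aid, "unknown") == "male":
            raise PedigreeError(f"male animal {aid!r} used as dam")


def validate_and_sort(records: Iterable[PedigreeRecord]) -> Pedigree:
    """Validate a pedigree and return it in parents-before-offspring order.

    Parents referenced but not listed are materialized as phantom founders
    (unknown parents, sex inferred from the role they were used in); their
    count is available as ``Pedigree.n_phantom``.  The topological sort is
    stable: input order is preserved among animals not forced apart by a
    parent link.

    Raises
    ------
    PedigreeError
        On an empty pedigree, duplicate ids, sex-role conflicts, or a
        cycle (the error names one animal on the cycle).
    """
    records = list(records)
    if not records:
        raise PedigreeError("pedigree is empty")
    ids = [r.animal_id for r in records]
    seen: set[str] = set()
    for aid in ids:
        if aid in seen:
            raise PedigreeError(f"duplicate animal_id {aid!r}")
        seen.add(aid)
    _check_sex_roles(records)

    known = set(ids)
    phantoms: list[PedigreeRecord] = []
    phantom_seen: set[str] = set()
    for r in records:
        for pid, sex in ((r.sire_id, "male"), (r.dam_id, "female")):
            if pid is not None and pid not in known and pid not in phantom_seen:
                phantoms.append(PedigreeRecord(pid, None, None, sex))
                phantom_seen.add(pid)
    all_records = phantoms + records

    # Kahn's algorithm with a stable queue keyed by input position.
    pos = {r.animal_id: i for i, r in enumerate(all_records)}
    children: dict[str, list[str]] = {r.animal_id: [] for r in all_records}
    n_parents: dict[str, int] = {r.animal_id: 0 for r in all_records}
    by_id = {r.animal_id: r for r in all_records}
    for r in all_records:
        for pid in (r.sire_id, r.dam_id):
            if pid is not None:
                if pid == r.animal_id:
                    raise PedigreeError(f"animal {r.animal_id!r} is its own parent (cycle)")
                children[pid].append(r.animal_id)
                n_parents[r.animal_id] += 1

    import heapq

    ready = [pos[a] for a, c in n_parents.items() if c == 0]
    heapq.heapify(ready)
    ordered: list[PedigreeRecord] = []
    order_ids = []
    while ready:
        i = heapq.heappop(ready)
        rec = all_records[i]
        ordered.append(rec)
        order_ids.append(rec.animal_id)
        for ch in children[rec.animal_id]:
            n_parents[ch] -= 1
            if n_parents[ch] == 0:
                heapq.heappush(ready, pos[ch])
    if len(ordered) != len(all_records):
        stuck = next(a for a, c in n_parents.items() if c > 0)
        raise PedigreeError(f"cycle detected in pedigree involving animal {stuck!r}")
    return Pedigree(ordered, n_phantom=len(phantoms))


def relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Build A by the tabular method.

    For animal *i* with parents *s*, *d* (unknown parents contribute 0):
    ``a(i, j) = 0.5 * (a(j, s) + a(j, d))`` for earlier *j*, and
    ``a(i, i) = 1 + 0.5 * a(s, d)``.
    """
    q = len(pedigree)
    A = np.zeros((q, q))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(q):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s[i] >= 0 and d[i] >= 0:
            aii += 0.5 * A[s[i], d[i]]
        A[i, i] = aii
    return RelationshipMatrix(pedigree.ids, A)


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficient per animal (via the tabular A diagonal)."""
    return relationship_matrix(pedigree).F


def mendelian_sampling_variance(
    pedigree: Pedigree, F: Optional[np.ndarray] = None
) -> np.ndarray:
    """Variance of the Mendelian-sampling deviation, in units of sigma2_u.

    ``0.5 - 0.25 (F_s + F_d)`` with both parents known, ``0.75 - 0.25 F_p``
    with one, and 1 for founders.
    """
    if F is None:
        F = inbreeding_coefficients(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    v = np.ones(len(pedigree))
    both = (s >= 0) & (d >= 0)
    v[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s >= 0) & (d < 0)
    v[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (s < 0) & (d >= 0)
    v[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return v


def a_inverse(pedigree: Pedigree, F: Optional[np.ndarray] = None) -> sparse.csr_matrix:
    """Assemble A^-1 directly by Henderson's rules, accounting for inbreeding.

    For each animal with Mendelian-sampling variance ``m`` and known-parent
    set P: add ``1/m`` at (i, i), ``-1/(2m)`` at (i, p), and ``1/(4m)`` at
    (p, p') for p, p' in P.  The product with the tabular A is the identity
    to numerical precision.
    """
    q = len(pedigree)
    m = mendelian_sampling_variance(pedigree, F)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(q):
        alpha = 1.0 / m[i]
        parents = [p for p in (s[i], d[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for p in parents:
            for p2 in parents:
                rows.append(p)
                cols.append(p2)
                vals.append(alpha / 4.0)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(q, q))
    )
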