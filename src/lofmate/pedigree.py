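"""Pedigree container, tabular kinship, and parental-coancestry evaluation.

The pedigree is the backbone of every downstream computation: gene dropping,
segregation analysis and optimal-contribution mate selection all walk the same
directed acyclic parent->offspring structure.  Animals are stored in a stable
topological order (parents before offspring) so that single-pass recursions
are valid and tie-breaking is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnimalRecord",
    "Pedigree",
    "PedigreeError",
    "build_pedigree",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "kinship_matrix",
    "parental_coancestry",
]

#: sentinel for an unknown parent in tabular input
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts, dupes)."""


@dataclass(frozen=True)
class AnimalRecord:
    id: str
    sire: str | None  # None = unknown
    dam: str | None
    sex: str  # "M" or "F"
    role: str  # "ancestor" or "candidate"


@dataclass
class Pedigree:
    """Topologically ordered list of animals with index lookups.

    Unknown parents are treated as unique, unrelated, non-inbred founders:
    they contribute nothing to kinship and their alleles are drawn from the
    base population.
    """

    animals: list[AnimalRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a.id: i for i, a in enumerate(self.animals)}

    def __len__(self) -> int:
        return len(self.animals)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def record(self, animal_id: str) -> AnimalRecord:
        return self.animals[self._index[animal_id]]

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.animals]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of [sire, dam] positional indices, -1 for unknown."""
        out = np.full((len(self.animals), 2), -1, dtype=np.int64)
        for i, a in enumerate(self.animals):
            if a.sire is not None:
                out[i, 0] = self._index[a.sire]
            if a.dam is not None:
                out[i, 1] = self._index[a.dam]
        return out

    def candidates(self, sex: str | None = None) -> list[AnimalRecord]:
        return [
            a
            for a in self.animals
            if a.role == "candidate" and (sex is None or a.sex == sex)
        ]

    def ancestors(self) -> list[AnimalRecord]:
        return [a for a in self.animals if a.role == "ancestor"]

    def counts(self) -> dict[str, int]:
        """Summary counts: male/female candidates and ancestors."""
        return {
            "male_candidates": len(self.candidates("M")),
            "female_candidates": len(self.candidates("F")),
            "ancestors": len(self.ancestors()),
        }


def _normalize_parent(value: object) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", UNKNOWN, "NA", "nan", "None"):
        return None
    return s


def build_pedigree(records: Iterable[Mapping[str, object]]) -> Pedigree:
    """Validate tabular rows and return a topologically sorted :class:`Pedigree`.

    Rows need keys ``id, sire, dam, sex, role``; the sentinel ``"0"`` (or an
    empty string) marks an unknown parent.  The output order is the stable
    topological order: parents precede offspring, ties broken by input order.

    Raises
    ------
    PedigreeError
        On duplicate ids, a missing named parent, a parent used with an
        inconsistent sex, or a cycle (including self-parenting).
    """
    rows: list[AnimalRecord] = []
    seen: set[str] = set()
    for r in records:
        aid = str(r["id"]).strip()
        if aid in seen:
            raise PedigreeError(f"duplicate animal id {aid!r}")
        if aid in ("", UNKNOWN):
            raise PedigreeError(f"invalid animal id {aid!r}")
        seen.add(aid)
        sex = str(r["sex"]).strip().upper()
        if sex not in ("M", "F"):
            raise PedigreeError(f"animal {aid!r}: sex must be M or F, got {r['sex']!r}")
        role = str(r.get("role", "ancestor")).strip().lower()
        if role not in ("ancestor", "candidate"):
            raise PedigreeError(f"animal {aid!r}: role must be ancestor or candidate")
        rows.append(
            AnimalRecord(
                id=aid,
                sire=_normalize_parent(r.get("sire")),
                dam=_normalize_parent(r.get("dam")),
                sex=sex,
                role=role,
            )
        )

    by_id = {a.id: a for a in rows}
    for a in rows:
        for parent, expected_sex, label in ((a.sire, "M", "sire"), (a.dam, "F", "dam")):
            if parent is None:
                continue
            if parent not in by_id:
                raise PedigreeError(f"animal {a.id!r}: {label} {parent!r} not in pedigree")
            if by_id[parent].sex != expected_sex:
                raise PedigreeError(
                    f"animal {a.id!r}: {label} {parent!r} has sex "
                    f"{by_id[parent].sex!r}, expected {expected_sex!r}"
                )
            if parent == a.id:
                raise PedigreeError(f"animal {a.id!r} is its own parent")

    # Stable topological sort: process in input order, emitting an animal as
    # soon as its parents have been emitted.
    ts: TopologicalSorter[str] = TopologicalSorter()
    input_pos = {a.id: i for i, a in enumerate(rows)}
    for a in rows:
        deps = [p for p in (a.sire, a.dam) if p is not None]
        ts.add(a.id, *deps)
    try:
        ts.prepare()
    except CycleError as exc:
        raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc
    order: list[str] = []
    while ts.is_active():
        ready = sorted(ts.get_ready(), key=input_pos.__getitem__)
        for aid in ready:
            order.append(aid)
            ts.done(aid)
    return Pedigree([by_id[aid] for aid in order])


def read_pedigree_csv(path) -> Pedigree:
    """Read the pedigree CSV dialect: columns ``id,sire,dam,sex,role``."""
    df = pd.read_csv(path, dtype=str).fillna(UNKNOWN)
    return build_pedigree(df.to_dict("records"))


def write_pedigree_csv(ped: Pedigree, path) -> None:
    pd.DataFrame(
        {
            "id": [a.id for a in ped.animals],
            "sire": [a.sire or UNKNOWN for a in ped.animals],
            "dam": [a.dam or UNKNOWN for a in ped.animals],
            "sex": [a.sex for a in ped.animals],
            "role": [a.role for a in ped.animals],
        }
    ).to_csv(path, index=False)


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Kinship (coancestry) coefficients by the tabular (recursive) method.

    ``f(i, i) = 0.5 * (1 + F_i)`` with the inbreeding coefficient
    ``F_i = f(sire_i, dam_i)`` (0 when a parent is unknown), and for j not an
    ancestor of i, ``f(i, j) = 0.5 * (f(i, sire_j) + f(i, dam_j))`` with
    unknown parents contributing 0.  Returned as a DataFrame indexed by animal
    id in pedigree order.
    """
    n = len(ped)
    par = ped.parent_indices()
    K = np.zeros((n, n))
    for j in range(n):
        s, d = par[j]
        fj = K[s, d] if (s >= 0 and d >= 0) else 0.0
        K[j, j] = 0.5 * (1.0 + fj)
        for i in range(j):
            v = 0.0
            if s >= 0:
                v += 0.5 * K[i, s]
            if d >= 0:
                v += 0.5 * K[i, d]
            K[i, j] = K[j, i] = v
    ids = ped.ids
    return pd.DataFrame(K, index=ids, columns=ids)


def contribution_vector(
    ped: Pedigree, matings: Sequence[tuple[str, str]]
) -> pd.Series:
    """Per-parent genetic contribution proportions implied by a mating list.

    Each sex's contributions sum to 1/2 (the standard optimal-contribution
    convention): a parent used in ``n_p`` of ``N`` matings contributes
    ``n_p / (2 N)``.
    """
    if len(matings) == 0:
        raise ValueError("empty mating list")
    counts: dict[str, int] = {}
    for s, d in matings:
        counts[s] = counts.get(s, 0) + 1
        counts[d] = counts.get(d, 0) + 1
    total = len(matings)
    return pd.Series({p: c / (2.0 * total) for p, c in counts.items()}, dtype=float)


def parental_coancestry(
    ped: Pedigree, kin: pd.DataFrame, matings: Sequence[tuple[str, str]]
) -> float:
    """Group coancestry x'Kx of the parents of a mating list.

    x is the contribution vector (each sex summing to 1/2); self-kinship
    diagonal terms are included.  One unrelated non-inbred sire mated to one
    unrelated non-inbred dam therefore gives 0.25.
    """
    x = contribution_vector(ped, matings)
    sub = kin.loc[x.index, x.index].to_numpy()
    v = x.to_numpy()
    return float(v @ sub @ v)
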