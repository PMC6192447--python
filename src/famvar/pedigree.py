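"""Pedigree container and pedigree-derived quantities.

A pedigree is a table of individuals with father/mother/spouse links. It
defines the nuclear-family units, full sibships and couple pairs used to
build shared-environment matrices, and the expected additive genetic
relationship matrix used to simulate pedigree-associated genetic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

MISSING_PARENT = "0"


@dataclass
class Pedigree:
    """Individuals with parent and spouse links.

    ``table`` has one row per individual with columns ``id``, ``father``,
    ``mother``, ``sex`` (0 = female, 1 = male), ``spouse`` and ``family``
    (founding-family label). Parents of founders and absent spouses are
    coded ``"0"``. Rows are ordered so that parents precede offspring.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"id", "father", "mother", "sex", "spouse"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table lacks columns: {sorted(missing)}")
        ids = self.table["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self._index = {i: k for k, i in enumerate(ids)}
        self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    def is_founder(self) -> np.ndarray:
        return (self.table["father"] == MISSING_PARENT).to_numpy()

    def validate(self) -> None:
        t = self.table
        known = set(t["id"])
        for col in ("father", "mother"):
            bad = set(t[col]) - known - {MISSING_PARENT}
            if bad:
                raise ValueError(f"unknown {col} ids: {sorted(bad)[:5]}")
        one_parent = (t["father"] == MISSING_PARENT) != (t["mother"] == MISSING_PARENT)
        if one_parent.any():
            raise ValueError("individuals with exactly one known parent are not supported")
        # spouse links must be mutual
        sp = dict(zip(t["id"], t["spouse"]))
        for i, j in sp.items():
            if j != MISSING_PARENT and sp.get(j) != i:
                raise ValueError(f"spouse link {i}->{j} is not mutual")
        # parents must appear before children
        for row in t.itertuples(index=False):
            if row.father != MISSING_PARENT:
                if self._index[row.father] > self._index[row.id] or (
                    self._index[row.mother] > self._index[row.id]
                ):
                    raise ValueError("pedigree rows must list parents before offspring")

    # -- relationship structure ------------------------------------------

    def couples(self) -> list[tuple[str, str]]:
        """Mutual spouse pairs, each reported once (order of first member)."""
        seen, out = set(), []
        for i, j in zip(self.table["id"], self.table["spouse"]):
            if j != MISSING_PARENT and i not in seen and j not in seen:
                out.append((i, j))
                seen.update((i, j))
        return out

    def sibships(self) -> list[list[str]]:
        """Groups of individuals sharing both parents (singletons included)."""
        t = self.table
        kids = t[t["father"] != MISSING_PARENT]
        groups = kids.groupby(["father", "mother"], sort=False)["id"].apply(list)
        return [list(g) for g in groups]

    def sib_pairs(self) -> list[tuple[str, str]]:
        return [p for g in self.sibships() for p in combinations(g, 2)]

    def nuclear_units(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """Nuclear-family units: a couple plus their common offspring.

        Childless couples form a unit of two, matching a minimum-two-member
        definition of a nuclear family.
        """
        t = self.table
        children: dict[tuple[str, str], list[str]] = {}
        for row in t[t["father"] != MISSING_PARENT].itertuples(index=False):
            children.setdefault((row.father, row.mother), []).append(row.id)
        units = []
        for a, b in self.couples():
            kids = children.get((a, b)) or children.get((b, a)) or []
            units.append((a, b, tuple(kids)))
        # offspring of non-spouse parent pairs (should not arise from the
        # generator, but tolerated for externally supplied pedigrees)
        couple_set = {frozenset(c) for c in self.couples()}
        for (fa, mo), kids in children.items():
            if frozenset((fa, mo)) not in couple_set:
                units.append((fa, mo, tuple(kids)))
        return units

    # -- expected additive relationships ---------------------------------

    def additive_relationship(self) -> np.ndarray:
        """Expected additive relationship matrix A (tabular method).

        ``A[i, i] = 1 + F_i`` where ``F_i`` is half the relationship of the
        parents; ``A[i, j] = (A[j, fa_i] + A[j, mo_i]) / 2`` taking each
        individual against earlier-listed ones.
        """
        t = self.table
        n = self.n
        fa = np.array([self._index.get(x, -1) for x in t["father"]])
        mo = np.array([self._index.get(x, -1) for x in t["mother"]])
        A = np.zeros((n, n))
        for i in range(n):
            if fa[i] < 0:
                A[i, i] = 1.0
            else:
                A[i, i] = 1.0 + 0.5 * A[fa[i], mo[i]]
                A[i, :i] = A[:i, i] = 0.5 * (A[fa[i], :i] + A[mo[i], :i])
        return A

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        t = pd.read_csv(path, sep="\t", dtype={c: str for c in ("id", "father", "mother", "spouse", "family")})
        t["sex"] = t["sex"].astype(int)
        return cls(t)


def kinship_coefficient(ped: Pedigree, i: str, j: str, _memo=None) -> float:
    """Kinship by direct recursion; reference oracle for small pedigrees."""
    if _memo is None:
        _memo = {}
    key = (i, j) if i <= j else (j, i)
    if key in _memo:
        return _memo[key]
    t = ped.table.set_index("id")
    order = ped._index

    def phi(a: str, b: str) -> float:
        k = (a, b) if a <= b else (b, a)
        if k in _memo:
            return _memo[k]
        # recurse on the later-born of the pair
        if order[a] < order[b]:
            a, b = b, a
        fa, mo = t.at[a, "father"], t.at[a, "mother"]
        if a == b:
            if fa == MISSING_PARENT:
                val = 0.5
            else:
                val = 0.5 * (1.0 + phi(fa, mo))
        elif fa == MISSING_PARENT:
            val = 0.0
        else:
            val = 0.5 * (phi(fa, b) + phi(mo, b))
        _memo[k] = val
        return val

    return phi(i, j)
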