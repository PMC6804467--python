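"""Pedigree structures and nuclear-family simulation.

A pedigree here is the family scaffold of a cell-line panel: a collection of
disjoint families (nuclear by default, optionally extended to a third
generation) whose members are the "individuals" that cell lines derive from.
Downstream modules use the pedigree for kinship computation, gene dropping
and sib-pair extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Individual", "Pedigree", "simulate_pedigrees"]


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both ``None`` (a founder) or
    both refer to members of the same family. ``sex`` uses the PED coding
    1 = male, 2 = female.
    """

    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: int

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad parents, cycles, duplicates)."""


class Pedigree:
    """An ordered collection of individuals forming disjoint families.

    Validates on construction: unique ids, parents either both absent or
    both present in the same family, and no individual is its own ancestor.
    Iteration order is the input order; :meth:`topological` yields parents
    before children, which gene dropping and kinship computation rely on.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise PedigreeError("duplicate individual ids")
        for ind in self.individuals:
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(f"{ind.id}: exactly one parent specified")
            if ind.father_id is not None:
                for pid in (ind.father_id, ind.mother_id):
                    parent = self._by_id.get(pid)
                    if parent is None:
                        raise PedigreeError(f"{ind.id}: unknown parent {pid}")
                    if parent.family_id != ind.family_id:
                        raise PedigreeError(
                            f"{ind.id}: parent {pid} in different family"
                        )
            if ind.sex not in (1, 2):
                raise PedigreeError(f"{ind.id}: sex must be 1 or 2")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS from each individual up the parent links
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"pedigree cycle involving {iid}")
            state[iid] = 0
            ind = self._by_id[iid]
            if ind.father_id is not None:
                visit(ind.father_id)
                visit(ind.mother_id)
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def topological(self) -> list[Individual]:
        """Individuals ordered so every parent precedes its children."""
        done: dict[str, Individual] = {}
        out: list[Individual] = []

        def visit(ind: Individual) -> None:
            if ind.id in done:
                return
            if ind.father_id is not None:
                visit(self._by_id[ind.father_id])
                visit(self._by_id[ind.mother_id])
            done[ind.id] = ind
            out.append(ind)

        for ind in self.individuals:
            visit(ind)
        return out

    def sib_pairs(self) -> list[tuple[str, str, str]]:
        """All distinct full-sib pairs as (id1, id2, family_id)."""
        by_parents: dict[tuple[str, str, str], list[str]] = {}
        for ind in self.individuals:
            if ind.father_id is not None:
                key = (ind.family_id, ind.father_id, ind.mother_id)
                by_parents.setdefault(key, []).append(ind.id)
        pairs = []
        for (fam, _f, _m), sibs in by_parents.items():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.append((sibs[i], sibs[j], fam))
        return pairs

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": [i.family_id for i in self.individuals],
                "id": [i.id for i in self.individuals],
                "father_id": [i.father_id or "0" for i in self.individuals],
                "mother_id": [i.mother_id or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        inds = [
            Individual(
                id=str(r.id),
                family_id=str(r.family_id),
                father_id=None if str(r.father_id) == "0" else str(r.father_id),
                mother_id=None if str(r.mother_id) == "0" else str(r.mother_id),
                sex=int(r.sex),
            )
            for r in df.itertuples()
        ]
        return cls(inds)


def simulate_pedigrees(
    n_families: int,
    children_per_family: int | tuple[int, int] | Sequence[int] = (2, 4),
    seed: int = 0,
    three_generation_fraction: float = 0.0,
) -> Pedigree:
    """Simulate disjoint nuclear families, optionally extended by a generation.

    Parameters
    ----------
    n_families
        Number of families; must be >= 1.
    children_per_family
        Either a fixed integer, an inclusive ``(low, high)`` range sampled
        uniformly per family, or an explicit per-family sequence.
    seed
        Seed for the family-size and sex draws; the same seed always
        produces the identical pedigree.
    three_generation_fraction
        Fraction of families whose eldest child is given a married-in
        founder spouse and a sibship of grandchildren (same size draw).

    Returns
    -------
    Pedigree
    """
    if n_families < 1:
        raise ValueError(f"n_families must be >= 1, got {n_families}")
    if not 0.0 <= three_generation_fraction <= 1.0:
        raise ValueError("three_generation_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if isinstance(children_per_family, int):
        n_children = [children_per_family] * n_families
    elif (
        isinstance(children_per_family, tuple)
        and len(children_per_family) == 2
        and all(isinstance(v, (int, np.integer)) for v in children_per_family)
    ):
        lo, hi = children_per_family
        n_children = rng.integers(lo, hi + 1, size=n_families).tolist()
    else:
        n_children = [int(v) for v in children_per_family]
        if len(n_children) != n_families:
            raise ValueError("children_per_family sequence length mismatch")
    if any(c < 0 for c in n_children):
        raise ValueError("children counts must be nonnegative")

    inds: list[Individual] = []
    for f in range(n_families):
        fam = f"F{f + 1:03d}"
        father = f"{fam}-01"
        mother = f"{fam}-02"
        inds.append(Individual(father, fam, None, None, 1))
        inds.append(Individual(mother, fam, None, None, 2))
        next_id = 3
        children: list[tuple[str, int]] = []
        for _ in range(n_children[f]):
            cid = f"{fam}-{next_id:02d}"
            sex = int(rng.integers(1, 3))
            inds.append(Individual(cid, fam, father, mother, sex))
            children.append((cid, sex))
            next_id += 1
        extend = children and rng.random() < three_generation_fraction
        if extend:
            eldest_id, eldest_sex = children[0]
            spouse = f"{fam}-{next_id:02d}"
            next_id += 1
            inds.append(Individual(spouse, fam, None, None, 3 - eldest_sex))
            g_father = eldest_id if eldest_sex == 1 else spouse
            g_mother = spouse if eldest_sex == 1 else eldest_id
            for _ in range(int(rng.integers(1, 4))):
                gid = f"{fam}-{next_id:02d}"
                next_id += 1
                inds.append(
                    Individual(gid, fam, g_father, g_mother, int(rng.integers(1, 3)))
                )
    return Pedigree(inds)
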