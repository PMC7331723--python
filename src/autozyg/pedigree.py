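"""Pedigree representation and 6-column PED file I/O.

A pedigree is a directed acyclic graph of individuals linked by
parent-offspring edges.  Founders have no parents inside the pedigree;
every non-founder must have both parents present.  Consanguineous
pedigrees contain loops: the two parents of a sibship share one or more
common ancestors, which is what makes autozygosity (homozygosity by
descent) possible in their children.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

MALE = 1
FEMALE = 2
UNKNOWN_SEX = 0


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are the identifiers of the parents, or ``None``
    for founders.  ``affected`` is ``True``/``False`` for a known
    affection status and ``None`` when unassigned (e.g. before the
    simulator has gene-dropped the disease allele).
    """

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: int = UNKNOWN_SEX
    affected: bool | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


class Pedigree:
    """An ordered collection of :class:`Individual` with structural checks.

    Enforces: unique identifiers, both-or-neither parents, parents present
    in the pedigree, correct parental sexes where known, and acyclicity.
    """

    def __init__(self, individuals: Iterable[Individual], family_id: str = "FAM1"):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self._members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self._members[ind.iid] = ind
        self._validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    # -- structure ----------------------------------------------------------

    def _validate(self) -> None:
        for ind in self:
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"{ind.iid}: non-founders need both parents present"
                )
            for parent, want_sex in ((ind.father, MALE), (ind.mother, FEMALE)):
                if parent is None:
                    continue
                if parent not in self._members:
                    raise PedigreeError(f"{ind.iid}: unknown parent {parent!r}")
                psex = self._members[parent].sex
                if psex not in (UNKNOWN_SEX, want_sex):
                    raise PedigreeError(
                        f"{ind.iid}: parent {parent!r} has inconsistent sex"
                    )
        self.topological_order()  # raises on cycles

    def founders(self) -> list[str]:
        return [i.iid for i in self if i.is_founder]

    def nonfounders(self) -> list[str]:
        return [i.iid for i in self if not i.is_founder]

    def parents(self, iid: str) -> tuple[str, str] | None:
        ind = self._members[iid]
        if ind.is_founder:
            return None
        return ind.father, ind.mother  # type: ignore[return-value]

    def children(self, iid: str) -> list[str]:
        return [i.iid for i in self if iid in (i.father, i.mother)]

    def affected_ids(self) -> list[str]:
        return [i.iid for i in self if i.affected is True]

    def unaffected_ids(self) -> list[str]:
        return [i.iid for i in self if i.affected is False]

    def topological_order(self) -> list[str]:
        """Identifiers ordered parents-before-children."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 in stack, 2 done

        def visit(iid: str) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise PedigreeError("pedigree contains a directed cycle")
            state[iid] = 1
            ind = self._members[iid]
            if not ind.is_founder:
                visit(ind.father)  # type: ignore[arg-type]
                visit(ind.mother)  # type: ignore[arg-type]
            state[iid] = 2
            order.append(iid)

        for iid in self._members:
            visit(iid)
        return order

    def ancestors(self, iid: str) -> set[str]:
        """All strict ancestors of ``iid`` (transitive closure of parents)."""
        out: set[str] = set()
        stack = [iid]
        while stack:
            cur = self._members[stack.pop()]
            for parent in (cur.father, cur.mother):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def common_ancestors(self, a: str, b: str) -> set[str]:
        return self.ancestors(a) & self.ancestors(b)

    def with_affection(self, status: dict[str, bool]) -> "Pedigree":
        """A copy with affection statuses overwritten from ``status``."""
        return Pedigree(
            [
                replace(ind, affected=status.get(ind.iid, ind.affected))
                for ind in self
            ],
            family_id=self.family_id,
        )


# -- PED file I/O ------------------------------------------------------------
#
# Standard 6-column linkage format: family, individual, father, mother,
# sex (1 male / 2 female / 0 unknown), affection (1 unaffected / 2
# affected / 0 unknown).  Missing parents are encoded as "0".

_AFF_CODE = {None: 0, False: 1, True: 2}
_AFF_DECODE = {0: None, 1: False, 2: True, -9: None}


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for ind in pedigree:
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    ind.iid,
                    ind.father or "0",
                    ind.mother or "0",
                    str(ind.sex),
                    str(_AFF_CODE[ind.affected]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path) -> Pedigree:
    individuals: list[Individual] = []
    family_id = "FAM1"
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise PedigreeError(f"PED line has {len(fields)} fields, expected 6")
        fam, iid, father, mother, sex, aff = fields
        family_id = fam
        individuals.append(
            Individual(
                iid=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex),
                affected=_AFF_DECODE[int(aff)],
            )
        )
    return Pedigree(individuals, family_id=family_id)
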