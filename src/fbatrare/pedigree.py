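"""Pedigree data model: individuals, families, founders, nuclear-family decomposition.

The pedigree is the backbone of every family-based test here: founders define
the population in which allele frequencies are estimated, and nuclear families
(father, mother, their common offspring) are the conditioning units of the
association test.  Extended pedigrees are decomposed into nuclear families; an
individual contributes as an offspring only in the family of its own parents,
while its role as a parent elsewhere is purely conditioning.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Base class for malformed pedigree input."""


class PedigreeFormatError(PedigreeError):
    """A row or field violates the file format contract."""


class PedigreeStructureError(PedigreeError):
    """The family graph itself is inconsistent (missing parents, cycles)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parents are either both known or both unknown: a single known parent is
    rejected because Mendelian conditioning needs both parental genotypes.
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeFormatError(
                f"individual {self.individual_id!r} (family {self.family_id!r}) "
                "has exactly one known parent; parents must be both present or both absent"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeFormatError(
                f"individual {self.individual_id!r}: invalid sex {self.sex!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A collection of individuals grouped into (possibly several) families.

    Validates on construction: referenced parents exist within the same
    family, and the parent graph is acyclic.  Generation depth is defined as
    1 for founders and max(parent depths) + 1 otherwise.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            prev = self._by_id.get(ind.individual_id)
            if prev is not None:
                if prev != ind:
                    raise PedigreeFormatError(
                        f"conflicting duplicate rows for individual {ind.individual_id!r}"
                    )
                continue
            self._by_id[ind.individual_id] = ind
        if not self._by_id:
            raise PedigreeFormatError("pedigree contains no individuals")
        self._depth = self._validate()

    def _validate(self) -> dict[str, int]:
        for ind in self._by_id.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeStructureError(
                        f"individual {ind.individual_id!r} references unknown parent {pid!r}"
                    )
                if parent.family_id != ind.family_id:
                    raise PedigreeStructureError(
                        f"individual {ind.individual_id!r} (family {ind.family_id!r}) "
                        f"references parent {pid!r} from family {parent.family_id!r}"
                    )
        # Kahn-style pass; anything unresolved at the end sits on a cycle.
        depth: dict[str, int] = {}
        children: dict[str, list[str]] = defaultdict(list)
        pending: dict[str, int] = {}
        queue: list[str] = []
        for ind in self._by_id.values():
            if ind.is_founder:
                depth[ind.individual_id] = 1
                queue.append(ind.individual_id)
            else:
                pending[ind.individual_id] = len({ind.father_id, ind.mother_id})
                for pid in {ind.father_id, ind.mother_id}:
                    children[pid].append(ind.individual_id)
        while queue:
            iid = queue.pop()
            for child in children[iid]:
                pending[child] -= 1
                if pending[child] == 0:
                    c = self._by_id[child]
                    depth[child] = max(depth[c.father_id], depth[c.mother_id]) + 1
                    queue.append(child)
        unresolved = [iid for iid, n in pending.items() if n > 0]
        if unresolved:
            raise PedigreeStructureError(
                f"cyclic parentage involving individual(s) {sorted(unresolved)[:5]}"
            )
        return depth

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __iter__(self):
        return iter(self._by_id.values())

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def individuals(self) -> tuple[Individual, ...]:
        return tuple(self._by_id.values())

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(sorted({ind.family_id for ind in self._by_id.values()}))

    @property
    def founders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self._by_id.values() if ind.is_founder)

    @property
    def nonfounders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self._by_id.values() if not ind.is_founder)

    def members(self, family_id: str) -> tuple[Individual, ...]:
        return tuple(i for i in self._by_id.values() if i.family_id == family_id)

    def generation_depth(self, family_id: str | None = None) -> int:
        """Maximum generation depth, overall or within one family."""
        if family_id is None:
            return max(self._depth.values())
        return max(self._depth[i.individual_id] for i in self.members(family_id))


@dataclass(frozen=True)
class NuclearFamily:
    """One father-mother pair and their common offspring (the test unit)."""

    family_id: str
    father_id: str
    mother_id: str
    offspring_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.offspring_ids:
            raise PedigreeStructureError("nuclear family must have at least one offspring")


def read_pedigree(path: str | Path, dialect: str = "ped") -> Pedigree:
    """Read a PED/FAM-style whitespace-delimited pedigree file.

    Columns: family, individual, father, mother, sex[, phenotype...]; "0"
    denotes a missing parent.  Rows with exactly one known parent raise a
    :class:`PedigreeFormatError` naming the row.
    """
    if dialect != "ped":
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeFormatError(
                    f"{path}, line {lineno}: expected >=5 columns, got {len(fields)}"
                )
            fam, iid, fa, mo, sex = fields[:5]
            try:
                individuals.append(
                    Individual(
                        individual_id=iid,
                        family_id=fam,
                        father_id=None if fa == "0" else fa,
                        mother_id=None if mo == "0" else mo,
                        sex=_SEX_FROM_CODE.get(sex, "unknown"),
                    )
                )
            except PedigreeFormatError as exc:
                raise PedigreeFormatError(f"{path}, line {lineno}: {exc}") from exc
    return Pedigree(individuals)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write a 6-column PED file (phenotype column fixed at 0)."""
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _CODE_FROM_SEX[ind.sex],
                        "0",
                    ]
                )
                + "\n"
            )


def decompose_nuclear_families(ped: Pedigree) -> list[NuclearFamily]:
    """Split extended pedigrees into nuclear families.

    One family per distinct (father, mother) pair with at least one common
    offspring.  Offspring are sorted lexicographically within a family and
    families by (family_id, father_id, mother_id), so the output is
    deterministic.  Every nonfounder appears as offspring in exactly one
    nuclear family (that of its own parents).
    """
    groups: dict[tuple[str, str, str], list[str]] = defaultdict(list)
    for ind in ped.nonfounders:
        groups[(ind.family_id, ind.father_id, ind.mother_id)].append(ind.individual_id)
    return [
        NuclearFamily(fam, fa, mo, tuple(sorted(offspring)))
        for (fam, fa, mo), offspring in sorted(groups.items())
    ]
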