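"""Pedigree model with a three-class phenotype.

Members of the family are labelled with one of three phenotype classes
(multiple primary lung cancer, multiple pulmonary nodules, unaffected)
plus an UNKNOWN class for members whose status is not recorded.
Segregation filters operate on per-class carrier counts, so the pedigree
is primarily a grouping of member ids by phenotype with validated parent
links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class Phenotype(str, Enum):
    """Phenotype class of a pedigree member."""

    MPLC = "MPLC"
    NODULE = "NODULE"
    UNAFFECTED = "UNAFFECTED"
    UNKNOWN = "UNKNOWN"


#: Numeric phenotype coding used in the PED-like TSV on disk.
PHENOTYPE_CODES = {2: Phenotype.MPLC, 1: Phenotype.NODULE, 0: Phenotype.UNAFFECTED, -9: Phenotype.UNKNOWN}
PHENOTYPE_TO_CODE = {v: k for k, v in PHENOTYPE_CODES.items()}


class PedigreeError(ValueError):
    """Raised when a pedigree violates its structural invariants."""


@dataclass(frozen=True)
class Member:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    phenotype: Phenotype = Phenotype.UNKNOWN


@dataclass
class Pedigree:
    """A validated family: unique ids, resolvable parents, no ancestry cycles."""

    members: list[Member] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.members:
            raise PedigreeError("pedigree has no members")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate member ids: {dupes}")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise PedigreeError(f"member {m.id!r}: parent {parent!r} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {m.id: [p for p in (m.father_id, m.mother_id) if p is not None] for m in self.members}
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise PedigreeError(f"ancestry cycle involving member {node!r}")
            state[node] = 0
            for p in parents[node]:
                visit(p, stack + [node])
            state[node] = 1

        for mid in parents:
            visit(mid, [])

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def phenotype_of(self, member_id: str) -> Phenotype:
        for m in self.members:
            if m.id == member_id:
                return m.phenotype
        raise KeyError(member_id)

    def members_in_class(self, phenotype: Phenotype) -> list[str]:
        return [m.id for m in self.members if m.phenotype is phenotype]

    def class_counts(self) -> dict[Phenotype, int]:
        counts = {p: 0 for p in Phenotype}
        for m in self.members:
            counts[m.phenotype] += 1
        return counts

    def founders(self) -> list[str]:
        return [m.id for m in self.members if m.father_id is None and m.mother_id is None]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterable[Member]:
        return iter(self.members)
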