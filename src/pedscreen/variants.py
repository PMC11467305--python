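"""Variant-level containers: annotated sites, genotype matrix, SV events.

Coordinates are 1-based inclusive throughout, matching VCF. Genotypes are
diploid alt-allele counts in {0, 1, 2}; a missing call is a distinct state
(pandas NA), never coerced to zero — segregation rules must decide how to
treat absent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .pedigree import Pedigree

#: Allowed SIFT / PolyPhen-2 categorical calls (consumed as annotations,
#: never computed here).
SIFT_CALLS = {"deleterious", "tolerated"}
POLYPHEN_CALLS = {"probably_damaging", "possibly_damaging", "benign"}
SV_TYPES = {"amplification", "deletion", "inversion", "translocation"}

SV_FIXED_COLUMNS = ["id", "type", "chrom1", "pos1", "chrom2", "pos2", "gene", "region_class"]


@dataclass(frozen=True)
class AnnotatedVariant:
    """A biallelic site with optional population-frequency and prediction
    annotations.

    Absent annotations carry meaning downstream: a variant with no AF in any
    population database is treated as *novel*, which is not the same as an
    AF of zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af_1kg_eas: Optional[float] = None
    af_esp: Optional[float] = None
    af_esp6500: Optional[float] = None
    sift_call: Optional[str] = None
    polyphen_call: Optional[str] = None
    region_class: Optional[str] = None  # "exonic" | "non_exonic"
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"{self.key}: empty allele string")
        for name in ("af_1kg_eas", "af_esp", "af_esp6500"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.key}: {name}={v} outside [0, 1]")
        if self.sift_call is not None and self.sift_call not in SIFT_CALLS:
            raise ValueError(f"{self.key}: unknown SIFT call {self.sift_call!r}")
        if self.polyphen_call is not None and self.polyphen_call not in POLYPHEN_CALLS:
            raise ValueError(f"{self.key}: unknown PolyPhen call {self.polyphen_call!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def af(self, database: str) -> Optional[float]:
        if database not in ("af_1kg_eas", "af_esp", "af_esp6500"):
            raise KeyError(f"unknown AF field {database!r}")
        return getattr(self, database)

    def with_annotations(self, **kwargs) -> "AnnotatedVariant":
        return replace(self, **kwargs)


AF_FIELDS = ("af_1kg_eas", "af_esp", "af_esp6500")


@dataclass
class GenotypeMatrix:
    """Variants x members table of alt-allele counts, with explicit missingness.

    Backed by a pandas DataFrame with nullable Int8 dtype; rows are variant
    keys (chrom:pos:ref:alt), columns are member ids in pedigree order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.astype("Int8")
        bad = self.table.stack().dropna()
        if len(bad) and not bad.isin([0, 1, 2]).all():
            raise ValueError("genotype entries must be in {0, 1, 2} or missing")

    @classmethod
    def from_calls(cls, variant_keys: Sequence[str], member_ids: Sequence[str], calls) -> "GenotypeMatrix":
        df = pd.DataFrame(calls, index=list(variant_keys), columns=list(member_ids), dtype="object")
        return cls(df.astype("Int8"))

    @property
    def variant_keys(self) -> list[str]:
        return list(self.table.index)

    @property
    def member_ids(self) -> list[str]:
        return list(self.table.columns)

    def carriers(self, variant_key: str) -> list[str]:
        """Member ids with alt-allele count >= 1 (dominant-model carrier)."""
        row = self.table.loc[variant_key]
        return [m for m, v in row.items() if pd.notna(v) and v >= 1]

    def check_members(self, pedigree: Pedigree) -> None:
        if set(self.member_ids) != set(pedigree.member_ids):
            raise ValueError("genotype matrix members do not match pedigree members")

    def subset(self, variant_keys: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.table.loc[list(variant_keys)])

    def __len__(self) -> int:
        return len(self.table)


def make_sv_table(events: pd.DataFrame, pedigree: Optional[Pedigree] = None) -> pd.DataFrame:
    """Validate an SV event table.

    Expected columns: the fixed schema (id, type, breakpoints, gene,
    region_class) followed by one 0/1 presence column per pedigree member.
    """
    missing = [c for c in SV_FIXED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"SV table missing columns: {missing}")
    bad_types = set(events["type"]) - SV_TYPES
    if bad_types:
        raise ValueError(f"unknown SV types: {sorted(bad_types)}")
    if events["id"].duplicated().any():
        raise ValueError("duplicate SV event ids")
    if pedigree is not None:
        member_cols = [c for c in events.columns if c not in SV_FIXED_COLUMNS]
        if set(member_cols) != set(pedigree.member_ids):
            raise ValueError("SV presence columns do not cover exactly the pedigree members")
    return events


def sv_member_columns(events: pd.DataFrame) -> list[str]:
    return [c for c in events.columns if c not in SV_FIXED_COLUMNS]
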