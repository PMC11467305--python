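"""SNV candidate cascade: frequency -> segregation -> deleteriousness,
plus the validation-cohort carrier-frequency statistic.

The cascade is set-based filtering under a dominant inheritance model, not
hypothesis testing; no multiple-testing correction applies. Each stage is a
pure predicate over a variant (and, for segregation, the genotype matrix
and pedigree), so the three filters commute and loosening any single rule
can only enlarge the candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .pedigree import Pedigree, Phenotype
from .variants import AF_FIELDS, POLYPHEN_CALLS, AnnotatedVariant, GenotypeMatrix

logger = logging.getLogger(__name__)


class RuleError(ValueError):
    """Raised for invalid filter-rule configuration."""


@dataclass
class FrequencyRule:
    """Retain variants rare in every consulted population database.

    A variant passes iff every *present* AF among ``databases`` is strictly
    below ``max_af``; a variant absent from all databases is novel and
    passes when ``treat_absent_as_pass`` (the default — novelty is evidence
    of rarity, not of commonness).
    """

    max_af: float = 0.01
    databases: Sequence[str] = AF_FIELDS
    treat_absent_as_pass: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.max_af <= 1.0):
            raise RuleError(f"max_af must be in (0, 1], got {self.max_af}")
        unknown = [d for d in self.databases if d not in AF_FIELDS]
        if unknown:
            raise RuleError(f"unknown AF field(s) {unknown}; known: {list(AF_FIELDS)}")

    def passes(self, variant: AnnotatedVariant) -> bool:
        afs = [variant.af(d) for d in self.databases]
        present = [a for a in afs if a is not None]
        if not present:
            return self.treat_absent_as_pass
        return all(a < self.max_af for a in present)


@dataclass
class SegregationRule:
    """Dominant-model co-segregation requirement with incomplete-penetrance
    tolerance.

    ``min_carriers`` gives the minimum number of carriers (alt count >= 1)
    per required phenotype class; ``max_carriers_unaffected`` caps carriers
    among unaffected members. UNKNOWN-class members are ignored. Missing
    genotypes are counted as non-carrier by default (conservative for a
    presence requirement) or the member can be excluded per variant.
    """

    min_carriers: dict[Phenotype, int] = field(
        default_factory=lambda: {Phenotype.MPLC: 5, Phenotype.NODULE: 8}
    )
    max_carriers_unaffected: int = 0
    missing_policy: str = "count_as_noncarrier"  # or "exclude_member"

    def __post_init__(self) -> None:
        if self.max_carriers_unaffected < 0:
            raise RuleError("max_carriers_unaffected must be >= 0")
        if self.missing_policy not in ("count_as_noncarrier", "exclude_member"):
            raise RuleError(f"unknown missing_policy {self.missing_policy!r}")
        if any(v < 0 for v in self.min_carriers.values()):
            raise RuleError("min_carriers values must be >= 0")

    def validate_against(self, pedigree: Pedigree) -> None:
        counts = pedigree.class_counts()
        for cls, need in self.min_carriers.items():
            if need > counts.get(cls, 0):
                raise RuleError(
                    f"rule demands {need} carriers in class {cls.value} "
                    f"but the pedigree has only {counts.get(cls, 0)} members there"
                )


def carrier_counts_by_class(
    variant_key: str, genotypes: GenotypeMatrix, pedigree: Pedigree
) -> dict[Phenotype, int]:
    """Number of carriers (alt count >= 1) per phenotype class; missing
    genotypes do not count as carriers under either missing policy."""
    row = genotypes.table.loc[variant_key]
    counts = {cls: 0 for cls in Phenotype}
    for m in pedigree:
        v = row[m.id]
        if pd.notna(v) and v >= 1:
            counts[m.phenotype] += 1
    return counts


def frequency_filter(
    variants: Sequence[AnnotatedVariant], rule: FrequencyRule
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Apply the population-frequency rule; returns (retained, verdicts)."""
    verdicts = []
    retained = []
    for v in variants:
        ok = rule.passes(v)
        verdicts.append({"variant": v.key, "stage": "frequency", "passed": ok})
        if ok:
            retained.append(v)
    return retained, pd.DataFrame(verdicts, columns=["variant", "stage", "passed"])


def segregation_filter(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    rule: SegregationRule,
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Apply the co-segregation rule; returns (retained, per-group counts)."""
    genotypes.check_members(pedigree)
    rule.validate_against(pedigree)
    n_missing = int(genotypes.table.isna().sum().sum())
    if n_missing and rule.missing_policy == "count_as_noncarrier":
        logger.warning("segregation_filter: %d missing genotypes counted as non-carrier", n_missing)
    retained, records = [], []
    for v in variants:
        counts = carrier_counts_by_class(v.key, genotypes, pedigree)
        ok = all(counts[cls] >= need for cls, need in rule.min_carriers.items())
        ok = ok and counts[Phenotype.UNAFFECTED] <= rule.max_carriers_unaffected
        records.append(
            {
                "variant": v.key,
                "carriers_MPLC": counts[Phenotype.MPLC],
                "carriers_NODULE": counts[Phenotype.NODULE],
                "carriers_UNAFFECTED": counts[Phenotype.UNAFFECTED],
                "passed": ok,
            }
        )
        if ok:
            retained.append(v)
    cols = ["variant", "carriers_MPLC", "carriers_NODULE", "carriers_UNAFFECTED", "passed"]
    return retained, pd.DataFrame(records, columns=cols)


@dataclass
class DeleteriousnessRule:
    """Retain variants predicted damaging by SIFT and/or PolyPhen-2.

    ``require`` is one of {either, both, sift_only, polyphen_only}; a
    variant with both calls absent is removed (and logged) — prediction
    evidence is required, unlike population-frequency evidence.
    """

    require: str = "either"
    damaging_polyphen_levels: frozenset = frozenset({"probably_damaging", "possibly_damaging"})

    def __post_init__(self) -> None:
        if self.require not in ("either", "both", "sift_only", "polyphen_only"):
            raise RuleError(f"unknown require mode {self.require!r}")
        if self.require != "sift_only" and not self.damaging_polyphen_levels:
            raise RuleError("damaging_polyphen_levels must be non-empty when PolyPhen is used")
        if not set(self.damaging_polyphen_levels) <= POLYPHEN_CALLS:
            raise RuleError(f"unknown PolyPhen levels {set(self.damaging_polyphen_levels) - POLYPHEN_CALLS}")

    def passes(self, variant: AnnotatedVariant) -> bool:
        sift_bad = variant.sift_call == "deleterious"
        poly_bad = variant.polyphen_call in self.damaging_polyphen_levels
        if variant.sift_call is None and variant.polyphen_call is None:
            return False
        if self.require == "either":
            return sift_bad or poly_bad
        if self.require == "both":
            return sift_bad and poly_bad
        if self.require == "sift_only":
            return sift_bad
        return poly_bad


def deleteriousness_filter(
    variants: Sequence[AnnotatedVariant], rule: DeleteriousnessRule
) -> list[AnnotatedVariant]:
    retained = [v for v in variants if rule.passes(v)]
    n_unscored = sum(1 for v in variants if v.sift_call is None and v.polyphen_call is None)
    if n_unscored:
        logger.info("deleteriousness_filter: %d variants removed for lacking any prediction call", n_unscored)
    return retained


@dataclass
class CascadeRules:
    frequency: FrequencyRule = field(default_factory=FrequencyRule)
    segregation: SegregationRule = field(default_factory=SegregationRule)
    deleteriousness: DeleteriousnessRule = field(default_factory=DeleteriousnessRule)


def run_snv_cascade(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    rules: Optional[CascadeRules] = None,
) -> pd.DataFrame:
    """Run frequency -> segregation -> deleteriousness and report candidates.

    Returns a candidate table (one row per retained variant, sorted by
    chrom/pos/ref/alt) with annotations, per-class carrier counts, and the
    per-stage filter trail. Per-stage removal counts are logged.
    """
    rules = rules or CascadeRules()
    after_freq, _ = frequency_filter(variants, rules.frequency)
    after_seg, seg_counts = segregation_filter(after_freq, genotypes, pedigree, rules.segregation)
    candidates = deleteriousness_filter(after_seg, rules.deleteriousness)
    logger.info(
        "snv cascade: %d -> frequency %d -> segregation %d -> deleteriousness %d",
        len(variants), len(after_freq), len(after_seg), len(candidates),
    )
    seg_by_key = seg_counts.set_index("variant") if len(seg_counts) else None
    rows = []
    for v in candidates:
        counts = seg_by_key.loc[v.key]
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "gene": v.gene,
                "carriers_MPLC": int(counts["carriers_MPLC"]),
                "carriers_NODULE": int(counts["carriers_NODULE"]),
                "carriers_UNAFFECTED": int(counts["carriers_UNAFFECTED"]),
                "af_1kg_eas": v.af_1kg_eas, "af_esp": v.af_esp, "af_esp6500": v.af_esp6500,
                "sift_call": v.sift_call, "polyphen_call": v.polyphen_call,
                "region_class": v.region_class,
                "passed_frequency": True, "passed_segregation": True, "passed_deleteriousness": True,
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "gene",
        "carriers_MPLC", "carriers_NODULE", "carriers_UNAFFECTED",
        "af_1kg_eas", "af_esp", "af_esp6500", "sift_call", "polyphen_call", "region_class",
        "passed_frequency", "passed_segregation", "passed_deleteriousness",
    ]
    report = pd.DataFrame(rows, columns=cols)
    return report.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort carrier frequency

@dataclass(frozen=True)
class CohortScreenResult:
    n_carriers: int
    n_total: int
    frequency: float
    ci95: tuple[float, float]
    method: str = "clopper-pearson"

    @property
    def percent(self) -> str:
        """Percentage rendered to one decimal, rounding half-up."""
        pct = Decimal(self.n_carriers) / Decimal(self.n_total) * 100
        return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def carrier_frequency(n_carriers: int, n_total: int) -> CohortScreenResult:
    """Carrier frequency with an exact (Clopper-Pearson) 95% interval.

    The interval endpoints are beta-distribution quantiles:
    low = B(alpha/2; k, n-k+1), high = B(1-alpha/2; k+1, n-k), with the
    conventional 0 and 1 at the k=0 and k=n boundaries.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_carriers <= n_total):
        raise ValueError(f"n_carriers {n_carriers} outside [0, {n_total}]")
    k, n, alpha = n_carriers, n_total, 0.05
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return CohortScreenResult(n_carriers=k, n_total=n, frequency=k / n, ci95=(low, high))
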