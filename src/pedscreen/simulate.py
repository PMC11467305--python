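"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes: a
small pedigree segregating a dominant heterozygous variant with incomplete
penetrance, rare and common background variants at Hardy-Weinberg genotype
frequencies, group-recurrent structural-variant events, multi-condition
expression with planted differential effects and a planted enriched gene
set, and binary tumor-take outcomes at graded cell doses under a single-hit
Poisson model.

``build_paper_fixture`` is a deterministic workspace that encodes the
published carrier patterns of the study family (5 MPLC / 9 nodule /
1 unaffected; three co-segregating candidate variants carried by 13 of 15
members; two group-recurrent non-exonic SV events) and is used as the
ground-truth fixture for end-to-end checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Member, Pedigree, Phenotype
from .variants import SV_FIXED_COLUMNS, AnnotatedVariant, GenotypeMatrix, make_sv_table


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


#: Default penetrance: carriers mostly express cancer or nodules, with a
#: small non-penetrant fraction; non-carriers are mostly unaffected but may
#: sporadically present nodules.
DEFAULT_PENETRANCE = {
    True: {Phenotype.MPLC: 0.35, Phenotype.NODULE: 0.55, Phenotype.UNAFFECTED: 0.10},
    False: {Phenotype.MPLC: 0.01, Phenotype.NODULE: 0.04, Phenotype.UNAFFECTED: 0.95},
}

PHENOTYPE_ORDER = (Phenotype.MPLC, Phenotype.NODULE, Phenotype.UNAFFECTED)


@dataclass
class SimConfig:
    """Configuration for the pedigree + genotype simulator."""

    n_members: int = 15
    class_counts: dict[Phenotype, int] = field(
        default_factory=lambda: {Phenotype.MPLC: 5, Phenotype.NODULE: 9, Phenotype.UNAFFECTED: 1}
    )
    planted_variant_count: int = 1
    background_variant_count: int = 200
    #: (alpha, beta) of the Beta distribution background AFs are drawn from.
    background_af_distribution: tuple[float, float] = (0.3, 3.0)
    penetrance: dict[bool, dict[Phenotype, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PENETRANCE.items()}
    )
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_members:
            raise ConfigurationError(
                f"class_counts sum {sum(self.class_counts.values())} != n_members {self.n_members}"
            )
        if not (0.0 <= self.genotype_missing_rate <= 1.0):
            raise ConfigurationError("genotype_missing_rate must be in [0, 1]")
        a, b = self.background_af_distribution
        if a <= 0 or b <= 0:
            raise ConfigurationError("Beta parameters must be positive")
        for status, row in self.penetrance.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"penetrance row for carrier={status} sums to {total}, not 1")
            if any(p < 0 or p > 1 for p in row.values()):
                raise ConfigurationError("penetrance probabilities must be in [0, 1]")


def _assign_phenotypes(
    rng: np.random.Generator,
    carrier: dict[str, bool],
    class_counts: dict[Phenotype, int],
    penetrance: dict[bool, dict[Phenotype, float]],
) -> dict[str, Phenotype]:
    """Assign phenotype classes matching exact class counts.

    Members are drawn into each class sequentially, without replacement,
    with weight equal to their penetrance probability for the class given
    carrier status. This conditions the penetrance model on the observed
    class sizes of the study design; with a deterministic (0/1) penetrance
    it reduces to the exact carrier-status labelling when feasible.
    """
    unassigned = list(carrier)
    assignment: dict[str, Phenotype] = {}
    for cls in PHENOTYPE_ORDER:
        need = class_counts.get(cls, 0)
        for _ in range(need):
            weights = np.array([penetrance[carrier[m]].get(cls, 0.0) for m in unassigned], dtype=float)
            if weights.sum() <= 0:
                raise ConfigurationError(
                    f"cannot fill class {cls.value}: no remaining member has positive "
                    f"penetrance for it (class_counts incompatible with penetrance)"
                )
            pick = rng.choice(len(unassigned), p=weights / weights.sum())
            assignment[unassigned.pop(int(pick))] = cls
    for m in unassigned:
        assignment[m] = Phenotype.UNKNOWN
    return assignment


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Simulate a two-generation pedigree with planted and background variants.

    Topology: a carrier founder and a non-carrier spouse, with all remaining
    members their children. Planted variants are heterozygous in the founder
    and transmitted Mendelianly (each child inherits the alternate allele
    with probability 1/2, independently per variant). Background variants are
    drawn per member at Hardy-Weinberg genotype frequencies for an allele
    frequency sampled from the configured Beta distribution.

    Returns the pedigree, the genotype matrix, and an annotation table
    consistent with planted/background status (planted variants rare and
    predicted damaging; background variants annotated at their simulated AF).
    """
    if config.n_members < 2:
        raise ConfigurationError("need at least founder couple (n_members >= 2)")
    rng = np.random.default_rng(config.seed)

    founder, spouse = "F1", "F2"
    children = [f"C{i}" for i in range(1, config.n_members - 1)]
    member_ids = [founder, spouse] + children

    # Planted variants: het in the founder, Mendelian transmission to children.
    planted_keys, planted_rows, annot_rows = [], [], []
    for i in range(config.planted_variant_count):
        v = AnnotatedVariant(
            chrom="17", pos=41_000_000 + i, ref="C", alt="T",
            af_1kg_eas=None, af_esp=None, af_esp6500=None,
            sift_call="deleterious", polyphen_call="probably_damaging",
            region_class="exonic", gene=f"PLANTED{i + 1}",
        )
        planted_keys.append(v.key)
        annot_rows.append(v)
        transmitted = rng.integers(0, 2, size=len(children))  # founder passes alt w.p. 1/2
        planted_rows.append([1, 0] + list(transmitted))

    # Background variants: independent Hardy-Weinberg draws at a Beta AF.
    a, b = config.background_af_distribution
    bg_keys, bg_rows = [], []
    for i in range(config.background_variant_count):
        af = float(rng.beta(a, b))
        v = AnnotatedVariant(
            chrom=str(int(rng.integers(1, 23))), pos=int(1_000_000 + i),
            ref="A", alt="G",
            af_1kg_eas=af,
            af_esp=af if rng.random() < 0.8 else None,
            af_esp6500=af if rng.random() < 0.8 else None,
            sift_call=str(rng.choice(["deleterious", "tolerated"], p=[0.1, 0.9])),
            polyphen_call=str(rng.choice(["probably_damaging", "possibly_damaging", "benign"], p=[0.05, 0.1, 0.85])),
            region_class=str(rng.choice(["exonic", "non_exonic"], p=[0.3, 0.7])),
            gene=f"BG{i + 1}",
        )
        bg_keys.append(v.key)
        annot_rows.append(v)
        bg_rows.append(list(rng.binomial(2, af, size=len(member_ids))))

    keys = planted_keys + bg_keys
    calls = np.array(planted_rows + bg_rows, dtype=object) if keys else np.empty((0, len(member_ids)), dtype=object)
    if config.genotype_missing_rate > 0 and len(keys):
        mask = rng.random(calls.shape) < config.genotype_missing_rate
        calls = calls.copy()
        calls[mask] = pd.NA

    genotypes = GenotypeMatrix.from_calls(keys, member_ids, calls)

    # Carrier status for phenotype assignment: carries any planted variant.
    if planted_keys:
        carrier = {
            m: any(
                pd.notna(genotypes.table.loc[k, m]) and genotypes.table.loc[k, m] >= 1
                for k in planted_keys
            )
            for m in member_ids
        }
    else:
        carrier = {m: False for m in member_ids}
    phenotypes = _assign_phenotypes(rng, carrier, config.class_counts, config.penetrance)

    members = [
        Member(id=founder, sex=1, phenotype=phenotypes[founder]),
        Member(id=spouse, sex=2, phenotype=phenotypes[spouse]),
    ]
    members += [
        Member(id=c, father_id=founder, mother_id=spouse, sex=int(1 + (i % 2)), phenotype=phenotypes[c])
        for i, c in enumerate(children)
    ]
    pedigree = Pedigree(members)

    from .io import annotations_to_table

    return pedigree, genotypes, annotations_to_table(annot_rows)


# ---------------------------------------------------------------------------
# SV simulation

@dataclass
class PlantedSv:
    gene: str
    #: carriers per phenotype group, e.g. {MPLC: 5, NODULE: 9, UNAFFECTED: 0}
    group_carriers: dict[Phenotype, int]
    region_class: str = "non_exonic"
    sv_type: str = "deletion"


@dataclass
class SvSimConfig:
    n_background_events: int = 40
    planted_events: list[PlantedSv] = field(default_factory=list)
    seed: int = 0


def simulate_sv_table(config: SvSimConfig, pedigree: Pedigree) -> pd.DataFrame:
    """Simulate an SV event table with per-member presence flags.

    Planted events are present in exactly the configured number of members
    per phenotype group (which members is random); background events have
    independent presence at a random per-event rate.
    """
    rng = np.random.default_rng(config.seed)
    members = pedigree.member_ids
    groups = {cls: pedigree.members_in_class(cls) for cls in PHENOTYPE_ORDER}
    rows = []

    for i, ev in enumerate(config.planted_events):
        presence = {m: 0 for m in members}
        for cls, k in ev.group_carriers.items():
            pool = groups.get(cls, [])
            if k > len(pool):
                raise ConfigurationError(
                    f"planted event {ev.gene}: {k} carriers requested in {cls.value} group of size {len(pool)}"
                )
            for m in rng.choice(pool, size=k, replace=False) if k else []:
                presence[m] = 1
        rows.append(
            {
                "id": f"SV_PLANTED_{i + 1}", "type": ev.sv_type,
                "chrom1": str(int(rng.integers(1, 23))), "pos1": int(rng.integers(1e6, 2e8)),
                "chrom2": str(int(rng.integers(1, 23))), "pos2": int(rng.integers(1e6, 2e8)),
                "gene": ev.gene, "region_class": ev.region_class,
                **presence,
            }
        )

    sv_types = ["amplification", "deletion", "inversion", "translocation"]
    for i in range(config.n_background_events):
        rate = float(rng.uniform(0.05, 0.7))
        presence = {m: int(rng.random() < rate) for m in members}
        rows.append(
            {
                "id": f"SV_BG_{i + 1}", "type": str(rng.choice(sv_types)),
                "chrom1": str(int(rng.integers(1, 23))), "pos1": int(rng.integers(1e6, 2e8)),
                "chrom2": str(int(rng.integers(1, 23))), "pos2": int(rng.integers(1e6, 2e8)),
                "gene": f"BGSV{i + 1}", "region_class": str(rng.choice(["exonic", "non_exonic"], p=[0.3, 0.7])),
                **presence,
            }
        )
    table = pd.DataFrame(rows, columns=SV_FIXED_COLUMNS + members)
    return make_sv_table(table, pedigree)


# ---------------------------------------------------------------------------
# Expression simulation

@dataclass
class ExprSimConfig:
    """Multi-condition expression simulator on the log2 scale.

    Expression for gene g in condition c is
    ``baseline_g + effect(g, c) + N(0, noise_sd)`` on the log2 scale;
    returned values are linear (2**log2). ``planted_de`` maps gene ->
    {condition -> log2 shift relative to the first (reference) condition};
    ``planted_enriched_set`` additionally shifts every member of a named
    gene set in one condition, creating rank-level enrichment.
    """

    n_genes: int = 1000
    conditions: Sequence[str] = ("vector", "wild", "mutant")
    n_replicates: int = 1
    planted_de: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (set name, member genes, log2 shift, condition receiving the shift)
    planted_enriched_set: Optional[tuple[str, Sequence[str], float, str]] = None
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        universe = {f"G{i + 1}" for i in range(self.n_genes)}
        for gene, effects in self.planted_de.items():
            if gene not in universe:
                raise ConfigurationError(f"planted DE gene {gene!r} outside the G1..G{self.n_genes} universe")
            for cond in effects:
                if cond not in self.conditions:
                    raise ConfigurationError(f"unknown condition {cond!r} in planted effects")
        if self.planted_enriched_set is not None:
            name, genes, _shift, cond = self.planted_enriched_set
            if cond not in self.conditions:
                raise ConfigurationError(f"unknown condition {cond!r} in planted enriched set")
            if not set(genes) <= universe:
                raise ConfigurationError(f"planted set {name!r} has genes outside the universe")

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]


def simulate_expression(config: ExprSimConfig) -> pd.DataFrame:
    """Simulate a genes x samples linear-scale expression matrix."""
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    baseline = rng.uniform(3.0, 10.0, size=config.n_genes)  # log2 scale
    shift = pd.DataFrame(0.0, index=genes, columns=list(config.conditions))
    for gene, effects in config.planted_de.items():
        for cond, eff in effects.items():
            shift.loc[gene, cond] += eff
    if config.planted_enriched_set is not None:
        _name, set_genes, set_shift, cond = config.planted_enriched_set
        shift.loc[list(set_genes), cond] += set_shift

    columns, data = [], []
    for cond in config.conditions:
        for r in range(config.n_replicates):
            name = cond if config.n_replicates == 1 else f"{cond}_r{r + 1}"
            columns.append(name)
            log2 = baseline + shift[cond].to_numpy()
            if config.noise_sd > 0:
                log2 = log2 + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            data.append(2.0 ** log2)
    return pd.DataFrame(np.column_stack(data), index=genes, columns=columns)


# ---------------------------------------------------------------------------
# Limiting dilution simulation

def simulate_limiting_dilution(
    f_true: float,
    doses: Sequence[float],
    n_per_dose: int,
    seed: int = 0,
    group: str = "sim",
) -> pd.DataFrame:
    """Simulate tumor-take outcomes under the single-hit Poisson model.

    Each animal implanted with ``d`` cells is positive with probability
    ``1 - exp(-f_true * d)``, independently.
    """
    if f_true < 0:
        raise ValueError(f"f_true must be >= 0, got {f_true}")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        p = -math.expm1(-f_true * d)
        rows.append({"group": group, "dose": d, "n_tested": n_per_dose, "n_positive": int(rng.binomial(n_per_dose, p))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deterministic study fixture

_FIXTURE_SEED = 202_410  # fixed: the fixture must be byte-reproducible

#: Candidate genes on chromosome 17 with their approximate positions (Mb
#: order 40/41/42) and planted annotations.
_FIXTURE_PLANTED_SNVS = [
    dict(chrom="17", pos=40_000_000, ref="G", alt="A", gene="KLHL10"),
    dict(chrom="17", pos=41_000_000, ref="C", alt="T", gene="ETV4"),
    dict(chrom="17", pos=42_000_000, ref="C", alt="T", gene="ASB16"),
]


def fixture_pedigree() -> Pedigree:
    """The 15-member study pedigree: 5 MPLC sibs, each with children among
    the 9 nodule members and the single unaffected member."""
    members = [Member(id=f"MPLC_{i}", sex=1 + (i % 2), phenotype=Phenotype.MPLC) for i in range(1, 6)]
    child_parent = {
        "NODULE_1": "MPLC_1", "NODULE_2": "MPLC_1",
        "NODULE_3": "MPLC_2", "NODULE_4": "MPLC_2",
        "NODULE_5": "MPLC_3", "NODULE_6": "MPLC_3",
        "NODULE_7": "MPLC_4", "NODULE_8": "MPLC_4",
        "NODULE_9": "MPLC_5", "UNAFFECTED_1": "MPLC_5",
    }
    for i, (child, parent) in enumerate(child_parent.items()):
        cls = Phenotype.UNAFFECTED if child.startswith("UNAFFECTED") else Phenotype.NODULE
        members.append(Member(id=child, father_id=parent, sex=1 + (i % 2), phenotype=cls))
    return Pedigree(members)


#: The one nodule member who does not carry the candidate variants
#: (8 of 9 nodule members are carriers).
_FIXTURE_NONCARRIER_NODULE = "NODULE_9"


def build_paper_fixture() -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Deterministic fixture reproducing the published carrier patterns.

    Returns (pedigree, genotypes, annotation table, SV table) with:

    * 15 members: 5 MPLC, 9 nodule, 1 unaffected;
    * 3 planted heterozygous candidate SNVs carried by all 5 MPLC members
      and 8 of 9 nodule members, absent in the unaffected member (13/15
      carriers), each rare (AF < 1% or novel) and predicted damaging;
    * 210 background SNVs, each violating at least one cascade rule
      (common AF, non-segregating genotype pattern, or benign predictions);
    * an SV table with 2 planted non-exonic events recurrent in all cancer
      and all nodule members and absent in the unaffected member, plus 40
      background events that are each under-recurrent or present in the
      unaffected member.

    Calling twice yields byte-identical outputs (fixed internal seed).
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    ped = fixture_pedigree()
    members = ped.member_ids
    mplc = ped.members_in_class(Phenotype.MPLC)
    nodule = ped.members_in_class(Phenotype.NODULE)
    unaffected = ped.members_in_class(Phenotype.UNAFFECTED)
    carriers = mplc + [m for m in nodule if m != _FIXTURE_NONCARRIER_NODULE]

    variants: list[AnnotatedVariant] = []
    keys, rows = [], []

    # Planted candidates: het in the 13 carriers, rare + damaging.
    planted_af = [None, 0.001, None]  # one rare, two novel
    for spec, af in zip(_FIXTURE_PLANTED_SNVS, planted_af):
        v = AnnotatedVariant(
            **spec,
            af_1kg_eas=af, af_esp=af, af_esp6500=None,
            sift_call="deleterious", polyphen_call="probably_damaging",
            region_class="exonic",
        )
        variants.append(v)
        keys.append(v.key)
        rows.append([1 if m in carriers else 0 for m in members])

    # Background SNVs, cycling through cascade-rule violations.
    n_background = 210
    for i in range(n_background):
        kind = i % 3
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1_000_000, 100_000_000))
        if kind == 0:  # common variant: fails the frequency rule
            af = float(rng.uniform(0.02, 0.5))
            genos = rng.binomial(2, af, size=len(members))
            sift, poly = "deleterious", "probably_damaging"
        elif kind == 1:  # rare + damaging but fails segregation
            af = float(rng.uniform(1e-5, 0.009))
            if rng.random() < 0.5:
                # carried by the unaffected member
                genos = np.array([1 if m in unaffected else int(rng.random() < 0.5) for m in members])
            else:
                # too few MPLC carriers (at most 3 of 5)
                genos = np.zeros(len(members), dtype=int)
                chosen = rng.choice(mplc, size=int(rng.integers(0, 4)), replace=False)
                for m in chosen:
                    genos[members.index(m)] = 1
            sift, poly = "deleterious", "probably_damaging"
        else:  # rare, segregates or not, but predicted benign
            af = float(rng.uniform(1e-5, 0.009)) if rng.random() < 0.7 else None
            genos = np.array([1 if m in carriers else 0 for m in members])
            sift, poly = ("tolerated", "benign") if rng.random() < 0.7 else (None, None)
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref="A", alt="G",
            af_1kg_eas=af, af_esp=af, af_esp6500=af,
            sift_call=sift, polyphen_call=poly,
            region_class=str(rng.choice(["exonic", "non_exonic"], p=[0.4, 0.6])),
            gene=f"BG{i + 1}",
        )
        if v.key in keys:  # collision on random coordinates: skip silently
            continue
        variants.append(v)
        keys.append(v.key)
        rows.append(list(genos))

    genotypes = GenotypeMatrix.from_calls(keys, members, rows)

    from .io import annotations_to_table

    annotations = annotations_to_table(variants)

    # SV table: two planted recurrent non-exonic events + background events
    # that are each under-recurrent or present in the unaffected member.
    sv_rows = []
    for gene, sv_type, chrom in (("ARHGAP19", "deletion", "10"), ("NRG1", "translocation", "8")):
        presence = {m: (0 if m in unaffected else 1) for m in members}
        sv_rows.append(
            {
                "id": f"SV_{gene}", "type": sv_type,
                "chrom1": chrom, "pos1": int(rng.integers(1e6, 2e8)),
                "chrom2": chrom, "pos2": int(rng.integers(1e6, 2e8)),
                "gene": gene, "region_class": "non_exonic",
                **presence,
            }
        )
    sv_types = ["amplification", "deletion", "inversion", "translocation"]
    for i in range(40):
        if i % 2 == 0:  # under-recurrent in at least one required group
            n_mplc = int(rng.integers(0, 5))       # < 5 cancer carriers
            n_nod = int(rng.integers(0, 10))
            in_unaff = int(rng.random() < 0.3)
        else:  # recurrent but present in the unaffected member
            n_mplc = int(rng.integers(0, 6))
            n_nod = int(rng.integers(0, 10))
            in_unaff = 1
        presence = {m: 0 for m in members}
        for m in rng.choice(mplc, size=n_mplc, replace=False) if n_mplc else []:
            presence[m] = 1
        for m in rng.choice(nodule, size=n_nod, replace=False) if n_nod else []:
            presence[m] = 1
        presence[unaffected[0]] = in_unaff
        sv_rows.append(
            {
                "id": f"SV_BG_{i + 1}", "type": str(rng.choice(sv_types)),
                "chrom1": str(int(rng.integers(1, 23))), "pos1": int(rng.integers(1e6, 2e8)),
                "chrom2": str(int(rng.integers(1, 23))), "pos2": int(rng.integers(1e6, 2e8)),
                "gene": f"BGSV{i + 1}", "region_class": str(rng.choice(["exonic", "non_exonic"])),
                **presence,
            }
        )
    sv_table = make_sv_table(pd.DataFrame(sv_rows, columns=SV_FIXED_COLUMNS + members), ped)
    return ped, genotypes, annotations, sv_table
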