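"""Readers and writers for the pipeline's on-disk formats.

Formats: VCF v4.2 (GT only; other FORMAT fields ignored), PED-like TSV with
a numeric phenotype column ({2=MPLC, 1=NODULE, 0=UNAFFECTED, -9=UNKNOWN}),
annotation TSV keyed by (chrom, pos, ref, alt), SV TSV with per-member 0/1
presence columns, expression TSV (genes x samples), GMT gene sets, and the
assay CSV schemas. Every writer here is paired with the reader that parses
its output, and round-trips are covered by tests.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF

from .pedigree import PHENOTYPE_CODES, PHENOTYPE_TO_CODE, Member, Pedigree, PedigreeError, Phenotype
from .variants import (
    AF_FIELDS,
    SV_FIXED_COLUMNS,
    AnnotatedVariant,
    GenotypeMatrix,
    make_sv_table,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "af_1kg_eas", "af_esp", "af_esp6500",
    "sift_call", "polyphen_call", "region_class", "gene",
]


class VcfFormatError(ValueError):
    """Raised when a VCF lacks required structure (e.g. no GT field)."""


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: PathLike) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read a VCF into bare variants (annotation fields absent) and genotypes.

    Multiallelic records are split into one biallelic row per alt allele;
    the genotype entry is the count of that specific alt in the diploid
    call. ``./.`` becomes a missing entry. Sample order is preserved.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no samples (GT field required)")
    variants: list[AnnotatedVariant] = []
    rows: list[list] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(rec.ALT, start=1):
            variants.append(AnnotatedVariant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt))
            row = []
            for g in gts:
                alleles = [a for a in g[:-1]]
                if any(a is None or a < 0 for a in alleles):
                    row.append(pd.NA)
                else:
                    row.append(sum(1 for a in alleles if a == alt_index))
            rows.append(row)
    vcf.close()
    keys = [v.key for v in variants]
    if len(set(keys)) != len(keys):
        raise VcfFormatError(f"{path}: duplicate biallelic sites after splitting")
    matrix = GenotypeMatrix.from_calls(keys, samples, rows)
    return variants, matrix


def write_vcf(variants: Sequence[AnnotatedVariant], genotypes: GenotypeMatrix, path: PathLike) -> None:
    """Write a minimal VCF v4.2 with diploid GT calls (unphased)."""
    seen, contigs = set(), []
    for v in variants:
        if v.chrom not in seen:
            seen.add(v.chrom)
            contigs.append(v.chrom)
    lines = (
        ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
        + [f"##contig=<ID={c}>" for c in contigs]
        + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.member_ids)]
    )
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for v in variants:
        row = genotypes.table.loc[v.key]
        calls = ["./." if pd.isna(x) else gt_strings[int(x)] for x in row]
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED

PED_COLUMNS = ["family_id", "member_id", "father_id", "mother_id", "sex", "phenotype"]


def read_ped(path: PathLike) -> Pedigree:
    """Read a PED-like TSV (6 columns, numeric phenotype coding)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise PedigreeError(f"{path}: empty pedigree file")
    members = []
    lines = text.splitlines()
    start = 1 if lines[0].lstrip("#").split("\t")[0] in ("family_id", "FID") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}")
        _, mid, fid, mo, sex, pheno = fields
        try:
            pheno_class = PHENOTYPE_CODES[int(pheno)]
        except (KeyError, ValueError):
            raise PedigreeError(f"{path}:{lineno}: unknown phenotype code {pheno!r}") from None
        members.append(
            Member(
                id=mid,
                father_id=None if fid in ("0", "", ".") else fid,
                mother_id=None if mo in ("0", "", ".") else mo,
                sex=int(sex),
                phenotype=pheno_class,
            )
        )
    return Pedigree(members)


def write_ped(pedigree: Pedigree, path: PathLike, family_id: str = "FAM1") -> None:
    lines = ["\t".join(PED_COLUMNS)]
    for m in pedigree:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    str(m.sex),
                    str(PHENOTYPE_TO_CODE[m.phenotype]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV

def read_annotations(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {missing}")
    return df


def write_annotations(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def join_annotations(
    variants: Sequence[AnnotatedVariant], annotation_table: pd.DataFrame
) -> list[AnnotatedVariant]:
    """Fill annotation fields by (chrom, pos, ref, alt) key.

    Unmatched variants keep all annotation fields absent (interpreted
    downstream as novel) and are counted in the log. Duplicate annotation
    keys are rejected.
    """
    keyed = annotation_table.set_index(
        annotation_table["chrom"].astype(str)
        + ":"
        + annotation_table["pos"].astype(int).astype(str)
        + ":"
        + annotation_table["ref"]
        + ":"
        + annotation_table["alt"]
    )
    if keyed.index.duplicated().any():
        dupes = sorted(keyed.index[keyed.index.duplicated()].unique())
        raise ValueError(f"duplicate annotation keys: {dupes[:5]}")
    out: list[AnnotatedVariant] = []
    n_unmatched = 0
    for v in variants:
        if v.key in keyed.index:
            row = keyed.loc[v.key]

            def _f(col):
                x = row[col]
                return None if pd.isna(x) else float(x)

            def _s(col):
                x = row[col]
                return None if pd.isna(x) else str(x)

            out.append(
                v.with_annotations(
                    af_1kg_eas=_f("af_1kg_eas"),
                    af_esp=_f("af_esp"),
                    af_esp6500=_f("af_esp6500"),
                    sift_call=_s("sift_call"),
                    polyphen_call=_s("polyphen_call"),
                    region_class=_s("region_class"),
                    gene=_s("gene"),
                )
            )
        else:
            n_unmatched += 1
            out.append(v)
    if n_unmatched:
        logger.info("join_annotations: %d/%d variants unannotated (treated as novel)", n_unmatched, len(variants))
    return out


def variants_from_table(annotation_table: pd.DataFrame) -> list[AnnotatedVariant]:
    """Materialize AnnotatedVariant objects from a full annotation table."""

    def _opt(x):
        return None if pd.isna(x) else x

    out = []
    for row in annotation_table.itertuples(index=False):
        out.append(
            AnnotatedVariant(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
                af_1kg_eas=_opt(row.af_1kg_eas), af_esp=_opt(row.af_esp), af_esp6500=_opt(row.af_esp6500),
                sift_call=_opt(row.sift_call), polyphen_call=_opt(row.polyphen_call),
                region_class=_opt(row.region_class), gene=_opt(row.gene),
            )
        )
    return out


def annotations_to_table(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "af_1kg_eas": v.af_1kg_eas, "af_esp": v.af_esp, "af_esp6500": v.af_esp6500,
                "sift_call": v.sift_call, "polyphen_call": v.polyphen_call,
                "region_class": v.region_class, "gene": v.gene,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# Candidate report

def write_candidate_report(candidates: pd.DataFrame, path: PathLike) -> None:
    """Write a candidate TSV with deterministic row order (chrom, pos, ref, alt).

    The frame is expected to carry at least chrom/pos/ref/alt columns;
    all other columns (carrier counts, filter trail, annotations) pass
    through in their given order.
    """
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in candidates.columns:
            raise ValueError(f"candidate report requires column {col!r}")
    ordered = candidates.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    ordered.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SV table

def read_sv_table(path: PathLike, pedigree: Optional[Pedigree] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    return make_sv_table(df, pedigree)


def write_sv_table(events: pd.DataFrame, path: PathLike) -> None:
    events.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression, gene sets, assay tables

def read_expression(path: PathLike) -> pd.DataFrame:
    """Genes x samples TSV; first column gene ids, header row sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.8g", index_label="gene")


def read_gmt(path: PathLike) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = fields
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: PathLike) -> None:
    lines = [name + "\t-\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_limiting_dilution(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"group", "dose", "n_tested", "n_positive"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: limiting-dilution CSV needs columns {sorted(needed)}")
    return df


def read_qpcr(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sample", "condition", "target_ct", "reference_ct"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: qPCR CSV needs columns {sorted(needed)}")
    if not all(math.isfinite(x) for x in df["target_ct"]) or not all(math.isfinite(x) for x in df["reference_ct"]):
        raise ValueError(f"{path}: non-finite Ct value")
    return df
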