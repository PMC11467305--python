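"""End-to-end orchestration: demo workspace generation and run-all.

A run is driven by a single YAML config naming the inputs and rules, with
per-stage toggles and one seed. The seed fans out deterministically to
per-stage child seeds, so toggling stages on or off never changes the
randomness any other stage sees; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .enrichment import RankedProfile, compute_log2fc, gene_set_overlap, gsea_permutation_p, intersect_de
from .assays import compare_frequencies, fit_single_hit, relative_expression
from .simulate import ExprSimConfig, build_paper_fixture, simulate_expression, simulate_limiting_dilution
from .snv import CascadeRules, carrier_frequency, run_snv_cascade
from .sv import RecurrenceRule, region_flag, screen_sv

logger = logging.getLogger(__name__)

STAGES = ("snv", "sv", "cohort", "expr", "lda", "qpcr")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (independent of stage toggles)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    workspace: Path
    outdir: Path
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    inputs: dict[str, Any] = field(default_factory=dict)
    rules: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        workspace = Path(raw.get("workspace", Path(path).parent))
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        return cls(
            workspace=workspace,
            outdir=Path(raw.get("outdir", workspace / "out")),
            seed=int(raw.get("seed", 0)),
            stages=stages,
            inputs=raw.get("inputs", {}),
            rules=raw.get("rules", {}),
        )


class StageError(RuntimeError):
    """A stage failed; partial artifacts from earlier stages are retained."""


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the toggled stages and write per-stage artifacts + a summary.

    Returns the summary dict (also written as summary.json and a plain-text
    summary.txt in the output directory).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ws = Path(config.workspace)
    summary: dict[str, Any] = {"seed": config.seed, "stages_run": [s for s in STAGES if config.stages.get(s)]}

    def inp(name: str, default: str) -> Path:
        return ws / config.inputs.get(name, default)

    for stage in STAGES:
        if not config.stages.get(stage):
            continue
        try:
            if stage == "snv":
                ped = pio.read_ped(inp("ped", "family.ped"))
                variants, genotypes = pio.read_vcf(inp("vcf", "variants.vcf"))
                annotated = pio.join_annotations(variants, pio.read_annotations(inp("annotations", "annotations.tsv")))
                report = run_snv_cascade(annotated, genotypes, ped, CascadeRules())
                pio.write_candidate_report(report, out / "snv_candidates.tsv")
                summary["snv"] = {
                    "n_input_variants": len(annotated),
                    "n_candidates": int(len(report)),
                    "candidate_genes": list(report["gene"]),
                }
                if len(report):
                    top = report.iloc[0]
                    key = f"{top.chrom}:{top.pos}:{top.ref}:{top.alt}"
                    summary["snv"]["top_variant"] = key
                    summary["snv"]["top_variant_family_carriers"] = len(genotypes.carriers(key))
                    summary["snv"]["family_size"] = len(ped)
            elif stage == "sv":
                ped = pio.read_ped(inp("ped", "family.ped"))
                events = pio.read_sv_table(inp("sv_table", "sv_events.tsv"), ped)
                retained, trail = screen_sv(events, ped, RecurrenceRule())
                flagged = region_flag(retained)
                pio.write_sv_table(flagged, out / "sv_retained.tsv")
                trail.to_csv(out / "sv_trail.tsv", sep="\t", index=False)
                summary["sv"] = {
                    "n_input_events": int(len(events)),
                    "n_retained": int(len(retained)),
                    "retained_genes": list(retained["gene"]),
                    "region_flags": list(flagged["region_flag"]),
                }
            elif stage == "cohort":
                cohort = config.inputs.get("cohort", {"n_carriers": 6, "n_total": 162})
                res = carrier_frequency(int(cohort["n_carriers"]), int(cohort["n_total"]))
                summary["cohort"] = {
                    "n_carriers": res.n_carriers,
                    "n_total": res.n_total,
                    "frequency_percent": res.percent,
                    "ci95": [round(x, 6) for x in res.ci95],
                    "method": res.method,
                }
            elif stage == "expr":
                expr = pio.read_expression(inp("expression", "expression.tsv"))
                cond_map = config.inputs.get("conditions", {c: c for c in expr.columns})
                pairs = config.inputs.get("de_pairs", [])
                gmt = pio.read_gmt(inp("gmt", "gene_sets.gmt"))
                de_results = []
                for pair in pairs:
                    de = compute_log2fc(expr, pair["a"], pair["b"], conditions=cond_map)
                    de_results.append(de)
                summary["expr"] = {"n_genes": int(len(expr))}
                if len(de_results) >= 2:
                    shared = intersect_de(de_results[0], de_results[1])
                    universe = list(expr.index)
                    overlap = gene_set_overlap(shared, gmt, universe)
                    overlap.to_csv(out / "set_overlap.tsv", sep="\t", index=False)
                    summary["expr"].update(
                        {
                            "n_de": [int(d["is_de"].sum()) for d in de_results],
                            "n_intersection": len(shared),
                        }
                    )
                    # Rank genes by the mean log2fc across the DE contrasts.
                    stat = sum(d.set_index("gene")["log2fc"] for d in de_results) / len(de_results)
                    profile = RankedProfile.from_series(stat)
                    gsea_rows = []
                    seed = stage_seed(config.seed, "expr")
                    for i, (name, members) in enumerate(sorted(gmt.items())):
                        res = gsea_permutation_p(
                            profile, members, n_perm=1000, seed=seed + i, set_name=name
                        )
                        gsea_rows.append(
                            {
                                "set_name": name, "es": res.es, "p_perm": res.p_perm,
                                "n_perm": res.n_perm, "significant": res.significant,
                            }
                        )
                    gsea_table = pd.DataFrame(gsea_rows)
                    gsea_table.to_csv(out / "gsea.tsv", sep="\t", index=False, float_format="%.6g")
                    summary["expr"]["significant_sets"] = list(gsea_table[gsea_table["significant"]]["set_name"])
            elif stage == "lda":
                table = pio.read_limiting_dilution(inp("lda", "limiting_dilution.csv"))
                groups = {g: t for g, t in table.groupby("group")}
                estimates = {}
                for g, t in sorted(groups.items()):
                    fit = fit_single_hit(t)
                    estimates[g] = {
                        "f_hat": fit.f_hat,
                        "one_in": fit.frequency_reciprocal,
                        "ci95": list(fit.ci95),
                    }
                summary["lda"] = {"estimates": estimates}
                compare = config.inputs.get("lda_compare")
                if compare and len(compare) == 2:
                    cmp_res = compare_frequencies(groups[compare[0]], groups[compare[1]])
                    summary["lda"]["comparison"] = {
                        "groups": list(compare),
                        "statistic": cmp_res.statistic,
                        "p_value": cmp_res.p_value,
                    }
            elif stage == "qpcr":
                records = pio.read_qpcr(inp("qpcr", "qpcr.csv"))
                control = config.inputs.get("qpcr_control", "vector")
                folds = relative_expression(records, control)
                folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False, float_format="%.6g")
                summary["qpcr"] = {
                    "control": control,
                    "fold_change": {r.condition: round(float(r.fold_change), 6) for r in folds.itertuples()},
                }
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            _write_summary(summary, out)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    lines = [f"pedscreen run summary (seed {summary.get('seed')})"]
    for stage in STAGES:
        if stage in summary:
            lines.append(f"[{stage}] " + json.dumps(summary[stage], sort_keys=True, default=str))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Demo workspace

STEMNESS_SET_SIZE = 30
DEMO_GENE_COUNT = 1000


def demo(workspace: Path, seed: int = 0) -> Path:
    """Write a ready-to-run demo workspace.

    Contains the deterministic family fixture (VCF, PED, annotation and SV
    tables), synthetic two-cell-line three-condition expression with a
    planted stemness-like enriched set, a two-group limiting-dilution
    table, a qPCR table, and a config.yaml wired for ``run_all``.
    Idempotent for a given seed.
    """
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    ped, genotypes, annotations, sv_table = build_paper_fixture()
    variants = [
        # reconstruct bare variants in matrix order for the VCF writer
        _variant_from_key(k) for k in genotypes.variant_keys
    ]
    pio.write_vcf(variants, genotypes, ws / "variants.vcf")
    pio.write_ped(ped, ws / "family.ped")
    pio.write_annotations(annotations, ws / "annotations.tsv")
    pio.write_sv_table(sv_table, ws / "sv_events.tsv")

    # Expression: two cell lines, three conditions each; shared planted DE
    # genes and a planted enriched set shifted in the mutant condition.
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(DEMO_GENE_COUNT)]
    de_genes = [f"G{i + 1}" for i in range(40)]
    set_genes = [f"G{i + 1}" for i in range(40, 40 + STEMNESS_SET_SIZE)]
    planted_de = {
        g: {"mutant": float(rng.choice([-2.5, 2.5]))} for g in de_genes
    }
    matrices = []
    for line_i, line in enumerate(("A549", "H322")):
        cfg = ExprSimConfig(
            n_genes=DEMO_GENE_COUNT,
            conditions=("vector", "wild", "mutant"),
            planted_de=planted_de,
            planted_enriched_set=("STEMNESS_UP", set_genes, 1.6, "mutant"),
            noise_sd=0.25,
            seed=seed * 10 + line_i,
        )
        m = simulate_expression(cfg)
        m.columns = [f"{line}_{c}" for c in m.columns]
        matrices.append(m)
    expr = pd.concat(matrices, axis=1)
    pio.write_expression(expr, ws / "expression.tsv")
    decoy_sets = {
        f"DECOY_SET_{j + 1}": list(rng.choice(genes[100:], size=STEMNESS_SET_SIZE, replace=False))
        for j in range(4)
    }
    pio.write_gmt({"STEMNESS_UP": set_genes, **decoy_sets}, ws / "gene_sets.gmt")

    # Limiting dilution: wild-type vs mutant stem-cell frequency.
    doses = [1e3, 1e4, 1e5]
    ld = pd.concat(
        [
            simulate_limiting_dilution(1e-4, doses, n_per_dose=10, seed=seed + 101, group="wild"),
            simulate_limiting_dilution(5e-4, doses, n_per_dose=10, seed=seed + 102, group="mutant"),
        ]
    )
    ld.to_csv(ws / "limiting_dilution.csv", index=False)

    # qPCR: a stemness marker across vector/wild/mutant, triplicate wells.
    qpcr_rows = []
    true_dct = {"vector": 8.0, "wild": 7.0, "mutant": 6.0}  # lower dCt = higher expression
    for cond, dct in true_dct.items():
        for s in range(3):
            for _rep in range(3):
                ref = 15.0 + rng.normal(0, 0.05)
                qpcr_rows.append(
                    {
                        "sample": f"{cond}_{s + 1}",
                        "condition": cond,
                        "target_ct": ref + dct + rng.normal(0, 0.1),
                        "reference_ct": ref,
                    }
                )
    pd.DataFrame(qpcr_rows).to_csv(ws / "qpcr.csv", index=False, float_format="%.4f")

    config = {
        "workspace": str(ws),
        "outdir": str(ws / "out"),
        "seed": seed,
        "stages": {s: True for s in STAGES},
        "inputs": {
            "vcf": "variants.vcf",
            "ped": "family.ped",
            "annotations": "annotations.tsv",
            "sv_table": "sv_events.tsv",
            "expression": "expression.tsv",
            "gmt": "gene_sets.gmt",
            "lda": "limiting_dilution.csv",
            "qpcr": "qpcr.csv",
            "cohort": {"n_carriers": 6, "n_total": 162},
            "conditions": {
                f"{line}_{c}": f"{line}_{c}" for line in ("A549", "H322") for c in ("vector", "wild", "mutant")
            },
            "de_pairs": [
                {"a": "A549_wild", "b": "A549_mutant"},
                {"a": "H322_wild", "b": "H322_mutant"},
            ],
            "lda_compare": ["wild", "mutant"],
            "qpcr_control": "vector",
        },
    }
    (ws / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return ws / "config.yaml"


def _variant_from_key(key: str):
    from .variants import AnnotatedVariant

    chrom, pos, ref, alt = key.rsplit(":", 3)
    return AnnotatedVariant(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
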