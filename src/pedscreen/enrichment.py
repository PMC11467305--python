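"""Differential expression thresholding, gene-set overlap, and permutation GSEA.

Differential expression is threshold-only (|log2 fold change| > 1 by
default, strict inequality), mirroring a design without biological
replicates per condition; functional annotation is a hypergeometric
over-representation test against user-supplied GMT collections; and the
enrichment score is the standard weighted Kolmogorov-Smirnov running sum
with a gene-label permutation null (single profiles per condition make a
phenotype-permutation null unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Differential expression

def compute_log2fc(
    expr: pd.DataFrame,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
    conditions: Optional[Mapping[str, str]] = None,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change of group_b over group_a on linear values.

    ``conditions`` maps sample (column) names to condition labels; when
    omitted, column names are taken as condition labels directly. Returns a
    frame with columns gene, mean_a, mean_b, log2fc, is_de; ``is_de`` uses
    a strict ``>`` on |log2fc| (a gene at exactly the threshold is not DE).
    """
    if pseudocount < 0:
        raise EnrichmentError("pseudocount must be >= 0")
    cond_of = dict(conditions) if conditions is not None else {c: c for c in expr.columns}
    cols_a = [c for c in expr.columns if cond_of.get(c) == group_a]
    cols_b = [c for c in expr.columns if cond_of.get(c) == group_b]
    if not cols_a or not cols_b:
        missing = group_a if not cols_a else group_b
        raise EnrichmentError(f"condition {missing!r} has no samples in the matrix")
    mean_a = expr[cols_a].mean(axis=1)
    mean_b = expr[cols_b].mean(axis=1)
    # log of the ratio (not difference of logs): exact at representable
    # fold changes, so the strict DE boundary behaves predictably.
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    return pd.DataFrame(
        {
            "gene": expr.index,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "is_de": (np.abs(log2fc) > threshold).to_numpy(),
        }
    ).reset_index(drop=True)


def intersect_de(
    results_a: pd.DataFrame, results_b: pd.DataFrame, direction_consistent: bool = True
) -> set[str]:
    """Genes DE in both result frames; optionally require matching sign."""
    a = results_a[results_a["is_de"]].set_index("gene")["log2fc"]
    b = results_b[results_b["is_de"]].set_index("gene")["log2fc"]
    shared = set(a.index) & set(b.index)
    if direction_consistent:
        shared = {g for g in shared if np.sign(a[g]) == np.sign(b[g])}
    return shared


def gene_set_overlap(
    de_genes: set[str], curated_sets: Mapping[str, Sequence[str]], universe: Sequence[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of each curated set in de_genes.

    The universe is the measured gene population; set members outside the
    universe are ignored. p is the upper hypergeometric tail
    P(X >= observed overlap).
    """
    uni = set(universe)
    if not de_genes <= uni:
        raise EnrichmentError("de_genes contains genes outside the universe")
    rows = []
    for name, members in curated_sets.items():
        in_uni = set(members) & uni
        if len(set(members)) > len(uni):
            raise EnrichmentError(f"gene set {name!r} larger than the universe")
        overlap = sorted(in_uni & de_genes)
        k, M, n, N = len(overlap), len(uni), len(in_uni), len(de_genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "set_name": name,
                "set_size_in_universe": n,
                "overlap_count": k,
                "overlap_genes": ",".join(overlap),
                "p_hypergeometric": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["set_name", "set_size_in_universe", "overlap_count", "overlap_genes", "p_hypergeometric"]
    )


# ---------------------------------------------------------------------------
# GSEA

@dataclass
class RankedProfile:
    """Genes ordered by a ranking statistic, descending; ties broken by
    gene label for determinism; duplicate genes rejected."""

    genes: list[str]
    stats: np.ndarray

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedProfile":
        if series.index.duplicated().any():
            raise EnrichmentError("duplicate genes in ranking")
        frame = series.rename("stat").rename_axis("gene").reset_index()
        frame = frame.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
        return cls(genes=list(frame["gene"]), stats=frame["stat"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    p_perm: float
    n_perm: int
    significant: bool


def _running_sum_extreme(weights: np.ndarray, hit_mask: np.ndarray) -> np.ndarray:
    """Signed maximum deviation of the GSEA running sum.

    ``weights``: |stat|^p in profile order, shape (N,).
    ``hit_mask``: boolean, shape (..., N); vectorized over leading axes.
    Hits step up by weight / (total in-set weight); misses step down by
    1 / (N - set size). Returns the extreme with the larger magnitude
    (positive on ties).
    """
    n = hit_mask.shape[-1]
    n_hit = hit_mask.sum(axis=-1)
    w_hit = np.where(hit_mask, weights, 0.0)
    w_total = w_hit.sum(axis=-1, keepdims=True)
    # Uniform fallback when all in-set weights are zero (e.g. flat statistic
    # with weight_p > 0): fall back to equal hit increments.
    uniform = np.broadcast_to(hit_mask / np.maximum(n_hit[..., None], 1), hit_mask.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(w_total > 0, w_hit / np.where(w_total > 0, w_total, 1.0), uniform)
    down = (~hit_mask) / (n - n_hit)[..., None]
    running = np.cumsum(up - down, axis=-1)
    top = running.max(axis=-1)
    bottom = running.min(axis=-1)
    return np.where(top >= -bottom, top, bottom)


def gsea_es(profile: RankedProfile, gene_set: Sequence[str], weight_p: float = 1.0) -> float:
    """Enrichment score: signed maximum deviation of the running sum.

    With ``weight_p = 0`` the statistic reduces to the classic unweighted
    Kolmogorov-Smirnov form and is invariant under monotone transformations
    of the ranking statistic.
    """
    if weight_p < 0:
        raise EnrichmentError("weight_p must be >= 0")
    members = set(gene_set)
    hit_mask = np.array([g in members for g in profile.genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise EnrichmentError("gene set does not intersect the ranked profile")
    if n_hits == len(profile):
        raise EnrichmentError("gene set covers the entire profile; ES undefined")
    weights = np.abs(profile.stats) ** weight_p
    return float(_running_sum_extreme(weights, hit_mask))


def gsea_permutation_p(
    profile: RankedProfile,
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    es_min: float = 0.4,
    p_max: float = 0.05,
    set_name: str = "gene_set",
) -> GseaResult:
    """Permutation p-value for the enrichment score.

    The null draws random same-size gene sets without replacement from the
    profile (gene-label permutation). The one-sided p uses the add-one
    correction p = (1 + #{null ES >= observed}) / (n_perm + 1) for a
    positive observed ES (mirrored for negative), so p is never 0.
    ``significant`` applies the default criteria es > es_min and p < p_max.
    """
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    members = set(gene_set) & set(profile.genes)
    size = len(members)
    if size == 0:
        raise EnrichmentError("gene set does not intersect the ranked profile")
    if size >= len(profile):
        raise EnrichmentError("gene set size must be smaller than the profile")
    observed = gsea_es(profile, members, weight_p=weight_p)
    rng = np.random.default_rng(seed)
    n = len(profile)
    weights = np.abs(profile.stats) ** weight_p
    # Random same-size sets: top-`size` positions of random keys per row.
    keys = rng.random((n_perm, n))
    positions = np.argpartition(keys, size - 1, axis=1)[:, :size]
    hit_mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit_mask, positions, True, axis=1)
    null_es = _running_sum_extreme(weights, hit_mask)
    if observed >= 0:
        exceed = int((null_es >= observed).sum())
    else:
        exceed = int((null_es <= observed).sum())
    p = (1 + exceed) / (n_perm + 1)
    return GseaResult(
        set_name=set_name,
        es=observed,
        p_perm=p,
        n_perm=n_perm,
        significant=bool(observed > es_min and p < p_max),
    )
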