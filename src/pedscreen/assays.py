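"""Quantitative models for the functional assays.

* Limiting-dilution stem-cell frequency under the single-hit Poisson model
  P(positive at dose d) = 1 - exp(-f d), fit by maximum binomial
  likelihood with a likelihood-ratio 95% interval (chi-square(1) cutoff
  3.84), plus a likelihood-ratio test for a frequency difference between
  two groups.
* Relative qPCR expression by the 2^-ddCt method, normalized to a
  reference gene and a control condition.
* Xenograft tumor volume, (length x width^2) / 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))  # 3.841...


class AssayInputError(ValueError):
    pass


def _validate_ld_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("dose", "n_tested", "n_positive"):
        if col not in table.columns:
            raise AssayInputError(f"limiting-dilution table needs column {col!r}")
    if len(table) == 0:
        raise AssayInputError("limiting-dilution table is empty")
    if (table["dose"] <= 0).any():
        raise AssayInputError("doses must be positive")
    if ((table["n_positive"] < 0) | (table["n_positive"] > table["n_tested"])).any():
        raise AssayInputError("need 0 <= n_positive <= n_tested")
    return table


def _loglik(f: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood of frequency f (combinatorial constant dropped)."""
    if f <= 0:
        return 0.0 if k.sum() == 0 else -np.inf
    p_neg = np.exp(-f * d)  # per-cell survival of the 'no active cell' event
    with np.errstate(divide="ignore"):
        log_p_pos = np.log1p(-p_neg)
    ll = np.where(k > 0, k * log_p_pos, 0.0) - (n - k) * f * d
    return float(ll.sum())


@dataclass(frozen=True)
class StemFrequencyEstimate:
    """Maximum-likelihood stem-cell frequency with a 95% LR interval.

    ``frequency_reciprocal`` is the conventional "1 in N cells" rendering.
    Boundary fits (no positives, or positives at every animal) produce
    one-sided intervals and are flagged.
    """

    f_hat: float
    ci95: tuple[float, float]
    loglik: float
    model: str = "single-hit Poisson"
    all_negative: bool = False
    all_positive: bool = False

    @property
    def frequency_reciprocal(self) -> float:
        return math.inf if self.f_hat == 0 else 1.0 / self.f_hat


def _score(f: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """d loglik / d f; strictly decreasing in f (the likelihood is concave)."""
    with np.errstate(over="ignore"):
        em1 = np.expm1(f * d)
    return float((k * d / em1 - (n - k) * d).sum())


def _interior_mle(d: np.ndarray, n: np.ndarray, k: np.ndarray) -> tuple[float, float]:
    """(f_hat, log-likelihood) for a non-boundary table, by solving the
    score equation with bracket expansion around a moment-style start."""
    p_obs = min(max(float(k.sum() / n.sum()), 1e-6), 1 - 1e-6)
    f0 = -math.log1p(-p_obs) / float(np.average(d, weights=n))
    lo, hi = f0, f0
    while _score(lo, d, n, k) < 0:
        lo /= 8.0
    while _score(hi, d, n, k) > 0:
        hi *= 8.0
    if lo == hi:
        f_hat = lo
    else:
        f_hat = optimize.brentq(_score, lo, hi, args=(d, n, k), xtol=1e-300, rtol=1e-15)
    return float(f_hat), _loglik(f_hat, d, n, k)


def fit_single_hit(table: pd.DataFrame, ci_method: str = "lr") -> StemFrequencyEstimate:
    """Fit the single-hit Poisson model to (dose, n_tested, n_positive) rows.

    The likelihood is maximized on log(f) (bounded scalar search with
    bracket expansion); the default interval inverts the likelihood-ratio
    statistic at the 95% chi-square(1) cutoff to tolerance 1e-8 on log(f).
    ``ci_method="wald"`` gives the normal-theory interval on log(f) instead.
    """
    table = _validate_ld_table(table)
    d = table["dose"].to_numpy(dtype=float)
    n = table["n_tested"].to_numpy(dtype=float)
    k = table["n_positive"].to_numpy(dtype=float)

    if k.sum() == 0:
        # Boundary: likelihood decreasing in f; one-sided upper limit where
        # the LR drop reaches the cutoff: sum(n*d)*f = chi2/2.
        upper = (_CHI2_95 / 2.0) / float((n * d).sum())
        return StemFrequencyEstimate(f_hat=0.0, ci95=(0.0, upper), loglik=0.0, all_negative=True)
    if (k == n).all():
        # Boundary: likelihood increasing in f (MLE at infinity); one-sided
        # lower limit from the LR equation.
        target = -_CHI2_95 / 2.0
        lo = 1e-12 / d.max()
        hi = 1.0 / d.min()
        while _loglik(hi, d, n, k) < target:
            hi *= 10
        while _loglik(lo, d, n, k) > target:
            lo /= 10
        lower = optimize.brentq(lambda lf: _loglik(math.exp(lf), d, n, k) - target,
                                math.log(lo), math.log(hi), xtol=1e-10)
        return StemFrequencyEstimate(
            f_hat=math.inf, ci95=(math.exp(lower), math.inf), loglik=0.0, all_positive=True
        )

    # Interior MLE on log(f): bracket around a moment-style start.
    f_hat, ll_hat = _interior_mle(d, n, k)
    lf_hat = math.log(f_hat)

    if ci_method == "wald":
        # Observed information on log f by central difference.
        h = 1e-5
        second = (
            _loglik(math.exp(lf_hat + h), d, n, k)
            - 2 * ll_hat
            + _loglik(math.exp(lf_hat - h), d, n, k)
        ) / h**2
        se = math.sqrt(-1.0 / second)
        z = stats.norm.ppf(0.975)
        ci = (math.exp(lf_hat - z * se), math.exp(lf_hat + z * se))
        return StemFrequencyEstimate(f_hat=f_hat, ci95=ci, loglik=ll_hat)

    target = ll_hat - _CHI2_95 / 2.0

    def drop(lf: float) -> float:
        return _loglik(math.exp(lf), d, n, k) - target

    left = lf_hat - 1.0
    while drop(left) > 0:
        left -= 1.0
    low = optimize.brentq(drop, left, lf_hat, xtol=1e-10)
    right = lf_hat + 1.0
    while drop(right) > 0 and right < lf_hat + 200:
        right += 1.0
    high = optimize.brentq(drop, lf_hat, right, xtol=1e-10)
    return StemFrequencyEstimate(f_hat=f_hat, ci95=(math.exp(low), math.exp(high)), loglik=ll_hat)


@dataclass(frozen=True)
class FrequencyComparison:
    statistic: float
    p_value: float
    f_a: float
    f_b: float
    f_pooled: float
    approximate: bool = False  # set when a group fit hit a boundary


def _max_loglik(d, n, k) -> tuple[float, float]:
    """(f_hat, max log-likelihood) tolerating boundary cases."""
    if k.sum() == 0:
        return 0.0, 0.0
    if (k == n).all():
        return math.inf, 0.0
    return _interior_mle(d, n, k)


def compare_frequencies(table_a: pd.DataFrame, table_b: pd.DataFrame) -> FrequencyComparison:
    """Likelihood-ratio test of equal stem-cell frequency in two groups.

    Compares the two-frequency model against a shared frequency;
    2 * delta-log-likelihood is referred to chi-square(1). When either
    group's MLE sits on a boundary (no positives or all positives) the
    chi-square reference is approximate and the result is flagged.
    """
    a = _validate_ld_table(table_a)
    b = _validate_ld_table(table_b)
    da, na, ka = (a[c].to_numpy(dtype=float) for c in ("dose", "n_tested", "n_positive"))
    db, nb, kb = (b[c].to_numpy(dtype=float) for c in ("dose", "n_tested", "n_positive"))
    f_a, ll_a = _max_loglik(da, na, ka)
    f_b, ll_b = _max_loglik(db, nb, kb)
    d_all = np.concatenate([da, db])
    n_all = np.concatenate([na, nb])
    k_all = np.concatenate([ka, kb])
    f_pool, ll_pool = _max_loglik(d_all, n_all, k_all)
    statistic = max(0.0, 2.0 * (ll_a + ll_b - ll_pool))
    p = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    boundary = f_a in (0.0, math.inf) or f_b in (0.0, math.inf)
    if boundary:
        logger.warning("compare_frequencies: boundary MLE in a group; chi-square p is approximate")
    return FrequencyComparison(
        statistic=statistic, p_value=p, f_a=f_a, f_b=f_b, f_pooled=f_pool, approximate=boundary
    )


# ---------------------------------------------------------------------------
# qPCR relative expression

def relative_expression(
    records: pd.DataFrame, control_condition: str, aggregate_replicates: bool = True
) -> pd.DataFrame:
    """Per-condition 2^-ddCt fold change relative to a control condition.

    Technical replicates sharing a sample label are averaged (mean Ct)
    before dCt = target_ct - reference_ct is formed per sample; ddCt is the
    condition mean dCt minus the control mean dCt; fold = 2^-ddCt. The
    control condition has fold 1 by construction.
    """
    needed = {"sample", "condition", "target_ct", "reference_ct"}
    if not needed <= set(records.columns):
        raise AssayInputError(f"qPCR records need columns {sorted(needed)}")
    if control_condition not in set(records["condition"]):
        raise AssayInputError(f"control condition {control_condition!r} not present")
    df = records.copy()
    if aggregate_replicates:
        df = df.groupby(["condition", "sample"], as_index=False)[["target_ct", "reference_ct"]].mean()
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    per_condition = df.groupby("condition")["delta_ct"].agg(["mean", "count"]).rename(columns={"mean": "delta_ct_mean", "count": "n_samples"})
    control_mean = per_condition.loc[control_condition, "delta_ct_mean"]
    per_condition["delta_delta_ct"] = per_condition["delta_ct_mean"] - control_mean
    per_condition["fold_change"] = 2.0 ** (-per_condition["delta_delta_ct"])
    return per_condition.reset_index()[["condition", "n_samples", "delta_ct_mean", "delta_delta_ct", "fold_change"]]


# ---------------------------------------------------------------------------
# Tumor volume

def tumor_volume(length: float, width: float) -> float:
    """Xenograft volume in mm^3 from caliper length and width (mm):
    (length x width^2) / 2. Warns (does not fail) when width > length."""
    if length < 0 or width < 0:
        raise AssayInputError(f"negative measurement: length={length}, width={width}")
    if width > length:
        logger.warning("tumor_volume: width %.3g exceeds length %.3g (swapped calipers?)", width, length)
    return length * width**2 / 2.0
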