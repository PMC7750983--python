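"""Standing-variation diagnostics and the pooling decision.

Whether locality or sex subsamples can be pooled into one species-level
sample is decided from pairwise Mann–Whitney U tests on the molar
ratios (Bonferroni-corrected within each ratio) together with a sign
test comparing subsample coefficients of variation (CV) against the
pooled CV.  A pooled-sample ratio CV above 15% flags possible
over-averaging (time, space, or sex), by analogy with the classical
CV < 10 rule of thumb for raw tooth sizes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RatioSample

logger = logging.getLogger(__name__)

OVER_AVERAGING_CV_PERCENT = 15.0

RATIOS = ("r21", "r31")


@dataclass
class GroupedRatios:
    """A RatioSample partitioned by a grouping key (locality or sex)."""

    sample: RatioSample
    by: str = "locality"

    def __post_init__(self) -> None:
        if self.by not in ("locality", "sex"):
            raise ValueError("grouping key must be 'locality' or 'sex'")

    def groups(self, ratio: str, min_n: int = 2) -> dict[str, np.ndarray]:
        out = {}
        for label, g in self.sample.frame.groupby(self.by):
            vals = g[ratio].to_numpy(float)
            if len(vals) < min_n:
                logger.warning(
                    "group %r has n=%d < %d; excluded", label, len(vals), min_n
                )
                continue
            out[str(label)] = vals
        return out


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD (n-1 denominator) / mean."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


def sign_test_pooled_cv(subsample_cvs, pooled_cv: float):
    """One-sided exact sign test of H1: subsample CVs < pooled CV.

    Ties are dropped.  Returns (k_below, n_informative, p_value) with
    p the binomial tail P(X >= k_below | n, 1/2).
    """
    cvs = np.asarray(subsample_cvs, float)
    if len(cvs) < 1:
        raise ValueError("need at least one subsample CV")
    below = cvs < pooled_cv
    ties = cvs == pooled_cv
    n = int(len(cvs) - ties.sum())
    if n == 0:
        raise ValueError("no informative comparisons: all subsample CVs tie")
    k = int(below.sum())
    p = stats.binomtest(k, n, p=0.5, alternative="greater").pvalue
    return k, n, float(p)


def _mannwhitney(x: np.ndarray, y: np.ndarray):
    """U of the first sample and two-sided p.

    Exact null enumeration when both groups are small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    exact = len(x) <= 20 and len(y) <= 20 and len(np.unique(np.r_[x, y])) == (
        len(x) + len(y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def pairwise_mannwhitney(
    grouped: GroupedRatios, ratio: str = "r31"
) -> pd.DataFrame:
    """Pairwise Mann–Whitney U with Bonferroni correction.

    Returns a long table (group_a, group_b, n_a, n_b, u, p_raw,
    p_corrected): U is the statistic of the first (row) group, and the
    correction multiplies each p by the number of pairs within this
    ratio, capped at 1.
    """
    groups = grouped.groups(ratio)
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups of size >= 2")
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        u, p = _mannwhitney(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "u": u,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    return out


def cv_report(grouped: GroupedRatios, flag_zero_ratios: bool = True) -> pd.DataFrame:
    """Per-group and pooled CVs for both ratios.

    Zero ratios (an absent M3 scored as size 0 upstream) are retained —
    they legitimately inflate the CV — but their presence is flagged.
    """
    rows = []
    for ratio in RATIOS:
        pooled_vals = grouped.sample.frame[ratio].to_numpy(float)
        rows.append(
            {
                "group": "(pooled)",
                "n": len(pooled_vals),
                "ratio": ratio,
                "cv_percent": coefficient_of_variation(pooled_vals),
            }
        )
        for label, vals in grouped.groups(ratio).items():
            rows.append(
                {
                    "group": label,
                    "n": len(vals),
                    "ratio": ratio,
                    "cv_percent": coefficient_of_variation(vals),
                }
            )
    return pd.DataFrame(rows)


def pooling_decision(grouped: GroupedRatios, alpha: float = 0.05) -> dict:
    """Pool subsamples unless any Bonferroni-corrected pairwise p falls
    below alpha for either ratio.

    The report carries the pairwise tables, the CV sign tests, and the
    CV > 15% over-averaging flag for the pooled sample.
    """
    any_significant = False
    tables = {}
    sign_tests = {}
    for ratio in RATIOS:
        table = pairwise_mannwhitney(grouped, ratio)
        tables[ratio] = table
        if (table["p_corrected"] < alpha).any():
            any_significant = True
        pooled_cv = coefficient_of_variation(
            grouped.sample.frame[ratio].to_numpy(float)
        )
        sub_cvs = [
            coefficient_of_variation(v) for v in grouped.groups(ratio).values()
        ]
        try:
            k, n, p = sign_test_pooled_cv(sub_cvs, pooled_cv)
        except ValueError:
            k, n, p = 0, 0, float("nan")
        sign_tests[ratio] = {
            "pooled_cv": pooled_cv,
            "k_below": k,
            "n": n,
            "p_value": p,
            "over_averaging_flag": pooled_cv > OVER_AVERAGING_CV_PERCENT,
        }
    decision = "split" if any_significant else "pool"
    return {
        "decision": decision,
        "alpha": alpha,
        "pairwise": tables,
        "cv_sign_tests": sign_tests,
        "over_averaging_flag": any(
            t["over_averaging_flag"] for t in sign_tests.values()
        ),
    }
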