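"""Sampling-design simulations for molar ratio studies.

Two resampling experiments assess what a sample must look like before
its molar-ratio statistics can be trusted:

*sample-size adequacy* — subsamples of size N are drawn without
replacement from the full sample; N is adequate for a statistic (mean
or SD of M2/M1 and M3/M1) once 95% of pseudoreplicates fall inside the
full sample's 95% bootstrap interval for that statistic.

*composite molar rows* — mimics a fossil collection of isolated teeth:
N teeth per tooth position are drawn independently with replacement,
the per-position means form one composite row whose ratio is the point
estimate, and an inner resampling (one tooth per position, repeated)
yields a "pseudosample" SD, the only spread estimate available to a
worker holding isolated teeth.  Because positions are drawn
independently, the within-specimen correlation of tooth sizes is
destroyed, so composite means converge but pseudosample SDs estimate
the wrong quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MolarRowSizes, RatioSample, compute_ratios

logger = logging.getLogger(__name__)

RATIOS = ("r21", "r31")
STATISTICS = ("mean", "sd")


@dataclass
class ReferenceIntervals:
    """Full-sample 95% intervals for mean and SD of each ratio.

    ``table`` maps (ratio, statistic) -> (point, lower, upper).
    """

    table: dict
    method: str
    n_boot: int
    seed: int | None

    def __post_init__(self) -> None:
        for key, (point, lo, hi) in self.table.items():
            if not (lo <= point <= hi):
                raise ValueError(f"reference interval violated for {key}")

    def interval(self, ratio: str, statistic: str) -> tuple[float, float]:
        _, lo, hi = self.table[(ratio, statistic)]
        return lo, hi

    def outside(self, ratio: str, statistic: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.interval(ratio, statistic)
        return (values < lo) | (values > hi)


@dataclass
class SampleSizeSimResult:
    """Per-N proportions of pseudoreplicate statistics outside the
    full-sample reference intervals."""

    frame: pd.DataFrame  # n, ratio, prop_mean_outside, prop_sd_outside, mean_sd
    n_pseudoreplicates: int
    seed: int | None

    def proportions(self, ratio: str, statistic: str) -> pd.Series:
        col = f"prop_{statistic}_outside"
        sub = self.frame[self.frame["ratio"] == ratio]
        return sub.set_index("n")[col]


@dataclass
class CompositeSimResult:
    """Per-N proportions of composite estimates outside the reference
    intervals (mean from the composite point estimate, SD from the
    inner pseudosample)."""

    frame: pd.DataFrame
    outer_reps: int
    inner_reps: int
    seed: int | None

    def proportions(self, ratio: str, statistic: str) -> pd.Series:
        col = f"prop_{statistic}_outside"
        sub = self.frame[self.frame["ratio"] == ratio]
        return sub.set_index("n")[col]


def reference_intervals(
    ratios: RatioSample,
    n_boot: int = 10_000,
    seed: int | None = 0,
    method: str = "population",
) -> ReferenceIntervals:
    """95% reference intervals for the mean and SD of each ratio.

    The default ``method='population'`` scales the mean's interval to
    the specimen-level spread (mean +/- 1.96 SD, the Gaussian 95%
    range of individual molar rows) and the SD's interval to the
    sampling uncertainty of the SD statistic (seeded bootstrap
    percentile).  This mixed construction is what makes tiny samples
    adequate for the mean while variance estimation stays demanding —
    a mean-of-the-statistic CI would force N close to the full sample
    for the mean as well.  ``method='bootstrap'`` uses bootstrap
    percentile CIs of both statistics; ``method='normal'`` the
    normal-theory CI of the mean (SD still bootstrapped).
    """
    n = len(ratios)
    if n < 10:
        raise ValueError("reference intervals need a full sample of n >= 10")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    table = {}
    z = 1.959963984540054
    for ratio in RATIOS:
        vals = ratios.ratio(ratio)
        boot = vals[idx]
        boot_means = boot.mean(axis=1)
        boot_sds = boot.std(axis=1, ddof=1)
        point_mean = float(vals.mean())
        point_sd = float(vals.std(ddof=1))
        if method == "population":
            mean_iv = (point_mean - z * point_sd, point_mean + z * point_sd)
        elif method == "normal":
            half = z * point_sd / np.sqrt(n)
            mean_iv = (point_mean - half, point_mean + half)
        elif method == "bootstrap":
            mean_iv = tuple(np.percentile(boot_means, [2.5, 97.5]))
        else:
            raise ValueError(f"unknown method {method!r}")
        sd_iv = tuple(np.percentile(boot_sds, [2.5, 97.5]))
        table[(ratio, "mean")] = (
            point_mean,
            min(mean_iv[0], point_mean),
            max(mean_iv[1], point_mean),
        )
        table[(ratio, "sd")] = (
            point_sd,
            min(sd_iv[0], point_sd),
            max(sd_iv[1], point_sd),
        )
    return ReferenceIntervals(table=table, method=method, n_boot=n_boot, seed=seed)


def sample_size_simulation(
    ratios: RatioSample,
    reference: ReferenceIntervals,
    n_grid=None,
    reps: int = 10_000,
    seed: int | None = 0,
) -> SampleSizeSimResult:
    """Subsample the full sample without replacement at each N.

    For every N in the grid, ``reps`` pseudoreplicates are drawn and
    the proportion of pseudoreplicate means and SDs falling outside the
    full-sample reference intervals is recorded, together with the mean
    pseudoreplicate SD (which reveals the small-N downward bias of the
    SD estimator).
    """
    n = len(ratios)
    if n_grid is None:
        n_grid = range(2, n)
    n_grid = list(n_grid)
    if any(N < 2 for N in n_grid):
        raise ValueError("subsample sizes must be >= 2")
    if any(N > n for N in n_grid):
        raise ValueError("subsample size exceeds the full sample")
    rng = np.random.default_rng(seed)
    values = {ratio: ratios.ratio(ratio) for ratio in RATIOS}
    records = []
    for N in n_grid:
        # reps subsets of size N without replacement
        order = np.argsort(rng.random((reps, n)), axis=1)[:, :N]
        for ratio in RATIOS:
            sub = values[ratio][order]
            means = sub.mean(axis=1)
            sds = sub.std(axis=1, ddof=1)
            records.append(
                {
                    "n": N,
                    "ratio": ratio,
                    "prop_mean_outside": float(
                        reference.outside(ratio, "mean", means).mean()
                    ),
                    "prop_sd_outside": float(
                        reference.outside(ratio, "sd", sds).mean()
                    ),
                    "mean_sd": float(sds.mean()),
                }
            )
    return SampleSizeSimResult(
        frame=pd.DataFrame(records), n_pseudoreplicates=reps, seed=seed
    )


def composite_simulation(
    rows: MolarRowSizes,
    reference: ReferenceIntervals,
    n_grid=range(1, 51),
    outer_reps: int = 1000,
    inner_reps: int = 1000,
    seed: int | None = 0,
    paired: bool = False,
) -> CompositeSimResult:
    """Simulate ratio estimation from composite molar rows.

    Per N and outer replicate: draw N teeth per tooth position with
    replacement (positions independent unless ``paired``), form the
    composite point estimate as the ratio of per-position means, then
    resample one tooth per position ``inner_reps`` times to build the
    pseudosample whose SD stands in for the sample SD.  Proportions of
    outer replicates outside the reference mean/SD intervals are
    recorded per N.  ``paired=True`` keeps specimen identity across
    positions (a validation mode, not the fossil scenario).
    """
    if len(rows) == 0:
        raise ValueError("no molar rows to resample")
    sizes = rows.sizes
    n = len(rows)
    rng = np.random.default_rng(seed)
    records = []
    for N in n_grid:
        if paired:
            idx = rng.integers(0, n, size=(outer_reps, N))
            drawn = sizes[idx]  # (outer, N, 3)
        else:
            idx = rng.integers(0, n, size=(outer_reps, N, 3))
            drawn = np.take_along_axis(
                np.broadcast_to(sizes, (outer_reps, n, 3)), idx, axis=1
            )
        pos_means = drawn.mean(axis=1)  # (outer, 3)
        est = {
            "r21": pos_means[:, 1] / pos_means[:, 0],
            "r31": pos_means[:, 2] / pos_means[:, 0],
        }
        if paired:
            # one specimen per inner replicate, identity kept across positions
            shared = rng.integers(0, N, size=(outer_reps, inner_reps, 1))
            inner_idx = np.broadcast_to(shared, (outer_reps, inner_reps, 3))
        else:
            inner_idx = rng.integers(0, N, size=(outer_reps, inner_reps, 3))
        picked = np.take_along_axis(drawn, inner_idx, axis=1)  # (outer, inner, 3)
        pseudo = {
            "r21": picked[:, :, 1] / picked[:, :, 0],
            "r31": picked[:, :, 2] / picked[:, :, 0],
        }
        for ratio in RATIOS:
            sd = pseudo[ratio].std(axis=1, ddof=1)
            records.append(
                {
                    "n": int(N),
                    "ratio": ratio,
                    "prop_mean_outside": float(
                        reference.outside(ratio, "mean", est[ratio]).mean()
                    ),
                    "prop_sd_outside": float(
                        reference.outside(ratio, "sd", sd).mean()
                    ),
                    "mean_estimate": float(est[ratio].mean()),
                    "mean_estimate_sd": float(est[ratio].std(ddof=1)),
                }
            )
    return CompositeSimResult(
        frame=pd.DataFrame(records),
        outer_reps=outer_reps,
        inner_reps=inner_reps,
        seed=seed,
    )


def adequacy_threshold(
    result: SampleSizeSimResult | CompositeSimResult,
    ratio: str,
    statistic: str,
    max_outside: float = 0.05,
) -> int | None:
    """Smallest grid N with <= ``max_outside`` of pseudoreplicates
    outside the reference interval, or None if no N qualifies.

    The first crossing is returned as stated even if the proportion
    later rises again; a non-monotone sequence is logged.
    """
    props = result.proportions(ratio, statistic).sort_index()
    ok = props[props <= max_outside]
    if len(ok) == 0:
        return None
    first = int(ok.index[0])
    after = props.loc[first:]
    if (after > max_outside).any():
        logger.info(
            "adequacy proportions non-monotone for %s/%s after N=%d",
            ratio,
            statistic,
            first,
        )
    return first


def composite_table(
    area_result: CompositeSimResult, length_result: CompositeSimResult
) -> pd.DataFrame:
    """Wide per-N table of outside-proportions for both metrics,
    columns n, area_r21_mean, area_r21_sd, ..., length_r31_sd."""
    pieces = {"n": sorted(area_result.frame["n"].unique())}
    out = pd.DataFrame(pieces)
    for metric, res in (("area", area_result), ("length", length_result)):
        for ratio in RATIOS:
            for stat in STATISTICS:
                col = f"{metric}_{ratio}_{stat}"
                series = res.proportions(ratio, stat).sort_index()
                out[col] = series.reindex(out["n"]).to_numpy()
    return out
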