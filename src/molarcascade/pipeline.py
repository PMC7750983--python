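"""End-to-end orchestration: data -> ratios -> pooling -> ICM test -> sims.

A single :class:`PipelineConfig` drives every stage with deterministic
per-stage seeds spawned from one global seed, and the report bundle is
written as plain CSV/JSON files so a run can be reproduced exactly from
the persisted config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as dm
from . import icm, sims, synthetic, varstats

logger = logging.getLogger(__name__)

# fixed stage order also defines the seed-spawning order
STAGES = ("simulate", "repeatability", "icm", "reference", "samplesize", "composite")


def spawn_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministically derive one sub-seed per pipeline stage.

    Uses numpy's SeedSequence spawning so stages can be re-run in
    isolation with the same stream; values are reduced below 2**31.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML."""

    input_csv: str | None = None  # measurement CSV; None -> synthetic
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    metrics: tuple = ("length", "area")
    grouping: str = "locality"
    alpha: float = 0.05
    pool_sexes: bool = True
    n_draws: int = 1000
    burn_in: int = 2000
    thin: int = 10
    n_boot: int = 10_000
    samplesize_reps: int = 10_000
    composite_outer: int = 1000
    composite_inner: int = 1000
    composite_grid_max: int = 50
    seed: int = 0
    out_dir: str = "results"

    def to_file(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["generator"] = {
            k: (list(map(list, v)) if k == "groups" and v is not None else v)
            for k, v in payload["generator"].items()
        }
        payload["metrics"] = list(self.metrics)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if gen.get("groups") is not None:
                gen["groups"] = tuple(tuple(g) for g in gen["groups"])
            raw["generator"] = synthetic.GeneratorConfig(**gen)
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


def _load_or_generate(config: PipelineConfig, stage_seeds: dict):
    """Return (measurement table, repeatability seed note)."""
    if config.input_csv is not None:
        return dm.read_measurement_table(config.input_csv)
    gen = dataclasses.replace(config.generator, seed=stage_seeds["simulate"])
    rows = synthetic.simulate_rows(gen)
    return synthetic.add_replicate_noise(
        rows,
        target_repeatability=gen.target_repeatability,
        replicates_per_measurement=gen.replicates_per_measurement,
        n_observers=gen.n_observers,
        seed=stage_seeds["simulate"] + 1,
        width_ratio=gen.width_ratio,
        width_noise_sd=gen.width_noise_sd,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Stage order: measurement table (read or simulated) -> repeatability
    -> row sizes and ratios per metric -> pooling decision -> posterior
    six-prediction test -> reference intervals -> sample-size and
    composite simulations.  Any stage error aborts with the stage name;
    outputs of earlier stages remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = spawn_stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": stage_seeds, "stages": {}}
    config.to_file(out_dir / "pipeline_config.yaml")

    stage = "data"
    try:
        table = _load_or_generate(config, stage_seeds)
        collapsed = dm.average_replicates(table)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "repeatability"
    repeatability = {}
    try:
        for metric in config.metrics:
            repeatability[metric] = dm.compute_repeatability(table, metric)
    except dm.MeasurementValidationError as exc:
        logger.warning("repeatability unavailable (%s); assuming 1.0", exc)
        repeatability = {metric: 1.0 for metric in config.metrics}
    report["stages"]["repeatability"] = repeatability

    per_metric: dict = {}
    for metric in config.metrics:
        stage = f"ratios[{metric}]"
        try:
            rows = dm.build_row_sizes(collapsed, metric=metric)
            if config.pool_sexes:
                ratios = dm.compute_ratios(rows)
            else:
                ratios = dm.compute_ratios(rows)  # grouping handled downstream
            dm.ratios_to_csv(ratios, rows, out_dir / f"ratios_{metric}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        stage = f"pooling[{metric}]"
        try:
            grouped = varstats.GroupedRatios(ratios, by=config.grouping)
            pooling = varstats.pooling_decision(grouped, alpha=config.alpha)
            cvs = varstats.cv_report(grouped)
            cvs.to_csv(out_dir / f"cv_{metric}.csv", index=False)
            for ratio, tab in pooling["pairwise"].items():
                tab.to_csv(
                    out_dir / f"pairwise_{metric}_{ratio}.csv", index=False
                )
        except ValueError as exc:
            logger.warning("pooling stage skipped for %s: %s", metric, exc)
            pooling = {"decision": "pool", "note": str(exc)}
        report["stages"][f"pooling_{metric}"] = {
            "decision": pooling["decision"],
            "over_averaging_flag": pooling.get("over_averaging_flag", False),
        }

        stage = f"icm[{metric}]"
        try:
            x, y = ratios.ratio("r21"), ratios.ratio("r31")
            fit = icm.rma_regression(
                x, y, n_resamples=min(config.n_boot, 9999), seed=stage_seeds["icm"]
            )
            r2, p1 = icm.prediction_one_fit(x, y, seed=stage_seeds["icm"] + 1)
            draws = icm.fit_posterior(
                rows,
                n_draws=config.n_draws,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=stage_seeds["icm"] + 2,
            )
            draws = icm.adjust_for_measurement_error(
                draws, repeatability[metric]
            )
            prediction = icm.evaluate_predictions(draws)
            _write_draws_csv(draws, out_dir / f"posterior_{metric}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][f"icm_{metric}"] = {
            "rma": {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "slope_ci": list(fit.slope_ci),
                "intercept_ci": list(fit.intercept_ci),
                "p_value": fit.p_value,
            },
            "prediction_one": {"r_squared": r2, "p_value": p1},
            "predictions": prediction.table,
            "n_consistent": prediction.n_consistent,
        }

        stage = f"sims[{metric}]"
        n = len(ratios)
        if n < 10:
            logger.warning(
                "sims stage refused for %s: n=%d < 10 complete rows", metric, n
            )
            report["stages"][f"sims_{metric}"] = {"skipped": f"n={n} too small"}
            per_metric[metric] = (rows, ratios, None)
            continue
        try:
            reference = sims.reference_intervals(
                ratios, n_boot=config.n_boot, seed=stage_seeds["reference"]
            )
            ss = sims.sample_size_simulation(
                ratios,
                reference,
                reps=config.samplesize_reps,
                seed=stage_seeds["samplesize"],
            )
            comp = sims.composite_simulation(
                rows,
                reference,
                n_grid=range(1, config.composite_grid_max + 1),
                outer_reps=config.composite_outer,
                inner_reps=config.composite_inner,
                seed=stage_seeds["composite"],
            )
            ss.frame.to_csv(out_dir / f"samplesize_{metric}.csv", index=False)
            comp.frame.to_csv(out_dir / f"composite_{metric}.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        adequacy = {
            f"{ratio}_{stat}": sims.adequacy_threshold(ss, ratio, stat)
            for ratio in ("r21", "r31")
            for stat in ("mean", "sd")
        }
        report["stages"][f"sims_{metric}"] = {
            "adequacy": adequacy,
            "composite_mean_outside_at_1": float(
                comp.proportions("r21", "mean").loc[1]
            ),
        }
        per_metric[metric] = (rows, ratios, comp)

    if all(per_metric.get(m, (None, None, None))[2] is not None for m in config.metrics) and set(
        config.metrics
    ) == {"length", "area"}:
        table4 = sims.composite_table(
            per_metric["area"][2], per_metric["length"][2]
        )
        table4.to_csv(out_dir / "composite_proportions.csv", index=False)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    _write_summary(report, out_dir / "summary.txt")
    return report


def _write_draws_csv(draws: icm.PosteriorDraws, path) -> None:
    cols = {
        "mu1": draws.mu[:, 0],
        "mu2": draws.mu[:, 1],
        "mu3": draws.mu[:, 2],
        "var1": draws.sigma[:, 0, 0],
        "var2": draws.sigma[:, 1, 1],
        "var3": draws.sigma[:, 2, 2],
        "cov12": draws.sigma[:, 0, 1],
        "cov13": draws.sigma[:, 0, 2],
        "cov23": draws.sigma[:, 1, 2],
    }
    pd.DataFrame(cols).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_summary(report: dict, path) -> None:
    lines = [f"pipeline seed: {report['seed']}"]
    for name, stage in report["stages"].items():
        if name.startswith("icm_"):
            metric = name.split("_", 1)[1]
            rma = stage["rma"]
            lines.append(
                f"[{metric}] RMA slope {rma['slope']:.3f} "
                f"(95% CI {rma['slope_ci'][0]:.3f}..{rma['slope_ci'][1]:.3f}), "
                f"intercept {rma['intercept']:.3f}; "
                f"{stage['n_consistent']}/6 predictions consistent"
            )
            for pname, row in stage["predictions"].items():
                if not row["stable"]:
                    lines.append(f"    {pname}: unstable (ratio undefined)")
                else:
                    verdict = "consistent" if row["consistent"] else "inconsistent"
                    lines.append(
                        f"    {pname}: mode {row['mode']:.3f} "
                        f"HPD [{row['hpd_low']:.3f}, {row['hpd_high']:.3f}] "
                        f"-> {verdict}"
                    )
        elif name.startswith("pooling_"):
            lines.append(
                f"[{name.split('_', 1)[1]}] pooling decision: {stage['decision']}"
                + (" (over-averaging CV flag)" if stage.get("over_averaging_flag") else "")
            )
        elif name.startswith("sims_") and "adequacy" in stage:
            lines.append(
                f"[{name.split('_', 1)[1]}] adequacy N: "
                + ", ".join(f"{k}={v}" for k, v in stage["adequacy"].items())
            )
        elif name == "repeatability":
            lines.append(
                "repeatability: "
                + ", ".join(f"{k}={v:.3f}" for k, v in stage.items())
            )
    Path(path).write_text("\n".join(lines) + "\n")
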