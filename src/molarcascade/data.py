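"""Measurement tables, repeatability, and molar-row size/ratio phenotypes.

The raw unit of data is a long-format table of replicated crown
measurements: one row per (specimen, tooth, dimension, replicate,
observer) with a value in mm.  Replicates are averaged into a single
measurement per variable; per-specimen molar-row sizes (M1, M2, M3) are
then assembled for a chosen metric — mesiodistal crown *length* or the
rectangular crown *area* estimate length x width — and converted into
the ratio phenotypes (M2/M1, M3/M1, and each tooth relative to the
total row size) that the inhibitory-cascade analyses consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TEETH = ("M1", "M2", "M3")
DIMENSIONS = ("length", "width")
MEASUREMENT_COLUMNS = [
    "specimen_id",
    "locality",
    "sex",
    "tooth",
    "dimension",
    "replicate",
    "observer",
    "value_mm",
]


class MeasurementFormatError(ValueError):
    """The CSV is not a measurement table (missing/renamed columns)."""


class MeasurementValidationError(ValueError):
    """A record violates a table invariant (e.g. non-positive value)."""


@dataclass
class MolarMeasurementTable:
    """Validated long-format table of replicated crown measurements."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MolarRowSizes:
    """Per-specimen (M1, M2, M3) crown sizes for one metric.

    ``metric`` is ``"length"`` (mm) or ``"area"`` (mm^2, rectangular
    length x width estimate).  Only complete rows (all three lower
    molars) belong here.
    """

    frame: pd.DataFrame  # specimen_id, locality, sex, m1, m2, m3
    metric: str = "length"

    def __post_init__(self) -> None:
        if self.metric not in ("length", "area"):
            raise ValueError(f"metric must be 'length' or 'area', got {self.metric!r}")
        required = {"specimen_id", "m1", "m2", "m3"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"MolarRowSizes missing columns: {sorted(missing)}")
        for col in ("locality", "sex"):
            if col not in self.frame.columns:
                self.frame[col] = ""
        sizes = self.frame[["m1", "m2", "m3"]].to_numpy(float)
        if not np.all(np.isfinite(sizes)) or np.any(sizes <= 0):
            raise MeasurementValidationError(
                "molar-row sizes must be strictly positive and finite"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sizes(self) -> np.ndarray:
        """(n, 3) array of (M1, M2, M3) sizes."""
        return self.frame[["m1", "m2", "m3"]].to_numpy(float)


@dataclass
class RatioSample:
    """Per-specimen molar size ratios with group labels.

    Columns: r21 = M2/M1, r31 = M3/M1, and rel1..rel3 = each tooth over
    the total row size (summing to 1 per specimen).
    """

    frame: pd.DataFrame
    metric: str = "length"

    def __post_init__(self) -> None:
        rel = self.frame[["rel1", "rel2", "rel3"]].to_numpy(float)
        if not np.allclose(rel.sum(axis=1), 1.0, rtol=1e-9, atol=1e-12):
            raise ValueError("relative sizes must sum to 1 per specimen")
        if np.any(self.frame[["r21", "r31"]].to_numpy(float) <= 0):
            raise ValueError("size ratios must be strictly positive")

    def __len__(self) -> int:
        return len(self.frame)

    def ratio(self, name: str) -> np.ndarray:
        if name not in ("r21", "r31"):
            raise KeyError(f"unknown ratio {name!r}; expected 'r21' or 'r31'")
        return self.frame[name].to_numpy(float)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementFormatError(f"missing required column(s): {missing}")
    df = df.loc[:, MEASUREMENT_COLUMNS].copy()
    df["value_mm"] = pd.to_numeric(df["value_mm"], errors="raise")
    bad = df[~np.isfinite(df["value_mm"]) | (df["value_mm"] <= 0)]
    if len(bad):
        rec = bad.iloc[0]
        raise MeasurementValidationError(
            "non-positive or non-finite value_mm for specimen "
            f"{rec['specimen_id']!r} tooth {rec['tooth']} "
            f"{rec['dimension']} replicate {rec['replicate']}: {rec['value_mm']}"
        )
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise MeasurementValidationError("replicate indices must be >= 1")
    dup = df.duplicated(
        subset=["specimen_id", "tooth", "dimension", "observer", "replicate"]
    )
    if dup.any():
        rec = df[dup].iloc[0]
        raise MeasurementValidationError(
            f"duplicate replicate index {rec['replicate']} for specimen "
            f"{rec['specimen_id']!r} tooth {rec['tooth']} {rec['dimension']} "
            f"observer {rec['observer']!r}"
        )
    return df.reset_index(drop=True)


def read_measurement_table(path, strict: bool = True) -> MolarMeasurementTable:
    """Read and validate a measurement CSV.

    In strict mode unknown tooth or dimension labels are rejected;
    otherwise the offending records are dropped with a logged warning.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "observer": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementFormatError(
            f"{path}: missing required column(s): {missing}"
        )
    bad_tooth = ~df["tooth"].isin(TEETH)
    bad_dim = ~df["dimension"].isin(DIMENSIONS)
    bad = bad_tooth | bad_dim
    if bad.any():
        labels = sorted(
            set(df.loc[bad_tooth, "tooth"]) | set(df.loc[bad_dim, "dimension"])
        )
        if strict:
            raise MeasurementValidationError(
                f"unknown tooth/dimension label(s): {labels}"
            )
        logger.warning(
            "dropping %d record(s) with unknown tooth/dimension label(s) %s",
            int(bad.sum()),
            labels,
        )
        df = df[~bad]
    df = df.copy()
    df["locality"] = df["locality"].fillna("")
    df["sex"] = df["sex"].fillna("unknown")
    return MolarMeasurementTable(df)


def average_replicates(table: MolarMeasurementTable) -> pd.DataFrame:
    """Collapse replicates (all observers pooled) to one value per
    specimen x tooth x dimension by the arithmetic mean."""
    df = table.records
    grouped = (
        df.groupby(["specimen_id", "locality", "sex", "tooth", "dimension"])[
            "value_mm"
        ]
        .mean()
        .reset_index()
    )
    return grouped


def _variable_frame(table: MolarMeasurementTable, dimension: str) -> pd.DataFrame:
    """Long frame of (specimen_id, tooth, observer, replicate, value)
    for a dimension ('length'/'width') or the derived 'area' metric."""
    df = table.records
    if dimension in DIMENSIONS:
        sub = df[df["dimension"] == dimension].rename(
            columns={"value_mm": "value"}
        )
        return sub[["specimen_id", "tooth", "observer", "replicate", "value"]]
    if dimension == "area":
        # Pair length and width replicates taken together (same
        # specimen/tooth/observer/replicate) into per-replicate areas.
        wide = df.pivot_table(
            index=["specimen_id", "tooth", "observer", "replicate"],
            columns="dimension",
            values="value_mm",
        ).dropna(subset=["length", "width"])
        wide = wide.reset_index()
        wide["value"] = wide["length"] * wide["width"]
        return wide[["specimen_id", "tooth", "observer", "replicate", "value"]]
    raise ValueError(
        f"dimension must be 'length', 'width' or 'area', got {dimension!r}"
    )


def _tooth_repeatabilities(sub: pd.DataFrame) -> list[float]:
    """Per-tooth one-way ANOVA repeatability (specimen as factor)."""
    out = []
    for tooth, tgroup in sub.groupby("tooth"):
        groups = [
            g["value"].to_numpy(float)
            for _, g in tgroup.groupby("specimen_id")
        ]
        usable = [g for g in groups if len(g) >= 2]
        n_dropped = len(groups) - len(usable)
        if n_dropped:
            logger.warning(
                "excluding %d singleton specimen(s) from %s repeatability",
                n_dropped,
                tooth,
            )
        if len(usable) < 2:
            raise MeasurementValidationError(
                f"repeatability for {tooth} needs >=2 specimens with >=2 "
                "replicates each"
            )
        out.append(_anova_repeatability(usable))
    return out


def compute_repeatability(
    table: MolarMeasurementTable, dimension: str = "length"
) -> float:
    """ANOVA percent repeatability of a replicated measurement.

    For each measured variable (tooth position) a one-way ANOVA with
    specimen as the grouping factor pools all replicate x observer
    measurements as within-group error; the among-specimen variance
    component follows the Lessells–Boag estimator
    s2_among = (MS_among - MS_within) / n0 with n0 the
    replicate-weighted group size, and repeatability is
    s2_among / (s2_among + MS_within), clipped to (0, 1].  The returned
    value is the average over the three tooth positions.

    Observers are deliberately pooled into measurement error, so the
    estimate reflects total measurement error within and between
    observers; this is the quantity later used to deflate posterior
    variances.  Specimens with a single measurement are excluded with a
    warning.
    """
    sub = _variable_frame(table, dimension)
    return float(np.mean(_tooth_repeatabilities(sub)))


def _anova_repeatability(groups: list[np.ndarray]) -> float:
    a = len(groups)
    ns = np.array([len(g) for g in groups], float)
    n_total = ns.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_among = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - np.sum(ns**2) / n_total) / (a - 1)
    s2_among = (ms_among - ms_within) / n0
    if ms_within == 0.0:
        return 1.0
    r = s2_among / (s2_among + ms_within)
    return float(np.clip(r, np.finfo(float).tiny, 1.0))


def compute_repeatability_two_way(
    table: MolarMeasurementTable, dimension: str = "length"
) -> float:
    """Two-way variant: observer means are removed per variable before
    the one-way ANOVA, so between-observer offsets do not enter the
    error term.  Exposed for sensitivity analysis; not the default."""
    sub = _variable_frame(table, dimension).copy()
    # centre within (variable, observer), then restore the variable mean
    var_mean = sub.groupby(["specimen_id", "tooth"])["value"].transform("mean")
    obs_mean = sub.groupby(["specimen_id", "tooth", "observer"])[
        "value"
    ].transform("mean")
    sub["value"] = sub["value"] - obs_mean + var_mean
    return float(np.mean(_tooth_repeatabilities(sub)))


def build_row_sizes(collapsed: pd.DataFrame, metric: str = "length") -> MolarRowSizes:
    """Assemble per-specimen (M1, M2, M3) sizes from a collapsed table.

    ``metric='length'`` uses the mesiodistal length of each crown;
    ``metric='area'`` the rectangular estimate length x width.
    Specimens lacking any of the three teeth (or a width, for area) are
    excluded and counted in a log line.
    """
    if metric not in ("length", "area"):
        raise ValueError(f"metric must be 'length' or 'area', got {metric!r}")
    wide = collapsed.pivot_table(
        index=["specimen_id", "locality", "sex"],
        columns=["tooth", "dimension"],
        values="value_mm",
    )
    rows = []
    n_excluded = 0
    for idx, rec in wide.iterrows():
        specimen_id, locality, sex = idx
        vals = {}
        ok = True
        for i, tooth in enumerate(TEETH, start=1):
            length = rec.get((tooth, "length"), np.nan)
            if metric == "length":
                size = length
            else:
                width = rec.get((tooth, "width"), np.nan)
                size = length * width
            if not np.isfinite(size):
                ok = False
                break
            vals[f"m{i}"] = float(size)
        if ok:
            rows.append(
                {"specimen_id": specimen_id, "locality": locality, "sex": sex, **vals}
            )
        else:
            n_excluded += 1
    if n_excluded:
        logger.info(
            "excluded %d specimen(s) without a complete molar row for metric %s",
            n_excluded,
            metric,
        )
    if not rows:
        raise MeasurementValidationError("no complete molar rows")
    return MolarRowSizes(pd.DataFrame(rows), metric=metric)


def compute_ratios(rows: MolarRowSizes) -> RatioSample:
    """Ratio phenotypes from complete molar rows.

    r21 = M2/M1 and r31 = M3/M1 summarize the size gradient; rel1..rel3
    standardize each tooth to the total row size and sum to 1.
    """
    df = rows.frame
    m1 = df["m1"].to_numpy(float)
    m2 = df["m2"].to_numpy(float)
    m3 = df["m3"].to_numpy(float)
    if np.any(m1 == 0):
        raise ZeroDivisionError("M1 size of zero: ratios undefined")
    total = m1 + m2 + m3
    out = df[["specimen_id", "locality", "sex"]].copy()
    out["r21"] = m2 / m1
    out["r31"] = m3 / m1
    out["rel1"] = m1 / total
    out["rel2"] = m2 / total
    out["rel3"] = m3 / total
    return RatioSample(out, metric=rows.metric)


def ratios_to_csv(sample: RatioSample, rows: MolarRowSizes, path) -> None:
    """Write the standard phenotype CSV
    (specimen_id,locality,sex,metric,m1,m2,m3,r21,r31,rel1,rel2,rel3)."""
    merged = rows.frame.merge(
        sample.frame, on=["specimen_id", "locality", "sex"], validate="one_to_one"
    )
    merged.insert(3, "metric", rows.metric)
    cols = [
        "specimen_id",
        "locality",
        "sex",
        "metric",
        "m1",
        "m2",
        "m3",
        "r21",
        "r31",
        "rel1",
        "rel2",
        "rel3",
    ]
    merged[cols].to_csv(path, index=False)
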