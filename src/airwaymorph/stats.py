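"""Between-scan variation and repeatability statistics.

Implements the study-style outcome variables for paired measurements:
relative difference ``(|a-b| / mean) * 100%``, intraclass correlation
(default ICC(2,1): two-way random effects, absolute agreement, single
measurement; ICC(1,1) and ICC(3,1) selectable), Bland-Altman limits of
agreement, and the smallest detectable difference ``1.96 * SD`` of the
paired differences (the 1.96 factor is fixed, not a t-quantile). The
difference SD uses the sample (n-1) denominator.

Reliability class labels follow the Fleiss benchmarks with boundaries
(0.40, 0.75) assigned to the lower class: icc <= 0.40 "poor",
0.40 < icc <= 0.75 "fair to good", icc > 0.75 "excellent".

Degenerate inputs (zero variance, zero mean) raise
:class:`~airwaymorph.errors.UndefinedStatisticError` rather than returning
a silent 0 or 1; the cohort summary records such cells as NaN with class
``"undefined"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ALL_REGIONS, PARAMETERS, AirwayParameters
from .errors import (DataError, SampleSizeError, UndefinedStatisticError,
                     ValidationError)

__all__ = [
    "PairedMeasurements", "relative_difference", "icc", "icc_class",
    "bland_altman", "sdd", "sdd_from_sd", "summarize_cohort",
    "parameters_to_frame", "load_raw_workbook", "REPORT_COLUMNS",
]

SDD_FACTOR = 1.96


@dataclass
class PairedMeasurements:
    """Same-length T0/T1 value vectors for one (parameter, region) cell."""

    values_t0: np.ndarray
    values_t1: np.ndarray
    subject_ids: tuple | None = None
    parameter_tag: str = ""
    region_tag: str = ""

    def __post_init__(self) -> None:
        self.values_t0 = np.asarray(self.values_t0, float)
        self.values_t1 = np.asarray(self.values_t1, float)
        if self.values_t0.shape != self.values_t1.shape or self.values_t0.ndim != 1:
            raise ValidationError("values_t0 and values_t1 must be equal-length vectors")
        if not (np.all(np.isfinite(self.values_t0))
                and np.all(np.isfinite(self.values_t1))):
            raise ValidationError("paired measurements must be finite")

    @property
    def n(self) -> int:
        return self.values_t0.size

    @property
    def differences(self) -> np.ndarray:
        return self.values_t0 - self.values_t1


def relative_difference(a, b):
    """``100 * |a - b| / ((a + b) / 2)`` — symmetric and scale-invariant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mean = (a + b) / 2.0
    if np.any(mean == 0):
        raise UndefinedStatisticError("relative difference undefined: zero mean")
    out = 100.0 * np.abs(a - b) / np.abs(mean)
    return float(out) if out.ndim == 0 else out


def icc_class(value: float) -> str:
    if value <= 0.40:
        return "poor"
    if value <= 0.75:
        return "fair to good"
    return "excellent"


def icc(pairs: PairedMeasurements, model: str = "icc2") -> tuple[float, str]:
    """Intraclass correlation for two measurements per subject.

    ``model``: ``"icc2"`` (two-way random, absolute agreement, single
    measurement — the default), ``"icc1"`` (one-way random) or ``"icc3"``
    (two-way mixed, consistency).
    """
    if pairs.n < 2:
        raise SampleSizeError(f"ICC requires >= 2 subjects, got {pairs.n}")
    X = np.stack([pairs.values_t0, pairs.values_t1], axis=1)   # (n, k)
    n, k = X.shape
    grand = X.mean()
    sst = float(((X - grand) ** 2).sum())
    scale = float((X ** 2).mean()) or 1.0
    if sst <= 1e-12 * scale * n * k:
        raise UndefinedStatisticError(
            "ICC undefined: zero total variance in the measurements")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
    elif model == "icc3":
        value = (msr - mse) / (msr + (k - 1) * mse)
    elif model == "icc1":
        msw = (ssc + sse) / (n * (k - 1))
        value = (msr - msw) / (msr + (k - 1) * msw)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    value = float(value)
    return value, icc_class(value)


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float, float]:
    """``(diff_mean, diff_sd, loa_upper, loa_lower)`` for d = T0 - T1."""
    if pairs.n < 2:
        raise SampleSizeError("Bland-Altman requires >= 2 pairs")
    d = pairs.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, mean + SDD_FACTOR * sd, mean - SDD_FACTOR * sd


def sdd_from_sd(diff_sd: float) -> float:
    """Smallest detectable difference from a difference SD: 1.96 * SD."""
    return SDD_FACTOR * float(diff_sd)


def sdd(pairs: PairedMeasurements) -> float:
    """Smallest detectable difference of the paired T0-T1 differences."""
    if pairs.n < 2:
        raise SampleSizeError("SDD requires >= 2 pairs")
    return sdd_from_sd(pairs.differences.std(ddof=1))


DEFAULT_WORKBOOK_COLUMNS = {
    "subject_id": "subject_id", "timepoint": "timepoint",
    "region": "region", "parameter": "parameter", "value": "value",
}


def load_raw_workbook(path, *, sheet=0,
                      column_map: dict | None = None) -> pd.DataFrame:
    """Read a per-subject raw-measurement workbook (XLSX) into long format.

    ``column_map`` maps the five required long-format fields to the
    workbook's actual column headers, so externally deposited spreadsheets
    can be ingested without editing.
    """
    colmap = dict(DEFAULT_WORKBOOK_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_excel(path, sheet_name=sheet)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise DataError(f"workbook {path} missing column(s): {missing}")
    out = df[[colmap[k] for k in DEFAULT_WORKBOOK_COLUMNS]].copy()
    out.columns = list(DEFAULT_WORKBOOK_COLUMNS)
    return out


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "parameter", "region", "n",
    "mean_t0", "sd_t0", "mean_t1", "sd_t1",
    "rd_mean", "rd_sd", "rd_min", "rd_max",
    "icc", "icc_class",
    "diff_mean", "diff_sd", "abs_diff_mean", "abs_diff_sd",
    "loa_upper", "loa_lower", "sdd",
]


def parameters_to_frame(subject_id, timepoint: str,
                        records: list[AirwayParameters]) -> pd.DataFrame:
    """Long-format rows (subject_id, timepoint, region, parameter, value)."""
    rows = []
    for rec in records:
        d = rec.as_dict()
        for p in PARAMETERS:
            rows.append({"subject_id": subject_id, "timepoint": timepoint,
                         "region": rec.region_tag, "parameter": p,
                         "value": d[p]})
    return pd.DataFrame(rows)


def _pairs_from_frame(df: pd.DataFrame, parameter: str, region: str
                      ) -> PairedMeasurements:
    cell = df[(df["parameter"] == parameter) & (df["region"] == region)]
    wide = cell.pivot_table(index="subject_id", columns="timepoint",
                            values="value", aggfunc="first")
    for tp in ("T0", "T1"):
        if tp not in wide.columns:
            raise DataError(f"no {tp} measurements for ({parameter}, {region})")
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing:
        raise DataError(
            f"subject(s) missing a timepoint for ({parameter}, {region}): {missing}")
    return PairedMeasurements(wide["T0"].to_numpy(), wide["T1"].to_numpy(),
                              subject_ids=tuple(wide.index),
                              parameter_tag=parameter, region_tag=region)


def summarize_cohort(measurements: pd.DataFrame, *, icc_model: str = "icc2",
                     parameters=PARAMETERS, regions=ALL_REGIONS) -> pd.DataFrame:
    """Cohort-level variation report: one row per (parameter, region).

    ``measurements`` is long-format with columns subject_id, timepoint
    ('T0'/'T1'), region, parameter, value. The default grids produce the
    50-row layout (10 parameters x 5 regions). The cohort relative
    difference is the mean over subjects of per-subject relative differences.
    Cells where ICC or relative difference is undefined are flagged (NaN /
    "undefined"), never silently numeric.
    """
    required = {"subject_id", "timepoint", "region", "parameter", "value"}
    if not required.issubset(measurements.columns):
        raise DataError(f"measurements frame must have columns {sorted(required)}")
    rows = []
    for parameter in parameters:
        for region in regions:
            pairs = _pairs_from_frame(measurements, parameter, region)
            t0, t1 = pairs.values_t0, pairs.values_t1
            try:
                rd = relative_difference(t0, t1)
                rd_stats = (float(rd.mean()), float(rd.std(ddof=1)),
                            float(rd.min()), float(rd.max()))
            except UndefinedStatisticError:
                rd_stats = (np.nan,) * 4
            try:
                icc_val, icc_cls = icc(pairs, model=icc_model)
            except UndefinedStatisticError:
                icc_val, icc_cls = np.nan, "undefined"
            diff_mean, diff_sd, loa_hi, loa_lo = bland_altman(pairs)
            d_abs = np.abs(pairs.differences)
            rows.append({
                "parameter": parameter, "region": region, "n": pairs.n,
                "mean_t0": float(t0.mean()), "sd_t0": float(t0.std(ddof=1)),
                "mean_t1": float(t1.mean()), "sd_t1": float(t1.std(ddof=1)),
                "rd_mean": rd_stats[0], "rd_sd": rd_stats[1],
                "rd_min": rd_stats[2], "rd_max": rd_stats[3],
                "icc": icc_val, "icc_class": icc_cls,
                "diff_mean": diff_mean, "diff_sd": diff_sd,
                "abs_diff_mean": float(d_abs.mean()),
                "abs_diff_sd": float(d_abs.std(ddof=1)),
                "loa_upper": loa_hi, "loa_lower": loa_lo,
                "sdd": sdd_from_sd(diff_sd),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
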