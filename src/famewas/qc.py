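"""Replicate-level QC and assembly of the subject x unit methylation matrix.

The pipeline mirrors the measurement workflow of a triplicate
mass-spectrometric methylation assay:

1. subjects whose raw calling rate (fraction of panel units with any
   replicate measured) falls below a threshold are rejected outright;
2. for retained subjects, replicate triplets are averaged per cell, and
   cells whose replicate standard deviation exceeds a cutoff are excluded;
3. units flagged as mass collisions are merged by averaging;
4. a regional-average column is appended as an additional analysis
   variable.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "aggregate_replicates",
    "subject_filter",
    "merge_ambiguous_units",
    "regional_average",
    "control_calibration",
    "build_methylation_matrix",
    "REGIONAL_AVERAGE_LABEL",
]

REGIONAL_AVERAGE_LABEL = "FABP3_AVG"


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC rules.

    ``replicate_sd_max``: a cell is excluded when the sample standard
    deviation of its replicates exceeds this (fraction units).
    ``min_calling_rate``: subjects with a raw calling rate strictly below
    this are rejected entirely.
    """

    replicate_sd_max: float = 0.1
    min_calling_rate: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.min_calling_rate <= 1:
            raise ValueError("min_calling_rate must be in (0, 1]")
        if self.replicate_sd_max < 0:
            raise ValueError("replicate_sd_max must be non-negative")


def aggregate_replicates(
    fractions: Sequence[float], sd_max: float = 0.1
) -> tuple[float, float]:
    """Collapse one cell's replicates to (mean, sd); high-scatter cells excluded.

    Missing replicates (NaN) are dropped.  The sample (n-1) standard
    deviation is used; a single surviving replicate has sd 0 and is kept.
    Returns ``(nan, sd)`` when sd exceeds ``sd_max`` and ``(nan, nan)``
    when no replicate is present.
    """
    vals = np.asarray([v for v in fractions if v is not None and not math.isnan(v)], dtype=float)
    if vals.size == 0:
        return float("nan"), float("nan")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("replicate fraction outside [0, 1]")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd > sd_max:
        return float("nan"), sd
    return float(np.mean(vals)), sd


def subject_filter(
    matrix: pd.DataFrame, min_calling_rate: float = 0.95
) -> tuple[pd.Index, pd.DataFrame]:
    """Drop subjects with too many missing units.

    Calling rate = non-missing units / total panel units (columns of
    ``matrix``).  Rejection uses strict inequality: rate < threshold.
    Returns the retained subject index and a per-subject report
    (columns ``calling_rate``, ``rejected``).
    """
    if not 0 < min_calling_rate <= 1:
        raise ValueError("min_calling_rate must be in (0, 1]")
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        return matrix.index, pd.DataFrame(columns=["calling_rate", "rejected"])
    rate = matrix.notna().sum(axis=1) / matrix.shape[1]
    rejected = rate < min_calling_rate
    report = pd.DataFrame({"calling_rate": rate, "rejected": rejected})
    return matrix.index[~rejected], report


def _merge_labels(labels: Sequence[str]) -> str:
    """Joined label for averaged collision units: "3a"/"3b" -> "3"."""
    stems = {re.sub(r"[a-z]+$", "", lab) for lab in labels}
    if len(stems) == 1:
        return stems.pop()
    return "+".join(labels)


def merge_ambiguous_units(
    values: Mapping[str, float] | Sequence[float],
    labels: Sequence[str] | None = None,
) -> tuple[str, float]:
    """Average the values of mass-colliding units into one reported unit.

    Missing members are ignored; with every member missing the merged
    value is missing.  Returns (merged_label, value).
    """
    if isinstance(values, Mapping):
        labels = list(values.keys())
        vals = list(values.values())
    else:
        vals = list(values)
        if labels is None:
            labels = [str(i) for i in range(len(vals))]
    present = [v for v in vals if v is not None and not math.isnan(v)]
    merged = float(np.mean(present)) if present else float("nan")
    return _merge_labels(labels), merged


def regional_average(row: Sequence[float]) -> float:
    """Unweighted mean methylation over the subject's non-missing units."""
    vals = np.asarray(row, dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def control_calibration(
    observed: Sequence[float],
    expected: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    max_deviation: float = 0.1,
) -> dict:
    """Check a batch's methylation-control panel against its nominal values.

    Fits the least-squares line of observed on expected and reports slope,
    intercept, and the maximum absolute deviation; the batch is flagged
    when that deviation exceeds ``max_deviation``.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected controls must pair up")
    if np.unique(exp).size < 2:
        raise ValueError("need at least two distinct expected control levels")
    slope, intercept = np.polyfit(exp, obs, 1)
    dev = float(np.max(np.abs(obs - exp)))
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "max_abs_deviation": dev,
        "flagged": dev > max_deviation,
    }


def build_methylation_matrix(
    records: pd.DataFrame,
    config: QCConfig = QCConfig(),
    collision_groups: Sequence[Sequence[str]] = (),
    panel_units: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full QC: replicate records -> analysis-ready subject x unit matrix.

    ``records`` is long-format with columns subject, unit, replicate,
    fraction (NaN = not measured).  Subject rejection is decided on the
    raw calling rate (any replicate present for a unit counts as called)
    before the replicate-scatter exclusion, matching an instrument-level
    call/no-call followed by a precision filter.  ``collision_groups``
    lists unit-label groups to merge by averaging.  The returned matrix
    carries the merged units plus a regional-average column; the report
    dict holds per-subject calling rates and per-cell exclusions.
    """
    required = {"subject", "unit", "replicate", "fraction"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")

    units = list(panel_units) if panel_units is not None else sorted(records["unit"].unique())
    recs = records[records["unit"].isin(units)]

    # raw called matrix: unit called iff any replicate measured
    called = (
        recs.dropna(subset=["fraction"])
        .groupby(["subject", "unit"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=units, fill_value=0)
    )
    all_subjects = recs["subject"].unique()
    called = called.reindex(index=all_subjects, fill_value=0)
    called_mask = called > 0
    retained, subject_report = subject_filter(
        called_mask.where(called_mask, np.nan), config.min_calling_rate
    )

    # per-cell aggregation for retained subjects
    kept = recs[recs["subject"].isin(retained)]
    agg = kept.groupby(["subject", "unit"])["fraction"].apply(
        lambda v: aggregate_replicates(v.values, config.replicate_sd_max)
    )
    if len(agg):
        means = agg.map(lambda t: t[0]).unstack().reindex(index=retained, columns=units)
        sds = agg.map(lambda t: t[1]).unstack().reindex(index=retained, columns=units)
    else:
        means = pd.DataFrame(index=retained, columns=units, dtype=float)
        sds = means.copy()
    excluded_cells = (sds > config.replicate_sd_max).stack()
    excluded_cells = excluded_cells[excluded_cells]

    # merge colliding units
    matrix = means.copy()
    for group in collision_groups:
        group = [g for g in group if g in matrix.columns]
        if len(group) < 2:
            continue
        label, _ = merge_ambiguous_units({g: float("nan") for g in group})
        merged = matrix[group].mean(axis=1, skipna=True)
        matrix = matrix.drop(columns=group)
        matrix[label] = merged

    matrix[REGIONAL_AVERAGE_LABEL] = matrix.apply(lambda r: regional_average(r.values), axis=1)

    report = {
        "subjects": subject_report,
        "n_rejected_subjects": int(subject_report["rejected"].sum()),
        "excluded_cells": [
            {"subject": s, "unit": u, "replicate_sd": float(sds.loc[s, u])}
            for (s, u) in excluded_cells.index
        ],
        "cell_exclusion_fraction": (
            float(
                (sds > config.replicate_sd_max).to_numpy().sum()
                / max(int(sds.notna().to_numpy().sum()), 1)
            )
            if sds.size
            else 0.0
        ),
    }
    return matrix, report
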