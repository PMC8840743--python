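"""Response factors from dilution-series calibration curves.

The response factor (RF, M^-1) of a compound under one (mode, pH) condition
is the slope of the linear range of its calibration curve: peak area
regressed on molar concentration by ordinary least squares with a free
intercept. Electrospray calibration curves flatten at high concentration
(droplet-surface saturation), so the linear range is found by trimming
points from the top of the concentration series.

Linear-range selection
----------------------
Starting from all detected points sorted by concentration, while more than
three points remain the highest-concentration point is dropped if either

* the full-fit coefficient of determination R^2 is below 0.99, or
* the top point's back-calculated area deviates by more than 30% from an
  OLS fit through the remaining points (leave-top-out check).

The leave-top-out check is what actually catches saturation: a saturated
top point can dominate the regression so strongly that R^2 on the raw area
scale stays above 0.99 even though the point lies far off the line through
the rest of the series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateCalibrationError, InsufficientDataError
from .tables import (
    ConditionKey,
    PeakRecord,
    ResponseFactorRecord,
    ValidationError,
    mean_retention_time,
    merge_split_peaks,
)

logger = logging.getLogger(__name__)

#: Full-fit R^2 below which the top concentration point is dropped.
R2_THRESHOLD = 0.99

#: Maximum tolerated leave-top-out relative deviation of the top point.
MAX_TOP_POINT_DEVIATION = 0.30


@dataclass(frozen=True, slots=True)
class CalibrationSeries:
    """Detected (concentration, area) pairs for one compound and condition."""

    compound_id: str
    condition: ConditionKey
    points: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if len(self.points) < 1:
            raise ValidationError("calibration series needs at least one point")
        if any(c <= 0 for c in concs) or len(set(concs)) != len(concs):
            raise ValidationError("concentrations must be positive and distinct")


def _ols(conc: np.ndarray, area: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of area ~ concentration."""
    res = stats.linregress(conc, area)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def select_linear_range(
    points: Sequence[tuple[float, float]],
    r2_threshold: float = R2_THRESHOLD,
    max_top_deviation: float = MAX_TOP_POINT_DEVIATION,
) -> list[tuple[float, float]]:
    """Return the contiguous low-concentration subset kept for the fit."""
    kept = sorted(points)
    while len(kept) > 3:
        conc = np.array([c for c, _ in kept])
        area = np.array([a for _, a in kept])
        _, _, r2 = _ols(conc, area)
        slope_lo, icept_lo, _ = _ols(conc[:-1], area[:-1])
        predicted_top = icept_lo + slope_lo * conc[-1]
        saturated = (
            predicted_top <= 0
            or abs(area[-1] - predicted_top) / abs(predicted_top) > max_top_deviation
        )
        if r2 >= r2_threshold and not saturated:
            break
        kept = kept[:-1]
    return kept


def fit_response_factor(
    series: CalibrationSeries, mean_rt: float = math.nan
) -> ResponseFactorRecord:
    """Fit the RF as the slope of the linear range of ``series``.

    Raises :class:`InsufficientDataError` with fewer than three detected
    points and :class:`DegenerateCalibrationError` if the fitted slope is
    not positive.
    """
    if len(series.points) < 3:
        raise InsufficientDataError(
            f"{series.compound_id} {series.condition}: "
            f"{len(series.points)} detected points, need >= 3"
        )
    kept = select_linear_range(series.points)
    conc = np.array([c for c, _ in kept])
    area = np.array([a for _, a in kept])
    slope, _, _ = _ols(conc, area)
    if not slope > 0 or not math.isfinite(slope):
        raise DegenerateCalibrationError(
            f"{series.compound_id} {series.condition}: non-positive slope {slope}"
        )
    return ResponseFactorRecord(
        compound_id=series.compound_id,
        condition=series.condition,
        rf=slope,
        log_rf=math.log10(slope),
        mean_rt=mean_rt,
        n_points_used=len(kept),
    )


def build_training_table(
    records: Iterable[PeakRecord],
    standards: Mapping[tuple[str, float], float],
) -> list[ResponseFactorRecord]:
    """Calibrate every (standard compound, condition) with >= 3 detections.

    ``standards`` maps (compound_id, dilution_factor) to the known molar
    concentration. Split peaks are merged first; the mean retention time
    over detected dilutions is attached to each record. Compound-conditions
    failing the preconditions (too few points, degenerate slope, unknown
    concentrations) are skipped with a logged reason.
    """
    merged = merge_split_peaks(records)
    by_cc: dict[tuple[str, ConditionKey], list[PeakRecord]] = {}
    for r in merged:
        by_cc.setdefault((r.compound_id, r.condition), []).append(r)

    out: list[ResponseFactorRecord] = []
    for (cid, cond), recs in sorted(
        by_cc.items(), key=lambda kv: (kv[0][0], kv[0][1]._sort_key)
    ):
        points = [
            (standards[(cid, r.dilution_factor)], r.area)
            for r in recs
            if r.detected and (cid, r.dilution_factor) in standards
        ]
        if len(points) < 3:
            logger.info("skip %s %s: %d detected points", cid, cond, len(points))
            continue
        try:
            rec = fit_response_factor(
                CalibrationSeries(cid, cond, points),
                mean_rt=mean_retention_time(recs),
            )
        except DegenerateCalibrationError as exc:
            logger.info("skip %s %s: %s", cid, cond, exc)
            continue
        out.append(rec)
    return out
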