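"""Concentration estimation, fold-error scoring and uncertainty combination.

With a predicted response factor RF_pred (M^-1) and a peak area A, the
concentration estimate is simply c = A / RF_pred (the calibration-curve
intercept is taken as negligible). Up to six per-condition estimates per
compound are aggregated into a (min, median, max) range. Accuracy is
scored with the symmetric fold error

    error = max(c_predicted / c_actual, c_actual / c_predicted) >= 1,

summarized by its mean, median, maximum, and the fraction of datapoints
with error strictly below a factor of 10. One datapoint is one compound at
one concentration in one condition.

Multiplicative (fold) uncertainties from independent sources — e.g. a
predicted concentration and a predicted toxicity endpoint in a risk
quotient — combine by quadrature of the relative uncertainties:
f_total = 1 + sqrt(sum (f_i - 1)^2), so the larger factor dominates
(factor 10 with factor 1.2 is still a factor of 10; two factors of 10
give a factor of 14).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .tables import ConditionKey


@dataclass(frozen=True, slots=True)
class ConcentrationEstimate:
    """Per-condition concentration estimates and their aggregated range."""

    compound_id: str
    per_condition: Mapping[ConditionKey, float]
    range_min: float
    range_median: float
    range_max: float

    def __post_init__(self) -> None:
        if not self.per_condition:
            raise ValidationError("per_condition must be nonempty")
        if not self.range_min <= self.range_median <= self.range_max:
            raise ValidationError("range must be ordered min <= median <= max")


@dataclass(frozen=True, slots=True)
class EvaluationRecord:
    """One scored datapoint: compound x concentration x condition."""

    compound_id: str
    condition: ConditionKey
    c_predicted: float
    c_actual: float
    fold_error: float


@dataclass(frozen=True, slots=True)
class ErrorSummary:
    mean_fold: float
    median_fold: float
    max_fold: float
    frac_below_10: float
    n: int


def estimate_concentration(area: float, rf_pred: float) -> float:
    """Molar concentration from peak area and predicted RF: area / RF."""
    if area <= 0 or rf_pred <= 0:
        raise ValidationError("area and rf_pred must be positive")
    return area / rf_pred


def aggregate_estimates(
    compound_id: str, per_condition: Mapping[ConditionKey, float]
) -> ConcentrationEstimate:
    """Collapse per-condition estimates into a (min, median, max) range.

    The median of an even number of estimates is the arithmetic midpoint
    of the two central values.
    """
    if not per_condition:
        raise InsufficientDataError("no per-condition estimates to aggregate")
    values = np.array(sorted(per_condition.values()), dtype=float)
    return ConcentrationEstimate(
        compound_id=compound_id,
        per_condition=dict(per_condition),
        range_min=float(values[0]),
        range_median=float(np.median(values)),
        range_max=float(values[-1]),
    )


def fold_error(c_predicted: float, c_actual: float) -> float:
    """Symmetric fold error, >= 1, equal to 1 iff the inputs are equal."""
    if c_predicted <= 0 or c_actual <= 0:
        raise ValidationError("concentrations must be positive")
    return max(c_predicted / c_actual, c_actual / c_predicted)


def summarize_errors(
    records: Iterable[EvaluationRecord], threshold: float = 10.0
) -> ErrorSummary:
    """Mean/median/max fold error and fraction strictly below ``threshold``."""
    errors = np.array([r.fold_error for r in records], dtype=float)
    if errors.size == 0:
        raise InsufficientDataError("no evaluation records to summarize")
    return ErrorSummary(
        mean_fold=float(errors.mean()),
        median_fold=float(np.median(errors)),
        max_fold=float(errors.max()),
        frac_below_10=float((errors < threshold).mean()),
        n=int(errors.size),
    )


def combine_uncertainty_factors(factors: Sequence[float]) -> float:
    """Combine independent fold-uncertainties by relative-error quadrature.

    Each factor f >= 1 corresponds to a relative uncertainty u = f - 1;
    the combined factor is 1 + sqrt(sum u_i^2). Commutative, at least as
    large as the largest input, and monotone in every argument.
    """
    factors = list(factors)
    if not factors:
        raise ValidationError("need at least one uncertainty factor")
    if any(f < 1 for f in factors):
        raise ValidationError("fold-uncertainty factors must be >= 1")
    rel = np.array(factors, dtype=float) - 1.0
    return float(1.0 + np.sqrt(np.sum(rel**2)))
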