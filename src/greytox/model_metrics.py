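"""Validation of externally supplied pharmacophore-model statistics.

A hypothesis-generation run reports cost/fit diagnostics per model
(total cost, fixed cost, RMS, correlation, configuration cost) and a
per-compound table of estimated vs. experimentally derived ("active")
activity values.  This module scores such summaries against the
conventional acceptance thresholds: configuration cost at most 17,
correlation above 0.7, and every compound's signed error ratio of
magnitude below 2.  The total-vs-fixed cost gap is reported without a
threshold (smaller is better; no conventional cutoff exists).

The signed error ratio is the fold-difference between estimated and
active values, signed by the direction of the miss:

    error(est, act) = +est/act  if est >= act,  else  -act/est

so its magnitude is always >= 1 and a perfect estimate scores +1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import SchemaError

__all__ = [
    "ModelStats",
    "CompoundFitRow",
    "ModelThresholds",
    "ModelVerdict",
    "error_ratio",
    "validate_model",
]


def error_ratio(estimated: float, active: float) -> float:
    """Signed max/min ratio of estimated vs active activity values.

    Both arguments must be strictly positive.  Returns ``+estimated/active``
    when the model over- (or exactly) estimates, ``-active/estimated``
    when it underestimates; the magnitude is ``max/min >= 1`` either way.
    """
    if not (estimated > 0 and active > 0) or not (
        math.isfinite(estimated) and math.isfinite(active)
    ):
        raise SchemaError(
            f"estimated and active must be positive finite, got "
            f"({estimated!r}, {active!r})"
        )
    if estimated >= active:
        return estimated / active
    return -active / estimated


@dataclass(frozen=True)
class ModelStats:
    """Summary diagnostics of one pharmacophore hypothesis."""

    model_id: str
    total_cost: float
    fixed_cost: float
    rms: float
    correlation: float
    configuration: float
    features: tuple = ()

    def __post_init__(self):
        if self.rms < 0:
            raise SchemaError(f"{self.model_id}: rms must be >= 0")
        if not (-1.0 <= self.correlation <= 1.0):
            raise SchemaError(f"{self.model_id}: correlation must lie in [-1, 1]")
        if self.configuration < 0:
            raise SchemaError(f"{self.model_id}: configuration must be >= 0")
        if len(self.features) == 0:
            raise SchemaError(f"{self.model_id}: feature list must be non-empty")


@dataclass(frozen=True)
class CompoundFitRow:
    """Per-compound fit diagnostics: fit value, estimated and active
    activity, and the signed error ratio (recomputed if omitted)."""

    compound_id: str
    fit_value: float
    estimated: float
    active: float
    error: float | None = None

    def __post_init__(self):
        if self.estimated <= 0 or self.active <= 0:
            raise SchemaError(
                f"{self.compound_id}: estimated and active must be positive"
            )
        if self.error is None:
            object.__setattr__(self, "error",
                               error_ratio(self.estimated, self.active))


@dataclass(frozen=True)
class ModelThresholds:
    """Acceptance thresholds; configuration is non-strict ('not greater
    than'), correlation strict, error magnitude strict."""

    max_configuration: float = 17.0
    min_correlation: float = 0.7
    max_abs_error: float = 2.0


@dataclass(frozen=True)
class ModelVerdict:
    """Per-criterion flags plus the unthresholded cost gap."""

    model_id: str
    configuration_ok: bool
    correlation_ok: bool
    errors_ok: bool
    cost_gap: float
    worst_abs_error: float
    thresholds: ModelThresholds

    @property
    def passed(self) -> bool:
        return self.configuration_ok and self.correlation_ok and self.errors_ok


def validate_model(stats: ModelStats, rows,
                   thresholds: ModelThresholds = ModelThresholds()) -> ModelVerdict:
    """Score a model summary and its per-compound table against the
    acceptance thresholds; returns a verdict object, never raises on a
    failing criterion."""
    rows = list(rows)
    if not rows:
        raise SchemaError("at least one compound fit row is required")
    errors = [error_ratio(r.estimated, r.active) for r in rows]
    worst = max(abs(e) for e in errors)
    return ModelVerdict(
        model_id=stats.model_id,
        configuration_ok=stats.configuration <= thresholds.max_configuration,
        correlation_ok=stats.correlation > thresholds.min_correlation,
        errors_ok=worst < thresholds.max_abs_error,
        cost_gap=stats.total_cost - stats.fixed_cost,
        worst_abs_error=worst,
        thresholds=thresholds,
    )
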