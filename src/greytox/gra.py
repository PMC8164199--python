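"""Grey relational aggregation of multi-receptor toxicity panels.

The comprehensive-toxicity statistic works on a compound x receptor
matrix of acute EC50/LC50 values (mg/L).  The reference sequence is the
constant acute-toxicity classification boundary (1.0 mg/L by default);
each receptor column is a comparison sequence.  For compound k and
receptor i, with absolute difference

    delta_i(k) = | x0 - x_i(k) |,

the grey interconnect coefficient is

    xi_i(k) = (d_min + rho * d_max) / (delta_i(k) + rho * d_max),

where rho in (0, 1) is the resolution coefficient (0.5 by convention)
and (d_min, d_max) are difference extremes.  Two extreme conventions are
supported:

* ``per_sequence`` (default): each comparison sequence uses its own
  minimum and maximum over compounds.  This is the convention under
  which the published worked example for the 14-phthalate panel is
  reproducible cell-for-cell.
* ``global``: a single min-of-mins and max-of-maxes over all sequences,
  the textbook double-extremum form of the coefficient.  On the same
  panel it yields visibly different coefficients (e.g. 0.6027 instead
  of 0.7268 for the least-toxic fish column entry of DEHP), which is
  why both modes exist and the choice is explicit.

The grey interconnect degree of a compound is the weighted (by default
arithmetic) mean of its coefficients across receptors.  Degrees lie in
(0, 1]; a degree of 1 means the compound's toxicity profile sits exactly
on the classification boundary profile, i.e. the lowest comprehensive
toxicity in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DegeneratePanelError
from .panel import ToxicityPanel

__all__ = [
    "GraConfig",
    "DifferenceMatrix",
    "GreyCoefficientMatrix",
    "GreyDegreeVector",
    "GreyResult",
    "GreyRelationalTransform",
    "abs_difference",
    "grey_coefficient",
    "grey_degree",
    "run_gra",
    "write_gra_results",
]

_NORMALIZATIONS = ("per_sequence", "global")


@dataclass(frozen=True)
class GraConfig:
    """Configuration of the grey relational computation.

    Parameters
    ----------
    reference_value : float
        Constant reference sequence, mg/L.  Default 1.0, the acute
        aquatic-toxicity classification boundary (EC50/LC50 < 1 mg/L =
        "very toxic").
    rho : float
        Resolution coefficient in (0, 1); damps the max-difference term.
    normalization : {"per_sequence", "global"}
        Which difference extremes govern the coefficient (see module
        docstring).
    weights : sequence of float or None
        Receptor weights for the degree; None means uniform.  Must be
        non-negative and sum to 1.
    """

    reference_value: float = 1.0
    rho: float = 0.5
    normalization: str = "per_sequence"
    weights: tuple | None = None

    def __post_init__(self):
        if not (self.reference_value > 0):
            raise ConfigError(f"reference_value must be > 0, got {self.reference_value}")
        if not (0.0 < self.rho < 1.0):
            raise ConfigError(f"rho must lie in the open interval (0, 1), got {self.rho}")
        if self.normalization not in _NORMALIZATIONS:
            raise ConfigError(
                f"normalization must be one of {_NORMALIZATIONS}, got {self.normalization!r}"
            )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", tuple(w))
            if (w < 0).any():
                raise ConfigError("weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(f"weights must sum to 1, got {w.sum()!r}")

    def weight_vector(self, n: int) -> np.ndarray:
        if self.weights is None:
            return np.full(n, 1.0 / n)
        w = np.asarray(self.weights, dtype=float)
        if w.size != n:
            raise ConfigError(f"{w.size} weights supplied for {n} receptor sequences")
        return w


@dataclass(frozen=True)
class DifferenceMatrix:
    """Absolute differences from the reference, with their extremes.

    ``values`` is compound x receptor; ``column_min``/``column_max`` are
    the per-sequence extremes over compounds; ``global_min``/``global_max``
    the double extremes.
    """

    values: pd.DataFrame
    column_min: pd.Series
    column_max: pd.Series
    global_min: float
    global_max: float


@dataclass(frozen=True)
class GreyCoefficientMatrix:
    """Grey interconnect coefficients in (0, 1], plus the config used."""

    values: pd.DataFrame
    config: GraConfig


@dataclass(frozen=True)
class GreyDegreeVector:
    """Per-compound grey interconnect degrees in (0, 1]."""

    values: pd.Series
    n: int


@dataclass(frozen=True)
class GreyResult:
    """Bundle of the three pipeline stages for one panel."""

    differences: DifferenceMatrix
    coefficients: GreyCoefficientMatrix
    degrees: GreyDegreeVector


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ToxicityPanel):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ConfigError("expected a 2-D compound x receptor matrix")
    return pd.DataFrame(arr)


class GreyRelationalTransform(TransformerMixin, BaseEstimator):
    """Grey relational coefficients/degrees as a scikit-learn transformer.

    ``fit`` learns the difference extremes of a training panel;
    ``transform`` maps a panel of the same receptor layout to its
    coefficient matrix under those extremes, so held-out compounds are
    scored against the training panel's difference range.  The common
    single-panel analysis is ``fit_transform`` on the panel itself (or
    the :func:`run_gra` convenience wrapper).

    Parameters are as in :class:`GraConfig`.  Fitted attributes (trailing
    underscore) expose the difference matrix and extremes.

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"a": [0.2, 0.5], "b": [0.1, 0.9]},
    ...                  index=["c1", "c2"])
    >>> t = GreyRelationalTransform().fit(X)
    >>> t.degrees(X).round(4).tolist()
    [0.5787, 1.0]
    """

    def __init__(self, reference_value=1.0, rho=0.5,
                 normalization="per_sequence", weights=None):
        self.reference_value = reference_value
        self.rho = rho
        self.normalization = normalization
        self.weights = weights

    # -- scikit-learn plumbing --------------------------------------
    def _config(self) -> GraConfig:
        return GraConfig(
            reference_value=self.reference_value,
            rho=self.rho,
            normalization=self.normalization,
            weights=None if self.weights is None else tuple(self.weights),
        )

    def fit(self, X, y=None):
        """Learn difference extremes from a compound x receptor panel."""
        cfg = self._config()
        frame = _as_frame(X)
        if frame.shape[0] < 1 or frame.shape[1] < 1:
            raise ConfigError("panel must have at least one compound and one receptor")
        diff = (frame - cfg.reference_value).abs()
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.difference_matrix_ = diff
        self.column_min_ = diff.min(axis=0)
        self.column_max_ = diff.max(axis=0)
        self.global_min_ = float(self.column_min_.min())
        self.global_max_ = float(self.column_max_.max())
        if cfg.normalization == "global":
            if self.global_max_ == 0.0:
                raise DegeneratePanelError(
                    "all comparison values equal the reference; "
                    "the grey coefficient is undefined"
                )
        elif (self.column_max_ == 0.0).any():
            bad = list(self.column_max_.index[self.column_max_ == 0.0])
            raise DegeneratePanelError(
                f"receptor sequence(s) {bad} equal the reference everywhere; "
                "per-sequence extremes are degenerate"
            )
        return self

    def _check_fitted(self):
        if not hasattr(self, "column_max_"):
            raise ConfigError("this GreyRelationalTransform instance is not fitted yet")

    def transform(self, X) -> pd.DataFrame:
        """Coefficient matrix of ``X`` under the fitted extremes."""
        self._check_fitted()
        cfg = self._config()
        frame = _as_frame(X)
        if list(frame.columns) != list(self.feature_names_in_):
            if frame.shape[1] != self.n_features_in_:
                raise ConfigError(
                    f"panel has {frame.shape[1]} receptors, transformer was "
                    f"fitted with {self.n_features_in_}"
                )
            frame = frame.set_axis(list(self.feature_names_in_), axis=1)
        diff = (frame - cfg.reference_value).abs()
        if cfg.normalization == "global":
            d_min = np.full(self.n_features_in_, self.global_min_)
            d_max = np.full(self.n_features_in_, self.global_max_)
        else:
            d_min = self.column_min_.to_numpy()
            d_max = self.column_max_.to_numpy()
        num = d_min + cfg.rho * d_max
        den = diff.to_numpy() + cfg.rho * d_max
        coeffs = pd.DataFrame(num / den, index=frame.index, columns=frame.columns)
        return coeffs

    def degrees(self, X) -> pd.Series:
        """Weighted horizontal mean of the coefficient matrix of ``X``."""
        coeffs = self.transform(X)
        w = self._config().weight_vector(coeffs.shape[1])
        return pd.Series(coeffs.to_numpy() @ w, index=coeffs.index, name="degree")


# ---------------------------------------------------------------------
# Functional surface: thin wrappers around the transformer.


def abs_difference(panel, config: GraConfig = GraConfig()) -> DifferenceMatrix:
    """Absolute differences |reference - value| with their extremes."""
    t = GreyRelationalTransform(**_params(config)).fit(panel)
    return DifferenceMatrix(
        values=t.difference_matrix_,
        column_min=t.column_min_,
        column_max=t.column_max_,
        global_min=t.global_min_,
        global_max=t.global_max_,
    )


def grey_coefficient(diffs: DifferenceMatrix,
                     config: GraConfig = GraConfig()) -> GreyCoefficientMatrix:
    """Coefficient matrix from a precomputed difference matrix."""
    if config.normalization == "global":
        d_min = np.full(diffs.values.shape[1], diffs.global_min)
        d_max = np.full(diffs.values.shape[1], diffs.global_max)
        if diffs.global_max == 0.0:
            raise DegeneratePanelError(
                "all comparison values equal the reference; coefficient undefined"
            )
    else:
        d_min = diffs.column_min.to_numpy()
        d_max = diffs.column_max.to_numpy()
        if (d_max == 0.0).any():
            raise DegeneratePanelError("a sequence's difference maximum is zero")
    num = d_min + config.rho * d_max
    den = diffs.values.to_numpy() + config.rho * d_max
    values = pd.DataFrame(num / den, index=diffs.values.index,
                          columns=diffs.values.columns)
    return GreyCoefficientMatrix(values=values, config=config)


def grey_degree(coeffs: GreyCoefficientMatrix,
                config: GraConfig | None = None) -> GreyDegreeVector:
    """Weighted horizontal mean of coefficients per compound."""
    config = config or coeffs.config
    n = coeffs.values.shape[1]
    w = config.weight_vector(n)
    values = pd.Series(coeffs.values.to_numpy() @ w,
                       index=coeffs.values.index, name="degree")
    return GreyDegreeVector(values=values, n=n)


def run_gra(panel, config: GraConfig = GraConfig()) -> GreyResult:
    """Full pipeline: differences -> coefficients -> degrees for one panel."""
    diffs = abs_difference(panel, config)
    coeffs = grey_coefficient(diffs, config)
    degrees = grey_degree(coeffs, config)
    return GreyResult(differences=diffs, coefficients=coeffs, degrees=degrees)


def _params(config: GraConfig) -> dict:
    return dict(
        reference_value=config.reference_value,
        rho=config.rho,
        normalization=config.normalization,
        weights=config.weights,
    )


def write_gra_results(result: GreyResult, out_dir, prefix="gra") -> list[str]:
    """Write differences (6 dp), coefficients and degrees (4 dp) as CSVs.

    Returns the list of paths written.  Rounding is display-only; the
    in-memory result keeps full precision.
    """
    import os

    paths = []
    layouts = [
        ("differences", result.differences.values, "%.6f"),
        ("coefficients", result.coefficients.values, "%.4f"),
        ("degrees", result.degrees.values.to_frame(), "%.4f"),
    ]
    for stem, frame, fmt in layouts:
        path = os.path.join(out_dir, f"{prefix}_{stem}.csv")
        frame.to_csv(path, float_format=fmt)
        paths.append(path)
    return paths
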