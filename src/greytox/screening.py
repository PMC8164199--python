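"""Derivative screening by change-rate rules.

Stage 1 compares the grey comprehensive-characterization value of each
candidate derivative with its parent and keeps derivatives whose value
rose by more than a threshold (default 10%) — a higher degree means a
profile closer to the 1 mg/L classification boundary, i.e. lower joint
toxicity.  Stage 2 re-examines the survivors on per-receptor
negative-log toxicity (pEC50/pLC50) and keeps those whose predicted
toxicity dropped on *every* receptor.  A proportionality diagnostic
summarizes how evenly the per-receptor drops are spread (a max/min
absolute-rate ratio near 1 means the decline is close to 1:1:...:1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedRateError
from .panel import PToxicityPanel

__all__ = [
    "DerivativeRecord",
    "ChangeRatePair",
    "ChangeRateReport",
    "ProportionalityResult",
    "MultiReceptorScreenResult",
    "change_rate",
    "screen_activity_increase",
    "screen_multireceptor_reduction",
    "proportionality",
]


def change_rate(old: float, new: float) -> float:
    """Percent change (new - old) / old * 100, sign preserved.

    The single comparison statistic used across all screening and
    evaluation stages.  The returned value is unrounded; rounding to two
    decimals is a display concern.
    """
    if old == 0:
        raise UndefinedRateError("change rate is undefined for a zero baseline")
    return (new - old) / old * 100.0


@dataclass(frozen=True)
class DerivativeRecord:
    """A parent -> derivative pair with estimated activity values."""

    parent_id: str
    derivative_id: str
    estimated_parent: float
    estimated_derivative: float
    substituent: str = ""

    def __post_init__(self):
        if not self.parent_id or not self.derivative_id:
            raise SchemaError("parent and derivative ids must be non-empty")
        for name in ("estimated_parent", "estimated_derivative"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise SchemaError(f"{self.derivative_id}: {name} must be finite")
        if self.estimated_parent == 0:
            raise SchemaError(
                f"{self.derivative_id}: parent estimate is zero; rate undefined"
            )


@dataclass(frozen=True)
class ChangeRatePair:
    label: str
    old: float
    new: float
    rate: float  # percent


@dataclass(frozen=True)
class ChangeRateReport:
    """Ordered change rates plus the labels passing a strict threshold."""

    pairs: tuple
    screen_threshold: float
    passed: tuple

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [(p.label, p.old, p.new, p.rate) for p in self.pairs],
            columns=["label", "old", "new", "rate_pct"],
        )
        frame["passed"] = frame["label"].isin(self.passed)
        return frame


def screen_activity_increase(records, threshold: float = 10.0) -> ChangeRateReport:
    """Keep derivatives whose estimated value rose strictly more than
    ``threshold`` percent over the parent's.

    Input order is preserved; the pass rule is a strict inequality on the
    unrounded rate, so a rate of exactly ``threshold`` does not pass.
    """
    pairs = []
    passed = []
    for rec in records:
        rate = change_rate(rec.estimated_parent, rec.estimated_derivative)
        pairs.append(ChangeRatePair(rec.derivative_id, rec.estimated_parent,
                                    rec.estimated_derivative, rate))
        if rate > threshold:
            passed.append(rec.derivative_id)
    return ChangeRateReport(pairs=tuple(pairs), screen_threshold=threshold,
                            passed=tuple(passed))


@dataclass(frozen=True)
class ProportionalityResult:
    """max|rate| / min|rate| across receptors, when well defined.

    ``applicable`` is False when rates mix signs or include a zero; in
    that case ``ratio`` and ``within_tolerance`` are None.  The flag is
    advisory: the raw ratio is always reported next to it.
    """

    ratio: float | None
    within_tolerance: bool | None
    applicable: bool
    tolerance: float


def proportionality(rates, tolerance: float = 2.5) -> ProportionalityResult:
    """How close a set of per-receptor change rates is to 1:1:...:1."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0 or (arr == 0).any() or not (np.all(arr > 0) or np.all(arr < 0)):
        return ProportionalityResult(ratio=None, within_tolerance=None,
                                     applicable=False, tolerance=tolerance)
    mags = np.abs(arr)
    ratio = float(mags.max() / mags.min())
    return ProportionalityResult(ratio=ratio, within_tolerance=ratio <= tolerance,
                                 applicable=True, tolerance=tolerance)


@dataclass(frozen=True)
class MultiReceptorScreenResult:
    """Per-receptor pToxicity change rates and the all-reduced verdicts.

    ``rates`` is derivative x receptor (percent); ``all_reduced`` is True
    only when every receptor's rate is strictly negative (toxicity fell
    everywhere); ``proportionality`` carries the max/min |rate| ratio per
    derivative (NaN where not applicable).
    """

    rates: pd.DataFrame
    all_reduced: pd.Series
    proportionality: pd.Series

    @property
    def passed(self) -> tuple:
        return tuple(self.all_reduced.index[self.all_reduced])

    def to_frame(self) -> pd.DataFrame:
        frame = self.rates.copy()
        frame["all_reduced"] = self.all_reduced
        frame["proportionality"] = self.proportionality
        return frame


def screen_multireceptor_reduction(parents, derivatives, parent_of,
                                   tolerance: float = 2.5) -> MultiReceptorScreenResult:
    """Stage-2 screen on negative-log toxicity panels.

    Parameters
    ----------
    parents, derivatives : PToxicityPanel or DataFrame
        Negative-log toxicity values, compounds x receptors, sharing one
        receptor set.  On this scale a *decrease* means the EC50/LC50
        concentration rose, i.e. toxicity to that receptor fell.
    parent_of : mapping derivative id -> parent id
    tolerance : float
        Ratio bound for the advisory 1:1 proportionality flag.
    """
    pf = parents.values if isinstance(parents, PToxicityPanel) else parents
    df = derivatives.values if isinstance(derivatives, PToxicityPanel) else derivatives
    if list(pf.columns) != list(df.columns):
        raise SchemaError(
            f"receptor mismatch: parents {list(pf.columns)} vs "
            f"derivatives {list(df.columns)}"
        )
    rows = {}
    for did in df.index:
        parent = parent_of.get(did)
        if parent is None:
            raise SchemaError(f"derivative {did!r} has no parent mapping")
        if parent not in pf.index:
            raise SchemaError(f"parent {parent!r} of {did!r} not in parent panel")
        old = pf.loc[parent]
        if (old == 0).any():
            raise UndefinedRateError(
                f"parent {parent!r} has a zero pToxicity value; rate undefined"
            )
        rows[did] = (df.loc[did] - old) / old * 100.0
    if not rows:
        empty = pd.DataFrame(index=df.index, columns=pf.columns, dtype=float)
        return MultiReceptorScreenResult(
            rates=empty,
            all_reduced=pd.Series(dtype=bool),
            proportionality=pd.Series(dtype=float),
        )
    rates = pd.DataFrame.from_dict(rows, orient="index")
    rates = rates.reindex(df.index)[pf.columns]
    all_reduced = (rates < 0).all(axis=1)
    def _ratio(row):
        p = proportionality(row, tolerance)
        return p.ratio if p.applicable else np.nan

    prop = rates.apply(_ratio, axis=1)
    return MultiReceptorScreenResult(rates=rates, all_reduced=all_reduced,
                                     proportionality=prop)
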