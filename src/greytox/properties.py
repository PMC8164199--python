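"""Post-screening evaluation of candidate derivatives.

Given externally computed quantum, partitioning, docking and
transition-state numbers for a parent/derivative pair, these evaluators
apply the decision rules of the screening workflow:

* functional properties — total electronic energy (stability: must not
  rise by more than a small percentage), HOMO-LUMO gap (insulation;
  reported, no threshold), lowest vibrational frequency (> 0 means the
  optimized structure is a true minimum and can exist stably);
* POPs properties — percent changes of log Kow (bioaccumulation),
  log Koa (long-range transport) and atmospheric half-life, with a
  persistence flag at the two-day half-life criterion;
* docking — per-protein percent change of the docking score (lower
  score = weaker receptor binding = lower toxic potency);
* metabolism — the reaction energy barrier dE = E_TS - sum(E_reactant)
  of the primary ester-hydrolysis step.

Note the percent changes of log Kow / log Koa are rates *on the
logarithmic descriptor itself*; that is unconventional but is the
convention the evaluated tables use, so reports keep it and say so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import SchemaError
from .screening import change_rate

__all__ = [
    "PropertyRecord",
    "BarrierInput",
    "DockingScores",
    "FunctionalVerdict",
    "PopsVerdict",
    "DockingChange",
    "reaction_barrier",
    "evaluate_functional",
    "evaluate_pops",
    "docking_change",
]

LOG_DESCRIPTOR_NOTE = (
    "log_kow/log_koa change rates are computed on the logarithmic "
    "descriptors themselves, not on Kow/Koa"
)


@dataclass(frozen=True)
class PropertyRecord:
    """Quantum and POPs descriptors for one compound.

    Units: ``total_energy`` hartree (a.u.), ``energy_gap`` eV,
    ``frequency`` cm^-1, ``half_life`` hours; ``log_kow``/``log_koa``
    dimensionless log10 partition coefficients.  Fields are optional;
    each evaluator names the ones it requires.
    """

    compound_id: str
    total_energy: float | None = None
    energy_gap: float | None = None
    frequency: float | None = None
    log_koa: float | None = None
    log_kow: float | None = None
    half_life: float | None = None

    def __post_init__(self):
        for name in ("total_energy", "energy_gap", "frequency",
                     "log_koa", "log_kow", "half_life"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise SchemaError(f"{self.compound_id}: {name} must be finite")
        if self.half_life is not None and self.half_life <= 0:
            raise SchemaError(f"{self.compound_id}: half_life must be positive")

    def require(self, *names):
        for name in names:
            if getattr(self, name) is None:
                raise SchemaError(f"{self.compound_id}: missing field {name!r}")


@dataclass(frozen=True)
class BarrierInput:
    """Transition-state energy and reactant energies, caller's units."""

    e_ts: float
    e_reactants: tuple

    def __post_init__(self):
        if len(self.e_reactants) == 0:
            raise SchemaError("at least one reactant energy is required")


def reaction_barrier(inp: BarrierInput) -> float:
    """dE = E_TS - sum of reactant energies (units as supplied)."""
    return inp.e_ts - sum(inp.e_reactants)


@dataclass(frozen=True)
class FunctionalVerdict:
    """Stability/insulation/existence assessment of one derivative.

    ``stability`` passes when total energy did not rise, or rose by less
    than the configured limit.  ``insulation_change`` (energy-gap rate)
    is informational only.  ``existence`` requires a positive lowest
    frequency.
    """

    compound_id: str
    energy_change: float  # percent
    gap_change: float  # percent
    frequency: float
    stability: bool
    existence: bool
    energy_increase_limit: float

    @property
    def passed(self) -> bool:
        return self.stability and self.existence

    @property
    def insulation_change(self) -> float:
        return self.gap_change


def evaluate_functional(parent: PropertyRecord, derivative: PropertyRecord,
                        energy_increase_limit: float = 5.0) -> FunctionalVerdict:
    """Apply the stability / insulation / existence rules to a pair.

    A derivative's total energy falling (or unchanged) passes outright;
    an increase passes only while strictly below
    ``energy_increase_limit`` percent.
    """
    parent.require("total_energy", "energy_gap", "frequency")
    derivative.require("total_energy", "energy_gap", "frequency")
    energy_change = change_rate(parent.total_energy, derivative.total_energy)
    gap_change = change_rate(parent.energy_gap, derivative.energy_gap)
    # The rule lives on the change rate itself: a non-positive rate is an
    # improved-or-unchanged verdict; a positive rate passes only while
    # strictly below the limit.  (On an all-negative energy axis the raw
    # rate's sign is inverted relative to the energy axis; the screening
    # convention follows the rate, as the evaluated tables do.)
    stability = energy_change <= 0 or energy_change < energy_increase_limit
    return FunctionalVerdict(
        compound_id=derivative.compound_id,
        energy_change=energy_change,
        gap_change=gap_change,
        frequency=derivative.frequency,
        stability=stability,
        existence=derivative.frequency > 0,
        energy_increase_limit=energy_increase_limit,
    )


@dataclass(frozen=True)
class PopsVerdict:
    """Persistent-organic-pollutant screening rates and persistence flag."""

    compound_id: str
    log_kow_change: float  # percent, on the log descriptor
    log_koa_change: float  # percent, on the log descriptor
    half_life_change: float  # percent
    half_life: float  # hours
    persistent: bool
    note: str = LOG_DESCRIPTOR_NOTE


def evaluate_pops(parent: PropertyRecord, derivative: PropertyRecord,
                  air_half_life_threshold: float = 48.0) -> PopsVerdict:
    """POPs-criteria rates; persistence = derivative half-life above the
    two-day (48 h) atmospheric threshold."""
    parent.require("log_koa", "log_kow", "half_life")
    derivative.require("log_koa", "log_kow", "half_life")
    return PopsVerdict(
        compound_id=derivative.compound_id,
        log_kow_change=change_rate(parent.log_kow, derivative.log_kow),
        log_koa_change=change_rate(parent.log_koa, derivative.log_koa),
        half_life_change=change_rate(parent.half_life, derivative.half_life),
        half_life=derivative.half_life,
        persistent=derivative.half_life > air_half_life_threshold,
    )


@dataclass(frozen=True)
class DockingScores:
    """Docking scores of one ligand against a set of receptor proteins.

    Scores are the docking program's non-negative fitness values; higher
    means stronger predicted binding.
    """

    compound_id: str
    scores: dict

    def __post_init__(self):
        for pid, s in self.scores.items():
            if not math.isfinite(s) or s < 0:
                raise SchemaError(
                    f"{self.compound_id}/{pid}: docking score must be non-negative"
                )


@dataclass(frozen=True)
class DockingChange:
    """Per-protein percent score changes; ``all_weaker`` iff every change
    is strictly negative (binding weakened at every receptor protein)."""

    compound_id: str
    rates: dict
    all_weaker: bool


def docking_change(parent: DockingScores, derivative: DockingScores) -> DockingChange:
    """Percent change of each protein's docking score, parent -> derivative."""
    if set(parent.scores) != set(derivative.scores):
        raise SchemaError(
            f"protein sets differ: {sorted(parent.scores)} vs "
            f"{sorted(derivative.scores)}"
        )
    rates = {pid: change_rate(parent.scores[pid], derivative.scores[pid])
             for pid in parent.scores}
    all_weaker = len(rates) > 0 and all(r < 0 for r in rates.values())
    return DockingChange(compound_id=derivative.compound_id, rates=rates,
                         all_weaker=all_weaker)
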