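"""Synthetic multi-receptor toxicity panels and derivative scenarios.

The generator emulates the numeric regime of an acute-toxicity panel
for strongly toxic lipophilic compounds: EC50/LC50 concentrations
spanning roughly five orders of magnitude, all strictly below the
1 mg/L classification boundary, with correlated receptor sensitivities
(one receptor — the crustacean in the reference panel — is consistently
the most sensitive).  Concentrations follow

    value(k, i) = 10 ** (p_k + s_i + eps),   eps ~ N(0, noise_sd),

with compound potencies p_k uniform on a log10 range, fixed per-receptor
offsets s_i, and log-normal noise, clipped (by default) to stay strictly
below the reference boundary.  Derivatives shift a parent's profile by a
log10 amount per receptor (positive shift = higher EC50 = less toxic).
No structure-activity relationship is modelled; only the numbers the
pipeline consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .panel import Receptor, ToxicityPanel
from .properties import BarrierInput, PropertyRecord

__all__ = [
    "SimConfig",
    "DerivativeSet",
    "PropertyCase",
    "generate_panel",
    "generate_derivatives",
    "generate_property_records",
]

#: Default per-receptor log10 offsets, mirroring the sensitivity ordering
#: of the reference acute-toxicity panel: mysid most sensitive, green
#: algae next, daphnid and fish similar and least sensitive.
DEFAULT_OFFSETS = {
    "green_algae": -0.35,
    "daphnid": 0.33,
    "mysid": -0.55,
    "fish": 0.28,
}

# Keep generated values strictly below the reference boundary: cap the
# exponent at log10(reference) minus this margin.
_CLIP_MARGIN = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the generator.

    ``receptor_offsets`` maps receptor id -> log10 offset; ``potency_range``
    is the uniform log10 mg/L range of compound potencies; ``noise_sd``
    the log10 noise standard deviation; ``derivative_effects`` the log10
    shifts applied when deriving child panels (positive = less toxic).
    """

    n_compounds: int = 14
    receptor_offsets: dict = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    potency_range: tuple = (-5.0, -0.2)
    noise_sd: float = 0.15
    seed: int = 0
    derivative_effects: tuple = (0.25, 0.5, 1.0)
    reference_value: float = 1.0
    clip: bool = True

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if not self.receptor_offsets:
            raise ConfigError("at least one receptor offset is required")
        lo, hi = self.potency_range
        if not (lo < hi):
            raise ConfigError(f"potency_range must be an interval, got {self.potency_range}")
        if self.clip is True and hi >= math.log10(self.reference_value):
            raise ConfigError(
                "potency_range upper bound must lie below log10(reference) "
                "so generated values stay under the classification boundary"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _clip_exponent(expo: np.ndarray, config: SimConfig) -> np.ndarray:
    if not config.clip:
        return expo
    return np.minimum(expo, math.log10(config.reference_value) - _CLIP_MARGIN)


def generate_panel(config: SimConfig = SimConfig(), rng=None) -> ToxicityPanel:
    """Draw one compound x receptor panel; bit-reproducible from the seed."""
    rng = config.rng() if rng is None else rng
    rids = list(config.receptor_offsets)
    offsets = np.array([config.receptor_offsets[r] for r in rids])
    lo, hi = config.potency_range
    potency = rng.uniform(lo, hi, size=config.n_compounds)
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_compounds, len(rids)))
    expo = potency[:, None] + offsets[None, :] + noise
    expo = _clip_exponent(expo, config)
    compounds = [f"C{k + 1:02d}" for k in range(config.n_compounds)]
    receptors = [Receptor(id=r, endpoint="EC50") for r in rids]
    return ToxicityPanel(10.0 ** expo, compounds=compounds, receptors=receptors)


@dataclass(frozen=True)
class DerivativeSet:
    """Derivative panel plus the derivative -> parent mapping."""

    panel: ToxicityPanel
    parent_of: dict


def generate_derivatives(panel: ToxicityPanel, config: SimConfig = SimConfig(),
                         rng=None, jitter_sd: float = 0.0) -> DerivativeSet:
    """Derive shifted copies of every compound in ``panel``.

    Each effect in ``config.derivative_effects`` produces one derivative
    per parent with value = parent * 10**shift at every receptor
    (optionally jittered per receptor by N(0, jitter_sd) in log10 units),
    clipped below the reference boundary when clipping is on.
    """
    rng = config.rng() if rng is None else rng
    values = panel.values
    rows, index, parent_of = [], [], {}
    for parent in values.index:
        base = np.log10(values.loc[parent].to_numpy())
        for effect in config.derivative_effects:
            did = f"{parent}+{effect:g}"
            shift = effect + (rng.normal(0.0, jitter_sd, size=base.size)
                              if jitter_sd > 0 else 0.0)
            rows.append(_clip_exponent(base + shift, config))
            index.append(did)
            parent_of[did] = parent
    dpanel = ToxicityPanel(10.0 ** np.array(rows), compounds=index,
                           receptors=list(panel.receptors))
    return DerivativeSet(panel=dpanel, parent_of=parent_of)


@dataclass(frozen=True)
class PropertyCase:
    """One parent/derivative property pair built to land on a requested
    side of each screening boundary, plus a barrier input."""

    label: str
    parent: PropertyRecord
    derivative: PropertyRecord
    barrier: BarrierInput
    requested: dict


#: (label, energy rate %, gap rate %, frequency cm^-1, half-life h) —
#: one case on each side of every decision boundary: the 5% energy
#: limit, the frequency sign, and the 48 h persistence threshold.
_BOUNDARY_CASES = (
    ("energy-drop", -6.0, -5.0, 15.0, 14.0),
    ("energy-just-under-limit", 4.99, -1.0, 10.0, 20.0),
    ("energy-over-limit", 5.01, -1.0, 10.0, 20.0),
    ("imaginary-frequency", -1.0, 0.5, -1.0, 20.0),
    ("persistent", 1.0, 0.0, 8.0, 49.0),
    ("just-not-persistent", 1.0, 0.0, 8.0, 47.0),
)


def generate_property_records(config: SimConfig = SimConfig()) -> list:
    """Parent/derivative property pairs exercising every rule boundary.

    Base descriptor values are drawn from the seeded stream; the
    derivative is then constructed to realize each requested change rate
    exactly, so tests can assert which side of a threshold each case
    falls on without re-deriving the arithmetic.
    """
    rng = config.rng()
    cases = []
    for label, e_rate, g_rate, freq, hl in _BOUNDARY_CASES:
        e0 = -float(rng.uniform(900.0, 1500.0))  # hartree, typical diester
        gap0 = float(rng.uniform(5.0, 6.0))  # eV
        kow0 = float(rng.uniform(7.0, 10.0))
        koa0 = float(rng.uniform(10.0, 14.0))
        hl0 = float(rng.uniform(10.0, 13.0))
        parent = PropertyRecord(
            compound_id=f"P-{label}", total_energy=e0, energy_gap=gap0,
            frequency=float(rng.uniform(5.0, 20.0)),
            log_kow=kow0, log_koa=koa0, half_life=hl0,
        )
        derivative = PropertyRecord(
            compound_id=f"D-{label}",
            total_energy=e0 * (1 + e_rate / 100.0),
            energy_gap=gap0 * (1 + g_rate / 100.0),
            frequency=freq,
            log_kow=kow0 * (1 - float(rng.uniform(0.05, 0.25))),
            log_koa=koa0 * (1 - float(rng.uniform(0.05, 0.15))),
            half_life=hl,
        )
        reactants = tuple(-float(rng.uniform(400.0, 800.0)) for _ in range(2))
        barrier = BarrierInput(
            e_ts=sum(reactants) + float(rng.uniform(0.001, 0.05)),
            e_reactants=reactants,
        )
        cases.append(PropertyCase(
            label=label, parent=parent, derivative=derivative, barrier=barrier,
            requested={"energy_change": e_rate, "gap_change": g_rate,
                       "frequency": freq, "half_life": hl},
        ))
    return cases
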