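"""Built-in reference datasets for the phthalate screening workflow.

These small tables are the published inputs of the workflow this package
implements: a 14-compound x 4-receptor acute-toxicity panel predicted by
an ECOSAR-class QSAR tool, the pharmacophore-estimated activity values
of 22 monosubstituted derivatives of DINP and DEHP, per-receptor
negative-log toxicity predictions for the screened derivatives, quantum
and POPs descriptors, docking scores against four receptor proteins, and
primary-metabolism energy barriers.  They let every stage of the
pipeline run end-to-end without any external download and serve as the
worked example in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model_metrics import CompoundFitRow, ModelStats
from .panel import PToxicityPanel, Receptor, ToxicityPanel, read_receptor_schema
from .properties import BarrierInput, DockingScores, PropertyRecord
from .screening import DerivativeRecord

__all__ = [
    "load_receptors",
    "load_acute_toxicity_panel",
    "load_derivative_records",
    "load_derivative_ptox",
    "load_receptor_model_ptox",
    "load_functional_properties",
    "load_pops_properties",
    "load_docking_scores",
    "load_metabolite_panel",
    "load_reaction_barriers",
    "load_pharmacophore_models",
    "load_pharmacophore_fit",
    "load_compound_names",
]

_DATA = resources.files("greytox") / "data"


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, **kw)


def load_receptors() -> list[Receptor]:
    """The four aquatic receptors with their endpoints (mg/L)."""
    with resources.as_file(_DATA / "receptors.yaml") as path:
        return read_receptor_schema(path)


def load_acute_toxicity_panel() -> ToxicityPanel:
    """14 phthalate diesters x 4 receptors, acute EC50/LC50 in mg/L."""
    frame = _read("pae_acute_toxicity.csv", index_col=0)
    return ToxicityPanel(frame, receptors=load_receptors())


def load_derivative_records() -> list[DerivativeRecord]:
    """22 monosubstituted derivatives with pharmacophore-estimated
    comprehensive-characterization values, paired with their parents."""
    frame = _read("pae_derivative_activity.csv")
    return [
        DerivativeRecord(
            parent_id=r.parent, derivative_id=r.derivative,
            substituent=r.substituent, estimated_parent=r.parent_value,
            estimated_derivative=r.derivative_value,
        )
        for r in frame.itertuples()
    ]


def _split_ptox(name: str):
    frame = _read(name)
    frame = frame.set_index("compound")
    parent_col = frame.pop("parent")
    is_parent = parent_col.isna() | (parent_col == "")
    receptors = [Receptor(id=c) for c in frame.columns]
    parents = PToxicityPanel(frame[is_parent], receptors=receptors)
    derivatives = PToxicityPanel(frame[~is_parent], receptors=receptors)
    parent_of = parent_col[~is_parent].astype(str).to_dict()
    return parents, derivatives, parent_of


def load_derivative_ptox():
    """QSAR-predicted pEC50/pLC50 panels for the 16 stage-1 survivors.

    Returns ``(parents, derivatives, parent_of)``: two
    :class:`PToxicityPanel` and the derivative -> parent mapping.
    """
    return _split_ptox("pae_derivative_ptox.csv")


def load_receptor_model_ptox():
    """Single-receptor pharmacophore-model toxicity predictions
    (negative-log scale) for derivatives; same return shape as
    :func:`load_derivative_ptox`."""
    return _split_ptox("pae_receptor_model_ptox.csv")


def _property_records(name: str, mapper):
    frame = _read(name)
    records, parent_of = {}, {}
    for r in frame.itertuples():
        records[r.compound] = mapper(r)
        if isinstance(r.parent, str) and r.parent:
            parent_of[r.compound] = r.parent
    return records, parent_of


def load_functional_properties():
    """Total energy (a.u.), HOMO-LUMO gap (eV) and lowest frequency
    (cm^-1) for the two screened derivatives and their parents.

    Returns ``(records, parent_of)``.
    """
    return _property_records(
        "functional_properties.csv",
        lambda r: PropertyRecord(
            compound_id=r.compound, total_energy=r.total_energy_au,
            energy_gap=r.energy_gap_ev, frequency=r.frequency_cm1,
        ),
    )


def load_pops_properties():
    """log Koa, log Kow and atmospheric half-life (h); ``(records, parent_of)``."""
    return _property_records(
        "pops_properties.csv",
        lambda r: PropertyRecord(
            compound_id=r.compound, log_koa=r.log_koa, log_kow=r.log_kow,
            half_life=r.half_life_hr,
        ),
    )


def load_docking_scores():
    """Docking scores against the four receptor proteins (SOD, glutathione
    peroxidase, chitinase, PPAR-alpha); ``(records, parent_of)``."""
    frame = _read("docking_scores.csv")
    proteins = [c for c in frame.columns if c not in ("compound", "parent")]
    records, parent_of = {}, {}
    for _, row in frame.iterrows():
        cid = row["compound"]
        records[cid] = DockingScores(
            compound_id=cid, scores={p: float(row[p]) for p in proteins},
        )
        parent = row["parent"]
        if isinstance(parent, str) and parent:
            parent_of[cid] = parent
    return records, parent_of


def load_metabolite_panel():
    """Acute toxicity (mg/L) of the primary monoester metabolites;
    returns ``(parents, derivatives, parent_of)`` as ToxicityPanels."""
    frame = _read("metabolite_toxicity.csv").set_index("compound")
    parent_col = frame.pop("parent")
    is_parent = parent_col.isna() | (parent_col == "")
    receptors = [Receptor(id=c) for c in frame.columns]
    parents = ToxicityPanel(frame[is_parent], receptors=receptors)
    derivatives = ToxicityPanel(frame[~is_parent], receptors=receptors)
    return parents, derivatives, parent_col[~is_parent].astype(str).to_dict()


def load_reaction_barriers():
    """Primary-metabolism reaction energy barriers (kJ/mol);
    ``(barriers, parent_of)`` with barriers as plain floats."""
    frame = _read("reaction_barriers.csv")
    barriers, parent_of = {}, {}
    for r in frame.itertuples():
        barriers[r.compound] = float(r.barrier_kj_mol)
        if isinstance(r.parent, str) and r.parent:
            parent_of[r.compound] = r.parent
    return barriers, parent_of


def load_pharmacophore_models() -> dict[str, ModelStats]:
    """Cost/fit statistics of the five candidate pharmacophore models."""
    frame = _read("pharmacophore_models.csv")
    return {
        r.model: ModelStats(
            model_id=r.model, total_cost=r.total_cost, fixed_cost=r.fixed_cost,
            rms=r.rms, correlation=r.correlation, configuration=r.configuration,
            features=tuple(r.features.split(";")),
        )
        for r in frame.itertuples()
    }


def load_pharmacophore_fit() -> list[CompoundFitRow]:
    """Per-compound fit/estimated/active/error rows of the selected model
    (training and test sets); the stored error column is the published
    display value and is kept alongside the recomputable ratio."""
    frame = _read("pharmacophore_fit.csv")
    return [
        CompoundFitRow(
            compound_id=r.compound, fit_value=r.fit_value,
            estimated=r.estimated, active=r.active, error=r.error,
        )
        for r in frame.itertuples()
    ]


def load_compound_names() -> dict[str, str]:
    """Optional abbreviation -> full chemical name lookup; panels may
    legitimately contain ids absent from it."""
    frame = _read("pae_names.csv")
    return dict(zip(frame.abbreviation, frame.full_name))
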