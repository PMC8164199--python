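"""Compound-by-receptor toxicity panels.

A :class:`ToxicityPanel` holds positive acute-toxicity concentrations
(EC50/LC50, mg/L) for a set of compounds against a set of aquatic
receptors.  :class:`PToxicityPanel` holds the same table on the
negative-log10 scale (pEC50/pLC50), where larger means more toxic.
Panels are thin, validated wrappers around a pandas DataFrame whose index
is the compound id and whose columns are receptor ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import PanelValidationError, SchemaError

__all__ = [
    "Receptor",
    "Finding",
    "ToxicityPanel",
    "PToxicityPanel",
    "load_panel",
    "write_panel",
    "neg_log10",
    "validate_panel",
    "read_receptor_schema",
]


@dataclass(frozen=True)
class Receptor:
    """A receptor organism column: id, display name and toxicity endpoint.

    ``endpoint`` is the duration-qualified label (e.g. ``96-EC50`` for a
    96 h algal growth-inhibition EC50); ``units`` is fixed to mg/L, the
    scale all panels share.
    """

    id: str
    endpoint: str = "EC50"
    name: str = ""
    units: str = "mg/L"

    def __post_init__(self):
        if not self.id:
            raise SchemaError("receptor id must be non-empty")
        if not self.endpoint:
            raise SchemaError(f"receptor {self.id!r}: endpoint must be non-empty")


@dataclass(frozen=True)
class Finding:
    """One validation finding: which cell, which rule, and why."""

    rule: str
    message: str
    compound: str | None = None
    receptor: str | None = None

    def __str__(self):
        where = ""
        if self.compound is not None or self.receptor is not None:
            where = f" [{self.compound or '*'}/{self.receptor or '*'}]"
        return f"{self.rule}{where}: {self.message}"


class _BasePanel:
    """Shared frame handling for concentration and negative-log panels."""

    _kind = "panel"

    def __init__(self, values, compounds=None, receptors=None, *, validate=True):
        if isinstance(values, pd.DataFrame):
            frame = values.copy()
            if compounds is not None:
                frame.index = list(compounds)
            if receptors is not None and not isinstance(receptors[0], Receptor):
                raise SchemaError("receptors must be Receptor instances")
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 2:
                raise SchemaError(f"{self._kind} values must be 2-D")
            if compounds is None or receptors is None:
                raise SchemaError(
                    f"{self._kind}: compounds and receptors are required "
                    "when values are not a DataFrame"
                )
            frame = pd.DataFrame(
                arr, index=list(compounds), columns=[r.id for r in receptors]
            )
        if receptors is None:
            receptors = [Receptor(id=str(c)) for c in frame.columns]
        if [r.id for r in receptors] != list(frame.columns):
            frame = frame[[r.id for r in receptors]]
        frame.index = frame.index.astype(str)
        frame.index.name = "compound"
        self._frame = frame.astype(float)
        self.receptors = tuple(receptors)
        if validate:
            findings = self.validate()
            if findings:
                raise PanelValidationError(findings)

    # -- accessors ---------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        """The underlying compound x receptor DataFrame (copy-safe view)."""
        return self._frame

    @property
    def compounds(self) -> list[str]:
        return list(self._frame.index)

    @property
    def receptor_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def row(self, compound: str) -> pd.Series:
        return self._frame.loc[compound]

    def to_numpy(self) -> np.ndarray:
        return self._frame.to_numpy()

    def __repr__(self):
        n, m = self.shape
        return f"<{type(self).__name__} {n} compounds x {m} receptors>"

    # -- validation --------------------------------------------------
    def validate(self) -> list[Finding]:
        findings = []
        if self._frame.shape[0] < 1 or self._frame.shape[1] < 1:
            findings.append(
                Finding("shape", "panel needs at least 1 compound and 1 receptor")
            )
            return findings
        dup = self._frame.index[self._frame.index.duplicated()].unique()
        for c in dup:
            findings.append(
                Finding("unique-compound", f"compound id {c!r} appears more than once",
                        compound=str(c))
            )
        rids = [r.id for r in self.receptors]
        if len(set(rids)) != len(rids):
            findings.append(Finding("unique-receptor", "receptor ids must be unique"))
        for c in self._frame.index:
            for r in self._frame.columns:
                v = self._frame.at[c, r]
                if isinstance(v, pd.Series):  # duplicated index
                    continue
                findings.extend(self._check_cell(str(c), str(r), v))
        return findings

    def _check_cell(self, compound, receptor, v):
        if not math.isfinite(v):
            yield Finding("finite", f"value {v!r} is not finite",
                          compound=compound, receptor=receptor)


class ToxicityPanel(_BasePanel):
    """Positive EC50/LC50 concentrations (mg/L) per compound and receptor.

    Invariants: all values strictly positive and finite, no missing cells,
    unique compound and receptor ids.  Construction validates by default;
    pass ``validate=False`` to build an intentionally broken panel and
    inspect it with :func:`validate_panel`.
    """

    _kind = "toxicity panel"

    def _check_cell(self, compound, receptor, v):
        if not math.isfinite(v):
            yield Finding("finite", f"value {v!r} is not finite",
                          compound=compound, receptor=receptor)
        elif v <= 0:
            yield Finding("positive", f"value {v!r} is not strictly positive",
                          compound=compound, receptor=receptor)


class PToxicityPanel(_BasePanel):
    """Negative-log10 toxicity values (pEC50/pLC50, dimensionless).

    Same shape and keying as the source :class:`ToxicityPanel`; values may
    take either sign but must be finite.
    """

    _kind = "pToxicity panel"


def read_receptor_schema(path) -> list[Receptor]:
    """Read a YAML receptor schema: mapping receptor id -> {name, endpoint}."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "receptors" not in doc:
        raise SchemaError(f"{path}: expected a top-level 'receptors' mapping")
    receptors = []
    for rid, meta in doc["receptors"].items():
        meta = meta or {}
        receptors.append(
            Receptor(id=str(rid), endpoint=str(meta.get("endpoint", "EC50")),
                     name=str(meta.get("name", "")))
        )
    return receptors


def load_panel(path, receptors=None, *, cls=ToxicityPanel):
    """Load a panel CSV: first column compound id, remaining columns receptors.

    ``receptors`` may be a list of :class:`Receptor`, a path to a YAML
    schema, or None (ids taken from the header, default endpoint labels).
    Raises :class:`SchemaError` for structural problems and
    :class:`PanelValidationError` (with cell-level findings) for invalid
    values.  Row order of the file is preserved.
    """
    try:
        frame = pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if frame.shape[1] < 2:
        raise SchemaError(f"{path}: need a compound column plus at least one receptor")
    frame = frame.set_index(frame.columns[0])

    if isinstance(receptors, (str, bytes)) or hasattr(receptors, "__fspath__"):
        receptors = read_receptor_schema(receptors)
    if receptors is not None:
        missing = [r.id for r in receptors if r.id not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing receptor column(s) {missing}")
        frame = frame[[r.id for r in receptors]]

    bad = [c for c in frame.columns
           if not pd.to_numeric(frame[c], errors="coerce").notna().all()]
    if bad:
        raise SchemaError(f"{path}: non-numeric values in column(s) {bad}")
    return cls(frame.astype(float), receptors=receptors)


def write_panel(panel: _BasePanel, path) -> None:
    """Write a panel back to the CSV layout :func:`load_panel` reads."""
    panel.values.to_csv(path, index=True)


def validate_panel(panel: _BasePanel) -> list[Finding]:
    """Return all invariant violations of ``panel`` (empty list if valid)."""
    return panel.validate()


def neg_log10(panel: ToxicityPanel) -> PToxicityPanel:
    """Transform mg/L concentrations to pEC50/pLC50 = -log10(value).

    Strictly decreasing: lower concentrations (more potent) map to larger
    negative-log values.
    """
    findings = [f for f in panel.validate() if f.rule in ("positive", "finite")]
    if findings:
        raise PanelValidationError(findings)
    return PToxicityPanel(
        -np.log10(panel.values), receptors=list(panel.receptors)
    )
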