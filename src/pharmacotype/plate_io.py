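"""Plate-reader I/O and screening configuration.

On-disk formats
---------------
Plate CSV (long format, one row per well)::

    pdo_id,drug_id,concentration_molar,replicate,s1,s2

Control wells use ``drug_id=CONTROL`` and an empty ``concentration_molar``.
``s1`` is the pre-lysis (dead-cell) luminescence, ``s2`` the post-lysis
(total) luminescence, both in RLU.

Panel JSON maps ``drug_id`` to its list of molar concentrations; regimen
JSON maps regimen name to its list of screened component drugs.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import PanelError, PlateFormatError, RegimenError

CONTROL = "CONTROL"

#: The five standard-of-care drugs of the small-scale screen.
DEFAULT_DRUGS = ("gemcitabine", "paclitaxel", "irinotecan", "5-FU", "oxaliplatin")

#: Default dose range: ten points spanning 13 nM to 50 uM, log-spaced.
DEFAULT_CMIN = 1.3e-8
DEFAULT_CMAX = 5.0e-5

#: Shipped regimen -> component-drug map. Leucovorin / the nab carrier are
#: modulators that were never screened and are deliberately absent.
DEFAULT_REGIMENS: Mapping[str, tuple[str, ...]] = {
    "FOLFIRINOX": ("5-FU", "irinotecan", "oxaliplatin"),
    "gemcitabine/nab-paclitaxel": ("gemcitabine", "paclitaxel"),
    "gemcitabine": ("gemcitabine",),
    "nal-iri/5-FU": ("irinotecan", "5-FU"),
    "5-FU/nab-paclitaxel": ("5-FU", "paclitaxel"),
}

PLATE_COLUMNS = ("pdo_id", "drug_id", "concentration_molar", "replicate", "s1", "s2")


def default_concentrations(n: int = 10, cmin: float = DEFAULT_CMIN, cmax: float = DEFAULT_CMAX) -> list[float]:
    """Log-spaced concentration ladder (mol/L), ascending."""
    lo, hi = math.log10(cmin), math.log10(cmax)
    return [10 ** (lo + (hi - lo) * i / (n - 1)) for i in range(n)]


@dataclass(frozen=True)
class DosePanel:
    """Concentration ladder for one drug.

    Concentrations are molar (mol/L), strictly ascending and positive.
    """

    drug_id: str
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) == 0:
            raise PanelError(f"{self.drug_id}: empty concentration list")
        if any(x <= 0 for x in c):
            raise PanelError(f"{self.drug_id}: concentrations must be positive")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise PanelError(f"{self.drug_id}: concentrations must be strictly increasing")

    @classmethod
    def default(cls, drug_id: str) -> "DosePanel":
        return cls(drug_id, tuple(default_concentrations()))

    def contains(self, concentration: float, rtol: float = 1e-6) -> bool:
        return any(math.isclose(concentration, c, rel_tol=rtol) for c in self.concentrations)


def default_panels(drugs: Sequence[str] = DEFAULT_DRUGS) -> dict[str, DosePanel]:
    return {d: DosePanel.default(d) for d in drugs}


@dataclass(frozen=True)
class WellMeasurement:
    """One well of the two-signal cytotoxicity read-out."""

    pdo_id: str
    drug_id: str
    concentration: float | None  # mol/L, None for control wells
    replicate: int
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise PlateFormatError(
                f"{self.pdo_id}/{self.drug_id}: negative luminescence (s1={self.s1}, s2={self.s2})"
            )
        if self.replicate < 1:
            raise PlateFormatError(f"{self.pdo_id}/{self.drug_id}: replicate index must be >= 1")

    @property
    def is_control(self) -> bool:
        return self.drug_id == CONTROL

    @property
    def net_signal(self) -> float:
        """Live-cell luminescence (post-lysis total minus dead-cell signal)."""
        return self.s2 - self.s1


@dataclass(frozen=True)
class RegimenMap:
    """A combination regimen and the screened drugs composing it."""

    regimen_name: str
    component_drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.component_drugs:
            raise RegimenError(f"regimen {self.regimen_name!r}: empty component list")


def read_plate(path: str | Path, panels: Mapping[str, DosePanel] | None = None) -> list[WellMeasurement]:
    """Read a long-format plate CSV into well measurements.

    Validates header, luminescence signs, presence of control wells for
    every PDO, and (if ``panels`` given) that each concentration belongs to
    the declared panel of its drug. Errors carry the 1-based data row.
    """
    path = Path(path)
    wells: list[WellMeasurement] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        got = tuple(reader.fieldnames or ())
        missing = [c for c in PLATE_COLUMNS if c not in got]
        if missing:
            raise PlateFormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            drug = row["drug_id"].strip()
            raw_conc = row["concentration_molar"].strip()
            try:
                conc = None if raw_conc == "" else float(raw_conc)
                rep = int(row["replicate"])
                s1 = float(row["s1"])
                s2 = float(row["s2"])
            except ValueError as exc:
                raise PlateFormatError(f"{path} row {i}: unparsable field ({exc})") from None
            if drug != CONTROL and conc is None:
                raise PlateFormatError(f"{path} row {i}: drug well without concentration")
            if drug == CONTROL and conc is not None:
                raise PlateFormatError(f"{path} row {i}: control well with a concentration")
            try:
                well = WellMeasurement(row["pdo_id"].strip(), drug, conc, rep, s1, s2)
            except PlateFormatError as exc:
                raise PlateFormatError(f"{path} row {i}: {exc}") from None
            if panels is not None and not well.is_control:
                panel = panels.get(drug)
                if panel is None:
                    raise PanelError(f"{path} row {i}: drug {drug!r} not in declared panel")
                if not panel.contains(conc):
                    raise PanelError(
                        f"{path} row {i}: concentration {conc:g} not in panel of {drug!r}"
                    )
            wells.append(well)
    pdos_with_drug = {w.pdo_id for w in wells if not w.is_control}
    pdos_with_ctrl = {w.pdo_id for w in wells if w.is_control}
    orphans = sorted(pdos_with_drug - pdos_with_ctrl)
    if orphans:
        raise PlateFormatError(f"{path}: no control wells for PDO(s) {', '.join(orphans)}")
    return wells


def write_plate(wells: Iterable[WellMeasurement], path: str | Path) -> None:
    """Write wells back to the plate CSV format (round-trips read_plate)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for w in wells:
            conc = "" if w.concentration is None else repr(w.concentration)
            writer.writerow([w.pdo_id, w.drug_id, conc, w.replicate, repr(w.s1), repr(w.s2)])


def read_panels(path: str | Path) -> dict[str, DosePanel]:
    """Read a drug-panel JSON ``{drug_id: [molar concentrations]}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {drug: DosePanel(drug, tuple(concs)) for drug, concs in raw.items()}


def write_panels(panels: Mapping[str, DosePanel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({d: list(p.concentrations) for d, p in panels.items()}, fh, indent=1)


def read_regimens(path: str | Path, screened_drugs: Iterable[str] | None = None) -> dict[str, RegimenMap]:
    """Read a regimen JSON mapping name -> component drug list.

    With ``screened_drugs`` given, any component outside the screened panel
    rejects the file, naming the offending regimen.
    """
    with open(path) as fh:
        raw = json.load(fh)
    regimens = {name: RegimenMap(name, tuple(drugs)) for name, drugs in raw.items()}
    if screened_drugs is not None:
        screened = set(screened_drugs)
        for name, reg in regimens.items():
            unknown = [d for d in reg.component_drugs if d not in screened]
            if unknown:
                raise RegimenError(
                    f"regimen {name!r}: component(s) {', '.join(unknown)} not in screened panel"
                )
    return regimens


def write_regimens(regimens: Mapping[str, RegimenMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({n: list(r.component_drugs) for n, r in regimens.items()}, fh, indent=1)


def default_regimens() -> dict[str, RegimenMap]:
    return {n: RegimenMap(n, drugs) for n, drugs in DEFAULT_REGIMENS.items()}
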