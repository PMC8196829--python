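"""Viability normalisation and dose-response AUC.

Percent viability at each dose is the net luminescence of the drug wells
relative to the net luminescence of the control wells on the same plate:
``100 * mean_drug(s2 - s1) / mean_ctrl(s2 - s1)``. The curve is then
integrated with the trapezoidal rule on a log10-concentration abscissa, so
the AUC is invariant to the concentration unit and matches the plotted
dose axis. Viability is not capped at 100% (stimulated wells keep their
signal); negative net drug signals clip to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, PharmacotypeError, PlateFormatError
from .plate_io import DosePanel, WellMeasurement


@dataclass(frozen=True)
class DoseResponseProfile:
    """One PDO x drug viability curve on the declared panel."""

    pdo_id: str
    drug_id: str
    concentrations: tuple[float, ...]  # mol/L, ascending
    viabilities: tuple[float, ...]  # percent, replicate-averaged
    replicate_viabilities: tuple[tuple[float, ...], ...]  # per-point raw replicates

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.viabilities):
            raise PharmacotypeError("profile: concentration/viability length mismatch")
        c = self.concentrations
        if any(b <= a for a, b in zip(c, c[1:])):
            raise PharmacotypeError("profile: concentrations must be strictly increasing")


@dataclass(frozen=True)
class AUCRecord:
    pdo_id: str
    drug_id: str
    auc: float  # percent x log10-concentration units


def compute_viability(
    wells: Iterable[WellMeasurement],
    panel: DosePanel,
    pdo_id: str | None = None,
) -> DoseResponseProfile:
    """Normalise one PDO x drug set of wells against its plate controls.

    ``wells`` holds the drug wells of a single drug plus the control wells
    of the same PDO plate. Replicates are averaged at the viability level.
    """
    wells = list(wells)
    controls = [w for w in wells if w.is_control]
    drug_wells = [w for w in wells if not w.is_control]
    if pdo_id is not None:
        controls = [w for w in controls if w.pdo_id == pdo_id]
        drug_wells = [w for w in drug_wells if w.pdo_id == pdo_id]
    if not drug_wells:
        raise PlateFormatError("no drug wells supplied")
    pdo_ids = {w.pdo_id for w in drug_wells}
    drug_ids = {w.drug_id for w in drug_wells}
    if len(pdo_ids) > 1 or len(drug_ids) > 1:
        raise PlateFormatError(
            f"expected one PDO x drug, got PDOs {sorted(pdo_ids)} drugs {sorted(drug_ids)}"
        )
    pdo = pdo_ids.pop()
    drug = drug_ids.pop()
    controls = [w for w in controls if w.pdo_id == pdo]
    if not controls:
        raise PlateFormatError(f"{pdo}: no control wells")
    ctrl_net = float(np.mean([w.net_signal for w in controls]))
    if ctrl_net <= 0:
        raise DegenerateControlError(f"{pdo}: degenerate control (net signal {ctrl_net:g} <= 0)")

    by_conc: dict[float, list[float]] = {}
    for w in drug_wells:
        by_conc.setdefault(w.concentration, []).append(w.net_signal)
    missing = [c for c in panel.concentrations if not any(np.isclose(c, k) for k in by_conc)]
    if missing:
        raise PlateFormatError(
            f"{pdo}/{drug}: panel concentration(s) missing: {', '.join(f'{c:g}' for c in missing)}"
        )

    viab: list[float] = []
    reps: list[tuple[float, ...]] = []
    for c in panel.concentrations:
        key = next(k for k in by_conc if np.isclose(c, k))
        rep_v = []
        for net in by_conc[key]:
            if net < 0:
                warnings.warn(
                    f"{pdo}/{drug} at {c:g} M: negative net signal {net:g} clipped to 0",
                    stacklevel=2,
                )
                net = 0.0
            rep_v.append(100.0 * net / ctrl_net)
        viab.append(float(np.mean(rep_v)))
        reps.append(tuple(rep_v))
    return DoseResponseProfile(pdo, drug, tuple(panel.concentrations), tuple(viab), tuple(reps))


def profiles_from_plate(
    wells: Iterable[WellMeasurement], panels: Mapping[str, DosePanel]
) -> list[DoseResponseProfile]:
    """Split a multi-PDO, multi-drug well collection into per-curve profiles."""
    wells = list(wells)
    controls_by_pdo: dict[str, list[WellMeasurement]] = {}
    drug_groups: dict[tuple[str, str], list[WellMeasurement]] = {}
    for w in wells:
        if w.is_control:
            controls_by_pdo.setdefault(w.pdo_id, []).append(w)
        else:
            drug_groups.setdefault((w.pdo_id, w.drug_id), []).append(w)
    profiles = []
    for (pdo, drug), group in sorted(drug_groups.items()):
        ctrl = controls_by_pdo.get(pdo)
        if not ctrl:
            raise PlateFormatError(f"{pdo}: no control wells")
        profiles.append(compute_viability(group + ctrl, panels[drug]))
    return profiles


def compute_auc(profile: DoseResponseProfile) -> AUCRecord:
    """Trapezoidal AUC of percent viability over log10(concentration)."""
    c = np.asarray(profile.concentrations, dtype=float)
    v = np.asarray(profile.viabilities, dtype=float)
    if c.size < 2:
        raise PharmacotypeError(f"{profile.pdo_id}/{profile.drug_id}: need >= 2 concentrations")
    if np.any(np.diff(c) <= 0):
        raise PharmacotypeError(f"{profile.pdo_id}/{profile.drug_id}: unsorted/duplicate concentrations")
    auc = float(np.trapezoid(v, np.log10(c)))
    return AUCRecord(profile.pdo_id, profile.drug_id, auc)


class AUCLibrary:
    """PDO x drug matrix of AUC values with explicit missingness (NaN)."""

    def __init__(self, matrix: pd.DataFrame):
        self.matrix = matrix  # index: pdo_id, columns: drug_id

    @property
    def pdo_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def drug_vector(self, drug_id: str) -> pd.Series:
        """Non-missing AUCs for one drug, indexed by PDO."""
        return self.matrix[drug_id].dropna()

    def drug_n(self, drug_id: str) -> int:
        return int(self.matrix[drug_id].notna().sum())

    def __len__(self) -> int:
        return len(self.matrix.index)

    def to_records(self) -> pd.DataFrame:
        long = self.matrix.stack().rename("auc").reset_index()
        long.columns = ["pdo_id", "drug_id", "auc"]
        return long

    def to_tsv(self, path: str | Path) -> None:
        self.to_records().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AUCLibrary":
        df = pd.read_csv(path, sep="\t")
        return build_library(
            [AUCRecord(r.pdo_id, r.drug_id, float(r.auc)) for r in df.itertuples()]
        )


def build_library(records: Sequence[AUCRecord]) -> AUCLibrary:
    """Assemble AUC records into a PDO x drug matrix; duplicates are errors."""
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.pdo_id, r.drug_id)
        if key in seen:
            raise PharmacotypeError(f"duplicate (pdo, drug) pair: {key}")
        seen.add(key)
    if not records:
        return AUCLibrary(pd.DataFrame())
    df = pd.DataFrame(
        [(r.pdo_id, r.drug_id, r.auc) for r in records],
        columns=["pdo_id", "drug_id", "auc"],
    )
    matrix = df.pivot(index="pdo_id", columns="drug_id", values="auc")
    matrix.index.name = "pdo_id"
    matrix.columns.name = "drug_id"
    return AUCLibrary(matrix)
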