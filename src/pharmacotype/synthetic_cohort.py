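"""Synthetic drug-screen plates and clinical cohorts with known ground truth.

Two generators (Hill-curve plates; outcome/survival cohorts) driven by one
config and seed, plus a deterministic packaged fixture whose category
counts reproduce the published cohort aggregates so the cohort statistics
can be recomputed without any external data.

Randomness is split into independent streams per artifact (archetypes,
plate noise, outcomes, censoring, PFS) so regenerating one artifact leaves
the others byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PharmacotypeError
from .plate_io import (
    DEFAULT_DRUGS,
    DEFAULT_REGIMENS,
    DosePanel,
    WellMeasurement,
    default_panels,
)

ARCHETYPES = ("high", "intermediate", "low")
ARCHETYPE_SCORE = {"high": 1, "intermediate": 2, "low": 3}

# log10 of the geometric mid-dose of the default 13 nM - 50 uM ladder
_LOG_MID = (math.log10(1.3e-8) + math.log10(5.0e-5)) / 2.0

#: Archetype IC50s at 0.1x, 1x and 10x the panel's geometric mid-dose.
DEFAULT_LOG_IC50 = {"high": _LOG_MID - 1.0, "intermediate": _LOG_MID, "low": _LOG_MID + 1.0}

_STREAMS = {"archetypes": 0, "plates": 1, "outcomes": 2, "censoring": 3, "pfs": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    n_pdos: int = 28
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    archetype_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    log10_ic50_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_IC50))
    hill_slope: float = 1.5
    floor_viability: float = 5.0
    replicate_sd: float = 3.0  # percent, multiplicative noise on net signal
    control_signal: float = 1000.0
    background: float = 100.0
    replicates: int = 2
    label_noise: float = 0.1
    pretreated_label_noise: float = 0.3
    pretreated_prob: float = 0.25
    pfs_scale_sensitive: float = 141.0
    pfs_scale_resistant: float = 46.0
    censor_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.archetype_probs
        if any(q < 0 or q > 1 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise PharmacotypeError("archetype_probs must lie in [0,1] and sum to 1")
        for prob in (self.label_noise, self.pretreated_label_noise, self.censor_prob, self.pretreated_prob):
            if not 0.0 <= prob <= 1.0:
                raise PharmacotypeError("probabilities must lie in [0, 1]")
        if self.hill_slope <= 0:
            raise PharmacotypeError("hill_slope must be > 0")
        if self.floor_viability < 0:
            raise PharmacotypeError("floor_viability must be >= 0")
        if self.pfs_scale_sensitive <= self.pfs_scale_resistant:
            raise PharmacotypeError("pfs_scale_sensitive must exceed pfs_scale_resistant")
        if self.n_pdos < 1 or self.replicates < 1:
            raise PharmacotypeError("n_pdos and replicates must be >= 1")


@dataclass
class GroundTruth:
    archetypes: dict[tuple[str, str], str]  # (pdo, drug) -> archetype
    ic50: dict[tuple[str, str], float]  # (pdo, drug) -> mol/L
    regimen: dict[str, str] = field(default_factory=dict)  # patient -> regimen
    true_sensitive: dict[str, bool] = field(default_factory=dict)  # patient -> sensitivity
    true_outcome: dict[str, str] = field(default_factory=dict)  # pre-noise outcome


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def _pdo_ids(config: GeneratorConfig) -> list[str]:
    width = max(3, len(str(config.n_pdos)))
    return [f"SIM{i + 1:0{width}d}" for i in range(config.n_pdos)]


def _draw_archetypes(config: GeneratorConfig) -> GroundTruth:
    rng = _rng(config, "archetypes")
    archetypes: dict[tuple[str, str], str] = {}
    ic50: dict[tuple[str, str], float] = {}
    for pdo in _pdo_ids(config):
        for drug in config.drugs:
            a = str(rng.choice(ARCHETYPES, p=config.archetype_probs))
            archetypes[(pdo, drug)] = a
            ic50[(pdo, drug)] = 10.0 ** config.log10_ic50_means[a]
    return GroundTruth(archetypes, ic50)


def hill_viability(conc: float, ic50: float, hill: float, floor: float) -> float:
    """Four-parameter logistic in log10 dose, top fixed at 100%."""
    return floor + (100.0 - floor) / (1.0 + 10.0 ** (hill * (math.log10(conc) - math.log10(ic50))))


def generate_plates(
    config: GeneratorConfig, panels: Mapping[str, DosePanel] | None = None
) -> tuple[list[WellMeasurement], GroundTruth]:
    """Emit two-signal wells for every simulated PDO x drug curve."""
    panels = panels or default_panels(config.drugs)
    truth = _draw_archetypes(config)
    rng = _rng(config, "plates")
    wells: list[WellMeasurement] = []
    for pdo in _pdo_ids(config):
        for rep in range(1, config.replicates + 1):
            wells.append(
                WellMeasurement(pdo, "CONTROL", None, rep, config.background,
                                config.background + config.control_signal)
            )
        for drug in config.drugs:
            ic50 = truth.ic50[(pdo, drug)]
            for conc in panels[drug].concentrations:
                v = hill_viability(conc, ic50, config.hill_slope, config.floor_viability)
                for rep in range(1, config.replicates + 1):
                    noise = rng.normal(0.0, config.replicate_sd / 100.0)
                    net = max(0.0, config.control_signal * v / 100.0 * (1.0 + noise))
                    wells.append(
                        WellMeasurement(pdo, drug, conc, rep, config.background,
                                        config.background + net)
                    )
    return wells, truth


def true_regimen_sensitivity(truth: GroundTruth, pdo: str, regimen_drugs: Sequence[str]) -> bool:
    """Sensitivity implied by the ground-truth archetype scores (mean <= 2)."""
    score = np.mean([ARCHETYPE_SCORE[truth.archetypes[(pdo, d)]] for d in regimen_drugs])
    return bool(score <= 2.0)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulated patients joined 1:1 to the simulated PDOs.

    Returns (patients, evaluations, truth). Clinical outcome equals the
    ground-truth sensitivity flipped with probability ``label_noise``
    (``pretreated_label_noise`` for pretreated patients); PFS is
    exponential with the scale of the received regimen's true sensitivity.
    """
    truth = _draw_archetypes(config)
    rng_out = _rng(config, "outcomes")
    rng_cens = _rng(config, "censoring")
    rng_pfs = _rng(config, "pfs")
    regimen_names = [n for n in DEFAULT_REGIMENS if set(DEFAULT_REGIMENS[n]) <= set(config.drugs)]
    if not regimen_names:
        raise PharmacotypeError("no default regimen is coverable by the configured drugs")
    patients, evaluations = [], []
    for pdo in _pdo_ids(config):
        patient = pdo.replace("SIM", "SIMPT")
        status = "pretreated" if rng_out.random() < config.pretreated_prob else "treatment-naive"
        regimen = regimen_names[int(rng_out.integers(len(regimen_names)))]
        sensitive = true_regimen_sensitivity(truth, pdo, DEFAULT_REGIMENS[regimen])
        noise_p = config.pretreated_label_noise if status == "pretreated" else config.label_noise
        flipped = bool(rng_out.random() < noise_p)
        responds = sensitive != flipped
        best = str(rng_out.choice(["CR", "PR", "SD"], p=[0.05, 0.45, 0.5])) if responds else "PD"
        scale = config.pfs_scale_sensitive if sensitive else config.pfs_scale_resistant
        pfs = float(rng_pfs.exponential(scale))
        event = 0 if rng_cens.random() < config.censor_prob else 1
        truth.regimen[patient] = regimen
        truth.true_sensitive[patient] = sensitive
        truth.true_outcome[patient] = "response" if sensitive else "no_response"
        predicted = "sensitive" if sensitive else "resistant"
        patients.append(
            dict(
                patient_id=patient, pdo_id=pdo, histology="ductal_adenocarcinoma",
                histology_confirmed_pc=True, treatment_status=status,
                prior_lines=1 if status == "pretreated" else 0,
                tumor_stage="metastasized", biopsy_site="liver_metastasis",
                sampling_method="us_biopsy", pharmacotyped=True,
                pdo_subtype="unknown", tissue_subtype="unknown",
                ki67_percent=float("nan"), regimen_received=regimen, therapy_line=1,
                predicted_call=predicted, best_response=best,
                pfs_days=round(pfs, 1), pfs_event=event,
            )
        )
        evaluations.append(
            dict(
                patient_id=patient, therapy_line=1, treatment_status=status,
                regimen=regimen, predicted_call=predicted, best_response=best,
            )
        )
    return pd.DataFrame(patients), pd.DataFrame(evaluations), truth


# ---------------------------------------------------------------------------
# packaged deterministic fixture


def paper_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 54-sample cohort encoding the published aggregates.

    Patients (54 rows) and evaluations (24 rows: 14 first-line
    treatment-naive of which 3 lack restaging, 5 second-line, 5
    pretreated). Encoded aggregates: 44 histology-confirmed PC (41 ductal
    adenocarcinoma), 30 treatment-naive (16 primary / 14 liver biopsies;
    8/16 and 11/14 pharmacotyped; primary sampling 11 percutaneous with 3
    successes, 3 EUS-FNB and 2 surgical all successful), 14 pretreated
    (9/14 pharmacotyped), match counts 10/11 first line, 4/5 second line,
    2/5 pretreated, and the 21-pair subtype table (16 concordant, 18/21
    classical tissue, 19/25 classical PDOs).

    PFS days and Ki-67 percentages are synthetic placeholders (drawn from
    a fixed seed) and must not be treated as published per-patient values.
    """
    rows: list[dict] = []
    rng = np.random.default_rng(20210521)

    def add(n: int, **kw) -> list[str]:
        ids = []
        for _ in range(n):
            pid = f"P{len(rows) + 1:02d}"
            base = dict(
                patient_id=pid, histology="ductal_adenocarcinoma",
                histology_confirmed_pc=True, treatment_status="treatment-naive",
                prior_lines=0, tumor_stage="metastasized",
                biopsy_site="liver_metastasis", sampling_method="us_biopsy",
                pharmacotyped=False, pdo_subtype="unknown", tissue_subtype="unknown",
                ki67_percent=float("nan"), regimen_received="", therapy_line=0,
                predicted_call="", best_response="not_available",
                pfs_days=float("nan"), pfs_event=0,
            )
            base.update(kw)
            rows.append(base)
            ids.append(pid)
        return ids

    # treatment-naive, liver metastases: 14, all metastasized, 11 pharmacotyped
    naive_liver_ok = add(11, pharmacotyped=True)
    add(3)
    # treatment-naive, primary tumor: 16 (4 metastasized / 8 locally advanced /
    # 4 resectable); successes: 3 of 11 percutaneous (one the anaplastic
    # tumor whose first-line prediction failed), all 3 EUS-FNB, both surgical
    prim_ok = add(2, biopsy_site="primary", pharmacotyped=True,
                  tumor_stage="locally_advanced")
    anaplastic = add(1, histology="anaplastic_carcinoma", pharmacotyped=True,
                     biopsy_site="primary", tumor_stage="locally_advanced")[0]
    prim_ok += add(3, biopsy_site="primary", sampling_method="eus_fnb",
                   pharmacotyped=True, tumor_stage="locally_advanced")
    prim_ok += add(2, biopsy_site="primary", sampling_method="surgical",
                   pharmacotyped=True, tumor_stage="resectable")
    prim_ok.append(anaplastic)
    add(2, biopsy_site="primary", tumor_stage="locally_advanced")
    add(1, biopsy_site="primary", tumor_stage="resectable")
    add(1, histology="acinar_cell_carcinoma", biopsy_site="primary",
        tumor_stage="resectable")
    add(3, biopsy_site="primary", tumor_stage="metastasized")
    add(1, histology="squamous_cell_carcinoma", biopsy_site="primary",
        tumor_stage="metastasized")
    # pretreated, all liver metastases: 14, 9 pharmacotyped
    # prior lines across the 14: four had 1, six had 2, four had >= 3
    pre_ok = add(3, treatment_status="pretreated", prior_lines=1, pharmacotyped=True)
    pre_ok += add(3, treatment_status="pretreated", prior_lines=2, pharmacotyped=True)
    pre_ok += add(2, treatment_status="pretreated", prior_lines=3, pharmacotyped=True)
    pre_ok += add(1, treatment_status="pretreated", prior_lines=4, pharmacotyped=True)
    add(1, treatment_status="pretreated", prior_lines=1)
    add(3, treatment_status="pretreated", prior_lines=2)
    add(1, treatment_status="pretreated", prior_lines=3)
    # ten excluded non-PC samples
    for hist, n in (("neuroendocrine_neoplasm", 4), ("lymphoma", 1),
                    ("serous_cystadenoma", 1), ("pancreatic_necrosis", 4)):
        add(n, histology=hist, histology_confirmed_pc=False, biopsy_site="primary",
            tumor_stage="", treatment_status="treatment-naive")

    patients = pd.DataFrame(rows)
    assert len(patients) == 54

    # --- evaluations -------------------------------------------------------
    ev: list[dict] = []

    def evaluate(pid: str, line: int, status: str, regimen: str, call: str, resp: str) -> None:
        ev.append(dict(patient_id=pid, therapy_line=line, treatment_status=status,
                       regimen=regimen, predicted_call=call, best_response=resp))
        sel = patients.patient_id == pid
        if line == 1:
            patients.loc[sel, ["regimen_received", "therapy_line", "predicted_call",
                               "best_response"]] = [regimen, line, call, resp]

    # first line, treatment-naive: 11 evaluable (7 control / 4 PD, 10 match)
    ordered = naive_liver_ok[:7] + prim_ok[:3] + [anaplastic]
    regs = ["FOLFIRINOX"] * 5 + ["gemcitabine/nab-paclitaxel"] * 6
    # 7 responders predicted sensitive; of 4 progressors 3 predicted resistant,
    # the anaplastic tumor was wrongly predicted sensitive
    plan = [("sensitive", "PR"), ("sensitive", "PR"), ("sensitive", "SD"),
            ("sensitive", "SD"), ("sensitive", "SD"), ("sensitive", "CR"),
            ("sensitive", "PR"), ("resistant", "PD"), ("resistant", "PD"),
            ("resistant", "PD"), ("sensitive", "PD")]
    for pid, reg, (call, resp) in zip(ordered, regs, plan):
        evaluate(pid, 1, "treatment-naive", reg, call, resp)
    # three treated naive patients never reached restaging
    for pid in naive_liver_ok[7:10]:
        evaluate(pid, 1, "treatment-naive", "FOLFIRINOX", "resistant", "not_available")

    # second line: 5 of the 11 (2 control / 3 PD, 4 match)
    second = ordered[:3] + ordered[7:9]
    regs2 = ["gemcitabine/nab-paclitaxel"] * 4 + ["5-FU/nab-paclitaxel"]
    plan2 = [("sensitive", "SD"), ("sensitive", "PR"), ("resistant", "PD"),
             ("resistant", "PD"), ("sensitive", "PD")]
    for pid, reg, (call, resp) in zip(second, regs2, plan2):
        evaluate(pid, 2, "treatment-naive", reg, call, resp)

    # pretreated: 5 evaluated (2 match; the failures had 1, 2 and 4 prior lines)
    pre_eval = [pre_ok[0], pre_ok[1], pre_ok[2], pre_ok[5], pre_ok[8]]
    regs3 = ["gemcitabine/nab-paclitaxel"] * 3 + ["nal-iri/5-FU"] * 2
    plan3 = [("sensitive", "PR"), ("resistant", "PD"), ("sensitive", "PD"),
             ("resistant", "SD"), ("sensitive", "PD")]
    for pid, reg, (call, resp) in zip(pre_eval, regs3, plan3):
        evaluate(pid, 1, "pretreated", reg, call, resp)

    evaluations = pd.DataFrame(ev)

    # --- molecular subtypes on 25 PDOs, 21 with paired tissue --------------
    pharmacotyped_ids = list(patients.loc[patients.pharmacotyped, "patient_id"])
    subtyped = pharmacotyped_ids[:25]
    pairs = (
        [("classical", "classical")] * 14
        + [("classical", "basal_like")] * 4  # tissue classical, PDO drifted basal
        + [("basal_like", "classical")] * 1
        + [("basal_like", "basal_like")] * 2
    )
    for pid, (tis, pdo) in zip(subtyped[:21], pairs):
        patients.loc[patients.patient_id == pid, ["tissue_subtype", "pdo_subtype"]] = [tis, pdo]
    for pid in subtyped[21:]:
        patients.loc[patients.patient_id == pid, "pdo_subtype"] = "classical"

    # --- synthetic per-patient extras (flagged, not published values) ------
    treated = patients.predicted_call.isin(["sensitive", "resistant"])
    for idx in patients.index[treated]:
        scale = 141.0 if patients.loc[idx, "predicted_call"] == "sensitive" else 46.0
        patients.loc[idx, "pfs_days"] = float(np.round(rng.exponential(scale) + 1.0))
        patients.loc[idx, "pfs_event"] = int(rng.random() > 0.15)
    for pid in subtyped:
        patients.loc[patients.patient_id == pid, "ki67_percent"] = float(
            np.round(rng.uniform(5, 95), 1)
        )
    return patients, evaluations


def write_cohort(patients: pd.DataFrame, evaluations: pd.DataFrame, patients_path, evaluations_path) -> None:
    patients.to_csv(patients_path, sep="\t", index=False)
    evaluations.to_csv(evaluations_path, sep="\t", index=False)


def read_cohort(patients_path, evaluations_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    patients = pd.read_csv(patients_path, sep="\t", keep_default_na=False,
                           na_values=[""], dtype={"patient_id": str})
    for col in ("histology_confirmed_pc", "pharmacotyped"):
        patients[col] = patients[col].astype(bool)
    evaluations = pd.read_csv(evaluations_path, sep="\t", keep_default_na=False,
                              na_values=[""], dtype={"patient_id": str})
    return patients, evaluations
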