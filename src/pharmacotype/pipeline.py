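"""End-to-end orchestration: plates -> AUC -> classes -> predictions -> report.

The JSON report emitted by :func:`run_pipeline` is the single source of
truth for downstream consumers; every statistic in it carries its counts
and exclusions so the human-readable summary can be derived rather than
recomputed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .errors import PharmacotypeError
from .natural_breaks import classify_drug
from .plate_io import default_panels, default_regimens, read_panels, read_plate, read_regimens
from .regimen_prediction import score_regimen
from .synthetic_cohort import read_cohort
from .viability_auc import build_library, compute_auc, profiles_from_plate

log = logging.getLogger("pharmacotype")


@dataclass
class RunConfig:
    plates: Path
    out_dir: Path
    cohort_patients: Path | None = None
    cohort_evaluations: Path | None = None
    panel: Path | None = None
    regimens: Path | None = None
    min_n: int = 25
    override_min_n: bool = False
    seed: int = 0


def evaluate_cohort(patients: pd.DataFrame, evaluations: pd.DataFrame) -> dict:
    """All cohort-level statistics with counts, exclusions and 2x2 tables."""
    naive = patients["treatment_status"] == cs.NAIVE
    pre = patients["treatment_status"] == cs.PRETREATED
    liver = patients["biopsy_site"] == "liver_metastasis"
    primary = patients["biopsy_site"] == "primary"

    def eff(mask: pd.Series | None) -> dict:
        r = cs.pharmacotyping_efficacy(patients, None if mask is None else (lambda df: mask.loc[df.index]))
        return {"percent": r.percent, "numerator": r.numerator, "denominator": r.denominator}

    def acc(line: int | None, status: str) -> dict:
        r = cs.prediction_accuracy(evaluations, therapy_line=line, treatment_status=status)
        return {
            "percent": r.percent,
            "matches": r.matches,
            "evaluated": r.evaluated,
            "excluded_not_available": r.excluded_not_available,
        }

    def success_failure(mask: pd.Series) -> list[int]:
        df = patients[patients["histology_confirmed_pc"].astype(bool) & mask]
        s = int(df["pharmacotyped"].astype(bool).sum())
        return [s, len(df) - s]

    tbl_liver = [success_failure(naive & liver), success_failure(pre & liver)]
    tbl_site = [success_failure(naive & liver), success_failure(naive & primary)]

    conc = cs.subtype_concordance(patients)
    pc = patients[patients["histology_confirmed_pc"].astype(bool)]

    report = {
        "cohort_counts": {
            "n_samples": int(len(patients)),
            "n_confirmed_pc": int(len(pc)),
            "n_ductal_adenocarcinoma": int((pc["histology"] == "ductal_adenocarcinoma").sum()),
            "n_treatment_naive": int((pc["treatment_status"] == cs.NAIVE).sum()),
            "n_pretreated": int((pc["treatment_status"] == cs.PRETREATED).sum()),
            "n_naive_metastasized": int(
                ((pc["treatment_status"] == cs.NAIVE) & (pc["tumor_stage"] == "metastasized")).sum()
            ),
            "n_pharmacotyped": int(pc["pharmacotyped"].astype(bool).sum()),
        },
        "pharmacotyping_efficacy": {
            "overall": eff(None),
            "treatment_naive_liver": eff(naive & liver),
            "treatment_naive_primary": eff(naive & primary),
            "pretreated": eff(pre),
        },
        "fisher": {
            "naive_liver_vs_pretreated_liver": {
                "table": tbl_liver,
                "p": cs.fisher_exact_two_sided(tbl_liver),
            },
            "naive_liver_vs_naive_primary": {
                "table": tbl_site,
                "p": cs.fisher_exact_two_sided(tbl_site),
            },
        },
        "prediction_accuracy": {
            "first_line_treatment_naive": acc(1, cs.NAIVE),
            "second_line_treatment_naive": acc(2, cs.NAIVE),
            "pretreated": acc(1, cs.PRETREATED),
        },
        "subtype_concordance": {
            "percent": conc.percent,
            "agreements": conc.agreements,
            "evaluable": conc.evaluable,
            "pdo_classical_percent": conc.pdo_classical_percent,
            "pdo_classical": conc.pdo_classical,
            "pdo_known": conc.pdo_known,
            "tissue_classical_percent": conc.tissue_classical_percent,
            "tissue_classical": conc.tissue_classical,
            "tissue_known": conc.tissue_known,
        },
    }

    # PFS by predicted regimen sensitivity among treated patients (synthetic
    # in the packaged fixture; reported with that caveat)
    treated = patients[
        patients["predicted_call"].isin(["sensitive", "resistant"]) & patients["pfs_days"].notna()
    ]
    if len(treated) > 0:
        sens = treated[treated["predicted_call"] == "sensitive"]
        res = treated[treated["predicted_call"] == "resistant"]
        pfs: dict = {"n_sensitive": int(len(sens)), "n_resistant": int(len(res))}
        if len(sens) > 0:
            pfs["median_sensitive"] = cs.km_curve(sens["pfs_days"], sens["pfs_event"]).median_days
        if len(res) > 0:
            pfs["median_resistant"] = cs.km_curve(res["pfs_days"], res["pfs_event"]).median_days
        if len(sens) > 0 and len(res) > 0:
            chi2, p = cs.logrank_test(
                sens["pfs_days"], sens["pfs_event"], res["pfs_days"], res["pfs_event"]
            )
            pfs["logrank_chi2"] = chi2
            pfs["logrank_p"] = p
        report["pfs_by_predicted_call"] = pfs
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, writing per-stage TSVs and a final report JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s at %.2fs", name, time.time() - t0)
        report["stages"][name] = round(time.time() - t0, 3)

    try:
        panels = read_panels(config.panel) if config.panel else default_panels()
        regimens = (
            read_regimens(config.regimens, screened_drugs=panels)
            if config.regimens
            else default_regimens()
        )
        stage("config")
        wells = read_plate(config.plates, panels=panels)
        stage("read_plate")

        profiles = profiles_from_plate(wells, panels)
        pd.DataFrame(
            [
                (p.pdo_id, p.drug_id, c, v)
                for p in profiles
                for c, v in zip(p.concentrations, p.viabilities)
            ],
            columns=["pdo_id", "drug_id", "concentration_molar", "viability_percent"],
        ).to_csv(out / "viability.tsv", sep="\t", index=False)
        stage("viability")

        library = build_library([compute_auc(p) for p in profiles])
        library.to_tsv(out / "auc.tsv")
        stage("auc")

        breaks_rows, call_rows = [], []
        calls_by_pdo: dict[str, list] = {}
        models = {}
        for drug in library.drug_ids:
            model, calls = classify_drug(
                library, drug, min_n=config.min_n, override=config.override_min_n
            )
            models[drug] = model
            breaks_rows.append(
                (drug, model.breaks[0], model.breaks[1], model.gvf, library.drug_n(drug))
            )
            for c in calls:
                call_rows.append((c.pdo_id, c.drug_id, c.category, c.drug_score))
                calls_by_pdo.setdefault(c.pdo_id, []).append(c)
        pd.DataFrame(
            breaks_rows, columns=["drug_id", "break1", "break2", "gvf", "n"]
        ).to_csv(out / "breaks.tsv", sep="\t", index=False)
        pd.DataFrame(
            call_rows, columns=["pdo_id", "drug_id", "category", "score"]
        ).to_csv(out / "calls.tsv", sep="\t", index=False)
        report["breaks"] = {
            d: {"breaks": list(m.breaks), "gvf": m.gvf, "n": library.drug_n(d),
                "cutoffs": m.cutoff_report()}
            for d, m in models.items()
        }
        stage("classify")

        pred_rows = []
        for pdo, calls in sorted(calls_by_pdo.items()):
            have = {c.drug_id for c in calls}
            for reg in regimens.values():
                if set(reg.component_drugs) <= have:
                    p = score_regimen(calls, reg)
                    pred_rows.append(
                        (p.pdo_id, p.regimen_name,
                         ";".join(f"{d}={s}" for d, s in p.component_scores.items()),
                         p.score, p.call)
                    )
        predictions = pd.DataFrame(
            pred_rows, columns=["pdo_id", "regimen", "component_scores", "score", "call"]
        )
        predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
        report["n_predictions"] = int(len(predictions))
        report["n_pdos"] = len(library)
        stage("predict")

        # per-PDO classification card: drug, AUC, category, score
        cards = {}
        for pdo, calls in sorted(calls_by_pdo.items()):
            cards[pdo] = [
                {
                    "drug": c.drug_id,
                    "auc": round(float(library.matrix.loc[pdo, c.drug_id]), 2),
                    "category": f"{c.category} responder",
                    "score": c.drug_score,
                }
                for c in calls
            ]
        report["classification_cards"] = cards
        stage("cards")

        if config.cohort_patients is not None:
            patients, evaluations = read_cohort(
                config.cohort_patients, config.cohort_evaluations
            )
            report["cohort"] = evaluate_cohort(patients, evaluations)
            stage("evaluate")
    except PharmacotypeError as exc:
        done = list(report["stages"])
        current = done[-1] if done else "config"
        raise PharmacotypeError(f"pipeline failed after stage {current!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
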