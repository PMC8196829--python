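"""Cohort-level evaluation statistics.

Operates on two plain tables (TSV on disk, pandas in memory):

``patients`` — one row per enrolled sample::

    patient_id, histology, histology_confirmed_pc, treatment_status,
    prior_lines, tumor_stage, biopsy_site, sampling_method, pharmacotyped,
    pdo_subtype, tissue_subtype, ki67_percent, pfs_days, pfs_event,
    predicted_call

``evaluations`` — one row per prediction-vs-outcome comparison::

    patient_id, therapy_line, treatment_status, regimen, predicted_call,
    best_response

Controlled vocabularies: treatment_status in {treatment-naive, pretreated};
biopsy_site in {primary, liver_metastasis}; sampling_method in {us_biopsy,
eus_fnb, surgical}; best_response in {CR, PR, SD, PD, not_available};
predicted_call in {sensitive, resistant}; subtypes in {classical,
basal_like, unknown}. Censoring is encoded by pfs_event 0/1.

All percentages are rounded half-up to one decimal. The exact tests
(Fisher, Mann-Whitney) are computed by direct enumeration over their
null support; Kaplan-Meier and the log-rank test follow the standard
product-limit and O-E/V forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .errors import CohortError

TUMOR_CONTROL = {"CR": "response", "PR": "response", "SD": "response", "PD": "no_response"}

NAIVE = "treatment-naive"
PRETREATED = "pretreated"

StratumFilter = Callable[[pd.DataFrame], pd.Series]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def tumor_control(best_response: str) -> str:
    """Map a RECIST best response to the binary tumor-control outcome."""
    if best_response == "not_available":
        return "not_available"
    try:
        return TUMOR_CONTROL[best_response]
    except KeyError:
        raise CohortError(f"unknown RECIST category {best_response!r}") from None


@dataclass(frozen=True)
class EfficacyResult:
    percent: float
    numerator: int
    denominator: int


def pharmacotyping_efficacy(
    patients: pd.DataFrame, stratum: StratumFilter | pd.Series | None = None
) -> EfficacyResult:
    """Share of histology-confirmed PC samples that reached drug testing."""
    df = patients[patients["histology_confirmed_pc"].astype(bool)]
    if stratum is not None:
        mask = stratum(df) if callable(stratum) else stratum.reindex(df.index).fillna(False)
        df = df[mask.astype(bool)]
    denom = len(df)
    if denom == 0:
        raise CohortError("empty stratum after filtering")
    num = int(df["pharmacotyped"].astype(bool).sum())
    return EfficacyResult(round_half_up(100.0 * num / denom), num, denom)


@dataclass(frozen=True)
class AccuracyResult:
    percent: float
    matches: int
    evaluated: int
    excluded_not_available: int


def prediction_accuracy(
    evaluations: pd.DataFrame,
    therapy_line: int | None = None,
    treatment_status: str | None = None,
) -> AccuracyResult:
    """Share of sensitive/resistant calls matching the tumor-control outcome.

    Patients without restaging (``best_response == not_available``) are
    excluded from the denominator and counted separately.
    """
    df = evaluations
    if therapy_line is not None:
        df = df[df["therapy_line"] == therapy_line]
    if treatment_status is not None:
        df = df[df["treatment_status"] == treatment_status]
    outcomes = df["best_response"].map(tumor_control)
    excluded = int((outcomes == "not_available").sum())
    df = df[outcomes != "not_available"]
    outcomes = outcomes[outcomes != "not_available"]
    if len(df) == 0:
        raise CohortError("no evaluable patients in the requested stratum")
    pred = df["predicted_call"]
    match = ((pred == "sensitive") & (outcomes == "response")) | (
        (pred == "resistant") & (outcomes == "no_response")
    )
    m, n = int(match.sum()), len(df)
    return AccuracyResult(round_half_up(100.0 * m / n), m, n, excluded)


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's (within a 1e-7
    relative guard). Cell counts are exact integers throughout.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise CohortError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise CohortError("all-zero table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalised weights share the denominator C(n, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs * (1.0 + 1e-7))
    return tail / total


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sv = values[order]
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float], exact_max_n: int = 20) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumerating every split of the pooled sample when the
    combined size is at most ``exact_max_n``; otherwise the normal
    approximation with tie correction. Two-sided p is twice the smaller
    tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("empty sample")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum()) - nx * (nx + 1) / 2.0
    n = nx + ny
    if n <= exact_max_n:
        const = nx * (nx + 1) / 2.0
        us = [sum(ranks[list(idx)]) - const for idx in combinations(range(n), nx)]
        us = np.asarray(us)
        eps = 1e-9
        p_lo = np.mean(us <= u_obs + eps)
        p_hi = np.mean(us >= u_obs - eps)
        return min(1.0, 2.0 * min(p_lo, p_hi))
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (u_obs - mu) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""

    event_times: tuple[float, ...]  # distinct event times, ascending
    survival_probabilities: tuple[float, ...]  # S(t) just after each event time
    at_risk: tuple[int, ...]  # subjects at risk at each event time
    median_days: float | None  # first time with S(t) <= 0.5, None if never

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sp in zip(self.event_times, self.survival_probabilities):
            if et <= t:
                s = sp
            else:
                break
        return s


def km_curve(durations: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimator; censored subjects at t stay at risk for
    the events occurring at t."""
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise CohortError("empty survival data")
    if np.any(t < 0):
        raise CohortError("negative survival time")
    event_times = np.unique(t[e == 1])
    s = 1.0
    surv, risks = [], []
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
    median = None
    for et, sp in zip(event_times, surv):
        if sp <= 0.5:
            median = float(et)
            break
    return SurvivalCurve(tuple(map(float, event_times)), tuple(surv), tuple(risks), median)


def logrank_test(
    durations_a: Sequence[float],
    events_a: Sequence[int],
    durations_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta = np.asarray(durations_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(durations_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise CohortError("empty group")
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("a group has zero events; log-rank p may be uninformative", stacklevel=2)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    event_times = np.unique(all_t[all_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & (grp == 0)).sum())
        d = int(((all_t == et) & (all_e == 1)).sum())
        d1 = int(((all_t == et) & (all_e == 1) & (grp == 0)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# subtype concordance


@dataclass(frozen=True)
class ConcordanceResult:
    percent: float
    agreements: int
    evaluable: int
    pdo_classical_percent: float
    pdo_classical: int
    pdo_known: int
    tissue_classical_percent: float
    tissue_classical: int
    tissue_known: int


def subtype_concordance(patients: pd.DataFrame) -> ConcordanceResult:
    """Agreement of PDO vs tissue classical/basal-like labels, plus the
    per-compartment classical fractions over all known labels."""
    known = {"classical", "basal_like"}
    pdo_known = patients[patients["pdo_subtype"].isin(known)]
    tissue_known = patients[patients["tissue_subtype"].isin(known)]
    paired = patients[
        patients["pdo_subtype"].isin(known) & patients["tissue_subtype"].isin(known)
    ]
    if len(paired) == 0:
        raise CohortError("no patients with paired subtype labels")
    agree = int((paired["pdo_subtype"] == paired["tissue_subtype"]).sum())
    pdo_cls = int((pdo_known["pdo_subtype"] == "classical").sum())
    tis_cls = int((tissue_known["tissue_subtype"] == "classical").sum())
    return ConcordanceResult(
        percent=round_half_up(100.0 * agree / len(paired)),
        agreements=agree,
        evaluable=len(paired),
        pdo_classical_percent=round_half_up(100.0 * pdo_cls / len(pdo_known)),
        pdo_classical=pdo_cls,
        pdo_known=len(pdo_known),
        tissue_classical_percent=round_half_up(100.0 * tis_cls / len(tissue_known)),
        tissue_classical=tis_cls,
        tissue_known=len(tissue_known),
    )
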