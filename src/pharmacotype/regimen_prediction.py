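"""Regimen prediction: mean-of-drug-scores rule and hard-margin linear SVM.

The prediction score of a regimen is the arithmetic mean of its component
drugs' responder scores (high=1, intermediate=2, low=3). A score <= 2
calls the regimen sensitive, > 2 resistant; the boundary is inclusive on
the sensitive side.

The alternative classifier is a hard-margin linear SVM trained per
regimen on AUC feature vectors; non-separable data is an explicit error
rather than a silent soft-margin fallback.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import NotSeparableError, PharmacotypeError
from .natural_breaks import ResponderCall
from .plate_io import RegimenMap
from .viability_auc import AUCLibrary

SENSITIVE = "sensitive"
RESISTANT = "resistant"
RESPONSE = "response"
NO_RESPONSE = "no response"

#: Functional-margin slack used both for separability checks and support
#: vector identification.
MARGIN_TOL = 1e-6


@dataclass(frozen=True)
class RegimenPrediction:
    pdo_id: str
    regimen_name: str
    score: float  # mean of component scores, in [1, 3]
    call: str  # sensitive | resistant
    component_scores: Mapping[str, int]


def score_regimen(
    calls: Iterable[ResponderCall], regimen: RegimenMap, pdo_id: str | None = None
) -> RegimenPrediction:
    """Average the per-drug scores of one PDO over the regimen components."""
    by_drug: dict[str, ResponderCall] = {}
    pdos = set()
    for c in calls:
        by_drug[c.drug_id] = c
        pdos.add(c.pdo_id)
    if pdo_id is None:
        if len(pdos) != 1:
            raise PharmacotypeError(f"calls span {len(pdos)} PDOs; pass pdo_id explicitly")
        pdo_id = pdos.pop()
    missing = [d for d in regimen.component_drugs if d not in by_drug]
    if missing:
        raise PharmacotypeError(
            f"{pdo_id}/{regimen.regimen_name}: missing responder call for {', '.join(missing)}"
        )
    comp = {d: by_drug[d].drug_score for d in regimen.component_drugs}
    score = float(np.mean(list(comp.values())))
    call = SENSITIVE if score <= 2.0 else RESISTANT
    return RegimenPrediction(pdo_id, regimen.regimen_name, score, call, comp)


@dataclass(frozen=True)
class SVMModel:
    regimen_name: str
    feature_drugs: tuple[str, ...]
    weights: tuple[float, ...]
    bias: float
    support_ids: tuple[str, ...]
    training_ids: tuple[str, ...]

    def decision_value(self, x: Sequence[float]) -> float:
        return float(np.dot(self.weights, x) + self.bias)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "regimen_name": self.regimen_name,
                    "feature_drugs": list(self.feature_drugs),
                    "weights": list(self.weights),
                    "bias": self.bias,
                    "support_ids": list(self.support_ids),
                    "training_ids": list(self.training_ids),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["regimen_name"],
            tuple(d["feature_drugs"]),
            tuple(d["weights"]),
            float(d["bias"]),
            tuple(d["support_ids"]),
            tuple(d["training_ids"]),
        )


def _solve_hard_margin(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Primal hard-margin QP: min 1/2 ||w||^2 s.t. y_i (w.x_i + b) >= 1."""
    n, d = X.shape
    scale = np.abs(X).max() or 1.0
    Xs = X / scale

    def obj(z):
        return 0.5 * float(np.dot(z[:d], z[:d]))

    def jac(z):
        g = np.zeros(d + 1)
        g[:d] = z[:d]
        return g

    cons = {
        "type": "ineq",
        "fun": lambda z: y * (Xs @ z[:d] + z[d]) - 1.0,
        "jac": lambda z: np.column_stack([y[:, None] * Xs, y]),
    }
    # feasible-ish start: least-squares hyperplane through class means
    mu_p, mu_n = Xs[y > 0].mean(axis=0), Xs[y < 0].mean(axis=0)
    w0 = mu_p - mu_n
    norm = np.linalg.norm(w0)
    w0 = w0 / norm if norm > 0 else np.ones(d)
    b0 = -float(w0 @ (mu_p + mu_n)) / 2.0
    margins = y * (Xs @ w0 + b0)
    if margins.min() > 0:
        z0 = np.concatenate([w0, [b0]]) / margins.min()
    else:
        z0 = np.concatenate([w0, [b0]])
    res = minimize(
        obj, z0, jac=jac, constraints=[cons], method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    w, b = res.x[:d], float(res.x[d])
    if not res.success or np.min(y * (Xs @ w + b)) < 1.0 - MARGIN_TOL:
        raise NotSeparableError("training data is not linearly separable with margin")
    w, b = _polish(Xs, y, w, b)
    return w / scale, b


def _polish(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float) -> tuple[np.ndarray, float]:
    """Refine the numerical QP solution by solving the KKT system of its
    active set exactly; falls back to the unpolished solution."""
    margins = y * (X @ w + b)
    support = np.where(margins <= 1.0 + 1e-4)[0]
    if support.size < 2:
        return w, b
    Xs, ys = X[support], y[support]
    r = support.size
    A = np.zeros((r + 1, r + 1))
    A[:r, :r] = (ys[:, None] * ys[None, :]) * (Xs @ Xs.T)
    A[:r, r] = ys
    A[r, :r] = ys
    rhs = np.concatenate([np.ones(r), [0.0]])
    alpha_b, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    alpha, b2 = alpha_b[:r], float(alpha_b[r])
    if np.any(alpha < -1e-8):
        return w, b
    w2 = (alpha * ys) @ Xs
    if np.min(y * (X @ w2 + b2)) < 1.0 - 1e-9:
        return w, b
    return w2, b2


def train_svm(
    library: AUCLibrary,
    labels: Mapping[str, str],
    regimen_name: str,
    feature_drugs: Sequence[str] | None = None,
    standardize: bool = False,
) -> SVMModel:
    """Fit the maximum-margin separating hyperplane on labelled PDO AUCs.

    ``labels`` maps pdo_id -> 'response' / 'no response'. Features default
    to all drugs in the library (the full pharmacotype); restrict via
    ``feature_drugs``. Non-separable data raises NotSeparableError.
    """
    drugs = tuple(feature_drugs) if feature_drugs is not None else tuple(library.drug_ids)
    ids = [p for p in library.pdo_ids if p in labels]
    if set(labels) - set(ids):
        raise PharmacotypeError(f"labelled PDO(s) missing from library: {sorted(set(labels) - set(ids))}")
    X = library.matrix.loc[ids, list(drugs)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [ids[i] for i in np.where(np.isnan(X).any(axis=1))[0]]
        raise PharmacotypeError(f"incomplete feature vector(s) for {', '.join(bad)}")
    y = np.array([1.0 if labels[p] == RESPONSE else -1.0 for p in ids])
    if len(set(y)) < 2 or min((y > 0).sum(), (y < 0).sum()) < 1:
        raise PharmacotypeError("need PDOs of both labels to train")
    if (y > 0).sum() < 1 or (y < 0).sum() < 1:
        raise PharmacotypeError("degenerate single-class labels")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if standardize:
        if np.any(sd == 0):
            raise PharmacotypeError("cannot standardize a constant feature")
        Xf = (X - mean) / sd
    else:
        Xf = X
    w, b = _solve_hard_margin(Xf, y)
    if standardize:
        # fold the z-score back into input units
        w = w / sd
        b = b - float(np.dot(w, mean))
    margins = y * (X @ w + b)
    support = tuple(ids[i] for i in np.where(margins <= 1.0 + MARGIN_TOL)[0])
    return SVMModel(regimen_name, drugs, tuple(float(v) for v in w), float(b), support, tuple(ids))


def predict_svm(model: SVMModel, auc_vector: Mapping[str, float] | Sequence[float]) -> str:
    """Label a new AUC vector; a point exactly on the hyperplane is
    'no response' with a boundary warning."""
    if isinstance(auc_vector, Mapping):
        missing = [d for d in model.feature_drugs if d not in auc_vector]
        if missing:
            raise PharmacotypeError(f"missing feature(s): {', '.join(missing)}")
        x = [float(auc_vector[d]) for d in model.feature_drugs]
    else:
        x = [float(v) for v in auc_vector]
        if len(x) != len(model.feature_drugs):
            raise PharmacotypeError(
                f"expected {len(model.feature_drugs)} features, got {len(x)}"
            )
    dv = model.decision_value(x)
    if dv == 0.0:
        warnings.warn("point lies exactly on the decision boundary", stacklevel=2)
        return NO_RESPONSE
    return RESPONSE if dv > 0 else NO_RESPONSE
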