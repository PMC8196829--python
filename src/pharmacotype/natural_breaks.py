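"""Jenks natural breaks: exact optimal 1-D partition into contiguous classes.

The classifier sorts the values and finds, by dynamic programming over
prefix sums (Fisher's method), the contiguous k-partition minimising the
total within-class sum of squared deviations. Among equal-cost partitions
the one whose leftmost differing break is smallest is chosen, which makes
the result deterministic and independent of input order.

Drug AUC vectors are cut into k=3 responder classes (lowest-AUC class =
high responder, score 1; highest = low responder, score 3); Ki-67 indices
into k=2 proliferation classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ClassificationError
from .viability_auc import AUCLibrary

CATEGORIES_3 = ("high", "intermediate", "low")
CATEGORY_SCORE = {"high": 1, "intermediate": 2, "low": 3}
SCORE_CATEGORY = {v: k for k, v in CATEGORY_SCORE.items()}

#: Library size below which per-drug classification refuses without override.
MIN_LIBRARY_N = 25


@dataclass(frozen=True)
class BreaksModel:
    """A fitted k-class natural-breaks partition of one variable."""

    drug_id: str
    k: int
    breaks: tuple[float, ...]  # k-1 interior boundaries = max of each lower class
    class_ranges: tuple[tuple[float, float], ...]  # per class (min, max) of members
    gvf: float  # goodness of variance fit, 1 - SDCM/SDAM

    def assign(self, value: float) -> int:
        """Class index of a new value under the frozen boundaries.

        Below the data range -> class 0; above -> class k-1. Values equal
        to a boundary fall in the lower class (boundary = its maximum).
        """
        for i, b in enumerate(self.breaks):
            if value <= b:
                return i
        return self.k - 1

    def cutoff_report(self) -> str:
        """Cut-offs in reporting style: high-sensitivity and low-sensitivity bounds."""
        if self.k != 3:
            return f"{self.drug_id}: breaks {', '.join(f'{b:.1f}' for b in self.breaks)}"
        return (
            f"{self.drug_id}: high sensitivity AUC < {self.breaks[0]:.1f} "
            f"and low sensitivity > {self.breaks[1]:.1f}"
        )


@dataclass(frozen=True)
class ResponderCall:
    pdo_id: str
    drug_id: str
    category: str  # high | intermediate | low
    drug_score: int  # 1 | 2 | 3

    def __post_init__(self) -> None:
        if CATEGORY_SCORE[self.category] != self.drug_score:
            raise ClassificationError(
                f"{self.pdo_id}/{self.drug_id}: category {self.category!r} does not "
                f"match score {self.drug_score}"
            )


def _segment_cost_table(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of sorted x[i..j] inclusive, via prefix sums."""
    n = x.size
    ps = np.concatenate(([0.0], np.cumsum(x)))
    ps2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = (j - i + 1).astype(float)
    s = ps[j + 1] - ps[i]
    s2 = ps2[j + 1] - ps2[i]
    with np.errstate(invalid="ignore"):
        cost = s2 - s * s / cnt
    # numerical floor: SSE cannot be negative
    return np.where(j >= i, np.maximum(cost, 0.0), np.inf)


def jenks_breaks(values: Sequence[float], k: int, drug_id: str = "") -> tuple[BreaksModel, np.ndarray]:
    """Fit the optimal k-class partition; returns the model and class labels.

    Labels are indices 0..k-1 aligned with the input order (class 0 holds
    the smallest values). Requires at least k distinct values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ClassificationError("empty input")
    if k < 2:
        raise ClassificationError(f"k must be >= 2, got {k}")
    if np.unique(x).size < k:
        raise ClassificationError(
            f"need >= {k} distinct values, got {np.unique(x).size}"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    cost = _segment_cost_table(xs)

    # suffix DP: S[i, c] = min cost of splitting xs[i:] into c classes
    S = np.full((n + 1, k + 1), np.inf)
    S[n, 0] = 0.0
    for c in range(1, k + 1):
        for i in range(n - 1, -1, -1):
            # class starting at i must leave room for c-1 more classes
            ends = np.arange(i, n - (c - 1))
            if ends.size == 0:
                continue
            S[i, c] = np.min(cost[i, ends] + S[ends + 1, c - 1])

    total = S[0, k]
    # reconstruct left to right, taking the smallest feasible boundary each
    # time -> lexicographically smallest break sequence among optima
    bounds: list[int] = []  # inclusive end index of each class
    i = 0
    for c in range(k, 0, -1):
        for j in range(i, n - (c - 1)):
            if cost[i, j] + S[j + 1, c - 1] <= S[i, c]:
                bounds.append(j)
                i = j + 1
                break
    assert len(bounds) == k and bounds[-1] == n - 1

    starts = [0] + [b + 1 for b in bounds[:-1]]
    class_ranges = tuple((float(xs[s]), float(xs[e])) for s, e in zip(starts, bounds))
    breaks = tuple(float(xs[b]) for b in bounds[:-1])

    sdam = float(np.sum((xs - xs.mean()) ** 2))
    gvf = 1.0 if sdam == 0 else 1.0 - total / sdam

    labels_sorted = np.empty(n, dtype=int)
    for ci, (s, e) in enumerate(zip(starts, bounds)):
        labels_sorted[s : e + 1] = ci
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    model = BreaksModel(drug_id, k, breaks, class_ranges, float(np.clip(gvf, 0.0, 1.0)))
    return model, labels


def classify_drug(
    library: AUCLibrary,
    drug_id: str,
    min_n: int = MIN_LIBRARY_N,
    override: bool = False,
) -> tuple[BreaksModel, list[ResponderCall]]:
    """Three-class responder partition of one drug's AUC vector.

    Refuses when fewer than ``min_n`` PDOs carry a value for the drug,
    unless ``override`` is set (then a warning is emitted instead).
    """
    if len(library) == 0:
        raise ClassificationError("empty AUC library")
    vec = library.drug_vector(drug_id)
    n = len(vec)
    if n < min_n:
        if not override:
            raise ClassificationError(
                f"{drug_id}: library has n={n} < {min_n}; pass override to classify anyway"
            )
        warnings.warn(f"{drug_id}: classifying with n={n} < {min_n}", stacklevel=2)
    model, labels = jenks_breaks(vec.to_numpy(), k=3, drug_id=drug_id)
    calls = [
        ResponderCall(pdo, drug_id, CATEGORIES_3[lab], lab + 1)
        for pdo, lab in zip(vec.index, labels)
    ]
    return model, calls


def score_new_auc(model: BreaksModel, pdo_id: str, auc: float) -> ResponderCall:
    """Score a new PDO against a frozen model without re-clustering."""
    if model.k != 3:
        raise ClassificationError("responder scoring requires a 3-class model")
    lab = model.assign(auc)
    return ResponderCall(pdo_id, model.drug_id, CATEGORIES_3[lab], lab + 1)


KI67_FIXED_CUTOFF = 45.0


def classify_ki67(values: Sequence[float], cutoff_mode: str = "jenks") -> list[str]:
    """Two-class proliferation labels ('low' / 'high') for Ki-67 percentages.

    ``fixed45`` labels high iff value > 45; ``jenks`` fits a k=2 partition.
    """
    x = np.asarray(values, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ClassificationError("Ki-67 percentages must lie in [0, 100]")
    if cutoff_mode == "fixed45":
        return ["high" if v > KI67_FIXED_CUTOFF else "low" for v in x]
    if cutoff_mode == "jenks":
        _, labels = jenks_breaks(x, k=2, drug_id="ki67")
        return ["high" if lab == 1 else "low" for lab in labels]
    raise ClassificationError(f"unknown cutoff_mode {cutoff_mode!r}")
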