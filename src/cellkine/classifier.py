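"""Sparse multi-instance learning (sMIL) over labeled bags.

The model is a linear max-margin classifier fitted on a mixed constraint
set. Negative bags are expanded instance-by-instance — under the MIL
assumption every instance of a negative bag is negative — each contributing
the usual constraint ``w.x + b <= -1 + xi``. A positive bag guarantees only
that *some* instance is positive, so it is represented by its averaged
instance vector ``phi = mean(x in B)`` with a bag-size-dependent margin::

    w.phi + b >= (2 - |B|)/|B| - xi_B

A singleton positive bag (margin 1) behaves exactly like an ordinary
positive example; larger bags get a relaxed (eventually negative) margin,
encoding that big bags are less informative — the expected fraction of
truly positive instances in them is lower. The program

    minimize  0.5 ||w||^2 + C * sum(slacks)

is solved in the dual with an SMO-style maximal-violating-pair solver
(deterministic, no random initialization). Confidence scores are the signed
distance to the hyperplane passed through a monotone logistic (Platt)
calibration fitted on training-bag scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .features import Vocabulary

__all__ = [
    "SmilModel",
    "PairScore",
    "smil_constraint_set",
    "train_smil",
    "confidence",
    "classify",
    "solve_svm_dual",
]


class ConvergenceError(RuntimeError):
    """The dual solver did not reach the requested tolerance."""


# --------------------------------------------------------------------------
# dual SMO solver for SVMs with per-example target margins
# --------------------------------------------------------------------------


def solve_svm_dual(
    X: np.ndarray | sp.spmatrix,
    y: np.ndarray,
    margins: np.ndarray,
    C: float,
    tol: float = 1e-8,
    max_iter: int = 2_000_000,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve ``min 0.5||w||^2 + C sum(xi)`` s.t. ``y_i(w.x_i+b) >= m_i - xi_i``.

    Standard soft-margin SVM generalized to per-example target margins
    ``m_i`` (which may be zero or negative, as sMIL requires for large
    positive bags). Returns ``(w, b, alpha)``.

    The dual ``min 0.5 a'Qa - m'a`` with ``Q_ij = y_i y_j x_i.x_j``,
    ``0 <= a <= C``, ``y'a = 0`` is solved by sequential minimal
    optimization with maximal-violating-pair working-set selection;
    ``tol`` bounds the final KKT violation.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    margins = np.asarray(margins, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len({*np.unique(y)}) < 2:
        raise ValueError("training set must contain both classes")

    K = X @ X.T  # n is bounded by corpus size at desk scale; dense Gram is fine
    diag = np.diag(K).copy()
    alpha = np.zeros(n)
    G = -margins.copy()  # gradient of the dual objective at alpha = 0

    for _ in range(max_iter):
        in_up = ((y > 0) & (alpha < C - 1e-15)) | ((y < 0) & (alpha > 1e-15))
        in_low = ((y > 0) & (alpha > 1e-15)) | ((y < 0) & (alpha < C - 1e-15))
        if not in_up.any() or not in_low.any():
            break
        crit = -y * G
        i = int(np.flatnonzero(in_up)[np.argmax(crit[in_up])])
        j = int(np.flatnonzero(in_low)[np.argmin(crit[in_low])])
        violation = crit[i] - crit[j]
        if violation <= tol:
            break
        quad = diag[i] + diag[j] - 2.0 * K[i, j]
        if quad <= 1e-14:
            quad = 1e-14
        d = violation / quad
        # box clipping for the update alpha_i += y_i d, alpha_j -= y_j d
        d = min(d, (C - alpha[i]) if y[i] > 0 else alpha[i])
        d = min(d, alpha[j] if y[j] > 0 else (C - alpha[j]))
        if d <= 0:
            break
        alpha[i] += y[i] * d
        alpha[j] -= y[j] * d
        G += d * y * (K[:, i] - K[:, j])
    else:
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations (violation {violation:.3e})"
        )

    w = X.T @ (alpha * y)
    # bias from KKT: every free support vector proposes b = -y_i G_i
    free = (alpha > 1e-9) & (alpha < C - 1e-9)
    cand = -y * G
    if free.any():
        b = float(np.mean(cand[free]))
    else:
        in_up = ((y > 0) & (alpha < C - 1e-15)) | ((y < 0) & (alpha > 1e-15))
        in_low = ((y > 0) & (alpha > 1e-15)) | ((y < 0) & (alpha < C - 1e-15))
        hi = cand[in_up].max() if in_up.any() else 0.0
        lo = cand[in_low].min() if in_low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return w, b, alpha


def svm_objective(
    X: np.ndarray | sp.spmatrix,
    y: np.ndarray,
    margins: np.ndarray,
    C: float,
    w: np.ndarray,
    b: float,
) -> float:
    """Primal objective 0.5||w||^2 + C * sum of hinge slacks."""
    if sp.issparse(X):
        X = np.asarray(X.todense())
    slack = np.maximum(0.0, margins - y * (X @ w + b))
    return 0.5 * float(w @ w) + C * float(slack.sum())


# --------------------------------------------------------------------------
# sMIL over bags
# --------------------------------------------------------------------------


def smil_constraint_set(
    bag_matrices: Sequence[np.ndarray | sp.spmatrix],
    labels: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expand labeled bags into the sMIL constraint set.

    Returns ``(X, y, margins, bag_index)`` where each negative-bag instance
    contributes one row (y=-1, margin 1) and each positive bag contributes
    its mean vector (y=+1, margin (2-|B|)/|B|). ``bag_index[r]`` maps row
    ``r`` back to its bag.
    """
    rows: list[np.ndarray] = []
    ys: list[float] = []
    ms: list[float] = []
    owners: list[int] = []
    for k, (mat, label) in enumerate(zip(bag_matrices, labels)):
        dense = np.asarray(mat.todense()) if sp.issparse(mat) else np.atleast_2d(mat)
        size = dense.shape[0]
        if label == "positive":
            rows.append(dense.mean(axis=0))
            ys.append(1.0)
            ms.append((2.0 - size) / size)
            owners.append(k)
        elif label == "negative":
            for r in range(size):
                rows.append(dense[r])
                ys.append(-1.0)
                ms.append(1.0)
                owners.append(k)
        else:
            raise ValueError(f"bag {k} is unlabeled")
    return np.vstack(rows), np.array(ys), np.array(ms), np.array(owners)


@dataclass
class SmilModel:
    """Linear sMIL decision function with frozen vocabulary and calibration."""

    weights: np.ndarray
    bias: float
    C: float
    vocab: Vocabulary | None = None
    calibration: tuple[float, float] = (1.0, 0.0)  # sigma(a*s + c), a > 0
    n_positive_bags: int = 0
    n_negative_bags: int = 0
    objective_: float = float("nan")

    def raw_score(self, bag_matrix: np.ndarray | sp.spmatrix) -> float:
        """Signed distance term w.phi(B) + b for a bag's instance matrix."""
        dense = (
            np.asarray(bag_matrix.todense()) if sp.issparse(bag_matrix) else np.atleast_2d(bag_matrix)
        )
        phi = dense.mean(axis=0)
        return float(self.weights @ phi + self.bias)

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "C": self.C,
            "calibration": list(self.calibration),
            "n_positive_bags": self.n_positive_bags,
            "n_negative_bags": self.n_negative_bags,
            "objective": self.objective_,
            "vocabulary": None
            if self.vocab is None
            else {
                "terms": list(self.vocab.terms),
                "idf": list(self.vocab.idf),
                "df": list(self.vocab.df),
                "min_df": self.vocab.min_df,
                "n_docs_fit": self.vocab.n_docs_fit,
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SmilModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        vocab = None
        if payload.get("vocabulary"):
            v = payload["vocabulary"]
            vocab = Vocabulary(
                tuple(v["terms"]), tuple(v["idf"]), tuple(v["df"]), v["min_df"], v["n_docs_fit"]
            )
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            C=float(payload["C"]),
            vocab=vocab,
            calibration=tuple(payload["calibration"]),
            n_positive_bags=payload["n_positive_bags"],
            n_negative_bags=payload["n_negative_bags"],
            objective_=payload.get("objective", float("nan")),
        )


@dataclass(frozen=True)
class PairScore:
    pair_key: tuple[str, str]
    confidence: float
    frequency: float
    label: str  # distant-supervision label of the bag


def train_smil(
    bag_matrices: Sequence[np.ndarray | sp.spmatrix],
    labels: Sequence[str],
    C: float = 1.0,
    tol: float = 1e-8,
    vocab: Vocabulary | None = None,
    calibrate: bool = True,
) -> SmilModel:
    """Fit the sMIL program on labeled bags.

    ``bag_matrices[k]`` holds the instance vectors of bag ``k`` (one row per
    instance); ``labels[k]`` is ``"positive"`` or ``"negative"``. Requires at
    least one bag of each class. When ``calibrate`` is true a logistic
    (Platt) mapping from raw scores to [0, 1] is fitted on the training
    bags' own scores.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    n_pos = sum(1 for l in labels if l == "positive")
    n_neg = sum(1 for l in labels if l == "negative")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training needs at least one positive and one negative bag")
    X, y, margins, _ = smil_constraint_set(bag_matrices, labels)
    w, b, _alpha = solve_svm_dual(X, y, margins, C, tol=tol)
    model = SmilModel(
        weights=w,
        bias=b,
        C=C,
        vocab=vocab,
        n_positive_bags=n_pos,
        n_negative_bags=n_neg,
        objective_=svm_objective(X, y, margins, C, w, b),
    )
    if calibrate:
        scores = np.array([model.raw_score(m) for m in bag_matrices])
        targets = np.array([1.0 if l == "positive" else 0.0 for l in labels])
        model.calibration = _fit_platt(scores, targets)
    return model


def _fit_platt(scores: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """Fit sigma(a*s + c) by penalized log-likelihood, a constrained positive.

    Targets are smoothed the way Platt prescribed (n+1 / n+2 pseudo-counts)
    so perfectly separable scores still give a finite, monotone mapping.
    """
    n_pos = float(targets.sum())
    n_neg = float(len(targets) - n_pos)
    t = np.where(targets > 0.5, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        a, c = params
        z = a * scores + c
        # stable log(1+exp(z)) formulations
        log1p_exp = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        return float(np.sum(log1p_exp - t * z))

    res = minimize(
        nll,
        x0=np.array([1.0, 0.0]),
        method="L-BFGS-B",
        bounds=[(1e-6, None), (None, None)],
    )
    a, c = res.x
    return float(a), float(c)


def confidence(model: SmilModel, bag_matrix: np.ndarray | sp.spmatrix) -> float:
    """Calibrated confidence in [0, 1], monotone in the hyperplane distance."""
    a, c = model.calibration
    s = model.raw_score(bag_matrix)
    z = a * s + c
    return float(1.0 / (1.0 + np.exp(-z)))


def classify(score: float, threshold: float) -> str:
    """Threshold rule: positive iff score >= threshold."""
    return "positive" if score >= threshold else "negative"
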