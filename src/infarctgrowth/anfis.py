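"""Sugeno-type adaptive neuro-fuzzy inference system (ANFIS) for growth rates.

The network maps the first two infarct growth rates (IGR1, IGR2) to the
third (IGR3).  Each input is fuzzified by Gaussian membership functions
(three by default, the clusters G1-G3); rules combine per-input memberships
with a product T-norm into firing strengths W; each rule carries a
first-order Sugeno consequent f = p*IGR1 + q*IGR2 + r; defuzzification is
the firing-strength-weighted average of the rule outputs (the centroid of
the singleton consequents).

Parameters are fitted by Jang's hybrid rule: with premises (MF centers and
widths) fixed, the consequents are the exact linear least-squares solution
in the normalized-firing design matrix (forward pass); the premises are
then moved one normalized gradient-descent step against the squared
prediction error (backward pass).  The two passes alternate per epoch with
an adaptive step size.

Default rule base: the three "diagonal" rules
    IGR1 is G_k and IGR2 is G_k  ->  IGR3 is f_k,   k = 1..3;
a full grid (one rule per MF combination) is available via
``ANFISModel.from_data_range(..., rule_base="grid")``.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._util import atomic_write_text
from .errors import (
    InvalidParameterError,
    OutOfSupportError,
    UnderdeterminedError,
)

__all__ = [
    "GaussianMF",
    "Rule",
    "ANFISModel",
    "membership",
    "fire_rules",
    "predict_igr3",
    "predict",
    "lse_consequents",
    "premise_gradients",
    "backprop_premises",
    "train",
    "decision_surface",
    "save_model",
    "load_model",
]

WIDTH_FLOOR = 1e-6
FORMAT_VERSION = 1


@dataclass
class GaussianMF:
    """Gaussian membership function mu(x) = exp(-(x - center)^2 / (2 width^2))."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.width) and self.width > 0):
            raise InvalidParameterError(
                f"membership width must be finite and > 0, got {self.width!r}"
            )
        if not math.isfinite(self.center):
            raise InvalidParameterError(f"membership center must be finite")


@dataclass
class Rule:
    """One fuzzy rule: per-input MF indices plus a Sugeno consequent.

    ``consequent`` has one coefficient per input followed by an intercept;
    for a zero-order model the linear coefficients are held at zero.
    """

    antecedent: Tuple[int, ...]
    consequent: np.ndarray

    def __post_init__(self) -> None:
        self.antecedent = tuple(int(i) for i in self.antecedent)
        self.consequent = np.asarray(self.consequent, dtype=float)
        if self.consequent.shape != (len(self.antecedent) + 1,):
            raise InvalidParameterError(
                "consequent must have one coefficient per input plus an intercept"
            )


@dataclass
class ANFISModel:
    """Membership functions, rule base and training metadata."""

    input_names: Tuple[str, ...]
    mfs: List[List[GaussianMF]]
    rules: List[Rule]
    order: int = 1
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input_names = tuple(self.input_names)
        n_in = len(self.input_names)
        if len(self.mfs) != n_in:
            raise InvalidParameterError("one MF list required per input")
        if not self.rules:
            raise InvalidParameterError("model needs at least one rule")
        if self.order not in (0, 1):
            raise InvalidParameterError("order must be 0 or 1")
        for rule in self.rules:
            if len(rule.antecedent) != n_in:
                raise InvalidParameterError("rule antecedent length != n inputs")
            for j, a in enumerate(rule.antecedent):
                if not 0 <= a < len(self.mfs[j]):
                    raise InvalidParameterError(
                        f"rule references MF {a} of input {j}, which does not exist"
                    )

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @classmethod
    def from_data_range(
        cls,
        X: np.ndarray,
        n_mf: int = 3,
        rule_base: str = "diagonal",
        order: int = 1,
        input_names: Sequence[str] = ("IGR1", "IGR2"),
    ) -> "ANFISModel":
        """Initialize MFs from the training-data range.

        Centers are placed at ``n_mf`` equispaced points from min to max of
        each input; widths are (max - min) / (2 (n_mf - 1)), floored at
        ``WIDTH_FLOOR``.  Consequents start at zero.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(input_names):
            raise InvalidParameterError("X column count != number of inputs")
        if n_mf < 2:
            raise InvalidParameterError("need at least 2 membership functions")
        mfs: List[List[GaussianMF]] = []
        for j in range(X.shape[1]):
            lo, hi = float(np.min(X[:, j])), float(np.max(X[:, j]))
            width = max((hi - lo) / (2.0 * (n_mf - 1)), WIDTH_FLOOR)
            centers = np.linspace(lo, hi, n_mf)
            mfs.append([GaussianMF(float(c), width) for c in centers])
        if rule_base == "diagonal":
            antecedents = [(k,) * len(input_names) for k in range(n_mf)]
        elif rule_base == "grid":
            antecedents = list(
                itertools.product(range(n_mf), repeat=len(input_names))
            )
        else:
            raise InvalidParameterError(f"unknown rule base {rule_base!r}")
        rules = [
            Rule(a, np.zeros(len(input_names) + 1)) for a in antecedents
        ]
        return cls(tuple(input_names), mfs, rules, order=order)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "input_names": list(self.input_names),
            "order": self.order,
            "mfs": [
                [{"center": mf.center, "width": mf.width} for mf in per_input]
                for per_input in self.mfs
            ],
            "rules": [
                {
                    "antecedent": list(r.antecedent),
                    "consequent": [float(c) for c in r.consequent],
                }
                for r in self.rules
            ],
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANFISModel":
        if d.get("format_version") != FORMAT_VERSION:
            raise InvalidParameterError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        return cls(
            input_names=tuple(d["input_names"]),
            mfs=[
                [GaussianMF(m["center"], m["width"]) for m in per_input]
                for per_input in d["mfs"]
            ],
            rules=[
                Rule(tuple(r["antecedent"]), np.array(r["consequent"], dtype=float))
                for r in d["rules"]
            ],
            order=int(d["order"]),
            training_meta=dict(d.get("training_meta", {})),
        )


def membership(x: float, mf: GaussianMF) -> float:
    """Degree of membership of ``x`` in a Gaussian fuzzy set, in [0, 1]."""
    z = (x - mf.center) / mf.width
    return math.exp(-0.5 * z * z)


def _memberships(model: ANFISModel, X: np.ndarray) -> List[np.ndarray]:
    """Per-input membership matrices, shapes (N, n_mf_j)."""
    out = []
    for j in range(model.n_inputs):
        centers = np.array([mf.center for mf in model.mfs[j]])
        widths = np.array([mf.width for mf in model.mfs[j]])
        z = (X[:, j:j + 1] - centers[None, :]) / widths[None, :]
        out.append(np.exp(-0.5 * z * z))
    return out


def _firing_matrix(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Rule firing strengths, shape (N, n_rules); product T-norm."""
    mu = _memberships(model, X)
    W = np.ones((X.shape[0], model.n_rules))
    for r, rule in enumerate(model.rules):
        for j, a in enumerate(rule.antecedent):
            W[:, r] *= mu[j][:, a]
    return W


def fire_rules(igr1: float, igr2: float, model: ANFISModel) -> np.ndarray:
    """Firing strength of each rule at one input point."""
    X = np.array([[igr1, igr2]], dtype=float)
    return _firing_matrix(model, X)[0]


def _rule_outputs(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Sugeno consequent values f_r(x), shape (N, n_rules)."""
    P = np.stack([r.consequent for r in model.rules])  # (R, n_in + 1)
    if model.order == 0:
        return np.broadcast_to(P[:, -1], (X.shape[0], model.n_rules)).copy()
    return X @ P[:, :-1].T + P[:, -1][None, :]


def predict(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Defuzzified output for each row of ``X`` (weighted average of rules)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = _firing_matrix(model, X)
    S = W.sum(axis=1)
    if np.any(S <= 0.0) or not np.all(np.isfinite(S)):
        raise OutOfSupportError(
            "no rule fires at some query point (input far outside the "
            "training range)"
        )
    F = _rule_outputs(model, X)
    return (W * F).sum(axis=1) / S


def predict_igr3(model: ANFISModel, igr1: float, igr2: float) -> float:
    """Predicted third growth rate, cm^3/hour, at one (IGR1, IGR2) point."""
    return float(predict(model, np.array([[igr1, igr2]]))[0])


def _design_matrix(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """LSE design: normalized firings times [x, 1] blocks, rule-major."""
    W = _firing_matrix(model, X)
    S = W.sum(axis=1, keepdims=True)
    if np.any(S <= 0.0):
        raise OutOfSupportError("no rule fires at some training point")
    Wn = W / S
    n = X.shape[0]
    if model.order == 0:
        return Wn
    blocks = []
    ones = np.ones((n, 1))
    Xa = np.hstack([X, ones])  # (N, n_in + 1)
    for r in range(model.n_rules):
        blocks.append(Wn[:, r:r + 1] * Xa)
    return np.hstack(blocks)


def lse_consequents(
    model: ANFISModel,
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
) -> ANFISModel:
    """Fit the consequents by linear least squares with premises fixed.

    The system is solved by `numpy.linalg.lstsq`; when rank-deficient (e.g.
    a rule that never fires on the training data) a ridge term ``ridge`` is
    added to the normal equations, which drives the unidentified
    coefficients to ~0, and a warning is emitted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    A = _design_matrix(model, X)
    n_coef = A.shape[1]
    if X.shape[0] < (n_coef if model.order == 1 else model.n_rules):
        raise UnderdeterminedError(
            f"{X.shape[0]} training pairs cannot determine {n_coef} "
            "consequent coefficients"
        )
    theta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < n_coef:
        warnings.warn(
            "rank-deficient consequent system (some rule barely fires); "
            "using ridge-regularized solution",
            RuntimeWarning,
            stacklevel=2,
        )
        AtA = A.T @ A + ridge * np.eye(n_coef)
        theta = np.linalg.solve(AtA, A.T @ y)
    per_rule = 1 if model.order == 0 else model.n_inputs + 1
    for r, rule in enumerate(model.rules):
        coef = theta[r * per_rule:(r + 1) * per_rule]
        if model.order == 0:
            rule.consequent = np.concatenate(
                [np.zeros(model.n_inputs), coef]
            )
        else:
            rule.consequent = coef.copy()
    return model


def premise_gradients(
    model: ANFISModel, X: np.ndarray, y: np.ndarray
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Analytic gradient of the SSE w.r.t. every MF center and width.

    Returns (d_centers, d_widths): per input, an array over that input's
    MFs of dE/dparam with E = sum_n (yhat_n - y_n)^2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    mu = _memberships(model, X)
    W = np.ones((X.shape[0], model.n_rules))
    for r, rule in enumerate(model.rules):
        for j, a in enumerate(rule.antecedent):
            W[:, r] *= mu[j][:, a]
    S = W.sum(axis=1)
    if np.any(S <= 0.0):
        raise OutOfSupportError("no rule fires at some training point")
    F = _rule_outputs(model, X)
    yhat = (W * F).sum(axis=1) / S
    err2 = 2.0 * (yhat - y)  # dE/dyhat
    # dE/dW_{n,r} = err2 * (F_{n,r} - yhat_n) / S_n
    dW = err2[:, None] * (F - yhat[:, None]) / S[:, None]

    d_centers = [np.zeros(len(per)) for per in model.mfs]
    d_widths = [np.zeros(len(per)) for per in model.mfs]
    for r, rule in enumerate(model.rules):
        for j, a in enumerate(rule.antecedent):
            # product of the other inputs' memberships for this rule
            other = np.ones(X.shape[0])
            for j2, a2 in enumerate(rule.antecedent):
                if j2 != j:
                    other *= mu[j2][:, a2]
            g_mu = dW[:, r] * other  # dE/dmu_{j,a} through rule r
            mf = model.mfs[j][a]
            diff = X[:, j] - mf.center
            mu_ja = mu[j][:, a]
            d_centers[j][a] += np.sum(g_mu * mu_ja * diff / mf.width**2)
            d_widths[j][a] += np.sum(g_mu * mu_ja * diff**2 / mf.width**3)
    return d_centers, d_widths


def backprop_premises(
    model: ANFISModel, X: np.ndarray, y: np.ndarray, step_size: float
) -> ANFISModel:
    """One normalized gradient-descent step on all MF centers and widths.

    The update is ``param -= step_size * grad / ||grad||`` (Jang's
    normalized step); ``step_size == 0`` leaves the premises untouched.
    Widths are clipped to a positive floor after the update.
    """
    if step_size < 0:
        raise InvalidParameterError("step_size must be >= 0")
    if step_size == 0:
        return model
    d_centers, d_widths = premise_gradients(model, X, y)
    norm = math.sqrt(
        sum(float(np.sum(g**2)) for g in d_centers)
        + sum(float(np.sum(g**2)) for g in d_widths)
    )
    if norm == 0.0 or not math.isfinite(norm):
        return model
    eta = step_size / norm
    for j, per_input in enumerate(model.mfs):
        for a, mf in enumerate(per_input):
            mf.center -= eta * float(d_centers[j][a])
            mf.width = max(mf.width - eta * float(d_widths[j][a]), WIDTH_FLOOR)
    return model


def _adapt_step(rmse_trace: Sequence[float], step: float) -> float:
    """Jang's step-size heuristic on the epoch RMSE trace.

    Grow by 10% after four consecutive decreases; shrink by 10% after two
    consecutive up/down oscillation pairs.
    """
    if len(rmse_trace) >= 5:
        d = np.diff(rmse_trace[-5:])
        if np.all(d < 0):
            return step * 1.1
    if len(rmse_trace) >= 5:
        d = np.diff(rmse_trace[-5:])
        signs = np.sign(d)
        if np.all(signs != 0) and np.all(signs[1:] != signs[:-1]):
            return step * 0.9
    return step


def train(
    model: ANFISModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 50,
    step_size: float = 0.01,
    tol: float = 1e-6,
    abs_tol: float = 1e-12,
    adapt_step: bool = True,
    ridge: float = 1e-8,
) -> Tuple[ANFISModel, List[float]]:
    """Hybrid training: per epoch, LSE forward pass then gradient backward pass.

    Early-stops when the relative RMSE improvement drops below ``tol`` or
    the RMSE itself drops below ``abs_tol`` (an exact fit; the normalized
    gradient step would otherwise keep perturbing the premises).
    With ``epochs=1`` and ``step_size=0`` this reduces to a pure
    least-squares consequent fit.  Returns the model and its RMSE trace;
    training metadata is recorded on the model.
    """
    if epochs < 1:
        raise InvalidParameterError("epochs must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rmse_trace: List[float] = []
    step_trace: List[float] = []
    step = step_size
    early_stopped = False
    for _ in range(epochs):
        lse_consequents(model, X, y, ridge=ridge)
        resid = predict(model, X) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        rmse_trace.append(rmse)
        step_trace.append(step)
        if rmse <= abs_tol:
            early_stopped = True
            break
        if len(rmse_trace) >= 2:
            prev = rmse_trace[-2]
            if abs(prev - rmse) <= tol * max(prev, 1e-300):
                early_stopped = True
                break
        backprop_premises(model, X, y, step)
        if adapt_step:
            step = _adapt_step(rmse_trace, step)
    if not early_stopped and step_size > 0:
        # premises moved after the last LSE; refit consequents to them
        lse_consequents(model, X, y, ridge=ridge)
        resid = predict(model, X) - y
        rmse_trace.append(float(np.sqrt(np.mean(resid**2))))
        step_trace.append(step)
    model.training_meta = {
        "epochs_run": len(rmse_trace),
        "final_rmse": rmse_trace[-1],
        "rmse_trace": rmse_trace,
        "step_trace": step_trace,
        "early_stopped": early_stopped,
    }
    return model, rmse_trace


def decision_surface(
    model: ANFISModel,
    igr1_values: np.ndarray,
    igr2_values: np.ndarray,
) -> np.ndarray:
    """Predicted IGR3 over the grid; entry [i, j] is at (igr1[i], igr2[j])."""
    igr1_values = np.asarray(igr1_values, dtype=float).ravel()
    igr2_values = np.asarray(igr2_values, dtype=float).ravel()
    G1, G2 = np.meshgrid(igr1_values, igr2_values, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel()])
    return predict(model, pts).reshape(G1.shape)


def save_model(model: ANFISModel, path) -> None:
    """Persist the model as JSON (lossless for IEEE doubles)."""
    atomic_write_text(path, json.dumps(model.to_dict(), indent=2))


def load_model(path) -> ANFISModel:
    with open(path, "r", encoding="utf-8") as fh:
        return ANFISModel.from_dict(json.load(fh))
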