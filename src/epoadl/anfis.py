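"""Sugeno-type adaptive neuro-fuzzy inference system (ANFIS).

Five layers: fuzzification with generalized-bell membership functions,
rule firing strengths by product, normalisation, first-order linear rule
consequents, and a weighted-sum output. The rule base is the full grid
(Cartesian product of the per-input membership functions), so the rule
count is ``n_mf ** n_inputs``.

Training is the classic hybrid scheme: with the premise (membership)
parameters fixed, the consequent coefficients are the exact solution of a
ridge-regularised least-squares problem; the premise parameters then take a
gradient step on the squared error. The binary classifier regresses the
output to the {0, 1} labels and thresholds at 0.5.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BellMF",
    "FuzzyRule",
    "ANFISModel",
    "ANFISTrainConfig",
    "bell_membership",
    "fuzzify",
    "firing_strengths",
    "normalize_firing",
    "rule_outputs",
    "forward",
    "fit",
    "predict",
    "model_to_json",
    "model_from_json",
]

_EPS_FIRING = 1e-12
MAX_RULES = 1024


@dataclass(frozen=True)
class BellMF:
    """Generalized bell membership function 1 / (1 + |(x-c)/a|^(2b))."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("bell width a must be positive")
        if self.b <= 0:
            raise ValueError("bell slope b must be positive")


@dataclass(frozen=True)
class FuzzyRule:
    """One rule: an MF index per input plus first-order consequent (p_1..p_n, r)."""

    mf_index: tuple[int, ...]
    consequent: tuple[float, ...]


@dataclass
class ANFISModel:
    """Grid-partition Sugeno model.

    ``a, b, c`` hold the bell parameters as (n_inputs, n_mf) arrays;
    ``rule_index`` is the (n_rules, n_inputs) MF-selection table and
    ``consequents`` the (n_rules, n_inputs + 1) coefficient table with the
    constant term last.
    """

    n_inputs: int
    n_mf: int
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    rule_index: np.ndarray
    consequents: np.ndarray
    loss_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("all bell widths a and slopes b must be positive")
        if self.rule_index.shape != (self.n_mf**self.n_inputs, self.n_inputs):
            raise ValueError("rule base must be the full MF grid")
        if self.consequents.shape != (self.n_rules, self.n_inputs + 1):
            raise ValueError("consequent table shape mismatch")

    @property
    def n_rules(self) -> int:
        return int(self.n_mf**self.n_inputs)

    @property
    def rules(self) -> list[FuzzyRule]:
        return [
            FuzzyRule(tuple(int(k) for k in idx), tuple(float(v) for v in coef))
            for idx, coef in zip(self.rule_index, self.consequents)
        ]

    @classmethod
    def from_grid(cls, X: np.ndarray, n_mf: int) -> "ANFISModel":
        """Initialise from data: centers evenly spaced over each feature's
        observed [min, max], width a = half the center spacing, slope b = 2.

        A feature with (near-)zero range gets unit width so the model stays
        well defined on degenerate inputs.
        """
        X = np.asarray(X, dtype=float)
        n_inputs = X.shape[1]
        if n_mf**n_inputs > MAX_RULES:
            raise ValueError(
                f"rule base {n_mf}^{n_inputs} exceeds the {MAX_RULES}-rule guard"
            )
        lo, hi = X.min(axis=0), X.max(axis=0)
        c = np.linspace(lo, hi, n_mf).T  # (n_inputs, n_mf)
        if n_mf > 1:
            spacing = (hi - lo) / (n_mf - 1)
        else:
            spacing = hi - lo
        a = np.repeat((spacing / 2.0)[:, None], n_mf, axis=1)
        a[a <= 1e-12] = 1.0
        b = np.full((n_inputs, n_mf), 2.0)
        rule_index = np.array(
            list(itertools.product(range(n_mf), repeat=n_inputs)), dtype=int
        )
        consequents = np.zeros((rule_index.shape[0], n_inputs + 1))
        return cls(n_inputs, n_mf, a, b, c.copy(), rule_index, consequents)


@dataclass(frozen=True)
class ANFISTrainConfig:
    epochs: int = 25
    premise_lr: float = 0.01
    hybrid: bool = True
    seed: int | None = None
    l2_ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.premise_lr < 0:
            raise ValueError("premise_lr must be >= 0")


# ---------------------------------------------------------------------------
# the five layers


def bell_membership(x: float, mf: BellMF) -> float:
    """Membership degree in (0, 1]: 1 at the center, 0.5 at c +/- a."""
    t = abs((x - mf.c) / mf.a)
    return 1.0 / (1.0 + t ** (2.0 * mf.b))


def _memberships(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """(n_samples, n_inputs, n_mf) membership grid."""
    t = np.abs((X[:, :, None] - model.c[None]) / model.a[None])
    return 1.0 / (1.0 + t ** (2.0 * model.b[None]))


def fuzzify(x: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Layer 1: membership degree per (input, MF) — shape (n_inputs, n_mf)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected {model.n_inputs}-vector, got shape {x.shape}")
    return _memberships(x[None], model)[0]


def firing_strengths(memberships: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Layer 2: product T-norm over each rule's selected memberships."""
    cols = np.arange(model.n_inputs)
    return np.prod(memberships[cols[None, :], model.rule_index], axis=1)


def normalize_firing(w: np.ndarray) -> np.ndarray:
    """Layer 3: w_i / sum(w); a vanishing total (< 1e-12) yields the uniform
    distribution so the output stays defined on far-out-of-range inputs."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("firing strengths must be non-negative")
    s = w.sum()
    if s < _EPS_FIRING:
        return np.full(w.size, 1.0 / w.size)
    return w / s


def rule_outputs(x: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Layer 4 consequents: f_i = sum_j p_ij x_j + r_i."""
    x = np.asarray(x, dtype=float)
    return model.consequents[:, :-1] @ x + model.consequents[:, -1]


def forward(x: np.ndarray, model: ANFISModel) -> float:
    """Layer 5: normalised-weight sum, equal to (sum w_i f_i) / (sum w_i)."""
    w = firing_strengths(fuzzify(x, model), model)
    return float(normalize_firing(w) @ rule_outputs(x, model))


def _firing_batch(mem: np.ndarray, model: ANFISModel) -> np.ndarray:
    # mem: (n, d, m) -> (n, n_rules)
    n = mem.shape[0]
    w = np.ones((n, model.n_rules))
    for j in range(model.n_inputs):
        w *= mem[:, j, model.rule_index[:, j]]
    return w


def _normalize_batch(w: np.ndarray) -> np.ndarray:
    s = w.sum(axis=1, keepdims=True)
    wn = np.where(s < _EPS_FIRING, 1.0 / w.shape[1], w / np.maximum(s, _EPS_FIRING))
    return wn


def _predict_values(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mem = _memberships(X, model)
    w = _firing_batch(mem, model)
    wn = _normalize_batch(w)
    f = X @ model.consequents[:, :-1].T + model.consequents[None, :, -1]
    return np.sum(wn * f, axis=1)


# ---------------------------------------------------------------------------
# training


def _design_matrix(X: np.ndarray, wn: np.ndarray) -> np.ndarray:
    """Stack per-rule [wn*x_1 .. wn*x_d, wn] blocks: (n, n_rules*(d+1))."""
    n, d = X.shape
    xa = np.concatenate([X, np.ones((n, 1))], axis=1)  # (n, d+1)
    return (wn[:, :, None] * xa[:, None, :]).reshape(n, -1)


def _solve_ridge(phi: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact ridge solution; the dual (kernel) form is used when the number
    of coefficients exceeds the sample count."""
    n, p = phi.shape
    if p <= n:
        return np.linalg.solve(phi.T @ phi + lam * np.eye(p), phi.T @ y)
    alpha = np.linalg.solve(phi @ phi.T + lam * np.eye(n), y)
    return phi.T @ alpha


def _premise_gradient(X, y, model: ANFISModel):
    """Analytic gradient of the mean squared error w.r.t. the bell a, b, c."""
    n, d = X.shape
    mem = _memberships(X, model)  # (n, d, m)
    w = _firing_batch(mem, model)  # (n, R)
    s = np.maximum(w.sum(axis=1, keepdims=True), _EPS_FIRING)
    wn = w / s
    f = X @ model.consequents[:, :-1].T + model.consequents[None, :, -1]
    out = np.sum(wn * f, axis=1)
    resid = 2.0 * (out - y) / n  # dL/d out

    # d out / d w_r = (f_r - out) / s ; chain to memberships through the rules
    g_w = (f - out[:, None]) / s  # (n, R)
    gm = np.zeros_like(mem)
    for j in range(d):
        idx = model.rule_index[:, j]
        contrib = resid[:, None] * g_w * w / np.maximum(mem[:, j, idx], 1e-300)
        for m in range(model.n_mf):
            gm[:, j, m] = np.sum(contrib[:, idx == m], axis=1)

    # bell partials via u = |t|^(2b), mu = 1/(1+u)
    diff = X[:, :, None] - model.c[None]
    t = np.abs(diff / model.a[None])
    u = t ** (2.0 * model.b[None])
    dmu_du = -(mem**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        du_da = -2.0 * model.b[None] * u / model.a[None]
        du_dc = np.where(diff != 0, -2.0 * model.b[None] * u / diff, 0.0)
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), 0.0)
        du_db = 2.0 * u * logt
    common = gm * dmu_du
    ga = np.sum(common * du_da, axis=0)
    gb = np.sum(common * du_db, axis=0)
    gc = np.sum(common * du_dc, axis=0)
    return ga, gb, gc


def fit(
    model: ANFISModel, X: np.ndarray, y: np.ndarray, config: ANFISTrainConfig
) -> ANFISModel:
    """Hybrid training; mutates and returns ``model`` with a per-epoch
    ``loss_trace`` (MSE after the consequent update).

    Each epoch: exact ridge least squares for the consequents given the
    current premises (when ``hybrid``), then one gradient step on the bell
    parameters. With ``premise_lr == 0`` the premises are frozen and the
    loss trace is non-increasing by least-squares optimality.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and labels must be finite")
    if model.n_rules > MAX_RULES:
        raise ValueError(f"rule base exceeds the {MAX_RULES}-rule guard")

    d = model.n_inputs
    model.loss_trace = []
    a_floor = 1e-6
    for _ in range(config.epochs):
        mem = _memberships(X, model)
        wn = _normalize_batch(_firing_batch(mem, model))
        if config.hybrid:
            phi = _design_matrix(X, wn)
            theta = _solve_ridge(phi, y, config.l2_ridge)
            model.consequents = theta.reshape(model.n_rules, d + 1)
        out = _predict_values(X, model)
        model.loss_trace.append(float(np.mean((out - y) ** 2)))
        if config.premise_lr > 0:
            ga, gb, gc = _premise_gradient(X, y, model)
            model.a = np.maximum(model.a - config.premise_lr * ga, a_floor)
            model.b = np.clip(model.b - config.premise_lr * gb, 0.1, 10.0)
            model.c = model.c - config.premise_lr * gc
    return model


def predict(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Binary labels: 1 iff the network output is >= 0.5 (boundary -> 1)."""
    return (_predict_values(X, model) >= 0.5).astype(int)


def predict_values(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs (regression scores before thresholding)."""
    return _predict_values(X, model)


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: ANFISModel) -> str:
    doc = {
        "n_inputs": model.n_inputs,
        "n_mf": model.n_mf,
        "a": model.a.tolist(),
        "b": model.b.tolist(),
        "c": model.c.tolist(),
        "rule_index": model.rule_index.tolist(),
        "consequents": model.consequents.tolist(),
    }
    return json.dumps(doc)


def model_from_json(doc: str) -> ANFISModel:
    d = json.loads(doc)
    return ANFISModel(
        n_inputs=int(d["n_inputs"]),
        n_mf=int(d["n_mf"]),
        a=np.asarray(d["a"], dtype=float),
        b=np.asarray(d["b"], dtype=float),
        c=np.asarray(d["c"], dtype=float),
        rule_index=np.asarray(d["rule_index"], dtype=int),
        consequents=np.asarray(d["consequents"], dtype=float),
    )
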