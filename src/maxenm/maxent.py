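"""Presence-background maximum-entropy model.

The model estimates a Gibbs density over the background cells of the
accessible area: raw(x) = exp(beta . f(x)) / Z, where f(x) are feature
transformations of the environmental variables (linear, quadratic,
product, threshold, hinge), and beta minimizes the L1-regularized
presence-background objective

    J(beta) = -(1/m) sum_i eta(x_i) + log sum_b exp(eta(x_b)) - log N_b
              + sum_j lambda_j |beta_j|

with eta = beta . f. At the optimum the KKT conditions bound the gap
between the presence mean of each feature and its expectation under the
model by lambda_j. Per-feature penalties follow the published per-class
sample-size tables scaled by a global regularization multiplier (RM).
The logistic output transforms raw through the entropy of the fitted
density so that a cell with "typical" suitability scores 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp, softmax

from .rasters import RasterStack

FEATURE_CLASSES = ("L", "Q", "P", "T", "H")
#: the five feature-class combinations of the calibration grid
ALLOWED_COMBOS: tuple[tuple[str, ...], ...] = (
    ("L",),
    ("L", "Q"),
    ("L", "Q", "P"),
    ("L", "Q", "P", "T"),
    ("L", "Q", "P", "T", "H"),
)


class ConvergenceError(RuntimeError):
    """Raised when the optimizer exhausts its iteration budget.

    Carries the objective trace for diagnosis."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature classes to expand, and the knot counts."""

    classes: tuple[str, ...]
    n_threshold_knots: int = 10
    n_hinge_knots: int = 20

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class required")
        bad = [c for c in self.classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes {bad}")

    @property
    def label(self) -> str:
        return "".join(c.lower() for c in FEATURE_CLASSES if c in self.classes)


@dataclass
class FeatureExpander:
    """Deterministic feature expansion with frozen min-max scaling.

    Scaling is fixed from the calibration data (presences plus
    background); columns are ordered class-major (L, Q, P, T, H), variables
    in input order, knots ascending. Constant variables scale to all-zero
    columns and are flagged rather than erroring.
    """

    variable_names: list[str]
    scaling: dict[str, tuple[float, float]]
    config: FeatureConfig
    constant_vars: list[str] = field(default_factory=list)

    @classmethod
    def from_calibration(
        cls, values: np.ndarray, names: list[str], config: FeatureConfig
    ) -> "FeatureExpander":
        values = np.asarray(values, dtype=float)
        scaling = {}
        constant = []
        for j, name in enumerate(names):
            lo = float(np.min(values[:, j]))
            hi = float(np.max(values[:, j]))
            scaling[name] = (lo, hi)
            if hi == lo:
                constant.append(name)
        return cls(list(names), scaling, config, constant)

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for j, name in enumerate(self.variable_names):
            lo, hi = self.scaling[name]
            out[:, j] = (X[:, j] - lo) / (hi - lo) if hi > lo else 0.0
        return out

    def feature_meta(self) -> list[dict]:
        meta: list[dict] = []
        names = self.variable_names
        cfg = self.config
        if "L" in cfg.classes:
            meta += [{"class": "L", "vars": (n,), "knot": None} for n in names]
        if "Q" in cfg.classes:
            meta += [{"class": "Q", "vars": (n,), "knot": None} for n in names]
        if "P" in cfg.classes:
            meta += [
                {"class": "P", "vars": (a, b), "knot": None}
                for a, b in combinations(names, 2)
            ]
        if "T" in cfg.classes:
            knots = _threshold_knots(cfg.n_threshold_knots)
            for n in names:
                meta += [{"class": "T", "vars": (n,), "knot": float(k)} for k in knots]
        if "H" in cfg.classes:
            fwd, rev = _hinge_knots(cfg.n_hinge_knots)
            for n in names:
                meta += [{"class": "H", "vars": (n,), "knot": float(k), "dir": "fwd"} for k in fwd]
                meta += [{"class": "H", "vars": (n,), "knot": float(k), "dir": "rev"} for k in rev]
        return meta

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Expand raw variable values (n x p) into the feature matrix (n x d)."""
        S = self._scaled(X)
        cfg = self.config
        cols: list[np.ndarray] = []
        if "L" in cfg.classes:
            cols.append(S)
        if "Q" in cfg.classes:
            cols.append(S**2)
        if "P" in cfg.classes:
            prods = [S[:, i] * S[:, j] for i, j in combinations(range(S.shape[1]), 2)]
            if prods:
                cols.append(np.column_stack(prods))
        if "T" in cfg.classes:
            knots = _threshold_knots(cfg.n_threshold_knots)
            t = (S[:, :, None] > knots[None, None, :]).astype(float)
            cols.append(t.reshape(S.shape[0], -1))
        if "H" in cfg.classes:
            fwd, rev = _hinge_knots(cfg.n_hinge_knots)
            f = np.maximum(0.0, (S[:, :, None] - fwd[None, None, :]) / (1.0 - fwd)[None, None, :])
            r = np.maximum(0.0, (rev[None, None, :] - S[:, :, None]) / rev[None, None, :])
            h = np.concatenate([f, r], axis=2)
            cols.append(h.reshape(S.shape[0], -1))
        return np.concatenate(cols, axis=1) if len(cols) > 1 else cols[0]


def _threshold_knots(k: int) -> np.ndarray:
    # k knots strictly inside (0, 1), evenly spaced
    return np.arange(1, k + 1) / (k + 1)


def _hinge_knots(k: int) -> tuple[np.ndarray, np.ndarray]:
    fwd = np.arange(0, k) / k          # includes 0 (a pure linear ramp)
    rev = np.arange(1, k + 1) / k      # includes 1
    return fwd, rev


@dataclass
class FeatureMatrix:
    """Expanded features for presences and background, plus metadata."""

    presence: np.ndarray
    background: np.ndarray
    expander: FeatureExpander

    def __post_init__(self) -> None:
        d = self.presence.shape[1]
        if self.background.shape[1] != d:
            raise ValueError("presence/background feature dimension mismatch")
        lo = min(self.presence.min(initial=0.0), self.background.min(initial=0.0))
        hi = max(self.presence.max(initial=1.0), self.background.max(initial=1.0))
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError("calibration features must be scaled to [0, 1]")

    @property
    def meta(self) -> list[dict]:
        return self.expander.feature_meta()


def build_feature_matrix(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    names: list[str],
    config: FeatureConfig,
) -> FeatureMatrix:
    """Freeze scaling on presences+background and expand both tables."""
    both = np.vstack([presence_values, background_values])
    expander = FeatureExpander.from_calibration(both, names, config)
    return FeatureMatrix(
        presence=expander.transform(presence_values),
        background=expander.transform(background_values),
        expander=expander,
    )


# Published per-class regularization tables: (sample sizes, beta values),
# linearly interpolated in m and clamped at the ends. Linear, quadratic and
# product features share one table; hinge is constant 0.5.
_BETA_TABLES = {
    "L": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "Q": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "P": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "T": ([10, 100], [2.0, 1.0]),
    "H": ([0], [0.5]),
}


def beta_class(feature_class: str, n_presences: int) -> float:
    """Per-class regularization base from the published interpolation table."""
    xs, ys = _BETA_TABLES[feature_class]
    return float(np.interp(n_presences, xs, ys))


def default_regularization(
    feature_meta: list[dict],
    presence_features: np.ndarray,
    n_presences: int,
    rm: float,
) -> np.ndarray:
    """Per-feature penalty lambda_j = rm * beta_class(m) * s_j / sqrt(m).

    s_j is the feature's standard deviation over the presences, floored at
    1/sqrt(m) so constant features still carry a positive penalty; the
    whole vector scales linearly with the regularization multiplier.
    """
    if n_presences < 1:
        raise ValueError("need at least one presence")
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    m = n_presences
    s = presence_features.std(axis=0, ddof=0)
    s = np.maximum(s, 1.0 / np.sqrt(m))
    classes = np.array([meta["class"] for meta in feature_meta])
    base = np.array([beta_class(c, m) for c in classes])
    return rm * base * s / np.sqrt(m)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model."""

    beta: np.ndarray
    log_z: float
    entropy: float
    rm: float
    lambdas: np.ndarray
    clamp_bounds: dict[str, tuple[float, float]]
    feature_config: FeatureConfig
    variable_set: list[str]
    expander: FeatureExpander
    n_iterations: int = 0

    @property
    def n_parameters(self) -> int:
        """Count of nonzero coefficients (the k of AICc)."""
        return int(np.count_nonzero(self.beta))

    # --- prediction ---------------------------------------------------

    def _eta(self, values: np.ndarray, clamp: bool) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if clamp:
            values = values.copy()
            for j, name in enumerate(self.variable_set):
                lo, hi = self.clamp_bounds[name]
                values[:, j] = np.clip(values[:, j], lo, hi)
        return self.expander.transform(values) @ self.beta

    def raw_values(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        """exp(eta - log Z) at a table of raw variable values."""
        return np.exp(self._eta(values, clamp) - self.log_z)

    def logistic_values(self, values: np.ndarray, clamp: bool = True, tau: float = 0.5) -> np.ndarray:
        raw = self.raw_values(values, clamp)
        c = tau * np.exp(self.entropy)
        return c * raw / ((1.0 - tau) + c * raw)

    def _predict_grid(self, stack: RasterStack, clamp: bool, logistic: bool, tau: float = 0.5) -> np.ndarray:
        missing = [v for v in self.variable_set if v not in stack.layers]
        if missing:
            raise KeyError(f"stack is missing model variables: {missing}")
        vals, idx = stack.table(self.variable_set)
        pred = (
            self.logistic_values(vals, clamp, tau) if logistic else self.raw_values(vals, clamp)
        )
        out = np.full(stack.grid.nrows * stack.grid.ncols, np.nan)
        out[idx] = pred
        return out.reshape(stack.grid.nrows, stack.grid.ncols)

    def predict_raw(self, stack: RasterStack, clamp: bool = True) -> np.ndarray:
        """Gibbs density raster; sums to 1 over the calibration background."""
        return self._predict_grid(stack, clamp, logistic=False)

    def predict_logistic(self, stack: RasterStack, clamp: bool = True, tau: float = 0.5) -> np.ndarray:
        """Suitability raster in (0, 1); 0.5 at cells of typical suitability."""
        return self._predict_grid(stack, clamp, logistic=True, tau=tau)

    # --- serialization ------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "rm": self.rm,
            "lambdas": self.lambdas.tolist(),
            "clamp_bounds": {k: list(v) for k, v in self.clamp_bounds.items()},
            "feature_config": {
                "classes": list(self.feature_config.classes),
                "n_threshold_knots": self.feature_config.n_threshold_knots,
                "n_hinge_knots": self.feature_config.n_hinge_knots,
            },
            "variable_set": self.variable_set,
            "scaling": {k: list(v) for k, v in self.expander.scaling.items()},
            "constant_vars": self.expander.constant_vars,
            "n_iterations": self.n_iterations,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        cfg = FeatureConfig(
            classes=tuple(doc["feature_config"]["classes"]),
            n_threshold_knots=doc["feature_config"]["n_threshold_knots"],
            n_hinge_knots=doc["feature_config"]["n_hinge_knots"],
        )
        expander = FeatureExpander(
            variable_names=list(doc["variable_set"]),
            scaling={k: tuple(v) for k, v in doc["scaling"].items()},
            config=cfg,
            constant_vars=list(doc["constant_vars"]),
        )
        return cls(
            beta=np.asarray(doc["beta"], dtype=float),
            log_z=float(doc["log_z"]),
            entropy=float(doc["entropy"]),
            rm=float(doc["rm"]),
            lambdas=np.asarray(doc["lambdas"], dtype=float),
            clamp_bounds={k: tuple(v) for k, v in doc["clamp_bounds"].items()},
            feature_config=cfg,
            variable_set=list(doc["variable_set"]),
            expander=expander,
            n_iterations=int(doc["n_iterations"]),
        )


def _objective_parts(beta, Fp, Fb, lambdas):
    eta_b = Fb @ beta
    lse = logsumexp(eta_b)
    smooth = -float(np.mean(Fp @ beta)) + lse - np.log(Fb.shape[0])
    return smooth + float(lambdas @ np.abs(beta)), smooth, eta_b, lse


def kkt_residual(beta, Fp, Fb, lambdas) -> float:
    """Max violation of the stationarity conditions of the L1 objective."""
    q = softmax(Fb @ beta)
    grad = -Fp.mean(axis=0) + Fb.T @ q
    res_zero = np.maximum(np.abs(grad) - lambdas, 0.0)
    res_active = np.abs(grad + lambdas * np.sign(beta))
    return float(np.max(np.where(beta == 0.0, res_zero, res_active), initial=0.0))


def fit_maxent(
    fm: FeatureMatrix,
    lambdas: np.ndarray,
    rm: float = 1.0,
    clamp_bounds: dict[str, tuple[float, float]] | None = None,
    tol: float = 1e-8,
    kkt_tol: float = 5e-5,
    max_iter: int = 5000,
) -> MaxentModel:
    """Fit by accelerated proximal gradient (FISTA) with soft-thresholding.

    Backtracking line search on the smooth part, monotone restart, and a
    dual stopping rule: KKT stationarity residual below ``kkt_tol`` or
    best-objective change below ``tol``. Raises :class:`ConvergenceError`
    (with the objective trace) if the iteration budget is exhausted.
    """
    Fp = np.asarray(fm.presence, dtype=float)
    Fb = np.asarray(fm.background, dtype=float)
    if Fp.shape[0] < 1 or Fb.shape[0] < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise ValueError("penalties must be nonnegative")
    d = Fp.shape[1]
    pbar = Fp.mean(axis=0)
    beta = np.zeros(d)
    y = beta.copy()
    t_mom = 1.0
    L = 1.0
    trace: list[float] = []
    f_best = np.inf
    beta_best = beta.copy()
    stall = 0

    def smooth_grad(b):
        eta_b = Fb @ b
        q = softmax(eta_b)
        g = -pbar + Fb.T @ q
        val = -float(pbar @ b) + logsumexp(eta_b) - np.log(Fb.shape[0])
        return val, g

    f_y, g_y = smooth_grad(y)
    for it in range(max_iter):
        # backtracking proximal step from y
        while True:
            step = 1.0 / L
            cand = np.sign(y - step * g_y) * np.maximum(np.abs(y - step * g_y) - step * lambdas, 0.0)
            diff = cand - y
            f_cand, _ = smooth_grad(cand)
            if f_cand <= f_y + g_y @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        beta_new = cand
        obj_new = f_cand + float(lambdas @ np.abs(beta_new))
        trace.append(obj_new)
        improved = f_best - obj_new
        if obj_new < f_best:
            f_best = obj_new
            beta_best = beta_new
        # adaptive restart: momentum reset when the objective rises
        if it > 0 and obj_new > trace[-2]:
            t_mom = 1.0
            y = beta_best.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            y = beta_new + ((t_mom - 1.0) / t_new) * (beta_new - beta)
            t_mom = t_new
        beta = beta_new
        f_y, g_y = smooth_grad(y)
        L = max(L / 2.0, 1e-6)  # allow the step to grow again
        if improved >= 0:
            stall = stall + 1 if improved < tol else 0
        if it % 10 == 9 or stall >= 5:
            if kkt_residual(beta_best, Fp, Fb, lambdas) < kkt_tol:
                break
            if stall >= 25:
                break
    else:
        if kkt_residual(beta_best, Fp, Fb, lambdas) > 10 * kkt_tol:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations (objective {f_best:.6g})", trace
            )

    beta = beta_best
    # tidy numerically-dead coefficients so the parameter count is meaningful
    beta[np.abs(beta) < 1e-12] = 0.0
    eta_b = Fb @ beta
    log_z = float(logsumexp(eta_b))
    q = softmax(eta_b)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    expander = fm.expander
    bounds = clamp_bounds or {k: v for k, v in expander.scaling.items()}
    return MaxentModel(
        beta=beta,
        log_z=log_z,
        entropy=entropy,
        rm=rm,
        lambdas=lambdas,
        clamp_bounds=bounds,
        feature_config=expander.config,
        variable_set=list(expander.variable_names),
        expander=expander,
        n_iterations=len(trace),
    )


def training_gain(model: MaxentModel, fm: FeatureMatrix, regularized: bool = True) -> float:
    """Improvement of the presence log-likelihood over the uniform model.

    gain = mean presence eta - log Z + log N_b (minus the L1 penalty when
    ``regularized``); zero for the all-uniform model.
    """
    eta_p = fm.presence @ model.beta
    gain = float(np.mean(eta_p)) - model.log_z + np.log(fm.background.shape[0])
    if regularized:
        gain -= float(model.lambdas @ np.abs(model.beta))
    return gain
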