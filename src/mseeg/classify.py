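"""RBF-SVM classification with grasshopper-optimized hyperparameters.

The classifier is a soft-margin SVM with the radial basis kernel
``K(u, v) = exp(-gamma ||u - v||^2)`` (the kernel width and the
Gaussian sigma are redundant and collapsed into the single ``gamma``).
Its two hyperparameters ``(C, gamma)`` are tuned by the grasshopper
optimization algorithm (GOA), a continuous swarm method: each agent
combines pairwise social attraction/repulsion

    ``s(r) = f * exp(-r / l) - exp(-r)``     (f = 0.5, l = 1.5)

with a pull toward the best position seen so far, damped by a comfort
coefficient that decays linearly from ``c_max`` to ``c_min`` over the
iteration budget:

    ``c(l) = c_max - l * (c_max - c_min) / L``.

The search runs in ``(log10 C, log10 gamma)`` space because both
hyperparameters act multiplicatively.  The tuning objective is

    ``Fitness = 1 - alpha * Accuracy + alpha * (1 - Gmean)``

with ``alpha = 1.25`` by default, evaluated by an inner stratified
3-fold cross-validation on the training rows; Gmean is the geometric
mean of sensitivity and specificity, so the objective penalizes
class-imbalanced solutions that plain accuracy would tolerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassifyError",
    "SvmSpec",
    "GoaConfig",
    "GoaState",
    "rbf_kernel",
    "train_svm",
    "gmean",
    "fitness",
    "comfort_zone",
    "goa_init",
    "goa_step",
    "goa_minimize",
    "tune_svm_goa",
]


class ClassifyError(ValueError):
    """Invalid input to the classification machinery."""


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """``exp(-gamma ||u - v||^2)`` for two equal-length vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ClassifyError(f"dimension mismatch: {u.size} vs {v.size}")
    if gamma <= 0:
        raise ClassifyError(f"gamma must be positive, got {gamma}")
    diff = u - v
    return float(np.exp(-gamma * (diff @ diff)))


@dataclass
class SvmSpec:
    """RBF-SVM hyperparameters plus, once trained, the fitted model."""

    C: float = 1.0
    gamma: float | str = "scale"
    model: SVC | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ClassifyError(f"C must be positive, got {self.C}")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ClassifyError(f"gamma must be positive, got {self.gamma}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise ClassifyError("SVM has not been trained")
        return self.model.predict(np.asarray(x, dtype=float))

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Signed distances to the separating hyperplane (for ROC)."""
        if self.model is None:
            raise ClassifyError("SVM has not been trained")
        return self.model.decision_function(np.asarray(x, dtype=float))


def train_svm(x: np.ndarray, y: np.ndarray, spec: SvmSpec | None = None) -> SvmSpec:
    """Fit the soft-margin dual on ``(x, y)`` and return a trained spec."""
    spec = spec or SvmSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise ClassifyError("training labels contain a single class")
    model = SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")
    model.fit(x, y)
    return SvmSpec(C=spec.C, gamma=spec.gamma, model=model)


def gmean(cm) -> float:
    """Geometric mean of sensitivity and specificity of a confusion matrix.

    Accepts any object exposing ``sensitivity`` and ``specificity``
    (e.g. :class:`mseeg.evaluate.ConfusionMatrix`).

    Raises
    ------
    ClassifyError
        If either class is absent (the rate is undefined, not zero).
    """
    tp_fn = cm.TP + cm.FN
    tn_fp = cm.TN + cm.FP
    if tp_fn == 0 or tn_fp == 0:
        raise ClassifyError("G-mean undefined: one class has no members")
    return float(np.sqrt(cm.sensitivity * cm.specificity))


def fitness(accuracy: float, g_mean: float, alpha: float = 1.25) -> float:
    """Tuning objective ``1 - alpha * accuracy + alpha * (1 - g_mean)``.

    Strictly decreasing in both arguments for ``alpha > 0``, so
    minimizing it maximizes accuracy and class balance jointly; with
    ``alpha > 1`` a perfect classifier scores below zero, which is
    immaterial for a minimizer.
    """
    if alpha <= 0:
        raise ClassifyError(f"alpha must be positive, got {alpha}")
    return 1.0 - alpha * accuracy + alpha * (1.0 - g_mean)


def comfort_zone(l: int, L: int, c_max: float = 1.0, c_min: float = 1e-5) -> float:
    """Linearly decaying comfort coefficient, ``c_max`` at l=0, ``c_min`` at l=L."""
    if not 0 <= l <= L:
        raise ClassifyError(f"iteration {l} outside [0, {L}]")
    if not c_max > c_min > 0:
        raise ClassifyError("need c_max > c_min > 0")
    # algebraically identical to c_max - l (c_max - c_min) / L, written as a
    # convex combination so both endpoints are exact in floating point
    frac = l / L
    return c_max * (1.0 - frac) + c_min * frac


@dataclass
class GoaConfig:
    """GOA swarm parameters and search-space bounds.

    Default bounds span ``log10 C in [-2, 4]`` and ``log10 gamma in
    [-5, 1]`` — six decades each, generous for standardized features.
    """

    n_grasshoppers: int = 25
    max_iter: int = 100
    c_max: float = 1.0
    c_min: float = 1e-5
    f_s: float = 0.5
    l_s: float = 1.5
    bounds: tuple[tuple[float, float], ...] = ((-2.0, 4.0), (-5.0, 1.0))
    alpha: float = 1.25
    cv_folds: int = 3
    cv_seed: int = 0


@dataclass
class GoaState:
    """Positions, fitness values and the best-seen target of the swarm."""

    positions: np.ndarray
    fitness: np.ndarray
    target: np.ndarray
    target_fitness: float
    lb: np.ndarray
    ub: np.ndarray
    l: int
    L: int
    c: float
    config: GoaConfig = field(repr=False, default_factory=GoaConfig)


def _social(r: np.ndarray, f_s: float, l_s: float) -> np.ndarray:
    """Attraction/repulsion strength s(r); negative at short range."""
    return f_s * np.exp(-r / l_s) - np.exp(-r)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[~np.isfinite(vals)][0]
        raise ClassifyError(f"objective returned a non-finite value at {bad}")
    return vals


def goa_init(
    objective,
    config: GoaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GoaState:
    """Scatter the swarm uniformly inside the bounds and evaluate it."""
    config = config or GoaConfig()
    rng = rng or np.random.default_rng()
    lb = np.array([b[0] for b in config.bounds], dtype=float)
    ub = np.array([b[1] for b in config.bounds], dtype=float)
    positions = rng.uniform(lb, ub, size=(config.n_grasshoppers, lb.size))
    vals = _evaluate(objective, positions)
    best = int(np.argmin(vals))
    return GoaState(
        positions=positions,
        fitness=vals,
        target=positions[best].copy(),
        target_fitness=float(vals[best]),
        lb=lb,
        ub=ub,
        l=0,
        L=config.max_iter,
        c=comfort_zone(0, config.max_iter, config.c_max, config.c_min),
        config=config,
    )


def goa_step(state: GoaState, objective) -> GoaState:
    """One swarm update.

    Each grasshopper moves to ``c * sum_j c*(ub-lb)/2 * s(|x_j - x_i|)
    * (x_j - x_i)/d_ij + T`` (canonical GOA update), is clipped to the
    bounds and re-evaluated; the target keeps the best position seen.
    """
    cfg = state.config
    x = state.positions
    n, dim = x.shape
    c = state.c
    if n > 1:
        diff = x[None, :, :] - x[:, None, :]  # (i, j, d) = x_j - x_i
        dist = np.linalg.norm(diff, axis=2)
        np.maximum(dist, 1e-12, out=dist)  # coincident-agent guard
        strength = _social(np.abs(diff), cfg.f_s, cfg.l_s)
        contrib = c * (state.ub - state.lb) / 2.0 * strength * (diff / dist[:, :, None])
        np.einsum("iid->id", contrib)[:] = 0.0  # no self-interaction
        social = contrib.sum(axis=1)
    else:
        social = np.zeros_like(x)
    new_positions = np.clip(c * social + state.target, state.lb, state.ub)
    vals = _evaluate(objective, new_positions)
    state.positions = new_positions
    state.fitness = vals
    best = int(np.argmin(vals))
    if vals[best] < state.target_fitness:
        state.target_fitness = float(vals[best])
        state.target = new_positions[best].copy()
    state.l += 1
    state.c = comfort_zone(min(state.l, state.L), state.L, cfg.c_max, cfg.c_min)
    return state


def goa_minimize(
    objective,
    config: GoaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full GOA loop; returns (best position, best value, trace).

    The trace records the best-seen fitness after every iteration and is
    nonincreasing by construction.
    """
    config = config or GoaConfig()
    state = goa_init(objective, config, rng)
    trace: list[float] = []
    for _ in range(config.max_iter):
        goa_step(state, objective)
        trace.append(state.target_fitness)
    return state.target, state.target_fitness, trace


def _cv_fitness(x: np.ndarray, y: np.ndarray, c: float, gamma: float, config: GoaConfig) -> float:
    """Eq.-style fitness of (C, gamma) under stratified inner CV."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed)
    pos_label = _positive_label(y)
    tp = tn = fp = fn = 0
    for tr, te in skf.split(x, y):
        clf = SVC(C=c, gamma=gamma, kernel="rbf")
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        truth = y[te]
        tp += int(((pred == pos_label) & (truth == pos_label)).sum())
        tn += int(((pred != pos_label) & (truth != pos_label)).sum())
        fp += int(((pred == pos_label) & (truth != pos_label)).sum())
        fn += int(((pred != pos_label) & (truth == pos_label)).sum())
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    g = float(np.sqrt(sens * spec))
    return fitness(accuracy, g, config.alpha)


def _positive_label(y: np.ndarray):
    """MS is the positive class when present; otherwise the last label."""
    labels = np.unique(y)
    return "MS" if "MS" in labels.tolist() else labels[-1]


def tune_svm_goa(
    x: np.ndarray,
    y: np.ndarray,
    config: GoaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SvmSpec, list[float]]:
    """GOA search over (log10 C, log10 gamma); returns the fitted best model.

    The returned spec is trained on all given rows with the best
    parameters found; the trace is the best-seen fitness per iteration.
    """
    config = config or GoaConfig()
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise ClassifyError("tuning requires both classes")
    if y.size < 10:
        raise ClassifyError("tuning requires at least 10 samples")

    def objective(pos: np.ndarray) -> float:
        return _cv_fitness(x, y, 10.0 ** pos[0], 10.0 ** pos[1], config)

    best_pos, _, trace = goa_minimize(objective, config, rng)
    spec = train_svm(x, y, SvmSpec(C=10.0 ** best_pos[0], gamma=10.0 ** best_pos[1]))
    return spec, trace


def save_trace(path, trace: list[float], best: SvmSpec, config: GoaConfig) -> None:
    """Serialize a tuning trace as JSON."""
    payload = {
        "best_C": best.C,
        "best_gamma": best.gamma,
        "trace": trace,
        "config": {
            "n_grasshoppers": config.n_grasshoppers,
            "max_iter": config.max_iter,
            "c_max": config.c_max,
            "c_min": config.c_min,
            "alpha": config.alpha,
            "bounds": [list(b) for b in config.bounds],
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
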