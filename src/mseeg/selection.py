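"""Wrapper feature selection by a modified ant colony optimization (m-ACO).

Ants build feature subsets of constrained size; each feature carries a
pheromone level tau (learned from past good subsets) and a static
heuristic eta (information gain of the feature about the class label).
An ant picks ``r`` distinct features with probability proportional to
``tau**a * eta**b``; the subset is scored by the misclassification rate
of a fixed-parameter RBF-SVM under an internal stratified 3-fold
cross-validation on the training rows only.  After each iteration the
pheromone evaporates, the iteration's best ant (elitist scheme)
deposits ``Q / (1 + error)`` on its features, and the best subset seen
so far is tracked.  Subset sizes are drawn uniformly from a configured
fraction band of the feature count — the constrained-size scheme that
keeps ants in small, guidable subsets.

Termination: iteration budget (default 50), stagnation patience, or a
target error.  After 10 stagnant iterations ants restart construction
biased toward the global best subset (the "jump" move) before the
patience runs out.

Heuristic values are computed once; pheromones are the only learned
state.  All randomness flows through one injected generator, so runs
are replayable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SelectionError",
    "MacoConfig",
    "ColonyState",
    "SelectionResult",
    "information_gain",
    "init_colony",
    "construct_subset",
    "evaluate_subset",
    "update_pheromone",
    "run_maco",
]


class SelectionError(ValueError):
    """Invalid input to the feature-selection machinery."""


def information_gain(
    feature_values: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """Information gain (nats) of an equal-width-binned feature about labels.

    ``IG = H(label) - H(label | bin)`` with Shannon entropies in nats.
    A constant feature occupies a single bin and scores 0.
    """
    x = np.asarray(feature_values, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise SelectionError("feature and label lengths differ")
    if n_bins < 2:
        raise SelectionError(f"n_bins must be >= 2, got {n_bins}")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise SelectionError("labels must contain at least two classes")

    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    bins = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)

    def _entropy(counts: np.ndarray) -> float:
        p = counts / counts.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_y = _entropy(np.bincount(y_idx))
    n = x.size
    h_cond = 0.0
    for b in range(n_bins):
        mask = bins == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        h_cond += nb / n * _entropy(np.bincount(y_idx[mask]))
    return max(h_y - h_cond, 0.0)


@dataclass
class MacoConfig:
    """m-ACO hyperparameters.

    ``a`` and ``b`` are the pheromone and heuristic influence exponents;
    ``rho`` the evaporation rate; ``q`` the deposit scale; subset sizes
    are drawn from ``ceil(r_bounds * n)``.  The classifier used to score
    subsets is a fixed RBF-SVM (no tuning inside the selection loop).
    """

    a: float = 1.0
    b: float = 1.0
    rho: float = 0.1
    q: float = 1.0
    tau0: float = 1.0
    tau_min: float = 1e-3
    eta_floor: float = 1e-6
    n_bins: int = 10
    r_bounds: tuple[float, float] = (0.25, 0.5)
    max_iter: int = 50
    patience: int = 15
    jump_after: int = 10
    target_error: float = 0.0
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    cv_folds: int = 3
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise SelectionError(f"rho must lie in (0, 1), got {self.rho}")
        lo, hi = self.r_bounds
        if not (0.0 < lo <= hi <= 1.0):
            raise SelectionError(f"r_bounds must satisfy 0 < lo <= hi <= 1, got {self.r_bounds}")


@dataclass
class ColonyState:
    """Mutable optimizer state: pheromones, heuristics, bests."""

    n: int
    tau: np.ndarray
    eta: np.ndarray
    k: int
    r_min: int
    r_max: int
    config: MacoConfig
    iteration: int = 0
    best_local: tuple[frozenset[int], float] | None = None
    best_global: tuple[frozenset[int], float] | None = None


@dataclass
class SelectionResult:
    """Outcome of a selection run."""

    selected: list[int]
    selected_names: list[str]
    error: float
    error_trace: list[float]
    iterations_run: int
    termination_reason: str
    config: MacoConfig = field(repr=False, default=None)

    def to_json(self) -> str:
        payload = {
            "selected": self.selected,
            "selected_names": self.selected_names,
            "error": self.error,
            "error_trace": self.error_trace,
            "iterations_run": self.iterations_run,
            "termination_reason": self.termination_reason,
        }
        if self.config is not None:
            cfg = {k: v for k, v in vars(self.config).items()}
            payload["config"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
        return json.dumps(payload, indent=2)


def _as_array(train_data) -> np.ndarray:
    if isinstance(train_data, pd.DataFrame):
        return train_data.to_numpy(dtype=float)
    return np.asarray(train_data, dtype=float)


def init_colony(train_data, labels, config: MacoConfig | None = None) -> ColonyState:
    """Step 1-4 setup: uniform pheromones, information-gain heuristics,
    ``k = n`` ants, subset-size bounds from the problem size."""
    config = config or MacoConfig()
    x = _as_array(train_data)
    y = np.asarray(labels).ravel()
    n = x.shape[1]
    if n < 2:
        raise SelectionError("need at least 2 features")
    if np.unique(y).size < 2:
        raise SelectionError("labels must contain at least two classes")
    eta = np.array(
        [information_gain(x[:, j], y, n_bins=config.n_bins) for j in range(n)]
    )
    eta = np.maximum(eta, config.eta_floor)
    lo, hi = config.r_bounds
    r_min = max(1, int(np.ceil(lo * n)))
    r_max = max(r_min, int(np.ceil(hi * n)))
    return ColonyState(
        n=n,
        tau=np.full(n, config.tau0, dtype=float),
        eta=eta,
        k=n,
        r_min=r_min,
        r_max=min(r_max, n),
        config=config,
    )


def construct_subset(
    state: ColonyState,
    ant_size: int,
    rng: np.random.Generator,
    seed_subset: frozenset[int] | None = None,
) -> frozenset[int]:
    """Draw ``ant_size`` distinct features with probability ~ tau^a * eta^b.

    Sequential proportional sampling without replacement is realized by
    the Efraimidis-Spirakis key trick (``u**(1/w)`` order statistics),
    which is distributionally equivalent and needs one uniform draw per
    feature.  If ``seed_subset`` is given (the stagnation "jump"), those
    features are kept first and only the remainder is sampled.
    """
    if not 1 <= ant_size <= state.n:
        raise SelectionError(f"ant size {ant_size} outside [1, {state.n}]")
    cfg = state.config
    w = np.maximum(state.tau**cfg.a * state.eta**cfg.b, 1e-300)
    chosen: list[int] = []
    if seed_subset:
        seeded = list(seed_subset)
        rng.shuffle(seeded)
        chosen = seeded[:ant_size]
    remaining = ant_size - len(chosen)
    if remaining > 0:
        keys = rng.random(state.n) ** (1.0 / w)
        if chosen:
            keys[np.array(chosen, dtype=int)] = -1.0  # already in the subset
        order = np.argsort(keys)[::-1]
        chosen.extend(order[:remaining].tolist())
    return frozenset(int(i) for i in chosen)


def evaluate_subset(
    subset,
    train_data,
    labels,
    config: MacoConfig | None = None,
    _cache: dict | None = None,
) -> float:
    """Misclassification rate of the base SVM on the subset's columns.

    Scored by pooled predictions of a stratified ``cv_folds``-fold CV on
    the training rows, with a fixed fold seed so the landscape the ants
    see is deterministic.
    """
    config = config or MacoConfig()
    subset = frozenset(int(i) for i in subset)
    if not subset:
        raise SelectionError("subset must be nonempty")
    if _cache is not None and subset in _cache:
        return _cache[subset]
    x = _as_array(train_data)
    if max(subset) >= x.shape[1]:
        raise IndexError(f"subset references column {max(subset)} of {x.shape[1]}")
    y = np.asarray(labels).ravel()
    cols = sorted(subset)
    xs = x[:, cols]
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed
    )
    wrong = 0
    for tr, te in skf.split(xs, y):
        clf = SVC(C=config.svm_c, gamma=config.svm_gamma, kernel="rbf")
        clf.fit(xs[tr], y[tr])
        wrong += int((clf.predict(xs[te]) != y[te]).sum())
    error = wrong / y.size
    if _cache is not None:
        _cache[subset] = error
    return error


def update_pheromone(state: ColonyState, iteration_results: list[tuple[frozenset[int], float]]) -> ColonyState:
    """Evaporate all pheromones, deposit on the iteration's best subset.

    ``tau <- (1 - rho) tau``; the best-local ant's features receive
    ``Q / (1 + error)``; all values are floored at ``tau_min``.  The
    global best is updated when improved.
    """
    if not iteration_results:
        raise SelectionError("no evaluated subsets this iteration")
    cfg = state.config
    best_subset, best_error = min(iteration_results, key=lambda t: t[1])
    state.best_local = (best_subset, best_error)
    state.tau *= 1.0 - cfg.rho
    deposit = cfg.q / (1.0 + best_error)
    for j in best_subset:
        state.tau[j] += deposit
    np.maximum(state.tau, cfg.tau_min, out=state.tau)
    if state.best_global is None or best_error < state.best_global[1]:
        state.best_global = (best_subset, best_error)
    state.iteration += 1
    return state


def run_maco(
    train_data,
    labels,
    config: MacoConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Full m-ACO loop; returns the best global subset and its trace."""
    config = config or MacoConfig()
    rng = rng or np.random.default_rng()
    state = init_colony(train_data, labels, config)
    cache: dict[frozenset[int], float] = {}
    trace: list[float] = []
    reason = "max_iter"
    stagnant = 0
    iterations = 0

    for _ in range(config.max_iter):
        sizes = rng.integers(state.r_min, state.r_max + 1, size=state.k)
        jumping = stagnant >= config.jump_after and state.best_global is not None
        seed = state.best_global[0] if jumping else None
        results = []
        for r in sizes:
            subset = construct_subset(state, int(r), rng, seed_subset=seed)
            results.append((subset, evaluate_subset(subset, train_data, labels, config, cache)))
        previous_best = state.best_global[1] if state.best_global else np.inf
        update_pheromone(state, results)
        iterations += 1
        trace.append(state.best_global[1])
        if state.best_global[1] < previous_best - 1e-12:
            stagnant = 0
        else:
            stagnant += 1
        if state.best_global[1] <= config.target_error:
            reason = "target_error"
            break
        if stagnant >= config.patience:
            reason = "stagnation"
            break

    subset, error = state.best_global
    selected = sorted(subset)
    names = (
        [str(train_data.columns[j]) for j in selected]
        if isinstance(train_data, pd.DataFrame)
        else [str(j) for j in selected]
    )
    return SelectionResult(
        selected=selected,
        selected_names=names,
        error=error,
        error_trace=trace,
        iterations_run=iterations,
        termination_reason=reason,
        config=config,
    )
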