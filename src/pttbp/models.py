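"""Regression models: ε-SVR with RBF kernel, 5-fold CV fitness, a binary
genetic algorithm for hyperparameter search, and an ordinary-least-squares
baseline.

The ε-SVR solves

    min 1/2 ||w||^2 + c * sum(xi_i + xi_i*)

subject to the ε-insensitive constraints, with the RBF kernel
``K(x, x') = exp(-gamma * ||x - x'||^2)``; predictions are reproduced from
the stored support vectors and dual coefficients alone,

    f(x) = sum_i (alpha_i* - alpha_i) K(x_i, x) + b.

The GA encodes (c, gamma, epsilon) as three fixed-width binary fields
decoded linearly onto their ranges, evolves them by fitness-proportional
selection on 1/(1 + MSE), single-point crossover and per-bit mutation, and
keeps the best individual ever seen (one elite), which makes the
best-MSE-per-generation curve nonincreasing. Fitness is the average
held-out MSE of a seeded 5-fold cross-validation whose folds are fixed for
the whole run, so fitness comparisons between individuals are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "SVRParams",
    "SVRModel",
    "GAConfig",
    "GAResult",
    "MLRModel",
    "DEFAULT_SVR_PARAMS",
    "fit_svr",
    "predict_svr",
    "cross_validate",
    "ga_optimize",
    "fit_mlr",
]

#: positivity floor applied to decoded c and gamma (their nominal ranges
#: start at 0, which the optimization problem does not admit)
PARAM_FLOOR = 1e-6


@dataclass(frozen=True)
class SVRParams:
    """Penalty factor c, RBF kernel parameter gamma, tube half-width epsilon."""

    c: float
    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("penalty factor c must be positive")
        if self.gamma <= 0:
            raise ValueError("kernel parameter gamma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


#: the conventional defaults (c=1, epsilon=0.1, gamma ~ 1/14 features)
DEFAULT_SVR_PARAMS = SVRParams(c=1.0, gamma=0.07, epsilon=0.1)


@dataclass
class SVRModel:
    """A fitted ε-SVR: support vectors, dual coefficients (alpha* - alpha),
    bias, and the hyperparameters used."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    params: SVRParams
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_svr(self, X)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "params": {"c": self.params.c, "gamma": self.params.gamma,
                       "epsilon": self.params.epsilon},
            "n_features": self.n_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float).reshape(
                -1, d["n_features"]
            ),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            params=SVRParams(**d["params"]),
            n_features=int(d["n_features"]),
        )


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    params: SVRParams,
    tol: float = 1e-6,
    max_iter: int = 2_000_000,
) -> SVRModel:
    """Fit the soft-margin ε-SVR with RBF kernel (libsvm SMO solver).

    The returned model satisfies the dual box constraints
    ``|alpha_i* - alpha_i| <= c`` and reproduces its predictions from the
    stored fields alone.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree in length")
    sk = _SkSVR(
        kernel="rbf", C=params.c, gamma=params.gamma, epsilon=params.epsilon,
        tol=tol, max_iter=max_iter, cache_size=100,
    )
    sk.fit(X, y)
    return SVRModel(
        support_vectors=np.array(sk.support_vectors_, dtype=float),
        dual_coef=np.array(sk.dual_coef_, dtype=float).ravel(),
        intercept=float(sk.intercept_[0]),
        params=params,
        n_features=X.shape[1],
    )


def predict_svr(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i beta_i K(x_i, x) + b from the stored duals."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"query has {X.shape[1]} features, model expects {model.n_features}"
        )
    if model.support_vectors.size == 0:
        return np.full(X.shape[0], model.intercept)
    d2 = cdist(X, model.support_vectors, metric="sqeuclidean")
    K = np.exp(-model.params.gamma * d2)
    return K @ model.dual_coef + model.intercept


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    params: SVRParams,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
) -> float:
    """Average held-out MSE over k near-equal folds from a seeded shuffle."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 2:
        raise ValueError("k must be at least 2")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    mses = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = fit_svr(X[mask], y[mask], params, tol=tol)
        resid = y[fold] - predict_svr(model, X[fold])
        mses.append(float(np.mean(resid**2)))
    return float(np.mean(mses))


@dataclass
class GAConfig:
    """Binary-GA settings; the defaults are the published search protocol:
    population 20, crossover 0.7, mutation 0.01, 100 generations, with
    c in [0, 100], gamma in [0, 1000] and epsilon in [0.01, 1]."""

    c_range: tuple[float, float] = (0.0, 100.0)
    gamma_range: tuple[float, float] = (0.0, 1000.0)
    epsilon_range: tuple[float, float] = (0.01, 1.0)
    bits_per_param: int = 16
    pop_size: int = 20
    p_crossover: float = 0.7
    p_mutation: float = 0.01
    max_gen: int = 100
    cv_folds: int = 5
    seed: int = 0
    fit_tol: float = 1e-3

    def validate(self) -> None:
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("population size must be at least 2")
        for name in ("c_range", "gamma_range", "epsilon_range"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.bits_per_param < 2:
            raise ValueError("need at least 2 bits per parameter")


@dataclass
class GAResult:
    best_params: SVRParams
    best_mse: float
    best_mse_per_gen: list[float] = field(default_factory=list)
    avg_mse_per_gen: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_params": {"c": self.best_params.c, "gamma": self.best_params.gamma,
                            "epsilon": self.best_params.epsilon},
            "best_mse": self.best_mse,
            "best_mse_per_gen": self.best_mse_per_gen,
            "avg_mse_per_gen": self.avg_mse_per_gen,
        }


def decode_chromosome(bits: np.ndarray, cfg: GAConfig) -> SVRParams:
    """Decode three fixed-width binary fields linearly onto the parameter
    ranges; c and gamma are clamped to a positivity floor."""
    nb = cfg.bits_per_param
    vals = []
    for i, (lo, hi) in enumerate((cfg.c_range, cfg.gamma_range, cfg.epsilon_range)):
        chunk = bits[i * nb : (i + 1) * nb]
        intval = int("".join("1" if b else "0" for b in chunk), 2)
        vals.append(lo + intval / (2**nb - 1) * (hi - lo))
    c, gamma, eps = vals
    return SVRParams(
        c=max(c, PARAM_FLOOR), gamma=max(gamma, PARAM_FLOOR), epsilon=max(eps, 0.0)
    )


def ga_optimize(X: np.ndarray, y: np.ndarray, cfg: GAConfig) -> GAResult:
    """Search (c, gamma, epsilon) by the binary GA; fitness is the seeded
    k-fold CV average MSE, minimized. Returns the best individual ever seen
    together with the per-generation best/average MSE curves."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rng = np.random.default_rng(cfg.seed)
    n_bits = 3 * cfg.bits_per_param
    pop = rng.random((cfg.pop_size, n_bits)) < 0.5

    cache: dict[bytes, float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        if key not in cache:
            params = decode_chromosome(bits, cfg)
            cache[key] = cross_validate(
                X, y, params, k=cfg.cv_folds, seed=cfg.seed, tol=cfg.fit_tol
            )
        return cache[key]

    best_bits: np.ndarray | None = None
    best_mse = np.inf
    best_curve: list[float] = []
    avg_curve: list[float] = []

    for _ in range(cfg.max_gen):
        mses = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmin(mses))
        if mses[gen_best] < best_mse:
            best_mse = float(mses[gen_best])
            best_bits = pop[gen_best].copy()
        best_curve.append(best_mse)
        avg_curve.append(float(np.mean(mses)))

        # fitness-proportional (roulette) selection on 1/(1+MSE)
        scores = 1.0 / (1.0 + mses)
        probs = scores / scores.sum()
        children: list[np.ndarray] = [best_bits.copy()]  # 1 elite
        while len(children) < cfg.pop_size:
            i, j = rng.choice(cfg.pop_size, size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < cfg.p_crossover:
                point = rng.integers(1, n_bits)
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            children.append(a)
            if len(children) < cfg.pop_size:
                children.append(b)
        pop = np.array(children)
        # bitwise mutation (the elite in slot 0 is preserved untouched)
        flips = rng.random((cfg.pop_size, n_bits)) < cfg.p_mutation
        flips[0] = False
        pop ^= flips

    return GAResult(
        best_params=decode_chromosome(best_bits, cfg),
        best_mse=best_mse,
        best_mse_per_gen=best_curve,
        avg_mse_per_gen=avg_curve,
    )


@dataclass
class MLRModel:
    """Ordinary least squares: P = beta0 + beta1 x1 + ... + betak xk."""

    intercept: float
    coef: np.ndarray
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.coef.size:
            raise ValueError("feature count mismatch")
        return self.intercept + X @ self.coef


def fit_mlr(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> MLRModel:
    """Least-squares fit with intercept; a rank-deficient design raises,
    naming the dependent columns."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than features ({p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify dependent columns from the tiny diagonal entries of R
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * diag.max())
        names = feature_names or [f"x{j}" for j in range(p)]
        offenders = [names[j - 1] if j > 0 else "intercept" for j in bad]
        raise ValueError(f"rank-deficient design; collinear column(s): {offenders}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(intercept=float(beta[0]), coef=beta[1:], feature_names=feature_names)
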