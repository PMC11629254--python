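"""Single-hidden-layer BP network with GA- and PSO-searched initial weights.

The classifier is the 11-6-2 multilayer perceptron used for the final
origin call: 11 marker inputs, 6 tanh hidden units, 2 softmax outputs,
trained by full-batch gradient-descent backpropagation on the cross-entropy
loss.  All S = 11·6 + 6 + 6·2 + 2 = 86 weights and biases live in one flat
parameter vector theta, with a fixed encode/decode ordering
(input→hidden weights, hidden biases, hidden→output weights, output
biases).

GA-BP and PSO-BP search the *initial* theta inside a bounded box (±2 by
default): candidate fitness is the training loss after a short BP burn-in
from that candidate, and full BP training then starts from the best
candidate found.  The published search budgets are deliberately tiny
(population 5, 30 updates); they are the defaults here, and test
configurations may enlarge them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LayerSizes",
    "MLPParams",
    "SwarmConfig",
    "GAConfig",
    "BPConfig",
    "encode",
    "decode",
    "forward",
    "loss_and_grad",
    "predict",
    "train_bp",
    "pso_optimize",
    "ga_optimize",
    "fit_hybrid",
]


@dataclass(frozen=True)
class LayerSizes:
    n_in: int = 11
    n_hidden: int = 6
    n_out: int = 2

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be positive")

    @property
    def n_params(self) -> int:
        return (
            self.n_in * self.n_hidden
            + self.n_hidden
            + self.n_hidden * self.n_out
            + self.n_out
        )


@dataclass
class MLPParams:
    layers: LayerSizes
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.layers.n_params,):
            raise ValueError(
                f"theta has length {self.theta.shape}, expected ({self.layers.n_params},)"
            )


def encode(W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Flatten (input→hidden W, hidden b, hidden→output W, output b)."""
    return np.concatenate([np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)])


def decode(params: MLPParams) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    L = params.layers
    theta = params.theta
    i = 0
    W1 = theta[i : i + L.n_in * L.n_hidden].reshape(L.n_in, L.n_hidden)
    i += L.n_in * L.n_hidden
    b1 = theta[i : i + L.n_hidden]
    i += L.n_hidden
    W2 = theta[i : i + L.n_hidden * L.n_out].reshape(L.n_hidden, L.n_out)
    i += L.n_hidden * L.n_out
    b2 = theta[i : i + L.n_out]
    return W1, b1, W2, b2


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Class probabilities (n_samples × n_out)."""
    W1, b1, W2, b2 = decode(params)
    H = np.tanh(X @ W1 + b1)
    return _softmax(H @ W2 + b2)


def predict(params: MLPParams, X: np.ndarray) -> np.ndarray:
    return np.argmax(forward(params, X), axis=1)


def loss_and_grad(
    params: MLPParams, X: np.ndarray, Y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its analytic gradient w.r.t. theta."""
    W1, b1, W2, b2 = decode(params)
    n = X.shape[0]
    A = X @ W1 + b1
    H = np.tanh(A)
    P = _softmax(H @ W2 + b2)
    eps = 1e-12
    loss = -float(np.sum(Y * np.log(P + eps))) / n

    dZ2 = (P - Y) / n
    gW2 = H.T @ dZ2
    gb2 = dZ2.sum(axis=0)
    dH = dZ2 @ W2.T
    dA = dH * (1.0 - H**2)
    gW1 = X.T @ dA
    gb1 = dA.sum(axis=0)
    return loss, encode(gW1, gb1, gW2, gb2)


@dataclass(frozen=True)
class BPConfig:
    learning_rate: float = 0.01
    max_epochs: int = 1000
    plateau_tol: float = 1e-6
    plateau_window: int = 50
    bounds: tuple[float, float] = (-2.0, 2.0)


@dataclass(frozen=True)
class SwarmConfig:
    iterations: int = 30
    population: int = 5
    v_max: float = 1.0
    v_min: float = -1.0
    bounds: tuple[float, float] = (-2.0, 2.0)
    inertia: float = 0.8
    c1: float = 1.5
    c2: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.v_min < self.v_max:
            raise ValueError("v_min must be below v_max")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")


@dataclass(frozen=True)
class GAConfig:
    generations: int = 30
    population: int = 5
    bounds: tuple[float, float] = (-2.0, 2.0)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sigma_frac: float = 0.1  # of the bound width
    tournament: int = 2
    elitism: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")


def _one_hot(y: np.ndarray, n_out: int) -> np.ndarray:
    Y = np.zeros((len(y), n_out))
    Y[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return Y


def random_init(layers: LayerSizes, rng: np.random.Generator, bounds=(-2.0, 2.0)) -> np.ndarray:
    return rng.uniform(bounds[0], bounds[1], layers.n_params)


def train_bp(
    X: np.ndarray,
    y: np.ndarray,
    layers: LayerSizes | None = None,
    init: np.ndarray | None = None,
    config: BPConfig = BPConfig(),
    seed: int | None = None,
) -> tuple[MLPParams, list[float]]:
    """Full-batch gradient-descent backpropagation.

    Starts from ``init`` if given, else from a bounded uniform random draw
    (deterministic under ``seed``).  Training stops at ``max_epochs`` or
    when the loss improves by less than ``plateau_tol`` over the plateau
    window.  A non-finite loss aborts with a diagnostic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if layers is None:
        layers = LayerSizes(n_in=X.shape[1], n_hidden=6, n_out=int(y.max()) + 1)
    Y = _one_hot(y, layers.n_out)
    if init is None:
        init = random_init(layers, np.random.default_rng(seed), config.bounds)
    params = MLPParams(layers, np.array(init, dtype=float))
    losses: list[float] = []
    for epoch in range(config.max_epochs):
        loss, grad = loss_and_grad(params, X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; lower the learning rate"
            )
        losses.append(loss)
        if (
            len(losses) > config.plateau_window
            and losses[-config.plateau_window - 1] - loss < config.plateau_tol
        ):
            break
        params.theta = params.theta - config.learning_rate * grad
    return params, losses


def pso_optimize(
    fitness,
    dim: int,
    config: SwarmConfig = SwarmConfig(),
    seed: int | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Inertia-weight particle swarm minimization inside a box.

    Velocities are clamped to [v_min, v_max] and positions to the bounds;
    the returned trace of global-best fitness is non-increasing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.bounds
    X = rng.uniform(lo, hi, (config.population, dim))
    V = rng.uniform(config.v_min, config.v_max, (config.population, dim))
    fit = np.array([fitness(x) for x in X])
    pbest, pbest_fit = X.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = X[g].copy(), float(fit[g])
    trace = [gbest_fit]
    for _ in range(config.iterations):
        r1 = rng.random((config.population, dim))
        r2 = rng.random((config.population, dim))
        V = (
            config.inertia * V
            + config.c1 * r1 * (pbest - X)
            + config.c2 * r2 * (gbest - X)
        )
        V = np.clip(V, config.v_min, config.v_max)
        X = np.clip(X + V, lo, hi)
        fit = np.array([fitness(x) for x in X])
        improved = fit < pbest_fit
        pbest[improved] = X[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)
    return gbest, trace


def ga_optimize(
    fitness,
    dim: int,
    config: GAConfig = GAConfig(),
    seed: int | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Real-coded genetic algorithm: tournament selection, whole-arithmetic
    crossover, Gaussian mutation clipped to bounds, elitism of 1."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.bounds
    sigma = config.mutation_sigma_frac * (hi - lo)
    pop = rng.uniform(lo, hi, (config.population, dim))
    fit = np.array([fitness(x) for x in pop])
    best_i = int(np.argmin(fit))
    best, best_fit = pop[best_i].copy(), float(fit[best_i])
    trace = [best_fit]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, config.population, config.tournament)
        return pop[idx[np.argmin(fit[idx])]]

    for _ in range(config.generations):
        children = []
        order = np.argsort(fit)
        for e in range(min(config.elitism, config.population)):
            children.append(pop[order[e]].copy())
        while len(children) < config.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                alpha = rng.random()
                child = alpha * p1 + (1 - alpha) * p2
            else:
                child = p1.copy()
            mutate = rng.random(dim) < config.mutation_rate
            child = np.where(mutate, child + rng.normal(0.0, sigma, dim), child)
            children.append(np.clip(child, lo, hi))
        pop = np.stack(children)
        fit = np.array([fitness(x) for x in pop])
        i = int(np.argmin(fit))
        if fit[i] < best_fit:
            best, best_fit = pop[i].copy(), float(fit[i])
        trace.append(best_fit)
    return best, trace


def fit_hybrid(
    X: np.ndarray,
    y: np.ndarray,
    optimizer: str = "pso",
    config: SwarmConfig | GAConfig | None = None,
    seed: int | None = None,
    layers: LayerSizes | None = None,
    bp_config: BPConfig = BPConfig(),
    burn_in_epochs: int = 50,
) -> tuple[MLPParams, dict]:
    """GA-BP / PSO-BP: search the initial theta inside the bounds, scoring a
    candidate by its training loss after a short BP burn-in, then train
    fully from the best candidate.  ``iterations``/``generations`` of 0
    reduce to plain BP from the best of the initial random population."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if layers is None:
        layers = LayerSizes(n_in=X.shape[1], n_hidden=6, n_out=int(y.max()) + 1)
    Y = _one_hot(y, layers.n_out)
    burn_cfg = replace(bp_config, max_epochs=burn_in_epochs, plateau_window=burn_in_epochs + 1)

    def fitness(theta: np.ndarray) -> float:
        params, _ = train_bp(X, y, layers, init=theta, config=burn_cfg)
        loss, _ = loss_and_grad(params, X, Y)
        return loss

    if optimizer == "pso":
        cfg = config if config is not None else SwarmConfig()
        best, trace = pso_optimize(fitness, layers.n_params, cfg, seed=seed)
    elif optimizer == "ga":
        cfg = config if config is not None else GAConfig()
        best, trace = ga_optimize(fitness, layers.n_params, cfg, seed=seed)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    params, losses = train_bp(X, y, layers, init=best, config=bp_config)
    return params, {"optimizer": optimizer, "fitness_trace": trace, "bp_losses": losses}
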