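"""Wrapper feature selection with the (Self-Improved) Seagull
Optimization Algorithm.

The SOA alternates a migration phase (collision avoidance ``V = K S``,
a stochastic pull ``M = B (S_best - S)`` toward the global best, and the
component-wise distance ``D = |V + M|``) with a spiral attack phase
(``x' = r cos l``, ``y' = r sin l``, ``z' = r l``, ``r = g e^{l h}``)
whose scalar product perturbs the new position around the global best.
The migration coefficient ``K`` decays linearly from ``fc`` to 0 over
the run, shifting the search from exploration to exploitation.  The
self-improved variant scales the perturbation by an inertia weight
``Iw(t) = 2 / (1 + omega e^{-2 t / t_max}) - 1`` that grows with the
iteration counter, accelerating convergence.

Feature subsets are encoded as continuous positions decoded through a
sigmoid threshold; the wrapper fitness is stratified 3-fold
cross-validated error of a nearest-centroid classifier plus a small
sparsity penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .synth import FeatureTable

__all__ = [
    "SpiralParams",
    "SOAConfig",
    "SelectionMask",
    "migration_coefficient",
    "inertia_weight",
    "soa_step",
    "sasoa_optimize",
    "binarize_position",
    "feature_fitness",
    "select_features",
]


@dataclass(frozen=True)
class SpiralParams:
    g: float = 1.0   # spiral base radius
    h: float = 0.5   # spiral growth constant
    l_max: float = 2 * np.pi  # spiral angle drawn uniformly on [0, l_max]

    def __post_init__(self):
        if self.g <= 0:
            raise ValueError("spiral base radius g must be positive")


@dataclass(frozen=True)
class SOAConfig:
    pop_size: int = 30
    max_iter: int = 200
    fc: float = 2.0          # migration frequency constant
    omega: float = 0.5       # inertia controlling factor in (0, 1)
    spiral: SpiralParams = field(default_factory=SpiralParams)
    bounds: tuple = (-10.0, 10.0)
    seed: int = 0
    variant: str = "self_improved"   # or "baseline"
    rd_per_dimension: bool = False

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0 < self.omega < 1:
            raise ValueError("omega must lie in (0, 1)")
        if self.fc <= 0:
            raise ValueError("fc must be positive")
        if self.variant not in ("baseline", "self_improved"):
            raise ValueError("variant must be 'baseline' or 'self_improved'")


@dataclass
class Agents:
    positions: np.ndarray   # pop x dim
    fitness: np.ndarray     # pop
    best: np.ndarray        # global best position
    best_fitness: float


@dataclass
class SelectionMask:
    bits: np.ndarray
    fitness: float
    trace: list


def migration_coefficient(m, config: SOAConfig):
    """K = fc - m * fc / max_iter: linear decay from fc to 0."""
    if not 0 <= m <= config.max_iter:
        raise ValueError("iteration counter out of range")
    return config.fc - m * (config.fc / config.max_iter)


def inertia_weight(t, config: SOAConfig):
    """Iw = 2 / (1 + omega e^{-2 t / t_max}) - 1, increasing in t."""
    if not 0 <= t <= config.max_iter:
        raise ValueError("iteration counter out of range")
    return 2.0 / (1.0 + config.omega * np.exp(-2.0 * t / config.max_iter)) - 1.0


def _evaluate(objective, positions, rng, bounds):
    """Evaluate, re-sampling any agent whose objective is non-finite."""
    fit = np.empty(positions.shape[0])
    for i in range(positions.shape[0]):
        f = float(objective(positions[i]))
        tries = 0
        while not np.isfinite(f) and tries < 20:
            positions[i] = rng.uniform(bounds[0], bounds[1], size=positions.shape[1])
            f = float(objective(positions[i]))
            tries += 1
        fit[i] = f
    return fit


def soa_step(agents: Agents, m, objective, config: SOAConfig, rng):
    """One synchronous SOA update of all agents (minimization)."""
    K = migration_coefficient(m, config)
    iw = inertia_weight(m, config) if config.variant == "self_improved" else 1.0
    pop, dim = agents.positions.shape
    lo, hi = config.bounds
    sp = config.spiral
    for i in range(pop):
        S = agents.positions[i]
        rd = rng.random(dim) if config.rd_per_dimension else rng.random()
        B = 2.0 * K * K * rd
        V = K * S
        M = B * (agents.best - S)
        D = np.abs(V + M)
        l = rng.uniform(0.0, sp.l_max)
        r = sp.g * np.exp(l * sp.h)
        spiral = (r * np.cos(l)) * (r * np.sin(l)) * (r * l)
        agents.positions[i] = np.clip(iw * D * spiral + agents.best, lo, hi)
    agents.fitness = _evaluate(objective, agents.positions, rng, config.bounds)
    j = int(np.argmin(agents.fitness))
    if agents.fitness[j] < agents.best_fitness:
        agents.best_fitness = float(agents.fitness[j])
        agents.best = agents.positions[j].copy()
    return agents


def sasoa_optimize(objective, dim, config: SOAConfig):
    """Run the optimizer; returns (best position, best fitness, trace).

    The trace records the best-so-far fitness after each iteration
    (elitist bookkeeping, hence non-increasing); the returned solution
    is the best ever seen, not the final population's.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    positions = rng.uniform(lo, hi, size=(config.pop_size, dim))
    fitness = _evaluate(objective, positions, rng, config.bounds)
    j = int(np.argmin(fitness))
    agents = Agents(positions=positions, fitness=fitness,
                    best=positions[j].copy(), best_fitness=float(fitness[j]))
    trace = [agents.best_fitness]
    for m in range(1, config.max_iter + 1):
        soa_step(agents, m, objective, config, rng)
        trace.append(agents.best_fitness)
    return agents.best, agents.best_fitness, trace


# ---------------------------------------------------------------------------
# Binary decoding and wrapper fitness
# ---------------------------------------------------------------------------


def binarize_position(position, threshold=0.5):
    """bit_i = 1 iff sigmoid(position_i) > threshold (strict); an
    all-zero decode forces the single largest-sigmoid coordinate on."""
    s = 1.0 / (1.0 + np.exp(-np.asarray(position, dtype=float)))
    bits = (s > threshold).astype(np.uint8)
    if bits.sum() == 0:
        bits[int(np.argmax(s))] = 1
    return bits


def _nearest_centroid_error(Xtr, ytr, Xte, yte):
    mu = Xtr.mean(axis=0)
    sd = np.maximum(Xtr.std(axis=0), 1e-9)
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    cents = np.stack([Xtr[ytr == c].mean(axis=0) for c in (0, 1)])
    d = ((Xte[:, None, :] - cents[None]) ** 2).sum(axis=2)
    return float(np.mean(d.argmin(axis=1) != yte))


def feature_fitness(bits, table: FeatureTable, lam=0.01, seed=0):
    """cv_error + lam * (selected fraction); stratified 3-fold error of a
    nearest-centroid classifier on the selected columns."""
    bits = np.asarray(bits)
    if bits.sum() == 0:
        raise ValueError("empty feature mask")
    X = table.matrix[:, bits.astype(bool)]
    y = table.labels
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    errs = [
        _nearest_centroid_error(X[tr], y[tr], X[te], y[te])
        for tr, te in skf.split(X, y)
    ]
    return float(np.mean(errs)) + lam * bits.sum() / bits.size


def select_features(table: FeatureTable, config: SOAConfig | None = None,
                    lam=0.01, threshold=0.5) -> SelectionMask:
    """SA-SOA wrapper selection over the columns of ``table``."""
    dim = table.matrix.shape[1]
    if dim == 1:
        return SelectionMask(bits=np.array([1], dtype=np.uint8),
                             fitness=float("nan"), trace=[])
    if config is None:
        config = SOAConfig(pop_size=30, max_iter=60, bounds=(-4.0, 4.0))
    def objective(pos):
        return feature_fitness(binarize_position(pos, threshold), table,
                               lam=lam, seed=config.seed)
    best, fit, trace = sasoa_optimize(objective, dim, config)
    return SelectionMask(bits=binarize_position(best, threshold),
                         fitness=fit, trace=trace)
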