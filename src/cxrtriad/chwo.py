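"""Chaotic Whale Optimization (ChWO) and the wrapper feature-selection front end.

The whale optimization algorithm (WOA) models bubble-net foraging: the
incumbent best solution plays the prey, and each candidate either

* **encircles** the prey, ``Q' = Q* − M·S`` with ``S = |R·Q* − Q|``,
  ``M = 2mg − m``, ``R = 2g``, ``g ~ U[0,1]``, ``m`` shrinking linearly
  from 2 to 0 over the run;
* follows a **logarithmic spiral** toward it,
  ``Q' = S'·e^{kq}·cos(2πq) + Q*`` with ``S' = |Q* − Q|``, ``q ~ U[−1,1]``;
* or **explores** toward a random population member,
  ``Q' = Q_r − M·S`` when ``|M| ≥ 1``.

ChWO keeps, per whale and dimension, an auxiliary chaotic state iterated
by the Chebyshev map ``q ← cos(X·arccos q)`` (chaotic for X ≥ 2). In the
spiral ("randomization") phase the chaotic state — affinely mapped from
[−1,1] onto that dimension's bounds — is blended with the spiral update,
``Q(p+1) = w·[Q]_chebyshev + (1−w)·[Q]_whale`` with ``w = 0.5`` by
default. The encircle and exploration branches are used as printed,
unblended, which is what lets the swarm actually converge while the
chaotic term keeps injecting diversity. ``blend_weight = 0`` reduces ChWO
to vanilla WOA exactly (identical rng consumption, bit-for-bit).

The feature-selection front end optimizes a continuous score vector in
[−1,1]^d; a feature is kept iff ``sigmoid(x_j) > 0.5`` (i.e. ``x_j > 0``),
and fitness is ``α·cv_error + (1−α)·|mask|/d`` with ``cv_error`` the
stratified 3-fold error of a 1-nearest-neighbor classifier restricted to
the selected columns (all-zero masks score the worst possible 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier


@dataclass
class ChwoConfig:
    pop_size: int = 20
    max_iters: int = 100
    chaos_X: float = 4.0
    spiral_k: float = 1.0
    bounds: tuple[float, float] | list[tuple[float, float]] = (-1.0, 1.0)
    blend_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.chaos_X < 2:
            raise ValueError("chaos_X must be >= 2 for the chaotic regime")
        if not (0.0 <= self.blend_weight <= 1.0):
            raise ValueError("blend_weight must lie in [0, 1]")

    def bounds_arrays(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        b = self.bounds
        if isinstance(b, tuple) and np.isscalar(b[0]):
            lo = np.full(dim, float(b[0]))
            hi = np.full(dim, float(b[1]))
        else:
            arr = np.asarray(b, dtype=np.float64)
            if arr.shape != (dim, 2):
                raise ValueError(f"bounds must be (lo, hi) or per-dimension ({dim}, 2)")
            lo, hi = arr[:, 0], arr[:, 1]
        if np.any(lo >= hi):
            raise ValueError("each dimension needs lo < hi")
        return lo, hi


@dataclass
class WhalePopulation:
    positions: np.ndarray  # (pop, dim)
    fitnesses: np.ndarray  # (pop,)
    best_position: np.ndarray
    best_fitness: float
    chaos_states: np.ndarray  # (pop, dim) in [-1, 1]
    iteration: int = 0


@dataclass
class SelectionMask:
    mask: np.ndarray  # length-d binary vector

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.int8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")

    @property
    def selected_count(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]


# ---------------------------------------------------------------------------
# primitive moves


def chebyshev_step(q, X: float):
    """One Chebyshev-map iteration cos(X·arccos q); stays in [−1, 1]."""
    q = np.asarray(q, dtype=np.float64)
    if np.any(np.abs(q) > 1.0 + 1e-12):
        raise ValueError("chebyshev_step requires |q| <= 1")
    out = np.cos(X * np.arccos(np.clip(q, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def whale_move(
    pos: np.ndarray,
    best: np.ndarray,
    m: float,
    rng: np.random.Generator,
    spiral_k: float = 1.0,
    others: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """One vanilla whale update; returns (proposal, took_spiral_branch).

    ``others`` supplies the population for the exploration branch; without
    it, exploration falls back to encircling the best.
    """
    pos = np.asarray(pos, dtype=np.float64)
    best = np.asarray(best, dtype=np.float64)
    if not (0.0 <= m <= 2.0):
        raise ValueError("m must lie in [0, 2]")
    g = rng.random()
    M = 2.0 * m * g - m
    R = 2.0 * g
    if rng.random() < 0.5:  # spiral bubble-net path
        q = rng.uniform(-1.0, 1.0)
        s_prime = np.abs(best - pos)
        return s_prime * np.exp(spiral_k * q) * np.cos(2.0 * np.pi * q) + best, True
    if abs(M) < 1.0 or others is None:  # shrinking encircle of the prey
        s = np.abs(R * best - pos)
        return best - M * s, False
    q_r = others[rng.integers(0, len(others))]  # random-whale exploration
    s = np.abs(R * q_r - pos)
    return q_r - M * s, False


# ---------------------------------------------------------------------------
# population loop


def init_population(objective, dim: int, cfg: ChwoConfig, rng: np.random.Generator) -> WhalePopulation:
    lo, hi = cfg.bounds_arrays(dim)
    positions = rng.uniform(lo, hi, size=(cfg.pop_size, dim))
    # chaos states start uniform in (−1, 1) excluding the map's 0 pre-fixed-point
    chaos = rng.uniform(-1.0, 1.0, size=(cfg.pop_size, dim))
    chaos[chaos == 0.0] = 0.5
    fitnesses = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("objective returned a non-finite value at initialization")
    ibest = int(np.argmin(fitnesses))
    return WhalePopulation(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[ibest].copy(),
        best_fitness=float(fitnesses[ibest]),
        chaos_states=chaos,
        iteration=0,
    )


def chwo_step(popn: WhalePopulation, objective, cfg: ChwoConfig, rng: np.random.Generator,
              max_iters: int | None = None) -> WhalePopulation:
    """Advance the swarm one iteration in place (and return it)."""
    dim = popn.positions.shape[1]
    lo, hi = cfg.bounds_arrays(dim)
    p_max = max_iters if max_iters is not None else cfg.max_iters
    m = 2.0 * max(0.0, 1.0 - popn.iteration / p_max)
    popn.chaos_states = chebyshev_step(popn.chaos_states, cfg.chaos_X)
    chaotic_pos = lo + (popn.chaos_states + 1.0) * 0.5 * (hi - lo)
    for i in range(len(popn.positions)):
        proposal, spiral = whale_move(
            popn.positions[i], popn.best_position, m, rng,
            spiral_k=cfg.spiral_k, others=popn.positions,
        )
        if spiral:  # Chebyshev blend applies in the randomization phase
            proposal = cfg.blend_weight * chaotic_pos[i] + (1.0 - cfg.blend_weight) * proposal
        np.clip(proposal, lo, hi, out=proposal)
        fit = float(objective(proposal))
        if not np.isfinite(fit):
            raise ValueError("objective returned a non-finite value")
        popn.positions[i] = proposal
        popn.fitnesses[i] = fit
        if fit < popn.best_fitness:  # ties keep the incumbent
            popn.best_fitness = fit
            popn.best_position = proposal.copy()
    popn.iteration += 1
    return popn


def chwo_minimize(
    objective,
    dim: int,
    cfg: ChwoConfig | None = None,
    fitness_target: float | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full loop; returns (best_position, best_fitness, history).

    ``history`` holds the best fitness after each iteration; the loop stops
    at ``max_iters`` or as soon as ``fitness_target`` is reached.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    cfg = cfg or ChwoConfig()
    rng = np.random.default_rng(cfg.seed)
    popn = init_population(objective, dim, cfg, rng)
    history: list[float] = []
    for _ in range(cfg.max_iters):
        chwo_step(popn, objective, cfg, rng)
        history.append(popn.best_fitness)
        if fitness_target is not None and popn.best_fitness <= fitness_target:
            break
    return popn.best_position, popn.best_fitness, history


def woa_minimize(objective, dim: int, cfg: ChwoConfig | None = None,
                 fitness_target: float | None = None):
    """Vanilla WOA baseline: the identical loop with the blend disabled."""
    cfg = replace(cfg or ChwoConfig(), blend_weight=0.0)
    return chwo_minimize(objective, dim, cfg, fitness_target)


# ---------------------------------------------------------------------------
# wrapper feature selection


def knn_cv_error(F: np.ndarray, y: np.ndarray, columns: np.ndarray, seed: int,
                 n_folds: int = 3, n_neighbors: int = 1) -> float:
    """Stratified k-fold error of a k-NN classifier on the selected columns."""
    X = F[:, columns]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for train_idx, test_idx in skf.split(X, y):
        knn = KNeighborsClassifier(n_neighbors=n_neighbors)
        knn.fit(X[train_idx], y[train_idx])
        errors.append(1.0 - knn.score(X[test_idx], y[test_idx]))
    return float(np.mean(errors))


def select_features(
    F: np.ndarray,
    y: np.ndarray,
    cfg: ChwoConfig | None = None,
    fs_alpha: float = 0.9,
) -> SelectionMask:
    """Wrapper feature selection driven by ChWO.

    ``y`` may be integer class labels or a one-hot/multi-label matrix (the
    first positive class is used). Fitness values are memoized per mask so
    the optimizer revisiting a subset costs nothing.
    """
    F = np.asarray(F, dtype=np.float64)
    y = np.asarray(y)
    if y.ndim == 2:
        y = np.argmax(y, axis=1)
    n, d = F.shape
    if n < 20:
        raise ValueError("select_features needs at least 20 samples")
    if d < 1:
        raise ValueError("select_features needs at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    cfg = cfg or ChwoConfig(max_iters=40)
    cache: dict[bytes, float] = {}

    def fitness(x: np.ndarray) -> float:
        mask = (x > 0.0)  # sigmoid(x) > 0.5
        key = np.packbits(mask).tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = 1.0  # degenerate: nothing selected
            else:
                err = knn_cv_error(F, y, np.nonzero(mask)[0], seed=cfg.seed)
                cache[key] = fs_alpha * err + (1.0 - fs_alpha) * mask.sum() / d
        return cache[key]

    sel_cfg = replace(cfg, bounds=(-1.0, 1.0))
    best_x, _, _ = chwo_minimize(fitness, d, sel_cfg)
    mask = (best_x > 0.0).astype(np.int8)
    if not mask.any():  # fall back to the single best column
        errs = [knn_cv_error(F, y, np.array([j]), seed=cfg.seed) for j in range(d)]
        mask[int(np.argmin(errs))] = 1
    return SelectionMask(mask)
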