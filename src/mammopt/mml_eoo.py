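"""Modified Mussel-Length Eurasian Oystercatcher Optimization (MML-EOO).

A population metaheuristic modelled on oystercatcher foraging. The bird's
behaviour is driven by a per-iteration schedule derived from the prey
("oyster") size O, which decays linearly from 5 to 3 over the run — the
"modified mussel length" — shifting the search from exploration to
exploitation:

* ``O = 5 - r * (2 / R)``                      (oyster size, dimensionless)
* ``J = ((O - 3) / 2) * 10 - 5``               (opening time, [-5, 5])
* ``Q = ((O - 3) / 2) * 2 + 0.6``              (calorie gain, [0.6, 2.6])
* ``D = (r - 1) / (R - 1) - 0.5``  for r > 1   (bird energy, [-0.5, 0.5])

The current energy requirement N is identified with D (the only computed
bird-energy quantity). While the bird can still open the oyster
(``J + N > 0``, early iterations) each candidate moves toward the global
best: ``P_r = P_{r-1} + O * f * (P_m - P_{r-1})`` with f ~ U[0,1] drawn
independently per dimension. Once opening capacity is exhausted
(``J + N <= 0``, late iterations) the position is rescaled multiplicatively
by the calorie gain, ``P_r = P_{r-1} * Q``, applied in bound-shifted
coordinates and reflected back into the box. Acceptance is greedy per
candidate with global-best elitism, so the best-so-far trace never
increases.

The search space mixes integer ranges, categorical choice lists and
continuous intervals; internally every dimension is a real interval and
candidates are decoded on evaluation (integer dims round to nearest,
choice dims map to a 1-based nearest index, ties rounding down).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "IntDim",
    "ChoiceDim",
    "FloatDim",
    "SearchSpace",
    "Candidate",
    "ScheduleState",
    "OptResult",
    "oyster_schedule",
    "propose_move",
    "optimize",
]


@dataclass(frozen=True)
class IntDim:
    """Integer range dimension, inclusive on both ends."""

    low: int
    high: int

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"integer range requires low <= high, got [{self.low}, {self.high}]")

    @property
    def bounds(self):
        return float(self.low), float(self.high)

    def decode(self, x: float):
        # round half down so internal midpoints land on the lower median
        v = int(math.ceil(x - 0.5))
        return min(max(v, self.low), self.high)

    def encode(self, v) -> float:
        return float(v)


@dataclass(frozen=True)
class ChoiceDim:
    """Ordered categorical dimension; internal coordinate is a 1-based index."""

    values: tuple

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("choice list must be nonempty")
        object.__setattr__(self, "values", tuple(self.values))

    @property
    def bounds(self):
        return 1.0, float(len(self.values))

    def decode(self, x: float):
        i = int(math.ceil(x - 0.5))
        i = min(max(i, 1), len(self.values))
        return self.values[i - 1]

    def encode(self, v) -> float:
        return float(self.values.index(v) + 1)


@dataclass(frozen=True)
class FloatDim:
    """Continuous interval dimension; decode is identity with clamping."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"float range requires low <= high, got [{self.low}, {self.high}]")

    @property
    def bounds(self):
        return float(self.low), float(self.high)

    def decode(self, x: float):
        return min(max(float(x), self.low), self.high)

    def encode(self, v) -> float:
        return float(v)


@dataclass(frozen=True)
class SearchSpace:
    """Ordered, named collection of mixed-type dimensions."""

    dims: tuple
    names: tuple

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(self.dims))
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.dims) == 0:
            raise ValueError("search space needs at least one dimension")
        if len(self.dims) != len(self.names):
            raise ValueError("dims and names must align")

    def __len__(self) -> int:
        return len(self.dims)

    def internal_bounds(self):
        """(lo, hi) arrays bounding the internal real coordinates."""
        lo, hi = zip(*(d.bounds for d in self.dims))
        return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)

    def decode(self, position) -> dict:
        """Map an internal position vector to named hyperparameter values."""
        position = np.asarray(position, dtype=float)
        if position.shape != (len(self.dims),):
            raise ValueError(f"position length {position.shape} != dimensionality {len(self.dims)}")
        return {n: d.decode(x) for n, d, x in zip(self.names, self.dims, position)}

    def encode(self, params: dict) -> np.ndarray:
        """Map named values back to internal coordinates (decode's right inverse)."""
        return np.asarray(
            [d.encode(params[n]) for n, d in zip(self.names, self.dims)], dtype=float
        )

    def midpoint(self) -> np.ndarray:
        lo, hi = self.internal_bounds()
        return (lo + hi) / 2.0


@dataclass
class Candidate:
    """A population member: internal position plus (possibly unset) fitness."""

    position: np.ndarray
    fitness: float | None = None


@dataclass(frozen=True)
class ScheduleState:
    """Per-iteration foraging quantities (see module docstring)."""

    r: int
    R: int
    O: float
    J: float
    Q: float
    D: float
    N: float
    f: float | None = None


def oyster_schedule(r: int, R: int, rng: np.random.Generator | None = None) -> ScheduleState:
    """Compute the iteration-r foraging schedule for a run of R iterations.

    ``f`` is populated with a single representative U[0,1] draw when an rng
    is supplied; position proposals draw their own f per dimension.
    """
    if R < 1:
        raise ValueError(f"max iterations R must be >= 1, got {R}")
    if not 0 <= r <= R:
        raise ValueError(f"iteration r={r} outside [0, {R}]")
    O = 5.0 - r * (2.0 / R)
    J = ((O - 3.0) / 2.0) * 10.0 - 5.0
    Q = ((O - 3.0) / 2.0) * 2.0 + 0.6
    D = ((r - 1.0) / (R - 1.0)) - 0.5 if (r > 1 and R > 1) else -0.5
    N = D  # current energy requirement: the bird's present energy level
    f = float(rng.uniform()) if rng is not None else None
    return ScheduleState(r=r, R=R, O=O, J=J, Q=Q, D=D, N=N, f=f)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold positions back into [lo, hi] by triangle-wave reflection."""
    span = hi - lo
    out = x.copy()
    free = span > 0
    t = np.mod(out[free] - lo[free], 2.0 * span[free])
    out[free] = lo[free] + np.where(t <= span[free], t, 2.0 * span[free] - t)
    out[~free] = lo[~free]
    return out


def propose_move(
    candidate: Candidate,
    best: Candidate,
    sched: ScheduleState,
    rng: np.random.Generator,
    space: SearchSpace,
) -> Candidate:
    """Propose the next position for one candidate.

    Exploitation (``J + N > 0``): move toward the global best with a
    per-dimension random step ``O * f``; clamped to bounds. Exploration
    (opening capacity exhausted): multiplicative rescale by Q in
    lower-bound-shifted coordinates, reflected back into the box so the
    update cannot change sign or escape the bounds.
    """
    lo, hi = space.internal_bounds()
    p = np.asarray(candidate.position, dtype=float)
    if sched.J + sched.N > 0:
        f = rng.uniform(size=p.shape)
        new = p + sched.O * f * (np.asarray(best.position, dtype=float) - p)
        new = np.clip(new, lo, hi)
    else:
        shifted = (p - lo) * sched.Q
        new = _reflect(lo + shifted, lo, hi)
    return Candidate(position=new, fitness=None)


@dataclass
class OptResult:
    """Outcome of one optimizer run."""

    best_params: dict
    best_position: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)
    evaluations: int = 0
    objective_calls: int = 0
    seed: int | None = None


def optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    pop_size: int = 10,
    max_iter: int = 50,
    seed: int | None = None,
    seed_midpoint: bool = False,
    cache: bool = True,
    log_path=None,
) -> OptResult:
    """Minimise ``objective`` over ``space`` with the MML-EOO loop.

    The objective receives decoded named hyperparameters. Evaluations are
    cached on the decoded value tuple (decode is many-to-one and objective
    evaluations may involve network training); the logical evaluation count
    is exactly ``pop_size * (max_iter + 1)``. With ``seed_midpoint`` the
    first initial candidate is placed at the internal-bounds midpoint, so
    the result can never be worse than the mid-range default configuration.
    Identical seeds give bit-identical results.
    """
    if pop_size < 2:
        raise ValueError(f"pop_size must be >= 2, got {pop_size}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    rng = np.random.default_rng(seed)
    lo, hi = space.internal_bounds()

    memo: dict = {}
    counters = {"evals": 0, "calls": 0}
    log_f = open(log_path, "w") if log_path is not None else None

    def evaluate(position: np.ndarray, iteration: int, idx: int) -> float:
        counters["evals"] += 1
        params = space.decode(position)
        key = tuple(params.values())
        if cache and key in memo:
            fit = memo[key]
        else:
            counters["calls"] += 1
            try:
                fit = float(objective(params))
            except Exception as exc:
                raise RuntimeError(
                    f"objective failed at iteration {iteration}, candidate {idx}: {exc}"
                ) from exc
            if cache:
                memo[key] = fit
        if log_f is not None:
            log_f.write(
                json.dumps(
                    {
                        "iteration": iteration,
                        "candidate": idx,
                        "decoded_params": params,
                        "fitness": fit,
                    }
                )
                + "\n"
            )
        return fit

    try:
        pop = [
            Candidate(position=rng.uniform(lo, hi)) for _ in range(pop_size)
        ]
        if seed_midpoint:
            pop[0] = Candidate(position=space.midpoint())
        for i, c in enumerate(pop):
            c.fitness = evaluate(c.position, 0, i)

        best = min(pop, key=lambda c: c.fitness)
        best = Candidate(position=best.position.copy(), fitness=best.fitness)
        history = [best.fitness]

        for r in range(1, max_iter + 1):
            sched = oyster_schedule(r, max_iter, rng)
            for i, c in enumerate(pop):
                prop = propose_move(c, best, sched, rng, space)
                prop.fitness = evaluate(prop.position, r, i)
                if prop.fitness <= c.fitness:
                    pop[i] = prop
                if prop.fitness < best.fitness:
                    best = Candidate(position=prop.position.copy(), fitness=prop.fitness)
            history.append(best.fitness)
    finally:
        if log_f is not None:
            log_f.close()

    return OptResult(
        best_params=space.decode(best.position),
        best_position=best.position,
        best_fitness=best.fitness,
        history=history,
        evaluations=counters["evals"],
        objective_calls=counters["calls"],
        seed=seed,
    )
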