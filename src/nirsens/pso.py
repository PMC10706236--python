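"""Hybrid particle-swarm + pattern-search minimization of RMSECV.

Global phase: global-best PSO on the unit hypercube (parameters are mapped
to [0, 1] per dimension, in log10 space where flagged), with velocity
clamping and boundary reflection.  Local phase: compass pattern search from
the swarm's best point, polling +/- each coordinate and contracting the step
when no poll improves, until the step drops below tolerance.  The combined
trajectory of best objective values is non-increasing by construction and
fully deterministic for a fixed seed.

:func:`tune_svr` instantiates the search box exactly as the SVR family and
kernel license it: C always; epsilon (epsilon-SVR) or nu (nu-SVR); gamma for
every kernel except linear; the intercept coef0 for polynomial and sigmoid;
the integer degree (2-5) for polynomial, handled as a rounded continuous
dimension.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .regression import PlsSpec, SvrSpec, kfold_rmsecv, make_folds

__all__ = [
    "ParamBound",
    "PsoConfig",
    "PsoResult",
    "TuningResult",
    "pso_minimize",
    "pattern_search_refine",
    "tune_svr",
    "default_bounds",
]


@dataclasses.dataclass(frozen=True)
class ParamBound:
    """Box bound for one search dimension, optionally log-scaled or integer."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: bound low must be < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log-scaled bound requires low > 0")

    # unit-cube coordinate <-> parameter value
    def decode(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.log:
            v = 10 ** (np.log10(self.low) + u * (np.log10(self.high) - np.log10(self.low)))
        else:
            v = self.low + u * (self.high - self.low)
        if self.integer:
            v = float(np.clip(round(v), self.low, self.high))
        return float(v)


@dataclasses.dataclass
class PsoConfig:
    """Swarm and pattern-search settings.

    Inertia/cognitive/social default to the Clerc-constriction-equivalent
    coefficients (0.729, 1.49445, 1.49445).  ``patience`` stops the global
    phase after that many iterations without improvement.  Pattern-search
    step sizes are in unit-cube coordinates.
    """

    swarm_size: int = 20
    max_iterations: int = 50
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int = 0
    patience: int = 10
    ps_initial_step: float = 0.1
    ps_contraction: float = 0.5
    ps_tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if min(self.inertia, self.cognitive, self.social) < 0:
            raise ValueError("PSO coefficients must be >= 0")
        if not 0 < self.ps_contraction < 1:
            raise ValueError("ps_contraction must be in (0, 1)")


@dataclasses.dataclass
class PsoResult:
    """Generic minimization result in parameter space."""

    x: np.ndarray
    fun: float
    trajectory: np.ndarray
    evaluations: int


@dataclasses.dataclass
class TuningResult:
    """Best SVR spec found by the hybrid tuner, with diagnostics."""

    best_params: SvrSpec
    best_rmsecv: float
    trajectory: np.ndarray
    evaluations: int


def _reflect(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reflect positions at the unit-cube walls, flipping velocity there."""
    for _ in range(2):  # at most two reflections needed for |v| <= 1
        below, above = u < 0.0, u > 1.0
        u = np.where(below, -u, u)
        u = np.where(above, 2.0 - u, u)
        v = np.where(below | above, -v, v)
        if not (np.any(u < 0.0) or np.any(u > 1.0)):
            break
    return np.clip(u, 0.0, 1.0), v


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[ParamBound],
    config: PsoConfig,
    refine: bool = True,
) -> PsoResult:
    """Global-best PSO over the box, optionally polished by pattern search.

    ``objective`` receives the decoded parameter vector.  Non-finite
    objective values are treated as +inf; if every initial particle is
    non-finite the search aborts with an error.
    """
    rng = np.random.default_rng(config.seed)
    d = len(bounds)
    evals = 0

    def f(u: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        val = objective(np.array([b.decode(ui) for b, ui in zip(bounds, u)]))
        return float(val) if np.isfinite(val) else np.inf

    u = rng.random((config.swarm_size, d))
    v = rng.uniform(-0.1, 0.1, size=(config.swarm_size, d))
    fitness = np.array([f(ui) for ui in u])
    if not np.any(np.isfinite(fitness)):
        raise ValueError("objective non-finite at every initial particle")
    pbest_u, pbest_f = u.copy(), fitness.copy()
    g = int(np.argmin(pbest_f))
    gbest_u, gbest_f = pbest_u[g].copy(), float(pbest_f[g])
    trajectory = [gbest_f]
    stall = 0
    vmax = 0.5
    for _ in range(config.max_iterations):
        r1 = rng.random((config.swarm_size, d))
        r2 = rng.random((config.swarm_size, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_u - u)
            + config.social * r2 * (gbest_u[None, :] - u)
        )
        v = np.clip(v, -vmax, vmax)
        u, v = _reflect(u + v, v)
        fitness = np.array([f(ui) for ui in u])
        improved = fitness < pbest_f
        pbest_u[improved] = u[improved]
        pbest_f[improved] = fitness[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_u, gbest_f = pbest_u[g].copy(), float(pbest_f[g])
            stall = 0
        else:
            stall += 1
        trajectory.append(gbest_f)
        if stall >= config.patience:
            break
    if refine:
        gbest_u, gbest_f, _ = _pattern_search_unit(f=f, x0=gbest_u, f0=gbest_f, config=config)
        trajectory.append(gbest_f)
    x = np.array([b.decode(ui) for b, ui in zip(bounds, gbest_u)])
    return PsoResult(
        x=x, fun=gbest_f, trajectory=np.asarray(trajectory), evaluations=evals
    )


def _pattern_search_unit(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    f0: float,
    config: PsoConfig,
) -> tuple[np.ndarray, float, int]:
    """Compass search on the unit cube; never returns a worse point than x0."""
    x, fx = x0.copy(), f0
    step = config.ps_initial_step
    evals = 0
    d = len(x)
    while step >= config.ps_tolerance:
        best_cand, best_val = None, fx
        for i in range(d):
            for sign in (+1.0, -1.0):
                cand = x.copy()
                cand[i] = min(max(cand[i] + sign * step, 0.0), 1.0)
                if cand[i] == x[i]:
                    continue
                val = f(cand)
                evals += 1
                if val < best_val:
                    best_cand, best_val = cand, val
        if best_cand is None:
            step *= config.ps_contraction
        else:
            x, fx = best_cand, best_val
    return x, fx, evals


def pattern_search_refine(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[ParamBound],
    config: Optional[PsoConfig] = None,
) -> PsoResult:
    """Pattern-search polish from ``x0`` (in parameter space) within bounds."""
    config = config or PsoConfig()
    x0 = np.asarray(x0, dtype=float)
    # encode x0 into the unit cube
    u0 = np.empty(len(bounds))
    for i, b in enumerate(bounds):
        if b.log:
            u0[i] = (np.log10(x0[i]) - np.log10(b.low)) / (np.log10(b.high) - np.log10(b.low))
        else:
            u0[i] = (x0[i] - b.low) / (b.high - b.low)
        if not -1e-9 <= u0[i] <= 1 + 1e-9:
            raise ValueError(f"x0 outside bounds in dimension {b.name!r}")
    u0 = np.clip(u0, 0.0, 1.0)
    evals = 0

    def f(u: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        val = objective(np.array([b.decode(ui) for b, ui in zip(bounds, u)]))
        return float(val) if np.isfinite(val) else np.inf

    f0 = f(u0)
    u, fu, _ = _pattern_search_unit(f=f, x0=u0, f0=f0, config=config)
    x = np.array([b.decode(ui) for b, ui in zip(bounds, u)])
    return PsoResult(x=x, fun=fu, trajectory=np.asarray([f0, fu]), evaluations=evals)


# ---------------------------------------------------------------------------
# SVR hyperparameter tuning
# ---------------------------------------------------------------------------
#: Default search box. C up to 1e2, epsilon down to 1e-3 and gamma of order
#: 1e-3..1 bracket the magnitudes at which tuned spectra models typically land.
DEFAULT_BOUNDS = {
    "C": ParamBound("C", 1e-2, 1e2, log=True),
    "epsilon": ParamBound("epsilon", 1e-3, 1.0, log=True),
    "nu": ParamBound("nu", 0.01, 0.99),
    "gamma": ParamBound("gamma", 1e-3, 1.0, log=True),
    "coef0": ParamBound("coef0", -1.0, 1.0),
    "degree": ParamBound("degree", 2.0, 5.0, integer=True),
}


def default_bounds(svr_type: str, kernel: str) -> list[ParamBound]:
    """The search dimensions licensed by the given SVR family and kernel."""
    if svr_type not in ("epsilon", "nu"):
        raise ValueError("svr_type must be 'epsilon' or 'nu'")
    if kernel not in ("linear", "polynomial", "radial_base", "sigmoid"):
        raise ValueError(f"unknown kernel {kernel!r}")
    names = ["C", "epsilon" if svr_type == "epsilon" else "nu"]
    if kernel != "linear":
        names.append("gamma")
    if kernel in ("polynomial", "sigmoid"):
        names.append("coef0")
    if kernel == "polynomial":
        names.append("degree")
    return [DEFAULT_BOUNDS[n] for n in names]


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    svr_type: str,
    kernel: str,
    pso_config: Optional[PsoConfig] = None,
    cv_seed: int = 0,
    k: int = 5,
    bounds: Optional[Sequence[ParamBound]] = None,
) -> TuningResult:
    """Minimize 5-fold RMSECV over the licensed hyperparameter box.

    The CV folds are built once from ``cv_seed`` and reused for every
    candidate, so all parameter vectors compete on identical folds.
    """
    pso_config = pso_config or PsoConfig()
    bounds = list(bounds) if bounds is not None else default_bounds(svr_type, kernel)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    folds = make_folds(X.shape[0], min(k, X.shape[0]), cv_seed)

    def make_spec(vec: np.ndarray) -> SvrSpec:
        params = {b.name: (int(v) if b.integer else float(v)) for b, v in zip(bounds, vec)}
        return SvrSpec(svr_type=svr_type, kernel=kernel, **params)

    def objective(vec: np.ndarray) -> float:
        try:
            return kfold_rmsecv(X, y, make_spec(vec), folds=folds)
        except (ValueError, ArithmeticError):
            return np.inf

    result = pso_minimize(objective, bounds, pso_config, refine=True)
    return TuningResult(
        best_params=make_spec(result.x),
        best_rmsecv=result.fun,
        trajectory=result.trajectory,
        evaluations=result.evaluations,
    )
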