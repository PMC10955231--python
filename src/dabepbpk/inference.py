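"""Top-down parameter estimation and Morris elementary-effects screening.

Estimation follows the platform recipe: a weighted least-squares objective
(relative weights 1/obs^2 by default, because plasma levels span orders of
magnitude between micro- and therapeutic doses) minimized by Nelder-Mead,
with box bounds enforced through log/logit transforms so the simplex
roams an unconstrained space.  Sensitivity screening is the standard
Morris elementary-effects design on a p-level grid (radial one-at-a-time
trajectories), reported as mu, mu* and sigma per parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import EstimationError, InvalidParameterError

__all__ = ["FreeParameter", "EstimationProblem", "MorrisResult", "wls_loss",
           "fit_parameters", "morris_screen"]


@dataclass
class FreeParameter:
    name: str
    initial: float
    lower: float
    upper: float
    log_scale: bool = True

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidParameterError(f"{self.name}: empty bounds")
        if not self.lower <= self.initial <= self.upper:
            raise InvalidParameterError(f"{self.name}: initial outside bounds")
        if self.log_scale and self.lower <= 0:
            raise InvalidParameterError(
                f"{self.name}: log-scale parameter needs positive bounds")

    # unconstrained <-> natural transforms: log for positive scale
    # parameters, logit otherwise
    def to_internal(self, x: float) -> float:
        if self.log_scale:
            return math.log(x)
        p = (x - self.lower) / (self.upper - self.lower)
        p = min(max(p, 1e-12), 1 - 1e-12)
        return math.log(p / (1 - p))

    def to_natural(self, z: float) -> float:
        if self.log_scale:
            return min(max(math.exp(z), self.lower), self.upper)
        return self.lower + (self.upper - self.lower) / (1 + math.exp(-z))


@dataclass
class EstimationProblem:
    """Weighted least-squares problem binding free parameters to a
    prediction function.

    ``predict(params: dict) -> np.ndarray`` must return predictions on the
    observation grid.  Weights default to 1/obs^2 (relative error).
    """

    parameters: list[FreeParameter]
    observations: np.ndarray
    predict: callable
    weights: np.ndarray | None = None
    penalty: float = 1e12

    def __post_init__(self):
        self.observations = np.asarray(self.observations, dtype=float)
        if self.weights is None:
            obs = np.where(self.observations > 0, self.observations, np.nan)
            w = 1.0 / obs**2
            self.weights = np.where(np.isfinite(w), w, 0.0)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise InvalidParameterError("weights must be > 0")


def wls_loss(problem: EstimationProblem, values: dict) -> float:
    """Sum of w_i*(obs_i - pred_i)^2; simulation failures inside the loss
    return a large penalty instead of raising, so the simplex can back
    away from pathological corners."""
    try:
        pred = np.asarray(problem.predict(values), dtype=float)
    except Exception as exc:  # noqa: BLE001 - deliberate catch-all
        warnings.warn(f"simulation failed inside loss ({exc}); penalized")
        return problem.penalty
    if pred.shape != problem.observations.shape or not np.all(np.isfinite(pred)):
        return problem.penalty
    resid = problem.observations - pred
    return float(np.sum(problem.weights * resid**2))


@dataclass
class FitResult:
    estimates: dict
    loss: float
    converged: bool
    n_evaluations: int
    trace: list = field(default_factory=list)


def fit_parameters(problem: EstimationProblem, xatol: float = 1e-4,
                   fatol: float = 1e-10, maxiter: int = 400) -> FitResult:
    """Nelder-Mead minimization of the WLS objective (deterministic: the
    initial simplex is built from the transformed initial values, no
    randomness involved)."""
    pars = problem.parameters
    z0 = np.array([p.to_internal(p.initial) for p in pars])
    trace = []

    def objective(z):
        values = {p.name: p.to_natural(zi) for p, zi in zip(pars, z)}
        loss = wls_loss(problem, values)
        trace.append(loss)
        return loss

    res = optimize.minimize(objective, z0, method="Nelder-Mead",
                            options={"xatol": xatol, "fatol": fatol,
                                     "maxiter": maxiter, "maxfev": 4 * maxiter})
    estimates = {p.name: p.to_natural(zi) for p, zi in zip(pars, res.x)}
    if not res.success and res.status != 2:  # 2 = maxiter, still report
        raise EstimationError("Nelder-Mead failed", last_objective=res.fun)
    return FitResult(estimates=estimates, loss=float(res.fun),
                     converged=bool(res.success),
                     n_evaluations=int(res.nfev), trace=trace)


@dataclass
class MorrisResult:
    parameters: list
    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray
    levels: int
    trajectories: int
    seed: int

    def ranking(self) -> list:
        order = np.argsort(self.mu_star)[::-1]
        return [self.parameters[i] for i in order]


def morris_screen(func, ranges: dict, levels: int = 4, trajectories: int = 10,
                  seed: int = 0) -> MorrisResult:
    """Morris elementary-effects screening.

    ``func(params: dict) -> float`` is evaluated along ``trajectories``
    one-at-a-time trajectories on a ``levels``-level grid in the unit
    hypercube (step delta = levels/(2*(levels-1))), mapped linearly onto
    each parameter's (lo, hi) range.  Elementary effects are computed in
    unit space, so mu* for an additive linear model y = sum a_j x_j over
    unit ranges is exactly |a_j|.  Degenerate ranges (lo == hi) are
    dropped with a warning.  Reproducible by seed.
    """
    if trajectories < 4:
        raise InvalidParameterError("need at least 4 trajectories")
    names, los, his = [], [], []
    for name, (lo, hi) in ranges.items():
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise InvalidParameterError(f"{name}: range must be finite")
        if lo == hi:
            warnings.warn(f"parameter {name!r} has a degenerate range; dropped")
            continue
        names.append(name)
        los.append(lo)
        his.append(hi)
    if not names:
        raise InvalidParameterError("no non-degenerate parameters")
    los = np.asarray(los)
    his = np.asarray(his)
    k = len(names)
    p = levels
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    grid = np.arange(p - 1) / (p - 1.0)   # start levels that allow +delta

    ee = np.zeros((trajectories, k))
    for r in range(trajectories):
        x = grid[rng.integers(0, p - 1, size=k)].astype(float)
        direction = np.where(x + delta <= 1.0 + 1e-12, 1.0, -1.0)
        y_prev = func(dict(zip(names, los + x * (his - los))))
        for j in rng.permutation(k):
            x_new = x.copy()
            x_new[j] = x[j] + direction[j] * delta
            y_new = func(dict(zip(names, los + x_new * (his - los))))
            ee[r, j] = (y_new - y_prev) / (direction[j] * delta)
            x, y_prev = x_new, y_new

    return MorrisResult(
        parameters=names,
        mu=ee.mean(axis=0),
        mu_star=np.abs(ee).mean(axis=0),
        sigma=ee.std(axis=0, ddof=1),
        levels=levels, trajectories=trajectories, seed=seed,
    )
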