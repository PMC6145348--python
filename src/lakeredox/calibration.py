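"""Stochastic, sequential, bounded parameter search.

The algorithm calibrates model parameters against an arbitrary scalar
objective (here, the average MAE over chemistry and gene observables):

1. *Burn-in*: sample every free parameter from a truncated Gaussian
   within its literature bounds, evaluate the objective for each of the
   m samples, and re-centre the Gaussians by per-parameter linear
   regression; nothing is fixed.
2. *Sequential fixing*: each subsequent iteration repeats the sampling,
   runs a univariate F test per free parameter (sampled values as the
   feature, objective as the response), fixes the parameter with the
   lowest p value at its value in the best-scoring sample, and
   re-centres the remaining Gaussians.  The distance the centre moved
   sets the next Gaussian width (with a floor).
3. *Polish*: once every parameter is fixed, a bounded quasi-Newton
   refinement (L-BFGS-B, numerical gradients) starts from the point of
   convergence.

Everything is driven by a single integer seed and is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ParameterSpec",
    "IterationRecord",
    "CalibrationResult",
    "sample_parameters",
    "f_test",
    "run_iteration",
    "calibrate",
    "polish",
]

#: Gaussian s.d. floor, as a fraction of the bound width
SIGMA_FLOOR_FRACTION = 0.02
#: re-centering step scale
RECENTER_LAMBDA = 1.0


@dataclass
class ParameterSpec:
    """One searchable parameter: bounds, current Gaussian, fixed state."""

    name: str
    lower: float
    upper: float
    center: float | None = None
    sigma: float | None = None
    fixed: bool = False
    fixed_value: float | None = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.center is None:
            self.center = 0.5 * (self.lower + self.upper)
        if not self.lower <= self.center <= self.upper:
            raise ValueError(f"{self.name}: center outside bounds")
        if self.sigma is None:
            self.sigma = 0.25 * self.width
        if not self.sigma > 0:
            raise ValueError(f"{self.name}: sigma must be > 0")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def sigma_floor(self) -> float:
        return SIGMA_FLOOR_FRACTION * self.width


@dataclass
class IterationRecord:
    samples: np.ndarray          # m x p, in spec order
    objectives: np.ndarray       # m
    slopes: dict[str, float]
    f_stats: dict[str, float]
    p_values: dict[str, float]
    fixed_parameter: str | None
    fixed_value: float | None
    new_centers: dict[str, float]
    new_sigmas: dict[str, float]
    n_failed: int = 0


@dataclass
class CalibrationResult:
    iterations: list[IterationRecord]
    fixing_order: list[str]
    converged_point: np.ndarray
    polished_point: np.ndarray
    final_objective: float
    parameter_names: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, self.polished_point))


def _truncated_normal(
    rng: np.random.Generator, center: float, sigma: float,
    lower: float, upper: float, size: int,
) -> np.ndarray:
    """Rejection-sampled truncated Gaussian (no probability atoms at the
    bounds, unlike clipping)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(center, sigma, size=2 * (size - filled))
        keep = draw[(draw >= lower) & (draw <= upper)][: size - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def sample_parameters(
    specs: Sequence[ParameterSpec], m: int, seed: int
) -> np.ndarray:
    """m x p sample matrix: truncated Gaussians for free parameters,
    replicated fixed values for fixed ones.  Deterministic given seed."""
    if m < 3:
        raise ValueError("need at least m=3 samples")
    rng = np.random.default_rng(seed)
    cols = []
    for spec in specs:
        if spec.fixed:
            cols.append(np.full(m, spec.fixed_value))
        else:
            cols.append(
                _truncated_normal(rng, spec.center, spec.sigma, spec.lower, spec.upper, m)
            )
    return np.column_stack(cols)


def f_test(values: np.ndarray, objectives: np.ndarray) -> tuple[float, float]:
    """Univariate regression F test of objective on one parameter.

    F = (m-2) R^2 / (1 - R^2) with (1, m-2) degrees of freedom; constant
    objectives give F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    objectives = np.asarray(objectives, dtype=float)
    m = len(values)
    if m < 3:
        raise ValueError("need at least 3 points for the F test")
    if np.ptp(values) == 0:
        raise ValueError("zero variance in parameter values")
    x = values - values.mean()
    y = objectives - objectives.mean()
    ss_y = float(y @ y)
    if ss_y == 0:
        return 0.0, 1.0
    r2 = float((x @ y) ** 2 / ((x @ x) * ss_y))
    r2 = min(r2, 1.0)
    if r2 == 1.0:
        return np.inf, 0.0
    F = (m - 2) * r2 / (1.0 - r2)
    p = float(stats.f.sf(F, 1, m - 2))
    return F, p


def _regression_slope(values: np.ndarray, objectives: np.ndarray) -> float:
    x = values - values.mean()
    y = objectives - objectives.mean()
    return float((x @ y) / (x @ x))


def _recenter(
    spec: ParameterSpec, slope: float, objectives: np.ndarray
) -> tuple[float, float]:
    """Move the Gaussian centre downhill proportionally to the
    standardised sensitivity; new sigma is the distance moved (floored)."""
    sd_obj = float(objectives.std())
    if sd_obj == 0:
        step = 0.0
    else:
        step = RECENTER_LAMBDA * spec.sigma * (slope * spec.sigma / sd_obj)
    new_center = float(np.clip(spec.center - step, spec.lower, spec.upper))
    new_sigma = max(abs(new_center - spec.center), spec.sigma_floor)
    return new_center, new_sigma


def run_iteration(
    specs: list[ParameterSpec],
    objective_fn: Callable[[np.ndarray], float],
    m: int,
    seed: int,
    burn_in: bool = False,
) -> IterationRecord:
    """One sampling round: evaluate, F-test each free parameter, fix the
    most sensitive one (unless burn-in), and re-centre the rest.

    Mutates ``specs`` in place (centres, sigmas, fixed flags).  Samples
    whose objective evaluation fails are discarded and counted.
    """
    free = [s for s in specs if not s.fixed]
    if not free:
        raise ValueError("no unfixed parameters left")
    samples = sample_parameters(specs, m, seed)
    objectives = np.empty(m)
    ok = np.ones(m, dtype=bool)
    for i in range(m):
        try:
            val = float(objective_fn(samples[i]))
            if not np.isfinite(val):
                raise FloatingPointError("non-finite objective")
            objectives[i] = val
        except Exception:
            ok[i] = False
    n_failed = int((~ok).sum())
    if ok.sum() < 3:
        raise RuntimeError(
            f"fewer than 3 valid samples remain ({n_failed} failures)"
        )
    samples_ok = samples[ok]
    obj_ok = objectives[ok]

    name_to_col = {s.name: j for j, s in enumerate(specs)}
    slopes, fs, ps = {}, {}, {}
    for spec in free:
        col = samples_ok[:, name_to_col[spec.name]]
        F, p = f_test(col, obj_ok)
        slopes[spec.name] = _regression_slope(col, obj_ok)
        fs[spec.name], ps[spec.name] = F, p

    fixed_parameter = None
    fixed_value = None
    if not burn_in:
        # lowest p wins; ties broken by spec order (dict preserves it)
        best_p = min(ps.values())
        fixed_parameter = next(n for n in ps if ps[n] == best_p)
        best_row = int(np.argmin(obj_ok))
        fixed_value = float(samples_ok[best_row, name_to_col[fixed_parameter]])
        for spec in specs:
            if spec.name == fixed_parameter:
                spec.fixed = True
                spec.fixed_value = fixed_value
                spec.center = fixed_value

    new_centers, new_sigmas = {}, {}
    for spec in specs:
        if spec.fixed:
            continue
        c, sg = _recenter(spec, slopes[spec.name], obj_ok)
        spec.center, spec.sigma = c, sg
        new_centers[spec.name], new_sigmas[spec.name] = c, sg

    return IterationRecord(
        samples=samples_ok,
        objectives=obj_ok,
        slopes=slopes,
        f_stats=fs,
        p_values=ps,
        fixed_parameter=fixed_parameter,
        fixed_value=fixed_value,
        new_centers=new_centers,
        new_sigmas=new_sigmas,
        n_failed=n_failed,
    )


def polish(
    objective_fn: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    step_fraction: float = 1e-6,
    maxiter: int = 200,
) -> np.ndarray:
    """Bounded quasi-Newton (L-BFGS-B) refinement.

    Gradients are central differences with step ``step_fraction`` of each
    bound width, falling back to one-sided differences at an active
    bound so the objective is never evaluated outside the box.  The
    returned point never scores worse than the start.
    """
    start = np.asarray(start, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(start < lo) or np.any(start > hi):
        raise ValueError("start point outside bounds")
    f0 = float(objective_fn(start))
    if not np.isfinite(f0):
        raise ValueError("non-finite objective at the start point")

    # optimise in unit-box coordinates: parameters may differ by orders
    # of magnitude, and L-BFGS-B's gradient-norm stopping rule is only
    # meaningful on a common scale
    width = hi - lo

    def to_x(z):
        return lo + z * width

    def fz(z):
        return objective_fn(to_x(z))

    h = step_fraction

    def grad(z):
        g = np.empty_like(z)
        for j in range(len(z)):
            zp, zm = z.copy(), z.copy()
            zp[j] = min(z[j] + h, 1.0)
            zm[j] = max(z[j] - h, 0.0)
            g[j] = (fz(zp) - fz(zm)) / (zp[j] - zm[j])
        return g

    z0 = (start - lo) / width
    res = optimize.minimize(
        fz,
        z0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * len(z0),
        options={"maxiter": maxiter, "maxfun": 20 * maxiter, "ftol": 1e-12, "gtol": 1e-10},
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        return np.clip(to_x(res.x), lo, hi)
    return start


def calibrate(
    objective_fn: Callable[[np.ndarray], float],
    specs: Sequence[ParameterSpec],
    m: int = 200,
    seed: int = 0,
    polish_maxiter: int = 200,
) -> CalibrationResult:
    """Full search: burn-in, sequential fixing until every parameter is
    fixed, then L-BFGS-B polish from the point of convergence.

    ``polish_maxiter`` caps the quasi-Newton iterations; lower it when
    each objective evaluation is an expensive simulation.
    """
    specs = [replace(s) for s in specs]  # work on copies
    rng = np.random.default_rng(seed)
    iterations: list[IterationRecord] = []
    fixing_order: list[str] = []

    rec = run_iteration(specs, objective_fn, m, int(rng.integers(2**31)), burn_in=True)
    iterations.append(rec)
    while any(not s.fixed for s in specs):
        rec = run_iteration(specs, objective_fn, m, int(rng.integers(2**31)))
        iterations.append(rec)
        fixing_order.append(rec.fixed_parameter)

    converged = np.array([s.fixed_value for s in specs])
    bounds = [(s.lower, s.upper) for s in specs]
    polished = polish(objective_fn, converged, bounds, maxiter=polish_maxiter)
    return CalibrationResult(
        iterations=iterations,
        fixing_order=fixing_order,
        converged_point=converged,
        polished_point=polished,
        final_objective=float(objective_fn(polished)),
        parameter_names=[s.name for s in specs],
    )
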