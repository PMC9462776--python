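"""Least-squares calibration against detection-vs-lag curves.

The objective compares the model's analytic (exact-product) detection
probabilities with an observed curve, so it is smooth and deterministic —
no Monte-Carlo jitter enters the fit.  Identifiability caveat: a detection
curve constrains the noise parameters only through the threshold margins
(y_B - mu - excess)/sigma, and the load axis itself can be rescaled by the
stage-2 gain, so (mu, y_B) are only jointly identified via y_B - mu unless
one of them (or g2) is held fixed.  Fits should therefore free at most one
of {mu, y_B} together with sigma and/or g2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .errors import ParameterError
from .model import ModelParams, SeedLike, as_rng, deterministic_excess
from .blinkprob import exact_noblink_from_excess

FREE_PARAM_NAMES = ("mu", "sigma", "y_B", "g2")


@dataclass(frozen=True)
class EmpiricalCurve:
    """A detection-rate-vs-lag curve, e.g. behavioral data or a synthetic
    replica generated by :func:`generate_synthetic_curve`."""

    lags: np.ndarray
    detection_rate: np.ndarray
    n_trials_per_lag: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        rate = np.asarray(self.detection_rate, dtype=float)
        if lags.size != rate.size or lags.size == 0:
            raise ParameterError("lags and detection_rate must have equal, nonzero length")
        if (rate < 0).any() or (rate > 1).any():
            raise ParameterError("detection rates must lie in [0, 1]")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "detection_rate", rate)

    def to_frame(self):
        import pandas as pd

        n = (
            self.n_trials_per_lag
            if self.n_trials_per_lag is not None
            else np.full(self.lags.size, np.nan)
        )
        return pd.DataFrame(
            {"lag": self.lags, "detection_rate": self.detection_rate, "n_trials": n}
        )

    @classmethod
    def from_frame(cls, frame, source: str = "") -> "EmpiricalCurve":
        n = None
        if "n_trials" in frame and not frame["n_trials"].isna().all():
            n = frame["n_trials"].to_numpy(dtype=float).astype(int)
        return cls(
            lags=frame["lag"].to_numpy(dtype=int),
            detection_rate=frame["detection_rate"].to_numpy(dtype=float),
            n_trials_per_lag=n,
            source=source,
        )


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    fitted_values: dict[str, float]
    objective_value: float
    n_evaluations: int
    converged: bool
    seed: SeedLike = None


def _apply_free(
    init: ModelParams, names: Sequence[str], values: np.ndarray
) -> ModelParams:
    updates = dict(zip(names, values))
    params = init
    mu = updates.get("mu", params.mu)
    sigma = updates.get("sigma", params.sigma)
    if "y_B" in updates:
        from dataclasses import replace

        params = replace(params, blink_threshold=float(updates["y_B"]))
    if "g2" in updates:
        from dataclasses import replace as _replace

        params = _replace(
            params, h2_spec=_replace(params.h2_spec, gain=float(updates["g2"]))
        )
    return params.with_noise(float(mu), float(sigma))


def fit_params(
    curve: EmpiricalCurve,
    free: Sequence[str],
    init: ModelParams,
    bounds: dict[str, tuple[float, float]],
    seed: SeedLike = None,
    n_grid: int = 4,
) -> FitResult:
    """Minimize the squared error between model and observed detection rates.

    ``free`` names the parameters to optimize (subset of mu, sigma, y_B,
    g2); all others are held at their ``init`` values.  Derivative-free
    simplex search restarted from the best point of a coarse grid over the
    (finite) bounds.
    """
    free = list(free)
    for name in free:
        if name not in FREE_PARAM_NAMES:
            raise ParameterError(f"unknown free parameter {name!r}")
        if name not in bounds:
            raise ParameterError(f"missing bounds for free parameter {name!r}")
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ParameterError(f"bounds for {name!r} must be finite with lo < hi")
    if not free:
        raise ParameterError("at least one free parameter is required")

    # The deterministic excess path scales linearly with g2 and is otherwise
    # independent of the free parameters, so compute it once at g2 = 1.
    from dataclasses import replace as _replace

    base = _replace(init, h2_spec=_replace(init.h2_spec, gain=1.0))
    paths = {
        int(lag): deterministic_excess(base.stimulus_spec(int(lag)), base)
        for lag in curve.lags
    }
    g2_init = init.h2_spec.gain

    def objective(x: np.ndarray) -> float:
        vals = dict(zip(free, x))
        mu = vals.get("mu", init.mu)
        sigma = vals.get("sigma", init.sigma)
        y_b = vals.get("y_B", init.blink_threshold)
        g2 = vals.get("g2", g2_init)
        if sigma <= 0 or g2 <= 0 or y_b <= mu:
            return np.inf
        sse = 0.0
        for lag, rate in zip(curve.lags, curve.detection_rate):
            det = exact_noblink_from_excess(g2 * paths[int(lag)], mu, sigma, y_b)
            sse += (det - rate) ** 2
        return sse

    init_vals = {
        "mu": init.mu,
        "sigma": init.sigma,
        "y_B": init.blink_threshold,
        "g2": g2_init,
    }
    x_init = np.array([init_vals[name] for name in free])
    lo = np.array([bounds[name][0] for name in free])
    hi = np.array([bounds[name][1] for name in free])

    # Coarse grid restart: best of init and an n_grid^d lattice interior.
    axes = [np.linspace(l, h, n_grid + 2)[1:-1] for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    candidates = np.column_stack([m.ravel() for m in mesh])
    n_evals = 0
    best_x, best_f = x_init, objective(x_init)
    n_evals += 1
    for x in candidates:
        f = objective(x)
        n_evals += 1
        if f < best_f:
            best_x, best_f = x, f

    result = minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        bounds=list(zip(lo, hi)),
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    n_evals += result.nfev
    if result.fun <= best_f:
        best_x, best_f = result.x, float(result.fun)
    converged = bool(result.success and np.isfinite(best_f))

    fitted = _apply_free(init, free, best_x)
    return FitResult(
        params=fitted,
        fitted_values={name: float(v) for name, v in zip(free, best_x)},
        objective_value=float(best_f),
        n_evaluations=int(n_evals),
        converged=converged,
        seed=seed,
    )


def generate_synthetic_curve(
    params: ModelParams,
    n_trials_per_lag: int,
    lags: Sequence[int] = tuple(range(1, 9)),
    seed: SeedLike = None,
) -> EmpiricalCurve:
    """Synthetic behavioral curve: binomial samples of the model's own
    exact detection probabilities, for calibration/recovery testing."""
    if n_trials_per_lag < 1:
        raise ParameterError("n_trials_per_lag must be >= 1")
    rng = as_rng(seed)
    lags_arr = np.asarray(list(lags), dtype=int)
    rates = np.empty(lags_arr.size)
    for i, lag in enumerate(lags_arr):
        excess = deterministic_excess(params.stimulus_spec(int(lag)), params)
        det = exact_noblink_from_excess(excess, params.mu, params.sigma, params.y_b)
        rates[i] = rng.binomial(n_trials_per_lag, det) / n_trials_per_lag
    return EmpiricalCurve(
        lags=lags_arr,
        detection_rate=rates,
        n_trials_per_lag=np.full(lags_arr.size, n_trials_per_lag),
        source="synthetic",
    )


def calibrate_stage2_gain(
    mu: float,
    sigma: float,
    y_b: float,
    g1: float,
    target_detection: float = 0.6,
    lag: int = 3,
    bracket: tuple[float, float] = (0.05, 5.0),
) -> float:
    """Solve for the stage-2 gain that pins the exact detection probability
    at the given lag to ``target_detection``.

    This is the one-dimensional root find whose output is frozen as
    :data:`ablink.presets.G2`; detection is strictly decreasing in the gain,
    so the root is unique within the bracket.
    """
    from .presets import make_params

    base = make_params(mu=mu, sigma=sigma, y_b=y_b, g1=g1, g2=1.0)
    excess = deterministic_excess(base.stimulus_spec(lag), base)

    def gap(g2: float) -> float:
        return (
            exact_noblink_from_excess(g2 * excess, mu, sigma, y_b)
            - target_detection
        )

    return float(brentq(gap, *bracket, xtol=1e-12))
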