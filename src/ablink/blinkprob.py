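"""Blink probability P(max_t y(t) >= y_B), three ways.

* ``monte_carlo`` — seeded simulation; the deterministic load path is
  computed once and independent noise realizations are drawn around it
  (distributionally identical to re-simulating every trial from scratch,
  since the noise enters after the second filter).
* ``exact_product`` — because the load samples are independent Gaussians
  around the deterministic path d(t), the no-blink probability is exactly
  prod_t Phi((y_B - d(t)) / sigma).  This is the reference oracle.
* ``gumbel`` — a double-exponential (extreme-value) approximation of the
  distribution of the maximum: P(max < z) = exp(-sum_t Phibar((z - d_t)/sigma)),
  the Poisson-clumping form whose tail is the Gumbel law.  For a flat
  deterministic path of n samples it reduces to the classical max-of-n
  Gaussians normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ParameterError
from .model import (
    ModelParams,
    SeedLike,
    as_rng,
    deterministic_excess,
    StimulusSpec,
)

#: Cap on the number of scalars drawn per Monte-Carlo chunk (memory bound).
_MC_CHUNK_SCALARS = 20_000_000


@dataclass(frozen=True)
class BlinkEstimate:
    probability: float
    method: str
    lag: int
    n_reps: Optional[int] = None
    std_error: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if (self.method == "monte_carlo") != (self.std_error is not None):
            raise ValueError("std_error is present iff method == 'monte_carlo'")


@dataclass(frozen=True)
class DetectionCurve:
    """T2 detection probability (1 - blink probability) per lag."""

    lags: np.ndarray
    detection_prob: np.ndarray
    method: str
    params_id: str = ""
    std_error: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {"lag": self.lags, "detection_prob": self.detection_prob}
        if self.std_error is not None:
            data["std_error"] = self.std_error
        data["method"] = self.method
        return pd.DataFrame(data)


def _excess(spec: StimulusSpec, params: ModelParams) -> np.ndarray:
    return deterministic_excess(spec, params)


def mc_blink_from_excess(
    excess: np.ndarray,
    params: ModelParams,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of noise realizations whose max load crosses threshold."""
    margin = params.y_b - params.mu - excess  # crossing iff sigma*z >= margin
    n_done, n_cross = 0, 0
    chunk = max(1, _MC_CHUNK_SCALARS // excess.size)
    while n_done < n_reps:
        n = min(chunk, n_reps - n_done)
        z = rng.standard_normal((n, excess.size))
        n_cross += int(((params.sigma * z) >= margin).any(axis=1).sum())
        n_done += n
    return n_cross / n_reps


def exact_noblink_from_excess(
    excess: np.ndarray, mu: float, sigma: float, y_b: float
) -> float:
    """Exact no-blink probability given the deterministic excess path."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    z = (y_b - mu - excess) / sigma
    return float(np.exp(norm.logcdf(z).sum()))


def gumbel_noblink_from_excess(
    excess: np.ndarray, mu: float, sigma: float, y_b: float
) -> float:
    """Double-exponential approximation of the no-blink probability."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    z = (y_b - mu - excess) / sigma
    return float(np.exp(-norm.sf(z).sum()))


def blink_prob_mc(
    spec: StimulusSpec,
    params: ModelParams,
    n_reps: int = 1000,
    seed: SeedLike = None,
) -> BlinkEstimate:
    """Monte-Carlo blink probability over ``n_reps`` independent trials."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rng = as_rng(seed)
    p = mc_blink_from_excess(_excess(spec, params), params, n_reps, rng)
    return BlinkEstimate(
        probability=p,
        method="monte_carlo",
        lag=spec.lag,
        n_reps=n_reps,
        std_error=float(np.sqrt(p * (1 - p) / n_reps)),
    )


def blink_prob_exact(spec: StimulusSpec, params: ModelParams) -> BlinkEstimate:
    """Exact blink probability under white post-filter Gaussian noise."""
    p = 1.0 - exact_noblink_from_excess(
        _excess(spec, params), params.mu, params.sigma, params.y_b
    )
    return BlinkEstimate(probability=p, method="exact_product", lag=spec.lag)


def blink_prob_gumbel(spec: StimulusSpec, params: ModelParams) -> BlinkEstimate:
    """Extreme-value (double-exponential) approximation of the blink probability."""
    p = 1.0 - gumbel_noblink_from_excess(
        _excess(spec, params), params.mu, params.sigma, params.y_b
    )
    return BlinkEstimate(probability=p, method="gumbel", lag=spec.lag)


def excess_paths(
    params: ModelParams, lags: Sequence[int]
) -> dict[int, np.ndarray]:
    """Deterministic excess path per lag (shared by sweep and curve code)."""
    return {
        int(lag): deterministic_excess(params.stimulus_spec(int(lag)), params)
        for lag in lags
    }


def detection_curve(
    lags: Sequence[int],
    params: ModelParams,
    method: str = "exact_product",
    n_reps: int = 1000,
    seed: SeedLike = None,
    params_id: str = "",
) -> DetectionCurve:
    """Detection probability (1 - blink probability) across lags."""
    if len(lags) == 0:
        raise ParameterError("lags must be non-empty")
    lags_arr = np.asarray(list(lags), dtype=int)
    if (lags_arr < 1).any():
        raise ParameterError("all lags must be >= 1")
    rng = as_rng(seed)
    paths = excess_paths(params, lags_arr)
    det = np.empty(lags_arr.size)
    se: Optional[np.ndarray] = None
    if method == "monte_carlo":
        se = np.empty(lags_arr.size)
        for i, lag in enumerate(lags_arr):
            p = mc_blink_from_excess(paths[int(lag)], params, n_reps, rng)
            det[i] = 1.0 - p
            se[i] = np.sqrt(p * (1 - p) / n_reps)
    elif method == "exact_product":
        for i, lag in enumerate(lags_arr):
            det[i] = exact_noblink_from_excess(
                paths[int(lag)], params.mu, params.sigma, params.y_b
            )
    elif method == "gumbel":
        for i, lag in enumerate(lags_arr):
            det[i] = gumbel_noblink_from_excess(
                paths[int(lag)], params.mu, params.sigma, params.y_b
            )
    else:
        raise ParameterError(f"unknown method {method!r}")
    return DetectionCurve(
        lags=lags_arr,
        detection_prob=det,
        method=method,
        params_id=params_id,
        std_error=se,
    )
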