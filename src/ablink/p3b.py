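"""Resource Allocation Index (RAI) and model P3b amplitude.

RAI = (max_t y(t) - mu) / (y_B - mu) measures the fraction of total
attentional capacity consumed by a trial; it is not clamped, so blink
trials have RAI >= 1.  The model P3b amplitude is the RAI divided by the
subject's mental-noise fluctuation level sigma: for a fixed attentional
demand, noisier subjects show smaller T1-evoked P3b potentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .model import (
    AttentionalLoad,
    ModelParams,
    NoiseParams,
    SeedLike,
    StimulusSpec,
    analysis_window,
    as_rng,
    deterministic_excess,
)


@dataclass(frozen=True)
class P3bSummary:
    """Mean per-trial P3b conditioned on blink outcome.

    A condition with zero trials reports its mean as None, never 0.
    """

    mean_p3b_noblink: Optional[float]
    mean_p3b_blink: Optional[float]
    n_noblink: int
    n_blink: int
    lag: int
    params_id: str = ""

    @property
    def n_total(self) -> int:
        return self.n_noblink + self.n_blink


def rai_from_max(max_load: float, params: ModelParams) -> float:
    """RAI of a trial given its maximal attentional load."""
    if params.y_b <= params.mu:
        raise ParameterError("RAI requires y_B > mu")
    return (max_load - params.mu) / (params.y_b - params.mu)


def rai(load: AttentionalLoad, params: ModelParams) -> float:
    """RAI of a simulated load trajectory (max over the analysis window)."""
    window = load.values[analysis_window(load.spec)]
    return rai_from_max(float(window.max()), params)


def deterministic_rai(
    spec: StimulusSpec, params: ModelParams, n_targets: int = 2
) -> float:
    """Noise-free RAI: peak of the deterministic load path, no noise drawn.

    Used for the smooth parameter-space maps and the training-consistency
    P3b factor, where per-trial noise would only add Monte-Carlo jitter.
    """
    if params.y_b <= params.mu:
        raise ParameterError("RAI requires y_B > mu")
    peak = float(deterministic_excess(spec, params, n_targets=n_targets).max())
    return peak / (params.y_b - params.mu)


def p3b_amplitude(rai_value: float, noise: NoiseParams) -> float:
    """Model P3b amplitude: RAI scaled by the subject's 1/sigma."""
    if noise.sd <= 0:
        raise ParameterError("noise sd must be positive")
    return rai_value / noise.sd


def conditioned_p3b(
    spec: StimulusSpec,
    params: ModelParams,
    n_reps: int = 1000,
    seed: SeedLike = None,
    params_id: str = "",
) -> P3bSummary:
    """Simulate trials and summarize mean P3b separately for blink and
    no-blink outcomes."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rng = as_rng(seed)
    excess = deterministic_excess(spec, params)
    maxes = np.empty(n_reps)
    chunk = max(1, 20_000_000 // excess.size)
    done = 0
    while done < n_reps:
        n = min(chunk, n_reps - done)
        z = rng.standard_normal((n, excess.size))
        maxes[done : done + n] = (
            params.mu + excess + params.sigma * z
        ).max(axis=1)
        done += n
    rai_values = (maxes - params.mu) / (params.y_b - params.mu)
    p3b_values = rai_values / params.sigma
    blinked = maxes >= params.y_b
    n_blink = int(blinked.sum())
    n_noblink = n_reps - n_blink
    return P3bSummary(
        mean_p3b_noblink=float(p3b_values[~blinked].mean()) if n_noblink else None,
        mean_p3b_blink=float(p3b_values[blinked].mean()) if n_blink else None,
        n_noblink=n_noblink,
        n_blink=n_blink,
        lag=spec.lag,
        params_id=params_id,
    )
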