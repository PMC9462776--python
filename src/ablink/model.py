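"""Core two-stage dynamics: sensory trace, attentional load, trial simulation.

Stage 1 filters the input impulse train with the Gaussian kernel and clips
the result at 1 (a likelihood cannot exceed certainty), yielding the
*sensory trace*.  The clipping makes the trace sub-linear in the input: two
temporally overlapping targets produce less combined trace than the sum of
their individual traces, which is the mechanism behind lag-1 sparing.

Stage 2 filters the sensory trace with the Gamma kernel and adds white
Gaussian *mental noise* n(t) ~ N(mu, sigma^2), yielding the *attentional
load* y(t).  Because the noise enters after the second filter, the load
samples are conditionally independent Gaussians around the deterministic
(noise-free) path — which is what makes the exact product form of the blink
probability available (see :mod:`ablink.blinkprob`).

An attentional blink occurs on a trial when the load reaches or crosses the
blinking threshold y_B anywhere in the analysis window, which runs from T1
onset to T2 offset plus the full support of both kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .errors import ParameterError
from .kernels import Kernel, KernelSpec, build_kernel
from .stimuli import ImpulseTrain, StimulusSpec, build_impulse_train

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Normalize a seed-like argument to a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseParams:
    """Mean (baseline) and standard deviation (fluctuation) of mental noise,
    both on the attentional-load scale."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterError("noise sd must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the two-stage model."""

    h1_spec: KernelSpec
    h2_spec: KernelSpec
    blink_threshold: float
    noise: NoiseParams
    clip_threshold: float = 1.0
    sample_period_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.clip_threshold != 1.0:
            raise ParameterError("the sensory trace is a likelihood; clip_threshold is fixed at 1")
        if self.blink_threshold <= self.noise.mean:
            raise ParameterError(
                "blink_threshold must exceed the noise mean (the system would blink at rest)"
            )
        for spec in (self.h1_spec, self.h2_spec):
            if spec.sample_period_ms != self.sample_period_ms:
                raise ParameterError("kernel and model sample periods disagree")

    @property
    def mu(self) -> float:
        return self.noise.mean

    @property
    def sigma(self) -> float:
        return self.noise.sd

    @property
    def y_b(self) -> float:
        return self.blink_threshold

    def h1(self) -> Kernel:
        return build_kernel(self.h1_spec)

    def h2(self) -> Kernel:
        return build_kernel(self.h2_spec)

    @property
    def kernel_lengths(self) -> tuple[int, int]:
        return (
            self.h1_spec.window_length_samples,
            self.h2_spec.window_length_samples,
        )

    def with_noise(self, mean: float, sd: float) -> "ModelParams":
        return replace(self, noise=NoiseParams(mean=mean, sd=sd))

    def stimulus_spec(self, lag: int) -> StimulusSpec:
        """A default stimulus spec sized to this model's kernels."""
        l1, _ = self.kernel_lengths
        return StimulusSpec(
            lag=lag,
            sample_period_ms=self.sample_period_ms,
            t1_onset_sample=l1,
            kernel_lengths=self.kernel_lengths,
        )


@dataclass(frozen=True)
class SensoryTrace:
    """Stage-1 output: filtered input clipped to [0, 1]."""

    values: np.ndarray
    spec: StimulusSpec

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("sensory trace must lie in [0, 1]")


@dataclass(frozen=True)
class AttentionalLoad:
    """Stage-2 output: deterministic path plus a mental-noise realization.

    ``values = deterministic - mu + noise_realization`` sample-wise, where
    the noise realization has mean mu.
    """

    values: np.ndarray
    deterministic: np.ndarray
    noise_realization: np.ndarray
    spec: StimulusSpec
    seed: SeedLike = None


@dataclass(frozen=True)
class TrialResult:
    """Per-trial observables: blink event, RAI and model P3b amplitude."""

    max_load: float
    blinked: bool
    rai: float
    p3b: float
    lag: int
    seed: SeedLike = None


def analysis_window(spec: StimulusSpec) -> slice:
    """Window over which the maximum load is taken: T1 onset to T2 offset
    plus the support of both kernels (the period in which the system is
    responding to the input)."""
    return slice(spec.t1_onset_sample, spec.response_end_sample)


def sensory_trace(u: ImpulseTrain, params: ModelParams) -> SensoryTrace:
    """Filter the impulse train with h1 and clip at the unit threshold."""
    if u.spec.sample_period_ms != params.sample_period_ms:
        raise ParameterError("impulse train and model sample periods disagree")
    h1 = params.h1().coefficients
    filtered = np.convolve(u.values, h1)[: u.values.size]
    return SensoryTrace(
        values=np.minimum(filtered, params.clip_threshold), spec=u.spec
    )


def deterministic_load(trace: SensoryTrace, params: ModelParams) -> np.ndarray:
    """Noise-free component of the attentional load: (trace * h2) + mu."""
    h2 = params.h2().coefficients
    return np.convolve(trace.values, h2)[: trace.values.size] + params.mu


def attentional_load(
    trace: SensoryTrace, params: ModelParams, seed: SeedLike = None
) -> AttentionalLoad:
    """Add white Gaussian mental noise to the filtered sensory trace."""
    rng = as_rng(seed)
    det = deterministic_load(trace, params)
    noise = rng.normal(params.mu, params.sigma, size=det.size)
    return AttentionalLoad(
        values=det - params.mu + noise,
        deterministic=det,
        noise_realization=noise,
        spec=trace.spec,
        seed=seed,
    )


def deterministic_excess(
    spec: StimulusSpec, params: ModelParams, n_targets: int = 2
) -> np.ndarray:
    """Deterministic load minus mu, restricted to the analysis window.

    This is the stimulus-driven part of the load; it does not depend on the
    noise parameters, which is exploited by the analytic blink probability
    and the parameter sweep.
    """
    u = build_impulse_train(spec, n_targets=n_targets)
    det = deterministic_load(sensory_trace(u, params), params)
    return det[analysis_window(spec)] - params.mu


def simulate_trial(
    spec: StimulusSpec,
    params: ModelParams,
    seed: SeedLike = None,
    n_targets: int = 2,
) -> TrialResult:
    """Run one full trial: impulse train -> trace -> load -> observables."""
    u = build_impulse_train(spec, n_targets=n_targets)
    load = attentional_load(sensory_trace(u, params), params, seed=seed)
    window = load.values[analysis_window(spec)]
    max_load = float(window.max())
    rai = (max_load - params.mu) / (params.y_b - params.mu)
    return TrialResult(
        max_load=max_load,
        blinked=bool(max_load >= params.y_b),
        rai=rai,
        p3b=rai / params.sigma,
        lag=spec.lag,
        seed=seed,
    )
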