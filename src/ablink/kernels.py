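"""Finite impulse responses for the two processing stages.

Stage 1 (sensory integration) uses a symmetric Gaussian window whose
standard deviation tau1 is given in milliseconds; stage 2 (attentional
allocation) uses a causal Gamma-shaped response t * exp(-t / tau2) that
peaks at t = tau2.  Both kernels carry an explicit normalization mode and a
multiplicative gain, because the load-scale parameters (noise mean, blink
threshold) are only meaningful relative to a fixed gain convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateKernelError, ParameterError

Normalization = Literal["unit_area", "unit_peak", "raw"]


@dataclass(frozen=True)
class KernelSpec:
    kind: Literal["gaussian", "gamma"]
    time_constant_ms: float
    window_length_samples: int
    sample_period_ms: float = 10.0
    normalization: Normalization = "unit_area"
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.time_constant_ms <= 0:
            raise ParameterError("time constant must be positive")
        if self.window_length_samples < 1:
            raise ParameterError("window length must be >= 1")
        if self.sample_period_ms <= 0:
            raise ParameterError("sample period must be positive")
        if self.gain <= 0:
            raise ParameterError("gain must be positive")
        if self.normalization not in ("unit_area", "unit_peak", "raw"):
            raise ParameterError(f"unknown normalization {self.normalization!r}")
        if self.kind not in ("gaussian", "gamma"):
            raise ParameterError(f"unknown kernel kind {self.kind!r}")


@dataclass(frozen=True)
class Kernel:
    """A finite impulse response with its generating specification."""

    coefficients: np.ndarray
    spec: KernelSpec

    def __len__(self) -> int:
        return self.coefficients.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample": np.arange(len(self)), "coefficient": self.coefficients}
        )


def _normalize(raw: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.normalization == "unit_area":
        total = raw.sum()
        if total <= 0:
            raise DegenerateKernelError("kernel has non-positive area")
        out = raw / total
    elif spec.normalization == "unit_peak":
        peak = raw.max()
        if peak <= 0:
            raise DegenerateKernelError("kernel has non-positive peak")
        out = raw / peak
    else:
        out = raw
    return out * spec.gain


def build_kernel(spec: KernelSpec) -> Kernel:
    """Materialize the coefficients for a kernel specification."""
    k = np.arange(spec.window_length_samples, dtype=np.float64)
    if spec.kind == "gaussian":
        center = (spec.window_length_samples - 1) / 2.0
        sigma_samples = spec.time_constant_ms / spec.sample_period_ms
        raw = np.exp(-0.5 * ((k - center) / sigma_samples) ** 2)
    else:
        # Causal: zero at t <= 0, peak at t = tau2.
        t = k * spec.sample_period_ms
        raw = np.where(t > 0, t * np.exp(-t / spec.time_constant_ms), 0.0)
    return Kernel(coefficients=_normalize(raw, spec), spec=spec)


def gaussian_kernel(
    tau1_ms: float,
    window_length_samples: int = 90,
    sample_period_ms: float = 10.0,
    normalization: Normalization = "unit_area",
    gain: float = 1.0,
) -> Kernel:
    """Stage-1 Gaussian impulse response (standard deviation ``tau1_ms``)."""
    return build_kernel(
        KernelSpec(
            kind="gaussian",
            time_constant_ms=tau1_ms,
            window_length_samples=window_length_samples,
            sample_period_ms=sample_period_ms,
            normalization=normalization,
            gain=gain,
        )
    )


def gamma_kernel(
    tau2_ms: float,
    window_length_samples: int = 263,
    sample_period_ms: float = 10.0,
    normalization: Normalization = "unit_peak",
    gain: float = 1.0,
) -> Kernel:
    """Stage-2 Gamma impulse response, peaking at ``t = tau2_ms``."""
    return build_kernel(
        KernelSpec(
            kind="gamma",
            time_constant_ms=tau2_ms,
            window_length_samples=window_length_samples,
            sample_period_ms=sample_period_ms,
            normalization=normalization,
            gain=gain,
        )
    )


def fwhm_ms(kernel: Kernel) -> float:
    """Full width at half maximum of a kernel, in ms.

    The peak height is estimated by parabolic interpolation around the
    argmax (the sampled maximum underestimates the true peak when the grid
    straddles the kernel center) and the crossings of the half-maximum
    level are then located with linear interpolation between samples, so
    the result is not quantized to the sample grid.  For the Gaussian
    stage-1 kernel this agrees with the closed form 2*sqrt(2*ln 2)*tau1 to
    within one sample period.
    """
    c = np.asarray(kernel.coefficients, dtype=np.float64)
    peak = c.max()
    if peak <= 0:
        raise DegenerateKernelError("cannot compute FWHM of an all-zero kernel")
    i = int(np.argmax(c))
    if 0 < i < c.size - 1:
        denom = c[i - 1] - 2 * c[i] + c[i + 1]
        if denom < 0:  # strictly concave around the maximum
            peak = c[i] - (c[i + 1] - c[i - 1]) ** 2 / (8 * denom)
    half = peak / 2.0
    above = np.flatnonzero(c >= half)
    first, last = above[0], above[-1]
    dt = kernel.spec.sample_period_ms

    left = float(first)
    if first > 0:
        left = first - (c[first] - half) / (c[first] - c[first - 1])
    right = float(last)
    if last < c.size - 1:
        right = last + (c[last] - half) / (c[last] - c[last + 1])
    return (right - left) * dt
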