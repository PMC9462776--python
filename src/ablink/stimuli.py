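"""Stimulus encoding for rapid serial visual presentation (RSVP) trials.

A trial is represented on a fixed sample grid (10 ms per sample by default).
Each target is a rectangular impulse of ``target_duration_samples`` samples
(100 ms by default).  The T1-T2 *lag* is 1-based: lag ``k`` places the T2
onset ``k`` target-durations after the T1 onset, i.e. a stimulus-onset
asynchrony of ``k x 100`` ms and an inter-stimulus interval of
``(k - 1) x 100`` ms.  Distractors draw no attentional resources in this
model and are encoded as 0, so the input signal is a binary impulse train
marking target positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidLagError, TrialLengthError

#: Default sample period (ms) — the temporal resolution of the model.
DEFAULT_DT_MS = 10.0
#: Default target duration in samples (100 ms at the default grid).
DEFAULT_TARGET_SAMPLES = 10
#: Default stage-1 / stage-2 kernel window lengths used to size trials.
DEFAULT_L1 = 90
DEFAULT_L2 = 263
#: Silent tail appended after the response support has ended.
DEFAULT_TAIL_SAMPLES = 50


def lag_to_isi_ms(lag: int, target_duration_ms: float = 100.0) -> float:
    """Inter-stimulus interval (T1 offset to T2 onset) in ms for a lag.

    Lag 1 means T2 starts immediately at T1 offset (ISI 0); each additional
    lag adds one target duration, so lag 3 corresponds to an ISI of 200 ms.
    """
    if int(lag) != lag or lag < 1:
        raise InvalidLagError(f"lag must be a positive integer, got {lag!r}")
    return (lag - 1) * target_duration_ms


@dataclass(frozen=True)
class StimulusSpec:
    """Specification of a two-target RSVP trial on the model sample grid.

    ``trial_length_samples=None`` selects the default length
    ``t2_offset + L1 + L2 + tail`` so that the full support of both filter
    responses (and a short silent tail) fits inside the trial.
    """

    lag: int
    sample_period_ms: float = DEFAULT_DT_MS
    target_duration_samples: int = DEFAULT_TARGET_SAMPLES
    t1_onset_sample: int = DEFAULT_L1
    trial_length_samples: int | None = None
    kernel_lengths: tuple[int, int] = field(default=(DEFAULT_L1, DEFAULT_L2))

    def __post_init__(self) -> None:
        if int(self.lag) != self.lag or self.lag < 1:
            raise InvalidLagError(f"lag must be a positive integer, got {self.lag!r}")
        if self.sample_period_ms <= 0:
            raise TrialLengthError("sample_period_ms must be positive")
        if self.target_duration_samples < 1:
            raise TrialLengthError("target_duration_samples must be >= 1")
        if self.t1_onset_sample < 0:
            raise TrialLengthError("t1_onset_sample must be non-negative")
        if self.trial_length_samples is None:
            object.__setattr__(
                self,
                "trial_length_samples",
                self.response_end_sample + DEFAULT_TAIL_SAMPLES,
            )
        if self.trial_length_samples < self.response_end_sample:
            raise TrialLengthError(
                f"trial_length_samples={self.trial_length_samples} is shorter than "
                f"the stimulus response support ({self.response_end_sample} samples)"
            )

    @property
    def t2_onset_sample(self) -> int:
        return self.t1_onset_sample + self.lag * self.target_duration_samples

    @property
    def t2_offset_sample(self) -> int:
        return self.t2_onset_sample + self.target_duration_samples

    @property
    def response_end_sample(self) -> int:
        """End of the window in which the system responds to the stimulus."""
        l1, l2 = self.kernel_lengths
        return self.t2_offset_sample + l1 + l2

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony between T1 and T2."""
        return self.lag * self.target_duration_samples * self.sample_period_ms

    @property
    def isi_ms(self) -> float:
        """Inter-stimulus interval between T1 offset and T2 onset."""
        return (self.lag - 1) * self.target_duration_samples * self.sample_period_ms

    def with_lag(self, lag: int) -> "StimulusSpec":
        """Copy of this spec at another lag, re-deriving the trial length."""
        return replace(self, lag=lag, trial_length_samples=None)


@dataclass(frozen=True)
class ImpulseTrain:
    """Binary input signal u(t) marking target positions on the sample grid."""

    values: np.ndarray
    spec: StimulusSpec
    n_targets: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("impulse train values must be 0 or 1")
        expected = self.n_targets * self.spec.target_duration_samples
        if int(v.sum()) != expected:
            raise ValueError(
                f"impulse train has {int(v.sum())} active samples, expected {expected}"
            )

    def to_frame(self):
        """Two-column table (sample_index, value) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"sample_index": np.arange(self.values.size), "value": self.values}
        )


def build_impulse_train(spec: StimulusSpec, n_targets: int = 2) -> ImpulseTrain:
    """Construct the input impulse train for a one- or two-target trial.

    T1 occupies ``[t1_onset, t1_onset + duration)``; with two targets T2
    starts ``lag x duration`` samples after the T1 onset.  Deterministic:
    repeated calls are bit-identical.
    """
    if n_targets not in (1, 2):
        raise ValueError(f"n_targets must be 1 or 2, got {n_targets}")
    u = np.zeros(spec.trial_length_samples, dtype=np.float64)
    d = spec.target_duration_samples
    u[spec.t1_onset_sample : spec.t1_onset_sample + d] = 1.0
    if n_targets == 2:
        if spec.t2_offset_sample > spec.trial_length_samples:
            raise TrialLengthError("trial too short to contain T2")
        u[spec.t2_onset_sample : spec.t2_onset_sample + d] = 1.0
    return ImpulseTrain(values=u, spec=spec, n_targets=n_targets)
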