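# ablink

A simulator of the **attentional blink** (AB): the reduced probability of
reporting a second target (T2) that appears 200–600 ms after a first target
(T1) in a rapid serial visual presentation (RSVP) stream. The package is
aimed at computational cognitive scientists who want to simulate AB
detection curves, study how "mental noise" (task-unrelated mental activity,
e.g. mind wandering) shapes them, and calibrate the model against behavioral
detection-rate data — for instance to model the effects of intensive
meditation training on the blink and on T1-evoked P3b potentials.

## The model

Targets are encoded as a binary impulse train u(t) on a 10 ms grid (each
target is a 100 ms pulse; a T1–T2 lag of k means a stimulus-onset asynchrony
of k × 100 ms). Two filtering stages follow:

1. **Sensory trace** — ŷ(t) = min{u ∗ h₁, 1}, where h₁ is a Gaussian window
   (σ = τ₁ = 60 ms, L₁ = 90 samples). The clip at 1 (a likelihood cannot
   exceed certainty) makes the trace sub-linear for overlapping targets and
   is the mechanism behind *lag-1 sparing*.
2. **Attentional load** — y(t) = (ŷ ∗ h₂) + n(t), where h₂ ∝ t·e^(−t/τ₂)
   (τ₂ = 500 ms, L₂ = 263 samples) and n(t) ~ 𝒩(μ, σ²) is white Gaussian
   *mental noise*.

A **blink** occurs when y(t) reaches the blinking threshold y_B anywhere in
the response window: P(Blink) = P(max_t y(t) ≥ y_B). Because the noise is
added after the second filter, this probability has an exact closed form,
1 − ∏_t Φ((y_B − d(t))/σ) with d(t) the noise-free load path — used as the
reference oracle for the Monte-Carlo estimator and for an extreme-value
(double-exponential) approximation.

Two observables connect the model to electrophysiology: the Resource
Allocation Index RAI = (max_t y(t) − μ)/(y_B − μ), and the model P3b
amplitude P3b = RAI/σ. Training effects are modeled purely as changes in
(μ, σ): the reference presets are (17.4, 3.2) before and (13.2, 3.8) after
training, with y_B = 53.3, under the package's calibrated filter gains
(g₁ = 1.5, g₂ ≈ 1.0288; see `docs/methods.md`).

## Worked example

Detection probability vs lag for the pre-training preset, computed with the
exact product form:

```bash
$ ablink curve --preset time1 --lags 1:8 --method exact
# ablink_version: 0.1.0
# preset: time1
# params: {"mu": 17.4, "sigma": 3.2, "y_B": 53.3, ...}
# seed: 0
lag,detection_prob,method
1,0.9439737578016782,exact_product
2,0.41791399009384206,exact_product
3,0.6000000000000106,exact_product
4,0.7845478400447039,exact_product
5,0.9094919632211441,exact_product
6,0.9691170008681944,exact_product
7,0.9909175091000917,exact_product
8,0.9975570115630311,exact_product
```

This is the classic U-shaped AB curve: detection at lag 1 (0.944) exceeds
lag 2 (0.418) — lag-1 sparing — the blink is deepest at lag 2, detection at
lag 3 sits at 0.60 (the calibration anchor, matching the pre-training
behavioral condition 0.6 ± 0.1), and performance recovers toward 1 by lags
6–8 as the two targets' attentional responses separate. Swapping
`--preset time2` (post-training noise) raises lag-3 detection to ≈ 0.95.

The same quantities are available from Python:

```python
import ablink as ab

params = ab.load_preset("time1")
est = ab.blink_prob_exact(params.stimulus_spec(3), params)
print(1 - est.probability)   # 0.6000000000000106
```

Other subcommands: `simulate` (per-sample trial traces), `sweep` (noise
parameter grid + consistent pre/post pairs), `fit` (least-squares
calibration to a detection curve), `p3b` and `interaction` (blink-
conditioned P3b summaries). Every output carries a `#` manifest header
(version, parameters, seed) sufficient to reproduce it bit-exactly.

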