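# Methods

## Model

The body centre of mass (BCOM) of a steadily walking person is treated as a
point moving with constant forward velocity v̄_ap plus zero-mean periodic
oscillations along the anatomical axes: medio-lateral sway at the stride
frequency (the BCOM shifts toward each stance foot once per stride), and
vertical lift and fore-aft speed modulation at the step frequency (every
footfall), i.e. at twice the ML frequency.  Over a window spanning an
integer number of strides the time-averaged kinetic energy per unit mass
splits exactly into

    Ēk = KE0 + APE + MLE + VTE,   KE0 = ½ v̄_ap²,

because the cross term v̄_ap·v_ap(t) averages to zero on such windows.  The
overhead energy percentage OEP = (APE+MLE+VTE)/KE0 and the energy-partition
shares EP% = 100·OE_axis/TOE are both per-unit-mass ratios and therefore
independent of body mass.  For near-sinusoidal oscillations each OE is
(amplitude·angular frequency)²/4, so OEP is quadratic in the peak-to-peak
displacement at fixed speed and cadence — the basis of the square-root
scaling helper (`oep_scaling`) and of the rule-of-thumb mean oscillatory
speed 2·d_pp/T (exact for a sinusoid, whose path length per period is
2·d_pp).

## Pipeline and numerical choices

**Calibration.**  Tilt is the minimal (Rodrigues) rotation taking the mean
specific force of a quasi-static neutral-pose window (≥ 1 s, per-axis std
< 0.2 m/s², |g| validated against [9.5, 10.1] m/s²) onto +z.  The heading —
the remaining rotation about the vertical — comes from the orientation
quaternions when the recording carries them; otherwise the horizontal
oscillatory velocity is band-passed to ±25% around the step frequency
(itself read off the vertical velocity spectrum) and its principal
direction is taken as AP.  The narrow band matters: broadband ML and AP
velocity variances can tie (they do exactly for the wide-stance preset),
making plain PCA degenerate, whereas the ML component has essentially no
power at the step frequency.  The travel-direction *sign* is unobservable
from oscillations alone and is fixed by convention; every reported metric
is quadratic in velocity and unaffected.  Gravity is subtracted as a
constant vector in the levelled frame; the residual of this approximation
is low-frequency and removed by the high-pass.

**Filtering.**  4th-order Butterworth, zero-phase (`sosfiltfilt`), 0.3 Hz
cut-on (well below the slowest gait component, the ML stride frequency
≈ 0.9 Hz, but high enough to suppress accelerometer drift) and an optional
15 Hz cut-off for jitter.  Zero-phase filtering preserves trajectory
shapes.  Inputs must exceed three settling times (10 s at the defaults).

**Integration and drift control.**  Cumulative trapezoid per axis; after
*each* integration stage the same 0.3 Hz high-pass is re-applied and the
series is mean-centred over the analysis window, because integrating a
finite noisy window drifts even for DC-free inputs.  The mean forward speed
cannot survive the high-pass by design and is supplied separately:
`treadmill` (metadata), `walkway` (default; walkway length divided by the
first-to-last step-event span plus one mean step period, compensating the
roughly half-step of walking outside the detected events at either end), or
`lowfreq` (mean of AP velocity integrated from the unfiltered calibrated
acceleration — kept for completeness; it recovers nothing when the
recording misses the gait-initiation acceleration).

**Segmentation.**  Steps are prominent peaks (≥ 0.5 m/s², ≥ 0.25 s apart)
of the band-passed vertical acceleration — one per step, since VT completes
one cycle per step.  Steady state drops the first two and last two steps of
each walking bout; out-and-back walks are split at the turn (the minimum of
the ~1 s-smoothed |AP velocity| envelope near mid-recording, or a supplied
time) with a ±1 s guard window.  Energy windows are snapped to an integer
number of strides (`n_periods = round(span/stride)`, shrunk to fit the
recording) so the cross term cancels exactly; the reported `n_steps` is the
trimmed-event count.  Dominant periods use a Hann-windowed, 8×-zero-padded
FFT restricted to 0.3–5 Hz with quadratic peak interpolation, and require
≥ 8 strides.

**Energies.**  Each OE is the plain sample mean of ½ v² over the
integer-stride window (for periodic signals this matches the continuous
average to O(dt²) and keeps OE ≡ ½·variance exact); Ēk is computed
independently from the full velocity vector including v̄_ap so the
decomposition identity is a genuine cross-check.  OEP is stored as a
fraction and displayed as percent.  When TOE is exactly zero the EP shares
are flagged undefined (not NaN) and OEP is 0; a zero v̄_ap with nonzero TOE
raises.  The typical-gait region uses strict inequalities (VTE% > 40,
MLE% < 35, APE% < 50); boundary values are atypical.  When an out-and-back
walk yields two segments the combined metrics pool duration-weighted axis
energies (equivalent to time-averaging over the union of the windows) and
recompute the ratios from the pooled energies.

**Peak-to-peak displacement.**  Measured per detected stride, then averaged
— but only over strides at least one filter settling time (1/cut-on
≈ 3.3 s) away from the walking-bout boundaries, falling back to all strides
when none qualify.  Rationale: double integration amplifies the high-pass
filter's transient response to the oscillation onset/offset by 1/ω², which
inflates displacement extrema near bout edges while leaving the energies
(dominated by the signal band) untouched.

## The simulator

`simulate_gait` produces the *minimal stated world*: pure sinusoids per
axis (ML at the stride period, VT and AP at the step period; AP additionally
translates at v̄), analytically differentiated twice, rotated into a tilted
sensor frame, with gravity, white Gaussian noise (default σ = 0.05 m/s²)
and a deterministic linear bias ramp (0.001 m/s² per s) added, all seeded.
A 3 s standing lead-in precedes the walk (the neutral-pose protocol) and a
3 s standing tail follows it; without the tail the walk would end on the
array edge, where the zero-phase filter's boundary transient — again
amplified by double integration — corrupts the final strides.  The forward
speed starts and stops abruptly; the corresponding acceleration impulse is
deliberately omitted (it lies entirely below the analysis band) so
`walk_distance = v̄·duration` stays exact.  Default phases are zero, which
yields the canonical bow-tie (figure-eight) frontal-plane trajectory.

Presets share v̄ = 1.3 m/s, 1.1 s stride, 30 s at 100 Hz and differ only in
amplitudes: normal (2/2/3 cm AP/ML/VT, closed-form EP ≈ 29/7/64 % and OEP
≈ 1.35%), wide_stance (ML doubled), bouncy (VT doubled), shuffle (VT halved,
1.0 s stride).  The irregular presets violate the typical region in the
qualitative directions their names imply; the centimetre values are fixture
parameters chosen to be physiologically plausible, not claims about any
cohort.

What a green test establishes — and what it does not: the simulator
exercises tilt, gravity, noise, drift, filtering, double-integration drift
and the 2:1 period structure, all with exact closed-form truth; it does not
emulate stride-to-stride variability, left/right asymmetry, double-support
dynamics, non-sinusoidal waveforms, turning kinematics or
magnetometer/fusion artefacts.  Recovery within a few percent on the
simulator therefore validates the signal-processing chain, not the
biomechanical fidelity of any particular subject's gait.

## Known limitations

* Heading from oscillations has a 180° ambiguity and assumes the dominant
  step-frequency horizontal motion is fore-aft; grossly lateral pathological
  gaits could defeat it (quaternions take precedence when available).
* The walkway speed heuristic carries ~±1–2% bias depending on where the
  first/last steps fall relative to the walkway ends.
* Gravity is removed as a constant; strong trunk pitching during walking
  leaks a small low-frequency error that the 0.3 Hz high-pass must absorb.
* `lowfreq` forward speed requires the recording to contain the
  gait-initiation acceleration, which the simulator intentionally omits.
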