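# Methods

## Signal model of the synthetic generator

The generator (`thetagamma.synth`) emulates a single-channel dentate-gyrus
LFP as the sum of four components, in microvolts:

* **Theta oscillator.** A cosine at `theta_freq_hz` (default 8 Hz, amplitude
  150 µV) whose phase φ(t) carries a random-walk component with diffusion
  coefficient `theta_phase_drift` (default 8 rad²/s, i.e. about 1 rad of phase
  diffusion per theta cycle). Real hippocampal theta wanders in frequency from
  cycle to cycle; a strictly periodic modulator would also invalidate
  time-shift surrogates, because shifting a perfect clock by whole cycles
  reproduces the original phase–envelope alignment. Setting the drift to zero
  recovers exact sinusoids for closed-form tests.
* **Coupled gamma.** A cosine carrier at `gamma_freq_hz` (default 78 Hz,
  amplitude 30 µV) with instantaneous amplitude
  `gamma_amp · (1 + d·cos(φ(t) − lag))`. The envelope modulation depth
  `(max − min)/(max + min)` equals the parameter `d = coupling_depth`
  exactly; `lag` moves the envelope peak off the theta peak, and at lag π the
  signed ESC flips sign.
* **Background.** Gaussian noise spectrally shaped to 1/f^α (α default 1),
  scaled to an RMS of `noise_amp_uv` (default 50 µV) — a plausible LFP
  background, not a biophysical model.
* **Mains.** A 50 Hz sinusoid (default 20 µV).

Stimulation artifacts are biphasic rectangles superposed at event times
(15 pulses at 200 Hz per HFS train; single pulses for test pulses), default
amplitude 10× the signal RMS so threshold detection is unambiguous.

**Evoked sweeps** are piecewise-linear canonical waveforms (mV, 10 kHz): a
linear rise of the model slope over 3 ms to a first positive peak, a
population-spike trough at 5.5 ms, a second positive peak at 7 ms, and a
linear decay — placed so the tangent-method amplitude and the maximum 1 ms
sliding slope equal the model parameters exactly in the noise-free case. Both
measures scale with the potentiation factor
f(t) = 1 + (P − 1)·exp(−t/τ) (τ = ∞ encodes persistent LTP); multiplicative
Gaussian noise of fraction `sweep_noise_frac` is applied per sample. The
trough must undercut the flanking peaks, which requires
`baseline_ps_mv > baseline_slope_mv_ms / 2` (defaults 5.0 and 5.0).

**Scenario presets** encode effect *directions*, not published magnitudes
(the source experiments report significance only): `control` has a transient
theta dip during HFS (amplitude × 0.85) with post-HFS rebound, constant
coupling depth 0.6 and persistent LTP; `mk801_w1`/`mk801_w4` suppress theta
more deeply (× 0.6 during HFS, × 0.7 sustained into one or three post
windows), spare gamma, halve the coupling depth in HFS sub-windows 6–10, and
decay LTP with τ = 240 min. These magnitudes are free parameters of the
generator, chosen once as plausible values; nothing downstream is tuned to
them.

## Epoching

The five 100 s windows are anchored at the first HFS-train onset; `pre` is the
100 s immediately before it. Artifact masks combine declared event intervals
± 50 ms with a 6×(1.4826·MAD) amplitude threshold, both configurable. Within
each 10 s sub-window the **earliest** fully clean 4.1 s run is taken — a
deterministic tie-break verified against an exhaustive search. Downsampling
uses polyphase FIR anti-aliasing and refuses targets without a Nyquist margin
over the requested analysis band.

## Spectra

Welch estimates with a Hann taper, NFFT = 2048, 50% overlap (segment averaging
reduces variance on 4.1 s epochs; total power matches signal variance within
Parseval/windowing tolerance of 10%). Band edges are half-open [low, high) so
δ/θ and θ/α boundaries are unambiguous. The mains notch is a second-order
Butterworth band-stop designed at 48.5–55 Hz and applied forward–backward
(zero phase — the coupling analysis downstream is phase-sensitive); the
two-pass magnitude response is steeper than one pass, which only deepens the
stop band. Relative powers divide by the pre-HFS window mean per band, per
subject, before any cross-subject averaging. The theta profile evaluates
integer frequencies 5–10 Hz as means of bins within ±0.5 Hz, each normalized
to the same frequency's baseline value. Per window, band powers are averaged
across the (up to ten) epochs after per-epoch spectral estimation.

## Phase-amplitude coupling

ESC is the Pearson correlation between the slow-bin filtered signal (real
part of the complex Morlet convolution, width 7 cycles, unit passband gain)
and the fast-bin amplitude envelope (magnitude of the convolution). Wavelet
edge cones of one temporal SD of the slower wavelet are trimmed before
correlation. Bin grids: 3–98 Hz in 5 Hz steps (±2 Hz nominal half-width) for
the full comodulogram, 33–98 Hz for the gamma grid; only pairs with slow
center < fast center are computed, the rest are null markers; cells whose
fast bin overlaps the notch band are flagged as notch-contaminated in the
output. Constant inputs yield a defined score of 0 with an explicit warning.

**Surrogates.** Each of the 200 surrogates cuts the envelope at a random
point and swaps the two segments — a circular shift, so all shift
correlations come from one FFT circular cross-correlation. Cuts are kept at
least 10% of the series length from either end: near-zero shifts barely move
the envelope and would let surrogates reproduce the original alignment
(standard practice for time-shift nulls). The reported normalized score is
z = (raw − mean)/SD of the surrogate distribution; raw correlations are
retained alongside.

**Pooling.** Per window, comodulograms are pooled across the (up to ten)
epochs: raw scores by averaging, z by Stouffer combination (Σz/√K). For
multiplicity-corrected cell tests the pooled map carries an across-epoch t
statistic (mean z over its standard error, dof K−1); on short narrowband
series the shift-surrogate null is mildly overdispersed (its SD
underestimates the across-realization SD by ~5–10%), and the across-epoch t
self-calibrates, holding the family-wise error at its nominal level. The
pooled theta–gamma score averages normalized ESC over all (θ-bin, γ-bin)
pairs with θ centers inside 4–10 Hz; the HFS coupling timecourse reports it
per HFS sub-window, plus values relative to the mean baseline score.

The z-score saturates once coupling is reliably detectable (it measures
evidence against the null, not coupling strength), so the second-half
coupling-drop comparison (sub-windows 6–10 vs 1–5, one-sided Mann–Whitney at
α = 0.05) is run on the raw pooled correlations; both raw and z are written
to the output tables.

## Evoked measures

The fEPSP slope is the maximum slope of a sliding 1 ms least-squares fit on
the rising phase between the stimulus and the first major positive peak. The
fits run over raw samples (the peak is located on a lightly smoothed copy);
the reported value is the median of the upper half of the sliding slopes,
which equals the strict maximum for a linear rise while avoiding the upward
selection bias a strict max incurs on noisy sweeps (≈ +2% residual bias at 5%
sweep noise, vs +11% for the strict max).

The population-spike amplitude is the tangent method: the first positive
peak, spike trough and second positive peak are located on a 1.5 ms
Savitzky–Golay smoothed copy, each extremum is refined as the intersection of
least-squares lines fit to its two flanks (exact for piecewise-linear
extrema, noise-averaging otherwise), and the amplitude is the drop from the
line joining the peaks to the trough.

Stimulation intensity selection follows the input–output rule: the tested
intensity whose response is closest to 40% of the maximum (ties to the lower
intensity; no interpolation, since selection is from discrete tested
intensities). Time courses average five sweeps per point and normalize to the
mean of the six baseline points; the decay fit uses bounded least squares on
the post-HFS points with τ capped at 10⁵ min (a fit at the cap indicates
persistence within the measured horizon).

## Statistics

The Anderson–Darling test (5% critical value) is applied to every group; any
rejection — or a zero-variance group, where the test is undefined (flagged) —
routes the comparison to the nonparametric branch. Two groups: Student/paired
t vs rank-sum/signed-rank. Three or more: one-way or repeated-measures ANOVA
vs Kruskal–Wallis. Post-hoc comparisons are reported only when the omnibus is
significant with >2 levels: Tukey HSD on the parametric branch and — since
Tukey-type pairs after Kruskal–Wallis are nonstandard — Tukey HSD on pooled
rank-transformed data on the nonparametric branch. Per-frequency grids are
tested per cell at α = 0.05 without multiplicity correction by default
(`grid_compare`), with an optional Benjamini–Hochberg correction across the
grid. The
end-to-end type-I error of the gated procedure is 0.044–0.047 under normal
and t₃ nulls (1000 replicates each).

## Scenario detection

Two markers, mirroring the within-subject design (each animal is its own
pre-treatment control):

* **Theta suppression** — one-sided Mann–Whitney comparing the ten per-epoch
  during-HFS relative theta powers of a run against those of its paired
  control run.
* **Coupling drop** — one-sided Mann–Whitney of raw pooled theta–gamma
  scores, HFS sub-windows 6–10 vs 1–5, within the run.

A scenario is "detected" when both fire at α = 0.05. Control false positives
are estimated by pairing independent control runs.

## Problem sizes and determinism

Validation studies (`thetagamma.validation`, also run by
`scripts/acceptance.py`) use: 20 seeded runs for comodulogram peak recovery
(each pooling ten 4.1 s epochs of a 41 s recording) and for the
depth-monotonicity, scenario-discrimination and LTP-recovery studies; 100
runs for surrogate-z calibration; 20 pooled comodulograms for the family-wise
null; 50 random 16.4 s fixtures for the ESC-vs-oracle comparison (carrier ≥ 7× the
modulating frequency, so the width-7 filters pass the modulation sidebands);
100 random artifact layouts for the epoching oracle; 1000 replicates per null
for the statistics calibration. All randomness flows through explicit integer
seeds; identical seeds give bit-identical outputs, including the pipeline's
output tables.

## What passing tests do and do not show

The generator produces stationary oscillators with cosine-kernel amplitude
modulation, Gaussian 1/f background and stereotyped artifacts. Real LFP has
nonstationary power, asymmetric (non-sinusoidal) theta, state-dependent
coupling, movement artifacts, and volume-conducted components — none of which
are modeled. Passing the suite shows the estimators recover the constructs
they target under realistic noise levels and that the statistical procedures
are calibrated; it does not validate the biological interpretation of those
constructs on real recordings. The evoked waveform is a stylized canonical
shape: measurement conventions (max-slope window, tangent amplitude) are
exact on it by construction, so the recovery tests validate noise behavior,
not robustness to real waveform diversity.
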