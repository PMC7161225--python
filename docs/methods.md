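# Methods

## Problem and pipeline

High-density surface EMG (HDsEMG) records muscle activity from a 2-D grid
of closely spaced electrodes — here 13 rows × 5 columns with 64 physical
electrodes, sampled at 1024 Hz, columns aligned with the muscle-fiber
direction. The spatial distribution of EMG amplitude over the grid carries
information about which motor-unit (MU) territories are active: clustering
of fibers innervated by the same motor neurons concentrates signal power
under few electrodes, while spatially dispersed recruitment spreads it.

The pipeline is:

1. **Band-pass** each monopolar channel, 10–500 Hz, zero-phase Butterworth
   of order 4. These corner frequencies mirror the analog acquisition band
   of typical HDsEMG amplifiers, so synthetic inputs traverse an
   equivalent transfer function; the filter is configurable and can be
   disabled. Zero-phase (forward-backward) filtering preserves epoch
   alignment at the cost of doubling the effective order.
2. **Single differential**: for every vertically adjacent populated pair
   (i, j), (i+1, j) within a column, form sEMG_{i,j} − sEMG_{i+1,j}
   (upper minus lower; the sign convention is irrelevant to all RMS-based
   features). The default grid leaves one corner site unpopulated, so 59
   of the 60 possible pairs survive — the canonical channel count. Which
   site is absent on the physical array is a property of the hardware, not
   of the method; it is configurable, and any single end-of-column gap
   yields 59 channels.
3. **Epoch** extraction: a 1-s window centered at the midpoint of the
   contraction (isometric trials), or four windows centered at 25/50/75/
   100% of the contraction cycle (isokinetic trials), the last
   right-aligned so it stays inside the cycle. Contraction bounds come
   from a torque threshold at 5% of the trial peak with 1% hysteresis, or
   are supplied explicitly. Sample counts round half away from zero and
   windows are half-open.
4. **Activation map**: per-channel RMS over the epoch, arranged at the
   grid position of each pair's upper electrode.

## Spatial features

For a map HM with N channels:

* **Intensity** `I = log10( (1/N) Σ HM_i )` — the common logarithm
  linearizes the strongly nonlinear EMG-amplitude-versus-force relation.
* **Differential intensity** `DI_c = log10(RMS(sEMG_{i,j} − sEMG_{i+1,j}))`
  per within-column pair, summarized by its mean over channels. When the
  input is monopolar (the default path) these differences are exactly the
  single-differential channels; for data that arrive already bipolar a
  `double_difference` flag re-differences consecutive bipolar channels
  instead. Channels with zero RMS are excluded from DI (their log is
  undefined) and the exclusion count is reported.
* **Modified entropy** `E = −Σ q_i log2 q_i` with
  `q_i = RMS_i² / Σ_j RMS_j²` the normalized channel **power**, using
  0·log 0 = 0. E is maximal at log2 N (5.883 bits for N = 59) when all
  channels are equal and 0 when one channel carries all power. The
  normalized-power convention is fixed by these extrema. Zero-RMS
  channels contribute 0.
* **Coefficient of variation** `CV = 100 · SD / mean` of the N RMS
  values, in percent. The sample (n−1) SD is used; at n = 59 the choice
  changes CV by under 1%.

E and CV are scale-invariant; I and DI shift by exactly log10 k under a
gain k. The tests assert these identities to 1e-10 and check all four
features against direct formula transliterations on random maps.

## Torque protocol

Peak torque is the maximum of the recorded trace (no windowing to the
constant-velocity phase, no gravity correction). The highest MVC peak
defines submaximal targets at exactly 25/50/75%. Among repeated trials of
one condition the highest-peak trial is selected; ties go deterministically
to the earliest trial and are flagged. Isokinetic trials carry the
protocol's 1.05 rad/s angular velocity.

## Synthetic grid EMG

Real recordings of this kind are not redistributable, so the generator
produces grid EMG whose ground truth is known:

* **MUAP kernel**: a Ricker (Mexican-hat) wavelet, width 2 ms, spectral
  peak ≈ 110 Hz — the simplest band-limited biphasic waveform landing in
  the surface-EMG band. No volume-conductor detail (innervation zones,
  tendon effects, subcutaneous-layer filtering) is modeled.
* **Firing**: each MU fires a renewal train, rates drawn from
  20 ± 4 Hz (clipped to 8–40 Hz), ISI coefficient of variation 0.15.
* **Projection**: an MU's contribution to electrode e decays as
  `exp(−d²/2)` with the anisotropic normalized distance d from its
  territory center (σ = 3 electrode pitches along fibers, 1.2 across),
  times the MU's gain.
* **Size principle**: MU gains span a 10× geometric range
  (median 0.1 mV); recruitment at 25/50/75/100 %MVC activates the
  smallest 40/60/80/100% of the pool, so active sets are nested.
* **Clustering κ ∈ [0, 1]**: each territory center is drawn, with
  probability κ, tightly around one of two random foci
  (σ ≈ 1.0 × 0.6 pitches), otherwise uniformly over the grid. κ is the
  single heterogeneity knob: κ = 0 spreads power (high E, low CV), κ = 1
  concentrates it. The generator draws a fixed number of variates per MU
  regardless of branch, so runs differing only in κ share their firing
  and noise realizations exactly (paired designs).
* **Noise**: additive white noise, 0.005 mV RMS per channel.
* **Torque**: the amplitude-weighted firing drive (mV·spikes/s), low-pass
  filtered at 2 Hz, times a gain of 1 Nm per unit plus 0.3 Nm measurement
  noise. With the defaults this yields ≈ 35/65/120/200 Nm peaks at the
  four levels — physiological knee-extension magnitudes — and is
  sufficient for the peak/target/trial-selection logic it feeds. An
  optional envelope (raised sine peaking mid-cycle) emulates the
  isokinetic torque profile.
* **Reproducibility**: one root seed; placement, firing and noise use
  independent substreams; cohort subjects get deterministic derived seeds.

Trials are 3 s long (analyzed over the 1-s midpoint epoch) and cohorts
mirror a 2 age × 2 sex design with 10 subjects per group at the four
isometric levels plus one isokinetic cycle.

What passing tests on this generator do **not** show: robustness to real
tissue filtering, electrode-skin artifacts, innervation-zone geometry, or
fatigue-related nonstationarity. They do show that the analysis chain
recovers injected spatial-heterogeneity and strength differences under
controlled, physiologically scaled conditions.

## Statistics

Features are gated per (age × sex × level) cell by Shapiro–Wilk at
α = 0.05; a feature is analyzed parametrically only if every cell passes,
and cells with fewer than 3 observations force the nonparametric route.

The parametric path is a split-plot ANOVA — two between-subject factors
(age, sex), one within-subject factor (contraction level), subjects nested
in age × sex. Between effects are tested against the subjects-within-
groups stratum and within effects against the subject-by-level stratum;
the implementation requires a balanced design and names any missing cells.
It reproduces R's `aov` with `Error(subject/level)` to all printed digits
on a frozen fixture. Greenhouse–Geisser correction (ε from the
double-centered pooled within-cell covariance) is reported alongside the
uncorrected p whenever the within factor has more than two levels. A
significant age × sex interaction triggers focused per-level comparisons
fixing one between factor at a time (pooled-variance t tests); all focused
comparisons form a single Bonferroni family whose size m is emitted with
every adjusted p — the family definition is explicit because such
protocols rarely state theirs.

Mann–Whitney U is exact (full enumeration) when both groups have ≤ 8
observations and no ties, and uses the tie-corrected normal approximation
otherwise; two fully tied samples return p = 1 (the statistic carries no
ordering information, and the tie-corrected variance is 0). Pearson
correlation uses the t transform and requires n ≥ 3 with nonzero variance.

Calibration is part of the test suite: null rejection rates for all tests
sit in [0.03, 0.07] at α = 0.05 over 500 replicates, and the simulated
power of an injected between-subject shift matches the noncentral-F
calculation within 10 percentage points.

## Numerical and degenerate-input choices

* All-zero maps: I, E and CV raise errors rather than returning −∞/NaN.
* Epoch windows that would leave the recording raise; isokinetic windows
  clamp to the cycle bounds, and a cycle exactly one epoch long emits a
  warning (all four epochs coincide).
* Filter high cut at or above Nyquist raises.
* Entropy uses base 2 (bits); intensity and DI use base 10, matching the
  common-logarithm definitions above.
* Tie-breaks (best trial) and rounding (half away from zero) are fixed
  and documented so results are bit-reproducible.

## Known limitations

* The simulator is phenomenological: no volume conductor, no MU
  synchronization, no fatigue; entropy/CV magnitudes are comparable to
  published human values but are not subject-level predictions.
* The split-plot ANOVA requires balance; unbalanced cohorts must be
  trimmed or analyzed with mixed models outside this package.
* The isokinetic "cycle" is defined on time between movement onset and
  end of range; no joint-angle normalization is applied.
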