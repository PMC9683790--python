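# Methods

`vipmode` re-implements, as a tested library, the analysis chain used to
characterize how cortical VIP (vasoactive intestinal polypeptide-expressing)
interneurons respond to reward and punishment during an auditory go/no-go
task. The package operates on trial-structured fluorescence recordings
(GCaMP6f ΔF/F), pupil and running-speed traces, and per-soma image tiles.
Because the real recordings are external data, every stage is exercised
against a synthetic session generator that plants known ground truth; this
note documents the models, the defaults, and what the tests do and do not
establish.

## Synthetic sessions

A session is a sequence of `n_trials` go/no-go trials. Trial outcomes are
drawn independently: go with probability `p_go` (default 0.5), a lick on go
trials with `p_lick_go` (0.8, matching a trained-animal hit rate) and on
no-go trials with `p_lick_nogo` (0.3, an early-training false-alarm rate).
Licked trials receive a reaction time drawn log-normally (mean 0.5 s, SD
0.2 s, truncated to [0.1, 1.5] s — positive and bounded by the time-warp
window) and reinforcement is delivered 0.5 s after the first lick. Inter-tone
intervals are 7 ± 1 s.

Each responsive neuron (92% of cells by default, matching the fraction of
task-responsive cells in sessions of this kind) carries one of five temporal
archetypes — *fast*, *delayed*, *sustained*, *biphasic*, *slow* — realized as
causal difference-of-exponentials kernels, peak-normalized to 1:

| archetype | rise τ (s) | decay τ (s) | latency (s) |
|-----------|-----------|-------------|-------------|
| fast      | 0.1       | 0.5         | 0           |
| delayed   | 0.1       | 0.5         | 0.5         |
| sustained | 0.1       | 3.0         | 0           |
| slow      | 1.0       | 5.0         | 0           |
| biphasic  | fast lobe + second lobe peaking near 2 s | | |

The mixture weights default to the relative sizes of the five functional
clusters reported for this cell type (109:88:177:120:112). The time
constants themselves are modeling choices: the source analyses publish only
mean cluster profiles, so recovery tests are calibrated against these
kernels, not against the published clusters.

A neuron's raw trace is `F0 · (1 + ΔF/F + noise)` with `F0 ~ N(100, 10)` a.u.,
response gain 0.3 ΔF/F (lognormal cell-to-cell spread), and white Gaussian
noise of 0.05 ΔF/F per sample. Response amplitude on each trial is
multiplied by `1 + arousal_gain · ΔP/P` of that trial (`arousal_gain` = 3,
chosen so that a median split by pupil dilation yields a high/low response
ratio near 1.4, the magnitude seen in somatosensory/motor recordings of
this kind).

Behavior: pupil diameter is an Ornstein–Uhlenbeck baseline (reversion rate
0.5 s⁻¹) plus an event-evoked dilation kernel peaking ~1 s after
reinforcement, with lognormal per-trial amplitude around `dilation_gain`
(0.12 ΔP/P); locomotion is sparse ~3 cm/s bouts on 30% of trials; licks are
a 7 Hz bout for 1.5 s. Blink gaps can be inserted as NaN runs. Soma
diameters are a two-component Gaussian mixture (means 8 and 11 µm, SD
0.8 µm) emulating the reported bimodal size distribution. Tile stacks are a
smoothed random scene plus a soma-like blob, translated per frame (linear
interpolation for sub-pixel shifts).

What the generator does **not** emulate: spike-to-calcium biophysics beyond
the double-exponential kernel, photon shot noise, neuropil contamination,
slow drift/bleaching, eye movements, or any 3-D scanning physics. Passing
recovery tests therefore demonstrate correctness of the analysis code under
the stated statistical model, not robustness to every artifact of real
recordings.

## Trace preprocessing

ΔF/F = (F − F0)/F0 with either a global per-neuron percentile baseline
(default 20th percentile, for continuous traces) or a per-trial baseline
(mean over [−2, 0] s before each tone, the convention used for the
trial-wise statistics). Event alignment interpolates linearly onto a grid
of integer sample multiples around the event; three modes are provided:
tone onset, actual reinforcement (Hit/FA only), and *expected*
reinforcement, which places Miss/CR events at tone onset + session-mean
reaction time (over Hit∪FA) + the 0.5 s delay. Trials whose window leaves
the recording are dropped with a warning rather than padded. Response
kinetics are summarized by the post-event argmax time and a least-squares
`a·exp(−t/τ)` fit to the post-peak segment; a non-decaying segment reports
τ = ∞.

## Responsiveness

Per neuron and trial type, per-trial response means (0–2 s after the event,
baseline-subtracted) feed two one-tailed one-sample t-tests at p < 0.05
(activated / suppressed). A Lilliefors normality p-value is recorded as
metadata but does not gate the t-test, mirroring the source procedure
(which verified that normality held for the large majority of cells and
applied the t-test throughout). No multiple-testing correction is applied
by default; a Benjamini–Hochberg switch exists. The combined type-I budget
of the two tails is ~0.10 and is verified on 2,000 null neurons.

Trial-level activity uses the strict criterion: mean of 250 ms around the
post-event peak minus the baseline mean > 2 × the *trial's own* baseline
sample SD — the only SD computable for a single trial. Synchronicity
(active cells per trial), reliability (active trials per cell), and
stability (active fraction vs. trial index, with a least-squares trend)
derive from that binary matrix and satisfy the double-counting identity
exactly. The coefficient-of-variation partition uses sample SD (n−1), with
the cell-to-cell CV averaged across sessions and the inter-individual CV
taken over session means.

## Temporal-archetype clustering

Mean Hit responses are z-scored against the first second of the aligned
segment, peak-normalized over 0–4 s post-reward, and reduced by PCA to the
smallest number of components reaching 90% cumulative variance; k-means
(k = 5, k-means++, best of 5 replicates) clusters the scores. Cells with
zero baseline SD, a non-positive post-reward peak, or a profile norm above
5× the median norm are excluded — the norm rule is a reproducible surrogate
for the source's exclusion of cells that disproportionately increased
reconstruction error. Because k-means mechanically splits even an
unstructured point cloud into k parts, clusters whose mean temporal
profiles correlate above 0.95 are merged afterwards (genuine archetype
pairs correlate ≤ 0.76 under the default kernels); this collapses the
partition when the population truly contains one response type. Cluster
mean profiles, unit-normalized, serve as feature vectors for projections;
area contrasts use two-sided Mann–Whitney tests, and the depth-homogeneity
test across clusters is a one-way ANOVA (the specific test behind the
published depth statistic is unnamed; ANOVA is an assumption here).
Cue-response heterogeneity is modeled by OLS on hit rate, or on
dummy-coded region identity, reporting R² and the overall F-test.

## Trial tensors and non-negative CP

Per trial, the segment from tone onset to the (expected) reinforcement plus
a 1 s post-event window is linearly warped to 30 samples, so that trials
with different reaction times share one axis. Miss/CR trials, which have no
reaction time, use tone + mean RT + delay as their endpoint, mirroring the
expected-reinforcement alignment; the 1 s extension guarantees the tensor
contains the reinforcement transient (an axis ending exactly at
reinforcement would exclude the response the decomposition is meant to
find). Per cell, the minimum is subtracted (non-negativity) and the result
divided by the mean over Hit trials of the per-trial maxima; the first 10
trials of each type are kept and cells concatenated across sessions.

Non-negative CP decomposition is computed by HALS (hierarchical alternating
least squares) with a 500-iteration cap and 1e-8 relative-error tolerance,
keeping the best of 10 random initializations by relative Frobenius error
‖X − X̂‖/‖X‖. The solver is written in-house (no installed package provides
non-negative CP) and is validated on planted-factor tensors. Trial factors
are compared between reinforced ({Hit, FA}) and unreinforced ({Miss, CR})
trials by two-sided Mann–Whitney per component; the minimal-p component is
reported as the reinforcement component.

## Arousal and locomotion

Pupil traces are blink-interpolated (linear across NaN gaps; gaps > 0.5 s
flag the overlapping trial for exclusion; boundary gaps extend the nearest
value), Gaussian filtered (σ = 100 ms — no published value exists, this is
a typical pupillometry choice), and normalized to ΔP/P against the 2 s
pre-tone baseline per trial. Trials are median-split per outcome type by
the trapezoidal ΔP/P area over 0–3 s after the event (or by Δspeed, the
mean absolute Gauss-filtered speed 0–2 s after the event minus the pre-tone
baseline); ties at the median go to "low", a deterministic and conservative
choice for the high-arousal effect. Group responses are compared by a
paired t-test across neurons, with initial (0–1 s) and late (2–3 s) phases
reported separately. Per-cell behavior correlations are whole-session
Pearson coefficients after interpolating behavior onto the imaging clock.

The "no-arousal-change" subset keeps Hit/FA trials whose post-reinforcement
(0–1 s; the published interval "[1;0] s" is internally inconsistent and is
read as [0, 1] s) pupil and speed changes stay within 2 SD of baseline
fluctuation. The fluctuation SD is estimated robustly across trials
(1.4826 × MAD of the change statistic): a within-trial 2 s sample SD
underestimates slow pupil drift and would reject most genuinely quiet
trials, while the robust across-trials estimate keeps ~95% of trials when
no dilation is planted and empties the subset when every trial dilates
strongly.

## Behavioral-kernel GLM

The design matrix holds five standardized predictors at the imaging rate: a
0.5 s cue boxcar; a water-availability kernel that rises as a Gaussian from
delivery to the peak of the session-average lick rate and then decays
linearly to baseline at the time the lick plateau has dropped 5% from its
peak (fallback: a fixed 2 s kernel when no licks exist); an air-puff kernel
peaking 0.2 s after valve opening (σ = 60 ms, putting the kernel below 1%
of peak at onset); the Gauss-filtered pupil diameter; and the absolute
running speed. Behavioral traces are block-mean downsampled; constant
columns are excluded; an optional uniform-random column serves as a
negative control. The response is the population-mean ΔF/F. The lasso
penalty is tuned on a 25-point log grid spanning 1e-4–1e1 × λ_max with
5-fold *contiguous-block* cross-validation (shuffled folds would leak
autocorrelated samples between train and test); variance explained is the
mean held-out R². 

## Visual tuning

Mean baseline-subtracted amplitudes over the 6 s moving-grating period (the
response window is not specified in the source; the moving period is used)
are computed per direction (8 directions, 45° apart, ≥ 3 repeats each), with
negative means clipped to zero for index computation. R_pref is the maximal
amplitude, R_opp the amplitude 180° away, and R_ortho the mean of the two
orthogonal directions (a symmetric reading of the singular "orthogonal
orientation"). OSI = (R_pref − R_ortho)/(R_pref + R_ortho) and
DSI = (R_pref − R_opp)/(R_pref + R_opp); both are scale-invariant, and for
a cosine-tuned cell with modulation depth m, DSI = m/(2 − m) exactly.

## Motion correction

Each soma tile is registered to a template by zero-mean normalized
cross-correlation computed via FFT; the correlation peak gives the integer
shift and a parabola through the peak and its axis neighbors the sub-pixel
refinement; the matching error is 1 − the normalized peak. A Hann window is
available as an option but is off by default: on 64 × 64 tiles windowing
biases the peak toward zero shift (a planted 5 px shift reads as 4 px),
breaking exact integer recovery. The translation-only model follows the
tile-scanning geometry, where within-frame rotation is negligible.
Templates are the mean of the best-correlating 20% of frames per tile
(manual templates supported); the per-frame consensus displacement is the
component-wise median over the lowest-error 20% of tiles (minimum 3),
making it robust to ~40% corrupted tiles. Optional preprocessing: 3 × 3
median filter or CLAHE on an 8 × 8 tile grid (clip limit 0.02 after
rescaling to [0, 1]).

## Soma morphometry

FWHM of an intensity line profile uses a baseline equal to the mean of the
outer 10% of samples, with half-maximum crossings located by linear
interpolation. Diameter bimodality is assessed by fitting one- and
two-component Gaussian curves to the 0.5 µm-binned histogram with
Poisson-weighted least squares (weight 1/max(count, 1)) and comparing them
with the weighted extra-sum-of-squares F-test; unweighted fitting makes
that test anticonservative on unimodal samples (~30% false positives at
α = 0.05 vs ~7% weighted). A two-component fit whose components are too
close to form two modes (Ashman's D ≤ 2) or whose smaller weight is below
1% is reported as unimodal. The R² quoted for the two-component fit is
descriptive (unweighted).

## Scan-performance arithmetic

Closed forms: point-scan volume rate 1/(nx·ny·nz·dwell); resonant-scanner
volume rate 1/(n_lines·n_planes/line_rate + n_planes·settle); ROI-scanning
combined gain (SNR gain)²·(speed gain) = V_total/ΣV_i (areas in 2-D). With
the reference geometry (548 × 507 × 193 px, 30 µs dwell, 16 kHz resonant
line rate, 27.8 Hz tile scanning) these give 0.00062 Hz, 0.16 Hz, ~1 Hz
(19 layers with 20 ms settling), and a ~170-fold speed advantage; 120 ROIs
of 1/600,000 of the volume give a 5,000-fold combined gain, and 1% 2-D
coverage a 100-fold gain. The resonant line count uses the slow-axis pixel
count (507), which reconciles the printed volume rate.

## Problem sizes in the test suite

The suite runs on deliberately compact problems chosen to keep each
statistical check well-powered: 2,000 null neurons for classifier
calibration, 10 × 200-neuron sessions for clustering recovery, 20-seed
ensembles for the tensor and GLM recoveries, 64 × 64 px tiles for
registration, n = 439 diameters for the mixture fit. `scripts/acceptance.py`
recomputes the same quantities from scratch at these sizes.

## Known limitations

- The archetype kernels and all generator noise parameters are modeling
  choices; none are fitted to real recordings.
- The Miss/CR warp endpoint and the depth-homogeneity ANOVA are assumptions
  where the source is silent or ambiguous (flagged above).
- The lasso models the population-mean signal only; per-neuron encoding
  models are out of scope.
- Registration assumes pure translation; non-rigid or line-wise motion is
  not corrected.
- The percentile ΔF/F baseline for continuous traces is provided but has no
  published counterpart to validate against.
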