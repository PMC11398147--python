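# Methods

This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not establish.

## Signal model and extraction front-end

A chest-worn triaxial accelerometer (nominally 250 Hz; 100 Hz is the default
for desk-scale work and both are supported) observes three superimposed
phenomena: gravity through the slowly varying sensor orientation, modulated
by respiration (small-angle tilts); seismocardiographic transients at each
heartbeat ("small peaks"); and broadband, high-amplitude bursts during gross
body movement.

**Heartbeat localization.** The three channels are summed into one signal —
the cardiac transient projects onto all axes and the sum preserves it while
costing nothing. The 5–20 Hz band-passed Hilbert envelope is normalized by a
per-10-s robust scale (95th percentile, capped at 3× the median scale so a
movement burst cannot flatten its whole block) and peak-picked. Beats are
the admissible peak sequence maximizing

    Σ (normalized amplitude − beat_cost) − w · Σ (IBI_{i+1} − IBI_i)²

found by dynamic programming over (previous peak, current peak) edges with
IBI bounds 0.33–2.0 s (30–180 bpm). The quadratic successive-difference
penalty (weight `smoothness_weight`, default 10 s⁻²; `beat_cost` 0.25)
encodes that beat times must sit on acceleration maxima *and* follow the
local periodicity; it rejects spurious insertions (halving an interval costs
two large IBI jumps) and skipped beats (a doubled interval likewise). Chains
may resume after gaps longer than the maximal IBI through penalty-free
"break" edges, so one movement artifact does not truncate the night.
Per-beat quality is the autocorrelation peak ratio of the envelope in a
±5 s window over the admissible IBI lag range, clipped to [0, 1]: ~0.6–0.7
on clean simulated signal, <0.2 on white noise, degrading near movements.
The threshold `q_min` (default 0.5) removes the governing hold interval of
low-quality beats from the IHR, producing the gaps the classifier sees.

**IHR.** 60/IBI, held constant on [t_i, t_{i+1}), sampled at 10 Hz; samples
outside beat coverage are invalid.

**Orientation and respiratory effort.** The channels are low-pass filtered
(8th-order Butterworth at 0.45 × 10 Hz, forward–backward, so a constant is
preserved to machine precision) and decimated to 10 Hz, then normalized
per sample to unit vectors. The gravity direction is their 0.05 Hz low-pass
(or an externally supplied reference); `v` is the projection onto it and
(h1, h2) the components in the orthogonal plane with a deterministic basis
(normalized projection of the device x-axis; the y-axis when gravity is
along x). Any fixed orthonormal pair would do: effort estimation is
rotation-covariant in that plane. The effort estimator projects (h1, h2)
onto the principal direction of their covariance per 60-s window (sign kept
continuous across windows), band-passes 0.1–0.7 Hz, and normalizes to unit
interquartile range per 5-min window. This is a transparent estimator with
the same 10 Hz contract as a learned one; it assumes respiration is the
dominant horizontal orientation oscillation, which holds outside movement.

**Activity counts and mixing.** Per full second, Act is the mean absolute
deviation from the window mean, summed over channels (trailing partial
second dropped). Act is scaled (`act_scale`), upsampled to 10 Hz by
sample-and-hold (the same convention as the IHR), and mixed as
ResAct = (1 + act_scale·Act)·Res — the offset by 1 leaves effort
unattenuated at rest while movement bursts dominate the product, emulating
belt-sensor artifact behavior that stagers trained on belts rely on.
`act_scale` defaults to 6.6, calibrated once on the default simulator so
that the 95th percentile of scaled Act over the movement seconds of a
calibration night equals 5 — movement then clearly dominates ResAct (a
factor ~6 against ~1.05 during quiet breathing). It is a global config
value, not adaptive.

## Clock synchronization

Two devices observing the same heart give IBI series identical up to the
affine clock relation t′ = o + r·t (crystal clocks: |r − 1| ≪ 1e-3). Both
series are rendered as tachograms (IBI held over its own beat interval) on
a shared 2 Hz grid and compared by Pearson correlation over mutually valid
samples (gaps excluded pairwise, never imputed; minimum 5 min overlap —
below that correlation cannot rank models). The search is a coarse grid
(o step 1 s over ±120 s, r step 1e-4 over [0.999, 1.001]) with two local
refinements (steps ÷10 each). Two numerical points:

* The score surface has a diagonal ridge — a rate error δr is compensated
  mid-recording by an offset shift — and at 2 Hz a δr of ~1e-4 misaligns
  the recording ends by less than one tachogram bin, so the coarse argmax
  can sit a few rate cells off. The first refinement therefore spans ±30
  rate steps, and each refinement quadruples the grid rate (2 → 8 → 32 Hz)
  so the finer steps are actually resolvable.
* A flat coarse surface (max − median < 0.05) raises a low-confidence flag:
  with constant IBIs (no HRV) the correlation is uninformative.

On 1-h simulated nights with default HRV, 20/20 random injections are
recovered within |Δo| ≤ 0.5 s and |Δr| ≤ 5e-5 (typical errors ~0.01 s and
~1e-5). Exact score symmetry under model inversion holds when the two
sample grids coincide (unit rate, grid-aligned offset); otherwise the two
directions sample the piecewise-constant tachograms at different points and
agree only to grid resolution.

## Staging surrogate

Per 30-s epoch the features are: IHR mean/std/range, successive-difference
RMS, 0.04–0.15 Hz and 0.15–0.4 Hz IHR band powers and their ratio (the
classical sympathetic/vagal proxy), the ResAct dominant respiratory
frequency and spectral peakedness in 0.1–0.7 Hz, the ResAct amplitude
coefficient of variation, the epoch activity sum, and the invalid-IHR
fraction — plus a ±2-epoch moving-average "context" copy of each and a
missing-IHR indicator. Epochs with under 50% valid IHR get missing IHR
features; at classification they are imputed from their context copies
(else training medians) and flagged as context-only.

A multinomial logistic regression on standardized features supplies
per-epoch class scores; whole-night context comes from a hidden-Markov
layer whose transition matrix is the Laplace-smoothed empirical label
transition frequency of the training nights. Labels are the most probable
path (Viterbi); reported probabilities are the forward–backward posteriors.
The two can disagree on rare epochs; both are exact dynamic programs and
are tested against exhaustive path enumeration. This stager honors the
input/output contract of a deep cardiorespiratory network while remaining
trainable at desk scale; it makes no claim of matching a trained deep
network's clinical accuracy.

## Evaluation battery

Agreement is computed four-class, three-class (N1+N2 and N3 merged into
NREM), and one-vs-rest per class; binary tasks add sensitivity,
specificity, and PPV, with undefined denominators reported as missing, not
zero. Cohen's κ uses the standard marginal chance correction; a recording
single-class on both sides is reported missing (flagged) rather than 0.
Cohort values are summarized mean ± SD when a Shapiro–Wilk test at α = 0.05
does not reject normality, else median {Q1, Q3}; both forms are always
computed and the appropriate one marked.

Sleep metrics count 30-s epochs as 0.5 min. Sleep onset is the first
non-Wake epoch (the recording start stands in for lights-off, which the
epoch files do not carry); sleep latency is onset from recording start,
stage-R latency is first REM from onset, WASO counts Wake epochs after
onset, TST counts non-Wake epochs, and sleep efficiency is TST over total
recording time. "Percentage of TST in Wake" is time-in-Wake / TST × 100 to
mirror the conventional report row, although Wake is not part of TST — the
quantity can exceed 100% on fragmented nights and is kept for table
compatibility. Bland–Altman errors are estimate − reference; limits of
agreement are mean ± 1.96 × sample SD (n − 1).

Stage intervals with gap tolerance M merge target-stage runs separated by
at most M other-stage epochs; the greedy merge provably yields the maximal
admissible intervals and is tested against an exhaustive O(n²) oracle.
Interval matching requires at least one shared epoch; one-to-one pairs go
to the greatest shared-epoch count, ties to the earliest reference
interval. Factor influence uses a two-sided Mann–Whitney U test for binary
factors (exact null distribution for group sizes ≤ 8, tie-corrected normal
approximation otherwise), Spearman rank correlation for continuous ones,
and a single joint Benjamini–Hochberg family at FDR 0.05.

## Synthetic data: what it emulates and what it does not

The generator draws a hypnogram from a first-order Markov chain (default
matrix biased toward long N1+N2 runs, N3 reachable only through N1+N2, REM
from N1+N2; any row-stochastic matrix can be configured). Given stages it
generates: beats with stage-conditional mean heart rate (defaults
W 72 / N1+N2 64 / N3 58 / REM 70 bpm) and successive-IBI-difference std
(0.050 / 0.035 / 0.020 / 0.060 s — deep sleep calmest, REM most variable),
plus a slow AR(1) heart-rate wander (std 2 bpm, τ = 60 s) that gives the
tachogram the low-frequency structure clock alignment needs; respiratory
effort by phase accumulation with stage-conditional rate
(0.27 / 0.24 / 0.22 / 0.28 Hz) and fractional rate jitter
(0.12 / 0.05 / 0.03 / 0.15 — breathing most regular in deep sleep);
movement bursts as a per-stage Poisson process (1.0 / 0.08 / 0.02 / 0.15
events/min, ~2 s, 0.3 g); and the acceleration itself as a drifting gravity
vector (default 3° postural drift over tens of minutes), a ≤5° small-angle
respiratory tilt (default 2°), one Gaussian-windowed 15 Hz biphasic pulse
per beat on the chest normal (0.01 g, 10× the 0.001 g sensor noise; the
carrier sits inside the detector's 5–20 Hz band, as physical
seismocardiographic energy does), burst noise inside movement intervals,
and white sensor noise. One root seed spawns child streams per component;
recordings are bit-reproducible. All default values are literature-
plausible choices, configurable, and estimated from no dataset.

These synthetic nights are deliberately well separated: stage physiology is
stationary within a stage, artifacts are benign, and no apnea, arrhythmia,
arousal, or sensor-detachment structure exists. Passing tests therefore
demonstrate that the machinery is correct (signals are recovered, the
stager learns and decodes, the statistics compute what they claim) — the
held-out synthetic κ (~0.9+) is a property gate for the pipeline, not a
forecast of clinical agreement, which for cardiorespiratory staging of real
sleep-disordered cohorts is known to sit far lower.

For stager training and the end-to-end gate, classifier inputs are
assembled from simulator ground truth (true beats → IHR, true effort,
movement intervals → expected activity counts, with beats inside movements
downgraded so quality masking produces realistic IHR gaps); the raw
acceleration → bundle path is exercised end-to-end on shorter recordings,
and beat detection and effort recovery have their own dedicated checks.
Problem sizes throughout (30 + 10 nights of 8 h for the staging gate,
30–60 min recordings for detection, 1 h for synchronization) are the
package's chosen desk-scale study conditions.

## Known limitations

* The beat detector assumes a broadly stable heart rate within its ±5 s
  quality window; arrhythmia (e.g. atrial fibrillation) would both break
  the smoothness prior and depress quality everywhere.
* The effort estimator fails inside sustained movement and under near-zero
  gravity norm (free fall / sensor detachment); those samples are masked,
  not reconstructed.
* Clock synchronization models only affine drift (o, r); thermal or aging
  drift beyond affine is out of scope.
* The staging surrogate's linear scorer cannot represent interactions a
  deep network would; its synthetic performance ceiling says nothing about
  clinical data.
* Sleep-onset and latency definitions reference recording start, not
  lights-off, which epoch-label files do not carry.
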