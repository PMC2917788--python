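# Methods

This note records the models, measurement definitions, numerical choices
and known limitations behind `fepsp`.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## The measurement problem

An optic-tract stimulus evokes a negative-going field EPSP in the
superficial superior colliculus.  Under intact inhibition the response is
brief (~4 ms).  Blocking all three GABA receptor classes (picrotoxin +
CGP55845) disinhibits the circuit and reveals a late excitatory phase
lasting tens of milliseconds; adding the competitive NMDA antagonist D-AP5
removes the NMDA-dependent part of it.  The analysis turns this three-step
pharmacology into two per-slice indices:

* `GABA% = 100·(AUC_block − AUC_baseline)/AUC_block` — the fraction of the
  disinhibited response area that intact inhibition suppresses;
* `NMDA% = 100·(AUC_block − AUC_block+AP5)/AUC_block` — the fraction removed
  by D-AP5,

where each AUC is taken from that condition's response peak to 100 ms
after stimulation.  Group inference is classical: per-group mean ± SEM,
paired t for within-slice drug effects, one-way ANOVA + Tukey HSD
(Tukey–Kramer for unequal n) across groups.

## Measurement definitions

All measurements operate on waveform averages (three consecutive sweeps,
i.e. 60 s of recording); an epoch's analysis window is its last 3 min
(nine sweeps → three averages whose measurements are averaged).

* **Baseline / noise**: mean and SD of the pre-stimulus window.
* **Peak**: minimum of the baseline-subtracted voltage in a 0.5–10 ms
  post-stimulus window (configurable); ties break earliest.  Amplitude is
  reported negative; latency is measured from the stimulus.
* **Duration**: onset is the first post-stimulus crossing of
  `θ = max(3·noise SD, 2% of |peak|)`; offset is the start of the first
  post-peak run that stays below θ for ≥ 1 ms; duration = offset − onset.
  This rule is this package's *declared operational definition* — the
  measurement has no unique standard.  The relative floor is 2%, not a
  more conventional 5%: a disinhibited late phase that carries roughly
  half the response area spread over ~80–100 ms has a mean depth of only a
  few percent of the peak, so a 5% floor would truncate every published
  duration/contribution combination into mutual inconsistency (staying
  above 5% of peak out to ~90 ms requires more area than the late phase
  contains).  Synthetic presets are calibrated under the same rule, so
  durations remain reproducible end to end.
* **Late-phase AUC**: trapezoidal integral of the deflection depth
  `baseline − V` from the peak sample to stimulus + 100 ms, reported in
  mV·ms.  The *signed* integral is the default: it equals the rectified
  area on a clean monotone deflection but, unlike pointwise rectification,
  adds no `≈0.4·noise_sd·window` noise-floor term to every condition.
  With rectification the D-AP5-condition AUC (whose window is mostly
  noise) is inflated, biasing NMDA% several points low at realistic noise;
  the signed form is unbiased.  `rectify=True` remains available, and
  negative (pure-noise) areas are clamped to zero with a QC flag in the
  feature table.

QC philosophy throughout: flag and report (`no-response`,
`duration-truncated`, out-of-range contributions), never silently exclude
or clamp.

## Synthetic-sweep generator

No raw recordings are available, so the generator is a phenomenological
stand-in with three design requirements: reproduce the published response
features under the package's own measurement rules, carry the published
between-slice variability, and keep the drug-condition algebra exact
(baseline = gated disinhibited response; D-AP5 = disinhibited response
with the NMDA component removed).

**Waveform.**  `V(t) = −[A_f·K_f(t)·G₀(t) + A_n·K_n(t)·G_fl(t)] + ε(t)`
for `t` past the stimulus, where `K` are peak-normalised biexponential
kernels (fast non-NMDA; slow NMDA) and `G` is a logistic gate falling from
1 to a floor, half-transition at `gate_time_ms`, 10–90% width
`gate_width_ms`, active only in the baseline condition.  The gate is
multiplicative because disinhibition *reveals* rather than adds the late
phase.  The two components are gated with different completeness: the
fast component is truncated fully (floor 0) while the slow NMDA component
escapes at `gate_floor`.  A single shared floor cannot reproduce the
observed combination of a ~4 ms baseline response with inhibition
suppressing ~85% of the disinhibited area — the fast tail leaking through
the floor would hold the response above the duration threshold — whereas a
partial escape of the slow phase is sub-threshold and adds area without
adding duration.  Physiologically this reads as inhibition clipping the
fast sink completely while attenuating, not abolishing, the late NMDA
current.

The stimulus artifact is not modelled: the measurements all start at or
after the fEPSP and an artifact would only complicate the peak search.

**Variability tiers.**  (1) i.i.d. Gaussian sample noise (`noise_sd_mV`,
default 0.01 mV — the published work does not report sweep noise; 0.01 mV
against a 0.5–0.7 mV response is a typical interface-chamber figure and
keeps single sweeps visibly noisy while three-sweep averages are clean);
(2) per-sweep lognormal amplitude jitter with CV `trial_cv` (default 0.05,
likewise an assumption, applied independently to the two components);
(3) per-slice lognormal component scalings drawn once per recording:
a common slice-quality factor scaling both components (it cancels in the
contribution ratios) plus component-specific factors that move the
NMDA/non-NMDA balance.  The split is what lets presets match *both* the
published amplitude SEMs (set by common + specific variance) and the
contribution SEMs (set by the specific variance alone); two independent
per-component CVs could not satisfy both at once.

**Preset calibration.**  For each experimental group (control and
ocular-hypertension animals at the 3/16/32-week timepoints, each
hemisphere/eye-of-input, plus a generic `control` preset and two
single-slice worked-example fixtures) the calibration solves the waveform
parameters so that the noiseless pipeline output matches six targets taken
from the published group tables: peak amplitude, latency, baseline
duration, disinhibited duration, GABA% and NMDA%.  Each parameter is found
by a 1-D root find *on the pipeline's own measurements*, iterated to joint
closure (≤ 0.5% on peak, half a sample on latency and durations,
≤ 0.35 percentage points on the contributions):

1. fast rise time ← latency (continuous argmax of the analytic waveform to
   initialise, then re-trimmed against the sampled measurement, which is
   piecewise-constant in the rise time and therefore settles);
2. NMDA/fast amplitude ratio ← NMDA% and NMDA decay ← disinhibited
   duration, alternated (they are coupled through the tail-crossing);
3. gate half-time ← baseline duration; gate floor ← GABA% (capped so the
   late leak stays below the duration threshold); where the floor cap
   binds, the gate *width* becomes the GABA% dial — a sharper gate sits
   later for the same duration and passes more of the early response
   (NMDA-heavy groups need ~0.4 ms widths, control-like groups ~1 ms);
4. a final pure rescale re-anchors the peak (all other quantities are
   scale-invariant).

Duration residuals are quantized to the 0.1 ms sampling grid, so those
root finds scan a coarse grid for the sign change nearest the current
value and bisect inside it.  Fixed by choice rather than solved: fast
decay 3 ms, NMDA rise 2 ms.  Calibration of all fifteen presets takes
~15 s and is cached per process.

**Between-slice CVs from the tables.**  The slice-level SD of NMDA% is set
to `SEM·√n` from the published contribution table (≈ 11 points for the
32-week operated-eye group); the delta method converts it to the log-SD of
the component ratio via `dNMDA%/dln r = p(1−p)·100`.  The common factor's
variance is then chosen so the total amplitude CV matches the published
amplitude SEMs.  Because NMDA% is a concave function of the ratio, mean-one
scalings would bias the expected measured contribution ≈ 2 points low at
these CVs; the NMDA scaling's log-offset is therefore solved (21-node
Gauss–Hermite quadrature over the exact, scale-invariant pipeline response)
so the *expected measured* NMDA% equals the table mean.  This is done at
preset-build time, before any simulation.

**Seeds.**  A cohort's master seed (integer or `SeedSequence`) spawns one
child per slice; each slice's child seeds its scalings and sweeps.
Identical seeds therefore reproduce identical datasets, and cohorts are
extensible without disturbing earlier slices.

## What the generator does and does not emulate

It reproduces: the published response features and their group means, the
between-slice dispersion of amplitudes and contributions, the
drug-condition algebra, and epoch/stimulation timing.  It does not model:
conductance-based biophysics, paired-pulse or frequency-dependent
dynamics, within-epoch drift or wash-in kinetics (sweeps are exchangeable
within an epoch, so analyses may simulate only the last-3-min windows —
the shortened 3/3/3-min protocol used in the heavier simulation tests —
without changing any statistic), stimulus artifacts, electrode drift, or
line noise.  Passing tests therefore demonstrate correctness of the
measurement and inference chain under the stated generative assumptions,
not robustness to every artifact of real recordings.

## Statistics

Raw-data tests delegate to scipy (`ttest_rel`, `f_oneway`, `tukey_hsd`);
the summary-statistics route reconstructs `s_i² = SEM_i²·n_i`,
`SS_within = Σ(n_i−1)s_i²`, `SS_between = Σ n_i(m_i − m̄)²` and takes Tukey
p-values from the studentized-range distribution, so the two routes
cross-check each other exactly on matching data.  Edge cases: identical
data in every group reports F = 0, p = 1; a tiny negative F from
floating-point cancellation is clamped to 0 with p recomputed; zero-variance
non-zero paired differences are flagged degenerate.  All tests are
two-sided; α = 0.05 with the conventional `*`/`**` starring; no multiple-
testing correction beyond Tukey.

## Problem sizes

Default simulations mirror the recording protocol (20 min baseline,
20 min GABA blockade, 10 min added D-AP5 at one sweep per 20 s → 150
sweeps per slice).  The acceptance computations simulate full-protocol
cohorts at the published group sizes (n = 14, 12, 15, 13).  The power and
null-calibration tests use 50 and 40 replicates respectively with the
shortened last-window protocol, chosen as the smallest designs whose
binomial uncertainty is well inside the asserted margins.

## Known limitations

* The contribution formulas assume the disinhibited-condition AUC as the
  common denominator; alternative normalisations would change the scale
  of both indices.
* With the published between-slice SDs (≈ 10–11 points), a single
  cohort's mean NMDA% has an SEM of ≈ 3 points at n = 12–14, so any one
  simulated cohort can land 3+ points from the table mean; only the
  expectation is calibrated.
* Duration is threshold-based and therefore noise-level dependent through
  the `3·noise SD` arm; very noisy averages shorten measured durations.
* The calibration solves six targets with six effective dials; target
  sets far outside the published ranges (e.g. a GABA% inconsistent with
  the baseline-duration cut) raise `CalibrationError` rather than
  returning a best effort.
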