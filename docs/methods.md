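# Methods

`latflow` implements a complete analysis chain for language lateralization
measured with functional transcranial Doppler sonography (fTCD): raw
bilateral cerebral blood-flow-velocity (CBFV) signals are reduced to
per-task laterality indices (LIs), assembled into a quality-controlled
subjects × (6 tasks × 2 sessions) table, and analysed with a battery of
structured mean/covariance latent-variable models fitted by
full-information maximum likelihood (FIML).  Generative simulators at both
the LI level and the signal level make every stage testable against known
ground truth.

## 1. The generative models of laterality indices

The LI of person *j* on task *i* is modelled additively,

    LI_ij = a + t_i + p_j + x_ij + e_ij

with a population bias *a*, task effects *t_i*, a stable person effect
*p_j* (constant across tasks and sessions), a task-by-person interaction
*x_ij* (constant across the two sessions of a task within a person), and
independent error *e_ij*.  Setting the standard deviation of a term to zero
removes it exactly, giving four nested scenarios: Population Bias (only
*a*), Task Effect (*a*, *t_i*), Person Effect (adds *p_j*), and Task ×
Person (adds *x_ij*).  All random terms are Gaussian.  Default standard
deviations are about one LI unit, chosen so simulated LI spread resembles
published fTCD data; they are plausible stand-ins, not estimates of any
particular dataset.  For power simulation the interaction is generated as a
second latent factor: `x_ij = g_i · q_j` with per-task loadings `g_i`
(`interaction_structure`) and a person-level score `q_j`, which matches the
one-factor versus two-factor discrimination design.

Implied correlation structure, used as oracles in the tests: under the
Person Effect model the test–retest correlation of any task equals the
reliability ratio `sd_p² / (sd_p² + sd_e²)` and equals the cross-task
correlation; under the Task Effect model test–retest correlations converge
to zero; under Task × Person, within-task correlations exceed cross-task
correlations.

## 2. The synthetic recording generator

`simulate_recording` builds one session per the study design: six tasks in
blocks of 15 trials of 33 s, at 100 Hz, with a marker channel encoding
trial onsets ('CLEAR' stimulus) and task labels.  Each channel is

    baseline · (1 + cardiac(t) + [common(t) ± diff(t)/2] / 100) + noise

* **Cardiac pulsatility** — a sum of three harmonics of the heart rate
  (default 1.17 Hz ≈ 70 bpm, relative amplitude 15 % of baseline).  The
  rate is snapped to the nearest frequency giving an integer number of
  cycles per session, so the waveform averages to exactly zero on the
  session grid and on any integer decimation of it.  Exact morphology is
  irrelevant to the pipeline contracts; the component exists to exercise
  heart-cycle integration.
* **Evoked response** — boxcar profiles over a window (default 3–24.48 s
  after trial onset) comfortably covering the analysis periods of interest:
  a bilateral common component plus a lateralized differential whose
  amplitude per task is the ground-truth LI in normalized units (percent of
  mean CBFV).  Both profiles have their session mean removed before being
  applied, so the session mean of each channel equals its baseline level
  exactly; mean-100 normalization is then exactly linear in the
  differential, and baseline correction restores the boxcar's zero
  reference.  The default window edges fall on the 25 Hz analysis grid.
  Together with the zero-mean cardiac construction this makes noise-free
  boxcar recovery exact to machine precision, so the truth-recovery test
  can use a 10⁻⁶ tolerance that measures the pipeline arithmetic rather
  than generator/analysis grid mismatch.
* **Artifacts** — `inject_artifacts` superimposes single-sample spikes and
  near-zero dropout runs at specified times and keeps a ground-truth log.

What the generator does *not* emulate: hemodynamic response shapes beyond a
boxcar, probe drift, motion artifacts with realistic spectra, respiratory
modulation, or any behavioural response process.  Passing tests show the
pipeline implements its stated rules and recovers known lateralization
under these idealized conditions; they do not certify performance on real
Doppler recordings.

## 3. Signal preprocessing

Stage order: downsample → segment → spike repair/reject → normalize →
heart-cycle integrate → range check → baseline correct → LI.

* Downsampling 100 → 25 Hz keeps indices 0, 4, 8, … (simplest deterministic
  phase convention).
* Epochs span [−7, 26) s around each trial onset (825 samples); windows are
  half-open, sample timestamps window-start aligned, peristimulus time 0 =
  'CLEAR' onset.
* Spike/dropout screening flags samples strictly outside the per-channel
  [0.0001, 0.9999] empirical quantiles (linearly interpolated order
  statistics) computed over the *whole downsampled session* — such extreme
  quantiles are meaningless within a single 825-sample epoch.  One flagged
  sample in an epoch is replaced by the epoch-channel mean over the
  remaining samples (a spike must not contribute to its own replacement);
  two or more reject the epoch.  Note the screen by construction flags the
  most extreme 0.02 % of samples even in artifact-free signals, so
  truth-recovery tests on clean synthetic data disable it
  (`spike_screening=False`); its behaviour is tested separately on
  constructed inputs.
* Normalization divides each channel by its session mean × 100 (per-epoch
  mode available behind `normalization_scope="epoch"`; which scope the
  original analysis used is not documented, session-level is the default
  here).
* Heart-cycle integration detects systolic peaks on the sum of the two
  normalized channels (minimum inter-beat interval 0.5 s), shares the cycle
  boundaries between channels, and replaces each sample by its cycle mean;
  partial first/last segments are averaged as their own segments, which
  preserves each channel's overall mean exactly.  Constant signals pass
  through unchanged; a non-constant signal without detectable cycles is an
  error.
* The 60 %/140 % range check runs on the mean-100 scale *before* baseline
  subtraction — after subtraction the percent thresholds would be
  meaningless — and rejects the epoch on any excursion in either channel.
* Baseline correction subtracts each channel's mean over [−5, 2) s.
* The mean-based LI is the time-average of the across-epoch mean
  left-minus-right difference over the period of interest: 6–23 s for the
  decision tasks (B, C, E, F), 6–17 s for the overt-report tasks (A, D) to
  avoid speech-movement artifacts.  POI endpoints are start-inclusive,
  end-exclusive.  Positive LI = left dominance.  The legacy peak-based LI
  (absolute peak of the difference wave, averaged over a 2 s window centred
  on it, clipped to the POI) is computed alongside.
* Per-trial LIs give a standard error (sample s.d. / √n); a task with fewer
  than 12 acceptable epochs of 15 is excluded, and a participant-session
  with more than one excluded task is excluded entirely.

Guaranteed invariances, asserted by tests: swapping the channels negates
every LI exactly; rescaling both channels by any positive constant leaves
every LI unchanged.

## 4. Table-level QC and descriptives

Trial standard errors of *all* cells (subjects × tasks × sessions pooled)
feed the Hoaglin–Iglewicz rule: cells with SE above `Q3 + 2.2·(Q3 − Q1)`
(linearly interpolated quartiles) lose their LI.  The threshold is a single
number for the dataset, never per task.  Excluded cells become explicit
missing values that propagate into the likelihood; nothing is imputed.

Descriptives: a pairwise-complete Pearson correlation matrix over the 12
conditions (cell-level deletion; entries with < 3 complete pairs are
missing and logged); per-condition one-sided one-sample t-tests of mean
> 0, Wilcoxon signed-rank tests against zero (two-sided by default, with a
one-sided option — published laterality figures do not always state
sidedness), and Shapiro–Wilk normality statistics.  Behavioural logs yield
accuracy (omissions scored incorrect), omission rates, word counts, and
reaction times averaged over correct trials after a single ±2 s.d. trim
around the subject × task × session mean (computed once over the untrimmed
correct trials, never iterated); session effects are tested by paired
t-tests and, for word counts, a task × session repeated-measures ANOVA.

## 5. The model battery

Seven structured mean/covariance models for the 12-variable table, in
reporting order, with free-parameter counts 24/12/2/6/6/18/23:

1. **Fully Saturated** — free mean and variance per condition, zero
   covariances (24).
2. **Task Effect** — means and variances tied across sessions within task
   (12).
3. **Population Bias** — a single mean and variance (2).
4. **Dorsal Stream** — mean/variance groups {A,B}, {C}, {D,E,F} (6).
5. **Lexical Retrieval** — groups {B,D}, {A,C,F}, {E} (6).
6. **Person Effect** — Task Effect means plus one common factor: anchor
   task loading fixed to 1, five free loadings tied across sessions, free
   factor variance, per-task residual variances (18).
7. **Task × Person Effect** — bifactor: additionally five free Factor-2
   loadings (anchor fixed to 0), Factor-2 variance fixed to 1, inter-factor
   covariance fixed to 0 (23).

Sentence Generation (task D) is the default anchor — the strongest, most
reliable indicator should carry the fixed paths.  The subset models impose
equalities only; the predicted orderings (AB > DEF > C, BD > ACF) are
descriptive hypotheses, not inequality constraints.  LIs enter the models
unstandardized.

**Estimation.**  FIML: each subject contributes the multivariate-normal
−2 log density restricted to that subject's observed cells, including the
k·ln 2π constant; rows are grouped by missingness pattern for speed.  The
optimizer is multi-start L-BFGS-B on an unconstrained scale (log variances,
free loadings; the saturated reference model uses a Cholesky factor with
log diagonal).  The first start is data-driven from pairwise-complete
sample moments; further starts are seeded Gaussian perturbations; a
non-positive-definite implied covariance returns +∞.  The battery is fitted
restricted-first and each more general model also receives the embedded
solution of its nested predecessor as a warm start, which makes the
deviance nesting chain (Population Bias ≥ Dorsal/Lexical ≥ Task Effect ≥
Fully Saturated ≥ saturated-full, and Task Effect ≥ Person Effect ≥
bifactor ≥ saturated-full) hold up to optimizer tolerance on every dataset.
Fits are deterministic given the seed.

**Fit statistics.**  df = (number of observed values) − (number of free
parameters); `BIC = −2logL − df·ln(N_subjects)` — the convention is pinned
by the identity df = (−2logL − BIC)/ln N, e.g. 1378.0 − 415·ln 37 = −120.6.
χ² for a model is its deviance minus that of the fully saturated
mean+covariance reference (free means, unstructured covariance, 90
parameters), with df the parameter-count difference;
`CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_0 − df_0, 0)` against the
independence (free means + variances, zero covariance) model, and
`RMSEA = sqrt(max(χ²_m − df_m, 0)/(df_m (N − 1)))`.  Nested models are
compared by χ² tests on the deviance difference; a negative difference
beyond tolerance is reported as an optimizer failure, never silently
clipped.  Wald confidence intervals for loadings come from the observed
information (central-difference Hessian).

**Power simulation.**  For each sample size, datasets are drawn from a
one-factor truth (person effect sd 0.8, error sd 0.6 — test–retest
reliability ≈ 0.64, mid-range for fTCD) and a two-factor truth (the same
plus a second factor with loadings 1 on tasks E and F and score sd 0.8;
the anchor task stays clean for identification); both factor models are
fitted to each and the bifactor model is scored as preferred by LRT at
α = 0.05 and by BIC.  At n = 60 with 200 replicates, BIC recovers the true
structure in well over 90 % of runs under either truth.  The LRT's χ²₅
null reference is asymptotic: at n = 60 the test over-rejects somewhat
(≈ 0.10), while at n = 300 the measured type-I error is 0.05; the
calibration check therefore runs at large n, and small-sample LRT
inflation is a documented property, not a defect.

## 6. Diagnostics

Leave-one-out refits of the one-factor and bifactor models report the BIC
winner per omitted subject and the maximum loading drift against the
full-sample fit.  Factor scores use the regression (Thomson) estimator,
`Φ Λ' Σ_oo⁻¹ (y_o − μ_o)`, restricted to each subject's observed cells — a
subject at the fitted means scores zero.  Bivariate outliers in the
(F1, F2) plane are flagged by Cook's distance from the simple regression of
F2 on F1 with threshold 4/n; the estimator, regression direction and
threshold are this package's documented choices, since published analyses
of this design rarely state them.  `refit_excluding` reruns the whole
battery on the reduced sample.

## 7. Problem sizes used in the test and acceptance runs

Truth-recovery uses full six-task sessions (90 trials, ~50 min of signal at
100 Hz) for the noise-free check and 100–200 two-task sessions for the bias
check; Monte-Carlo reliability checks use n = 5000 subjects at the LI
level; model-recovery uses 200 replicates at n = 60 and the LRT calibration
200 replicates at n = 300; FIML oracles use 2–3-variable tables with ≤ 35
subjects where brute-force optimization is dependable.  These sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances.

## 8. Known limitations

* The heart-cycle detector (peak picking on the channel sum) is a
  reasonable default, not a reproduction of any specific published
  implementation; morphologically unusual pulsatility may need tuning of
  the minimum inter-beat interval.
* Session-level vs epoch-level normalization changes LIs slightly; both are
  provided, and the default (session) is a documented choice.
* The SEM engine covers exactly the structured-mean/covariance family used
  here — no regression paths, multi-group models, categorical indicators,
  robust corrections, or Bayesian estimation.
* Wald intervals for loadings can be optimistic near boundaries (e.g.
  factor variances close to zero); profile-likelihood intervals are not
  implemented.
* Real fTCD data contain artifact classes the generator does not produce;
  see §2.
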