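# Methods

## Task model and the synthetic-session generator

The generator reproduces the structure of a visually paced finger-tapping
paradigm with two task conditions and timing jitter:

- 1008 trials per session: 50% *chosen* (three permitted responses), 25%
  *specified* (one instructed response), 25% *null* (blank 2400 ms
  periods carrying no stimulus and no response).  The condition multiset
  is exact, not in expectation.
- Task trials last 2400 ms (1000 ms stimulus + 1400 ms interval); nulls
  2400 ms.  Onsets are the cumulative sum of durations.
- No more than four consecutive trials share a condition.  Orders are
  drawn by sampling conditions one at a time with probability
  proportional to remaining counts, excluding any condition that would
  overrun the limit, with bounded whole-sequence restarts.  A plain
  shuffle-and-check sampler is impractical here — a random permutation of
  the default multiset almost always contains an over-long run of chosen
  trials — and the sequential sampler is simple, fast and reproducible.
  Its draw is not exactly uniform over the set of valid orders; for the
  loose default constraint the deviation is immaterial to every statistic
  computed downstream, all of which condition on the realized order.
- Stimulus identity depends on the previous response.  Chosen stimuli
  a–d are labeled by their single unfilled (non-permitted) circle, and
  specified stimuli e–h by their single filled (instructed) circle.  The
  option (chosen) or instruction (specified) to repeat the previous
  action is assigned to exactly half of the eligible trials per
  condition (±1), enforced by a balancing urn that emits the lagging
  flag whenever counts are unequal and a fair draw at ties.  Trials with
  no usable previous response (session start, after an error or a null
  start-of-block) draw uniformly from the condition's four stimuli and
  do not consume a flag.  When several stimuli satisfy a flag the choice
  among them is uniform.
- Agents are pluggable policies (uniform, sticky, biased) with
  log-normal response times (median 500 ms, log-scale 0.25, rounded to
  whole milliseconds) and a 2% default error rate, matching the high
  response rates of practiced participants.  RTs are generated
  independently of the randomness measures, so the null result of the RT
  regression holds by construction; `apply_rt_modulation` injects known
  effects for power analyses.

What the generator does *not* emulate: perceptual/motor noise beyond the
error flag, learning or fatigue trends, and the idiosyncratic choice
tendencies of real participants beyond the provided policies.  Passing
tests therefore validate the analysis machinery and its calibration, not
claims about human behavior.

## Randomness measures

All three measures are estimated from the `n` most recent *task* trials;
null trials carry no stimulus and do not advance the window.  Values are
assigned to the window's last trial, so series are valid from task trial
`n` onward; earlier entries are NaN, never zero.  Selection entropy is
computed for every task trial — including specified trials — from the
chosen trials inside the window, and is NaN for a window without chosen
trials.  Error trials contribute their stimulus to the TE/SUP counts (the
stimulus was displayed) but their responses are excluded from the SE joint
counts; an `include_error_actions` flag flips the latter choice for
sensitivity analyses.

The log base is 2 by default with natural logs available; every
correlation- and GLM-based result downstream is invariant to the base.
The implementation uses cumulative one-hot counts so each series is
computed vectorized in one pass; unit tests verify every window against a
brute-force recount at 1e-12.

## Behavioral statistics

Cross-window similarity of each measure is the Pearson correlation between
series at two window lengths, restricted to trials valid under both
(early trials lack large-window values).  Group summaries use Fisher
z = atanh(r) off the diagonal.  Friedman tests use average-rank tie
handling; a fully tied table is reported as statistic 0, p 1.  The
one-sample Wilcoxon signed-rank test drops zero differences, uses the
exact null distribution for n ≤ 25 without ties and the tie-corrected
normal approximation otherwise.  The RT model is an ordinary
least-squares regression of single-trial RT on TE, SE and SUP (plus
intercept) per subject and window, with coefficients entered into
group-level signed-rank tests.  Bootstrap CIs are percentile bootstraps
over subjects (10,000 resamples, seeded).

## Design matrices

Each window length gets its own first-level model with columns, in order:
stimulus-onset regressor over all correct task trials; +1/−1
chosen-vs-specified contrast; TE, SUP and SE parametric modulators;
RT nuisance modulator; error-trial regressors per condition (omitted when
empty after trimming); optional 6 motion covariates; discrete-cosine
high-pass basis (cutoff 400 s, `floor(2·N·TR/cutoff)+1` functions
counting the constant); intercept.

Numerical choices:

- HRF: double-gamma with 6 s peak and 16 s undershoot delays, unit
  dispersions, peak:undershoot 6:1, 32 s kernel normalized to unit sum —
  the widely used canonical form; all parameters are exposed in
  `HRFSpec`.  Events are impulses at stimulus onset by default (a boxcar
  option exists); trains are built at 16 microtime bins per TR and read
  out at the middle bin.
- Modulator amplitudes are mean-centred across the session's events;
  after convolution and trimming the columns are additionally demeaned
  over retained volumes.  Serial orthogonalization is classical
  Gram–Schmidt residualization in the order intercept → onset →
  condition → TE → SUP → SE (the intercept and onset are protected
  targets), so shared variance is credited to the earlier regressor and
  SE keeps only variance unexplained by the trial information it is
  conditioned on.  A variant residualizes each modulator against the
  intercept and onset only, leaving the modulators' shared variance in
  place.
- Trimming removes (by row exclusion, preserving degrees of freedom) all
  volumes acquired before the onset of the first task trial with a full
  window.
- High-pass filtering is implemented as DCT nuisance regressors — the
  regression equivalent of filtering.  The stated column-count convention
  may differ by one basis function from other implementations; it is
  fixed and recorded in the design provenance.
- The RT nuisance is a convolved parametric modulator on the onset
  regressor's events; it is never orthogonalized.
- Design condition numbers above 1e6 raise a warning.

## BOLD simulation and recovery

ROI signals are `y = X·β + drift + noise` on the retained-volume grid,
with white or AR(1) noise (default φ = 0.3, a common empirical value;
stationary start, 100-sample burn-in) and optional slow cosine drifts.
Ground truth attaches betas to named (post-orthogonalization) design
columns, so recovered coefficients are directly comparable to injected
ones; presets encode the canonical coupling directions (TE−, SE−, SUP+).
`target_cnr` rescales each ROI's innovation sigma so that
`|β|·sd(column)/σ` hits a chosen contrast-to-noise ratio (0.5 in the
recovery checks).  Groups default to 16 subjects; each subject's betas
may scatter around the group truth with a chosen SD.  BOLD is generated
from the design at one *generating* window length; fitting designs at
other lengths then probes timescale specificity, since series at nearby
window lengths correlate more strongly.

First-level estimation is OLS by default; AR(1) prewhitening
(Cochrane–Orcutt with φ from the lag-1 residual autocorrelation, or a
fixed φ) is optional.  The second-level window ANOVA is the standard
one-way repeated-measures decomposition with subjects as the blocking
factor and no sphericity correction by default, so 16 subjects × 6
windows reports F(5, 75); a Greenhouse–Geisser epsilon is available.  It
is implemented directly from the sums of squares (and cross-checked
against statsmodels' AnovaRM in the tests) so that zero-variance tables
degrade gracefully and the 1000-replicate calibration loop stays fast.

## Problem sizes in the routine checks

The recovery and calibration checks run at deliberately scaled-down
sizes — 4-subject groups, 300-trial sessions, two window lengths (25 and
50) and 380-volume scans — chosen so the whole suite re-runs in seconds
while leaving contrast-to-noise and test calibration at the same operating
point as the full-size design.  The null calibration draws each
replicate's subjects from a 12-member design pool and fresh noise per
replicate: under the null the signal is independent of the design, so the
rejection rate is estimated over both noise realizations and design
draws.  Full-size defaults (16 subjects, 1008 trials, six windows, 1294
retained volumes at TR 2 s) remain the package defaults throughout.

## Known limitations

- ROI-level only: voxelwise maps, random-field cluster inference and
  anatomical labeling are out of scope; the ROI time-series analogue
  carries all testable statistics.
- The generator's sequential order sampler is reproducible but not
  exactly uniform over valid orders (see above).
- The AR(1) prewhitening uses a single lag-1 estimate per ROI rather
  than a full autoregressive model selection.
- Second-level non-sphericity handling is limited to the optional
  Greenhouse–Geisser correction.
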