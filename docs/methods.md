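# Methods

This note documents the models, procedures and numerical choices behind
`accelstates`, and what its synthetic validation does and does not show.

## Problem and model

Free-ranging semi-aquatic reptiles alternate among four coarse activity
states: motionless or in motion, on land or in water. A carapace-mounted
logger records tri-axial acceleration (±2 g, ~1 Hz) and a water-
conductivity channel (10-bit, 0–1023 device units). The classifier is a
deliberately transparent two-step decision tree:

- **Step 1 (motion):** a single dynamic-body-acceleration (DBA) metric is
  compared against a per-habitat threshold θ; a window is in-motion iff
  its metric value strictly exceeds θ. The strict inequality puts
  boundary values in the motionless class in both training and deployment.
- **Step 2 (habitat):** aquatic iff the window's water summary strictly
  exceeds the water threshold (default 500 device units); a reading of
  exactly 500 is terrestrial.

The simplicity is the point: every stage (smoothing, metric choice,
threshold choice) is explicit and auditable, unlike black-box classifiers.

## Static/dynamic decomposition

Raw acceleration mixes gravity/posture (static) with movement (dynamic).
The static estimate is a centred running **median** per axis (a running
mean is available via `decompose(..., method="mean")` for sensitivity
checks); dynamic = raw − static. At trace edges the median uses the
truncated in-bounds window, so no samples are lost. The window must hold
an odd number of samples ≥ 3.

The smoothing duration is selected by scanning candidates (default odd
durations 3–131 s), computing mean per-sample ODBA over a habitat's
in-motion samples for each, and keeping the *shortest* candidate whose
mean is ≥ 95% of the scan maximum **and** whose per-sample ODBA does not
differ from the next-longer candidate's (paired two-tailed t, p ≥ 0.05);
if every consecutive test is significant the argmax candidate is used.
One window is selected per habitat; the per-dataset window is the longer
of the two (a too-long window wastes edge data, a too-short one
underestimates dynamic acceleration — the asymmetric risk favours the
longer choice). Too short a window genuinely leaks locomotor signal into
the static estimate: for a pure sinusoid of period p the mean-ODBA curve
rises steeply until the window reaches ~p and then saturates near 2A/π,
which is the saturation shape the selection rule exploits.

## DBA metrics

Six metrics summarise each trailing sampling window (default 10 s,
stride 1 sample): TODBA, TVeDBA, ΔODBA, ΔVeDBA, SDODBA, SDVeDBA (formulas
in the README). Two axis-combination conventions circulate for ODBA-type
quantities: `sum_of_abs` (|X_d|+|Y_d|+|Z_d|, the literature standard) and
`abs_of_sum` (|X_d+Y_d+Z_d|). Defaults: `sum_of_abs` for TODBA/SDODBA,
`abs_of_sum` for the delta metrics; both are switchable in `MetricConfig`
and every invariant in the test suite holds under either. Standard
deviations use the n−1 denominator. The window's water summary is the
median reading (robust to single-sample splash artefacts). In training
mode windows must lie entirely inside one censored bout so labels never
mix; in deployment mode they slide over the whole trace.

## Censoring and time conventions

Bout intervals are half-open [start, end) seconds; a sample belongs to a
bout iff its timestamp falls inside. Censoring removes bouts shorter than
two sample periods and trims one sample period from each end of the rest
(annotation-edge sync uncertainty); the trim is expressed in sample
periods so the rule scales under rarefaction. Censoring is idempotent: a
censored ethogram carries a flag and is returned unchanged, because
trimmed edges are no longer annotation boundaries. Time synchronisation
between video and logger is a user-supplied per-individual constant
offset.

## Threshold training

Labelled metric windows are split 70/30 per state (floor(n×0.7+0.5) to
train, seeded, both halves non-empty). Percent overlap between two class
samples is 100 × Σ_bins min(p_a, p_b) on shared bins of width 0.1 aligned
to multiples of 0.1 (the bin width equals the threshold increment so the
two grids align). The model-wide metric minimises the worst-case overlap
across the two habitat pairings, ties broken by a fixed preference order
(ΔODBA, ΔVeDBA, TODBA, TVeDBA, SDODBA, SDVeDBA). The threshold scan
covers the overlap region extended one increment each way (for disjoint
supports, the gap between them) in 0.1 steps; each candidate's
sensitivity, specificity and accuracy are recorded and the winner is
chosen by accuracy, then sensitivity+specificity, then the smaller
(conservative) θ. Individuals are pooled; per-individual blocking is the
caller's concern if pseudo-replication matters.

## Evaluation

Reports contain the 4×4 confusion matrix (predicted rows × observed
columns), one-vs-rest sensitivity and specificity per state, and overall
accuracy with an exact Clopper–Pearson binomial 95% CI (via statsmodels'
beta-quantile implementation; the test suite cross-checks it against a
bisection of the binomial tail equations). Displayed values are rounded
to one decimal; stored values keep full precision. Cross-population
transfer applies one dataset's fitted model to another's labelled windows
through the identical evaluation path.

## Rarefaction

Keeping every k-th sample (k = 2, 4, 8, 16) emulates 0.5–0.0625 Hz
loggers. The full calibration is repeated per k with the same seed:
candidate smoothing windows are re-expressed as odd sample counts ≥ 3 at
the reduced frequency; the DBA metric is re-selected by histogram
separation per k (as at the native frequency); and the 10-s metric window
is lengthened to keep at least five samples (20/40/80 s at k = 4/8/16).
The five-sample floor matters: with one inter-sample delta per window, a
stroke period close to the sample spacing aliases into the posture band
and delta metrics lose their discrimination; with five samples and free
metric choice, held-out accuracy on the synthetic preset stays within
one point of the 1 Hz run at every factor. A failure at one factor is
recorded on that factor's result and does not abort the others.

## Activity budgets

Budgets are per-civil-day proportions of classified windows in each state
(day boundary: local midnight in a configurable time zone; default UTC).
Denominators are classified windows, not wall-clock seconds, so
unclassified gaps do not distort proportions. Aggregation: per-individual
mean ± SD across days, then population mean ± SD across individual means
(SD over a single individual is undefined and reported as NaN).
Comparative statistics on budgets (e.g. Dirichlet regression) are out of
scope; the long-format daily table is directly consumable by such tools.

## Synthetic data

The generator emulates the statistical structure the classifier assumes:
per state, a gravity vector ((0,0,1) g terrestrial; (0.3,0,0.95)
normalised aquatic, a tilted floating posture), plus for in-motion states
a surge-axis sinusoid (amplitude 0.25 g) with per-bout random phase;
isotropic Gaussian sensor noise (SD 0.02 g); water channel Gaussian
around 100 (terrestrial) or 800 (aquatic) device units, SD 20, clipped at
0. Bout durations are geometric (discretised exponential, mean 60 s per
state); successive states always differ, drawn with configurable weights.
A small nonzero amplitude on a motionless state emulates passive motion
from waves or currents, which reproduces the empirically observed
ordering θ_aquatic ≥ θ_terrestrial.

The default stroke period is **3.7 s**, chosen deliberately off the 1 Hz
sampling grid. A 4.0-s period sampled at 1 Hz hits only four repeating
phase levels, and a running median can lock onto that pattern and cancel
the dynamic signal entirely at some phases (measured ΔODBA → 0); real
stroke cycles are never phase-locked to the logger clock, and 3.7 s keeps
the worst-case in-motion window ΔODBA (≈ 1.1) well above the motionless
noise ceiling (≈ 0.55) across all candidate windows and phases.

What passing synthetic tests shows: the machinery — decomposition,
metrics, selection rules, threshold scan, evaluation, rarefaction
plumbing — is correct, deterministic under seeding, and recovers injected
separations. What it does not show: performance on real animals, where
movement is broadband and irregular, postures drift, water sensors foul,
and device placement varies. The near-perfect synthetic accuracies are a
property of the preset's clean class separation, not a field prediction.

## Numerical choices and degenerate inputs

- Paired t-test: all-zero differences give p = 1 (indistinguishable);
  zero-variance nonzero differences have no finite t and raise an error.
- Zero-variance metrics are excluded from correlation means and flagged
  NaN in the correlation matrix.
- Histogram bin edges are floating-point-safe multiples of the bin width;
  a degenerate pooled range gets one bin.
- Threshold grids with disjoint class supports that contain no interior
  grid point fall back to the rounded gap midpoint.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the trace synthesiser derives a separate
  stream from the config seed so bout structure and channel noise are
  independent. Reruns of the pipeline with the same config are
  byte-identical, recorded in a manifest with config and input digests.

## Problem sizes used in validation

Synthetic checks use 0.5–2 h of 1 Hz data per draw (1 800–7 200 samples),
20 independent seeds for parameter recovery, and a 17-point smoothing
candidate grid (3–131 s, step 8 s) for the end-to-end experiments; these
sizes give stable statistics while keeping the whole suite fast on a
single CPU.

## Known limitations

- The water threshold (500) is a device-calibration constant, not fitted.
- A single metric and two thresholds cannot represent behaviours with
  overlapping DBA distributions (foraging vs travelling); the four-state
  repertoire is the design scope.
- Metric windows at heavy rarefaction are long (80 s at 0.0625 Hz), so
  short bouts contribute no training windows and sample sizes shrink.
- The bout model has no diel structure; budgets from synthetic data are
  uniform across the day by construction.
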