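# Methods

This note documents the models, estimators and design choices behind
`hdsemg`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical conventions
used throughout.

## Setting

High-density surface electromyography (HD-sEMG) records the myoelectric
activity of a muscle with a 2-D array of closely spaced electrodes, giving a
signal with two spatial dimensions and one temporal dimension. The package
targets the standard protocol for isometric elbow contractions: three
monopolar arrays — a 6-row forearm array with 16–19 columns covering
brachioradialis, anconeus and pronator teres, and two 8×15 arrays over
biceps and triceps — sampled at 2048 Hz with 10 mm inter-electrode distance
(IED), plus two torque meters whose signs agree for flexion/extension and
oppose for pronation/supination. Trials are 10 s contractions at 10, 30 or
50 %MVC (maximal voluntary contraction).

## Activation maps

An activation map (AM) is the image whose pixel (i, j) is the RMS of the
signal at electrode row i, column j over one epoch:

    AM_ij = sqrt( (1/N) * sum_n sEMG_ij(n)^2 ),

with N = 1024 samples (500 ms at 2048 Hz). Before map computation the
signals are band-pass filtered 12–350 Hz with a 4th-order Butterworth
applied forward and backward (zero phase; odd reflective padding of one
settling length suppresses edge transients). The analysed map averages six
consecutive non-overlapping 500 ms maps from the 3 s window of greatest
torque stability; the window minimizes the standard deviation (optionally
max−min) of the mean absolute two-channel torque, evaluated every 0.5 s
with ties going to the earliest window.

Maps can be expressed in a normalized anatomical frame: x = (offset_x +
col·IED)/segment circumference, y = (offset_y + row·IED)/segment length,
with the origin at the SENIAM-recommended sensor site of each array.
Display interpolation uses an interpolating bivariate spline (values at the
electrode sites are preserved; output clipped at zero); analysis always runs
at electrode resolution.

## h-dome segmentation

Active areas are segmented with the h-dome transform: D = v −
R(v − h; v), where R is grayscale geodesic reconstruction by dilation under
v. D is bounded by 0 ≤ D ≤ h and positive only on peaks rising more than
h above their surroundings. Choices:

* h = α·(max − min) of the averaged map, α = 0.2 by default — scale-free,
  so segmentation behaves consistently across effort levels;
* regions are 8-connected components of {D > 0} (4-connectivity fragments
  the coarse grids);
* low-intensity areas are discarded: components with fewer than 2 pixels or
  whose dome prominence is below 0.25·h (a genuine peak taller than h
  reaches prominence h exactly; noise bumps stay far below);
* a note on monotonicity: the support of the dome is {v > local max − h},
  so *larger* h produces *larger* regions — the property tests pin this
  direction down.

For the forearm array the active area must be divided among three muscles.
`segment_for_muscles` intersects the dome support with each muscle's column
band (columns closer to its anatomical reference column than to any
other's), so a dome bridging two overlapping muscles is cut at their
midline. When a weakly active muscle's band contains no dome, the strict
mode raises; the feature-extraction pipeline instead falls back to a 3×3
patch around the band's map maximum, because every feature vector needs all
five muscles even at 10 %MVC.

## Channel quality

Four features per channel, computed on the raw monopolar signals (the
low-frequency artifact band must not be filtered away first):

* relative power at 0–12 Hz (movement artifacts: large slow transients);
* relative power at 50 Hz and its first four harmonics (poor contact);
* RMS per 500 ms epoch, summarized by the median;
* mean of the maximum normalized cross-correlation with the 8-connected
  neighbors over lags within ±10 ms (tolerating inter-row propagation
  delays).

Spectra come from Welch averaging over 500 ms Hann-windowed segments; the
±2 Hz line tolerance covers the Hann mainlobe at the resulting 2 Hz bin
spacing.

A channel is an outlier if ANY rule fires. Because one array can cover
strongly and weakly active regions simultaneously, the power and similarity
rules are *relative to the spatial neighborhood*, not to the bulk of the
grid:

* power rule: the residual of the channel's log10 RMS from the median of
  its 8 neighbors (which tracks the smooth activation field) must stay
  within 5 robust-z units of the residual spread over the surrounding 5×5
  patch (MAD floored at 0.05 decades ≈ 12% so homogeneous regions do not
  produce false alarms);
* similarity rule: flagged when the channel's neighbor correlation falls
  more than 0.35 below the patch median — an absolute correlation floor
  would flag entire noise-dominated quiet regions wholesale;
* spectral rules: absolute fractions > 0.5.

The unsupervised alternative scores channels with the local distance-based
outlier factor, LDOF(p) = mean distance to p's k nearest neighbors divided
by the mean pairwise distance among those neighbors (k = 10, flag above
2.0), on the robustly standardized 4-feature space.

Flagged channels are repaired by neighbor interpolation: each bad position
is initialized from its valid neighbors and clusters are relaxed (Jacobi) to
the harmonic fixed point where every bad cell equals the mean of its
neighbors — making the repair idempotent and well-defined for bad-channel
clusters. A bad region with no path to any good channel is an error.

## Feature sets (150 ms epochs)

Features are computed per 150 ms epoch (307 samples; floor convention) of
the stability window, per muscle, then concatenated:

* **I** — intensity per muscle: I = log10 of the mean AM value over the
  muscle's segmented region (5 values). The segmentation of the recording's
  3 s averaged map is reused for all of its epochs (per-epoch segmentation
  is unstable at low effort).
* **IMS** — the 5 intensities plus mean-shift mode descriptors of each
  array's epoch map. Mean-shift ascends the amplitude-weighted Gaussian KDE
  over pixel coordinates (bandwidth 2 electrodes, weights normalized to sum
  1); the feature builder starts from every 3×3 local grid maximum only
  (seeded random restarts are available but add epoch-to-epoch jitter
  without finding extra modes on these small maps); modes closer than
  bandwidth/2 merge. The top 3 modes per array by density are reported as
  (x, y, density) triplets ordered spatially (density-ordered output swaps
  triplets whenever two modes have similar density, turning a stable map
  into a discontinuous feature); missing modes repeat the dominant one. An
  array without localized activation — KDE peak below 1.1× the peak a
  uniform-amplitude map of the same geometry would give — contributes the
  all-zero descriptor: its mode position would be noise-driven wandering,
  and "no significant mode" is itself informative. That significance
  decision is made once per recording on the 3 s averaged map (like the
  segmentation), so consecutive epochs cannot flap around the threshold.
  27 extra dimensions, reduced by PCA at classification time.
* **ICG** — the 5 intensities plus the amplitude-weighted center of gravity
  (x̄, ȳ) of each muscle's masked epoch map (15 dimensions, no PCA).
* **TD** — the classical time-domain set per channel: RMS, mean absolute
  value, zero crossings, waveform length, slope-sign changes (deadband 0 by
  default), concatenated over all 336 channels (1680 dimensions, reduced by
  PCA).

PCA keeps the minimal prefix of components whose cumulative explained
variance strictly exceeds 90%, is fit on the training split of each holdout
repeat only, and centers with the training mean (no leakage).

## Classification

The linear discriminant classifier (LDC) uses pooled covariance with
Ledoit-Wolf shrinkage (150 ms epochs give few samples relative to the TD
dimensionality; plain pooled covariance would be singular). Scores for ROC
analysis are class posteriors — unlike raw discriminant values they are
comparable across samples, which one-vs-rest AUC requires.

Task identification is 4-class over all recordings regardless of effort.
Task + effort identification is 2-step: step 1 predicts the task from the
full feature set; step 2 routes the sample to one of four per-task effort
classifiers (10/30/50 %MVC) restricted to the features of that task's
agonist–antagonist muscles — biceps+triceps for flexion and extension;
biceps, brachioradialis and anconeus for supination; pronator teres and
anconeus for pronation. Step-2 models are trained on the true task
partitions; at prediction time a step-1 error makes the 12-class composite
label wrong by construction. Composite scores are P(task)·P(effort | task).

Evaluation: repeated stratified holdout (N = 20, 70/30 per class), with
per-class ACC = (TP+TN)/(TP+TN+FP+FN), F1 = 2TP/(2TP+FP+FN) and
one-vs-rest AUC, macro-averaged and aggregated as mean ± sd over repeats.
Feature sets are compared with a paired one-sided Wilcoxon signed-rank test
across seeds/subjects.

## Synthetic generator

The generator reproduces the *map-level statistics* the pipeline consumes,
not volume-conductor physics:

* each muscle contributes 3 sources near its anatomical centroid
  (per-source placement jitter sd 0.5 electrodes); a source is a renewal
  train (13 Hz, ISI CV 0.12) of biphasic templates (first derivative of a
  Gaussian, ~6 ms wide) propagating along the column axis at 4 m/s — rows
  at distance d see the template delayed by d·IED/velocity (2.5 ms ≈ 5.12
  samples per row at defaults) — with Gaussian spatial decay (σ = 2
  columns, 3 rows);
* task structure enters through per-muscle activation weights matching the
  agonist sets above; effort scales source amplitude linearly;
* nuisance terms chosen to mirror real recordings: additive white noise at
  0.05 a.u. (comparable to the weakest-effort signals, as baseline noise is
  for 10 %MVC monopolar sEMG), a common 50 Hz line component (0.01 a.u.,
  ±30% per channel), per-channel log-gain jitter (sd 0.1, fixed within a
  recording, as electrode-skin impedance is), and a slow (~0.3 Hz)
  per-muscle log-amplitude drift (sd 0.2) emulating common-drive force
  fluctuation during sustained contractions;
* torque is a 10 s plateau at effort·MVC/100 with 0.5 s cosine ramps, 2%
  low-frequency jitter, and the task sign convention;
* artifacts: `dead` (noise at 0.1% of the grid median RMS), `line_contam`
  (50/100/150 Hz at 5× median RMS), `lowfreq_transient` (0.3–5 Hz drift at
  5× median RMS), `high_power` (gain ×5), `decorrelated` (white noise at
  the channel's own RMS). Ground truth records task, effort, the
  amplitude-weighted realized source centroid per muscle, and the
  bad-channel set.

What the generator does **not** emulate: physiological MUAP waveform
diversity, motor-unit recruitment/rate-coding detail, innervation zones,
fatigue, electrode-shift nonstationarity, or anatomically realistic
crosstalk beyond Gaussian field overlap. Validation results on synthetic
data therefore demonstrate the pipeline's correctness and its behavior
under controlled nuisance, not clinical performance.

## Validation studies and problem sizes

* *Detection power*: 200 single-array trials (tasks/efforts cycled), 2–5
  injected artifacts each drawn from the four location-independent kinds
  (dead, line, drift, high-power); rule-mode precision and sensitivity are
  scored against ground truth. A `decorrelated` channel inside an already
  noise-dominated quiet region carries no detectable signature, so that
  kind is exercised in unit tests but not in the power study.
* *Centroid recovery*: 50 trials at 50 %MVC; for each dominant agonist
  (weight ≥ 0.65) the COG of its segmented region must fall within 1 IED of
  the realized source centroid. Secondary synergists are excluded: an
  adjacent agonist at twice their amplitude leaks into their band and
  biases the COG by 1–2 electrodes — a crosstalk limit of map-resolution
  COG, not an estimator defect.
* *Mean-shift oracle*: on 50 random one/two-blob maps the dominant
  mean-shift mode must lie within 0.5 electrodes of the brute-force
  weighted-KDE maximum on a 0.05-electrode grid.
* *Feature-set ordering*: 20 synthetic subjects (12 recordings each);
  task-identification AUC of IMS and ICG vs TD, compared by paired
  one-sided Wilcoxon across seeds. The reproduction script runs 12 subjects
  and 100/30-trial versions of the detection/recovery studies to keep a
  single-CPU run within minutes; the test suite runs the full sizes above.

## Known limitations

* The ascii dialect and file-name tokens of the public dataset are
  documented assumptions validated only against self-written fixtures; the
  reader sniffs delimiter/header and the writer pins the dialect in
  round-trip tests.
* Channel ordering over the grid (column-major by default) is configurable
  because the deposited order is not published.
* The rule thresholds are robust defaults, not the original expert system's
  values (which were never published); both detection modes expose every
  threshold in configuration.
* COG and mean-shift features carry a small bias toward the grid interior
  near array borders (mask truncation); at 10 mm IED this stays well below
  one electrode for centrally placed sources.
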