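# Methods

## Scope and models

The package quantifies two linked aspects of *Mortierella alpina* batch
cultures: the macro-morphology of the mycelium (hollow pellets, fluffy
pellets with radial filaments, or dispersed filaments) from 2-D projected
colony images, and the fermentation kinetics of each morphological form.

### Growth and product kinetics

Biomass follows the logistic model

    dX/dt = mu_max * X * (1 - X/X_m),
    X(t)  = X_m / (1 + C e^{-mu_max t}),   C = (X_m - X_0)/X_0,

with mu_max the maximum specific growth rate (1/day), X_m the carrying
capacity (g/L DCW) and X_0 the inoculum biomass (g/L). Lipid follows the
Luedeking-Piret equation dP/dt = alpha*dX/dt + beta*X, whose integral
against the logistic trajectory is also closed-form:

    P(t) = P_0 + alpha*(X(t) - X_0)
               + (beta*X_m/mu_max) * ln((C + e^{mu_max t})/(C + 1)).

The log term is evaluated with `logaddexp`, so large mu_max*t cannot
overflow; C = 0 (inoculation at capacity) degenerates cleanly to
∫X dt = X_m t. Both closed forms are verified in the tests against a
high-accuracy DOP853 integration of the ODE pair at 1e-6 relative
tolerance over randomized parameter sets.

### Trajectory anchoring

Published parameter tables for this system report mu_max, X_m, alpha and
beta but not X_0 or P_0. The daily growth-rate table pins the missing
X_0: the rate law mu_max*X*(1 - X/X_m) = Q is a downward parabola in X,
so the reported day-1 rate gives the day-1 biomass as its pre-inflection
(smaller) root, and the closed form run backwards one day yields X_0.
Cultures inoculate far below X_m/2, which makes the pre-inflection branch
the physical one. P_0 is set to 0 where only rates are compared — they do
not involve it. With this anchoring, the three published morphologies
reproduce all 48 published daily (Q_X, Q_L) values to at most 1.3e-3
g/L/day absolute, i.e. within the rounding of the four-decimal printed
parameters; the back-computed inocula are 3.63 (hollow), 4.00 (fluffy)
and 2.17 g/L (dispersed).

The published per-morphology rate maxima coincide with the maxima of the
*daily grid*, not the continuous maximum mu_max*X_m/4 (for the hollow
culture the grid value 1.7678 differs from the continuous 1.770); the
`RateTable` therefore reports grid maxima.

### Fitting

The logistic curve is fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`) over (mu_max, X_m, X_0), with an
optional mode fixing X_0 when the inoculum is known. Starting values come
from the data (X_m from 1.05·max X, X_0 from the first positive point,
mu_max from the early log-slope); bounds are mu_max ∈ (0, 10],
X_m ∈ [max X, 10·max X], X_0 ∈ (0, X_m]. Flat or boundary-pinned fits are
flagged `converged = False` rather than returned silently. Loss is
ordinary (unweighted) least squares.

(alpha, beta) are *not* obtained by differentiating the measurements.
With the logistic parameters in hand, Luedeking-Piret integrates to

    P(t_i) - P(t_1) = alpha*(X(t_i) - X(t_1)) + beta * ∫_{t_1}^{t_i} X dτ,

linear in (alpha, beta) with the integral from the closed form. Anchoring
at the first observation makes the regression exact on model data for any
starting time and keeps the unknown initial lipid level out of the
coefficients. Because product formation is partially growth-associated
(alpha and beta both nonzero in this system), negative estimates are
treated as noise artifacts: the offending coefficient is clipped to zero,
the other refitted, and the result flagged. Noise-free round trips recover
generating parameters to better than 1e-6 relative; under observation
noise of 0.5 g/L the median fitted mu_max over 200 replicates stays within
5 % of truth (seeded Monte-Carlo test).

## Morphometrics

Images are thresholded (Otsu by default; a numeric threshold can be
supplied), cleaned with one radius-1 disk opening, and small components
below a configurable area are dropped. A uniform image raises rather than
returning an arbitrary mask. The physical mm-per-pixel scale must be
supplied (argument or image sidecar); no magnification inference is
attempted.

Core extraction is granulometric: the (hole-filled) mask is opened with
disk structuring elements of radius r = 1, 2, … and the retained area
recorded. Filaments disappear once the disk outgrows their width; the
compact core barely changes, so the area curve drops and then plateaus.
The loop stops at the first radius where the relative area change from
r−1 to r falls below `stop_tol` (default 0.02); the opened mask at that
radius is the core and mask∧¬core the filamentous part. Two numerical
choices matter here:

* the plateau test only applies from `min_radius` (default 2) onwards —
  after the binarize-stage radius-1 cleanup the r = 0 → 1 change is
  always near zero, and testing it would stop the loop before a single
  filament had been removed;
* hole filling is on by default, since projected pellets are solid;
  "hollow" pellets are hollow in 3-D but project as filled disks, so
  hollowness is a classification outcome, never a detected geometry.

If no plateau appears by `max_radius` the core at `max_radius` is used
and the record flagged. Area is pixel count × scale²; the equivalent
diameter is 2·√(A/π); the fluffy degree A_pc/A_m is defined as 0 for an
empty colony. Compactness idealizes the n counted colonies as spheres of
the mean equivalent diameter: DCW / (n·(4/3)π(D_m/2)³), reported in
mg/cm³ with D_m converted to cm. n is a parameter (conventionally 50
colonies are counted). Published compactness values for this organism
carry no stated unit, so they are not used as numerical targets.

Classification uses two thresholds, both configurable: fluffy degree
≤ 0.05 → dispersed; fluffy degree ≥ 0.7 *and* core diameter > 3 mm →
hollow pellet (the 3 mm cut reflects the hollow form's defining oversized
core); otherwise fluffy pellet. Aggregation over a sample reports
per-metric mean and SD, flags samples below 20 colonies, and takes a
majority vote for the class with a deterministic tie-break toward the
more compact class (hollow > fluffy > dispersed).

## Synthetic data

The image generator renders what the granulometric contract needs, not
hyphal realism: a central disk core (absent for the dispersed form) plus
straight radial filaments with seeded angle jitter, drawn as 1-px lines
dilated to width 3 px — a shape a radius-1 opening preserves exactly and
a radius-2 opening removes cleanly. Dispersed filaments start at random
radial offsets so no artificial dense center forms. Hollow pellets get a
brighter rim over a filled disk (a projection cannot depict interior
hollowness). Intensities are 0 background / 0.75 filament / 0.9 core /
1.0 rim on a 0-1 scale with additive Gaussian noise (default sd 0.02).
Defaults: 384×384 canvas at 0.02 mm/px; core radii 1.94 mm (hollow) and
1.455 mm (fluffy), matching the published core diameters of 3.88 and
2.91 mm; 24 radial filaments of 1.2 mm (fluffy); 40 scattered filaments
(dispersed). The generator returns exact pixel-count ground-truth areas —
the oracle the morphometric pipeline is tested against (A_m within 5 %,
A_pc within 10 % under noise).

Time courses are sampled from the closed forms with additive zero-mean
Gaussian noise, floored at 0 (defaults: 0.5 g/L biomass, 0.2 g/L lipid —
a few percent of typical working concentrations, consistent with
triplicate DCW and gravimetric lipid determinations). The default grid is
daily, t = 0..8 days, mirroring an 8-day batch. Residual glucose, when
requested, is generated by constant-yield bookkeeping
S(t) = S_0 − Y·(X(t) − X_0) floored at 0 (defaults S_0 = 80 g/L,
Y = 1.8 g/g); this is a simulation convenience only — no substrate model
is fitted anywhere in the package.

What the synthetic data does not emulate: hyphal branching, filament
curvature, uneven illumination, touching colonies, lag phases, or
non-Gaussian measurement error. Passing tests therefore demonstrate the
correctness of the algorithms under their stated assumptions, not
segmentation robustness on real micrographs.

## Problem sizes

The test suite and analysis scripts run at desk scale by design: 20
colonies per morphology at 384×384 px, 9-point daily time courses, 200
Monte-Carlo fit replicates, 1000-replicate noise-bias checks. The full
suite completes in well under a minute on one CPU.

## Known limitations

* The granulometry plateau rule assumes filaments are thin relative to
  the core; colonies whose "filaments" are blob-like will stop late and
  over-assign core area.
* Equivalent diameters assume near-circular projections; the dispersed
  form's D_m is reported but physically loose.
* The fitted kinetics assume a single logistic phase; diauxic or lagged
  growth is out of scope.
* Rate tables evaluate the model, not the data; they inherit any misfit
  of the logistic stage.
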