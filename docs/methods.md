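# Methods

This note documents the models implemented in emnav, the conventions and
defaults that matter, and the boundaries of what the test suite establishes.

## Coordinate frames and pose algebra

Every rigid transform carries explicit string frame labels
(`"tracker"`, `"plan"`, `"sensor:<id>"`) and maps points from its source
frame to its target frame; composition and application check that labels
chain. The convention set (and enforced in the I/O schemas) is:

* quaternions **w-first** `(w, x, y, z)`, unit norm, canonical sign `w ≥ 0`
  (the double cover is collapsed so round-trips are bit-stable);
* active rotations, right-handed frames;
* millimetres everywhere — all published errors in this domain are in mm.

The **reference-sensor construction** re-expresses each sensor pose as
`invert(reference.pose) ∘ sensor.pose`. Because a common rigid motion of
both poses (the patient's head moving relative to the field generator)
cancels algebraically, every downstream quantity is head-motion invariant;
this is a property test (1,000 random common motions, 1e-9).

Timestamp synchronization tolerance between paired samples defaults to
**5 ms** — half a 40 Hz sample interval. Tracking hardware does not
guarantee simultaneous sampling across sensors; the tolerance is
configurable and the default is a convention, not a measured value.

## Landmark acquisition

A fiducial measurement is the arithmetic mean of the first contiguous run of
`n_samples = 60` probe-tip points (40 Hz, 1.5 s) in which every consecutive
step is at most `max_step_mm = 0.5`. A violating step discards the series
(`restarts` is incremented) — this is what detects probe slippage, which a
plain average would smear into the fiducial.

Two details are underdetermined by the stated rule and were fixed here:

* **The violating sample seeds the new series.** A probe that slipped now
  rests at a new stable position; dropping the sample instead is available
  via `restart_seeds_with_violator=False`.
* **The first sample of a series never restarts** — the rule references a
  predecessor, and a fresh series has none.

The step test uses the 3-D Euclidean distance between consecutive raw
points, the same distance notion as the navigation display. Acquisition
consumes tip points already expressed in the reference frame, so head motion
during the 1.5 s capture is tolerated by construction.

With Gaussian hand tremor of per-axis sigma 0.1 mm, consecutive steps are
Maxwell-distributed with scale σ√2 ≈ 0.14 mm, so a 60-sample series
occasionally (order 10 % per series) trips the 0.5 mm rule by chance; a live
stream simply keeps going, which is why the simulator's probe streams
default to several series' worth of samples.

## Registration

`horn_register` solves the orthogonal Procrustes problem with the unit
quaternion closed form: with centred pairs `p'ᵢ, q'ᵢ` and cross-covariance
`S = Σᵢ p'ᵢ q'ᵢᵀ`, the optimal rotation is the eigenvector of the symmetric
4×4 matrix N(S) with the largest eigenvalue, read as `(w, x, y, z)`; the
translation maps the moving centroid onto the fixed one. Because a unit
quaternion cannot encode a reflection, `det(R) = +1` holds by construction,
including for noisy near-planar fiducial configurations where naive SVD
solutions can flip. Equality with an independent Kabsch/SVD oracle (residual
sum of squares within 1e-9 over 1,000 random instances) is an acceptance
test; the oracle lives only in the test suite. Eigenvalue ties (degenerate
data) resolve through the symmetric eigensolver's deterministic ordering
plus the `w ≥ 0` sign convention. Inputs are rejected as degenerate when
fewer than 3 pairs are given or the second singular value of the centred
moving set falls below 1e-8 of the first (collinearity).

**FRE** defaults to the root-mean-square residual — the standard definition
in the registration-error literature — with a mean-absolute variant behind
`kind="mean"`, because published per-case tables generally cannot
disambiguate the two conventions on physical data.

**TRE** has two contracts: in simulation it is measured against the known
ground-truth transform; in physical/replay mode against a probe-acquired
target position. Exactly one must be supplied.

**Expected TRE** follows Fitzpatrick's first-order prediction
`⟨TRE²(r)⟩ = FLE²/N · (1 + ⅓ Σₖ d²ₖ/f²ₖ)`, with `dₖ` the target's distance
from the k-th principal axis of the fiducial configuration and `fₖ` the RMS
fiducial distance from that axis; for isotropic per-axis noise σ,
`FLE² = 3σ²`. The Monte-Carlo acceptance test (10,000 reps per σ) uses a
tolerance fixed a priori at 4 standard errors + 2 % of the prediction; the
2 % term covers the first-order nature of the approximation and was chosen
from the σ²/f² magnitude of the neglected terms before running the test.

`registration_session` loops acquisition → registration → metrics until an
acceptance policy accepts or attempts run out. **No default threshold is
provided**: acceptable registration error is patient-specific surgical
judgement, so the policy object is a required argument
(`FREThresholdPolicy` is a convenience implementation).

## Navigation

Tracked and planned bone segments are the same virtual object, so
correspondence is **by index** — no nearest-neighbour search, which would
mask rotational error behind locally similar surface patches. The per-point
deviation is the Euclidean distance between matching indices, and the
current cloud is the registered cloud carried along by the sensor's relative
pose change since registration.

The color scale is normative only at its endpoints: deviations below
1.0 mm render exactly dark green, above 4.0 mm exactly dark red. Between
the endpoints the default continuous mode interpolates linearly through
yellow and orange control stops (evenly spaced); a binned mode steps in
1.0 mm bins colored at bin centres. Both are monotone in deviation by
construction (a property test). The intermediate ramp is a display choice,
not a specified quantity — configure `midpoint_colors=()` for a plain
two-color gradient.

A tick recomputes clouds, distances, colors and summary statistics for all
objects; an object whose sensor has not reported within `stale_timeout_s`
(default 0.5 s) is flagged `tracking_lost` and keeps its previous map.
Scene snapshots serialize to JSON with `repr`-exact floats, so re-evaluating
a loaded snapshot reproduces the distance maps bit for bit. The 25 Hz rate
is a soft real-time contract; this library emits data a renderer would
consume and does no rendering itself.

## Simulator: what the stated world is, and is not

The phantom is parametric-synthetic: the residual mandible and graft are
square prisms along a 50 mm circular arc, the graft split into 2–4 straight
segments. Segment 1 carries the reconstructed condyle (CON), the corner
between segments 1 and 2 is the mandibular angle (ANG), and the graft end
adjacent to the residual mandible is the junction (JUN). Anatomical mesh
realism is deliberately absent — it is irrelevant to the mathematics under
test — and STL/PLY import exists for users with real planned surfaces.

Defaults are the stated world of the emulated setup: 60-sample/40 Hz/0.5 mm
acquisition, 25 Hz navigation, 3 graft segments, 5 fiducials per object,
and fiducial localization noise `fle_sigma_mm = 0.3` with small-angle
orientation noise 0.05° per pose sample — the order of magnitude of EMT
accuracy, stated rather than calibrated, since clinical sensor noise specs
for a specific hardware stack are proprietary. Randomness flows from one
global seed through named substreams (per sensor, per landmark) derived via
a stable digest, so a case is byte-identical across runs and processes.

Placement errors are limited to 20 mm / 15°; beyond that the scenario no
longer models a plausible fixation error. A rotational placement error about
the junction reproduces the **leverage effect**: the free-standing condyle
swings through the largest arc (CON > ANG > JUN deviation, with JUN ≈ 0),
verified both in closed form (chord length `2r·sin(θ/2)`) and across random
axes.

What a green simulator-based test does **not** establish: robustness to
metallic field distortion, OR interference, sensor dropout patterns of real
hardware, or soft-tissue effects. None of these are modelled.

## Postoperative accuracy analysis

Outcome-to-plan registration uses artificial landmarks on the residual
mandible only (on real data, the graft's lateral surface is corrupted by
metal-plate imaging artefacts). Per-landmark deviations aggregate to
`Tx_total` (mean over all graft landmarks), `Segment_k` (per fibular
segment, segment 1 condylar, highest number adjacent to the mandible), and
the named points CON/ANG/JUN.

Agreement between the intraoperative navigation measurement and the CBCT
ground truth is reported as Pearson r, an OLS regression, and Bland–Altman
limits of agreement with the conventions **difference = navigation − CBCT**
and **multiplier 1.96**; both were fixed by requiring that the bundled
reference dataset reproduce its published CON and ANG limits, and both are
arguments. Normality of the differences is tested with a one-sample KS test
against a normal with sample-estimated mean/SD; estimated parameters make
the plain KS p-value conservative, and a Lilliefors-corrected variant is
available (`lilliefors=True`).

Summary formatting follows the reference tables' printing: round half away
from zero to 2 decimals, then trim trailing zeros (yielding `2.16`, `1.1`,
`0.2`, `3`); limits of agreement print at 1 decimal and correlations at 2.

### Known discrepancies in the bundled reference summaries

Recomputing the published summary cells from their own printed per-case
rows reproduces 18 of 22 statistics exactly. Four published values are
internally inconsistent with the printed per-case data, each by one unit in
the last printed digit, consistent with the publication having summarized
unrounded internal measurements:

| statistic | published | from per-case rows |
|---|---|---|
| mandible TRE-CONDYLE mean ± SD | 0.91 ± 0.2 | 0.90 ± 0.2 |
| navigation JUN mean ± SD | 2.08 ± 1.41 | 2.08 ± 1.40 |
| JUN Pearson r | 0.44 | 0.43 |
| JUN limits of agreement | −1.5 / 3.5 | −1.5 / 3.4 |

These rows are flagged `exact=0` in `emnav/data/printed_summary.csv`; the
test suite asserts the values the per-case data actually yield, and
`emnav reproduce-tables` reports them as known discrepancies without
failing.

## Numerical choices

* Unit-quaternion tolerance 1e-9; rotation matrices validated orthonormal
  with `det = +1` at 1e-6 on input, produced at ≤ 1e-9.
* Collinearity threshold: second singular value ≤ 1e-8 × first.
* JSON serialization uses `repr`-exact floats (streams, snapshots) so
  round-trips are lossless; reports carry full-precision values alongside
  6-significant-digit mm strings.
* STL vertices deduplicate by bitwise coordinate equality, preserving
  first-occurrence order, so cloud indices are stable across save/load.
* Degenerate statistics inputs raise typed errors rather than returning
  NaN; the one deliberate exception is Bland–Altman on zero-variance
  differences, which returns collapsed limits with a trivially passing
  normality flag.

## Limitations

* No surface-based or ICP registration; fiducial correspondence is by
  declared order.
* No EM field distortion model; the simulator's noise is i.i.d. Gaussian,
  real EMT noise is spatially correlated and pose-dependent.
* The 25 Hz / ≤ 50k-point soft real-time figure is hardware-dependent and
  asserted nowhere; the implementation is vectorized numpy throughout.
* Rendering, GUI and audio feedback are out of scope; the library emits
  colored point lists, summary rows and snapshots for a front end to
  consume.
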