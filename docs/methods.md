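# Methods

## The measurement model

One subject contributes a paired observation: a tumor-draining (left)
inguinal node and the contralateral control (right) node, imaged the same
day. Every per-node quantity is therefore interpreted *relative to the
within-animal control*, which removes the large between-animal variation
in baseline node size and perfusion.

### Morphometry

A node is an ordered stack of simple closed planar contours (mm
coordinates, common in-plane frame) at uniform elevational spacing `h`.

- **Volume** is the plain Cavalieri slab sum `V = h Σ A_k` with shoelace
  slice areas and no end-cap correction. For convex node-like bodies at
  `h = 0.038` mm the discretization error is far below 1% (the midpoint
  error is O(h²) and the lost end slivers contribute ~(h/c)² relative,
  with `c` the elevational semiaxis); tests verify < 1% against analytic
  ellipsoids and < 0.5% change under spacing refinement.
- **Length** is the global maximum in-plane chord across slices, found as
  the convex-hull diameter of the boundary densified to 256 equal
  arc-length points (densification because a sparse polygon need not
  carry its extremal chord on vertices). An exhaustive O(n²) chord search
  is the test oracle; the two agree exactly since the diameter endpoints
  lie on the hull.
- **Width** is measured in the slice that carries the length. Default is
  the perpendicular caliper breadth: the extent between the two
  supporting lines parallel to the length chord, i.e.
  `max_ij |(p_j − p_i)·n̂|` with `n̂ ⊥` the length direction — this is how
  a perpendicular-diameter caliper is placed on a 2D image, and for a 4x1
  rectangle it gives 8/√17 ≈ 1.94 against the diagonal length √17
  (ratio 2.12, non-round). An alternative rule — the longest chord within
  ±5° of perpendicular (`width_method="chord"`) — is exposed; the two
  coincide on ellipses.
- **Roundness** uses the strict inequality `L/W < 2`; a ratio of exactly
  2 is non-round.

### Perfusion

The CEUS enhancement after a bolus is modelled as a lognormal transit:
`I(t) = I₀ + A·f_LN(t − t_a; μ, σ)` for `t > t_a`, the standard
single-pass bolus shape; the vendor software fits a smooth unimodal curve
whose form is undisclosed, and the lognormal is the field's default.
Excluded (motion-corrupted) frames are carried as a mask and never enter
the baseline window, the arrival search, the fit, or the wash-in window.

- **Quality gate**: a curve with more than 40% of frames excluded is
  unusable (inclusive threshold); its node's TTP and WiR become
  unavailable and shrink the scorecard denominator.
- **Baseline and arrival**: baseline is the median of the first 10% of
  usable frames; its sd sets a detection threshold `I₀ + 3·sd`.
  Enhancement is detected at the first run of ≥ 3 consecutive usable
  frames above threshold; because that crossing triggers systematically
  late in noise, arrival is refined by walking back to the start of the
  contiguous run above `I₀ + 1·sd`.
- **Fit**: nonlinear least squares on usable samples with baseline fixed
  and `(t_a, μ, σ, A)` free, `t_a` bounded to (−2.5 s, +0.5 s) around the
  detected arrival (the asymmetry mirrors the late-detection bias). Six
  deterministic method-of-moments starts (three σ values, three arrival
  offsets) guard against local minima; the best converged start wins and
  the fit is deterministic given the curve. Non-convergence marks the
  node unusable rather than aborting a cohort run.
- **TTP** is the mode of the fitted curve relative to arrival,
  `exp(μ − σ²)` in closed form. **WiR** is the OLS slope of enhancement
  over `[t_a, t_peak]`, computed on the fitted curve at the frame times
  by default (`wir_source="raw"` uses the raw usable samples; the two
  agree within ~10% at ≤ 5% noise).
- Identifiability note: the shifted-lognormal family trades arrival
  against shape, so at a fixed 10% peak noise the median TTP recovery
  error is ~7% — an estimation floor, not an optimizer artifact (fits
  started at the truth land in the same place). Across noise levels up to
  10% the median errors are ~2% (TTP) and ~3% (WiR).

### Scoring

Five binary parameters (Volume ratio ≥ 5x, round shape, hilum absent,
TTP lengthened, WiR reduced), one point each, no weighting. A per-subject
"significantly increased/reduced" cannot be a statistical test with one
measurement per node; the package uses a relative-margin rule — TTP
positive iff `left > right·1.2`, WiR positive iff `left < right·0.8`,
margins configurable — and reports the cohort-level paired t-test
separately (it never gates a subject's score). This margin rule is the
single largest interpretive choice in the package: the original
procedure behind the per-animal calls is not documented, and 20% was
fixed a priori as a margin comfortably inside the observed involved/
control contrasts (TTP ratio ~2.1, WiR ratio ~0.25) yet outside typical
repeat-measurement noise. Unavailable parameters shrink the sum-score
denominator (a 3/3 node scores 100%), never impute 0. Percent values are
rounded (half away from zero) only at display time.

### Diagnostics

Evaluation unit: the left node of each subject against its own pathology
label; right nodes are controls and never evaluated. Unavailable
predictions drop out of that parameter's confusion matrix only. All five
metrics carry exact Clopper–Pearson 95% intervals (beta-quantile form;
verified against brute-force inversion of the binomial CDF to 1e−9, and
exact enumerated coverage ≥ 95% over p and n grids). At sum-score
threshold 0 a node is positive iff its percent is strictly positive —
otherwise the threshold-0 row would classify every node positive and
carry no information. Metrics with empty denominators are reported as
undefined, never as 0. The embedded pilot fixture reproduces the
originally reported performance table cell-for-cell except one bound:
the exact upper bound for 3/4 is 0.9937, which rounds to 99, while the
reported table prints 100 in one place and 99 elsewhere for the same
fraction; the replica reports the computed value and flags the cell.

## The synthetic cohort

`CohortSpec` defaults encode the pilot-study conditions: 5 tumor-injected
+ 3 control-injected subjects; involved left/right volume ratio lognormal
around 9.92 (cv 0.2); control volumes 1.44 ± 0.69 mm³ (tumor group) and
1.38 mm³ (control group); shape ratios 1.62 ± 0.18 (involved) vs
2.43 ± 0.17 (uninvolved); hilum lost on involved nodes with probability
1; TTP 4.01 ± 1.26 s (involved) vs 1.93 ± 0.77 s (control). The observed
group means and the mean ratio are not mutually consistent under
independent sampling, so the generator draws the control volume and the
left/right *ratio* (the scored quantity) directly. WiR has no published
absolute scale; the generator uses 6.0 a.u./s (control) vs 1.5
(involved, ratio 0.25) with cv 0.3, and calibrates the bolus amplitude so
that the noiseless fitted-curve wash-in slope equals the drawn WiR
(σ is fixed at 0.5 and μ = ln TTP + σ²). Curves are 1000 frames at
20 Hz with additive Gaussian noise (0.2 a.u.) and 5% of frames excluded
uniformly at random.

Special subjects (when enabled, the last two tumor-group subjects): the
*missing-CEUS* case gets 60% excluded frames on the control node (above
the gate, so TTP/WiR go unavailable), and the *imaging-positive/
pathology-negative* case keeps the involved morphology and long TTP but
draws its WiR at 2x the control mean (a hyperperfused outlier) and a
negative pathology label.

Geometry is an axis-aligned ellipsoid (`c = b`, `a/b` = the drawn L/W)
sliced along the third axis, with a star-shaped wedge notch carved into
the central slices of hilum-visible nodes. All randomness flows from the
single spec seed through a spawned SeedSequence tree (one stream per
subject; within a subject: left geometry, right geometry, left curve,
right curve), so identical specs give byte-identical cohorts.

What the generator does *not* emulate: B-mode speckle or any pixel data,
segmentation error in contour placement, longitudinal tumor growth,
bolus recirculation and wash-out shape deviations, or inter-injection
carryover (two boluses per animal are modelled as independent). Passing
tests therefore demonstrate correctness of the measurement and scoring
chain under the assumed data model, not robustness to segmentation or
acquisition artifacts in real scans.

## Numerical choices and problem sizes

Contours are continuous mm coordinates (no pixel grid), slice indices
0-based. Ellipsoid fixtures use 64-gon contours (inscribed-polygon area
deficit 0.16%, inside the 1% volume budget). Degenerate inputs raise
typed errors (`DegenerateGeometryError`, `NoEnhancementError`,
`DegenerateTestError`, ...) rather than returning sentinel values; the
cohort pipeline degrades per-node only for CEUS quality failures. Tests
and the acceptance script size their simulations to run on a single CPU
in well under their stated budgets: 10-ellipsoid volume grids, 100-curve
Monte-Carlo recovery, and 5 replicate 8-subject cohorts (~10 s total for
the acceptance script).

## Known limitations

- The relative-margin stand-in for per-subject significance is a design
  choice, not a validated decision rule; with one measurement per node
  nothing stronger is identifiable.
- TTP is measured from contrast arrival, not injection; vendor software
  may differ.
- The Cavalieri estimator assumes contours cover the whole node; partial
  stacks underestimate volume silently.
- Sum-score behaviour with more than two unavailable parameters is
  untested territory (the study design never produces it).
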