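# Methods

This note documents the models, defaults and numerical choices behind
`sobplet`, and what the synthetic study conditions do and do not show about
clinical data.

## Pristine Bragg curves

Depth-dose curves in water are analytic, not Monte Carlo. The unstraggled
curve is a Bortfeld-style power law in residual depth `x = R − z`:

    D0(z) ∝ a1 · x^(−0.435) + a2 · x^(0.565),   x > 0

convolved with a Gaussian of width `σ` (range straggling). The `x^(−0.435)`
term is integrable-singular at `x = 0`; each fine-grid cell (0.1 mm) takes
the analytic cell average of the antiderivative rather than a point sample,
which keeps the curve — and everything fitted to it — smooth in `R` to
machine precision. The nominal range `R` is iterated so the distal
80%-of-maximum depth of the blurred curve equals the requested `r80`
exactly.

Defaults, with reasons:

* `σ = 0.01·r80 / 1.68` — makes the distal 80%–20% falloff ≈ 1% of the
  range, the scale observed for clinical double-scattered beams.
* `a1 = 17.93`, `a2 = 0.30` — the `a2/a1` balance fixes the
  entrance-to-peak ratio. `a2` is set so that even the widest modulated
  field delivered here (16 cm) keeps its entrance dose a few percent below
  the 90% level; with a higher entrance the proximal D90 crossing ceases to
  exist and the modulation-width metric degenerates (a failure mode the
  D98-based alternative metric was designed to avoid).
* `fluence_loss_slope = 3·10⁻⁴ /mm` — exponential primary-fluence loss,
  lowering the peak of deep curves relative to the entrance.

## LET model

LET depends on depth only through the residual range `rr = r80 − z`:

    LET(rr) = 2.0 · rr_cm^(−0.435)  keV/µm,  clipped to [0.3, 15]

This follows from the range–energy relation `R ∝ E^1.77` and reproduces
continuous-slowing-down stopping powers within a few tens of percent over
1–30 cm — sufficient, because every analysis here uses LET *contrasts*
between geometries, not absolute values. The cap (15 keV/µm) represents the
track end and persists through the distal falloff, so LET_D rises
monotonically toward and beyond the distal edge. Dose-averaged LET of a
mixture is always the dose-weighted mean `Σ w·d·L / Σ w·d`, both across
wheel steps and across treatment fields.

## Modulation wheel and delivery

A wheel is three stacked plates — stepped low-Z upstream (RSP 1.15), fixed
1 mm aluminium centre (RSP 2.1), stepped lead downstream (RSP 5.0) — plus a
brass block between the thickest and thinnest steps, treated as fully
blocking. Each step's water-equivalent thickness (thickness × RSP, summed
over plates) pulls the pristine peak back relative to the thinnest step.

The generated wheels have 80 steps covering 165 mm of pull-back with
irregular (±30%) increments and angular spans. Two considerations size the
step count: pull-back increments must be comparable to the pristine peak
width (σ ≈ 1.3 mm at 21 cm) or the superposition is a comb rather than a
plateau (<3% ripple requires increments ≲ 2.5 mm); and the irregularity is
what makes the zero-angle identifiable — on a perfectly regular wheel,
shifting the sweep by a whole step reproduces almost the same spread-out
Bragg peak (SOBP).

The hardware's repeated rotate-and-return passes with beam-current
modulation are collapsed into one per-step weight vector: *flat-SOBP
current weight* × *dwell fraction of the step's span inside the swept arc*.
Flat-SOBP weights are a non-negative least-squares fit of the pulled-back
pristine curves to a constant over the plateau interval
`[r80 − P + 2 mm, r80 − 3 mm]` (P = largest swept pull-back); duplicate
pull-backs share their weight equally.

A requested modulation width is translated into a rotation angle by
bisection on the swept pull-back span so the delivered D90-to-D90 width
matches the request (delivered width grows monotonically with the span).
For wide modulations the D90 metric sweeps up the slow proximal build-up
and no span reproduces the request; the nominal (geometric) span is then
used unchanged, mirroring how such fields behave on real delivery systems.

## Zero-angle calibration

The delivered SOBP depends on the requested modulation width *and* on the
zero-angle — the wheel position at beam-on, inside the brass block. The
machine's rotation angle for each delivery is recorded metadata; the
unknown is where the blueprint coordinate system sits relative to the beam.
Calibration therefore replays each recorded rotation at candidate
zero-angles and compares modulation widths. (Re-deriving the rotation at
each candidate would make every candidate inside the brass block deliver
the identical SOBP and the search degenerate.)

* Objective: mean |modulation-width difference| over a wheel's measurement
  set. Range is reported but not optimized — it is pinned by the beam
  energy, not the zero-angle.
* Search: coarse 2° scan over [0°, 360°) starting at 0°, then a grid of
  center ± {0, 0.5, …, 3.5}° (15 candidates, ties toward the smaller
  angle).
* Both measured and simulated curves are smoothed with a 1 mm Gaussian
  before metrics are read off — standard scan preprocessing. Applying the
  identical filter to both sides cancels its (small) bias in the
  differences; without it, point noise on the nearly flat proximal ramp of
  wide-modulation fields moves the D90 crossing by several millimetres.
* Curves are normalized to mean 100 over the SOBP centre ± 25% of the
  requested modulation width before any metric, so everything is invariant
  to detector scale. The centre is anchored to the well-determined distal
  edge: `centre = distal D90 − 0.5 · requested width`.
* The plateau (normalization reference) level of an arbitrary curve is the
  median of all samples within 10% of the maximum — robust to ripple and to
  a small distal crest. D80/D90/D98 are percentages of this level, not of
  the global maximum.

The delivered range is trimmed to the request by adjusting the pristine
`r80` (vendor energy selection), so range differences in validation reflect
only measurement noise. Accuracy goals in the validation report: 1 mm for
range, 2 mm for modulation width.

## Phantoms and 3-D dose

Phantoms are voxelized idealizations (3 mm isotropic by default): an
elliptical soft-tissue body (~360 × 240 mm axial, RSP 1.0, air 0.001),
a near-spherical prostate CTV (r ≈ 22.5 mm) at mid-pelvis, bladder abutting
anterior–superior, a rectal tube abutting posterior, and PTV = CTV expanded
6 mm axially and 8 mm superior–inferior (anisotropic distance transform).
Sizes and positions jitter by a configurable fraction (default 5%);
optional femoral-head inserts at RSP 1.5 are off by default. Dimensions are
typical-adult values chosen for geometric plausibility.

Each field is an idealized broad beam. Radiological depth is the midpoint
rule line integral of RSP upstream of each voxel centre (step = half the
smallest axial spacing). The SOBP is chosen per field to cover the deepest
PTV radiological depth plus 5 mm, with modulation covering the PTV extent
plus 5 mm each side. The aperture is the PTV beam's-eye-view projection
expanded by a 7 mm margin with an error-function rolloff of σ = 5 mm
(penumbra); the lateral bin grid is centred on the beam axis so mirrored
fields are computed on the same lattice and symmetric plans come out
symmetric to numerical precision. Plan dose is rescaled so the median CTV
dose equals the prescription (78 Gy default; only iso-dose levels, not the
prescription, are fixed by the analyses).

## Gamma comparison

Global gamma: dose difference as % of the reference global maximum,
distance-to-agreement in mm, 10% low-dose cutoff. The evaluated grid is
trilinearly subsampled 3× per axis; the displacement search is capped at
3 × DTA and visits offsets in order of increasing distance, stopping when
no voxel's gamma can improve. Tests compare against an exhaustive
fine-grid oracle (independent interpolator, denser lattice, no early stop);
agreement is required within 0.5 percentage points.

## LET volume statistics

`mean LET_D(D_T)` is the arithmetic mean of LET_D over organ voxels with
dose strictly above D_T, on the grid 0–80 Gy in 0.1 Gy steps (801 points).
Empty voxel sets yield NaN, which propagates through ratios and is excluded
threshold-wise from group summaries. Group summaries are per-threshold
means with normal-based 95% intervals (±1.96·sd/√n); a Shapiro–Wilk p-value
per threshold is reported as a normality diagnostic, never as a gate. The
RBE conversion is the marginal linear slope `ΔRBE = c·ΔLET` with
c = 0.04 µm/keV.

## Problem sizes

The packaged analyses run at desk scale: two wheels × 11 delivery-QA
configurations for calibration; 20 wheels for the identifiability study;
matched cohorts of 5 phantoms × 3 field configurations (~340k voxels each)
for the field-angle analysis; 20³ grids for the gamma-oracle comparison.
These sizes were chosen so each analysis still exercises every code path
with clear statistical margins.

## What the synthetic conditions do and do not show

The generator reproduces the *structure* of the study — hidden-parameter
wheels, noisy chamber scans, contoured pelvic anatomy, grouped two-field
plans — but not clinical textures: no CT heterogeneity, organ deformation,
compensators, scattering halo, or Monte Carlo noise. Consequences worth
stating:

* Passing the calibration round trip shows the *procedure* identifies the
  zero-angle under the stated noise; it cannot certify the authors'
  hardware-specific 16.0°/28.0° values.
* The bladder-to-rectum LET_D ratio ordering (posterior > lateral >
  anterior, posterior > 1 and anterior < 1 at 10 Gy) reproduces with wide
  margins, but the *magnitudes* of the contrasts are larger than clinical
  values (median rectum−bladder differences of order 1 keV/µm versus
  ~0.2 keV/µm): idealized broad beams place clean distal edges directly in
  organs that abut the target, with no scatter or anatomy variation to
  dilute them. In this geometry the lateral-opposing group also shows a
  bladder-high ratio (>1), where the clinical cohort sat slightly on the
  rectum-high side; the group remains strictly between the two oblique
  groups, which is the property the analysis relies on.
* Range/modulation accuracy numbers reflect an analytic, noise-free forward
  model; they bound interpolation and search error, not transport physics.

## Known limitations

D90-based modulation width is ill-conditioned for wide fields (high
proximal build-up); the D98-based width `measure_modwidth_d98` is provided
as the better-behaved alternative. The LET model ignores secondary
particles and scores in water only. The broad-beam model has no lateral
scatter coupling, so penumbral LET structure (a known feature of scanned
beams) is out of scope.
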