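# Methods

## The measurement problem

Post-surgical low-grade glioma follow-up compares tumor size across scans
taken every 3–6 months over many years. The reference quantity is the
manually segmented FLAIR volume; the clinical workhorses are linear
measurements. This package operationalizes both on label volumes
(0 background, 1 tumor, 2 resection cavity) and quantifies how well each
linear method reproduces volume-derived growth metrics.

## Linear measurement conventions

All measurements are taken after reorienting the input NIfTI to canonical
RAS axes, so x is transversal, y antero–posterior, z inferior–superior,
and axial slices are constant-z planes.

**Largest residue.** Linear measurements are restricted to the largest
26-connected tumor component. 26-connectivity was chosen because diffuse
FLAIR lesions often hang together through thin infiltrative bridges that
6-connectivity would sever. Exact volume ties (which do not occur on real
data) are broken toward the smaller lexicographic centroid, with a
warning. The segmented volume, by contrast, always counts every residue —
that asymmetry is deliberate and is the source of the "residue effect"
discussed below.

**W and PW.** W is the longest chord between two tumor boundary pixels in
any axial slice whose *crossing fraction* — the fraction of the chord
lying outside tumor tissue — does not exceed 0.10. Crossing counts both
cavity and background pixels: a chord spanning a concavity through normal
brain is penalized exactly like one through the cavity (configurable in
principle, but a hard zero would leave W undefined on annular residues).
If no compliant chord exists in any slice, the minimal-crossing chord is
used and the result flagged `noncompliant`. PW is the longest chord in
W's slice within ±5° of perpendicular to W under the same rule; exact
90° is rarely attainable on a voxel grid, so the tolerance is part of the
definition. The crossing fraction is evaluated at 257 evenly spaced
samples per chord with nearest-neighbor lookup — a fixed count, so the
fraction is a deterministic function of the endpoints alone.

**Caliper convention.** Chord lengths are voxel-center distances plus one
voxel step along the chord direction; D1/D2/D3 are axis-aligned index
extents (max − min + 1 voxels) converted to mm. The +1 compensates the
half-voxel truncation at each end and makes the identities W = PW = D1 =
D2 = D3 hold on a voxelized sphere. On a 1 mm grid each extent carries up
to ±1 voxel of quantization error.

**Performance.** The chord search sorts candidate boundary pairs by
length and evaluates crossing fractions in descending-length chunks,
stopping at the first compliant chord; slices with more than 2000
boundary pixels are uniformly subsampled (an `exact` flag disables both
shortcuts; the test suite's exhaustive oracle runs in exact mode).

## Size estimates and growth metrics

* 1D = W (mm), 2D = W·PW (mm²), 3D = (D1·D2·D3)/2 (mm³, reported in mL).
  For a true ellipsoid the half-product converges to 3/π ≈ 0.955 of the
  true volume — the familiar small systematic underestimate built into
  the halving convention.
* Measurability floors: 10 mm (1D), 100 mm² (2D), 0.5 mL (3D), applied
  at baseline; a follow-up that shrinks below a floor still classifies
  (as non-progression) rather than being dropped, since dropping would
  bias sensitivity.
* MTD.3D = (D1·D2·D3)^(1/3); MTD.V = (2·V)^(1/3) with V in mm³. The two
  coincide exactly when V is the half-product estimate. On a true sphere
  of diameter d, MTD.V = (π/3)^(1/3)·d ≈ 1.0156·d.
* VDE is the ordinary-least-squares slope of MTD (mm) against time
  (years of 365.25 days) over all scans of an eligible window. A window
  is a maximal treatment-free run of scans spanning ≥ 182 days; a scan
  falling exactly on a treatment date closes one segment and opens the
  next, belonging to both. Maximal segments (rather than all qualifying
  scan pairs) avoid double-counting correlated pairs in concordance
  analyses; a pairwise mode exists for per-assessment analyses. Repeat
  surgeries split windows; they do not reset the series.

## Response assessment

The baseline is the first scan between 72 hours and 2 years after
surgery (earlier scans are confounded by post-surgical changes; a later
first scan excludes the series), or the last pre-chemotherapy scan in
chemotherapy-response mode. Progression is a percent change from
baseline at or above the method threshold. Two threshold sets are
encoded:

| method | RANO-derived (inclusive ≥) | LGG-optimized (strict >) |
|--------|---------------------------|--------------------------|
| 1D     | 20%                       | 16%                      |
| 2D     | 25%                       | 33%                      |
| 3D     | 40%                       | 52%                      |
| MTD.3D | 20% (1D rule)             | 15%                      |
| volume | 40%                       | 40% (ground truth rule)  |

The inclusive/strict split mirrors how each set is defined: the
RANO-style criteria read "≥ X% increase", while ROC-derived operating
points read "progression if change > t". The volume rule stays at ≥ 40%
in both modes because the ground-truth definition of progression is
itself RANO-based; this asymmetry is configurable. The RANO 1D rule
applied to MTD.3D in RANO mode is an interpolation (no published MTD
threshold exists for that framework) and is documented as such. The
geometric argument for LGG-specific thresholds is the sphere model: a
20% increase of every diameter implies a 44% area and 72.8% volume
increase, so a 40% volume cut and a 20% diameter cut are mutually
inconsistent.

## Statistics

* Lin's concordance correlation uses population (1/n) variances, the
  classical form; a sample-variance variant is a flag away. Its CI
  applies the Fisher z-transform with Lin's 1989 asymptotic variance.
  Pearson CIs use the standard Fisher z with 1/√(n−3).
* Bland–Altman limits are mean(d) ± 1.96·sd(d) with sample sd.
* Cross-tabulation diagnostics are computed in exact rational arithmetic
  on the 2×2 counts before float conversion; sensitivity/specificity
  carry Clopper–Pearson 95% CIs; any diagnostic whose defining class is
  absent is reported as undefined (None), never silently NaN.
* ROC analysis classifies "progression if change > t" over the distinct
  observed changes, integrates AUC by trapezoid (equal to the normalized
  Mann–Whitney U, ties counting ½), and reports the Youden-J maximizer,
  breaking ties toward higher specificity; a closest-to-corner criterion
  is available. Youden was chosen as the standard operationalization of
  "optimal threshold" in clinical ROC software.
* The ΔMTD concordance sweep recomputes the VDE CCC after discarding
  windows with |ΔMTD| below a cutoff (default grid 0–10 mm in 0.5 mm
  steps, configurable). Note a subtlety verified by simulation: with a
  *fixed* VDE error, truncating small-ΔMTD windows only shrinks signal
  variance and concordance falls. Concordance improves under truncation
  when the VDE error scales inversely with ΔMTD — a fixed MTD
  measurement error divided by the window's change — which is the regime
  the sweep is meant to probe; the property tests encode that model.
* No multiplicity correction is applied anywhere; reported CIs are
  per-comparison.

## Synthetic cohorts

The generator emulates post-surgical LGG geometry: a main residue
modeled as an ellipsoid with a smooth angular irregularity, an optional
spherical resection cavity, 0–3 satellite residues, scan intervals of
90–180 days, and planted growth rates (default uniform 0–8 mm/year,
spanning indolent disease to the anaplastic alarm level; default
image grid 128³ at 1 mm isotropic — fine enough for <3% voxelization
error on 30 mm lesions).

The irregularity is a band-limited random field on the sphere (real
spherical harmonics, degrees 2–4, normalized to unit maximum) applied in
the ellipsoid's normalized coordinates: a point is inside iff
‖ξ‖ ≤ 1 + a·f(ξ̂). Because the field lives in normalized coordinates,
the lesion volume factors as (4/3)π·abc·κ where κ depends only on the
field — computed exactly by Gauss–Legendre × trapezoid quadrature of
(1 + a·f)³ (the integrand is band-limited, so the quadrature is exact to
machine precision). This keeps the ground truth closed-form: scene
volume is V_main + ΣV_satellites − V_cavity, with satellites placed
disjoint and cavities placed (at cohort-generation time) fully enclosed
in the main residue. Satellite placement around the cavity is uniform on
a shell — an arbitrary choice; no published spatial distribution exists
to emulate.

Growth advances the scene so that the scene MTD increases by exactly
VDE·Δt. The cavity does not grow; the required tumor-part scale factor
solves (MTD₀ + v·Δt)³/2 = s·V_parts − V_cavity in closed form. Isotropic
mode scales all semi-axes and satellite offsets by s^(1/3); anisotropic
mode — mimicking growth along white matter tracts — puts the whole
factor on the longest semi-axis. Drawn lesion sizes are capped so the
scene still fits the image at the end of follow-up.

**What the synthetic cohorts do not emulate:** rater variability in the
delineation itself, MRI intensity and partial-volume effects, irregular
infiltrative margins beyond the smooth harmonic perturbation,
non-ellipsoidal topology of real residues, inter-scan head-positioning
differences, and nonlinear (saturating or accelerating) growth. Passing
recovery tests therefore demonstrate correctness of the measurement and
statistics chain under known geometry — not clinical performance. On real
lesions the 3D-vs-volume agreement is markedly looser than on these
phantoms, and sensitivity/specificity values from synthetic cohorts
should not be quoted as expected clinical operating characteristics.

## Validation studies and problem sizes

The recovery studies (also run by `scripts/acceptance.py`) use a
30-patient cohort at 96³ voxels, 1 mm spacing, 4–6 scans per patient,
with bare ellipsoidal residues so that voxelization is the only
measurement noise: the volume-based VDE then recovers planted growth
rates with a mean error well inside ±0.5 mm/year, and the ROC-optimal 3D
threshold lands at the 40% volume-truth boundary within the voxelization
discordance band. A separate planted-threshold study builds a
measurement table whose progressor/non-progressor 3D-change
distributions are separated around a known cutoff and checks the
pipeline recovers it to the exact grid value. The exhaustive
chord-search oracle runs on ≥ 25 randomized ≤ 64³ masks, including
cavity-bearing and C-shaped residues. The voxelization-consistency check
averages six random ellipsoids (semi-axes 10.3–17 mm) per spacing, which
suppresses grid-phase noise in the convergence comparison at 2/1/0.5 mm.

## Known limitations

* W/PW are defined per axial slice; a lesion whose true longest diameter
  is oblique to the axial plane is underestimated, exactly as with
  manual calipers on axial images.
* The crossing rule treats background like cavity; two lobes of one
  connected component separated by a concave notch are measured
  through the notch only if the crossing stays within tolerance.
* The analytic ground-truth volume requires enclosed cavities and
  disjoint satellites; `generate_lesion_mask` itself has no such
  restriction, but ground truth for abutting-cavity scenes would need
  numerical overlap integration.
* Anisotropic growth with satellites keeps satellite centers fixed, so
  very long anisotropic horizons can make the main residue engulf a
  satellite; cohort defaults keep horizons short enough that this does
  not occur.
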