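# Methods

## Constitutive model

The package models passive levator ani tissue as an isotropic,
incompressible, hyperelastic Ogden solid.  The strain-energy density in
principal stretches is

    W = Σᵢ₌₁³ Σⱼ₌₁ᴺ 2 (μⱼ/αⱼ) ((J^(−1/3) λᵢ)^αⱼ − 1) + (K/2)(J − 1)²,

with N = 2 terms by default.  Note the `2 μⱼ/αⱼ` prefactor: this differs
from the classical Ogden convention (`μⱼ/αⱼ`) by a factor of two per shear
modulus.  The convention is kept because the packaged cohort parameter
table is only meaningful under it; `ogden.to_classical` /
`ogden.from_classical` convert (classical μ = 2 × this convention's μ).

On the incompressible uniaxial path (λ₂ = λ₃ = λ₁^(−1/2), J = 1) the
volumetric penalty K contributes nothing and the nominal stress is the
closed form

    P(λ) = Σⱼ 2 μⱼ (λ^(αⱼ−1) − λ^(−αⱼ/2−1)).

This form is verified in the test suite against central finite differences
of W along the uniaxial path (relative agreement ≤ 1e-6 at h = 1e-6 over
100 random stable parameter sets and four stretches).  The small-strain
limits are dP/dλ|₁ = 3 Σⱼ μⱼαⱼ and shear modulus Σⱼ μⱼαⱼ; material
stability requires Σⱼ μⱼαⱼ > 0, which the parameter container enforces
(an explicit opt-out exists for deliberately degenerate states such as the
pure-volumetric-penalty check).

All stresses are MPa (≡ N/mm²), lengths mm, so no unit-conversion
constants appear anywhere.  Physiological passive-muscle moduli here are
kPa-scale (μ of order 1e-3..1e-1 MPa); α₂ of order 10–20 captures the
strong strain-stiffening toe-to-linear transition of muscle in the fiber
direction.

## Tensile-test reduction

Nominal conventions exactly: stress = force / initial cross-section
(width × thickness of the cuboid specimen), strain = elongation / initial
gauge length, stretch λ = 1 + ε.  When a record contains preconditioning
cycles the reducer keeps only the final monotone loading ramp (the longest
suffix with non-decreasing elongation), since it is that ramp's curve that
is fitted.

Rupture truncation: the curve is cut at the first sample from which the
stress never again recovers above (1 − f) × its running maximum, f = 0.2
by default.  Two points about this rule are deliberate design: the drop
fraction is a free parameter because the experiment being emulated only
states that extension continued until rupture, and the "never recovers"
(suffix-maximum) form — rather than flagging the first below-threshold
sample — is what makes the rule robust to isolated noise dips on strongly
stiffening curves, where a few percent force noise at peak dwarfs the
entire toe region.  The rule is idempotent: a truncated curve has no
surviving permanent drop (any candidate would have needed a post-candidate
peak, which would itself have cleared the threshold).

## Parameter identification

The objective is the unweighted half-sum-of-squares stress error
E = ½ Σᵢ (Pᵢ^test − Pᵢ^model)² in MPa², reported alongside
RMSE = sqrt(2E/ND).  Minimisation uses scipy's trust-region-reflective
bounded least squares with an analytic Jacobian, restarted from
`n_multistarts` (default 32) feasible points drawn log-uniformly within the
bounds from a seeded generator.  Draws are sequential from one stream, so
enlarging the multistart count extends rather than reshuffles the start
list — the returned objective is monotone non-increasing in the number of
starts, and the whole fit is bit-reproducible under a fixed seed.

Default bounds are μⱼ ∈ [1e-6, 0.5] MPa and αⱼ ∈ [1e-3, 50]: wide enough to
bracket every value in the packaged cohort table with at least 2× margin,
and all-positive so that every feasible point automatically satisfies
Σ μⱼαⱼ > 0 (no nonlinear constraint needed).  Convergence tolerances
(xtol = ftol = gtol) default to 1e-12; tighter settings make the optimiser
exhaust its evaluation budget in the flat valley near machine-zero cost
without changing the solution.  After fitting, terms are sorted by
ascending α so the low-exponent term is reported first.

Ogden parameters are weakly identifiable from one uniaxial curve: different
(μ, α) combinations produce nearly indistinguishable stresses.  Accordingly
the package's recovery guarantee — exercised in the test suite — is on
*predicted stress* (noiseless end-to-end RMSE ≤ 0.1% of each specimen's
peak stress across all 20 cohort parameter sets), with exact parameter
recovery demanded only for the 1-term case, where the tests corroborate the
optimiser with an independent brute-force oracle (fine α scan with the
exactly minimising μ per candidate, E being quadratic in μ).

Cohort statistics use the arithmetic mean and *population* standard
deviation (divisor n).  That convention is verified in-suite: it is the one
under which the packaged table's α₁ and μ₂ columns reproduce their summary
row to four decimals (0.1803 ± 0.1299 and 0.0216 ± 0.0173 MPa).  The
table's μ₁ and α₂ printed summaries do not recompute from their own columns
(the μ₁ mean/SD appear transposed; the α₂ column mean recomputes to ≈
14.11, not 15.112); the package reports recomputed values and does not
attempt to repair the source table.

## Synthetic cohorts

The generator inverts the reduction: elongation = v·t at v = 6 mm/min on a
uniform grid (10 Hz default, including t = 0), force = P(λ)·A₀ plus
additive Gaussian noise with SD equal to `force_noise_rel` (default 0.5%)
times the peak noiseless force, until a rupture stretch drawn uniformly
from (1.4, 2.0), followed by a three-sample force collapse for the
truncation stage to cut.  Specimen geometry is jittered around 6 × 4 × 10
mm.  Ground truth defaults to the packaged 20-row cohort table (matching
the 20-specimen / 10-animal design of the emulated experiment); a sampled
mode draws rows with replacement.  Per-specimen randomness is spawned from
the cohort seed, so cohorts are reproducible at every level.

The sampling rate, noise model and rupture window are generator choices —
the emulated experiment reports none of them.  What passing tests show is
therefore that the pipeline is internally consistent (generate → reduce →
fit recovers the generating stress law, and fit error grows monotonically
with injected noise); they cannot certify behaviour against features absent
from the forward model: viscoelastic rate dependence, anisotropy,
slippage/toe artefacts, humidity or temperature drift, or non-Gaussian
transducer error.  Twenty triangular preconditioning cycles to 15% strain
can be prepended (off by default); the reducer discards them by
construction.

## Mesh quality auditing

Per tet4 element: aspect ratio = longest edge / smallest of the four
vertex-to-opposite-face altitudes (regular tet: sqrt(3/2); the published
phrase "minimum altitude of the smallest side" is ambiguous and this
standard reading was adopted); six dihedral angles from inward face
normals; scaled Jacobian = min over the four corners of
det(e₁,e₂,e₃)·√2/(|e₁||e₂||e₃|) with corner edge orderings chosen as even
permutations so all four corners score +6V for a positively oriented
element — the √2 normalisation makes the regular tet score exactly 1, which
is what thresholds like 0.2 and 0.7 presuppose.  Degenerate elements yield
+inf aspect ratio and 0 Jacobian rather than exceptions, so audits never
abort on a bad mesh.

Default acceptance thresholds: < 5% of aspect ratios above 3, dihedrals in
[30°, 120°], edges in [1, 3] mm, Jacobians positive and ≥ 0.2 with < 5%
below 0.7.  Percentage criteria are evaluated as integer-count inequalities
(count × 100 < pct × n), so a fixture with exactly 5% violations fails the
strict "< 5%" test with no float drift.  Readers cover legacy ASCII VTK
unstructured grids and Gmsh MSH v2.2 ASCII, tet4 cells only, written
in-package (no general mesh-IO dependency is required for two ASCII
formats); any other cell type is rejected with a clear error.

## Head kinematics

The fetal-head pose (anterior/caudal displacement, internal rotation,
flexion) is piecewise-linearly interpolated in obstetric station (cm
relative to the ischial-spine plane).  Linear progression is a deliberate
simplification of labour kinetics.  The default OP table anchors the
numeric facts of the emulated descent — entry at 45° internal rotation,
completion at station +3, 20° flexion at the midpelvis increasing past the
spine, 100.0 mm total anterior displacement over stations −3..+8 — while
intermediate displacement magnitudes are neutral placeholders flagged in
the data file; the module's contract is the interpolation, not anatomical
truth.  (Descriptions of OP rotation completion differ between station 0
and +3 in the source material; the default follows +3 and the value is
configurable.)  The OA default completes rotation at station 0.  Convention:
anterior = +x, caudal = +z, both mm.

## Pipeline and problem sizes

`run_pipeline` chains simulate → reduce → fit → summarise, writing per-stage
artifacts plus a run log with the package version, seeds and a hash of the
scientific configuration (cohort, fit, rupture fraction — not output
paths), and is byte-reproducible under identical configuration.  Default
problem sizes throughout — 20 specimens, ~500–1700 samples per record at
10 Hz, 32 multistarts — run the full noiseless recovery in well under a
minute on one CPU; the test suite's noise-scaling study drops the sampling
rate to 2 Hz and 4 multistarts, which leaves its monotonicity conclusion
unchanged.

## Known limitations

Uniaxial data with an isotropic model cannot characterise the anisotropic,
fiber-reinforced reality of skeletal muscle; biaxial or cross-fiber
protocols would be needed.  The identification is deterministic point
estimation — no uncertainty quantification beyond cohort SDs.  Clinical-
scale outputs (stress fields over a ~527k-element pelvic mesh, OP/OA stress
ratios) require a contact FEM solve outside this package's scope; the
von Mises utility covers the reporting side of such analyses only.
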