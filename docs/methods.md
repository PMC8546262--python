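# Methods

`lesioncond` simulates, end to end, a proposed experimental protocol for
measuring the electrical conductivity of a chronic stroke lesion *in vivo*:
a weak transcranial current (0.1 mA) is injected through a scalp electrode
pair, the induced scalp potentials are recorded with a high-density EEG
cap, and the lesion conductivity in a patient-specific volume-conductor
model is adjusted until simulated and recorded potentials agree.  Because
no patient MRIs ship with this package, all geometry is synthetic:
concentric-sphere head models with spherical lesion inclusions that span
the clinically reported lesion volume range.

## Volume conductor model

The head is a nested four-compartment conductor: scalp, skull,
cerebrospinal fluid (CSF) and brain, with conductivities
0.414 / 0.016 / 1.71 / 0.37 S/m and zero conductivity outside the scalp.
A lesion is a fifth closed surface strictly inside the brain compartment
whose interior conductivity σ_lesion is the quantity of interest; the
study models it at 0.74, 1.23 and 1.71 S/m, spanning the range between
twice the brain value and CSF.

Synthetic surfaces are geodesic icosahedral spheres with `20 f²` triangles
(default radii 92 / 86 / 80 / 78 mm, adult-head scale, scalp thick enough
to contain the stimulation monopoles).  A request of 3 200 elements per
surface yields f = 13 (3 380 triangles); local 4-way refinement of scalp
and skull within 25 mm of the stimulation electrodes brings those surfaces
to roughly 4 000 elements.  Refinement is conforming (neighbours sharing
split edges are subdivided into two or three triangles) so every surface
remains closed and consistently oriented, and new vertices are re-projected
onto the analytic sphere.

Stimulation electrodes are current monopoles ±I placed 3 mm inside the
scalp along the local inward normal.  Lesion *depth* is the distance from
the area-weighted lesion-surface centroid to the nearest scalp mesh
vertex; *volume* is the divergence-theorem volume of the lesion mesh.

## Boundary-element forward solver

For piecewise-homogeneous conductors the potential satisfies the classical
boundary integral equation

    σ̄(r) φ(r) = g(r) + (1/4π) Σ_j (σ_j⁻ − σ_j⁺) ∮_{S_j} φ(r′) dΩ_r(r′),

with σ̄ the mean of the inside/outside conductivities at the observation
surface, dΩ the solid angle subtended at r, and
g(r) = Σ_k I_k / (4π |r − r_k|) the monopole source term (independent of
any conductivity).  Discretization is linear collocation: potentials are
vertex unknowns interpolated linearly on triangles, and the hat-function
solid-angle integrals are evaluated with de Munck's analytic formulas
(verified against brute-force subdivision quadrature).  Triangles coplanar
with the observation point contribute zero; the self-surface row deficit
against the flat-surface limit 2π is redistributed half to the vertex and
half to its neighbours.  The rank-one constant null space of the operator
is removed by deflation (adding a rank-one term built from vertex areas),
which fixes the gauge to zero area-weighted mean; all recordings are
re-referenced to the nasion electrode so the gauge never matters.

The dense operator is LU-factorized once per geometry.  The dependence on
σ_lesion is an affine update confined to the lesion-vertex columns, so
re-solving for a new lesion conductivity uses the Woodbury identity on the
cached factorization: one triangular solve plus a small (lesion-sized)
dense solve, milliseconds instead of seconds.  This is exact, not an
approximation, and is what makes the 190-pair montage sweep and the
multi-start estimation loop tractable.

An isolated-skull ("isolated problem") treatment turned out to be
unnecessary: with sources in the scalp compartment the plain formulation
already reproduces the analytic four-shell solution well within the
acceptance gates (see below), because scalp potentials are not attenuated
through the skull the way deep-source EEG potentials are.

Electrode potentials are obtained by projecting each electrode to the
closest point on the scalp mesh and interpolating barycentrically
(tolerance 2 mm for nominal layouts, 10 mm for perturbed ones), then
subtracting the nasion value.  Internally everything is SI; geometry I/O
is in millimetres.

## Analytic oracle

The solver is validated against the closed-form Legendre series for a
point current monopole inside a concentric layered sphere with an
insulating exterior.  Per harmonic degree n the radial coefficients solve
a small linear system expressing continuity of potential and radial
current at each interface; per-layer scaling of the radial basis keeps the
system well conditioned to high degree.  A monopole 3 mm under the surface
needs roughly n ≈ 550 for 8-digit convergence ((r₀/R)ⁿ decay with
r₀/R ≈ 0.967), so oracle comparisons use n_max ≈ 1200 and the series
raises an explicit error when the requested tail tolerance (1e-8) is not
reached.  The n = 0 harmonic is omitted: an insulated conductor cannot
carry a net monopole current, and the term cancels exactly when anode and
cathode at equal source radius are superposed — the only configuration the
package uses.  The single-shell limit reproduces the classical
insulated-sphere surface formula to machine precision, and equal-σ
multi-shell models collapse onto it.

Forward solutions are compared with the standard topography/magnitude
split: RDM = ‖ψ̂_ref − ψ̂_test‖ of the normalized vectors and
MAG = ‖test‖/‖ref‖.  At 3 200 requested elements per surface with local
refinement, the four-shell sphere with an antipodal pair gives RDM ≈ 0.013
and |ln MAG| ≈ 0.02, improving to RDM ≈ 0.010 with one extra local
refinement pass.

## Optimal stimulation pair

The lesion is only measurable through electrodes whose potentials it
affects, so the stimulation pair is chosen per lesion model as the pair of
outer-edge electrodes (20 candidates, 190 unordered pairs) maximizing the
RMSD of the 126 remaining electrodes between the model with the lesion and
the same model without it.  The without-lesion solution is obtained from
the with-lesion operator at zero lesion contrast, which is exactly
equivalent and free.  The default scores each pair on per-pair refined
meshes; the coarse mode scores on the unrefined operator (one
factorization, 190 right-hand sides) and refines only the winner — the
ranking agreed between the two modes in every configuration we examined,
and the coarse mode is what the study runner and the acceptance script
use.  Ties break lexicographically.

## Electrode model: 10/5 layout, rotations, subsets

The canonical 128-channel 10/5 layout plus nasion is packaged as a static
table of unit-sphere directions built by the classical proportional-arc
construction (head frame x right, y anterior, z superior; Cz on top;
midline in 10 % steps; a 72°-polar circumferential ring in 18° azimuth
steps; a lower ring on the equator for the 9/10- and I-labelled positions;
interior rows by great-circle interpolation).  Electrodes are placed by
radial projection onto the scalp.  The exact coordinate convention is a
package choice — no standard fixes one — but all
labelled positions used by the method (the 20 outer-edge stimulation
candidates, the 8 vertex-area electrodes, nasion) are present and
geometrically sensible.

Coregistration error is a rigid rotation of the whole measurement layout
(reference included) about a head axis through the head center: "coronal"
about the interaural x axis, "sagittal" about the anterior-posterior y
axis, 0–5°.  Rotated positions are not re-projected (on a sphere head they
remain on the scalp); recording tolerates up to 10 mm off-surface.  Only
measurement electrodes are perturbed — the stimulation monopoles stay at
their true positions.  Subsets of 8/16/32/64/128 electrodes emulate
sparser caps: the 8-subset is the fixed vertex set
{Cz, FCz, CPz, C1, C2, FFC1h, Fz, AFF1}; 16/32/64 are deterministic
farthest-point samples seeded at Cz (uniform coverage, nested prefixes).

## Conductivity estimation

The recorded potentials ψ are the forward solution of the true model
sampled at the (rotated) subset electrodes.  The estimator minimizes
S(σ) = ‖ψ − φ(σ)‖² over the scalar lesion conductivity, with φ evaluated
at the *nominal* electrode positions.  Ten initial values are drawn
uniformly in [0.033, 2] S/m from a caller-provided seed; each start runs a
damped Gauss-Newton iteration (central finite differences with 1 %
relative step; step halved until the residual decreases) until the
relative inter-iterate change drops below 0.1 % or 100 iterations are
reached.  Iterates are clamped to [0.01, 4] S/m; a start that lands on a
guard bound is flagged non-converged, and a result with no converged start
reports that explicitly rather than returning a number.  The best
converged start (smallest residual) is the estimate.  A brute-force grid
scan of the same residual (0.033–2 S/m in 0.005 steps) serves as the
independent cross-check; the two agree to well under 0.5 %.

"Converged" (the 0.1 % stopping rule fired) and "correct" (close to
σ_true) are distinct: with rotated electrodes the iteration often
converges to a biased minimizer; this is the expected behaviour at larger
rotation angles.

## Study runner and problem sizes

`run_study` sweeps lesions × conductivities × (axes × angles) × subsets,
sharing one assembled operator per lesion model and evaluating the 0°
rotation once (it is axis-independent).  Non-converged rows are excluded
from mean ± sd summaries (sample sd) but counted.  Every row derives its
estimation seed from the study seed, and the output records the seed and a
config hash.

Defaults mirror the study conditions: lesion radii
{2.9, 14.2, 23.0, 27.3} mm (≈ 0.1, 12, 51, 85 ml) at a fixed left-temporal
center (−49.5, 0, 0) mm — as superficial as the largest lesion allows
while keeping a 1 mm nesting margin inside the brain surface — lesion
conductivities {0.74, 1.23, 1.71} S/m, angles {0, 0.1, 0.5, 1, 5}°,
subsets {8, 16, 32, 64, 128}, 0.1 mA.  The test-suite and the
reproduction script run on 1 280-element surfaces, where the forward
solver is already well inside its validation gates, so that a full
pair-search-plus-estimation case completes in about two minutes; the
forward-solver validation itself runs at the full 3 200-element density.

## What the synthetic geometry does and does not show

Passing tests demonstrate that the algorithmic chain — forward model,
pair search, perturbation model, estimator — is internally consistent and
recovers the true conductivity exactly when electrode positions are known,
and they reproduce the qualitative robustness trends (error grows with
rotation angle; estimation fails beyond ~1°; larger and more conductive
lesions are easier).  They do not show that a real lesion's conductivity
can be estimated to any particular accuracy: real lesions are irregular,
often touch the cortical surface (the nesting constraint forces a ≥1 mm
brain shell around the synthetic lesion, which weakens the lesion's scalp
signature), heads are not spheres, and EEG background noise is not
modelled.

One consequence of the idealized spherical symmetry deserves note.  The
max-RMSD pair search on a sphere tends to select an *ipsilateral*
anterior-posterior pair (e.g. Fp1 with a temporal electrode over the
lesion), whose scores exceed left-right temporal pairs by only a few
percent.  For such a pair the nasion reference electrode sits in a region
of steep potential gradient, and a small rotation about the interaural
axis displaces the nasion enough to inject a common-mode reference error
comparable to the lesion's entire signature — inflating the estimation
error on that axis (tens of percent at 0.1°) while the orthogonal axis
stays below ~5 %.  With a left-right temporal pair — the configuration one
expects for realistic temporal-lobe lesions, and for which the nasion lies
near the zero-potential midline — both axes stay below 5 % on the same
geometry.  The package implements the selection rule as
specified; the reproduction script therefore reports the worst-axis error
honestly, and users targeting robust in-vivo estimation should treat
reference-electrode placement relative to the stimulation pair as a design
variable.

## Numerical choices

* Linear collocation chosen over constant collocation for accuracy at the
  study's mesh density; validated against the oracle rather than against a
  named reference implementation.
* Deflation scale: mean σ̄; any gauge residue is removed by re-referencing.
* Interpolation tolerances: 2 mm (nominal electrodes), 10 mm (perturbed).
* Gauss-Newton damping: plain halving, at most 10 halvings per step.
* Degenerate pair search (all RMSD ≤ 1e-12 of the scalp RMS, e.g. a
  zero-contrast lesion) raises an explicit error.
* All randomness (initial estimates) flows from explicit seeds; studies
  derive per-row seeds from the study seed.
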