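# Methods

`irisid` estimates the in vivo material parameters of the iris by fitting
an axisymmetric finite-element model of the pressurized anterior segment
to displacement-versus-pressure data of a few points on the iris surface.
This note records the model, its assumptions, the numerical choices, and
what the synthetic-data studies do and do not demonstrate.

## Constitutive model

The iris is a nearly incompressible, isotropic, second-order Ogden solid.
With deviatoric principal stretches λ̄ₐ = J^(−1/3) λₐ and volume ratio J,

    U = Σᵢ 2μᵢ/αᵢ² (λ̄₁^αᵢ + λ̄₂^αᵢ + λ̄₃^αᵢ − 3) + Σᵢ (1/Dᵢ)(J − 1)^(2i)

with stresses in MPa.  Under this prefactor convention the initial shear
modulus is μ₀ = Σμᵢ and the bulk modulus 2/D₁.  D is interpreted as
MPa⁻¹; the working value D = 10⁻⁶ MPa⁻¹ makes the bulk modulus 2×10⁶ MPa,
i.e. κ/μ₀ ≈ 10⁷ for the identified moduli — numerically incompressible
(per-element |J − 1| stays below 10⁻⁷ in practice, comfortably within the
10⁻⁴ contract).  A single D is supplied; higher-order Dᵢ default to it.
The volumetric series is implemented as printed in the material module;
the FE solver's volumetric path uses the leading compliance only, which
at |J − 1| ≤ 10⁻⁴ differs by O(10⁻¹²) relative.

Unknowns of the inverse problem: (μ₁, α₁, μ₂, α₂).  The search restricts
μᵢ > 0, αᵢ > 0, which guarantees U ≥ 0 and a monotone uniaxial response;
the forward evaluator additionally guards α·log λ̄ against overflow and
reports such states as invalid deformations.

**Label switching.** The Ogden series is invariant under permutation of
its (μᵢ, αᵢ) terms, so identified parameter sets are defined only up to
relabelling — exactly the label-switching ambiguity of mixture models.
Identification results are therefore reported in canonical order
(descending μ).  This was fixed before any study was run.

## Forward model

Geometry (configurable; defaults are idealized stand-ins for a rabbit
eye, since no specimen dimensions are available): an annular plate from
pupil margin (r = 2 mm) to iris root (r = 6 mm), 0.4 mm thick, flat
midsurface, optionally bowed and tapered to a sharp tip.  The crystalline
lens is an analytical rigid sphere of radius 6 mm posterior to the iris
with 0.1 mm axial clearance at the pupil-margin radius — in vivo the iris
nearly rests on the lens.  The cornea is replaced by a rigid clamp of the
iris root: with E ≈ 19.8 MPa it is two orders of magnitude stiffer than
the iris, so its compliance contributes negligibly to iris kinematics.

Loading: the anterior–posterior pressure differential (0–25 mmHg;
1 mmHg = 1.33322×10⁻⁴ MPa) acts as a follower load on the current
anterior surface, with the consistent (nonsymmetric) load stiffness.  The
lens translates posteriorly by the change in anterior chamber depth,
linear in the pressure differential; the slope comes from an ordinary
least-squares fit of the ACD series (the reference perfusion series gives
0.00485 mm/mmHg).

Elements: 4-node axisymmetric quadrilaterals, total-Lagrangian, with the
deviatoric response integrated at 2×2 Gauss points and the volumetric
response carried by an element-constant pressure conjugate to the
element-mean volume ratio (perturbed-Lagrangian, statically condensed
each Newton iteration) — the classical hybrid / constant-pressure
element.  This is not a convenience: with κ = 2×10⁶ MPa a pure
displacement penalty diverges, because every finite rotation increment θ
creates O(κθ²) spurious volumetric residuals.  3-node triangles (used
only in tapered-tip meshes) carry one point for both parts.  The default
mesh is 20×3 elements (radial × thickness); its peak displacements agree
with a 40×6 refinement to within 1.3% (the contract is 2%), and the
identification is in any case self-consistent because synthetic data and
re-simulation use the same mesh.

Contact: candidate nodes (posterior surface + pupil margin) against the
analytical sphere, penalty normal force with a C¹-smoothed law of width
10⁻⁴ mm (a hard complementarity law chatters indefinitely on a structure
this compliant), normal intensity 10³·μ₁/thickness; Coulomb friction with
coefficient 0.1 via a tangential penalty (10·μ₁/thickness) around a stick
anchor updated at converged increments.  Equilibrium penetrations are
~10⁻⁵ mm.

Solver: incremental Newton with exact consistent tangents, a residual
line search that prefers the full step, load stepping controlled by a
displacement trust radius (0.2 mm predicted step displacement; the first
step is sized from the linear response — the unloaded iris is an
ultra-compliant plate whose stiffness varies by orders of magnitude over
the search box), step-halving cutbacks, convergence at relative residual
10⁻⁸ plus a 10⁻⁹ bound on the volumetric constraint residual.  Failures
(non-convergence, overflow, displacement beyond 4 mm, iteration budget)
raise a forward-failure error carrying the converged prefix; the inverse
pipeline maps them to a 10⁶ mm² penalty.

Sign conventions: r radial, y axial positive posterior, so pressurization
produces positive u_y; reported "displacement amplitudes" are |u_y|.

## Objective functional

For N tracked points and P pressure levels,

    ε = (1/N) Σₙ Σₚ (u_exp − u_sim)²   [mm²]

— normalization by N only, as is conventional for this functional; a
normalize-by-N·P variant exists but is off by default.  Simulated tracks
are linearly interpolated onto the experimental pressure grid.  ε is
evaluated at the tracked characteristic points only, since experimental
displacements exist nowhere else.

## Optimizer

Multi-island GA: 2 islands × 10 generations × 25 individuals (500
objective evaluations per optimization), crossover rate 1, per-bit
mutation 0.01, migration rate 0.01 at interval 5.  Individuals are
Gray-coded at 16 bits per parameter (quantization ≪ biological scatter;
Gray coding avoids Hamming cliffs), selection is binary tournament with
one elite per island, crossover is single-point on the concatenated
string, and migration moves max(1, round(rate·population)) = 1 best
individual along a ring, replacing the destination's worst — with a
literal reading of rate 0.01 the expected migrant count would be below
one and migration would never happen.  Identical seeds give bit-identical
traces.  On the 4-D sphere benchmark at this budget the median best value
over 20 seeds is ≈1.4×10⁻² (an independently scripted GA of the same
operator family gives ≈1.1×10⁻²), i.e. coordinates are localized to a few
percent of their range — which bounds how finely 500 evaluations can
polish any 4-parameter fit.

Search bounds default to μᵢ ∈ [0.001, 1] MPa, αᵢ ∈ [1, 100], covering
reported iris values with wide margin.

Evaluations are memoized on the Gray-quantized candidate.  The cache
stores simulated tracks, which do not depend on the experimental data, so
a cache may be shared between identifications of the same forward problem
(e.g. stability replicates) without any effect on results.

## Synthetic experiments

The generator fabricates the observables the identification consumes:
it solves the forward model at a known ground truth, samples n points
(default 3) at anterior-surface nodes over the middle segment of the
span (35–65% of the annulus), and applies independent multiplicative
errors u → u(1 + η), η ~ U(−a, +a) per point per nonzero level
(default a = 0, stability studies use a = 0.10).  Multiplicative rather
than additive error was chosen because displacement magnitudes span an
order of magnitude across the pressure range; an additive mode exists.
The ACD series is built from the configured linear relation with the same
noise model on depth changes.  Cohorts draw per-specimen truths from
independent Gaussians at the reference cohort mean ± SD truncated to the
search bounds.  Everything regenerates bit-identically from its seed.

What the generator does *not* emulate: ultrasound image formation,
observer digitization bias, specimen-specific geometry (all synthetic
eyes share the idealized geometry), anisotropy from sphincter/dilator
muscle fibre directions, active muscle tone, and viscoelasticity (the
loading lasts under a minute in the emulated protocol, so an elastic
model is appropriate).  Passing recovery tests therefore demonstrate the
correctness and robustness of the inverse machinery under the model's own
assumptions — not that those assumptions hold for real tissue.

## Identifiability (known limitation)

With exponents as close as α₁ ≈ 54 and α₂ ≈ 48, the two Ogden terms are
nearly redundant over physiological strains: the response is controlled
by μ₀ = μ₁ + μ₂ and an effective stiffening exponent.  The objective has
a long, flat valley along which (μ₁, α₁, μ₂, α₂) trade off at nearly
constant ε.  In noise-free recovery studies the pipeline reproduces the
data to ε ~ 10⁻⁵–10⁻⁶ mm² (far below the 0.0275 mm² reference worst
case) and recovers μ₁ + μ₂ to a couple of percent, while individual μ₁
and α₁ land anywhere along the valley — tens of percent from the truth —
and re-identification under 10% data noise moves them similarly.
Resolving individual terms to ~10% would require polishing ε several
orders of magnitude below the valley's floor curvature, which a
500-evaluation genetic search cannot do.  The one-at-a-time sensitivity
analysis reproduces the expected ordering (α₁ most influential, then μ₁,
then μ₂, then α₂) — single-parameter sensitivity is healthy; it is the
joint directions that are degenerate.  Consumers of identified parameters
should treat μ₁ + μ₂ (and the fitted response curves) as the robust
quantities.

## Study defaults and problem sizes

Synthetic recovery studies use the default geometry (20×3 mesh, 168
degrees of freedom), pressure levels 0–25 mmHg in 5-mmHg steps, 3
characteristic points, 5 GA seeds for recovery medians, and 3 replicates
× 3 master seeds for stability.  The solver runs 5 nominal load
increments (the trust-controlled stepper refines adaptively; converged
states match 10-increment runs to ~10⁻¹⁰ mm).  With the compiled element
kernel a single forward solve takes ~0.1 s and one 500-evaluation
identification about a minute on one CPU; the pure-numpy fallback is
roughly twice as slow.
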