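# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make results deterministic.

## Coordinate model and periodic geometry

All internal lengths are nm, times ps, masses amu, energies kJ/mol; radii
are converted to Å only in printed reports, matching how micellar radii are
conventionally tabulated. Boxes are orthorhombic; triclinic GRO input is
rejected outright rather than silently truncated, since every supported
workflow uses cubic cells.

The minimum-image displacement wraps each component of (b − a) into
(−L/2, L/2]; the half-open boundary (exactly +L/2, never −L/2) makes
behaviour at the exact boundary deterministic. Molecule identity is the GRO
residue id. Atom masses are inferred from the first alphabetic character of
the atom name (H, C, N, O, S, P, F); two-letter elements such as Cl, Na or
Br must carry an explicit mass in the species map — the map supports
per-atom `mass` overrides and a per-residue `"*"` wildcard rule.

Re-assembly of a wrapped micelle ("make whole") references a circular-mean
centre: each axis is mapped to an angle 2πx/L and the vector mean taken, so
the estimate is correct wherever the boundary cuts the cluster, provided
the cluster's true extent stays below the box edge. A first-atom reference
would fail already when the micelle diameter exceeds half the box; the
circular mean tolerates anything that physically fits the cell. All shape
math (COM, inertia, R_g) runs on re-assembled coordinates.

## Shape descriptors

The inertia tensor is the mass-weighted Σᵢ mᵢ[(rᵢ·rᵢ)𝟙 − rᵢrᵢᵀ] about the
selection COM; eigenvalues come from a symmetric eigensolver and are
reported ascending. Eccentricity is e = 1 − I_min/I_mean with I_mean the
arithmetic mean of the three moments: 0 for a sphere, growing with
elongation — the sphere limit fixes this sign convention. R_g is the
mass-weighted RMS distance from the COM, and R_s = √(5/3)·⟨R_g⟩ is the
radius of the homogeneous sphere with the same R_g.

Run averages use every frame by default (configurable burn-in), and an
equilibration diagnostic flags the series when the linear R_g trend over
the last half of the run exceeds twice its standard error. Which atoms
define the micelle is a selection argument; the default in the pipeline is
all atoms of the surfactant species.

## Conformation

For a (head, centre, tail) atom-name triplet present exactly once per
molecule, the head–tail distance is the minimum-image separation and the
bend angle is measured at the centre atom between minimum-image
centre→head and centre→tail vectors. Averaging runs molecules → frame
means → run mean; the headline spread is the SD over frame means (the
convention for run-averaged MD tables), with the SD over per-molecule
means also reported since the two answer different questions.

## Radial distribution functions

Site–site g(r) histograms minimum-image A–B distances, excludes self-pairs
always and same-molecule pairs by default (the inter-molecular convention
for same-species site pairs, switchable), and normalises per frame by
N_A·ρ_B·V_shell with V_shell = (4π/3)[(r+Δ)³ − r³] and ρ_B the bulk number
density of the B selection. When A and B are the same selection the ordered
pair count (each pair twice) is used, consistent with that normalisation.
COM-centred curves use the per-frame micelle COM as a single reference site
(N_A = 1) with the target selection's own density — they are genuine g(r)
curves, not raw density profiles, so a uniform fluid reads 1 at large r.

Default bin width is 0.002 nm — fine enough to resolve peak positions at
the 0.02 nm level — with r_max capped at half the smallest box edge.
Neighbour search uses periodic k-d trees; an O(N²) enumeration oracle in
the tests must agree with the histogram totals exactly.

## Hydrogen bonds

A donor–hydrogen–acceptor triplet is a bond when the minimum-image
donor–acceptor distance is ≤ 0.35 nm and the angle at the donor heavy atom
between donor→H and donor→A is ≤ 30°. Both cutoffs are inclusive, and the
comparisons carry a 1e-12 numeric guard so geometries constructed exactly
on a boundary classify deterministically under floating-point rounding.
The angle-at-donor convention is the standard geometric criterion for
hydrogen-bonded liquids and matches the 30° cutoff semantics of the common
MD analysis tools.

Donor (heavy, hydrogen) pairs and acceptor lists derive from `site_role`
labels in the species map; each hydrogen attaches to the nearest
donor-heavy atom in its own molecule, and a hydrogen further than 0.15 nm
from its heavy atom triggers a topology warning. Same-molecule
donor–acceptor pairs are skipped unless explicitly included. Each
(donor, hydrogen, acceptor) triplet counts once — multiple hydrogens of
one donor reaching the same acceptor are separate entries. Halide anions
act as acceptors only; alkali counter-ions are neither donors nor
acceptors, which is why the table has Surf–Cl and Cl–HBD categories but
none for Na. Detected bonds are binned by unordered species pair into the
fixed category order Surf–Surf, Surf–Ch, Surf–HBD, Surf–Cl, Ch–Ch, Ch–HBD,
Ch–Cl, Cl–HBD, HBD–HBD, other; shares are percentages of the total mean
count, with the grouped surfactant-involving vs DES-only split on top. A
frame set with no bonds yields an all-zero table flagged `empty` rather
than an error.

The production detector prunes candidates with a periodic k-d tree; its
output must be (and is, by test) identical triplet-for-triplet to a brute
force double loop.

## Transport

MSD uses every time origin through the FFT autocorrelation identity
(O(T log T) per particle), equivalent to the direct multiple-origin average
— a configurable origin stride is unnecessary since all origins cost less
than striding a direct sum. Per-particle mode averages single-atom MSDs;
COM mode reduces the selection to its mass-weighted centre first (made
whole at the first frame when only wrapped input exists). Wrapped-only
trajectories are unwrapped by accumulating minimum-image steps; a step
reaching half the box edge between stored frames aborts with an unwrap
error, since larger motions are aliased and undetectable.

β(τ) = d ln MSD/d ln τ by centred finite differences on the log–log
series. The diffusive window is the longest contiguous run with
|β − 1| ≤ 0.1, and must span at least 20% of the available lags, otherwise
the series is flagged non-diffusive; these two thresholds are the package's
choice of standard practice for viscous liquids, where pre-diffusive
plateaus are common. D is the least-squares MSD slope over the window
divided by 6 (any additive offset is absorbed by the intercept), reported
in nm²/ps with ×10⁵ converting to the 10⁻¹¹ m²/s used in solvent tables.
The surfactant convention is D_surf from per-molecule COM MSDs and D_mic
from the single micelle-COM MSD.

The deviation metric for simulated vs experimental observables is
|X_exp − X_sim|/X_exp × 100%.

## Free-energy perturbation

Each window's increment is the forward Zwanzig estimator
−k_BT ln⟨exp(−ΔU/k_BT)⟩ with log-sum-exp stabilisation; the ladder total
is the exact sum of increments, gas → solvated, negative meaning
favourable solvation. Uncertainty is the SD of totals over a seeded
bootstrap (default 200 resamples) that resamples each window
independently. k_B = 0.0083144621 kJ mol⁻¹ K⁻¹. BAR/MBAR are deliberately
out of scope: the estimator ladder abstraction consumes ΔU samples from
any origin and does not care whether electrostatic and van der Waals
decoupling were staged separately. The Zwanzig estimate of a window never
exceeds the window's mean ΔU (Jensen's inequality), and its finite-sample
bias shrinks with the number of samples — both are enforced as tests.

## Synthetic generators — what they emulate and what they do not

All generators are pure functions of (spec, seed) and carry their ground
truth with the data, so no test reads an expected value from the code
under test.

- `build_micelle` places chains on Fibonacci-sphere directions, scaled per
  direction by |(a·u₁, b·u₂, c·u₃)|/mean(a,b,c) to produce an ellipsoidal
  envelope; sites sit at strictly decreasing radial offsets (head
  outermost), with optional Gaussian jitter and an optional kink of a
  prescribed angle at the second site. Jitter is truncated by redraw so
  the heads-outward ordering holds for every seed. Defaults — 60 chains, a
  2.0 nm spherical envelope, a 13-site SDS-like chain (S1 head at 2.0 nm
  down to C12 at 0.68 nm, ~1.3 nm head-to-tail, the scale of
  dodecyl-chain micelles), 0.02 nm jitter — are chosen to resemble a small
  SDS micelle. The builder is a geometric stand-in: no force field, no
  excluded volume, no solvent packing, so it validates geometry pipelines,
  not liquid-state physics.
- `ellipsoid_cloud` samples uniformly in (solid) or on (shell) an
  ellipsoid; solid-mode inertia has the closed form Iₐ = m(b² + c²)/5, so
  a 2:1:1 cloud converges to e = 1 − 0.4/0.8 = 0.5. Shell mode uses
  rejection against the surface-area element, giving uniformity on the
  surface rather than on the parameter sphere.
- `brownian_trajectory` evolves independent Gaussian steps of per-axis
  variance 2·D·dt, storing wrapped frames plus the exact unwrapped paths,
  because wrapping destroys MSD and the unwrapping heuristic is itself
  under test elsewhere.
- `make_hbond_fixture` builds donor/H/acceptor triplets at exactly the
  requested distance and angle, 2 nm apart so no cross-case bond is
  possible, with the expected flag computed from the prescribed geometry.
- `harmonic_fep_samples` draws Boltzmann positions at k(λᵢ) and records
  ΔU = ½(k(λᵢ₊₁) − k(λᵢ))x²; k interpolates as k₀ + λ(k₁ − k₀), exact when
  k₁ = k₀, and the total has the closed form (k_BT/2)·ln(k₁/k₀).

Passing on these fixtures demonstrates that the estimators are correct on
data matching their model assumptions; it says nothing about force-field
quality, sampling adequacy or finite-size effects in real DES
trajectories.

## Problem sizes and tolerances in the validation suite

Stochastic recoveries state their tolerance as a multiple of an estimated
standard error, never an ad-hoc constant: ideal-gas g(r) within 3 Poisson
standard errors of 1 (with the √2 factor from ordered pair counts),
Brownian D within 5% at 1000 particles × 2000 steps (a few slope standard
errors), FEP totals within 3 bootstrap SDs of the closed form. Oracle
agreements are exact (pair counts, hydrogen-bond sets) or at 1e-8
(eccentricity vs the characteristic-polynomial eigensolver). The suite
uses 10⁵-point clouds for closed-form moments and ~10³-particle walks for
transport — sizes at which the analytic standard errors are comfortably
below the stated tolerances.

## Known limitations

- No aggregation-number detection: one predefined micelle per system.
- Orthorhombic boxes only; no XTC/TRR binary readers (the Trajectory
  contract admits them later).
- No hydrogen-bond lifetime/kinetics analysis, no finite-size (Yeh–Hummer)
  diffusion corrections, no Green–Kubo viscosity.
- The COM-RDF normalises with the selected target type's own bulk density;
  if a whole-system density is wanted, rescale by the density ratio.
- Element inference reads one character: two-letter elements need explicit
  masses in the species map.
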