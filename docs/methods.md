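# Methods

This note documents the models implemented by poreflux, their assumptions,
the parameters that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units

Lengths in Å, times in ns, energies in kcal/mol, temperatures in K, charges
in elementary charges, dipoles in Debye (1 e·Å = 4.80320425 D),
permeabilities in cm³·s⁻¹. k_B = R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹. The default
temperature is 310.15 K everywhere.

## Collective-diffusion permeability

The collective coordinate n(t) accumulates, over consecutive frame pairs,
Σᵢ dzᵢ/L for the waters inside the pore cylinder in both frames
(minimum-image dz). At equilibrium n(t) is a driftless random walk;
⟨n(t)²⟩ = 2·D_n·t, and the osmotic permeability is pf = v_w·D_n.

*v_w* defaults to 2.989×10⁻²³ cm³ (18.07 cm³ mol⁻¹ / N_A, liquid water at
~310 K) and is configurable — analyses of coarse or non-water permeants
should supply their own molecular volume.

**Fitting D_n.** The n(t) path is cut into non-overlapping restart segments;
each segment is rebased to its first value; the ensemble MSD over segments is
fitted by ordinary least squares (with intercept) over the first 20 % of the
segment length. Two bias/variance choices are deliberate:

- *Many short segments.* By default one segment per ~50 frames (minimum 10
  segments). Long segments make the MSD tail essentially a handful of
  correlated Brownian excursions and the slope estimate skewed and noisy;
  short restarts trade a little short-time bias for a large variance
  reduction. The acceptance sweep (D_n from 0.1 to 10 ns⁻¹, 20 seeds,
  10⁵ steps) quantifies the residual error of this default.
- *Fitted intercept.* Absorbs short-lag artifacts instead of forcing the
  line through zero.

A negative fitted slope (possible in short, noisy windows) is clamped: pf = 0
with a warning. Per-block permeabilities (the 10 ns replicates used by the
statistics pipeline) rerun the same estimator inside each block.

## Dk barrier correction

Closed channels still show thermal n(t) fluctuations, so raw pf overstates
their permeability. The correction multiplies pf by

    Dk = exp(−ΔG_max / k_B·T),

where ΔG_max is the highest free-energy barrier along the pore section
relative to the bulk zero level. This Boltzmann form is adopted as the
package's definition because it has the three properties the correction
needs: Dk ∈ (0, 1], flat profiles are untouched, and Dk decreases
monotonically with barrier height. ΔG_max is clamped at ≥ 0 so that
free-energy *wells* never inflate pf. Undefined (zero-occupancy) slices
inside the section are a hard error rather than silently skipped, because
they could hide the true barrier.

## Permeation counting

A crossing is an end-to-end passage of the cylinder: enter through one
z-face, leave through the opposite one, never leaving through the radial
wall in between. Implementation details that define the contract:

- Entry/exit faces are decided on the *continuous* (minimum-imaged) z
  displacement between consecutive frames, so periodic wraps are never
  mistaken for crossings.
- A radial exit resets the attempt; a lateral (through-wall) entry leaves
  the particle ineligible until it re-enters through a face.
- Particles already inside at frame 0 are ineligible for their first exit.
- A "slab" mode ignores the radius entirely — appropriate for thin sections
  such as a 5 Å constriction slab where radial gating is not meaningful.
  Strict mode is the default.

Undersampled trajectories (frame spacing comparable to the transit time)
undercount; the counter warns on very short inputs but cannot detect missed
transits.

## Occupancy free-energy profiles

G(z) = −k_B·T·ln(ρ(z)/ρ_bulk) on 0.5 Å slices (configurable) of the pore
cylinder, ρ averaged over frames. The bulk reference is configurable:
everything outside the cylinder (default), the z-slab reservoirs outside the
pore bounds, or an explicit slab. For membrane systems the reservoir option
is the right choice — the membrane interior is inaccessible volume and would
dilute the default estimate. Zero-occupancy slices are masked (NaN + mask),
never ±∞; `barrier()` reports the maximum over defined slices and breaks
ties toward smaller z.

## Binding free energy → K_D

K_D = exp(ΔG/RT) in molar with a 1 M standard state: a favourable (negative)
ΔG gives K_D < 1 M, e.g. −9.22 kcal/mol ↦ ≈3.2×10⁻⁷ M at 310.15 K. Series
summaries report min/mean/max ΔG and their K_D values; note K_D(mean ΔG), not
the mean of per-frame K_D, since the map is convex. ΔG series are inputs
(two-column CSV); contact-based scoring of structures is out of scope.

## Structural observables

- **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å and H–D–A angle ≤ 30°
  (both configurable); hydrogens are attached to donors by topology naming
  (name starts with H, same residue, within 1.25 Å in the first frame).
  These cutoffs are the common geometric default; analyses sensitive to the
  criterion should sweep them.
- **Pore radius**: per slice, min over atoms of (lateral distance to the
  pore axis − vdW radius), clamped at 0, frame-averaged. This is a
  *simplified* inscribed-radius profile, not a sphere-propagation pore
  finder; it is meant for comparisons between conditions, and all outputs
  label it simplified.
- **RDF**: minimum-image distances, normalised by the ideal-gas expectation
  at the target's mean density over the box; self-pairs excluded.
- **Dipole moment**: μ = Σ qᵢ(rᵢ − r_cog) about the selection's center of
  geometry, which keeps non-neutral selections well defined (the reference
  is recorded in the result). The z-angle is reported in [0°, 180°]; the
  C→O vs O→C orientation of a bond vector is the caller's choice of atom
  order in `bond_vector_angle`.
- **Membrane potential**: charge density binned along z, Poisson double
  integration with vacuum permittivity and φ = dφ/dz = 0 at the lower box
  edge (the convention of the standard z-potential tools). Non-neutral
  systems are flagged; the profile then acquires a spurious slope.

## Statistics pipeline

Blocks are contiguous, non-overlapping, anchored at the trajectory start;
a trailing partial block is dropped and logged. A block is functional when
≥ 5 waters crossed the 30 Å section within it (inclusive threshold,
configurable). χ² association is Pearson without continuity correction by
default (Yates optional). Group comparison follows a fixed decision rule:
Shapiro–Wilk per group and Levene across groups, both at α = 0.05; all pass
→ Student's t (2 groups) or one-way ANOVA + Tukey (> 2); otherwise
Mann–Whitney (2) or pairwise Wilcoxon rank-sum with Bonferroni (> 2, the
pairwise reading matching per-pair reporting). Constant groups force the
non-parametric branch; fully identical data short-circuits to p = 1. The
chosen path is recorded in the result. Pre-testing makes the procedure's
level only approximately nominal; measured on 1000-repeat Gaussian and
heavy-tailed nulls it stays within the 99 % binomial band of α = 0.05 (the
acceptance script recomputes this).

Slab-wise dipole correlation assigns frames to 10 Å z-slabs by the ligand's
center-of-geometry z and computes Spearman's rho per slab; slabs with fewer
than 5 frames are reported as "insufficient data" rather than tested.

## Synthetic generator: what it emulates, what it does not

`simulate_pore` runs overdamped-Langevin point particles
(z += −βD·∂U·dt + √(2·D·dt)·ξ per axis, Euler–Maruyama) in a periodic box.
The membrane is an impermeable annulus (pore z-range, lateral distance >
pore radius): moves from a reservoir into the annulus are rejected, and
particles inside the pore reflect off the radial wall — so the only z-flux
path is through the pore, as in a real membrane. One consequence is that
radial *exits* from the pore cannot occur in generated data; the permeation
counter's radial-exit logic is exercised by hand-built fixtures instead.
U(z) acts only inside the pore cylinder; reservoirs are force-free. Initial
positions are drawn from the stationary (Boltzmann) density, so no burn-in
is needed. The integrator rejects dt values whose deterministic drift per
step exceeds the profile grid spacing.

The generator reproduces exactly the two properties the estimators consume —
a known diffusion coefficient and a known stationary density — and nothing
else of real water: no hydrogen-bond network, no single-file correlation
inside narrow pores, no electrostatics, no protein flexibility. Passing
tests therefore validate the *estimators*, not any claim about how close a
Brownian particle is to TIP3P water. Default D = 100 Å²/ns is within a
factor of ~4 of bulk-water self-diffusion at 310 K and irrelevant to
correctness (only recovery of whatever value was imposed is tested).

The end-to-end study (`poreflux.pipeline.two_condition_pore_study`)
simulates four open (flat-profile) and four blocked channels for 50 ns each
(box 25×25×70 Å, pore radius 4 Å over z = 20–50 Å, 250 particles, dt = 1 ps,
frames every 20 ps). The blocked profile is a 3 kcal/mol Gaussian barrier of
σ = 4 Å: the mean-first-passage suppression factor L/∫e^{U/kT}dz ≈ 1/20
separates the per-10 ns transit counts of the two conditions decisively at
the ≥ 5-waters threshold. Problem sizes here (50 ns, 250 particles) are the
package's chosen study scale; they keep block counts high enough that the
classification margin is analytic, not tuned.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- The Euler–Maruyama stationary density carries an O(dt) bias and the hard
  walls an O(√dt) boundary layer; both are far below the tested tolerances
  at the default dt but matter for steep profiles — hence the drift guard.
- The pf estimator assumes equilibrium (no net flux) and uniform frame
  spacing.
- The simplified pore profile underestimates radii in strongly non-convex
  or tilted pores where a sphere-propagation algorithm would find an
  off-axis path.
- Hydrogen attachment by naming convention fails for exotic atom naming;
  donors without resolvable hydrogens are excluded with a warning.
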