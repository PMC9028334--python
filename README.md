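# poreflux

Water-permeation and free-energy analysis of membrane-channel molecular-dynamics
trajectories, built for studies of ligand-modulated aquaporin gating — e.g. how
an amphipathic corticosteroid bound in the extracellular vestibule of an AQP2
monomer throttles its water flux. The package is aimed at computational
biophysicists who have equilibrium MD trajectories of a channel protein and
want the full chain from raw coordinates to a statistical verdict on channel
function.

## What it computes

**Osmotic permeability (pf).** At equilibrium the collective permeation
coordinate of a pore section of length *L*,

    n(t) = Σ_pairs Σ_i dz_i / L   (sum over waters inside the cylinder),

performs a 1-D random walk whose diffusion constant *D_n* (ns⁻¹) gives the
single-channel osmotic permeability

    pf = v_w · D_n,

with *v_w* = 2.989×10⁻²³ cm³ the volume of one water molecule. *D_n* is fitted
as half the slope of ⟨n(t)²⟩ over non-overlapping restart segments
(`CollectiveDiffusionModel.fit()` → `PermeabilityResults`).

**Barrier correction (Dk).** Thermal agitation of waters inside a blocked pore
still produces n(t) fluctuations, so raw pf overstates the permeability of
closed channels. The correction

    Dk = exp(−ΔG_max / k_B T),  pf_corrected = Dk · pf,

uses the highest free-energy barrier ΔG_max along the pore (relative to bulk):
a barrier-free channel is untouched, a k_BT barrier costs a factor 1/e.

**Free-energy (PMF) profile.** From water occupancy in 0.5 Å slices of the
pore cylinder: G(z) = −k_B·T·ln(ρ(z)/ρ_bulk), with a configurable bulk
reference region; zero-occupancy slices are masked, never ±∞.

**Permeation events.** A strict end-to-end state machine: a water must enter
through one z-face of the cylinder and leave through the opposite face while
staying inside the radius; radial exits reset the attempt; z-jumps larger than
half the box are periodic wraps, never crossings.

**Binding energetics.** K_D = exp(ΔG/RT) in molar (1 M standard state),
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, default T = 310.15 K; series summaries pair
min/mean/max ΔG with their dissociation constants.

**Structural observables.** Geometric hydrogen bonds (3.5 Å / 30° default),
minimum group distances, a simplified (slice-wise inscribed-radius) pore
profile, radial distribution functions, dipole moments with z-axis angles, and
membrane-potential profiles by double integration of Poisson's equation.

**Statistics pipeline.** 10 ns block tables per channel; functional-state
calls (≥ 5 end-to-end waters per block); χ² contingency between binary
factors; parametric/non-parametric group comparison with an explicit decision
rule (Shapiro + Levene at α = 0.05 → t-test/ANOVA+Tukey, otherwise
Mann–Whitney / pairwise rank-sum with Bonferroni); and per-10 Å-slab Spearman
correlation of dipole z-angles conditioned on ligand position.

**Synthetic ground truth.** A Brownian-dynamics generator places point
particles around an impermeable membrane slab pierced by a cylindrical pore
with an imposed free-energy profile U(z); stationary occupancy is Boltzmann in
U and the diffusion coefficient is an input, so every estimator above can be
validated against known truth without running MD. Companion generators produce
collective-coordinate paths with known D_n, angle-series pairs with a
controlled Spearman correlation, and charged-slab density profiles with an
analytic potential.

## Worked example

```python
from poreflux import generate_collective_series, pf_from_collective

t, n = generate_collective_series(Dn=1.0, n_frames=100_000, dt=1e-3, seed=42)
res = pf_from_collective((t, n))
print(res.summary())
```

```
Collective-diffusion permeability
============================================
n(t) frames                           100000
Dn (ns^-1)                          0.987396
Dn std err (ns^-1)                    0.0125
v_w (cm^3)                         2.989e-23
pf (cm^3 s^-1)                     2.951e-14
Dk                                         1
pf corrected (cm^3 s^-1)           2.951e-14
============================================
```

The true D_n of 1 ns⁻¹ is recovered within its standard error, and
pf = v_w·D_n lands at 2.95×10⁻¹⁴ cm³·s⁻¹ — the order of magnitude of a single
functional aquaporin channel. Converting a binding free energy to a
dissociation constant:

```sh
$ poreflux kd --dg -9.22
{"dG_kcal_mol": -9.22, "T_K": 310.15, "Kd_M": 3.1855e-07, "Kd_nM": 318.55}
```

A −9.22 kcal/mol interaction at 310.15 K corresponds to a ~319 nM dissociation
constant — a specific, pharmacologically relevant affinity. On real data the
same analyses run from the shell (`poreflux permeation`, `poreflux fep`,
`poreflux hbond`, `poreflux rdf`, `poreflux zpot`, ...) against PDB/GRO
topologies with XTC/DCD trajectories.

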