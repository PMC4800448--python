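# Methods

## Physical model

The package implements the restricted primitive model of an electrolyte
around fixed nanospheres.  All species are charged hard spheres in a
structureless solvent of dielectric constant eps = 78 at T = 25 °C
(Bjerrum length l_B = e^2 / (4 pi eps0 eps k_B T) ≈ 7.19 Å).  Defaults:

| quantity | default | notes |
| --- | --- | --- |
| nanoparticle radius | 10 Å | comparable to the radial radius of duplex nucleic acids |
| nanoparticle charge Z | -24 e | -16…-28 e studied for charge-density trends |
| ion radius | 2 Å | equal for all mobile species |
| salt | 1:1 or 2:2, 10^-4 – 0.5 mol/L | counterions identical to the salt cation |
| temperature | 298.15 K | target temperature of the annealing schedule |

Two, three or four nanoparticles are held on a line, an equilateral
triangle, or a regular tetrahedron with every centre-to-centre distance
equal to the separation x, so all particles are geometrically equivalent.
Counterions are added so the cell is exactly electroneutral.

Pair energies are bare Coulomb terms q_i q_j l_B / r in k_B T plus a
hard-core exclusion; nanoparticles carry a single central point charge,
which is exact outside the hard core in a uniform dielectric.  Periodic
boundaries use the minimum-image convention without Ewald summation: the
cubic cell edge is at least eight Debye lengths (and at least the geometric
extent of the assembly at the reference separation plus four ion diameters
per side), so interactions are screened well inside half a box.  At
extremely low salt the 8 kappa^-1 rule is capped at a configurable 1300 Å.

## Free energies by thermodynamic integration

The coupling variable is the inverse temperature: lam = beta/beta_T scales
the electrostatic energy in the Metropolis acceptance rule while hard cores
are enforced at every lam.  Integrating the canonical mean energy,

    beta_T G_ex = Integral_0^(beta_T) <U>_beta d(beta),

is discretized as a sum over 20 equal intervals of the lam grid with
midpoint values interpolated from the 21 endpoint samples (the trapezoidal
rule).  The lam = 0 reference is therefore the hard-sphere fluid, whose
configurational free energy is independent of the nanoparticle separation
for non-overlapping spheres; it cancels exactly in the PMF

    Delta G_x = G_ex(x) - G_ex(x_ref),   x_ref = 40 Å,

and is never computed.  On a constant integrand the 20-interval sum is
exact, which the ion-free closed-form oracle exercises.

### Sampling

Single-ion moves are uniform displacements in a cube whose half-width
adapts toward 30-50% acceptance during the burn-in of each lam point and is
frozen afterwards.  A fraction (default 15%) of proposals instead relocate
the chosen ion uniformly in the cell.  These "jump" proposals are symmetric,
so the Metropolis rule is unchanged, and they shorten the autocorrelation
time dramatically at low lam, where the energy fluctuations that dominate
the TI error budget would otherwise decorrelate only diffusively.  In
desk-scale tests they reduce the per-seed PMF standard error roughly
threefold at equal cost.

For dilute systems, where binding a counterion from a several-hundred-Å box
is a rare event under either move type, an optional third proposal
("targeted insertion", off by default) places the ion uniformly inside a
ball of radius R = nanoparticle radius + 10 Å around a uniformly chosen
nanoparticle.  This proposal is asymmetric, so the acceptance rule carries
the exact Metropolis-Hastings density ratio built from all three mixture
components (the local and jump components are symmetric; the targeted
density at a point is proportional to the number of balls containing it).
Correctness is checked against numerical quadrature on a one-ion system.
Binding/unbinding exchange then happens at the targeted-proposal rate
instead of the diffusive one; the desk-scale 2:2 comparisons use a 20-30%
targeted fraction and reach the same precision in roughly half the steps,
while the extremely dilute conditions change from kinetically trapped to
equilibrated.

The chain at each lam runs until the cumulative post-burn-in mean changes
by at most a threshold over a 10^4-step window (0.005 k_BT for 1:1 salt,
0.001 k_BT for 2:2 salt by default), with a hard step cap; hitting the cap
flags the point rather than failing the run.  Standard errors per lam point
come from batch means over the 10^4-step windows; the TI error is propagated
through the trapezoid weights.

PMF scans reuse one cell (sized at x_ref) for every separation, and each
replicate seed drives the chains at x and at x_ref with the same underlying
random stream (common random numbers), so part of the low-lam noise cancels
in the difference.  Replicate scatter across >= 2 seeds provides the quoted
PMF uncertainty; with a single seed the propagated TI error is used.

Annealing chains the final configuration at each lam into the next higher
lam, following the simulated-annealing protocol: equilibration at high
temperature is cheap and each subsequent point starts close to equilibrium.

### Non-additivity statistics

The additive four-body prediction multiplies the direct two-body PMF by the
six equivalent tetrahedron pairs (or the three-body PMF by two).  Reported
statistics are

* ddG(x) = Delta G_4(x) - 6 Delta G_2(x) at x = 25 Å,
* percent overestimation (6 Delta G_2 - Delta G_4)/|Delta G_4| x 100 — the
  direct four-body value is used as the denominator, a choice recorded in
  the output metadata since the convention is not unique (suppressed when
  the four-body PMF is within noise of zero),
* the signed gap between curve minima for attractive (2:2) conditions,
  taken on seed-averaged curves over a small separation grid.

## Ion-binding analysis

The net charge fraction Q(r) sums the signed charges of all ions within r
of any nanoparticle centre (union convention — an ion inside two spheres
counts once; the convention only matters for r > x/2) and normalises by
M |Z|.  The binding shell is 8 Å from the nanoparticle surface (two ion
layers, r = 18 Å from the centre).  Concentration maps are frame-averaged
voxel histograms in mol/L; bridge profiles resolve the cation concentration
in a thin slab bisecting a nanoparticle pair along the in-plane direction
toward the remaining nanoparticles.  Analysis frames are taken every 10^3
steps at the target temperature to decorrelate.

## Nonlinear Poisson-Boltzmann solver

The mean-field comparison solves

    lap(phi) = -4 pi l_B [ n_f + sum_a z_a n_a0 exp(-z_a phi) ]

for the reduced potential phi = e psi / k_B T on uniform grids, with the
Boltzmann source restricted outside an exclusion layer of one ion radius
around each nanoparticle and point charges spread to the eight surrounding
nodes by trilinear weights (charge conserved to 10^-6 e).  Nonlinear SOR
with one Newton update per node per sweep (omega = 1.9, reduced
automatically if updates grow; per-update clamp of 1 k_BT/e guards the
exponential) iterates until the largest update falls below 1e-4 k_BT/e.

Three-level focusing: the outer grid reaches six Debye lengths beyond the
nanoparticle surfaces with superposed single-sphere Debye-Hückel boundary
values (the standard far-field closure; bare Coulomb when no salt); child
grids take Dirichlet boundaries interpolated from their parent.  The
desk-scale default focuses onto (125, 120, 120) Å at 1.0 Å and
(75, 70, 70) Å at 0.5 Å per node; `paper_protocol()` restores the
full-resolution 0.5 / 0.25 Å grids.

The electrostatic free energy uses the charging form
G = U_M + 1/2 sum rho_f (psi - psi'), where psi' solves the identical grid
problem with no mobile ions, so the grid self-energy of the mapped point
charges cancels node by node; U_M is the bare nanoparticle Coulomb energy.
This expression is a reconstruction from the solver's definitions of U_M
and psi' (the source presentation of the full formula is not available) and
is validated against the Debye-Hückel charging closed form
-Z^2 l_B kappa / (2 (1 + kappa a)) to 3% for weak charges.

## What the tests do and do not show

The synthetic systems used as oracles (ion-free sphere pairs, an enumerable
two-ion lattice toy, a weakly charged sphere) have exact reference values
and validate the machinery, not the science.  The desk-scale stochastic
checks reproduce the many-body trends — additive overestimation of the
repulsive PMF at 0.05 M 1:1 salt, the weakly "weakened" attraction at
0.01 M 2:2 salt, concentration ordering of the bound-ion fraction — at
reduced sampling lengths:

* convergence thresholds for the desk-scale 1:1 comparisons are relaxed to
  0.009-0.012 k_BT with per-lam caps of 1.2-1.5 x 10^6 steps;
* the 2:2 minimum-gap comparison is evaluated at x = 25 Å, where a
  23-26 Å scan places the minimum of both the direct four-body curve and
  the additive pair prediction, against the 40 Å reference (threshold
  0.001 k_BT, caps of 3 x 10^6 steps, a 20% targeted-insertion fraction,
  and six seeds on the pair system, whose error enters the gap six-fold);
* the scaled-down low-salt 2:2 sign check runs in a 930 Å cell rather than
  the 8-Debye-length (~1200 Å) box, with a 30% targeted-insertion
  fraction so counterion binding equilibrates.

Statistical tolerances in the tests (three combined standard errors or 15%,
whichever is looser) reflect that reduced effort.  Full-strength
convergence (0.005/0.001 k_BT thresholds, unlimited steps, the
full-resolution PB grids) is a configuration change, not a code change.

Real colloidal or nucleic-acid systems differ from the model in known ways:
no dielectric discontinuity at the particle surface, no ion-specific or
soft-core interactions, rigid symmetric geometries only, and a 40 Å outer
reference that is not asymptotically far at very low salt.

## Numerical choices and degenerate inputs

* Energies are reported in k_B T at 298.15 K throughout; lam rescales the
  acceptance rule only.
* Overlapping configurations are rejected outright; energy sums never
  contain infinities.
* Zero salt concentration makes the Debye length infinite: cell sizing then
  falls back to the geometric bound, and the PB outer boundary uses the
  bare Coulomb superposition.
* An uncharged nanoparticle set makes Q(r) undefined (zero normalisation);
  the binding analysis raises instead of returning NaN.
* Counterion counts must be integral (|M Z| divisible by the cation
  valence); violations are errors at population time.
* The cumulative-mean convergence rule is a stopping heuristic, not an
  error bound; flagged (capped) lam points propagate a warning and the TI
  sum can be forced or refused via `require_converged`.
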