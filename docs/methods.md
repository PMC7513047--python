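# Methods

## Model

The system is a Kremer–Grest bead–spring melt of `M` monodisperse, fully
flexible chains of `N = 40` monomers at fixed number density
`rho = 0.85 sigma^-3` in a fully periodic orthorhombic box.  All quantities
are in reduced Lennard-Jones units (`sigma`, `epsilon`,
`tau = sigma sqrt(m/epsilon)`, `m = 1`, `k_B = 1`).

Nonbonded monomers interact through the purely repulsive shifted-truncated
Lennard-Jones (WCA) potential

    U_LJ(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ] + eps,   r < rc = 2^(1/6) sigma,

zero beyond the cutoff; bonded neighbors additionally feel the FENE spring

    U_FENE(r) = -(K rmax^2 / 2) ln[ 1 - (r/rmax)^2 ],  K = 30 eps/sigma^2,  rmax = 1.5 sigma.

Half the chains ("hot", the scalar-active species) couple to a Langevin
thermostat at `Th`, the other half ("cold") at `Tc = 1.0`; both use the same
friction `zeta = 1.5 tau^-1`.  The two-temperature drive models activity as
stronger-than-thermal fluctuations: above a critical temperature asymmetry
the blend phase-separates into a hot (dilute) and a cold (dense) phase with
two interfaces per box.

The natural control variable is not `Th` but the measured asymmetry

    chi = (Theff - Tceff) / Tceff,

where `Theff`/`Tceff` are one third of the mean squared velocity of each
species; inter-species heat flow keeps `Tc < Tceff <= Theff < Th`.  chi is
largely insensitive to the choice of friction; it does depend on system size
in the separated state (the interface occupies a finite volume fraction), so
chi is always *measured*, never assumed.

## Integration

Langevin dynamics is discretized with the Grønbech-Jensen–Farago (GJF)
scheme at `dt = 0.005 tau`.  GJF reduces exactly to velocity Verlet at
`zeta = 0` and gives the exact Maxwell stationary velocity distribution for
a free particle at any time step; the per-species target temperature enters
only through the noise amplitude `sqrt(2 zeta T_i dt)`.

Neighbor search uses a linked-cell build of a Verlet pair list with cutoff
`rc + 0.3 sigma`, rebuilt whenever any particle has moved more than half the
skin since the last build.  Gaussian noise is drawn in fixed 200-step chunks
from a single master PCG64 generator seeded by the run seed, so trajectories
are bitwise reproducible for a given seed.  (A counter-based per-particle
stream would buy thread-order independence, but the kernels here are
single-threaded and the single master stream keeps them simple.)

Initial states are built as random walks with 0.97-sigma bonds, pushed off
with a ramped soft cosine pair potential until no pair lies below
0.9 sigma, then equilibrated with the full force field at `T = 1` with both
thermostats cold.  Even-index chains are labeled hot — a reproducible 50/50
split.

## Profiles and the order parameter

Separated snapshots are aligned by (i) picking the interface normal as the
box axis with the largest first circular harmonic of the hot-monomer
distribution, rotated onto z, and (ii) shifting each snapshot so the
circular-mean hot position sits at `Lz/2`.  Snapshots whose harmonic
amplitude falls below 0.2 carry no detectable interface and are skipped.

Slab observables (default 100 slabs across `Lz`) are averaged per snapshot
and then over snapshots; with this convention the mean-square-velocity
profile equals the composition-weighted effective-temperature profile
`<Theff phi_h + Tceff (1 - phi_h)>` identically, and the difference between
that and the factorized form `<Theff><phi_h> + <Tceff>(1 - <phi_h>)`
isolates the composition–velocity correlation.

The demixing order parameter is `Phi = 2x - 1`, where `x` is the
like-species fraction among *inter-chain* neighbors within `rc`, averaged
over monomers with at least one such neighbor (monomer-weighted; the
contact-weighted variant differs negligibly in dense melts).

The slab pressure tensor's kinetic part defaults to the per-component form
`rho(z) <v_i v_j>` (diagonal `rho T` for Maxwell velocities); a
strict-as-printed mode divides by 3.  The virial part assigns each pair
whose minimum-image segment crosses a slab mid-plane the dyad
`(r x F)/(2A)` for that slab.  This printed convention differs from
segment-weighted Irving–Kirkwood normalization by a factor of order
`|r_z|/Delta-z`; it is retained as a *diagnostic* (the tension integral
`gamma = 1/2 int (p_N - p_T) dz` is reported with an uncertainty but is too
noisy to be a converged estimator, and no quantitative claim rests on it).

## Critical-point estimators

* **Entropy production.**  `S/3zeta = Theff/Th + Tceff/Tc - 2` per hot
  particle; zero iff both species sit at their reservoir temperatures,
  positive when heat flows down-gradient.  Its growth is quadratic in chi in
  the mixed regime and plateaus once the interface develops; chi* is the
  intersection of an origin-constrained quadratic fit below a scanned split
  point with a constant above it.  Splits whose summed squared error is
  within a factor two of the best split are averaged (spread = quoted
  uncertainty); if a single quadratic explains all the data at least as well
  as any split, there is no plateau and the estimator refuses.

* **Sub-box cumulants.**  `Un = <m4>/<m2>^2` with `m4`, `m2` the fourth and
  second central moments of hot-monomer densities in `n^3` equal sub-boxes
  about the global mean hot density (0.425 sigma^-3 at the standard
  composition).  Wrapped coordinates are used without alignment — sub-box
  statistics must not depend on where the interface sits.  Gaussian
  fluctuations give 3, a symmetric two-state distribution 1; curves for
  different `n` cross near the critical point (mean-field reference level
  `[Gamma(1/4)]^4/(8 pi^2) ~ 2.188`).  Crossings are located by linear
  interpolation on the shared chi grid; mean and standard deviation over
  curve pairs are the estimate and error.  No automatic sub-box selection is
  attempted: all requested `n` are reported.

* **Binodal power law.**  Plateau values (slabs farther than 1.5 interfacial
  widths from both mid-level crossings of the profile) give the two branches
  of the phase diagram; the density difference is fitted to
  `Delta-rho = A (chi - chi*)^beta'` by weighted least squares in log–log
  space, with any subset of the parameters fixable.  When free, chi* is
  parametrized logistically into `(0, min chi)`: the asymmetry is
  nonnegative, and without the lower bound the three-parameter model has a
  runaway ridge (`chi* -> -inf` with growing beta') that additive noise of
  0.02 sigma^-3 excites in a noticeable fraction of replicates.  Nonpositive
  noisy observations are dropped before taking logs.

## Capillary-wave analysis

The two interfaces of an aligned snapshot are resolved by splitting the box
at the hot-phase center.  On an `nB x nB` block grid the interface height in
each block is the linearly interpolated zero crossing of the hot-minus-cold
slab density difference nearest the whole-box interface position (default
slab resolution ~1 sigma; much finer slabs make block-level sign changes
noise-dominated).  A snapshot with any crossing-free block is rejected for
that `nB`; a snapshot without two-phase structure (hot-monomer harmonic
amplitude < 0.2) is rejected outright.

Heights are expanded as `h = sum A cos(q r) + B sin(q r)` over *unique*
half-plane modes (one entry per +-k pair), with phases referenced to block
centers and `C^2 = (A^2 + B^2)/2`.  With this bookkeeping the spatial
variance of a height field equals `sum C^2` exactly (Parseval), and the
equilibrium-like spectrum reads `L^2 <C^2> = 2/(gamma beta q^2)`; note that
conventions which enumerate +k and -k separately state the same identities
with an extra factor of two.  Modes with a Nyquist component are excluded
from spectra and generators (they lack a sine partner or alias it) but
retained in the Parseval sum.

The stiffness `gamma beta` comes from (i) a weighted one-parameter fit of
the spectrum prefactor, optionally excluding the slowest (0,1)/(1,0) modes
whose correlation time `tau_c` is measured from the exponential decay of the
normalized autocovariance of `C_01`, and (ii) the growth of the apparent
squared width with block resolution, `w^2 = ln(nB/c)/(2 pi gamma beta)`,
fitted two-parameter over `nB` in [5, 9] by default.  A further chi*
estimate is the root of a weighted linear fit of `gamma beta` against
`sqrt(chi)`; widths are also reported as `w sqrt(chi)` to exhibit the
`w ~ chi^(-1/2)` regime.

## Synthetic generators

The fixtures module makes every analysis operation testable without MD:

* two-phase particle slabs with tanh-smoothed density/composition
  crossovers, per-phase species purity, per-species Maxwell temperatures and
  optional cosine corrugation of the dividing surfaces (defaults: phase
  densities 0.92/0.78 sigma^-3 and species temperatures 1.2/2.6, the
  separated steady state at `Th = 3`); chains are label-topological blocks of
  40, sufficient for every analysis that never evaluates bonded forces;
* Gaussian height-field ensembles with `Var A = Var B = 2/(gamma beta L^2 q^2)`
  per mode, the exact sampling law of the capillary spectrum;
* stationary AR(1) mode series with autocorrelation `exp(-spacing/tau_c)`;
* critical-curve families with the published study conditions as defaults:
  binodal law `(A, chi*, beta') = (0.143 sigma^-3, 0.36, 0.47)` with
  0.02 sigma^-3 Gaussian noise, entropy-production crossover at chi* = 0.43,
  cumulant families pinned to cross at level ~2.0.

What the generators deliberately do not emulate: chain connectivity in the
mechanical sense, the interfacial velocity anisotropy (a simulator-only
observable), capillary-mode temporal correlations inside one ensemble
(fields are independent draws), and bubbles/overhangs that violate the
small-gradient assumption.  Passing round-trip tests on these fixtures
therefore validates the estimators, not the molecular dynamics; the
simulator itself is validated separately (force/energy oracles, Maxwell and
equipartition checks, and the scaled-down separation run below).

## Problem sizes and numerical choices

Published campaigns at this model's full scale use M = 5000 chains and
2x10^6 tau of steady state; the package's own test battery runs desk-scale
versions: fixture ensembles of ~400 snapshots (enough for ~2% stiffness
recovery), Monte-Carlo batteries of 100-200 replicates, and a scaled-down
separation demonstration with M = 64 chains (2560 monomers) at `Th = 3.0`,
`zeta = 1.5` in a 1:1:3 box.

At 64 chains the box edge is only about three gyration radii and the mixed
state sits barely above the critical asymmetry (chi ~ 0.6), so spontaneous
nucleation of the slab morphology is far beyond desk timescales: driven
runs from the well-mixed melt at two box aspects and several seeds stay
mixed (Phi < 0.15) through 6,000-12,000 tau.  The demonstration therefore
uses the standard direct-coexistence protocol: the equilibrated mixed melt
is given the slab composition (the 32 chains nearest the box center along z
are labeled hot), relaxed under the drive for 1,500 tau and then sampled
for 1,000 tau.  The physics demonstrated is that the two-temperature drive
*sustains* phase separation against mixing entropy — sustained Phi ~ 0.6,
chi jumping to its separated-branch value (~1.3 versus ~0.6 when mixed,
mirroring the system-size dependence of chi in the separated state),
effective-temperature ordering Tc < Tceff < Theff < Th, positive entropy
production, and a two-plateau density profile.  In a 1:1:2 box the same
protocol decays toward a partially mixed state (Phi ~ 0.3): the wider
interfaces occupy too much of the shorter box, which is why the
demonstration uses the 1:1:3 geometry.  Quantitative phase-diagram values
are out of reach at this size.

Other numerical choices: tie-breaks in the interface extraction pick the
zero crossing nearest the whole-box interface; degenerate inputs (mixed
states, plateau-free profiles, non-crossing cumulant pairs, zero-variance
series) raise typed errors rather than returning numbers; all estimators
use plain linear interpolation or (weighted) least squares — no splines or
smoothing — so results are exactly reproducible from the data and seed.

## Known limitations

* The virial slab profile follows the printed crossing-pair convention (see
  above); absolute values of the full pressure profile and the tension
  integral are diagnostics only.
* `Phi` depends weakly on the neighborhood radius; the interaction cutoff
  `rc` is used, with monomers lacking inter-chain neighbors excluded.
* The width- and spectrum-route stiffnesses agree on synthetic q^-2
  ensembles by construction; on real trajectories the two routes are known
  to differ systematically, and no attempt is made to reconcile them.
* No grand-canonical or field-mixing universality analysis, no vectorial
  (self-propelled) activity, no NPT, no GPU kernels.
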