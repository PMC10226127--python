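# Methods

This note documents the models, estimators and numerical choices behind
`condrheo`, in the spirit of a simulation package's model documentation: what
is computed, under which assumptions, with which defaults, and what the
bundled synthetic tests do and do not demonstrate.

## Coarse-grained condensate models

**Generic IDP model.** Each intrinsically disordered protein (IDP) is a
flexible bead-spring chain of N = 50 beads (one bead per group of residues).
Nonbonded beads attract through a Lennard-Jones potential
U = 4eps[(sigma/r)^12 - (sigma/r)^6] whose force is truncated to zero at
r_c = 3 sigma (no energy shift: the energy is only a diagnostic, the
dynamics are driven by forces).  Consecutive beads are joined by a stiff
harmonic bond U = K(r - r0)^2 with K = 7.5e4 eps/sigma^2 and r0 = 1 sigma.
The convention without the 1/2 prefactor follows the major MD engines'
`bond_style harmonic`; at this stiffness observables are insensitive to the
convention, and the single switch `potentials.BOND_HALF_PREFACTOR`
selects the alternative.  Directly bonded pairs are excluded from nonbonded
interactions.  The solvent is implicit: the dilute phase is a vapor.
Everything is expressed in reduced LJ units (T* = kB T / eps,
rho* = N sigma^3 / V, tau = sigma sqrt(m/eps), kB = 1).

**Sequence-dependent residue model.** For residue-resolution work the
engine accepts a per-residue parameter table (diameter, hydropathy lambda,
charge, mass) driving an Ashbaugh-Hatch short-range potential (an LJ whose
attractive tail is scaled by lambda, interpolating from a WCA sphere at
lambda = 0 to full LJ at lambda = 1) plus a Yukawa/Debye-Hueckel screened
electrostatic term.  Cross interactions use arithmetic-mean diameters with
arithmetic (default) or geometric hydropathy mixing.  The package ships only
a clearly labelled non-physical toy table for tests; published force-field
tables are read from CSV/TSV.

## MD engine

Velocity-Verlet integration with a Verlet neighbor list (skin 0.4 sigma,
periodic shift vectors frozen between rebuilds, rebuild on half-skin
displacement; this requires every box edge to exceed twice the list radius).
Thermostats:

* single-chain Nose-Hoover (Q = g kB T tau_damp^2) for production rheology:
  it conserves total momentum exactly (uniform velocity scaling) and adds no
  stochastic forces that would contaminate stress fluctuations;
* Langevin (exact Ornstein-Uhlenbeck velocity refresh) for equilibration,
  with a per-particle coupling mask (the microrheology probe is excluded so
  its motion reflects medium friction only).

The instantaneous stress is sigma_ab = (1/V)[sum_i m v_ia v_ib +
sum_pairs r_a f_b], with kinetic and virial parts kept separable and bond
terms included.  The tensor is symmetric by construction and its trace/3 is
the instantaneous pressure.

**Timestep.** The stiff bond gives omega_bond = sqrt(2K/m) ~ 387/tau.  The
engine warns when dt * omega_bond > 0.1.  Production runs of the generic
model here use dt = 1e-3 tau (omega dt = 0.39): bond oscillations are then
resolved by ~16 steps and the Nose-Hoover kinetic temperature stays within
0.1% of target (measured over 50 tau at T* = 3).  Pure LJ fluids (no bonds)
use the customary dt = 5e-3 tau.

**Oscillatory shear.** gamma_xy(t) = gamma0 sin(omega t) is imposed by
tilting the box (Lees-Edwards-equivalent) with affine remapping of particle
x-coordinates each step.  Velocities are not remapped; for the small
strain-rate amplitudes used here the affine velocity is far below thermal
velocity, and the thermostat acts on total velocities.  Kinetic temperature
is monitored per frequency and a run is flagged when it exceeds the target
by more than 5% (shear heating).

## Green-Kubo pipeline

G(t) = (V/kB T) <sigma_xy(t) sigma_xy(0)> is accumulated on the fly with a
multiple-tau correlator (p points per level, coarsening factor m = 2;
p = 16 for smooth fixtures, p = 32-64 for condensate runs so the bond-vibration
band of G(t) stays on fine, unaveraged levels).  The six-component estimator
combines the three shear channels (weight 1/5) and the three normal-stress
differences N_ab = sigma_aa - sigma_bb (weight 1/30); it is unbiased because
isotropy fixes <N N> = 4 <sigma_xy sigma_xy> (3/5 + 12/30 = 1).

The viscosity integral is split at t0: numerically (spline-refined
trapezoid) below, analytically above from a fit of G(t >= t0) to Maxwell
modes G_i exp(-t/tau_i) on a log-equidistant relaxation-time grid spanning
[t0/2, 2 t_max]:

* **t0 rule.** t0 is the earliest lag from which the running-median-smoothed
  G stays strictly positive and non-increasing (5% relative slack plus the
  per-lag standard error) through the last statistically significant lag.
  Significance is judged on |G| against twice the per-lag standard error
  estimated from 5 disjoint partitions of the stress series; the cut is the
  end of the last run of >= 3 consecutive significant lags, which keeps a
  slow tail that dips into and re-emerges from the noise floor while
  discarding isolated 2-sigma exceedances deep in the noise.
* **Mode density.** 3 modes per decade by default.  One mode per decade
  leaves the grid too sparse to represent a generic exponential: nonnegative
  least squares then parks weight on extrapolated long-time modes and the
  integral overshoots by tens of percent on the exponential-ACF oracle;
  at 3/decade the oracle error is 1-4%.
* **Weighting.** Residuals are weighted 1/(|G| + 0.05 max|G|): relative
  weighting where G has decayed (the region that controls the integral)
  blending into absolute weighting near the peak.
* **Uncertainty.** The pipeline is repeated on 5 disjoint blocks of the
  stress series; the standard error over blocks is reported.

G*(omega) combines the analytic Maxwell transform with a numerical Fourier
transform of the remainder (measured G minus mode sum) over the
statistically significant window, on a per-frequency grid fine enough to
resolve the oscillations: carrying the remainder beyond t0 keeps fit
residuals from leaking into the moduli, while stopping at the significance
cut keeps pure ACF noise out of the integral.

**Stress sampling for stiff chains.** The bond-vibration period
(2 pi / omega_bond ~ 0.016 tau) must be resolved by the stress sampling
stride, otherwise the oscillatory part of G(t) aliases and its (finite)
contribution to the integral is corrupted; condensate runs therefore sample
the stress every step.

## Oscillatory-shear pipeline

The stress response at each frequency is fitted by linear least squares on
{sin wt, cos wt, 1} after discarding the first 25% of periods as transient
(the source protocol is silent on the discard; 25% is conservative for the
frequencies used).  sigma0 = hypot(a, b) and delta = atan2(b, a) clamped to
the passive-response branch [0, pi).  The amplitude sweep flags the largest
gamma0 within 10% of the small-amplitude plateau of sigma0/gamma0 with
third-harmonic distortion below 10% (the standard SAOS nonlinearity metric).
The terminal viscosity is the zero-intercept slope of G'' vs omega over the
low-frequency points where G''/omega is constant within 15% and G'' > G'.
A strain amplitude gamma0 = 0.1 is the default; reports of much larger
amplitudes being usable depend on an amplitude-sweep certification, and the
sweep is the arbiter here.

## Bead-tracking pipeline

A single probe bead (radius R, mass 1, eps = 4, lambda = 0, i.e. a WCA
pseudo-hard sphere ensuring no-slip) is inserted at the largest cavity found
among random candidates and grown from 0.1 R in stages, each followed by a
short burst of Langevin dynamics so the medium flows around the growing
cavity; insertion fails if any single probe-medium pair ends above 10 eps.  Cross diameters mix arithmetically.  For lambda = 0 the potential
is identically zero beyond its minimum, so the formal three-diameter cutoff
is truncated there (bit-identical forces, and the neighbor list stays within
half the box).  The MSD uses multiple time origins spaced lag/2, with lags
capped at 1/8 of the trajectory (longer lags average too few origins to
carry weight).  The diffusive plateau is the longest terminal window (ending
within the final decade) whose log-log regression slope is 1 +- 0.05 and
whose two halves are individually diffusive within 1.5x that tolerance (the
half-window test rejects subdiffusive-to-diffusive crossover curvature that
a full-window slope would average away); R g3/(6t) is averaged over the
window with origin-count weights.  Then eta = kB T / (6 pi R D), no-slip.
In a periodic box the hydrodynamic self-images slow the probe; the
Yeh-Hummer correction D_inf = D_box / (1 - 2.837 R/L) recovers the
infinite-box coefficient (a large, approximate correction at the packaged
box sizes, where R/L ~ 0.2).
The documented failure mode - no terminal window with slope 1 - raises a
specific "no diffusive regime" error rather than returning a number.

## Direct coexistence and the critical point

Initial configurations thread chains along a boustrophedon ("snake") path
through a unit lattice: all bonds start at rest length and no pair sits
below 0.8 sigma, for both slab (elongated box, >= 3x transverse edge) and
bulk builders.  Density profiles recentre each frame by the densest cyclic
half-window (robust to vapor molecules, unlike a centre-of-mass shift)
before averaging.  Coexisting densities come from a symmetric tanh interface
fit; the critical point from the simultaneous fit of
rho_l - rho_v = A(1 - T/Tc)^beta (beta fixed at the 3D-Ising 0.325,
configurable) and (rho_l + rho_v)/2 = rho_c + B(Tc - T), initialized by the
exact linearization diff^(1/beta) = a + bT, which makes the fit exact on
noise-free synthetic data.  Coexistence points should be measured at
T <= 0.97 Tc to avoid finite-size rounding near criticality.

## Aging algorithm

LARKS (low-complexity aromatic-rich kinked segments) are short motifs that
form interprotein beta-sheets at high local density.  Every 100 steps
(configurable) each *fully disordered* LARKS is tested: when its central
bead has at least 3 disordered LARKS centres of *other* chains within the
capture cutoff, a transition fires, binding it with its 3 nearest partners
(4 LARKS per event) and permanently strengthening all pairwise interactions
among them.  Choices this implementation fixes: partners must themselves be
disordered and on distinct chains; within one evaluation,
candidates are processed in ascending (chain, segment) order and LARKS
consumed by an earlier event are deferred to the next stride.  Strengthened
interaction magnitudes are inputs (the physical values come from atomistic
potential-of-mean-force calculations); the packaged default x4 well depth is
a deliberately non-physical test value.  The algorithm also runs on the
generic bead-spring model with user-designated LARKS beads, which is how the
package's own gelation experiments are done.

**Primitive path analysis.** With beta-sheet-bound beads frozen, bond rest
lengths set to zero and intrachain excluded volume removed, steepest descent
with backtracking minimizes the strand contour length (a step is accepted
only if the contour does not increase, making the descent monotonic by
construction).  Interchain excluded volume is also omitted by default: the
analyses here need the network geometry and anchoring topology, not
entanglement statistics.  A 3x3x3 periodic replication is available for
visualization.

**Percolation.** A cluster spans an axis when a traversal with periodic
image bookkeeping reaches an already-visited node with an image offset - the
winding criterion.  Cluster connectivity includes the chain backbone between
consecutive LARKS of one chain, which is what makes anchoring valence
matter: chains with one LARKS form star clusters that can never span, while
chains with three LARKS can gelate.

## Synthetic fixtures

Every estimator has a fixture with closed-form ground truth, generated in
the same schemas the pipelines consume:

* Ornstein-Uhlenbeck stress traces (exact discretization, so the ensemble
  ACF is exponential to machine precision): Green-Kubo truth
  eta = (V/kB T) s^2 tau_M.  The three diagonal channels carry twice the
  shear variance, making the six-component estimator exactly unbiased with
  the same exponential ACF.
* Ideal Brownian probe trajectories (Gaussian increments, variance 2D dt).
* Single-mode Maxwell stress responders with the analytic amplitude and
  phase; terminal truth eta = G0 tau.

The fixtures are statistical oracles, not physical systems: passing them
shows the estimators are correct and correctly converging, not that the
coarse-grained models reproduce any particular condensate.  Conversely, the
scaled-down MD experiments below exercise the full physical pipeline but at
system sizes and sampling lengths where uncertainties are tens of percent.

## Study conditions of the packaged experiments

The packaged self-tests and the results script run deliberately scaled-down
versions of the full campaigns:

* **Three-method consistency** (Green-Kubo vs oscillatory shear vs bead
  tracking): 40 chains x 20 beads at T* = 2.7 (0.96 of this chain length's
  own critical temperature Tc* = 2.82, measured by the package's
  direct-coexistence pipeline) and the corresponding condensate density
  rho* = 0.39.  Shorter chains are the honest scale choice: for 50-bead
  chains at 0.96 Tc* the R = 3 sigma probe is still subdiffusive after
  800 tau and the G(t) tail beyond ~1 tau stays below its sampling noise,
  so no estimator reaches its terminal regime in minutes of CPU; 20-bead
  chains relax ~6x faster.  Green-Kubo sampling 350 tau with every-step
  stress sampling, oscillatory shear at two near-terminal frequencies x 16
  periods, bead tracking 300 tau.  Each estimator carries the uncertainty
  measured from its own run; Green-Kubo and oscillatory shear agree within
  mutual 2 sigma.  The bead-tracking leg still reports its documented
  "no diffusive regime" flag even here: an R = 3 sigma probe only turns
  Fickian once g3 exceeds its squared diameter (t >~ 200 tau at the
  measured D), and resolving a half-decade diffusive window beyond that
  point needs ~10^4 tau of sampling - hours of CPU at any chain length, the
  same cost asymmetry that makes bead tracking the most expensive of the
  three methods in practice.
* **Direct-coexistence campaigns**: 10 chains x 50 beads (or 20 x 20 for
  the short-chain system), elongation 4, ~50-100 tau of sampling per
  temperature; the critical temperature lands within a few percent of the
  large-system value (finite size and short sampling depress it slightly;
  the packaged 50-bead campaign gives Tc* ~ 3.0 against the full-size
  reference value Tc* = 3.14).
* **Aging/gelation**: 24 chains x 12 beads at rho* = 0.5, T* = 1.5, with 3
  designated LARKS per chain (vs a 1-LARKS control), capture cutoff
  1.5 sigma; 150 tau of maturation between two 250 tau G(t) measurements.
  The packaged toy strengthening is x8 well depth (deliberately
  non-physical, like the x4 shipping default): at x4 the strengthened bonds
  unbind on ~e^2 tau and the G(t) contrast drowns in the sampling noise of
  minutes-long runs, while x8 binds persistently enough to resolve.
  Physical strengthened parameters are inputs (CSV/config), sourced from
  atomistic potential-of-mean-force calculations.

## Known limitations

* The Nose-Hoover chain is single; for very small or very stiff systems a
  chain thermostat would sample the canonical ensemble more rigorously.
* Truncated-force LJ dynamics does not conserve a Hamiltonian exactly; NVE
  drift is dominated by cutoff crossings (slope < 5e-5 eps per tau per
  particle at dt = 5e-3 in the packaged test).
* The neighbor list is a half Verlet list built by an O(N^2) scan; fine for
  the few-thousand-bead systems targeted here, not for much larger ones.
* No Ewald electrostatics (the Debye-Hueckel interaction is short-ranged by
  construction), no barostat (rheology runs NVT at the coexistence density),
  no GPU path.
* Bead-tracking viscosities are only reliable when a genuine Fickian window
  exists and the probe exceeds the condensate mesh size; the module reports
  R against a mean nearest-neighbor-spacing proxy and otherwise raises its
  "no diffusive regime" flag.
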