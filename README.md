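# condrheo

Computational rheology of biomolecular condensates.

Protein/RNA condensates formed by liquid-liquid phase separation are
viscoelastic liquids whose viscosity spans orders of magnitude and changes as
condensates mature.  `condrheo` implements, for coarse-grained molecular
models of such condensates, the three standard routes to their viscosity and
the analyses around them:

* **Green-Kubo (GK)**: the shear stress relaxation modulus from equilibrium
  stress fluctuations,
  `G(t) = (V/kB T) <sigma_xy(t) sigma_xy(0)>`, integrated as
  `eta = int_0^t0 G dt + sum_i G_i tau_i exp(-t0/tau_i)` with the noisy tail
  fitted to Maxwell modes `G_i exp(-t/tau_i)` log-equidistant in time;
  accumulated on the fly by a multiple-tau correlator, with the
  six-component isotropic estimator (shear channels weighted 1/5,
  normal-stress differences 1/30) and `G*(omega)` by transform.
* **Oscillatory shear (OS)**: a sinusoidal box strain
  `gamma_xy(t) = gamma0 sin(omega t)`; fitting the stress response
  `sigma0 sin(omega t + delta)` gives `G' = (sigma0/gamma0) cos delta`,
  `G'' = (sigma0/gamma0) sin delta`, and the terminal limit
  `eta = lim_{omega->0} G''/omega`, with amplitude sweeps certifying the
  linear regime.
* **Bead tracking (BT)**: a single pseudo-hard-sphere probe bead; its
  mean-squared displacement plateau `R g3/(6t) -> R D` gives
  `eta = kB T/(6 pi R D)` by Stokes-Einstein.

Around these sit a velocity-Verlet MD engine (Lennard-Jones /
Ashbaugh-Hatch / Debye-Hueckel pair potentials, stiff harmonic bead-spring
chains, Nose-Hoover and Langevin thermostats, tilting-box oscillatory
shear), direct-coexistence phase diagrams with critical points by the law of
rectilinear diameters, a nonequilibrium aging algorithm (density-triggered
irreversible LARKS beta-sheet transitions with interaction strengthening),
and primitive-path / percolation analysis of the matured cross-beta
network.  Synthetic fixtures with closed-form ground truth (Ornstein-
Uhlenbeck stress traces, Brownian probe trajectories, Maxwell responders)
make every estimator testable without any simulation.

All quantities are in reduced Lennard-Jones units (kB = 1,
tau = sigma sqrt(m/eps)); see `docs/methods.md` for models, defaults and
numerical choices.

## Worked example

Viscosity of a synthetic stress series whose ground truth is known: six
Ornstein-Uhlenbeck stress channels with stationary variance s^2 = 2 and
correlation time tau_M = 5 in a volume V = 10 at T* = 2.5 have the exact
Green-Kubo viscosity (V/kB T) s^2 tau_M = 40.

```python
from condrheo.fixtures import OUStressSpec, ou_stress_trace
from condrheo.gk import viscosity_from_stress_log

spec = OUStressSpec(variance=2.0, tau_M=5.0, dt=0.5, n=1_000_000,
                    seed=1, volume=10.0, temperature=2.5)
res = viscosity_from_stress_log(ou_stress_trace(spec))
print(f"eta = {res['eta']:.2f} +- {res['eta_err']:.2f}  (exact: 40)")
print(f"integral split at t0 = {res['t0']:.1f}")
```

prints

```
eta = 40.56 +- 0.19  (exact: 40)
integral split at t0 = 0.5
```

i.e. the pipeline recovers the exact viscosity within ~1.5% from one million
samples, with the uncertainty estimated from five disjoint blocks of the
series.  The same pipelines run on real MD systems; a minimal condensate
run from the shell:

```sh
condrheo simulate --config run.toml          # stress log + trajectory
condrheo gk --stress-log out/stress.tsv --volume 2857 --temperature 3.0
condrheo os --maxwell 1.0 1.0 --omegas 0.01,0.02   # synthetic responder
condrheo bt --traj probe.xyz --radius 3.0 --temperature 3.0
condrheo phase-diagram --points coexistence.tsv
condrheo age --config age.toml
```

Externally produced stress logs (TSV with header
`time sxx syy szz sxy sxz syz`, e.g. written by a LAMMPS run) are analyzed
by `condrheo gk` without using the bundled engine.

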