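# cpus — curvilinear-path umbrella sampling toolkit

`cpus` implements the curvilinear-path umbrella sampling (CPUS) strategy for
estimating standard binding free energies of a host–guest complex, together
with the trajectory analyses used to interpret the dissociation mechanism.
It is aimed at people studying enhanced-sampling free-energy protocols — the
estimator itself, its de-biasing, its standard-state bookkeeping — rather
than at production molecular dynamics: the "molecular system" is a built-in
synthetic host–guest landscape whose potential of mean force and binding
free energy are known exactly by quadrature, so every stage of the pipeline
can be validated against an analytic answer.

## The method

The reaction coordinate is the distance `D` between the centers of geometry
(CoG) of host and ligand.  A short unbiased run of the bound complex gives
the reference bound distance `D_ref`; umbrella windows then restrain `D`
with a harmonic bias (spring constant `k = 10 kcal/mol/Å²`) to targets
`D_ξ = D_ref + δ(ξ−1)`, `δ = 0.1 Å`, *sequentially*: each window starts
from the last conformation of the previous one, so the ligand's exit path
evolves spontaneously (curvilinearly) instead of along a predefined vector.
A backward sweep (10 windows by default, restarted from the bound state)
completes the profile below `D_ref`.  Window histograms are combined by
self-consistent WHAM into the profile `A(r)`, `r = D − D_ref`, and

    ΔG_PMF = −A(r_final)

is the uncorrected estimate of one walker.  The 1 M standard-state value is

    ΔG⁰_bind = ΔG_PMF − k_B T ln[ (4π r*²_cut / V₀) ∫_bound dr e^(−βA(r)) ],

with `V₀ = 1663 Å³` and `r*_cut` the separation at which the vdW-like
host–guest interaction component first vanishes persistently.  Because each
finite-time pull dissipates differently, an ensemble of independent walkers
(15 in the reference protocol) is run and the *lower-bound* profile — the
smallest plateau work — is retained as the variationally best estimate.

The analysis layer reproduces the accompanying mechanistic toolbox:
atom-pair distance traces between host pseudo-atom sites and ligand beads,
their histograms with peak lists, ground-level/plateau segmentation,
H-bond-style acceptor switching between two competing sites, ligand RMSD
after optimal superposition, and the traced dissociation path from
per-window representative conformations.

## Worked example

`cpus` is also a command-line tool.  With a minimal configuration

```json
{
 "landscape": {},
 "schedule": {"n_forward": 120, "n_backward": 10},
 "n_walkers": 3,
 "master_seed": 7
}
```

(`toy.json`; every omitted key takes the protocol default, e.g. `δ = 0.1 Å`,
`k = 10 kcal/mol/Å²`, `T = 295 K`, `V₀ = 1663 Å³`), running

```
cpus all --config toy.json --outdir run
```

simulates the three walkers, de-biases each one, applies the standard-state
correction and prints

```
INFO cpus: d_ref = 2.7429 A, 3 walkers
INFO cpus: walker 0: WHAM converged in 2572 iterations
INFO cpus: lower bound: walker 0, dG_PMF=-3.727, dG0_bind=-3.382 kcal/mol
```

`run/summary.tsv` then holds one row per walker with the lower-bound flag:

```
walker_id  dg_pmf      r_cut  bound_integral  correction  dg_bind0    selected
0          -3.7267757  11.5   0.5558716       0.3446290   -3.3821467  1
1          -3.9391103  11.5   0.5690048       0.3309397   -3.6081706  0
2          -4.1341535  11.5   0.5605344       0.3397320   -3.7944215  0
```

Reading the selected row: this walker dissipated least — its profile rises
only 3.73 kcal/mol to the final separation (`dg_pmf = −3.73`), the vdW
component of the host–guest interaction vanished 11.5 Å beyond the bound
distance (`r_cut`), and the standard-state correction (+0.34 kcal/mol here)
turns the plateau into `ΔG⁰_bind = −3.38 kcal/mol`.  For this synthetic
system the exact answer from the configurational integral is
−3.83 kcal/mol, i.e. the desk-scale budget recovers it to a few tenths of
kcal/mol; per-walker profiles, paths and results are under `run/walker_*/`.

The same stages are available as a library (`cpus.pipeline`,
`cpus.wham`, `cpus.binding`, `cpus.analysis`) and accept externally
produced two-column window dumps via `cpus.io.read_window_file`.

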