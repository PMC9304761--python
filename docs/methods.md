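# Methods

This note documents the models, conventions and numerical choices behind
`cpus`, in the order the pipeline uses them.  Units throughout: kcal/mol,
Å, ps, K; `k_B = 1.9872041e-3 kcal/mol/K`, default temperature 295.0 K
(21.85 °C), standard-state volume `V₀ = 1663 Å³` (one molecule per 1 M).

## The synthetic host–guest system

The host is static at the origin; the ligand is one bead (free-energy
studies) or a rigid three-bead triad (geometry-dependent analyses).  The
potential acts on the ligand center of geometry and decomposes exactly into
a vdW-like and an electrostatic-like component; the decomposition is what
the cutoff detector consumes, so it is part of the model's contract.

vdW-like component:

* Born–Mayer repulsive core `A_rep e^(−D/L_rep)` (defaults `A_rep = 694`,
  `L_rep = 0.4`).  The core stiffness in the thermally sampled region is
  ~30–50 kcal/mol/Å², i.e. a few times the umbrella spring.  This is
  deliberate: a 12-6 wall of comparable height has curvature an order of
  magnitude larger and would force the integration step several-fold
  smaller for no validation benefit.  A capped 12-6 Lennard-Jones term is
  still available (fields `lj_epsilon`, `lj_sigma`, default ε = 0) for
  studies that want it.
* Exponential dispersion tail `−A_disp e^(−D/L_disp)` (defaults 4.2, 3.2).
  It models the collective many-atom attraction of a macromolecular host,
  which persists far beyond contact: with the defaults the component
  crosses ±0.05 kcal/mol near `D ≈ 14 Å`, so the cancellation separation is
  comparable to the length of a 120-window schedule, as in the
  protein–ligand setting the method was designed for.  A point LJ between
  centers would instead vanish ~1.5 σ beyond contact and make the
  standard-state prefactor degenerate.
* Both repulsive terms are clamped at +50 kcal/mol (`core_cap`) so all
  configurational integrals are finite; the clamp radius lies far inside
  the thermally accessible region.

Electrostatic-like component: a screened term `A_e e^(−D/L_e)` (defaults
−1.0, 1.5), the Gaussian association well
`−d · exp(−(D − r₀)²/2w²)` (defaults d = 5, r₀ = 2.4, w = 0.8), and, when
exit channels are configured, a barrier shell
`g(D)·B(û)` with `g` Gaussian in `D` around `barrier_radius` and `B`
interpolating between `background_barrier` and each channel's height
through von-Mises angular factors `exp((û·ĉ − 1)/w_ch²)`.  The association
well and the channels ride in this component so that the vdW-like channel
stays a pure dispersion/repulsion signal for cutoff detection.

With the defaults the bound minimum sits near `D ≈ 2.5 Å` with total depth
≈ 5.5 kcal/mol — a buried-ligand geometry in which the bound CoG
separation is small compared with the interaction range.  At 295 K the
bound state is metastable (unbiased escape on the ~ns scale), which is
physically faithful; analyses that need a stationary bound ensemble use a
deepened well.

## Oracles

Because the potential is analytic, two oracles are available:

* `analytic_pmf` computes `−k_B T ln⟨e^(−βU)⟩_angles` on a distance grid by
  Gauss–Legendre × trapezoid angular quadrature (isotropic landscapes
  collapse to a single radial evaluation).  With `include_jacobian` it adds
  the distance-distribution term `−2 k_B T ln(D/r₀)` — the scalar-distance
  histograms WHAM sees intrinsically carry the `D²` geometric factor, so
  this is the profile WHAM should be compared against.  Convergence is
  checked by doubling the rule; a shortfall is reported as a warning with
  the achieved tolerance.
* `analytic_binding_dG` evaluates
  `−k_B T ln[(1/V₀)∫₀^b 4πD²⟨e^(−βU)⟩ dD]` by adaptive radial quadrature —
  the exact 1 M standard-state binding free energy of the toy system.  The
  result is insensitive to the bound boundary `b` beyond the interaction
  range except for the slowly growing free-volume term, which for a bound
  system is a ≲0.05 kcal/mol perturbation over several Å of boundary.

## Dynamics

Overdamped Brownian dynamics: free-energy estimates depend only on the
stationary distribution, so inertia would add cost without information.
The single-step primitive is Euler–Maruyama with noise variance
`2 k_B T dt/γ` per coordinate.  The production window loop uses the
Leimkuhler–Matthews variant (noise `(ξ_n + ξ_{n+1})/2`): same drift and
long-time diffusion, but the stationary configurational distribution is
sampled with O(dt²) accuracy — exactly, for harmonic forces — whereas
Euler–Maruyama inflates the stationary variance by `k_eff dt/2γ`.  That
error budget is what allows the defaults `dt = 0.01 ps`, `γ = 1 ps⁻¹` to be
quantitative: the stiffest sampled curvature (~50 kcal/mol/Å²) gives
`k_eff dt/γ ≈ 0.5`, stable and, under Leimkuhler–Matthews, unbiased to
within a percent-level anharmonic correction, while the relaxation time in
a window (`γ/k_eff ≈ 8` steps) makes samples at the default recording
stride of 10 nearly independent.

Each window runs 10⁴ steps by default (the reference protocol's 1 ns per
window mapped onto the toy's time scale); the first 10 % are discarded as
within-window equilibration, because the handed-off start is centered on
the *previous* target and recording the relaxation would skew every
forward histogram in the same direction — a bias that accumulates along
the sweep.  Multi-bead ligands translate via the CoG force and undergo
free rotational diffusion (variance `2 k_B T dt/rot_friction` per axis),
applied at the recording stride inside the window loop; the landscape acts
on the CoG, so orientation carries geometry for the analyses without
affecting the distance statistics.

Reproducibility: every walker draws from a counter-based Philox stream
keyed `(master_seed, walker_id)`; the unbiased pre-run has a reserved
stream.  Identical configuration and seed give byte-identical outputs.

## WHAM

Standard self-consistent iteration on shared uniform bins (default width
0.05 Å = δ/2), window shifts converged to 1e-6 kcal/mol (default), honest
`converged` flag, `+inf` for unvisited bins, and a warning naming any gap
in support inside the biased-target range.  The profile is anchored with
its minimum at zero; re-anchoring is a constant shift.  `ΔG_PMF` is the
*negated* profile value at the final separation, so a deep well reports a
negative binding free energy.  The `−2 k_B T ln D` geometric term is *not*
subtracted: the downstream correction is defined on exactly this profile,
and consistency is validated against the quadrature oracle rather than
assumed.

For the isotropic validation study the windows of all walkers are pooled
into one WHAM solve (they sample identical radial statistics; pooling is
simply the best use of the fixed budget), while per-walker profiles feed
the lower-bound selection and spread analyses, mirroring the per-run
treatment of the multi-walker protocol.

## Standard-state correction and its convention error

`r*_cut` is the first window whose mean vdW component stays within ±0.05
kcal/mol (default) for 5 consecutive windows — the persistence guards the
"first cancellation" rule against single-sample zero crossings.  The bound
integral is a trapezoid of `e^(−βA)` over the basin, by default from the
contiguous visited block around the minimum out to the first bin within
`k_B T` of the plateau (the integrand is negligible beyond).  All
intermediates are stored and the defining identity is re-computable from
them.

One consequence of applying the correction *literally* in the shifted
coordinate `r = D − D_ref` can be derived in closed form for an isotropic
system: the corrected estimate differs from the exact configurational
answer by `2 k_B T ln(D_final/r*_cut) − U(D_final)`.  With the default
geometry (bound distance ≈ 2.7 Å, cancellation ≈ 14 Å, schedule end
≈ 14.6 Å) this is ≈ +0.29 kcal/mol — the dominant part of the end-to-end
error at the validation budget, and the reason the toy geometry keeps
`D_ref` small relative to the interaction range.  The offset is a property
of the convention, reported rather than silently absorbed; making the
prefactor use the absolute cancellation distance would remove it but would
be a different formula than the one this toolkit implements.

The lower-bound selection takes the result with the smallest plateau work
`|ΔG_PMF|` (ties to the lowest walker index): every finite-time profile
overestimates the reversible work by its excess dissipation, so the least
plateau is the variationally best estimate.  `ΔG ↔ K_d` conversion uses
`K = e^(βΔG) · 1 M`, and measured affinities are moved between
temperatures by van't Hoff extrapolation with temperature-independent
enthalpy and entropy.

## Trajectory analyses

* Plateau detection is a greedy running-mean change-point pass (a new
  segment opens when a sample departs from the running mean by more than
  `level_tol`), followed by merging of segments shorter than
  `min_duration` into the nearer-level neighbour; the first segment is the
  ground level.  The reference analyses identified plateaus by eye, so the
  two thresholds are exposed rather than hard-coded.
* Switching between two competing acceptor sites counts changes of the
  nearer-site identity among frames where the nearer distance is below
  `engage_cut`; disengaged frames do not reset the state.
* Path tracing keeps windows with `target − D_ref ≤ max_r` (default 10 Å,
  which with δ = 0.1 Å retains 101 windows — the `r ≤ max_r` rule is
  normative, the count is derived), takes the mean of the recorded frame
  CoGs as the window-center and the earliest frame nearest to it as the
  representative.  The toy host is static, so the all-atom protocol's
  alignment step is the identity here.
* RMSD uses the standard SVD superposition with reflection correction.

## Validation-study sizes

The built-in studies are sized for a desktop CPU: the isotropic study uses
5 walkers × (120 forward + 10 backward) windows × 10⁴ steps (≈ 10 s), and
recovers the analytic PMF within ≲0.2 kcal/mol on all bins with ≥100
samples and the analytic ΔG⁰ within ≈0.2–0.45 kcal/mol (the convention
offset above plus ≈0.1 kcal/mol of plateau noise).  The two-channel study
(8 walkers × 75 windows × 4·10³ steps) exhibits the expected walker-to-
walker plateau spread and populates both exit channels.  These numbers are
produced, not asserted: `scripts/acceptance.py` recomputes all of them
from scratch for any seed.

## Known limitations

* No statistical-inefficiency correction or bootstrap error bars in WHAM;
  uncertainty is assessed across walkers and seeds instead.
* The synthetic landscape has no solvent, no conformational degrees of
  freedom in host or ligand, and a static host frame; passing tests here
  validates the estimator chain, not force-field or sampling adequacy for
  real complexes.
* The cutoff definition inherits the convention error discussed above;
  comparisons with tabulated corrected free energies of real systems
  should bear in mind that their correction magnitudes also depend on the
  authors' anchoring conventions.
* Rotational dynamics of multi-bead ligands is torque-free diffusion; it
  provides realistic-looking geometry for the analyses but no coupling of
  orientation to the potential.
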