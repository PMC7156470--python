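# Methods

`ioncage` models the local structural damage an intense femtosecond X-ray
pulse inflicts on a disulfide bridge inside a protein nanocrystal, with a
hybrid continuum treatment: atomic rate equations for ionization, a
mean-field description of the trapped-electron plasma, and classical
dynamics of the ions in Debye-screened pair potentials. This note records
the model, its assumptions, the defaults, and what the synthetic fixtures
do and do not establish.

## The physical picture

A ~15 fs, ~7 keV pulse photoionizes the sample, mostly in the K shell of
the heavier constituents (S ≫ O > N > C ≫ H per atom). Each K hole decays
within femtoseconds, predominantly by Auger emission, so one absorbed
photon typically costs two electrons. Fast photoelectrons initially leave
the (100 nm scale) crystal; slower secondaries are stopped inside it and,
once the crystal has charged up, even keV electrons are pulled back. The
retained electrons form a dense, warm gas that (i) ionizes further by
electron impact and (ii) screens ion–ion Coulomb interactions with an
exponentially decaying (Debye) factor. The doubly-to-triply charged
sulfurs of a disulfide bridge would fly apart at several km/s in vacuum;
inside the crystal the combination of screening and the repulsion of the
surrounding ion cage throttles the separation to ~1–2 Å over 100 fs.

## Stage (i): atomic rates

Per element (H, C, N, O, S) and charge state `q`:

* photoionization rate `σ_ph(q)·Φ(t)`, with Φ the instantaneous photon
  flux; cross sections at 7.14 keV from the standard Henke `f₂`
  tabulation (`σ = 2 r_e λ f₂`), scaled by the K-shell occupation
  `min(2, Z−q)/2`;
* effective single K-hole decay rate `Γ = ħ/ΔE_K` from tabulated K-level
  widths, with the Krause fluorescence yield as the non-ionizing branch;
* electron-impact ionization in the Lotz form
  `σ(E) = a·ln(E/B)/(E·B)` (single-outer-electron constant
  `a = 450 Å²·eV²`), Maxwell-averaged by Gauss–Laguerre quadrature, times
  the trapped-electron density. `B` is the NIST sequential ionization
  energy of charge state `q`.

The table ships as a versioned JSON resource and can be replaced by path.
The charge-state scaling of `σ_ph` and the K-binding shift (linear in `q`)
are screened-hydrogenic conveniences; rate changes at the tens-of-percent
level move the predicted charges by only a few percent.

## Stage (ii): rate equations and the plasma

For each element a real-valued occupation vector over `q = 0..Z` plus a
K-hole population evolves under the three channels (photoionization
creates a hole for Z ≥ 5; Auger consumes one; impact ionization moves
valence charge). Flows use exponential survival probabilities per substep
(exact for pure decay, positivity-safe); substeps are capped so the
fastest channel advances < 0.2 per step, and the pulse envelope is
sampled every ≤ 0.05 fs.

Electron bookkeeping assumes a spherical crystal of radius `R`
(`sample_radius`, default 1000 Å = 100 nm):

* every ejected electron is compared, at birth, with the Coulomb barrier
  `k_e·Q_net/R` of the positively charged sphere (`Q_net` = escaped
  electrons of the whole sphere; the per-cell escape count is scaled by
  the sphere-to-supercell volume ratio);
* an electron also counts as retained when its collisional stopping range
  (`≈ 400·(E/keV)^1.75 Å`, a water-density CSDA fit) is below `R`; this
  is what keeps sub-keV Auger and cascade electrons inside from the very
  first ionization, while multi-keV photoelectrons and the ~2.1 keV
  sulfur Auger electrons escape until the barrier catches them;
* retained *secondary* electrons thermalize instantly: the thermal count
  `N` and energy budget `E` (photon energy book-kept per channel, impact
  ionization debits the binding energy) define `T_e = (2/3)·E/N`;
* retained *photoelectrons* are kept on a separate non-thermal ledger:
  they enter the charge balance but not `n_e`/`T_e`, because a multi-keV
  electron needs far longer than the pulse to thermalize and its Debye
  contribution at keV temperature is negligible. Setting
  `pe_thermalize=True` folds them into the bath instead (roughly 7×
  more thermal energy at these fluences, and correspondingly harder
  impact-driven charging).

The screening parameter is `κ = sqrt(4π·k_e·n_e/T_e)` (eV–Å units,
`k_e = 14.3996 eV·Å`); `κ = 0` for an empty gas. There is no
recombination: continuum three-body rates (`∝ n_e² T^-9/2`) diverge in
this strongly coupled regime and would demand an arbitrary cap, so charge
staircases are monotone and the model systematically *over*-estimates
late-pulse charge states relative to explicit-particle simulations — most
visibly at the highest fluence, where sulfur averages ~3–4 K-shell
absorptions and photo/Auger alone push it past +10 by the probe, versus
the ~+5 an explicit treatment with recombination reports. Observables
that hinge on absolute charge states at the top fluence inherit this
bias; the fluence *trends* and the screening/caging phenomenology do not.

Per-atom charge trajectories are sampled from the population history by a
quantile coupling: each atom draws one uniform variate and follows its
element's inverse CDF through time. Marginals match the populations
exactly at every instant and every staircase is non-decreasing.

## Stage (iii): screened ion dynamics

Pair energies: `V_D = k_e·Q_i·Q_j·e^{-κr}/r` plus the collision wall
`V_C = D(1−e^{−a(r−r_e)})²` for `r ≤ r_e` (zero outside), active only
between two *ions*. Defaults `D = 27.2 eV`, `a = 2 Å⁻¹`,
`r_e` = sum of single-bond covalent radii — the wall's hardness is not
prescribed by the physics and is config-exposed. Forces are the analytic
gradients; trajectories use classical fixed-step RK4 from rest. Charges
are piecewise-constant on the rate-equation grid (ionization is an
integer event); κ is interpolated linearly (a smooth bath property).

Periodic replication is summed out to the radius where `e^{-κr}` falls
below `image_cutoff_tolerance` (default 3×10⁻³), clamped to
[4.5 Å, 12 Å]; the nearest-image shell is always included. The truncated
tail contributes < 0.01 eV at the κ values that matter, and the screening
collapse during the pump is what makes this cutoff — rather than Ewald
summation — adequate. Atoms outside a free sphere (default radius 7 Å,
the inscribed sphere of the 14 Å cell) around the S–S midpoint are held
fixed; membership is decided once at t = 0.

Numerical defaults: production step 0.05 fs (library default 0.01 fs).
Individual 300-ion Coulomb trajectories are chaotic, so convergence is
judged at ensemble level: 0.05 fs is statistically indistinguishable from
0.025 fs, while 0.1 fs occasionally mis-integrates hard collision-wall
crossings. A step that moves any atom > 0.5 Å aborts with advice to
reduce `dt`. Energy conservation (frozen charges, κ = 0, no wall
contact) holds to < 10⁻³ relative over 100 fs at 0.01 fs, with the
RK4 fourth-order drift scaling verified.

## Pump–probe driver

Two Gaussian profiles of 15 fs FWHM share the total fluence (half each by
default); the pump is centred at 30 fs so its leading tail is inside the
window, the probe at 30 fs + delay. Fluence cases follow the experiment:
8.8×10¹¹, 4.4×10¹², 7.0×10¹² photons/µm² total (1 µm² = 10⁸ Å²). The
observable is the tracked S–S distance (minimum-image) at the probe-pulse
*centre* — the delay-axis convention of the published curves; a
probe-profile-weighted mean is available (`observable="probe_mean"`)
since the published convention is not stated. Note the probe has
delivered half its fluence by its centre, so late ionization by the probe
is included but barely moves the ions.

Ensembles: fresh seeded supercell per trajectory (dense) or the four-atom
fixture (vacuum), one shared rate-equation solve per (fluence, delay)
(the composition is seed-independent), stochastic charge sampling and
dynamics per trajectory. All randomness derives from
`SeedSequence([master, delay_idx, traj_idx, stream])`, so any trajectory
can be replayed. Vacuum mode is the same pipeline with a molecule-scale
trapping radius (5 Å): every ejected electron outruns both trapping
criteria, so no plasma forms, and screening and impact ionization vanish
without special-casing — vacuum charging is purely photo + Auger.

Study sizes used by the analysis scripts and the acceptance run:
50 trajectories per (fluence, delay), 100 for vacuum ensembles, delay
grid {20, 60, 100} fs (the separation is monotone in delay — verified as
an ensemble property — so window maxima sit at the 100 fs endpoint; the
mid-fluence deceleration check adds the 40 and 80 fs points). The
trajectory-to-trajectory dispersion at F_low is ~0.7 Å, so a 50-member
mean carries a ~0.1 Å standard error.

## Bragg termination

Reference (single-pulse) intensities are acentric-Wilson distributed:
exponential with mean `∝ exp(−2·B·s²)`, `s = sinθ/λ` sampled uniformly in
reciprocal volume. The self-gating simulator applies
`B_eff(t) = b_end·(t/T)³` at `N = 100` uniform time points over the
`T = 100 fs` window and averages the damped intensities — the standard
intensity-space Debye–Waller convention `exp(−2·B·s²)` (the
amplitude-space alternative is not used). Endpoints of 125 Å² and 500 Å²
correspond to the light-protein and heavy-atom-complex scenarios.
Diagnostics: Wilson fit (least squares of `ln⟨I⟩` vs `s²` in 20
equal-reciprocal-volume bins) and the cumulative distribution `N(z)` of
resolution-normalized intensities against the ideal acentric
`1 − e^{−z}`. Because the time average is dominated by the
early-pulse window, the fitted Wilson B saturates with `b_end` — damage
masquerades as a modest global B inflation, not as a slope proportional
to the endpoint disorder.

## Jackknife dispersion

Error bars on ensemble observables use the delete-fraction scheme: the
standard deviation over `n_resamples` (default 100) means of random 75%
subsets drawn without replacement — the same resampling protocol used for
refinement error bars on crystallographic datasets, applied to trajectory
ensembles.

## What the synthetic supercell is — and is not

The generator packs a cystine motif (Cβ–Sγ bond 1.81 Å, 104° angles, 90°
dihedral, S–S at 2.08 Å) into a 14 Å cube with ~300 randomly placed
H/C/N/O atoms (H 0.58 / C 0.16 / N 0.045 / O 0.215 of the light atoms —
a ≈50/50 protein/water atom-count mix, hydrogens included; the density
argument is what fixes ~300 atoms in 2744 Å³). Two sulfurs per 300 atoms
reproduce the crystal's sulfur-to-light-atom ratio. Placement enforces a
pairwise floor of `max(1.0 Å, r_cov_i + r_cov_j)`: random configurations
inside the covalent-contact radius would store tens of eV in the
collision wall and detonate artificially on ionization — real matter has
no such contacts.

The fixture has no bonds, no solvent structure, no crystal contacts and
no conformational realism; passing tests on it demonstrate the
ionization–screening–caging mechanics and their fluence trends, not
side-chain-resolved damage in a real protein. An optional PDB cut-out
reader builds the same cell type from a crystal structure when one is
available.

## Known limitations

* No recombination (see above) — charge states at the top fluence are
  upper bounds, and the vacuum/dense contrast at the lowest fluence is
  distorted: impact ionization charges the dense cell harder than the
  sparse photo-only statistics charge the vacuum fixture, so at F_low the
  *mean* vacuum separation can undercut the dense one even though every
  strongly-charged vacuum pair separates far more violently.
* Mean-field electrons: no spatially resolved cloud, no local
  neutralization next to the most-charged ions, no electron–ion energy
  exchange after trapping.
* Vacuum ensembles are dominated by the Poisson statistics of a handful
  of absorption events: most trajectories never charge both sulfurs at
  the lowest fluence, so vacuum means are small while the rare +2/+2
  explosions coast to tens of Å — the ensemble maximum is an extreme
  statistic with large seed-to-seed spread.
* No bonded force field (deliberate: the target observable is the bare
  ion response), no thermostat, no explicit electron particles, no Ewald
  sums.
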