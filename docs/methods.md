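# Methods

## Model

`biofetsim` solves the stationary semiconductor device equations on a 2D
cross-section of an electrolyte-gated FET:

* Poisson: ∇·(ε∇ψ) = −q(p − n + N_D − N_A) − ρ_fix, everywhere;
* electron/hole continuity: ∇·J_n = +qR, ∇·J_p = −qR, in the silicon body
  and in the electrolyte region;
* Boltzmann densities n = n_i e^{(ψ−β−φ_n)/V_T}, p = n_i e^{(β+φ_p−ψ)/V_T},
  where β is the material band offset and φ_n, φ_p the quasi-Fermi
  potentials;
* SRH recombination with a midgap trap,
  R = (np − n_i²)/(τ_p(n+n_i) + τ_n(p+n_i)).

Insulators (gate oxide, receptor blocks) carry no carriers and enter
Poisson only; receptor charge is a fixed volume charge spread uniformly
over the block.

### The electrolyte as an intrinsic semiconductor

The solution is a material whose carriers are the ion pair: hydronium ↔
holes, hydroxide ↔ electrons. Concentrations come from pH via
c(mol/L)·6.022·10²⁰ cm⁻³ and the ionic product 10^−pKw; the effective
densities of states follow by inverting the Boltzmann relations with the
Fermi level of the *neutral* (pH = pKw/2) solution at midgap:
N_V = p·e^{Eg/2kT}, N_C = n·e^{Eg/2kT}. Two conventions matter:

* **Temperature.** K_W = 10⁻¹⁴ is a 25 °C value, but the conversion to
  N_C = N_V = 2.4·10²⁶ cm⁻³ requires kT at **300 K** (298.15 K would give
  ≈ 2.9·10²⁶). All DOS work is therefore defined at 300 K; the ~0.6%
  inconsistency is far below any quantity of interest here.
* **Fermi-level placement for pH ≠ 7.** Only the DOS *ratio* is physical.
  We keep n_i fixed (it is pH-independent by construction:
  n_i = √(np) = 6.022·10¹³ cm⁻³ for water) and express the asymmetry as a
  band offset β = (kT/2)·ln(N_V/N_C) = kT·ln10·(pKw/2 − pH). The neutral
  bulk then satisfies n = p = n_i (charge neutrality of an undoped
  material), and β shifts by exactly kT·ln10 per pH unit — the Nernst
  response. One can show the full device problem satisfies
  I_D(β, V_REF) = I_D(0, V_REF + β), so the simulated transfer curves at
  different pH are rigid translations and the extracted sensitivity is the
  Nernst slope up to threshold-extraction discretization.

The mapping assumes Eg/2 ≫ kT (enforced: Eg/2 > 10 kT), a single
monovalent ion pair, ideal activity, no site-binding chemistry at the
oxide and no Stern layer — the diffuse (Gouy–Chapman) layer emerges from
the solver; surface protonation does not. Real oxide surfaces are
sub-Nernstian for exactly that reason, which is why measured ISFETs show
~50 mV/pH against the ~59.5 mV/pH this model produces.

Ion transport uses the mobilities of Na⁺ (4.98·10⁻⁴ cm²/V·s → holes) and
Cl⁻ (6.88·10⁻⁴ cm²/V·s → electrons), so the "semiconductor" is as slow as
a real ionic solution. τ_n = τ_p = 10⁻⁵ s (configurable) controls the
generation/recombination of the ion pair and the silicon SRH lifetimes.

### Reference device

Geometry defaults (all configurable via `default_isfet_device(**overrides)`
or the `[device]` config section):

| parameter | default | note |
|---|---|---|
| channel length | 5 µm | tiled exactly by 10 receptor blocks of 0.5 µm |
| source/drain windows | 1 µm, n⁺ Gaussian peak 10¹⁹ cm⁻³ | junction depth 0.5 µm, lateral straggle 0.1 µm |
| substrate | p-type, N_A = 10¹⁵ cm⁻³, 2 µm deep | "low doped" |
| gate oxide | 25 nm SiO₂ | |
| electrolyte column | 2 µm, ε_r = 78 | reference electrode on top |
| receptor blocks | 0.5 × 0.05 µm, ε_r = 2.5, standoff 0 | |Q_T| = 4.8·10⁻¹⁶ C when bound |
| out-of-plane width | 1 µm | currents reported in A/µm |

The bound-receptor charge sign defaults to **positive** (attracting
channel electrons): over a p substrate that is the polarity that turns the
n-channel on and gives increasing I_D with occupancy; both signs are
supported. Source/drain ohmic contacts cover only 70% of the junction
depth — an ohmic boundary reaching into the space-charge region would pin
near-equilibrium densities there and act as a parasitic carrier sink.

The reference electrode is an ideal conductor (Dirichlet ψ = V_REF + β,
n = p = n_i) with zero workfunction offset.

## Numerics

* **Discretization.** Finite volumes on a graded tensor-product mesh;
  mesh lines are forced onto all material boundaries, so every cell is
  single-material and the receptor-charge integral is conserved exactly.
  The default device meshes to ≈ 3.5k nodes (1 nm silicon spacing at the
  interface, 5 nm first electrolyte spacing); `MeshSpec(scale=s)` scales
  all target spacings.
* **Fluxes.** Scharfetter–Gummel exponential fitting with the Bernoulli
  function evaluated via `expm1` (relative accuracy 10⁻¹²; asymptotic
  branches beyond |x| = 500).
* **Outer iteration.** Gummel: nonlinear Poisson (Newton, update clipped
  at 0.5 V with residual backtracking, tolerance 10⁻⁹ V) alternating with
  linear electron and hole solves (SRH linearized in the solved carrier).
  Convergence: max |Δψ| < 10⁻⁶ V and terminal-current change below
  10⁻⁵·|I| + 10⁻¹⁵ A/µm. Bias continuation steps 50 mV with automatic
  halving.
* **Exact per-system equilibria.** A carrier system whose contacts all
  share one voltage V (the electrolyte always — it has a single electrode;
  the silicon whenever V_S = V_D = V_B) has the exact steady state
  φ_n = φ_p = V, np = n_i², zero current; such systems are set analytically
  instead of iterated. This removes a slow recombination-relaxation mode
  and makes zero-bias currents identically zero.
* **Current extraction.** Contact currents are summed in the quasi-Fermi
  form J = −g·B(Δψ/V_T)·c·expm1(Δφ/V_T), which has no large-term
  cancellation. After convergence, one extra pass re-solves both
  continuity equations against a single frozen recombination field so the
  discrete contact currents telescope to Σ I = q∫R − q∫R = 0 up to linear
  solver round-off. The remaining absolute resolution of a terminal
  current on the default device is ≈ 10⁻¹⁵ A/µm (set by round-off on the
  majority-carrier flux scale at the n⁺ contacts); currents below that
  floor are reported but carry no information, and current ratios in the
  experiment drivers clamp the denominator at the floor (which can only
  shrink a reported ratio). Kirchhoff conservation to 10⁻⁶ relative is
  verified at operating points whose currents are far above the floor.
* **Mobility.** Simplified Lombardi surface model in silicon only:
  1/µ = 1/µ_max + E⊥/B + E⊥²/δ with B_n = 4.75·10⁷ cm/s,
  δ_n = 5.82·10¹⁴, B_p = 9.93·10⁶ cm/s, δ_p = 2.05·10¹⁴ — conventional
  calibration constants, not fitted values; E⊥ is the local vertical
  field, lagged one Gummel iteration. Ion mobilities are field-independent.
* Density exponents are clipped at ±60 kT during Newton transients;
  Boltzmann statistics throughout (no Fermi–Dirac, no incomplete
  ionization, no impact ionization or tunnelling); temperature fixed at
  300 K.

## Experiments and operating points

* **pH sensitivity**: I_D–V_REF sweeps at V_DS = 2 V for pH {4, 7, 10};
  constant-current threshold at I_crit = 1·10⁻⁷·(W/L) = 2·10⁻⁸ A/µm with
  log-linear interpolation; ordinary least-squares slope in mV/pH.
  Measured on the default mesh: **59.6 mV/pH** (the Nernst value, as the
  translation argument above predicts), inside the expected 45–62 mV/pH
  band for this idealized electrode model.
* **Occupancy studies** (random combinations, modulation ratio): V_DS =
  100 mV, V_REF ∈ {0, 1} V. Patterns are drawn uniformly without
  replacement from the C(N, n_on) combinations with a seeded numpy PCG64
  generator; identical seeds give identical patterns and currents.
* **Position scan / pattern comparison** default operating point: V_DS =
  100 mV, **V_REF = 0.5 V** — sub-threshold (threshold is ≈ 0.89 V at
  pH 7) but three decades above the current-extraction floor, so the
  single-block orderings (mid-channel C5/C6 strongest, source side C2/C3
  above the mirrored drain side C8/C9, edge blocks C1/C10 weakest) are
  resolved cleanly.
* **Channel profiles**: electron density 2 nm below the Si/SiO₂ interface
  (configurable).

## Known limitations

* The device calibration (doping, oxide, ideal electrode) puts the pH-7
  threshold at ≈ 0.89 V, so at V_REF = 0 the transistor sits ~11
  sub-threshold decades down and its off-current is below the numerical
  floor. Consequently the simulated I_D step from V_REF = 0 to 1 V spans
  ~8 orders of magnitude, and experiments at V_REF = 0 resolve only
  multi-block charge patterns; single-block effects need the 0.5 V scan
  point. A lower-threshold calibration (higher substrate doping or an
  electrode workfunction offset) compresses this step.
* A *neutral* receptor block is not a negligible perturbation: it replaces
  conductive electrolyte with a 50 nm, ε_r = 2.5 series dielectric and
  shifts the threshold by ~0.2–0.3 V relative to the bare ISFET. The
  bare-device limit is recovered as the block thickness → 0. All
  comparisons in the experiment drivers are therefore made against the
  all-neutral baseline of the *same* geometry.
* Absolute current magnitudes depend on the geometry calibration and the
  Lombardi constants; orderings, ratios and threshold shifts are the
  robust outputs.
* 2D only (out-of-plane width is a scale factor), DC only, two carrier
  species, no electro-chemical surface reactions.

## Configuration reference

TOML sections and keys (all optional): `[electrolyte]` pH, temperature_K,
eps_r, pKw, mu_cation, mu_anion, Eg0, alpha, beta, tau_n, tau_p;
`[device]` n_receptors, pattern, channel_length_um, sd_window_um,
substrate_depth_um, oxide_thickness_um, electrolyte_height_um,
junction_depth_um, lateral_straggle_um, nd_peak_cm3, na_substrate_cm3,
receptor_length_um, receptor_thickness_um, receptor_eps, Q_T_coulomb,
charge_sign, width_um; `[mesh]` scale and per-region target spacings;
`[solver]` gummel_tol_V, current_rel_tol, max_gummel_iters,
newton_damping, continuation_step_V, current_floor_A_per_um, newton_tol_V,
max_newton_iters, psi_update_clip_V, verbose; `[experiment]` name, seed,
v_ds, v_ref, sweep_start/stop/step, ph_values, i_crit_A_per_um, n_on,
n_samples, cut_x_um, profile_depth_um. Canonical serialization
(`serialize_config`) is deterministic and hashed into the run record.
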