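# biofetsim

2D drift–diffusion simulation of ISFET and BioFET biosensors, built around
the *electrolyte-as-semiconductor* device model.

## The problem

An ISFET (ion-sensitive field-effect transistor) is a MOSFET whose metal
gate is replaced by an electrolyte contacted from above by a reference
electrode; its threshold voltage shifts with solution pH. Functionalizing
the gate oxide with biological receptors turns it into a BioFET: charged
target molecules captured at the surface gate the channel and modulate the
drain current. Designing such sensors needs device-level simulation, but
standard semiconductor solvers have no electrolyte material.

`biofetsim` closes that gap by representing the ionic solution as an
**equivalent intrinsic semiconductor**: hydronium ions map to holes,
hydroxide ions to electrons, and the effective densities of states encode
the solution chemistry through the ionic product of water
K_W = [H₃O⁺][OH⁻] = 10⁻ᵖᴷʷ and the Avogadro conversion
1 mol/L → 6.022·10²⁰ cm⁻³. With Boltzmann statistics
(n = N_C e^−(E_C−E_f)/kT, p = N_V e^−(E_f−E_V)/kT) and the Fermi level of
the neutral (pH 7) solution at midgap,

    N_V = p(pH)·e^{Eg/2kT},   N_C = n(pH)·e^{Eg/2kT},   Eg = 1.5 eV,

which gives N_C = N_V ≈ 2.4·10²⁶ cm⁻³ at pH 7 and T = 300 K, an intrinsic
density n_i = 6.022·10¹³ cm⁻³ independent of pH, and a pH-dependent band
offset (kT/2)·ln(N_V/N_C) that advances by exactly kT·ln10 ≈ 59.6 meV per
pH unit — the Nernstian response. The Poisson–Boltzmann double layer then
*emerges* from the ordinary semiconductor equations, so one
finite-volume Poisson / electron–hole continuity solver
(Scharfetter–Gummel fluxes, Gummel outer iteration, SRH recombination,
simplified Lombardi surface mobility) handles silicon, oxide, electrolyte
and charged receptor blocks self-consistently.

The reference device is a planar ISFET (p substrate, n⁺ source/drain,
25 nm gate oxide, 2 µm electrolyte column) whose 5 µm channel is segmented
by ten 0.5 µm receptor blocks; a bound target deposits a fixed charge
|Q_T| = 4.8·10⁻¹⁶ C in one block.

## Worked example

```python
from biofetsim import ElectrolyteSpec, build_electrolyte_material
m = build_electrolyte_material(ElectrolyteSpec(pH=7.0))
print(f"NC = {m.NC:.3e} cm^-3, NV = {m.NV:.3e} cm^-3")
print(f"ni = {m.ni:.3e} cm^-3, band offset = {m.band_reference*1e3:.1f} meV")
m4 = build_electrolyte_material(ElectrolyteSpec(pH=4.0))
print(f"pH 4 band offset = {m4.band_reference*1e3:.1f} meV")

from biofetsim import default_isfet_device, BiasPoint
from biofetsim.experiments import compare_patterns
dev = default_isfet_device(10, 7.0)
table = compare_patterns(dev, [(), (1, 2, 3), (2, 5, 8)], 4.8e-16,
                         BiasPoint(V_drain=0.1, V_ref=0.5))
print(table.to_string(index=False))
```

prints

```
NC = 2.394e+26 cm^-3, NV = 2.394e+26 cm^-3
ni = 6.022e+13 cm^-3, band offset = 0.0 meV
pH 4 band offset = 178.6 meV
pattern  n_on  I_D_A_per_um
            0  1.306674e-12
  1;2;3     3  2.723559e-12
  2;5;8     3  3.749947e-10
```

Reading the numbers: the pH-7 solution maps to a symmetric material
(N_C = N_V, zero band offset); at pH 4 the bands shift by
3 × 59.5 meV = 178.6 meV, which is what shifts the transistor threshold.
In the sub-threshold operating point (V_DS = 0.1 V, V_REF = 0.5 V) three
charged receptors grouped at the source end ({1,2,3}) barely double the
drain current, while the same three charges spread along the channel
({2,5,8}) raise it by more than two orders of magnitude — channel
conductance is an exponential, not additive, function of the local barrier
profile, so charge *position* matters as much as charge *amount*.

## Command line

```sh
biofetsim sweep --kind vref --config run.toml   # I_D–V_REF curve -> CSV
biofetsim ph-scan                                # V_T vs pH, mV/pH slope
biofetsim receptor-scan                          # single-block position scan
biofetsim occupancy --seed 7                     # random occupancy patterns
biofetsim simulate                               # field dump (x, y, ψ, n, p)
```

Each subcommand reads an optional TOML config (all keys documented in
`docs/methods.md`, all defaults sensible), writes CSV tables plus a JSON
run record (config hash, seed, manifest), and is deterministic in
(config, seed).

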