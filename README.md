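# camphase

Phase behavior of binary drug–drug co-amorphous systems: eutectic phase
diagrams from the solubility equation under ideal or PC-SAFT activity
models, Gordon–Taylor/Kwei glass-transition modelling, and Tammann-plot
eutectic-composition estimation.

Co-amorphous formulation stabilizes a poorly glass-forming drug by
co-melting it with a partner drug and quenching the melt.  Designing such
formulations needs two pieces of thermodynamics: the **liquidus curve /
eutectic point** of the crystalline blend (where to melt, what composition
minimizes the melting temperature) and the **glass transition** of the
amorphous mixture (how stable the glass is, and what the Tg of a pure
component that cannot be vitrified alone would be).  `camphase` implements
both for blends of indomethacin (IND), ibuprofen (IBU), naproxen (NAP),
paracetamol (PAR) and probucol (PRO), with the measured pure-component
data bundled as fixtures.

## Models

Solubility of crystalline API i in the melt:

    ln(x_i γ_i) = −Δ_fus H/(R T)·(1 − T/T_m) − Δ_fus Cp/(R T)·(T − T_m)
                  + (Δ_fus Cp/R)·ln(T/T_m)

with γ_i = 1 (ideal) or from a full PC-SAFT equation of state
(hard-chain + dispersion + association, k_ij = 0, complex-step
thermodynamic derivatives).  The eutectic (T_E, x_E) is the intersection of
the two liquidus branches.  Mixture glass transitions follow
Gordon–Taylor, Tg = (x₁Tg₁ + k x₂Tg₂)/(x₁ + k x₂), or Kwei
(+ q x₁x₂), fitted with arbitrary free/fixed parameter masks.  Tammann
plots (eutectic-peak enthalpy vs composition) give an independent,
model-free x_E estimate.  Details and all numerical choices:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import camphase as cp

system = cp.binary_system("NAP", "IND")        # bundled fixtures
ideal  = cp.eutectic_point(system, "ideal")
saft   = cp.eutectic_point(system, "pcsaft")
print(f"ideal : T_E = {ideal.temperature - 273.15:.1f} C, "
      f"x_NAP = {ideal.composition:.2f}")
print(f"pcsaft: T_E = {saft.temperature - 273.15:.1f} C, "
      f"x_NAP = {saft.composition:.2f}")
```

prints

```
ideal : T_E = 128.3 C, x_NAP = 0.55
pcsaft: T_E = 124.8 C, x_NAP = 0.55
```

i.e. the naproxen–indomethacin blend melts jointly at ≈128 °C (ideal
mixing) or ≈125 °C once PC-SAFT activity coefficients are included, at a
near-equimolar eutectic composition — the composition window where a
co-amorphous formulation is easiest to produce.  The same surface exists
on the command line:

```sh
camphase eutectic --system nap-ind --model pcsaft
camphase phase-diagram --system nap-ibu --model ideal --grid 101 --out diagram.csv
camphase tg-fit --data tg.csv --model kwei --free k,q,Tg_1
camphase tammann --data tammann.csv
camphase reproduce
```

The numbered scripts under `analysis/` run the full study — phase diagrams
and eutectics for all four blends (`01`), liquidus deviation statistics
against the bundled DSC data (`02`), the pooled pure-naproxen Tg of
6.4 ± 1.4 °C plus synthetic-data recovery of the Kwei fits (`03`), and the
Tammann recovery study (`04`) — writing their tables under `results/`.

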