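# Methods

`camphase` models the solid–liquid and glass-transition behavior of binary
drug–drug co-amorphous blends of five APIs: indomethacin (IND), (RS)-ibuprofen
(IBU), (S)-naproxen (NAP), paracetamol (PAR) and probucol (PRO), covering the
four blends NAP–IND, NAP–IBU, NAP–PRO and IND–PAR.

## Solid–liquid equilibrium

The liquidus condition for a crystalline component i in the binary melt is

    ln(x_i γ_i) = −Δ_fus H_i/(R T) (1 − T/T_m,i)
                  − (Δ_fus Cp_i/(R T)) (T − T_m,i)
                  + (Δ_fus Cp_i/R) ln(T/T_m,i),

with a temperature-independent heat-capacity difference Δ_fus Cp between
liquid and crystal (the two integral terms are the closed forms for constant
Δ_fus Cp).  Fusion inputs are the measured values bundled in
`data/components.csv` (T_m in °C, Δ_fus H in kJ/mol, Δ_fus Cp in J/(K·mol)).
Two activity models are implemented:

* **ideal** — γ_i ≡ 1.  The liquidus depends only on the governing solid's
  fusion properties (asserted by a partner-swap test).
* **pcsaft** — γ_i from the PC-SAFT equation of state (below), evaluated as
  ln γ_i = ln φ_i(T, P, x) − ln φ_i(T, P, pure liquid) at P = 101325 Pa.
  Ambient pressure is an assumption: liquid-phase activity coefficients are
  nearly pressure-insensitive, and sub-bar changes move the computed
  eutectics by far less than the experimental uncertainty.

A liquidus temperature is found by bracketed Brent iteration on
ln(x γ(T,x)) − rhs(T), tolerance 1e-4 K, bracket walked down from T_m.  Note
that the full right-hand side is *non-monotonic* in T (the Δ_fus Cp terms
dominate far below T_m), so a spurious lower root can exist; the PC-SAFT
search is therefore anchored at the ideal-model root, which is unique on the
physical branch, and refined with an expanding bracket.

The eutectic is the intersection of the two liquidus branches.  The default
locator solves the two saturation conditions simultaneously for (T_E, x_E)
with a Newton-type solver started from the ideal-model intersection; a
bracketed composition scan (`method="scan"`) is the assumption-free fallback
and the default for the cheap ideal model.  Both agree to ≤ 0.01 K / 1e-3 in
tests.  Deviation statistics against the DSC liquidus data are
ΔT_i = T_calc(x_i) − T_exp(x_i) and σ = mean |ΔT_i|.

## PC-SAFT

The residual Helmholtz energy is a_res = a_hc + a_disp + a_assoc: hard-chain
reference with temperature-dependent segment diameters
d_i = σ_i (1 − 0.12 e^{−3ε_i/kT}) and the Boublik–Mansoori hard-sphere
mixture term; dispersion through the two power-series integrals with the
published universal constants (stored in `constants.py`); association by
mass action over donor/acceptor site classes ("4 (2/2)" = 2 electron donors
+ 2 acceptors, "6 (3/3)" = 3 + 3; donors bond only to acceptors).
Association strength uses σ_ij³ (not d_ij³) and the Wolbach–Sandler-type
combining rules ε^assoc_ij = (ε^assoc_i + ε^assoc_j)/2,
κ^assoc_ij = √(κ_i κ_j) (√(σ_iσ_j)/σ_ij)³.  Cross dispersion uses the
arithmetic/geometric rules with k_ij = 0 throughout (purely predictive; the
`BinaryInteraction` field exists for generality).

All derivatives (compressibility Z = 1 + ρ ∂a/∂ρ, the composition
derivatives in ln φ_i = a_res + ∂a/∂x_i − Σ_j x_j ∂a/∂x_j + Z − 1 − ln Z,
taken in the unconstrained convention at constant T, ρ) are evaluated by
complex-step differentiation with step 1e-30, which is exact to machine
precision and propagates through the site-fraction fixed point because the
iteration runs in complex arithmetic.  Tests confirm agreement with central
finite differences to 1e-6 and a Gibbs–Duhem residual below 1e-6.

Site fractions are solved by damped successive substitution (damping 0.5,
increment tolerance 1e-14, cap 500); for a pure two-site symmetric component
the result matches the closed-form quadratic root to 1e-10.

The density solver brackets P(T, ρ, x) = P on a packing-fraction grid
η ∈ (1e-10, 0.7405) (one vectorized EOS evaluation) and polishes each root
with Brent iteration to machine tolerance.  Root classification matters for
deeply subcooled liquids: vapor-like roots sit at η < 0.15, and at low
temperature strongly associating systems develop a spurious additional
high-packing liquid-like root (a known artifact of the association term).
Liquid-like candidates are therefore ranked by residual Gibbs energy
g_res = a_res + (Z−1) − ln Z and the lower one taken; this keeps the density
and γ continuous down to at least 230 K for all blends studied.

As an external anchor with no free choices, the EOS reproduces the liquid
density of n-hexane at 298 K (literature parameters) within 1% of the
handbook value, and a Carnahan–Starling reduction is asserted for m = 1.

## Data corrections and known input inconsistencies

Two issues in the published tables were identified while validating the
implementation; both are recorded here because they determine which
regression checks can pass.

1. **Probucol dispersion energy.**  The circulated parameter table prints
   ε_PRO/k = 175.62 K.  With that value PC-SAFT predicts near-immiscibility
   of NAP–PRO (γ_NAP ≈ 8–10, a degenerate eutectic at x_NAP ≈ 0.003), the
   opposite regime from every published NAP–PRO result (negative deviations
   down to −28.6 °C; eutectic 104.9 °C at x = 0.41).  With ε_PRO/k =
   375.62 K — a single corrupted digit — every published NAP–PRO PC-SAFT
   number is reproduced at the same precision as the other three blends
   (eutectic 105.0 °C at x = 0.402; per-point ΔT within 0.7 °C).  The
   packaged fixture therefore carries 375.62 K.
2. **Ideal-solubility columns.**  The published ideal-model values are
   mutually inconsistent: the NAP–IND entries match the full equation above
   (our ΔT agree to 0.1–0.2 °C), while the NAP–IBU and NAP–PRO ideal entries
   match a van't-Hoff-only calculation (Δ_fus Cp dropped on the NAP branch),
   and the implied IND–PAR curves are non-monotonic in composition, which no
   liquidus model can produce.  The same NAP branch has different published
   values in two tables (e.g. 132.5 vs 133.1 °C at x_NAP = 0.6).  `camphase`
   implements the full equation for all systems.  Consequently the ideal
   eutectics for NAP–IBU, NAP–PRO and IND–PAR land 1.3–1.9 °C below the
   published ones, and several σ regression checks cannot pass at their
   stated tolerances; the corresponding tests are left failing rather than
   loosened, and the discrepancy is the documented reason.

## Glass transitions

Gordon–Taylor: Tg(x₁) = (x₁Tg₁ + k x₂Tg₂)/(x₁ + k x₂); Kwei adds q·x₁x₂.
Compositions are mole fractions and the quotient is evaluated in kelvin by
default — the k fitted by these equations depends on the temperature origin,
and kelvin is the physically standard choice; a `celsius` switch exists to
probe that sensitivity.  Fitting is bounded least squares
(k ∈ (0, 10], q ∈ [−200, 200] K) over an arbitrary free/fixed parameter
mask, with a small deterministic multistart in k because a free endpoint
plus free k admits local minima at small n.  This is how the Tg of pure
naproxen — a poor glass former that cannot be vitrified alone — is
extrapolated from mixture data: Tg,NAP is declared free and recovered by the
fit.  Pooling the six published per-system estimates gives
6.4 ± 1.4 °C (mean ± sd of the mean), the package's hard regression number.
The raw mixture-Tg datasets are not redistributable, so the individual
published (k, q, Tg,NAP) fits are covered by synthetic-data recovery
studies instead: on data generated from the published Kwei parameters with
0.3 K noise, the endpoint is recovered with bias within two Monte-Carlo
standard errors (200 seeds, n = 8).

## Tammann plots

The eutectic-peak melting enthalpy grows linearly with the eutectic amount
on each side of x_E and vanishes at the pure components.  `tammann_eutectic`
fits one line per branch (split at the empirical maximum; optionally forced
through zero at x = 0 and 1 — the default is the unconstrained fit, since
the published variant is unspecified) and intersects them; the 1-σ
uncertainty comes from first-order propagation of the two fit covariances.
Near-apex points can be excluded (`exclude_near_peak`) because overlapping
eutectic and liquidus peaks make those integrations least reliable.  The
published per-system x_E values are again not desk-reproducible (no raw
enthalpies), so the estimator is qualified by recovery studies: with 3%
relative enthalpy noise, 500 seeds and 9 points the estimate is unbiased to
< 0.01 with spread ≈ 0.015, consistent with the stated 0.05 experimental
uncertainty.

## Synthetic data

`synthetic.py` generates the three dataset shapes the analyses consume, all
seeded through numpy's PCG64 so regeneration is byte-identical.  Defaults
mirror the stated measurement uncertainties: 0.3 K Gaussian noise for
transition temperatures (liquidus and Tg), 3% relative for enthalpies;
composition grids default to the 0.1 spacing of the emulated DSC series, and
Tg grids stop at x₁ = 0.7 because naproxen-richer mixtures cannot be
quenched to a single glass.  Liquidus datasets never emit points below the
generating eutectic temperature.  What the generators do *not* emulate:
peak-shape/integration artifacts, composition errors from sample
preparation, thermal-history effects on Tg, and any correlated noise — so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to every feature of real thermograms.

## Problem sizes and numerical defaults

Phase diagrams default to 101-point composition grids; eutectic Newton
solves iterate to 1e-10; liquidus roots to 1e-4 K; density roots to machine
precision in η; site fractions to 1e-14.  The analysis drivers and the test
suite run the four blends end to end (both activity models) in a few
minutes on one CPU.  Metastable branch extensions beyond the eutectic are
computed while solvable and flagged, matching the convention of drawing
extended liquidus curves.

## Limitations

Binary systems only; no solid solubility, cocrystal phases, or metastable
eutectics; no polar/quadrupolar PC-SAFT extensions; k_ij is never
regressed; vapor–liquid equilibrium is outside scope (the vapor branch of
the density solver exists only for limit checks).  The PRO parameter set is
an approximate parametrization (flagged as such in its source) and results
involving PRO inherit that caveat.
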