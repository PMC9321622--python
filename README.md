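# specbind

Analysis of small-molecule binding to serum albumin from multi-spectroscopic
titrations. Given fluorescence quenching titrations, UV-Vis / CD / FTIR
traces and DPPH assay absorbances, `specbind` computes the quantities a
protein–ligand binding study reports: the quenching mechanism, binding
constant and stoichiometry, thermodynamic driving forces, the Förster
energy-transfer distance, site-marker competition, secondary-structure
changes and the attenuation of the ligand's antioxidant activity on
binding. A synthetic-data generator emulates every input, so the whole
chain is testable without instrument data.

## The models

* **Stern–Volmer quenching** — `F0/F = 1 + Ksv[Q] = 1 + kq·τ0·[Q]`.
  `Ksv` is fitted by OLS; `kq = Ksv/τ0` (τ0 = 10⁻⁸ s for HSA). Ksv
  decreasing with temperature together with `kq` above the diffusion limit
  (2×10¹⁰ L·mol⁻¹·s⁻¹) indicates static quenching via a ground-state
  complex.
* **Double-logarithm binding plot** — `lg((F0−F)/F) = lg Ka + n·lg[Q]`
  gives the apparent binding constant `Ka` (intercept) and the number of
  binding sites `n` (slope).
* **Van't Hoff thermodynamics** — `ln Ka = −ΔH⁰/RT + ΔS⁰/R`, then
  `ΔG⁰ = ΔH⁰ − TΔS⁰` (with `−RT ln Ka` reported as a cross-check), and
  sign-based force typing: ΔH⁰ < 0 with ΔS⁰ > 0 → electrostatic with a
  hydrophobic contribution, both > 0 → hydrophobic, both < 0 → hydrogen
  bonding / van der Waals.
* **FRET** — `E = 1 − F/F0`, overlap integral
  `J = Σ F(λ)ε(λ)λ⁴Δλ / Σ F(λ)Δλ`, critical distance
  `R0⁶ = 8.79×10⁻⁵ k² n⁻⁴ Φ J` (Å⁶, nm⁴·M⁻¹·cm⁻¹ convention; a legacy
  cm-axis convention is also supported), and the donor–acceptor distance
  `r = R0((1−E)/E)^{1/6}`, flagged valid when `r < 7 nm` and
  `0.5 R0 < r < 1.5 R0`.
* **Conformation** — synchronous-fluorescence quench slopes and peak
  shifts at Δλ = 15/60 nm (tyrosine / tryptophan); mean residue
  ellipticity `MRE = θobs/(10·cp·n·l)` and the two-anchor α-helix estimate
  `α% = (−MRE₂₀₈ − 4000)/29000 × 100`; amide-I (1600–1700 cm⁻¹) Gaussian
  band decomposition into β-sheet / random coil / α-helix / β-turn /
  β-antiparallel area fractions.
* **DPPH antioxidant assay** — scavenging
  `% = 100(A_control − A_sample)/A_control`, IC50 from a two-parameter
  log-logistic fit (or monotone interpolation), and the free-vs-complexed
  attenuation ratio.

## Worked example

Generate a synthetic study (three-temperature titration, FRET pair, CD, FTIR
and DPPH inputs) and analyse it end to end:

```sh
specbind simulate --outdir demo --seed 0
specbind report demo/config.yaml --markdown
```

The report reproduces the generating ground truth. With the default
parameters (ΔH⁰ = −14.12 kJ·mol⁻¹, ΔS⁰ = 43.57 J·mol⁻¹·K⁻¹, 1:1 binding,
noiseless):

```
Ksv(288 K) = 6.87e4 L/mol   kq = 6.87e12 L/mol/s
Ksv(298 K) = 5.64e4         kq = 5.64e12
Ksv(310 K) = 4.52e4         kq = 4.52e12      mechanism: static
ΔH⁰ = −14.12 kJ/mol   ΔS⁰ = 43.57 J/mol/K
ΔG⁰ = −26.67 / −27.10 / −27.63 kJ/mol (288/298/310 K)
force: electrostatic (with hydrophobic contribution)
α-helix (CD, 208 nm): 59.24 %
DPPH IC50: free 9.653 → complexed 10.68 µg/mL, ratio 1.106 (attenuated)
```

Ksv decreasing with temperature while kq stays ~100× above the collisional
diffusion limit classifies the quenching as static (complex formation); the
negative ΔG⁰ values mean spontaneous binding; the IC50 ratio > 1 means the
protein partially masks the ligand's radical-scavenging sites.

Individual stages are available as `specbind quench | binding | compete |
thermo | fret | cd | ftir | dpph`, all reading plain CSV/TSV and printing
JSON; the same functions are importable from Python (`import specbind`).

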