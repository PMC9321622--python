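# Methods

This note documents the models implemented in `specbind`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Quenching and binding fits

Fluorescence titrations are analysed with two linearisations of the 1:1
complex-formation model. The Stern–Volmer regression fits `F0/F` against
`[Q]` by unweighted ordinary least squares with a **free intercept**: the
intercept is definitionally 1, and its fitted deviation from 1 is a useful
diagnostic of inner-filter effects or baseline drift. The `[Q] = 0` point
is excluded from the regression — it is exact by construction and would
otherwise over-weight the origin. The reported `SD` is the standard error
of the slope (i.e. of Ksv), and `R` the Pearson correlation, matching how
such tables are customarily printed. An optional inner-filter correction
`F·10^((A_ex+A_em)/2)` is provided but off by default.

The double-logarithm fit regresses `log10((F0−F)/F)` on `log10[Q]`.
Points with `F ≥ F0` (negative apparent quench from noise) have no defined
logarithm and are **dropped with a warning** rather than clamped, so the
exclusion is auditable. `Ka = 10^intercept`; its standard deviation is
propagated as `Ka·ln(10)·SE(intercept)`. Note that the intercept sits ~5
decades outside the sampled `log10[Q]` range (µM concentrations), so `Ka`
from noisy data has a heavy-tailed, roughly log-normal error: single-fit
errors of tens of percent at 1% intensity noise are expected, while the
median over replicates is within a few percent of truth. Recovery tests
therefore assert ensemble medians, not single fits.

Mechanism classification requires **both** criteria jointly: "static"
needs Ksv non-increasing with temperature and every `kq = Ksv/τ0` above
the collisional diffusion limit (default 2.0×10¹⁰ L·mol⁻¹·s⁻¹, τ0 default
10⁻⁸ s); "dynamic" the converse; anything mixed is "indeterminate" with
both pieces of evidence reported.

## Thermodynamics

The Van't Hoff fit is the two-parameter form (ΔH⁰ assumed constant over
the fitted 22 K span); curvature (heat-capacity) terms are out of scope.
The headline ΔG⁰ uses the `ΔH⁰ − TΔS⁰` route, which is how the reference
tables are computed; `−RT ln Ka` is reported alongside so the (small)
discrepancy between the two routes is visible rather than hidden. ΔS⁰ is
standardised to J·mol⁻¹·K⁻¹. Force typing follows the sign-quadrant rules
(electrostatic / hydrophobic / H-bond+vdW), with exact zeros mapped to
"indeterminate". The kcal→kJ conversion uses the International Table
calorie (4.1868 J) by default; the factor is configurable.

## FRET

Donor emission and acceptor molar absorptivity are linearly interpolated
onto their overlapping wavelength range at the finer of the two median
grid spacings, and the overlap integral uses trapezoid weights; the
denominator normalises away the donor's absolute scale. Two unit
conventions exist because the literature is inconsistent: "standard"
(λ in nm, `J` in nm⁴·M⁻¹·cm⁻¹, `R0(Å)⁶ = 8.79×10⁻⁵ k²n⁻⁴ΦJ`) and
"legacy" (coefficient 8.78×10⁻²³ applied on a cm wavelength axis).
Printed (J, coefficient, R0) triplets in older papers are frequently not
mutually consistent under any single reading, so the `(E, R0) → r`
inversion is treated as the canonical chain and the validity flags
(`r < 7 nm`, `0.5·R0 < r < 1.5·R0`, strict) are evaluated on it. The
defaults k² = 2/3, n = 1.336, Φ = 0.118 are the customary values for the
tryptophan donor of serum albumin in aqueous buffer; they are
configuration, not constants.

## Conformation metrics

Peak localisation everywhere is grid-based (no sub-grid interpolation),
because instruments report peaks on their scan grids; ties break toward
the shorter wavelength. 3D-fluorescence peak picking masks first- and
second-order Rayleigh bands (|λem − λex| and |λem − 2λex| ≤ 15 nm by
default) but performs the local-maximum comparison on the raw matrix, so
a peak buried inside a scatter band is dropped without creating spurious
maxima at the band edges.

The CD chain is the two-anchor estimate only: `MRE = θobs/(10·cp·n·l)`
(n = 585 residues and l = 0.1 cm by default) and
`α% = (−MRE₂₀₈ − 4000)/29000 × 100`, exact at both anchors and clamped to
[0, 100] with a warning outside. Basis-set deconvolution (SELCON etc.) is
deliberately out of scope.

The amide-I decomposition subtracts a linear baseline anchored on the mean
of the three edge points of the 1600–1700 cm⁻¹ region, then fits a sum of
Gaussian bands by least squares (lmfit/Levenberg–Marquardt). Two
identifiability constraints matter: all component bands share a **single
fitted width** (bounded 3–14 cm⁻¹), and each centre may move at most
±4 cm⁻¹ from its nominal position (1630, 1645, 1654, 1670, 1685 cm⁻¹).
With per-band free widths the decomposition is degenerate — the 1645/1654
pair trades area freely and per-class errors reached ~16 percentage
points; with the constraints, five-class recovery on synthetic envelopes
at 0.1% noise stays within ~2 points. Fractions are component areas over
the total area, assigned to classes by fitted centre (β-sheet 1610–1640,
coil 1640–1648, helix 1648–1660, turn 1660–1680, antiparallel
1680–1695 cm⁻¹), and sum to exactly 100 by construction. Band positions
and windows are configuration (`BandSpec`), not code constants.

## DPPH

The standard scavenging definition `100(A_control − A_sample)/A_control`
is the default; the dimensionally inconsistent literal form sometimes
printed (`A_control − A_sample/A_sample`) is retained behind
`mode="literal"` purely for audit. IC50 defaults to a two-parameter
log-logistic fit with asymptotes fixed at 0 and 100% (the assay's bounded
response); `method="interp"` linearly interpolates the 50% crossing and
demands a monotone response. Results are flagged `extrapolated` when the
responses do not bracket 50% or the estimate falls outside the measured
span.

## Synthetic data

The generators mirror a typical serum-albumin/flavonoid study: protein at
2.5×10⁻⁶ M, ligand titrated 0→2.5×10⁻⁵ M in 2.5×10⁻⁶ M steps, excitation
280 nm, a Gaussian emission band at 327 nm (σ = 18 nm) red-shifting
0.2 nm per titration step, binding constants generated from
ΔH⁰ = −14.12 kJ·mol⁻¹ and ΔS⁰ = 43.57 J·mol⁻¹·K⁻¹ at 288/298/310 K
(within 3% of the published triplet), a two-Gaussian FRET pair whose
reference overlap integral comes from a 10×-finer quadrature, CD traces
scaled to hit a target helix content exactly at 208 nm, amide-I envelopes
as sums of the five default Gaussian bands, and DPPH absorbances from an
exact log-logistic law (IC50 9.653 / 10.68 µg·mL⁻¹, Hill slope 1.2).
Noise is Gaussian, with σ specified per channel as a fraction of the
signal maximum, drawn from a single explicitly seeded generator; outputs
are byte-identical under a fixed seed, and every generator is the exact
right-inverse of its analysis stage at zero noise.

What the generators do **not** emulate: inner-filter attenuation,
photobleaching, ligand depletion, wavelength-dependent detector response,
correlated (pink) noise, and scattering backgrounds other than the
Rayleigh bands in the EEM generator. Passing recovery tests therefore
demonstrate correctness of the estimators under idealised conditions, not
robustness to every instrumental artefact.

## Problem sizes and determinism

Stochastic recovery studies use 100–200 seeds for the titration/IC50
ensembles and 50 seeds for the five-band amide-I study; all complete in
seconds. Pipeline reports are deterministic given identical inputs and
configuration, and the report's config hash covers both the constants and
the input file bytes.
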