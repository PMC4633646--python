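# Methods

This note records the models behind each module, the default parameters
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that shape the results.

## Unit system and cell parameters

All internal quantities use the electroanalytical convention: V, A, C, s,
cm², cm² s⁻¹ and mol cm⁻³.  Interfaces accept the units practitioners
quote — mM for dissolved O₂, rpm for rotation rates, mV/µA in data files —
and convert on ingestion, so the Levich prefactor 0.62 applies verbatim.
`ElectrochemConstants` defaults describe an air-saturated pH 7 buffer at
25 °C on a 0.096 cm² gold disc: [O₂] = 0.26 mM, D(O₂) = 1.8 × 10⁻⁵ cm² s⁻¹,
ν = 0.009 cm² s⁻¹.  The Ag/AgCl→NHE shift is configuration, defaulting to
+0.197 V (saturated-KCl filling); it depends on the reference electrode's
filling solution and is never guessed implicitly — conversions are exact
involutions so no information is lost re-referencing.

## Voltammetry

Baseline subtraction fits the straight line through the (mean E, mean i)
points of two caller-chosen anchor windows and removes it; anchor-window
residual means are zero by construction.  A `BaselineWarning` is raised
when a window's local slope deviates from the anchor line by more than
20% *and* the deviation is more than three standard errors of the local
slope — the second condition stops noise alone from triggering the flag,
while windows placed on a peak flank still do.

Peak charge uses the trapezoidal rule on the as-sampled grid (no
resampling, hence no interpolation artifacts), divided by the scan rate
and folded to a magnitude.  Cyclic sweeps are split into monotonic
branches first; a duplicated vertex sample is attributed to the reverse
branch.  Peak potentials are global branch extrema refined by a parabolic
fit over ±3 points; an extremum below 6× the detrended tail noise is
rejected (the maximum of a few hundred pure-noise samples stays below
this, so a peak-free branch raises an error instead of returning noise).

The catalytic onset is operational: the most positive potential at which
the current magnitude exceeds 5% of the plateau (threshold configurable).
Overlapping couples (e.g. a Cu²⁺/⁺ process on top of the heme Fe³⁺/²⁺
couple) are integrated as a single feature and interpreted with a
caller-supplied electrons-per-site count; no CV peak deconvolution is
attempted.

## Koutecky–Levich analysis

The fit is ordinary least squares of 1/|i| on ω^(−1/2); currents are
sign-normalised to magnitudes before inversion, so cathodic sign
conventions never flip a slope.  The slope is interpreted through the full
Levich form — including the bulk O₂ concentration, which the textbook
slope expression requires for dimensional consistency — giving
n = 1/(slope · 0.62 F A D^{2/3} ν^{−1/6} [O₂]).  The kinetic current is
modelled first order in both substrate and catalyst,
i_K = n F A [O₂] Γ k_ORR, the only dimensionally consistent first-order
form in those symbols; its inversion returns k_ORR in M⁻¹ s⁻¹ and
k₁ = k_ORR[O₂] in s⁻¹.  A non-positive fitted intercept is flagged and the
kinetic-current-derived fields are left unset rather than returning a
negative rate.  Which coverage enters k_ORR (the single-couple or the
merged-couple value) is an experimental judgement; the API therefore takes
coverage as an explicit argument.

## Ring-disc selectivity

PROS is defined on the two-vs-four-electron partition only (superoxide and
peroxide aggregated), with the collection efficiency N a required,
hardware-specific configuration value (default 0.25, typical of
commercial Pt-ring assemblies).  The identity n = 4 − 2·PROS/100 is exact
by construction and is enforced as a property test.

## Raman deconvolution

Components are parameterised by (center, FWHM, height), matching how band
positions and intensities are quoted; area = height·π·FWHM/2 is derived.
A first-order baseline is co-fitted inside the window because turnover
SERRS backgrounds slope.  Fits run through lmfit's Levenberg–Marquardt
with per-component bounds: centers boxed to caller windows (default seed
±4 cm⁻¹), FWHM bounded (default 2–60 cm⁻¹), amplitudes non-negative.
Non-convergence triggers up to three deterministically jittered restarts
before an error carrying the last residual; identical inputs always give
identical results.

The default assignment table carries the heme oxidase marker bands — ν₄
1357 (HS Fe(II)) / 1375 (HS Fe(III)); ν₃ 1473 / 1493 / 1504 / 1508 for HS
Fe(II), HS Fe(III), LS Fe(III) and Fe(IV)=O; ν₂ 1585 / 1591; ν₁₀ 1641 —
with ±4 cm⁻¹ windows except the near-degenerate ν₃ 1504/1508 pair, which
gets deliberately disjoint ±2 cm⁻¹ boxes so low-spin ferric and ferryl are
never conflated.  A fitted center falling in two overlapping windows (the
ν₂ pair can overlap at 1587–1589) raises an ambiguity error listing the
candidates rather than guessing.  Reported "populations" are relative band
areas with no Raman cross-section correction; since cross-sections differ
between species, fractions rank classes rather than measure
concentrations.

**Resolution limit.**  Quantifying the areas of two Lorentzians split by
4 cm⁻¹ is statistically possible only when their widths are comparable to
the splitting: a linear error analysis (and fit replicates) shows that at
1% noise the area partition of a 12 cm⁻¹-wide pair is unidentifiable —
solutions trading ~40% of area between the bands fit within the noise.
The bundled ν₃ turnover fixture therefore gives the 1504/1508 pair
5 cm⁻¹ widths (the isolated 1473/1493 bands keep a typical 10 cm⁻¹), on
the reasoning that a 4 cm⁻¹ splitting is experimentally resolvable
precisely when the underlying components are narrow.  Recovery claims
(centers to 1.5 cm⁻¹, areas to 10% at 1% noise) hold for such data and
are not claimed for broader overlapping pairs.

## Steady-state microkinetics

The cycle is an irreversible unicycle of ≥3 states with effective
first-order step rates; electron-transfer and protonation steps are folded
into single rates, as appropriate for reasoning about which intermediates
accumulate.  Steady state is closed-form (p_i ∝ 1/k_i,
J = (Σ 1/k_i)⁻¹) and every call is cross-checked against an independent
null-space solution of the full rate matrix (relative tolerance 10⁻⁷; the
SVD route loses digits when rates span many decades, while the
flux-balance identity p_i·k_i = J holds to 10⁻¹⁰ throughout).  The flux
never exceeds the minimum step rate and approaches it as all other rates
grow.

Two scenarios ship as text files.  Quoted rates: 500 s⁻¹ for hydroxide
dissociation in the solution enzyme and 5000 s⁻¹ for peroxo protonation
in the wired mimic; O₂ binding enters as k₂[O₂] with k₂ = 10⁷ M⁻¹ s⁻¹.
Remaining rates are modelling choices, set fast (10⁴–10⁵ s⁻¹) so they are
never rate limiting.  One choice needs flagging: at air saturation
10⁷ M⁻¹ s⁻¹ × 0.26 mM = 2600 s⁻¹, which is *slower* than the mimic's
5000 s⁻¹ protonation step and would predict a large high-spin ferrous
population — contrary to the turnover spectra, which show essentially no
HS Fe(II).  The `electrode_model` scenario therefore uses an effective
O₂-binding rate of 5 × 10⁴ s⁻¹, constrained by that spectroscopic
observation rather than by the bulk-solution rate constant (local
concentration and rebinding effects at a film plausibly raise the
effective rate); `native_solution` keeps 2600 s⁻¹, where the distinction
is immaterial because hydroxide dissociation dominates.  The ferryl
reduction step is given 10⁴ s⁻¹, the slower of the "fast" steps,
consistent with the visible ferryl accumulation during turnover.
Accumulation is reported above a configurable 5% population threshold.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)`; identical
`GeneratorSpec`s give bit-identical outputs.  Additive noise is scaled by
the peak *signal* magnitude (faradaic peak height, Lorentzian mixture
maximum) — not by the background-inflated trace maximum — so "1% noise"
means an s.d. of 1% of the peak height; a multiplicative model is also
available and is the natural choice for rotation-series currents.

* `simulate_surface_cv`: ideal Nernstian surface wave
  i(E) = (n²F²vAΓ/RT)·θ(1−θ); integrated faradaic charge is exactly
  nFAΓ per branch before noise, and the peak current n²F²vAΓ/4RT.  A
  `peak_separation` argument mimics quasi-reversibility by offsetting the
  branch centers; the capacitive background is a constant offset plus
  small tilt (default 5 × 10⁻⁸ A + 2 × 10⁻⁸ A/V) whose sign follows the
  sweep direction, emulating a stable SAM capacitance.  A warning fires if
  the potential step exceeds a fifth of the peak FWHM (3.53RT/nF).
* `simulate_rde_set`: exact Koutecky–Levich composition
  (1/i_K + 1/i_L(ω))⁻¹, so the noiseless series is perfectly linear in
  the K–L coordinates.
* `simulate_ring_disc`: solves the PROS formula for the escaped-peroxide
  current; the noiseless pair round-trips exactly.
* `simulate_spectrum`: Lorentzian sum on a sloping baseline (default
  2.0 − 10⁻³·ν̃).  The finite-window integral of a band falls short of the
  closed-form area by the Lorentzian tail mass ~FWHM/(πL) per side —
  about 1.6% on the default 1300–1700 cm⁻¹ grid — a property of heavy
  tails, not a numerical error.

What the generators do **not** emulate: uncompensated resistance and
quasi-reversible peak broadening in CV; film substrate depletion or
Michaelis-type saturation in the rotation series; potential-dependent
collection efficiency; Raman cross-section differences, cosmic-ray
spikes, or non-linear fluorescence backgrounds.  Passing round-trip tests
therefore demonstrates the correctness of the inference chain under its
own model assumptions, not robustness to every artefact of real
instruments.

## Problem sizes and tolerances

Round-trip tests use 8 rotation rates (200–1000 rpm) with 100 noisy
replicates for the K–L chain, 10 replicates for the coverage chain, and
50 replicates for the four-band ν₃ recovery — sizes chosen to make median
statistics stable while keeping the whole suite and the reproduction
script in the seconds range.  Recovery tolerances: coverage within 2% at
1% noise; electron count within 5% and k_ORR within 10% at 2% noise;
fitted centers within 1.5 cm⁻¹ and areas within 10% at 1% noise; steady
states to 10⁻¹⁰ on flux balance.

## Known limitations

* No Laviron analysis of ΔEp vs scan rate; peak separation is reported
  observationally.
* No potential-resolved PROS traces; the accounting applies to a single
  held potential or to integrated charge.
* The cycle model is irreversible and unbranched; reversible steps,
  two-site cooperativity and proton-pumping thermodynamics are out of
  scope.
* Band-area fractions are not concentrations (no cross-section
  correction).
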