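# hemecat

Analysis toolkit for **protein-film electrocatalysis of oxygen reduction**
by heme/Cu enzymes and their electrode-attached biosynthetic mimics.  It
implements the full inference chain used to characterise such a catalyst —
from raw potential sweeps and Raman traces to rate constants, selectivity
and a mechanistic steady-state picture — together with seeded forward
models of every input, so the whole chain is testable without instrument
data.

## What it computes

**Voltammetry** (`hemecat.voltammetry`).  For a surface-confined redox
couple, the integrated faradaic charge gives the catalyst coverage,

&nbsp;&nbsp;&nbsp;&nbsp;Γ = Q / (n F A)  (mol cm⁻²),

along with E½ = (Epc + Epa)/2, ΔEp, and the gap between the catalytic
onset E_ORR and E½ that locates the potential-determining step.

**Koutecky–Levich analysis** (`hemecat.hydrodynamics`).  Rotating-disc
currents obey 1/i = 1/i_K + 1/i_L(ω) with the Levich current
i_L = 0.62 n F A D^{2/3} ω^{1/2} ν^{−1/6} [O₂].  The fitted slope yields
the electron count n per O₂, and the intercept the kinetic current
i_K = n F A [O₂] Γ k_ORR, hence the second-order rate constant k_ORR and
the pseudo-first-order turnover rate k₁ = k_ORR·[O₂].

**Ring-disc selectivity** (`hemecat.rrde`).  With collection efficiency N
and x = i_ring/N, the peroxide escape fraction is
PROS% = 200·x/(i_disc + x) and the effective electron count
n = 4·i_disc/(i_disc + x) = 4 − 2·PROS/100; total charge converts to moles
of O₂ and a turnover number.

**Raman deconvolution** (`hemecat.raman`).  Heme oxidation/spin marker
bands (ν₄, ν₃, ν₂, ν₁₀) are fitted as a linear baseline plus Lorentzian
mixture (via lmfit) and assigned to high-spin Fe(II), high-spin Fe(III),
low-spin Fe(III) or ferryl Fe(IV)=O species through a band table.

**Microkinetics** (`hemecat.mechanism`).  The catalytic cycle is an
irreversible unicycle with effective first-order step rates k_i; at steady
state p_i ∝ 1/k_i and the flux is J = (Σ 1/k_i)⁻¹, so the state feeding
the slowest step accumulates.  Bundled scenarios contrast the
solution enzyme (hydroxide dissociation, 500 s⁻¹, rate limiting) with the
electrode-wired mimic, where direct reduction of Fe(III)–OH (an
electron-transfer shunt) leaves peroxo protonation (5000 s⁻¹) rate
limiting.

**Synthetic data** (`hemecat.synthetic`).  Seeded generators for
Nernstian surface CVs on capacitive backgrounds, Koutecky–Levich rotation
series, ring/disc pairs at a chosen PROS, and Lorentzian-mixture spectra —
each the exact forward model of its analysis, so noiseless outputs
round-trip to the generating parameters.

## Worked example

`examples/02_koutecky_levich.py` simulates catalytic currents at eight
rotation rates (2% noise) for a film of 2.55 × 10⁻¹² mol cm⁻² catalyst
with k_ORR = 1.98 × 10⁷ M⁻¹ s⁻¹, then inverts them:

```
K-L slope       = 1.1124e+05 A^-1 rad^1/2 s^-1/2
K-L intercept   = 2.0964e+03 A^-1  (r^2 = 0.997585)
electron count  = 4.00 e- per O2 (true 4)
kinetic current = 4.770e-04 A
k_ORR           = 1.943e+07 M^-1 s^-1 (true 1.98e+07)
k1 = k_ORR[O2]  = 5052 s^-1
```

An electron count of ~4 marks clean reduction of O₂ to water, and the
recovered rate constants sit within a few percent of the generating
values.  The other examples cover coverage from CV
(`01_surface_coverage.py`), ring-disc selectivity and turnover
(`03_rrde_selectivity.py`), ν₃ marker-band deconvolution
(`04_raman_deconvolution.py`) and the steady-state cycle scenarios
(`05_catalytic_cycle.py`); each prints the numbers it computes with a
note on what they mean.

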