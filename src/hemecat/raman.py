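"""Lorentzian-mixture deconvolution of heme resonance-Raman marker bands.

The oxidation- and spin-state marker bands of a heme (nu4 ~1355-1375,
nu3 ~1470-1510, nu2 ~1560-1595, nu10 ~1610-1645 cm^-1) shift with the iron
oxidation state, spin state and axial ligation, so a crowded marker-band
region recorded during steady-state turnover can be decomposed into
Lorentzian components and each component read as a population of a
catalytic intermediate class:

    high-spin Fe(II)  — five-coordinate ferrous (nu4 1357, nu3 1473)
    high-spin Fe(III) — resting ferric (nu4 1375, nu3 1493, nu2 1585)
    low-spin Fe(III)  — six-coordinate ferric adducts, including oxy/peroxo/
                        hydroperoxo intermediates (nu3 1504, nu10 1641)
    Fe(IV)=O          — ferryl (nu3 1508, nu2 1591)

Fitting is linear-baseline + sum-of-Lorentzians nonlinear least squares
(via lmfit); "populations" are reported as relative band-area fractions
with no Raman cross-section correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi
from typing import Mapping, Sequence

import numpy as np
from lmfit.models import LinearModel, LorentzianModel

from .exceptions import AmbiguousAssignmentError, FitConvergenceError
from .io import RamanSpectrum

__all__ = [
    "LorentzianComponent",
    "BandAssignment",
    "SpeciesAssignmentTable",
    "DeconvolutionResult",
    "OBSERVABLE_CLASSES",
    "fit_mixture",
    "assign_species",
    "default_assignment_table",
    "class_fractions",
]

OBSERVABLE_CLASSES = ("HS-FeII", "HS-FeIII", "LS-FeIII", "FeIV=O")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class LorentzianComponent:
    """One Lorentzian band, parameterised by center, FWHM and peak height;
    the integrated area follows as height * pi * fwhm / 2."""

    center: float   # cm^-1
    fwhm: float     # cm^-1
    height: float   # arb. units

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def area(self) -> float:
        return self.height * pi * self.fwhm / 2.0

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        half = self.fwhm / 2.0
        return self.height / (1.0 + ((np.asarray(x, dtype=float) - self.center) / half) ** 2)


@dataclass(frozen=True)
class BandAssignment:
    band: str            # e.g. "nu3"
    center: float        # nominal center, cm^-1
    window: tuple[float, float]
    species: str         # human-readable species label
    klass: str           # one of OBSERVABLE_CLASSES

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"degenerate window {self.window} for {self.band}")
        if self.klass not in OBSERVABLE_CLASSES:
            raise ValueError(f"unknown observable class {self.klass!r}")

    def contains(self, x: float) -> bool:
        lo, hi = self.window
        return lo <= x <= hi


@dataclass(frozen=True)
class SpeciesAssignmentTable:
    """Marker-band lookup: center windows mapped to species and observable
    classes."""

    entries: tuple[BandAssignment, ...]

    def matches(self, center: float) -> list[BandAssignment]:
        return [e for e in self.entries if e.contains(center)]

    def overlapping_pairs(self) -> list[tuple[BandAssignment, BandAssignment]]:
        """All window pairs that overlap (potential ambiguity sources)."""
        out = []
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if a.window[0] < b.window[1] and b.window[0] < a.window[1]:
                    out.append((a, b))
        return out

    def species_class(self, species: str) -> str:
        for e in self.entries:
            if e.species == species:
                return e.klass
        raise KeyError(species)


@dataclass(frozen=True)
class DeconvolutionResult:
    """Fitted mixture: components, co-fitted linear baseline (intercept,
    slope), optional species assignments and area fractions."""

    components: tuple[LorentzianComponent, ...]
    baseline: tuple[float, float]
    residual_rms: float
    assignments: tuple[str, ...] = ()
    fractions: Mapping[str, float] = field(default_factory=dict)


def default_assignment_table() -> SpeciesAssignmentTable:
    """Marker-band table for a heme-protein oxidase cycle.

    Windows are +-4 cm^-1 around the nominal band positions except the
    near-degenerate nu3 pair at 1504 (low-spin ferric) and 1508 cm^-1
    (ferryl), which get deliberately disjoint +-2 cm^-1 boxes so the two
    are never conflated.
    """
    w4 = 4.0
    rows = [
        ("nu4", 1357.0, w4, "HS ferrous", "HS-FeII"),
        ("nu4", 1375.0, w4, "resting HS ferric", "HS-FeIII"),
        ("nu3", 1473.0, w4, "HS ferrous", "HS-FeII"),
        ("nu3", 1493.0, w4, "resting HS ferric", "HS-FeIII"),
        ("nu3", 1504.0, 2.0, "LS ferric", "LS-FeIII"),
        ("nu3", 1508.0, 2.0, "ferryl", "FeIV=O"),
        ("nu2", 1585.0, w4, "resting HS ferric", "HS-FeIII"),
        ("nu2", 1591.0, w4, "ferryl", "FeIV=O"),
        ("nu10", 1641.0, w4, "LS ferric", "LS-FeIII"),
    ]
    entries = tuple(
        BandAssignment(band, c, (c - hw, c + hw), species, klass)
        for band, c, hw, species, klass in rows
    )
    return SpeciesAssignmentTable(entries=entries)


def _lorentzian_seed_height(x, y, base, center):
    """Initial height guess: data minus baseline at the seed position."""
    h = float(np.interp(center, x, y) - np.polyval(base[::-1], center))
    return max(h, 1e-3 * (np.ptp(y) + 1e-300))


def fit_mixture(
    s: RamanSpectrum,
    window: Sequence[float],
    seeds: Sequence[float],
    center_windows: Sequence[Sequence[float]] | None = None,
    center_halfwidth: float = 4.0,
    fwhm_bounds: tuple[float, float] = (2.0, 60.0),
    max_restarts: int = 3,
) -> DeconvolutionResult:
    """Fit a linear baseline plus one Lorentzian per seed inside a window.

    Parameters
    ----------
    s : RamanSpectrum
        The measured trace.
    window : (lo, hi)
        Wavenumber interval (cm^-1) to fit; must lie inside the spectrum.
    seeds : sequence of float
        Initial band centers; one Lorentzian is fitted per seed.
    center_windows : optional
        Per-seed (lo, hi) boxes constraining the fitted centers; defaults
        to ``seed +- center_halfwidth``.
    fwhm_bounds : (lo, hi)
        Bounds on every component's FWHM (cm^-1).
    max_restarts : int
        Deterministically jittered re-initialisations attempted on
        non-convergence before raising :class:`FitConvergenceError`.

    The fit is deterministic for identical inputs.
    """
    lo, hi = sorted(window)
    if lo < s.wavenumber[0] or hi > s.wavenumber[-1]:
        raise ValueError("fit window extends beyond the spectrum")
    if len(seeds) < 1:
        raise ValueError("at least one seed center is required")
    for c in seeds:
        if not (lo <= c <= hi):
            raise ValueError(f"seed {c} lies outside the fit window {tuple(window)}")
    if center_windows is None:
        center_windows = [(c - center_halfwidth, c + center_halfwidth) for c in seeds]
    if len(center_windows) != len(seeds):
        raise ValueError("need one center window per seed")

    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    x = s.wavenumber[mask]
    y = s.intensity[mask]
    if x.size < 3 * len(seeds) + 2:
        raise ValueError("too few points in window for the requested components")

    # endpoint-based baseline guess
    k = max(3, x.size // 20)
    bx = np.concatenate([x[:k], x[-k:]])
    by = np.concatenate([y[:k], y[-k:]])
    b_slope, b_int = np.polyfit(bx, by, 1)

    model = LinearModel(prefix="bkg_")
    params = model.make_params(slope=b_slope, intercept=b_int)
    for j, (c0, (clo, chi)) in enumerate(zip(seeds, center_windows)):
        comp = LorentzianModel(prefix=f"c{j}_")
        model = model + comp
        h0 = _lorentzian_seed_height(x, y, (b_int, b_slope), c0)
        sigma0 = max(fwhm_bounds[0] / 2.0 * 1.5, min(5.0, fwhm_bounds[1] / 2.0))
        params.update(
            comp.make_params(
                center=dict(value=float(np.clip(c0, clo, chi)), min=clo, max=chi),
                sigma=dict(value=sigma0, min=fwhm_bounds[0] / 2.0, max=fwhm_bounds[1] / 2.0),
                amplitude=dict(value=h0 * pi * sigma0, min=0.0),
            )
        )

    rng = np.random.default_rng(0)  # deterministic restart jitter
    result = None
    for attempt in range(max_restarts + 1):
        p = params.copy()
        if attempt > 0:
            for j, (c0, (clo, chi)) in enumerate(zip(seeds, center_windows)):
                jitter = rng.uniform(-0.25, 0.25) * (chi - clo)
                p[f"c{j}_center"].value = float(np.clip(c0 + jitter, clo, chi))
        result = model.fit(y, p, x=x)
        if result.success:
            break
    rms = float(np.sqrt(np.mean(result.residual**2)))
    if not result.success:
        raise FitConvergenceError(
            f"mixture fit failed to converge after {max_restarts + 1} attempts",
            residual_rms=rms,
        )

    comps = []
    for j in range(len(seeds)):
        sigma = float(result.params[f"c{j}_sigma"].value)
        amp = float(result.params[f"c{j}_amplitude"].value)
        comps.append(
            LorentzianComponent(
                center=float(result.params[f"c{j}_center"].value),
                fwhm=2.0 * sigma,
                height=max(amp / (pi * sigma), 0.0),
            )
        )
    baseline = (
        float(result.params["bkg_intercept"].value),
        float(result.params["bkg_slope"].value),
    )
    return DeconvolutionResult(
        components=tuple(comps), baseline=baseline, residual_rms=rms
    )


def assign_species(
    result: DeconvolutionResult, table: SpeciesAssignmentTable
) -> DeconvolutionResult:
    """Label each fitted component by the assignment window containing its
    center and compute relative area fractions per species.

    Components outside every window are labelled ``"unassigned"`` and
    excluded from the fraction normalisation; a center inside two
    overlapping windows raises :class:`AmbiguousAssignmentError`.
    """
    labels: list[str] = []
    for comp in result.components:
        hits = table.matches(comp.center)
        if len(hits) > 1:
            raise AmbiguousAssignmentError(
                comp.center, [f"{h.band} {h.center:g} ({h.species})" for h in hits]
            )
        labels.append(hits[0].species if hits else UNASSIGNED)

    assigned_area = sum(
        c.area for c, lab in zip(result.components, labels) if lab != UNASSIGNED
    )
    fractions: dict[str, float] = {}
    if assigned_area > 0:
        for comp, lab in zip(result.components, labels):
            if lab == UNASSIGNED:
                continue
            fractions[lab] = fractions.get(lab, 0.0) + comp.area / assigned_area
    return replace(result, assignments=tuple(labels), fractions=fractions)


def class_fractions(
    result: DeconvolutionResult, table: SpeciesAssignmentTable
) -> dict[str, float]:
    """Aggregate a labelled result's species fractions by observable class
    (HS-FeII / HS-FeIII / LS-FeIII / FeIV=O), for direct comparison with a
    steady-state cycle model's predictions."""
    if not result.assignments:
        raise ValueError("run assign_species first")
    out: dict[str, float] = {}
    for species, frac in result.fractions.items():
        klass = table.species_class(species)
        out[klass] = out.get(klass, 0.0) + frac
    return out
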