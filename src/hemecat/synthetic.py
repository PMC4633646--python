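"""Seeded forward models of every input class the analyses consume.

Each generator implements the same physics its analysis counterpart
inverts, so noiseless output fed back through the analysis recovers the
generating parameters exactly (the package-wide round-trip property):

* ideal surface-confined Nernstian CV peaks on a capacitive background
  (integrated faradaic charge n F A Gamma by construction);
* rotation-rate series obeying the Koutecky-Levich composition of a
  kinetic and a Levich current;
* ring/disc current pairs at a chosen peroxide escape fraction and
  collection efficiency;
* Lorentzian-mixture Raman spectra on a sloping linear baseline.

All randomness flows from the seed in :class:`GeneratorSpec`; identical
specs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import GAS_CONSTANT, ElectrochemConstants
from .exceptions import GridWarning
from .hydrodynamics import RotationSeries, kinetic_current, levich_current
from .io import RamanSpectrum, Reference, Voltammogram, rpm_to_angular
from .raman import LorentzianComponent
from .rrde import RingDiscPair

__all__ = [
    "GeneratorSpec",
    "simulate_surface_cv",
    "simulate_rde_set",
    "simulate_ring_disc",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Shared generator settings.

    ``noise_fraction`` scales additive Gaussian noise by the maximum signal
    magnitude (``noise_model="additive"``, the default) or multiplies each
    sample by ``1 + noise_fraction * N(0,1)`` (``"multiplicative"``).
    ``baseline`` is an (offset, slope) pair in the output's own units; when
    ``None`` each generator applies its own small default background.
    ``grid`` is an optional (lo, hi, step) sampling grid.
    """

    seed: int = 0
    noise_fraction: float = 0.01
    noise_model: str = "additive"
    baseline: tuple[float, float] | None = None
    grid: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(
    trace: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    signal_scale: float | None = None,
):
    """Additive noise is scaled by the peak *signal* magnitude (baselines
    and capacitive backgrounds excluded), so ``noise_fraction=0.01`` means
    a noise s.d. of 1% of the peak height."""
    if spec.noise_fraction == 0:
        return trace
    if spec.noise_model == "additive":
        scale = spec.noise_fraction * (
            signal_scale if signal_scale is not None else np.abs(trace).max()
        )
        if scale == 0:
            return trace
        return trace + rng.normal(0.0, scale, size=trace.shape)
    return trace * (1.0 + spec.noise_fraction * rng.standard_normal(trace.shape))


#: Default capacitive background for synthetic CVs: (offset A, tilt A/V).
_CV_BASELINE = (5e-8, 2e-8)


def simulate_surface_cv(
    e_half: float,
    coverage: float,
    n: int,
    scan_rate: float,
    c: ElectrochemConstants | None = None,
    spec: GeneratorSpec | None = None,
    peak_separation: float = 0.0,
    window: float = 0.35,
    step: float = 0.002,
    branch: str = "full",
    potential_range: tuple[float, float] | None = None,
    reference: Reference = Reference.AgAgCl,
    label: str = "synthetic surface CV",
) -> Voltammogram:
    """Ideal surface-confined Nernstian redox couple on a capacitive
    background.

    The faradaic current is i(E) = (n^2 F^2 v A Gamma / RT) theta(1-theta)
    with theta the Nernst occupancy, giving a peak current
    n^2 F^2 v A Gamma / (4RT) and an integrated faradaic charge of exactly
    n F A Gamma per branch (before noise).  ``peak_separation`` offsets the
    cathodic and anodic peak centers symmetrically about ``e_half`` to
    mimic quasi-reversible behaviour; the capacitive background is a
    constant offset plus linear tilt whose sign follows the sweep
    direction.  ``branch`` selects ``"cathodic"``, ``"anodic"`` or the
    full ``"full"`` cycle (cathodic first).
    """
    c = c or ElectrochemConstants()
    spec = spec or GeneratorSpec()
    if min(coverage, scan_rate) <= 0 or n < 1:
        raise ValueError("coverage, scan_rate must be > 0 and n >= 1")
    if branch not in ("cathodic", "anodic", "full"):
        raise ValueError("branch must be 'cathodic', 'anodic' or 'full'")

    if spec.grid is not None:
        lo, hi, step = spec.grid
    elif potential_range is not None:
        lo, hi = sorted(potential_range)
    else:
        lo, hi = e_half - window, e_half + window

    rt = GAS_CONSTANT * c.temperature
    fwhm = 3.53 * rt / (n * c.faraday_constant)
    if step > fwhm / 5.0:
        warnings.warn(
            f"potential step {step*1e3:.1f} mV is coarser than a fifth of the "
            f"peak FWHM ({fwhm*1e3:.1f} mV); the peak will be under-resolved",
            GridWarning,
            stacklevel=2,
        )

    grid = np.arange(lo, hi + 0.5 * step, step)
    prefactor = (
        n**2
        * c.faraday_constant**2
        * scan_rate
        * c.electrode_area
        * coverage
        / rt
    )

    def faradaic(e: np.ndarray, center: float) -> np.ndarray:
        u = n * c.faraday_constant * (e - center) / rt
        theta = 1.0 / (1.0 + np.exp(u))
        return prefactor * theta * (1.0 - theta)

    b0, b1 = spec.baseline if spec.baseline is not None else _CV_BASELINE
    e_mid = 0.5 * (lo + hi)

    segments = []
    if branch in ("cathodic", "full"):
        e_c = grid[::-1]  # sweep from positive to negative potentials
        i_c = -faradaic(e_c, e_half - peak_separation / 2.0) - (b0 + b1 * (e_c - e_mid))
        segments.append((e_c, i_c))
    if branch in ("anodic", "full"):
        e_a = grid
        i_a = faradaic(e_a, e_half + peak_separation / 2.0) + (b0 + b1 * (e_a - e_mid))
        segments.append((e_a, i_a))

    potential = np.concatenate([s[0] for s in segments])
    current = np.concatenate([s[1] for s in segments])
    current = _apply_noise(current, spec, spec.rng(), signal_scale=prefactor / 4.0)
    return Voltammogram(
        potential=potential,
        current=current,
        scan_rate=scan_rate,
        rotation_rate=0.0,
        reference=reference,
        label=label,
    )


def simulate_rde_set(
    n: int,
    k2: float,
    coverage: float,
    rotation_rates: Sequence[float],
    c: ElectrochemConstants | None = None,
    spec: GeneratorSpec | None = None,
    potential_hold: float = -0.300,
) -> RotationSeries:
    """Catalytic currents at a held potential across rotation rates (rpm),
    composed as (1/i_K + 1/i_L(omega))^-1 plus noise.

    ``k2`` is the second-order O2-reduction rate constant (M^-1 s^-1) and
    ``coverage`` the catalyst surface coverage (mol cm^-2); the noiseless
    output satisfies the Koutecky-Levich linearity exactly.  Currents are
    emitted with cathodic (negative) sign.
    """
    c = c or ElectrochemConstants()
    spec = spec or GeneratorSpec()
    rates = [float(r) for r in rotation_rates]
    if len(rates) < 3:
        raise ValueError("need at least 3 rotation rates")
    if len(set(rates)) != len(rates):
        raise ValueError("rotation rates must be distinct")
    i_k = kinetic_current(n, k2, coverage, c)
    currents = []
    omegas = []
    for rpm in rates:
        w = rpm_to_angular(rpm)
        il = levich_current(n, w, c)
        i = il if not np.isfinite(i_k) or i_k <= 0 else 1.0 / (1.0 / i_k + 1.0 / il)
        omegas.append(w)
        currents.append(i)
    noisy = _apply_noise(np.array(currents), spec, spec.rng())
    return RotationSeries(
        potential_hold=potential_hold,
        entries=tuple(zip(omegas, (-noisy).tolist())),
        constants=c,
    )


def simulate_ring_disc(
    disc_flux: float,
    pros_fraction: float,
    efficiency: float = 0.25,
    spec: GeneratorSpec | None = None,
) -> RingDiscPair:
    """Ring/disc current pair realising a chosen PROS percentage.

    The escaped-peroxide equivalent current x solves
    200 x / (disc + x) = pros_fraction; the ring reads efficiency * x.
    With zero noise the pair round-trips through the PROS formula exactly.
    """
    spec = spec or GeneratorSpec()
    if disc_flux <= 0:
        raise ValueError("disc flux must be > 0")
    if not (0 <= pros_fraction <= 100):
        raise ValueError("pros_fraction must lie in [0, 100]")
    x = pros_fraction * disc_flux / (200.0 - pros_fraction)
    ring = efficiency * x
    rng = spec.rng()
    if spec.noise_fraction > 0:
        disc_flux = float(
            _apply_noise(np.array([disc_flux]), spec, rng)[0]
        )
        ring = float(np.clip(_apply_noise(np.array([ring]), spec, rng)[0], 0.0, None))
    return RingDiscPair(
        disc_current=disc_flux, ring_current=ring, collection_efficiency=efficiency
    )


def nu3_turnover_fixture() -> list[LorentzianComponent]:
    """Reference four-component nu3 mixture emulating a marker-band region
    recorded during steady-state turnover.

    Centers sit at the high-spin ferrous (1473), resting high-spin ferric
    (1493), low-spin ferric (1504) and ferryl (1508 cm^-1) band positions.
    The two isolated bands carry a typical 10 cm^-1 width; the
    near-degenerate 1504/1508 pair is given 5 cm^-1 widths — components
    split by only 4 cm^-1 are experimentally distinguishable precisely
    because they are narrow, and area quantification of a pair broader
    than ~1.5x its separation is not claimed (see the methods note).
    """
    return [
        LorentzianComponent(1473.0, 10.0, 0.8),
        LorentzianComponent(1493.0, 10.0, 1.0),
        LorentzianComponent(1504.0, 5.0, 0.9),
        LorentzianComponent(1508.0, 5.0, 0.7),
    ]


#: Default sloping baseline for synthetic Raman traces (intercept, slope
#: per cm^-1, intensity units).
_RAMAN_BASELINE = (2.0, -1.0e-3)
_RAMAN_GRID = (1300.0, 1700.0, 0.5)


def simulate_spectrum(
    components: Sequence[LorentzianComponent],
    spec: GeneratorSpec | None = None,
    label: str = "synthetic Raman spectrum",
) -> RamanSpectrum:
    """Sum of Lorentzians on a sloping linear baseline plus noise.

    Each component's noiseless integral matches its closed-form area
    height * pi * fwhm / 2 up to the finite-window deficit: Lorentzian
    tails are heavy, so the missing mass is ~ fwhm/(pi*L) for a window
    extending L to either side of the band (< 2% once L >= ~16 FWHM, as
    with the default grid).  Components must lie inside the sampling grid.
    """
    spec = spec or GeneratorSpec()
    lo, hi, step = spec.grid if spec.grid is not None else _RAMAN_GRID
    x = np.arange(lo, hi + 0.5 * step, step)
    for comp in components:
        if not (lo <= comp.center <= hi):
            raise ValueError(
                f"component center {comp.center} outside grid [{lo}, {hi}]"
            )
    b0, b1 = spec.baseline if spec.baseline is not None else _RAMAN_BASELINE
    mixture = np.zeros_like(x)
    for comp in components:
        mixture = mixture + comp.profile(x)
    y = b0 + b1 * x + mixture
    scale = float(np.abs(mixture).max()) if components else 0.0
    y = _apply_noise(y, spec, spec.rng(), signal_scale=scale)
    return RamanSpectrum(wavenumber=x, intensity=y, label=label)
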