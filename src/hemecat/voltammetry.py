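"""Stationary cyclic-voltammetry processing for surface-confined couples.

The chain implemented here turns an anaerobic CV of an electrode-attached
redox protein into a surface coverage: subtract a linear capacitive
baseline anchored on the flat tails, integrate the faradaic peak to a
charge Q, and apply Q = n F A Gamma.  Peak potentials give the midpoint
potential E1/2 = (Epc + Epa)/2 and the peak separation dEp; the onset of a
catalytic wave relative to E1/2 locates the potential-determining step of
the catalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .constants import ElectrochemConstants
from .exceptions import BaselineWarning, PeakDetectionError
from .io import Reference, Voltammogram

__all__ = [
    "RedoxFeature",
    "CoverageResult",
    "split_branches",
    "subtract_linear_baseline",
    "integrate_peak",
    "coverage_from_charge",
    "find_redox_feature",
    "find_onset",
    "area_ratio",
    "onset_gap",
]


@dataclass(frozen=True)
class RedoxFeature:
    """Peak description of one (possibly merged) surface redox couple."""

    e_cathodic: float
    e_anodic: float
    charge_cathodic: float
    charge_anodic: float

    def __post_init__(self) -> None:
        if self.charge_cathodic < 0 or self.charge_anodic < 0:
            raise ValueError("peak charges are magnitudes and must be >= 0")

    @property
    def e_half(self) -> float:
        """Midpoint potential (V), mean of the two peak potentials."""
        return 0.5 * (self.e_cathodic + self.e_anodic)

    @property
    def delta_ep(self) -> float:
        """Cathodic-to-anodic peak separation (V), non-negative."""
        return self.e_anodic - self.e_cathodic


@dataclass(frozen=True)
class CoverageResult:
    """Surface coverage derived from an integrated voltammetric charge."""

    charge: float
    n_electrons: int
    coverage: float       # mol cm^-2
    moles_total: float    # mol


def split_branches(v: Voltammogram) -> tuple[Voltammogram, Voltammogram]:
    """Split a cyclic sweep into its cathodic (falling-E) and anodic
    (rising-E) branches.

    Returns ``(cathodic, anodic)``.  Raises if the sweep is monotonic
    (a single branch) or has more than one turning point.
    """
    de = np.diff(v.potential)
    sign = np.sign(de)
    nonzero = sign[sign != 0]
    if nonzero.size == 0:
        raise ValueError("potential program is constant")
    d0 = nonzero[0]
    opposing = np.flatnonzero(sign == -d0)
    if opposing.size == 0:
        raise ValueError("sweep is monotonic: it has a single branch, not a cycle")
    k = int(opposing[0])
    if np.any(sign[:k] == -d0) or np.any(sign[k:] == d0):
        raise ValueError("potential program has more than one turning point")
    # a duplicated vertex sample belongs to the reverse branch only
    cut_first = k if (k > 0 and de[k - 1] == 0) else k + 1
    first = replace(v, potential=v.potential[:cut_first], current=v.current[:cut_first])
    second = replace(v, potential=v.potential[k:], current=v.current[k:])
    if d0 < 0:
        return first, second
    return second, first


def _window_mask(potential: np.ndarray, window: Sequence[float]) -> np.ndarray:
    lo, hi = sorted(window)
    return (potential >= lo) & (potential <= hi)


def subtract_linear_baseline(
    v: Voltammogram,
    anchor_windows: Sequence[Sequence[float]],
    slope_tolerance: float = 0.20,
) -> Voltammogram:
    """Subtract the straight line through the means of two anchor windows.

    The anchor windows are potential intervals on the flat tails of the
    sweep, each holding at least 3 points; the line through their
    (mean E, mean i) points is removed from the whole sweep, leaving the
    anchor-window residual means at zero.  If the local slope inside either
    window deviates from the anchor-line slope by more than
    ``slope_tolerance`` (relative), a :class:`BaselineWarning` is raised —
    the window likely sits on the peak rather than the background.
    """
    if len(anchor_windows) != 2:
        raise ValueError("exactly two anchor windows are required")
    (lo1, hi1), (lo2, hi2) = (sorted(w) for w in anchor_windows)
    if max(lo1, lo2) < min(hi1, hi2):
        raise ValueError("anchor windows must not overlap")

    masks = [_window_mask(v.potential, w) for w in anchor_windows]
    for w, m in zip(anchor_windows, masks):
        if m.sum() < 3:
            raise ValueError(f"anchor window {tuple(w)} holds {m.sum()} points, need >= 3")

    x = np.array([v.potential[m].mean() for m in masks])
    y = np.array([v.current[m].mean() for m in masks])
    if x[0] == x[1]:
        raise ValueError("anchor windows have identical mean potentials")
    slope = (y[1] - y[0]) / (x[1] - x[0])
    intercept = y[0] - slope * x[0]

    scale = max(abs(slope), 1e-12 * (abs(y).max() + 1e-300))
    for m in masks:
        ew, iw = v.potential[m], v.current[m]
        coeffs = np.polyfit(ew, iw, 1)
        local_slope = coeffs[0]
        resid = iw - np.polyval(coeffs, ew)
        # standard error of the local slope, to ignore noise-driven deviations
        se = np.std(resid) / (np.std(ew) * np.sqrt(m.sum()) + 1e-300)
        ref = max(abs(local_slope), scale)
        deviation = abs(local_slope - slope)
        if deviation > slope_tolerance * ref and deviation > 3.0 * se:
            warnings.warn(
                "anchor-window slope deviates from the anchor line by more than "
                f"{slope_tolerance:.0%}; window may lie inside the peak",
                BaselineWarning,
                stacklevel=2,
            )
    return replace(v, current=v.current - (slope * v.potential + intercept))


def integrate_peak(v: Voltammogram, window: Sequence[float]) -> float:
    """Integrate a baseline-subtracted peak to its charge magnitude (C).

    Q = |integral of i dE| / scan_rate over the potential window, by the
    trapezoidal rule on the as-sampled grid (no resampling).  The sweep
    segment inside the window must be monotonic in potential — split a
    cyclic sweep into branches first (:func:`split_branches`).
    """
    mask = _window_mask(v.potential, window)
    if mask.sum() < 2:
        raise ValueError(f"integration window {tuple(window)} selects < 2 points")
    e = v.potential[mask]
    i = v.current[mask]
    de = np.diff(e)
    if not (np.all(de > 0) or np.all(de < 0)):
        raise ValueError(
            "potential is not monotonic inside the window; integrate one branch at a time"
        )
    return abs(np.trapezoid(i, e)) / v.scan_rate


def coverage_from_charge(
    q: float, n_electrons: int, constants: ElectrochemConstants
) -> CoverageResult:
    """Convert an integrated faradaic charge to a surface coverage.

    Gamma = Q / (n F A) in mol cm^-2; total moles = Gamma * A = Q / (n F).
    """
    if q < 0:
        raise ValueError("charge must be >= 0")
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    gamma = q / (n_electrons * constants.faraday_constant * constants.electrode_area)
    return CoverageResult(
        charge=q,
        n_electrons=n_electrons,
        coverage=gamma,
        moles_total=gamma * constants.electrode_area,
    )


def _refine_extremum(e: np.ndarray, i: np.ndarray, idx: int, half: int = 3) -> float:
    """Parabolic vertex through +-``half`` points around index ``idx``."""
    lo = max(0, idx - half)
    hi = min(len(e), idx + half + 1)
    if hi - lo < 3:
        return float(e[idx])
    a, b, _ = np.polyfit(e[lo:hi], i[lo:hi], 2)
    if a == 0:
        return float(e[idx])
    vertex = -b / (2 * a)
    # keep the refinement local: fall back if the vertex left the stencil
    if not (min(e[lo:hi]) <= vertex <= max(e[lo:hi])):
        return float(e[idx])
    return float(vertex)


def _tail_noise(current: np.ndarray, fraction: float = 0.1) -> float:
    """Noise floor: s.d. of detrended leading/trailing tails of the sweep."""
    k = max(4, int(fraction * current.size))
    pieces = []
    for seg in (current[:k], current[-k:]):
        t = np.arange(seg.size)
        trend = np.polyval(np.polyfit(t, seg, 1), t)
        pieces.append(seg - trend)
    return float(np.std(np.concatenate(pieces)))


def find_redox_feature(v: Voltammogram, noise_sigma: float = 6.0) -> RedoxFeature:
    """Locate the cathodic/anodic peak pair of a baseline-subtracted cyclic
    sweep and integrate each branch's charge.

    Peaks are the global current extrema of each branch, refined by a
    parabolic fit over +-3 points.  An extremum smaller than
    ``noise_sigma`` times the tail noise raises
    :class:`PeakDetectionError` (e.g. a single-branch or peak-free sweep);
    the default multiple is high enough that the maximum of a few hundred
    pure-noise samples does not pass as a peak.
    """
    cathodic, anodic = split_branches(v)
    floor = noise_sigma * _tail_noise(v.current) + 1e-15 * np.abs(v.current).max()

    ic = int(np.argmin(cathodic.current))
    if -cathodic.current[ic] < floor:
        raise PeakDetectionError("no cathodic peak above the noise floor")
    ia = int(np.argmax(anodic.current))
    if anodic.current[ia] < floor:
        raise PeakDetectionError("no anodic peak above the noise floor")

    e_c = _refine_extremum(cathodic.potential, cathodic.current, ic)
    e_a = _refine_extremum(anodic.potential, anodic.current, ia)
    q_c = abs(np.trapezoid(cathodic.current, cathodic.potential)) / v.scan_rate
    q_a = abs(np.trapezoid(anodic.current, anodic.potential)) / v.scan_rate
    return RedoxFeature(
        e_cathodic=e_c, e_anodic=e_a, charge_cathodic=q_c, charge_anodic=q_a
    )


def find_onset(v: Voltammogram, threshold: float = 0.05) -> float:
    """Onset potential of a cathodic catalytic wave.

    Defined operationally as the most positive potential at which the
    current magnitude exceeds ``threshold`` (default 5%) of the plateau
    (maximum) magnitude; the sweep should be background-subtracted.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mag = np.abs(v.current)
    plateau = mag.max()
    if plateau <= 0:
        raise PeakDetectionError("sweep carries no current")
    order = np.argsort(v.potential)[::-1]  # from most positive E downward
    e_sorted = v.potential[order]
    m_sorted = mag[order]
    above = np.flatnonzero(m_sorted >= threshold * plateau)
    if above.size == 0:
        raise PeakDetectionError("current never exceeds the onset threshold")
    k = above[0]
    if k == 0:
        return float(e_sorted[0])
    # linear interpolation between the straddling samples
    e0, e1 = e_sorted[k - 1], e_sorted[k]
    m0, m1 = m_sorted[k - 1], m_sorted[k]
    if m1 == m0:
        return float(e1)
    frac = (threshold * plateau - m0) / (m1 - m0)
    return float(e0 + frac * (e1 - e0))


def area_ratio(feature_a: RedoxFeature, feature_b: RedoxFeature) -> float:
    """Ratio of cathodic charges, feature_b / feature_a.

    Used to compare the merged Fe+Cu couple against the Fe-only couple: two
    superposed one-electron couples at equal coverage integrate to twice
    the single-couple charge.
    """
    if feature_a.charge_cathodic <= 0 or feature_b.charge_cathodic <= 0:
        raise ValueError("both cathodic charges must be > 0")
    return feature_b.charge_cathodic / feature_a.charge_cathodic


def onset_gap(
    e_onset: float,
    e_half: float,
    reference_onset: Reference | str | None = None,
    reference_half: Reference | str | None = None,
) -> float:
    """Signed gap e_onset - e_half (V) between the catalytic onset and the
    couple's midpoint potential.

    A negative gap means catalysis turns on below E1/2, i.e. the
    potential-determining step is the reduction of a species other than the
    resting couple.  Both potentials must be quoted against the same
    reference; pass the reference tags to have that checked.
    """
    if reference_onset is not None and reference_half is not None:
        if Reference(reference_onset) != Reference(reference_half):
            raise ValueError("onset and midpoint potentials use different references")
    if not (np.isfinite(e_onset) and np.isfinite(e_half)):
        raise ValueError("potentials must be finite")
    return e_onset - e_half
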