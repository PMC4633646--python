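"""Sweep/spectrum containers, delimited-table I/O and unit plumbing.

File dialect: two numeric columns (comma- or whitespace-separated) with
optional ``#key: value`` metadata header lines, the plain-table style that
potentiostat and spectrograph exports reduce to.  Recognised metadata keys
for sweeps: ``scan_rate_V_s``, ``rotation_rate_rpm``, ``reference``
(``AgAgCl`` or ``NHE``), ``label``, ``potential_units`` (``V``/``mV``),
``current_units`` (``A``/``mA``/``uA``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
import numpy as np

from .exceptions import ConfigurationError, ParseError

__all__ = [
    "Reference",
    "Voltammogram",
    "RamanSpectrum",
    "read_sweep_table",
    "write_sweep_table",
    "read_spectrum_table",
    "write_spectrum_table",
    "convert_reference",
    "rpm_to_angular",
    "mV_to_V",
    "V_to_mV",
    "uA_to_A",
    "A_to_uA",
    "DEFAULT_AGCL_TO_NHE_OFFSET",
]

#: Conventional Ag/AgCl (sat. KCl) -> NHE shift (V); configurable everywhere
#: it is used because the exact value depends on the reference filling.
DEFAULT_AGCL_TO_NHE_OFFSET = 0.197


class Reference(str, Enum):
    """Reference-electrode tag attached to a potential axis."""

    AgAgCl = "AgAgCl"
    NHE = "NHE"


def mV_to_V(x):
    return np.asarray(x, dtype=float) / 1000.0


def V_to_mV(x):
    return np.asarray(x, dtype=float) * 1000.0


def uA_to_A(x):
    return np.asarray(x, dtype=float) * 1e-6


def A_to_uA(x):
    return np.asarray(x, dtype=float) / 1e-6


def rpm_to_angular(rate: float) -> float:
    """Convert a rotation rate in revolutions per minute to rad s^-1.

    Raises
    ------
    ValueError
        If ``rate`` is negative.
    """
    if rate < 0:
        raise ValueError(f"rotation rate must be >= 0 rpm, got {rate}")
    return 2.0 * math.pi * rate / 60.0


_MIN_SWEEP_POINTS = 16


@dataclass(frozen=True)
class Voltammogram:
    """A single potential sweep: potential (V, referenced) vs current (A).

    ``rotation_rate`` is in rpm with 0 meaning a stationary electrode.
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    rotation_rate: float = 0.0
    reference: Reference = Reference.AgAgCl
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "potential", np.asarray(self.potential, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        if self.potential.ndim != 1 or self.current.ndim != 1:
            raise ValueError("potential and current must be 1-D")
        if self.potential.size != self.current.size:
            raise ValueError(
                f"potential ({self.potential.size}) and current "
                f"({self.current.size}) differ in length"
            )
        if self.potential.size < _MIN_SWEEP_POINTS:
            raise ValueError(
                f"sweep needs >= {_MIN_SWEEP_POINTS} points, got {self.potential.size}"
            )
        if not self.scan_rate > 0:
            raise ValueError(f"scan_rate must be > 0 V/s, got {self.scan_rate}")
        if self.rotation_rate < 0:
            raise ValueError(f"rotation_rate must be >= 0 rpm, got {self.rotation_rate}")
        object.__setattr__(self, "reference", Reference(self.reference))

    def __len__(self) -> int:
        return self.potential.size


@dataclass(frozen=True)
class RamanSpectrum:
    """A Raman trace: strictly increasing wavenumber (cm^-1) vs intensity."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavenumber", np.asarray(self.wavenumber, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.wavenumber.shape != self.intensity.shape or self.wavenumber.ndim != 1:
            raise ValueError("wavenumber and intensity must be equal-length 1-D arrays")
        if self.wavenumber.size and not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumber.size


def _parse_table(path: str | Path) -> tuple[dict[str, str], np.ndarray]:
    """Parse a ``#key: value`` headed two-column table.

    Returns the metadata dict and an (N, 2) float array.  Errors name the
    offending 1-based line number.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(
                f"expected 2 numeric columns, found {len(parts)}: {raw!r}", lineno
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric row: {raw!r}", lineno) from None
    if not rows:
        raise ParseError(f"no data rows found in {path}")
    return meta, np.asarray(rows, dtype=float)


def read_sweep_table(path: str | Path, **overrides) -> Voltammogram:
    """Read a potential/current sweep table into a :class:`Voltammogram`.

    Keyword overrides (``scan_rate``, ``rotation_rate``, ``reference``,
    ``label``, ``potential_units``, ``current_units``) take precedence over
    metadata in the file header.  Potentials and currents are normalised to
    V and A on ingestion.

    Raises
    ------
    ParseError
        Malformed rows (naming the line).
    ConfigurationError
        No scan rate in the header and no override supplied.
    """
    meta, data = _parse_table(path)

    def pick(override_key: str, meta_key: str, default=None):
        if override_key in overrides:
            return overrides[override_key]
        return meta.get(meta_key, default)

    scan_rate = pick("scan_rate", "scan_rate_V_s")
    if scan_rate is None:
        raise ConfigurationError(
            f"{path}: no '#scan_rate_V_s:' header and no scan_rate override"
        )
    rotation = pick("rotation_rate", "rotation_rate_rpm", 0.0)
    reference = Reference(pick("reference", "reference", Reference.AgAgCl))
    label = pick("label", "label", "")

    potential = data[:, 0]
    current = data[:, 1]
    pot_units = str(pick("potential_units", "potential_units", "V")).strip()
    cur_units = str(pick("current_units", "current_units", "A")).strip()
    if pot_units == "mV":
        potential = mV_to_V(potential)
    elif pot_units != "V":
        raise ConfigurationError(f"unknown potential_units {pot_units!r}")
    scale = {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "μA": 1e-6}.get(cur_units)
    if scale is None:
        raise ConfigurationError(f"unknown current_units {cur_units!r}")
    current = current * scale

    return Voltammogram(
        potential=potential,
        current=current,
        scan_rate=float(scan_rate),
        rotation_rate=float(rotation),
        reference=reference,
        label=str(label),
    )


def write_sweep_table(v: Voltammogram, path: str | Path, precision: int = 10) -> None:
    """Write a sweep as a ``#key: value`` headed two-column table.

    Values are written with ``precision`` significant digits in scientific
    notation; reading the file back reproduces the numeric content at that
    precision.
    """
    lines = [
        f"# scan_rate_V_s: {v.scan_rate!r}",
        f"# rotation_rate_rpm: {v.rotation_rate!r}",
        f"# reference: {v.reference.value}",
    ]
    if v.label:
        lines.append(f"# label: {v.label}")
    lines.append("# potential_units: V")
    lines.append("# current_units: A")
    fmt = f"%.{precision}e"
    for e, i in zip(v.potential, v.current):
        lines.append(f"{fmt % e} {fmt % i}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_table(path: str | Path, label: str | None = None) -> RamanSpectrum:
    """Read a wavenumber/intensity table into a :class:`RamanSpectrum`."""
    meta, data = _parse_table(path)
    order = np.argsort(data[:, 0])
    return RamanSpectrum(
        wavenumber=data[order, 0],
        intensity=data[order, 1],
        label=label if label is not None else meta.get("label", ""),
    )


def write_spectrum_table(s: RamanSpectrum, path: str | Path, precision: int = 10) -> None:
    lines = []
    if s.label:
        lines.append(f"# label: {s.label}")
    fmt = f"%.{precision}e"
    for w, i in zip(s.wavenumber, s.intensity):
        lines.append(f"{fmt % w} {fmt % i}")
    Path(path).write_text("\n".join(lines) + "\n")


def convert_reference(
    v: Voltammogram,
    target: Reference | str,
    offset: float = DEFAULT_AGCL_TO_NHE_OFFSET,
) -> Voltammogram:
    """Re-reference a sweep's potential axis.

    ``offset`` is the Ag/AgCl -> NHE shift in V (added going AgAgCl->NHE,
    subtracted going back), so the conversion is an exact involution.
    Converting to the sweep's current reference is a warned no-op.
    """
    target = Reference(target)
    if not math.isfinite(offset):
        raise ValueError("reference offset must be finite")
    if v.reference == target:
        warnings.warn(
            f"sweep is already referenced to {target.value}; returning unchanged",
            stacklevel=2,
        )
        return v
    sign = +1.0 if target == Reference.NHE else -1.0
    return replace(v, potential=v.potential + sign * offset, reference=target)
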