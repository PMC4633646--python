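"""Physical constants and the electrochemical parameter set.

Internal unit system follows electroanalytical convention: potentials in V,
currents in A, charge in C, lengths in cm (areas cm^2), diffusion
coefficients and kinematic viscosities in cm^2 s^-1, and bulk concentrations
in mol cm^-3.  Interfaces accept the units practitioners quote (mM for
dissolved O2, rpm for rotation rates) and convert on ingestion, so the
Levich expression can be evaluated with its textbook prefactor 0.62.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Faraday constant (C mol^-1), CODATA.
FARADAY = 96485.33212
#: Molar gas constant (J mol^-1 K^-1).
GAS_CONSTANT = 8.31446261815324

#: 1 M = 1 mol L^-1 = 1e-3 mol cm^-3.
MOLAR_TO_MOL_PER_CM3 = 1.0e-3
MM_TO_MOL_PER_CM3 = 1.0e-6


@dataclass(frozen=True)
class ElectrochemConstants:
    """Cell and solution parameters entering the Levich and kinetic-current
    expressions.

    Defaults describe an air-saturated pH 7 aqueous buffer at 25 degC on a
    0.096 cm^2 rotating gold disc: [O2] = 0.26 mM, D(O2) = 1.8e-5 cm^2 s^-1,
    kinematic viscosity 0.009 cm^2 s^-1.

    Attributes
    ----------
    faraday_constant : float
        Charge per mole of electrons (C mol^-1).
    electrode_area : float
        Macroscopic (geometric) disc area (cm^2).
    o2_concentration : float
        Bulk O2 concentration in internal units (mol cm^-3); use
        :meth:`with_o2_mM` or the :attr:`o2_mM` / :attr:`o2_molar`
        properties to work in the usual concentration units.
    o2_diffusion : float
        O2 diffusion coefficient (cm^2 s^-1).
    kinematic_viscosity : float
        Solution kinematic viscosity (cm^2 s^-1).
    temperature : float
        Absolute temperature (K).
    """

    faraday_constant: float = FARADAY
    electrode_area: float = 0.096
    o2_concentration: float = 0.26 * MM_TO_MOL_PER_CM3
    o2_diffusion: float = 1.8e-5
    kinematic_viscosity: float = 0.009
    temperature: float = field(default=298.15)

    def __post_init__(self) -> None:
        for name in (
            "faraday_constant",
            "electrode_area",
            "o2_concentration",
            "o2_diffusion",
            "kinematic_viscosity",
            "temperature",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @classmethod
    def with_o2_mM(cls, o2_mM: float, **kwargs) -> "ElectrochemConstants":
        """Build a parameter set quoting the bulk O2 concentration in mM."""
        return cls(o2_concentration=o2_mM * MM_TO_MOL_PER_CM3, **kwargs)

    @property
    def o2_mM(self) -> float:
        """Bulk O2 concentration in mM."""
        return self.o2_concentration / MM_TO_MOL_PER_CM3

    @property
    def o2_molar(self) -> float:
        """Bulk O2 concentration in mol L^-1 (M)."""
        return self.o2_concentration / MOLAR_TO_MOL_PER_CM3
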