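"""Rotating ring-disc selectivity and turnover accounting.

During O2 reduction at the disc, any peroxide (or superoxide) escaping the
four-electron pathway is swept to the ring and re-oxidised there, so the
ring current — corrected by the hardware collection efficiency N — counts
the partially reduced oxygen species (PROS).  With x = i_ring / N the
standard accounting is

    PROS% = 200 x / (i_disc + x),        n_eff = 4 i_disc / (i_disc + x),

which satisfy n_eff = 4 - 2 PROS/100 identically: an all-water product
stream gives 0% PROS and n = 4, an all-peroxide stream 100% and n = 2.
The total charge passed over an experiment converts to moles of O2 reduced
and, per mole of catalyst on the electrode, to a turnover number.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import FARADAY

__all__ = [
    "RingDiscPair",
    "TurnoverAccount",
    "pros_percent",
    "electrons_per_o2",
    "turnover_account",
]


@dataclass(frozen=True)
class RingDiscPair:
    """Simultaneous disc and ring current magnitudes (A) plus the ring
    collection efficiency N (fraction in (0, 1], hardware-specific)."""

    disc_current: float
    ring_current: float
    collection_efficiency: float = 0.25

    def __post_init__(self) -> None:
        if self.disc_current < 0 or self.ring_current < 0:
            raise ValueError("currents are magnitudes and must be >= 0")
        if not (0 < self.collection_efficiency <= 1):
            raise ValueError("collection efficiency must lie in (0, 1]")


@dataclass(frozen=True)
class TurnoverAccount:
    """Faradaic O2 accounting over a whole experiment."""

    total_charge: float       # C
    electrons_per_o2: float
    moles_o2: float           # mol
    moles_catalyst: float     # mol
    turnover_number: float


def pros_percent(pair: RingDiscPair) -> float:
    """Percentage of O2 diverted to partially reduced species."""
    if pair.disc_current <= 0:
        raise ValueError("disc current must be > 0")
    x = pair.ring_current / pair.collection_efficiency
    return 200.0 * x / (pair.disc_current + x)


def electrons_per_o2(pair: RingDiscPair) -> float:
    """Effective electrons transferred per O2 molecule (4 = all water,
    2 = all peroxide); equals 4 - 2*PROS/100."""
    if pair.disc_current <= 0:
        raise ValueError("disc current must be > 0")
    x = pair.ring_current / pair.collection_efficiency
    return 4.0 * pair.disc_current / (pair.disc_current + x)


def turnover_account(
    total_charge: float,
    electrons_per_o2: float,
    moles_catalyst: float,
    faraday_constant: float = FARADAY,
) -> TurnoverAccount:
    """Convert total catalytic charge to moles of O2 and a turnover number.

    moles_O2 = Q / (n F);  TON = moles_O2 / moles_catalyst.
    """
    if total_charge <= 0:
        raise ValueError("total charge must be > 0")
    if electrons_per_o2 <= 0:
        raise ValueError("electrons per O2 must be > 0")
    if moles_catalyst <= 0:
        raise ValueError("catalyst amount must be > 0")
    moles_o2 = total_charge / (electrons_per_o2 * faraday_constant)
    return TurnoverAccount(
        total_charge=total_charge,
        electrons_per_o2=electrons_per_o2,
        moles_o2=moles_o2,
        moles_catalyst=moles_catalyst,
        turnover_number=moles_o2 / moles_catalyst,
    )
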