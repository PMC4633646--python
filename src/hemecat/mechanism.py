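"""Steady-state microkinetics of an irreversible unicyclic oxidase cycle.

The O2-reduction cycle of cytochrome c oxidase and its heme/Cu mimics is
modelled as an ordered ring of states — resting Fe(III), Fe(II), oxy
Fe(II)-O2, peroxo Fe(III)-O2(2-), hydroperoxo Fe(III)-OOH, ferryl Fe(IV)=O
and hydroxide Fe(III)-OH — connected by irreversible effective
first-order steps (electron transfers, O2 binding, protonations and O-O
cleavage folded into single rates k_i, s^-1).  At steady state the flux
through every step is equal,

    J = p_i k_i  for all i   =>   p_i proportional to 1/k_i,
    J = (sum_i 1/k_i)^-1,

so the state feeding the slowest step accumulates: a species builds up
exactly when its formation outruns its decay.  Each state carries a
Raman-observable class so the predicted steady-state populations can be
compared with marker-band deconvolution of spectra taken during turnover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.linalg import null_space

from .exceptions import ConfigurationError
from .raman import OBSERVABLE_CLASSES

__all__ = [
    "CycleModel",
    "SteadyState",
    "RdsReport",
    "steady_state",
    "steady_state_populations_linear",
    "effective_rate_from_bimolecular",
    "predicted_observables",
    "rds_report",
    "load_cycle_model",
    "scenario",
    "SCENARIOS",
]

SCENARIOS = ("native_solution", "electrode_model")


@dataclass(frozen=True)
class CycleModel:
    """An irreversible unicyclic catalytic mechanism.

    ``step_rates[i]`` is the effective first-order rate (s^-1) of the step
    leaving ``states[i]`` for ``states[i+1]`` (cyclically).  Optional
    ``step_labels`` name the chemistry of each step;
    ``observable_class`` maps each state to a Raman-observable class.
    """

    states: tuple[str, ...]
    step_rates: tuple[float, ...]
    observable_class: Mapping[str, str] = field(default_factory=dict)
    step_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        states = tuple(self.states)
        rates = tuple(float(r) for r in self.step_rates)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "step_rates", rates)
        if len(states) < 3:
            raise ValueError("a cycle needs at least 3 states")
        if len(set(states)) != len(states):
            raise ValueError("state labels must be unique")
        if len(rates) != len(states):
            raise ValueError("need one step rate per state (cyclic topology)")
        if any(r <= 0 for r in rates):
            raise ValueError("all step rates must be > 0 s^-1")
        labels = tuple(self.step_labels) or tuple(
            f"{states[i]} -> {states[(i + 1) % len(states)]}"
            for i in range(len(states))
        )
        if len(labels) != len(states):
            raise ValueError("need one step label per step")
        object.__setattr__(self, "step_labels", labels)
        for st, cls in self.observable_class.items():
            if st not in states:
                raise ValueError(f"observable_class refers to unknown state {st!r}")
            if cls not in OBSERVABLE_CLASSES:
                raise ValueError(f"unknown observable class {cls!r} for state {st!r}")


@dataclass(frozen=True)
class SteadyState:
    """Normalised steady-state populations, cycle flux and accumulation."""

    populations: Mapping[str, float]
    flux: float                 # turnover frequency, s^-1
    rds_state: str              # state feeding the slowest step
    accumulated: tuple[str, ...]  # states above the reporting threshold


@dataclass(frozen=True)
class RdsReport:
    """Slowest step(s) of a cycle; ``steps`` lists all ties."""

    steps: tuple[str, ...]
    rate: float
    flux: float


def steady_state_populations_linear(model: CycleModel) -> np.ndarray:
    """Steady-state populations via the null space of the full rate matrix.

    Independent of the closed form; used as a cross-check of p_i ~ 1/k_i.
    """
    m = len(model.states)
    a = np.zeros((m, m))
    for i, k in enumerate(model.step_rates):
        a[i, i] -= k
        a[(i + 1) % m, i] += k
    ns = null_space(a)
    if ns.shape[1] != 1:
        raise RuntimeError("rate matrix null space is not one-dimensional")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-12):
        raise RuntimeError("negative steady-state population from null space")
    return np.clip(p, 0.0, None)


def steady_state(
    model: CycleModel, accumulation_threshold: float = 0.05
) -> SteadyState:
    """Closed-form steady state of an irreversible unicycle.

    p_i = (1/k_i) / sum_j (1/k_j) and J = (sum_j 1/k_j)^-1; the result is
    cross-verified against the general linear-solver (null-space) path
    before being returned.
    """
    inv = np.array([1.0 / k for k in model.step_rates])
    p = inv / inv.sum()
    flux = 1.0 / inv.sum()

    p_lin = steady_state_populations_linear(model)
    # the SVD route loses a few digits for rate spreads of many decades,
    # hence the slightly relaxed internal agreement threshold
    if not np.allclose(p, p_lin, rtol=1e-7, atol=1e-12):
        raise RuntimeError("closed-form and linear-solver steady states disagree")

    populations = dict(zip(model.states, p.tolist()))
    rds_idx = int(np.argmin(model.step_rates))
    accumulated = tuple(
        st for st, frac in populations.items() if frac > accumulation_threshold
    )
    return SteadyState(
        populations=populations,
        flux=float(flux),
        rds_state=model.states[rds_idx],
        accumulated=accumulated,
    )


def effective_rate_from_bimolecular(k2: float, concentration: float) -> float:
    """Effective first-order rate (s^-1) of a bimolecular step: k2 [S].

    ``k2`` in M^-1 s^-1, ``concentration`` in M — e.g. O2 binding at
    1e7 M^-1 s^-1 in an air-saturated buffer (0.26 mM) gives 2600 s^-1.
    """
    if k2 < 0 or concentration < 0:
        raise ValueError("rate constant and concentration must be >= 0")
    return k2 * concentration


def predicted_observables(ss: SteadyState, model: CycleModel) -> dict[str, float]:
    """Sum steady-state populations by Raman-observable class.

    Output is directly comparable with the class fractions from
    marker-band deconvolution of spectra recorded during turnover.
    """
    out: dict[str, float] = {}
    for st, frac in ss.populations.items():
        cls = model.observable_class.get(st)
        if cls is None:
            raise ConfigurationError(f"state {st!r} has no observable class mapping")
        out[cls] = out.get(cls, 0.0) + frac
    return out


def rds_report(model: CycleModel) -> RdsReport:
    """Identify the rate-determining step(s): the minimum step rate, with
    all ties listed, and the cycle flux (always <= the minimum rate)."""
    rates = np.array(model.step_rates)
    kmin = rates.min()
    steps = tuple(
        lab for lab, r in zip(model.step_labels, model.step_rates) if r == kmin
    )
    flux = 1.0 / np.sum(1.0 / rates)
    return RdsReport(steps=steps, rate=float(kmin), flux=float(flux))


def load_cycle_model(path: str | Path) -> CycleModel:
    """Read a mechanism definition from a delimited text file.

    Each non-comment line: ``state  observable_class  step_rate  [step label]``
    (whitespace/tab separated; the optional step label may contain spaces).
    The step rate on a line is the rate of the step leaving that state for
    the next line's state (the last line wraps to the first).
    """
    states, classes, rates, labels = [], {}, [], []
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 3)
        if len(parts) < 3:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'state class rate [label]', got {raw!r}"
            )
        state, klass, rate = parts[0], parts[1], parts[2]
        try:
            rate_val = float(rate)
        except ValueError:
            raise ConfigurationError(
                f"{path}:{lineno}: non-numeric step rate {rate!r}"
            ) from None
        states.append(state)
        classes[state] = klass
        rates.append(rate_val)
        labels.append(parts[3].strip() if len(parts) == 4 else "")
    if any(labels):
        step_labels = tuple(
            lab
            or f"{states[i]} -> {states[(i + 1) % len(states)]}"
            for i, lab in enumerate(labels)
        )
    else:
        step_labels = ()
    return CycleModel(
        states=tuple(states),
        step_rates=tuple(rates),
        observable_class=classes,
        step_labels=step_labels,
    )


def scenario(name: str) -> CycleModel:
    """Load one of the bundled cycle scenarios.

    ``"native_solution"`` — the solution enzyme with fast electron supply:
    hydroxide dissociation from Fe(III)-OH (500 s^-1) is rate limiting, so
    the high-spin ferric hydroxide accumulates.

    ``"electrode_model"`` — the electrode-wired biosynthetic mimic: every
    electron-transfer step, including direct reduction of Fe(III)-OH (the
    electron-transfer shunt), is fast, leaving protonation of the bound
    peroxo species (5000 s^-1) rate limiting; low-spin ferric and ferryl
    species dominate the steady state.
    """
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        )
    ref = resources.files("hemecat") / "scenarios" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return load_cycle_model(path)
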