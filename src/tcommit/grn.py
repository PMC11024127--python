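"""Transcriptional level: stochastic and deterministic GRN dynamics.

The gene regulatory network couples six species — Runx1 (R), Tcf7 (T),
Gata3 (G), PU.1/Spi1 (P), the Bcl11b-opposing function X, and the Notch
signal (N).  Production follows the Shea-Ackers thermodynamic form: the
rate is a ratio of statistical weights of regulator-bound promoter states,
so every production propensity is bounded and saturating.  Degradation is
first order with per-gene rates gamma (h^-1); the Notch signal has no decay
channel and is therefore non-decreasing along any trajectory.

The stochastic mode is an exact Gillespie SSA on integer molecule counts.
The deterministic mode integrates the same rate laws as ODEs over real
counts; it exists for validation and knockdown sanity checks only and is
never used inside a colony simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "SPECIES",
    "KD_GENES",
    "GeneState",
    "GRNParameters",
    "GRNTrajectory",
    "production_propensities",
    "degradation_propensities",
    "gillespie_step",
    "simulate_grn",
    "integrate_ode",
    "apply_knockdown",
]

#: species names in canonical vector order
SPECIES = ("Runx1", "Tcf7", "Gata3", "PU.1", "X", "Notch")
#: short column labels used in trajectory tables
SPECIES_SHORT = ("R", "T", "G", "P", "X", "N")
#: genes that may be knocked down
KD_GENES = ("Runx1", "Tcf7", "Gata3", "PU.1")

_GENE_INDEX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class GeneState:
    """Molecule counts of the six species at simulation time ``t`` (hours)."""

    R: int
    T: int
    G: int
    P: int
    X: int
    N: int
    t: float = 0.0

    def __post_init__(self):
        for name in SPECIES_SHORT:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.T, self.G, self.P, self.X, self.N],
                        dtype=np.int64)

    @classmethod
    def from_array(cls, arr: Sequence[int], t: float = 0.0) -> "GeneState":
        return cls(*(int(v) for v in arr), t=float(t))


@dataclass(frozen=True)
class GRNParameters:
    """Regulation parameters p1..p16, decay rates gamma (h^-1), KD factors.

    Defaults are the fitted wild-type values.  ``kd_factors`` multiply the
    six production propensities (species order); values of exactly 0 are
    accepted so that validation tests can disable channels, but the public
    knockdown operation only produces factors in (0, 1].
    """

    p1: float = 0.10
    p2: float = 1.00
    p3: float = 5.00
    p4: float = 1.00
    p5: float = 1.50
    p6: float = 0.01
    p7: float = 0.50
    p8: float = 0.70
    p9: float = 0.50
    p10: float = 1.00
    p11: float = 0.20
    p12: float = 2.50
    p13: float = 2.60
    p14: float = 2.00
    p15: float = 1.00
    p16: float = 0.01
    gamma_R: float = 0.15
    gamma_T: float = 0.15
    gamma_G: float = 0.23
    gamma_P: float = 0.06
    gamma_X: float = 0.02
    kd_factors: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        for i in range(1, 17):
            v = getattr(self, f"p{i}")
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"p{i}={v!r} must be finite and non-negative")
        for g in ("gamma_R", "gamma_T", "gamma_G", "gamma_P", "gamma_X"):
            v = getattr(self, g)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{g}={v!r} must be finite and non-negative")
        if len(self.kd_factors) != 6:
            raise ValueError("kd_factors must have six entries (species order)")
        for f_ in self.kd_factors:
            if not (math.isfinite(f_) and 0.0 <= f_ <= 1.0):
                raise ValueError(f"kd factor {f_!r} outside [0, 1]")

    def p_array(self) -> np.ndarray:
        return np.array([getattr(self, f"p{i}") for i in range(1, 17)])

    def gamma_array(self) -> np.ndarray:
        return np.array([self.gamma_R, self.gamma_T, self.gamma_G,
                         self.gamma_P, self.gamma_X])

    def kd_array(self) -> np.ndarray:
        return np.asarray(self.kd_factors, dtype=float)


@dataclass
class GRNTrajectory:
    """Record of SSA events; the state is piecewise constant between events.

    ``times[0]`` is the initial time and ``states[0]`` the initial state; the
    last recorded state holds up to ``t_end``.
    """

    times: np.ndarray
    states: np.ndarray  # (n, 6) int64
    t_end: float

    def __len__(self) -> int:
        return len(self.times)

    @property
    def initial_state(self) -> GeneState:
        return GeneState.from_array(self.states[0], t=self.times[0])

    @property
    def final_state(self) -> GeneState:
        return GeneState.from_array(self.states[-1], t=self.t_end)

    def state_at(self, t: float) -> GeneState:
        if t < self.times[0] or t > self.t_end:
            raise ValueError(f"t={t} outside trajectory [{self.times[0]}, {self.t_end}]")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return GeneState.from_array(self.states[idx], t=t)

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("negative molecule count in trajectory")
        d = np.diff(self.states, axis=0)
        if len(d) and not (np.all(np.abs(d).sum(axis=1) == 1)):
            raise ValueError("consecutive states must differ by one molecule")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES_SHORT))
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def concatenate(self, other: "GRNTrajectory") -> "GRNTrajectory":
        """Join a trajectory that continues this one at ``self.t_end``."""
        if not np.array_equal(other.states[0], self.states[-1]):
            raise ValueError("trajectories do not join continuously")
        keep = other.times > self.times[-1]
        return GRNTrajectory(
            times=np.concatenate([self.times, other.times[keep]]),
            states=np.vstack([self.states, other.states[keep]]),
            t_end=other.t_end,
        )


def _check_state(state: GeneState) -> None:
    if not isinstance(state, GeneState):
        raise TypeError("expected a GeneState")


def production_propensities(state: GeneState, params: GRNParameters) -> np.ndarray:
    """Six Shea-Ackers production rates (h^-1) at integer counts.

    Each rate is multiplied by the gene's knockdown factor; the Notch input
    grows self-limitingly at p16/(1+N).
    """
    _check_state(state)
    rates = _kernels.grn_production_rates(
        state.as_array().astype(float), params.p_array(), params.kd_array()
    )
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ValueError("non-finite or negative production propensity")
    return rates


def degradation_propensities(state: GeneState, params: GRNParameters) -> np.ndarray:
    """First-order decay propensities gamma_i * count; exactly 0 for Notch."""
    _check_state(state)
    return _kernels.grn_degradation_rates(
        state.as_array().astype(float), params.gamma_array()
    )


def gillespie_step(state: GeneState, params: GRNParameters,
                   rng: np.random.Generator, t_max: float) -> GeneState:
    """Advance the SSA by one reaction, or censor at ``t_max``.

    Draws an exponential waiting time at the total propensity and picks one
    channel proportionally.  A zero total propensity is an absorbing state
    and returns the unchanged counts stamped at ``t_max``.
    """
    if state.t >= t_max:
        raise ValueError("state.t must be below t_max")
    prod = production_propensities(state, params)
    deg = degradation_propensities(state, params)
    rates = np.concatenate([prod, deg])
    total = rates.sum()
    if total <= 0.0:
        return replace(state, t=t_max)
    dt = rng.exponential(1.0 / total)
    if state.t + dt > t_max:
        return replace(state, t=t_max)
    idx = int(np.searchsorted(np.cumsum(rates), rng.random() * total, side="right"))
    idx = min(idx, 11)
    arr = state.as_array()
    if idx < 6:
        arr[idx] += 1
    else:
        arr[idx - 6] -= 1
    return GeneState.from_array(arr, t=state.t + dt)


def _draw_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def simulate_grn(initial: GeneState, t0: float, t1: float,
                 params: GRNParameters, rng: np.random.Generator,
                 params_after: Optional[GRNParameters] = None,
                 switch_time: float = math.inf) -> GRNTrajectory:
    """Run the SSA over [t0, t1] and return the full event record.

    ``params_after``/``switch_time`` implement a mid-interval parameter
    change (delayed knockdown): production factors switch at ``switch_time``
    (only the knockdown factors may differ between the two parameter sets).
    """
    if t0 > t1:
        raise ValueError("t0 must not exceed t1")
    kd0 = params.kd_array()
    kd1 = kd0 if params_after is None else params_after.kd_array()
    times, states = _kernels.grn_ssa(
        initial.as_array(), float(t0), float(t1),
        params.p_array(), params.gamma_array(), kd0, kd1,
        float(switch_time), _draw_seed(rng),
    )
    return GRNTrajectory(times=times, states=states, t_end=float(t1))


def integrate_ode(initial, t_span, params: GRNParameters, rtol: float = 1e-8,
                  atol: float = 1e-10):
    """Integrate the rate laws deterministically over real-valued counts.

    ``initial`` may be a GeneState or a length-6 float vector.  Returns the
    scipy ``OdeResult`` (fields ``t`` and ``y`` with species in rows).  Used
    for validation and knockdown sanity checks only.
    """
    if isinstance(initial, GeneState):
        y0 = initial.as_array().astype(float)
    else:
        y0 = np.asarray(initial, dtype=float)
        if y0.shape != (6,):
            raise ValueError("initial must have six entries")
    p = params.p_array()
    g = params.gamma_array()
    kd = params.kd_array()

    def rhs(_t, y):
        return (_kernels.grn_production_rates(y, p, kd)
                - _kernels.grn_degradation_rates(y, g))

    sol = solve_ivp(rhs, t_span, y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_knockdown(params: GRNParameters, state: Optional[GeneState],
                    gene: str, factor: float, scale_initial: bool = False):
    """Scale a gene's production by ``factor``; optionally its initial count.

    The initial-count scaling (used when knockdown starts at t=0) rounds to
    the nearest integer, ties away from zero, because the SSA requires
    integer counts.  Returns the modified (params, state) pair; inputs are
    left untouched.
    """
    if gene not in KD_GENES:
        raise ValueError(f"unknown knockdown gene {gene!r}; expected one of {KD_GENES}")
    if not (0.0 < factor <= 1.0):
        raise ValueError("knockdown factor must lie in (0, 1]")
    idx = _GENE_INDEX[gene]
    kd = list(params.kd_factors)
    kd[idx] = kd[idx] * factor
    new_params = replace(params, kd_factors=tuple(kd))
    new_state = state
    if state is not None and scale_initial and factor < 1.0:
        arr = state.as_array()
        arr[idx] = _round_half_away(arr[idx] * factor)
        new_state = GeneState.from_array(arr, t=state.t)
    return new_params, new_state
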