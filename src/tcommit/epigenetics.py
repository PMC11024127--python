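"""Epigenetic level: the 500-site three-state Bcl11b regulatory region.

Each of the S regulatory sites is closed (C), intermediate (I) or open (O);
only the counts matter (sites are exchangeable and carry no identity or
spatial arrangement).  Sites never jump directly between O and C.  Nine
transition channels exist: four driven by the transcriptional inputs — X
closes (O->I, I->C at attempt rate k1*X), Runx1 and Notch open (C->I, I->O
at k2*N + k3*R) — and five mediated by a second site with a required state.
A channel fires at its attempt rate; the transitioning site is chosen
uniformly among all S sites and must match the channel's source state, and
a mediated channel additionally requires a uniformly chosen mediator site
to match.  The aggregated propensity is therefore
rate * (source_count/S) [* mediator_count/S], which makes the region's
spontaneous dynamics slow (a few site transitions per hour out of 500):
between divisions the open fraction drifts, and the large opening leaps
happen at divisions of X-depleted cells.  The mediator may coincide with
the transitioning site for the I-mediated I->C channel; at S = 500 the
distinction is negligible.

The region counts as open when at least ``open_fraction_threshold`` of the
sites are open (default 75 %, i.e. O >= 375 of 500), the model's proxy for
Bcl11b expression and hence T-lineage commitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .grn import GRNTrajectory

__all__ = [
    "RegulatoryRegion",
    "EpigeneticParameters",
    "TransitionChannel",
    "RegionTrajectory",
    "channel_propensities",
    "epigenetic_step",
    "evolve_region",
    "is_region_open",
]

_STATE_NAMES = ("C", "I", "O")


@dataclass(frozen=True)
class RegulatoryRegion:
    """Counts of closed / intermediate / open sites; C + I + O = S always."""

    C: int
    I: int
    O: int
    S: int = 500

    def __post_init__(self):
        for name in ("C", "I", "O"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"site count {name}={v!r} must be a non-negative integer")
        if self.C + self.I + self.O != self.S:
            raise ValueError(
                f"site counts C+I+O={self.C + self.I + self.O} != S={self.S}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.I, self.O], dtype=np.int64)

    @property
    def open_fraction(self) -> float:
        return self.O / self.S


@dataclass(frozen=True)
class EpigeneticParameters:
    """Site-transition rates.

    k1 couples X to closing, k2/k3 couple Notch/Runx1 to opening;
    alpha..epsilon are the mediated-transition rates (gamma_m renamed from
    the region model's gamma to avoid collision with the GRN decay rates).
    """

    k1: float = 0.28
    k2: float = 0.20
    k3: float = 0.20
    alpha: float = 0.002
    beta: float = 0.002
    gamma_m: float = 0.0005
    delta: float = 0.0005
    epsilon: float = 0.002
    S: int = 500
    open_fraction_threshold: float = 0.75

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "alpha", "beta", "gamma_m", "delta",
                     "epsilon"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name}={v!r} must be finite and non-negative")
        if not (0.0 < self.open_fraction_threshold <= 1.0):
            raise ValueError("open_fraction_threshold must lie in (0, 1]")
        if self.S < 1:
            raise ValueError("S must be positive")

    def rate_tuple(self) -> Tuple[float, ...]:
        return (self.k1, self.k2, self.k3, self.alpha, self.beta,
                self.gamma_m, self.delta, self.epsilon)


@dataclass(frozen=True)
class TransitionChannel:
    source: str
    target: str
    mediator: Optional[str]
    propensity: float


@dataclass
class RegionTrajectory:
    """Record of site-transition events; piecewise constant between events."""

    times: np.ndarray
    states: np.ndarray  # (n, 3) int64, columns C, I, O
    t_end: float
    S: int

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_region(self) -> RegulatoryRegion:
        c, i_, o = (int(v) for v in self.states[-1])
        return RegulatoryRegion(C=c, I=i_, O=o, S=self.S)

    def to_frame(self, params: Optional[EpigeneticParameters] = None) -> pd.DataFrame:
        params = params or EpigeneticParameters(S=self.S)
        df = pd.DataFrame(self.states, columns=["C", "I", "O"])
        df.insert(0, "time_h", self.times)
        df["open_flag"] = df["O"] >= params.open_fraction_threshold * self.S
        return df

    def to_csv(self, path, params: Optional[EpigeneticParameters] = None) -> None:
        self.to_frame(params).to_csv(path, index=False)


def channel_propensities(region: RegulatoryRegion, inputs: Sequence[float],
                         params: EpigeneticParameters):
    """The nine transition channels with their propensities (h^-1).

    ``inputs`` is the (X, Runx1, Notch) count triple read from the
    transcriptional level.
    """
    X, R, N = (float(v) for v in inputs)
    if X < 0 or R < 0 or N < 0:
        raise ValueError("input counts must be non-negative")
    rates = _kernels.epi_channel_rates(
        float(region.C), float(region.I), float(region.O), float(region.S),
        X, R, N, *params.rate_tuple(),
    )
    meta = [("O", "I", None), ("I", "C", None), ("C", "I", None), ("I", "O", None),
            ("O", "I", "C"), ("I", "C", "C"), ("I", "O", "O"), ("C", "I", "O"),
            ("I", "C", "I")]
    return [TransitionChannel(s, t, m, float(r))
            for (s, t, m), r in zip(meta, rates)]


def epigenetic_step(region: RegulatoryRegion, t: float, inputs: Sequence[float],
                    params: EpigeneticParameters, rng: np.random.Generator,
                    t_max: float):
    """One SSA event (or censoring at ``t_max``); returns (region, time).

    Site conservation holds by construction: each event decrements one
    source count and increments one target count.
    """
    if t >= t_max:
        raise ValueError("t must be below t_max")
    channels = channel_propensities(region, inputs, params)
    rates = np.array([ch.propensity for ch in channels])
    total = rates.sum()
    if total <= 0.0:
        return region, t_max
    dt = rng.exponential(1.0 / total)
    if t + dt > t_max:
        return region, t_max
    idx = int(np.searchsorted(np.cumsum(rates), rng.random() * total, side="right"))
    idx = min(idx, 8)
    counts = {"C": region.C, "I": region.I, "O": region.O}
    counts[channels[idx].source] -= 1
    counts[channels[idx].target] += 1
    return RegulatoryRegion(C=counts["C"], I=counts["I"], O=counts["O"],
                            S=region.S), t + dt


def evolve_region(region: RegulatoryRegion, grn_traj: GRNTrajectory,
                  t0: float, t1: float, params: EpigeneticParameters,
                  rng: np.random.Generator, record: bool = True) -> RegionTrajectory:
    """SSA over [t0, t1] with (X, R, N) read piecewise-constant from the GRN.

    The waiting-time draw is restarted at every GRN event time with updated
    propensities, which is exact by memorylessness for piecewise-constant
    hazards.  ``record=False`` keeps only the final state (used inside the
    colony simulator to bound memory).
    """
    if grn_traj.times[0] > t0 or grn_traj.t_end < t1:
        raise ValueError("GRN trajectory does not cover the requested interval")
    seed = int(rng.integers(2**31))
    times, states, c, i_, o = _kernels.epi_ssa(
        int(region.C), int(region.I), int(region.O), int(region.S),
        grn_traj.times, grn_traj.states[:, 4].astype(float),
        grn_traj.states[:, 0].astype(float), grn_traj.states[:, 5].astype(float),
        float(t0), float(t1), *params.rate_tuple(), seed, record,
    )
    if not record:
        times = np.array([t0, t1]) if t1 > t0 else np.array([t0])
        states = np.array([[region.C, region.I, region.O]] * len(times),
                          dtype=np.int64)
        states[-1] = (c, i_, o)
    return RegionTrajectory(times=times, states=states, t_end=float(t1),
                            S=region.S)


def is_region_open(region: RegulatoryRegion,
                   params: Optional[EpigeneticParameters] = None) -> bool:
    """True iff the open-site count reaches the commitment threshold (>=)."""
    params = params or EpigeneticParameters(S=region.S)
    return region.O >= params.open_fraction_threshold * region.S
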