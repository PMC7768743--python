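"""Discrete-time synaptic vesicle pool simulator for evoked DA release.

The model is a mean-field bookkeeping of three vesicle pools and the active
zones (AZ) that gate fusion, designed to reproduce the qualitative
genotype-dependent phenotypes of repeated-burst stimulation:

* readily releasable pool (RRP) — docked vesicles, capacity ``rrp_cap``;
* recycling pool (RP) — a staging pool between reserve and RRP;
* reserve — a deep pool; released vesicles return to it only after a fixed
  recycling delay.

Per stimulus pulse, ``released = p_release * min(rrp, free AZ)`` vesicles
fuse; the collapsing vesicle membrane occupies active zones, which clear
exponentially at ``k_clear`` (enhanced by α-synuclein).  Refilling is
calcium-gated (active during a burst and for 1 s after it): reserve
vesicles are mobilised into the RP at ``k_reserve`` (inhibited by α-syn at
rest but the dominant supply during activity) and RP vesicles dock into the
RRP at ``k_refill``, capped by the RRP deficit.  Outside gated windows the
pools are frozen — the rested state is an exact steady state.

The update rules are artifact-defined: the source model is qualitative and
publishes no rate equations.  Preset rate constants and pool sizes are
calibration artifacts chosen so that the wild-type (WT) preset shows
within-train facilitation and ~50 % six-sweep depression while the
synuclein-knockout (KO) preset shows within-train depression with flat
sweeps; they are not measured quantities.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace, field

import numpy as np

from .plasticity import StimulusProtocol, burst_onsets, protocol_timeline

__all__ = [
    "PoolParams",
    "PoolState",
    "WT_PRESET",
    "KO_PRESET",
    "step",
    "simulate_release",
    "ReleaseSimulation",
]


@dataclass(frozen=True)
class PoolParams:
    """Rates, pool sizes, and conversion factor of the pool model.

    n_az            number of active zones
    rrp0/rp0/reserve0   initial pool sizes (vesicle units)
    rrp_cap         RRP docking capacity (refill stops here)
    p_release       fusion probability per pulse per available vesicle/AZ
    k_clear         AZ clearance rate after fusion, 1/s (α-syn-enhanced)
    k_refill        RP -> RRP docking rate, 1/s, calcium-gated
    k_reserve       reserve -> RP mobilisation rate, 1/s, calcium-gated
                    (α-syn-inhibited: low in WT, high in KO)
    k_rest          constitutive (ungated) reserve -> RRP trickle, 1/s;
                    zero in WT (α-syn suppresses resting remobilisation),
                    fast in KO so the RRP re-docks fully between bursts
    k_demob         RP -> reserve re-sequestration while the calcium gate is
                    closed, 1/s: mobilised vesicles that are not used decay
                    back to the reserve between stimulation episodes
    recycle_delay   s until a released vesicle returns to the reserve
                    (long in WT — α-syn slows vesicle remobilisation)
    q               µM extracellular DA per released vesicle unit
    """

    n_az: int = 100
    rrp0: float = 100.0
    rp0: float = 0.0
    reserve0: float = 5000.0
    rrp_cap: float = 100.0
    p_release: float = 0.6
    k_clear: float = 5.0
    k_refill: float = 0.35
    k_reserve: float = 0.01
    k_rest: float = 0.0
    k_demob: float = 0.02
    recycle_delay: float = 1800.0
    q: float = 0.0145
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.n_az < 1:
            raise ValueError("n_az must be at least 1")
        if not (0.0 <= self.p_release <= 1.0):
            raise ValueError("p_release must lie in [0, 1]")
        for name in ("rrp0", "rp0", "reserve0", "rrp_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("k_clear", "k_refill", "k_reserve", "k_rest", "k_demob", "recycle_delay", "q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Wild type: fast AZ clearance, slow vesicle remobilisation (α-syn present).
WT_PRESET = PoolParams(k_clear=5.0, k_reserve=0.01, k_rest=2e-5, recycle_delay=1800.0)

#: Synuclein knockout: slow AZ clearance, fast remobilisation and recycling.
KO_PRESET = PoolParams(k_clear=0.5, k_reserve=0.002, k_rest=0.002, recycle_delay=90.0)


@dataclass
class PoolState:
    """Mutable pool inventory at time ``t`` (s).

    ``in_transit`` holds (return_time, count) pairs for released vesicles on
    their way back to the reserve.  Vesicle conservation holds exactly:
    rrp + rp + reserve + sum(in_transit counts) is invariant.
    """

    rrp: float
    rp: float
    reserve: float
    occupied_az: float = 0.0
    t: float = 0.0
    in_transit: deque = field(default_factory=deque)

    @classmethod
    def from_params(cls, params: PoolParams) -> "PoolState":
        return cls(rrp=params.rrp0, rp=params.rp0, reserve=params.reserve0)

    @property
    def total_vesicles(self) -> float:
        return self.rrp + self.rp + self.reserve + sum(n for _, n in self.in_transit)

    def copy(self) -> "PoolState":
        return PoolState(
            self.rrp, self.rp, self.reserve, self.occupied_az, self.t,
            deque(self.in_transit),
        )


def step(
    state: PoolState,
    params: PoolParams,
    dt: float,
    pulse: bool = False,
    calcium_gate: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[PoolState, float]:
    """Advance the pool state by ``dt`` seconds; returns (new state, released).

    If ``pulse`` is true a stimulus pulse fires at the start of the step.
    Relaxations use exact exponential factors, so the update is robust to
    the step size as long as pulses and gate changes fall on step edges.
    ``calcium_gate`` reflects activity-dependent calcium: refill flows run
    only while it is open.  With ``params.stochastic`` the fusion step draws
    binomial vesicle counts from ``rng``; all other flows stay mean-field.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.copy()
    released = 0.0

    if pulse:
        available = min(s.rrp, params.n_az - s.occupied_az)
        available = max(available, 0.0)
        if params.stochastic:
            if rng is None:
                raise ValueError("stochastic fusion requires an rng")
            released = float(rng.binomial(int(available), params.p_release))
        else:
            released = params.p_release * available
        s.rrp -= released
        s.occupied_az += released
        if released > 0:
            s.in_transit.append((s.t + params.recycle_delay, released))

    # membrane clearance from active zones
    s.occupied_az *= np.exp(-params.k_clear * dt)

    if calcium_gate:
        # reserve -> RP mobilisation
        mobilised = s.reserve * -np.expm1(-params.k_reserve * dt)
        s.reserve -= mobilised
        s.rp += mobilised
        # RP -> RRP docking, capped at the RRP capacity
        dock = min(s.rp * -np.expm1(-params.k_refill * dt), max(params.rrp_cap - s.rrp, 0.0))
        s.rp -= dock
        s.rrp += dock
    else:
        # unused mobilised vesicles re-sequester into the reserve
        demob = s.rp * -np.expm1(-params.k_demob * dt)
        s.rp -= demob
        s.reserve += demob

    if params.k_rest > 0:
        # constitutive re-docking straight from the reserve (KO phenotype)
        trickle = min(
            s.reserve * -np.expm1(-params.k_rest * dt),
            max(params.rrp_cap - s.rrp, 0.0),
        )
        s.reserve -= trickle
        s.rrp += trickle

    # recycled vesicles returning to the reserve
    s.t += dt
    while s.in_transit and s.in_transit[0][0] <= s.t:
        _, n = s.in_transit.popleft()
        s.reserve += n

    if min(s.rrp, s.rp, s.reserve) < -1e-9:
        raise RuntimeError("negative pool size: dt too large for the given rates")
    return s, released


@dataclass(frozen=True)
class ReleaseSimulation:
    """Per-pulse release plus bookkeeping of the driving protocol."""

    pulse_times: np.ndarray
    released: np.ndarray
    events: tuple  # burst records from plasticity.burst_onsets
    protocol: StimulusProtocol
    trajectory_t: np.ndarray
    trajectory: np.ndarray  # columns: rrp, rp, reserve, occupied_az

    def per_burst(self) -> list[dict]:
        """Summed release per burst, with sweep/role keys."""
        n = self.protocol.pulses_per_burst
        out = []
        for i, ev in enumerate(self.events):
            rel = float(self.released[i * n : (i + 1) * n].sum())
            out.append({**ev, "released": rel})
        return out

    def first_pulse_releases(self) -> np.ndarray:
        n = self.protocol.pulses_per_burst
        return self.released[:: n]


GATE_TAIL = 1.0  # s of calcium gating after each burst ends


def _gate_intervals(protocol: StimulusProtocol) -> list[tuple[float, float]]:
    dur = protocol.burst_duration
    iv = [(e["onset"], e["onset"] + dur + GATE_TAIL) for e in burst_onsets(protocol)]
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(iv):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def simulate_release(
    protocol: StimulusProtocol,
    params: PoolParams,
    dt: float = 0.001,
    quiet_dt: float = 0.25,
    seed: int | None = None,
) -> ReleaseSimulation:
    """Drive the pool model through a full stimulus protocol.

    Steps at ``dt`` inside gated (active) windows and coarsens to
    ``quiet_dt`` in the long rests, where the pools are frozen anyway; the
    exponential-exact relaxations make the result insensitive to both step
    sizes.  Deterministic unless ``params.stochastic``; then ``seed`` feeds
    the binomial fusion draws.
    """
    if dt <= 0 or quiet_dt <= 0:
        raise ValueError("step sizes must be positive")
    pulses = protocol_timeline(protocol)
    gates = _gate_intervals(protocol)
    events = tuple(burst_onsets(protocol))
    rng = np.random.default_rng(seed) if params.stochastic else None

    # breakpoints where stepping must land exactly
    horizon = float(gates[-1][1] + GATE_TAIL)
    marks = {0.0, horizon}
    marks.update(float(t) for t in pulses)
    for lo, hi in gates:
        marks.add(float(lo))
        marks.add(float(hi))
    marks = sorted(marks)

    def gated(t: float) -> bool:
        # half-open [lo, hi): the state during the step starting at t
        for lo, hi in gates:
            if lo <= t < hi:
                return True
            if lo > t:
                break
        return False

    state = PoolState.from_params(params)
    released = np.zeros(pulses.size)
    pulse_set = {round(float(t), 9): i for i, t in enumerate(pulses)}
    traj_t: list[float] = []
    traj: list[tuple[float, float, float, float]] = []

    def record() -> None:
        traj_t.append(state.t)
        traj.append((state.rrp, state.rp, state.reserve, state.occupied_az))

    record()
    for a, b in zip(marks[:-1], marks[1:]):
        span = b - a
        step_size = dt if gated(a) else min(quiet_dt, span)
        n_sub = max(1, int(round(span / step_size)))
        sub = span / n_sub
        t = a
        for k in range(n_sub):
            is_pulse = k == 0 and round(t, 9) in pulse_set
            state, rel = step(state, params, sub, pulse=is_pulse, calcium_gate=gated(t), rng=rng)
            if is_pulse:
                released[pulse_set[round(t, 9)]] = rel
            t = a + (k + 1) * sub
        record()

    return ReleaseSimulation(
        pulse_times=pulses,
        released=released,
        events=events,
        protocol=protocol,
        trajectory_t=np.asarray(traj_t),
        trajectory=np.asarray(traj),
    )


def simulate_single_burst(
    n_pulses: int,
    hz: float,
    params: PoolParams,
    dt: float = 0.001,
    seed: int | None = None,
) -> float:
    """Total release for one burst of ``n_pulses`` at ``hz`` from rest."""
    proto = StimulusProtocol(
        pulses_per_burst=n_pulses,
        intra_burst_hz=hz,
        bursts_per_train=1,
        single_to_train_gap=max(120.0, 2 * n_pulses / hz + 1),
        n_sweeps=1,
    )
    sim = simulate_release(proto, params, dt=dt, seed=seed)
    # the protocol opens with the "single" burst; use it alone
    n = proto.pulses_per_burst
    return float(sim.released[:n].sum())
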