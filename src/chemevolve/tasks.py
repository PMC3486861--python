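"""Classical-conditioning task protocols and the fitness function.

A *protocol* is one simulated lifetime: a time series of input boluses on
two channels plus a time series of target output values.  Channel "B"
carries the stimulus (conditioned stimulus S, delivered to the species at
io-list position 0) and channel "A" the control (unconditioned stimulus
C, io-list position 1).  Targets are (window, value, weight) triples;
times outside every window are "don't care" and excluded from scoring.

Five tasks of increasing difficulty are generated here.  In each, the
network lives in one of two (or, for the 2-bit task, four) environments
and must produce a high output-species concentration in the 20-time-unit
window after a stimulus pulse only in the environment where the stimulus
reliably predicts the control:

* ``clocked`` -- stimulus pulses on a 100-unit clock (probability 0.5 per
  tick); in the associated condition every stimulus is followed 20 units
  later by a control pulse, in the unassociated condition the control
  never occurs.
* ``noisy_clocked`` -- as above, but each stimulus tick independently has
  probability 0.1 of *flipping* its pairing (a control appears in the
  unassociated condition, or fails to appear in the associated one).
  Noise positions are matched between the paired conditions.
* ``nonclocked`` -- stimulus pulses at i.i.d. uniform[100, 300]
  intervals; associated: control follows each stimulus by 20 units;
  unassociated: control pulses arrive on an independent uniform[100, 300]
  renewal process, so both conditions see the same control rate.
* ``abba`` -- events (pulse pairs with 20-unit internal spacing) start at
  rate 0.025 per unit time with a 50-unit refractory period over a
  2000-unit horizon.  In the "S->C" condition 75% of events are
  stimulus-then-control and 25% the reverse; the "C->S" condition swaps
  the proportions.  The response target follows every stimulus pulse.
* ``twobit`` -- a hand-designed deterministic battery: 4 protocols (one
  per noise-pair type) x 4 conditions (typical-pair type) = 16 input
  series of pulse pairs every 100 units, probed twice; errors in the
  S-then-C condition are weighted three times as heavily.

Fitness is the negative weighted mean square difference between the
output-species concentration and the target, pooled over every in-window
integration step of every protocol; a diverged simulation scores -inf.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import kinetics
from .kinetics import Bolus, SimulationDiverged
from .network import Network

__all__ = [
    "TargetWindow",
    "ChannelBolus",
    "Protocol",
    "ProtocolSet",
    "gen_clocked",
    "gen_noisy_clocked",
    "gen_nonclocked",
    "gen_abba",
    "gen_2bit",
    "gen_protocols",
    "gen_environments",
    "resolve_boluses",
    "simulate_protocol",
    "fitness",
    "TASK_NAMES",
]

TASK_NAMES = ("clocked", "noisy_clocked", "nonclocked", "abba", "twobit")

#: Default bolus size in concentration units (a package choice, matching
#: the order of magnitude of the initial-concentration range).
DEFAULT_BOLUS_AMOUNT = 1.0

PAIR_DELAY = 20.0  # time units between the two pulses of a pair
RESPONSE_WINDOW = 20.0  # target window length after a stimulus pulse

#: Condition labels counted as "associated" (response target high).
ASSOCIATED_LABELS = frozenset({"associated", "S->C", "B->A"})


@dataclass(frozen=True)
class TargetWindow:
    """Desired output over the half-open window (start, end]."""

    start: float
    end: float
    value: float
    weight: float = 1.0


@dataclass(frozen=True)
class ChannelBolus:
    """An input bolus on channel "A" (control) or "B" (stimulus)."""

    time: float
    channel: str
    amount: float = DEFAULT_BOLUS_AMOUNT


@dataclass
class Protocol:
    """One input series (a single experimental condition of one draw)."""

    horizon: float
    boluses: list[ChannelBolus]
    targets: list[TargetWindow]
    condition: str
    pair_id: int = 0

    @property
    def is_associated(self) -> bool:
        return self.condition in ASSOCIATED_LABELS

    def channel_times(self, channel: str) -> np.ndarray:
        return np.array(sorted(b.time for b in self.boluses if b.channel == channel))

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "condition": self.condition,
            "pair_id": self.pair_id,
            "boluses": [
                {"t": b.time, "channel": b.channel, "amount": b.amount}
                for b in self.boluses
            ],
            "targets": [
                {"t0": w.start, "t1": w.end, "value": w.value, "weight": w.weight}
                for w in self.targets
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            horizon=float(d["horizon"]),
            condition=d["condition"],
            pair_id=int(d.get("pair_id", 0)),
            boluses=[
                ChannelBolus(time=float(b["t"]), channel=b["channel"], amount=float(b["amount"]))
                for b in d["boluses"]
            ],
            targets=[
                TargetWindow(
                    start=float(w["t0"]),
                    end=float(w["t1"]),
                    value=float(w["value"]),
                    weight=float(w["weight"]),
                )
                for w in d["targets"]
            ],
        )


@dataclass
class ProtocolSet:
    """A saved training or test set of protocols for one task."""

    task: str
    protocols: list[Protocol]
    seed: int | None = None

    def __iter__(self):
        return iter(self.protocols)

    def __len__(self):
        return len(self.protocols)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "seed": self.seed,
            "protocols": [p.to_dict() for p in self.protocols],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ProtocolSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            task=d["task"],
            seed=d.get("seed"),
            protocols=[Protocol.from_dict(p) for p in d["protocols"]],
        )


# ---------------------------------------------------------------------------
# generators


def _response_targets(
    b_times: Iterable[float], value: float, weight: float = 1.0
) -> list[TargetWindow]:
    return [
        TargetWindow(t, t + RESPONSE_WINDOW, value, weight) for t in sorted(b_times)
    ]


def gen_clocked(
    rng: np.random.Generator,
    n_protocols: int = 10,
    n_ticks: int = 10,
    tick_interval: float = 100.0,
    p_bolus: float = 0.5,
    bolus_amount: float = DEFAULT_BOLUS_AMOUNT,
) -> ProtocolSet:
    """Clocked task: stimulus on a regular clock, control 20 units later.

    Each draw produces a matched pair of conditions sharing identical
    stimulus (channel B) boluses.
    """
    protocols: list[Protocol] = []
    horizon = tick_interval * n_ticks + PAIR_DELAY
    for pid in range(n_protocols):
        ticks = tick_interval * (1 + np.arange(n_ticks))
        b_times = [float(t) for t in ticks if rng.random() < p_bolus]
        for condition in ("unassociated", "associated"):
            boluses = [ChannelBolus(t, "B", bolus_amount) for t in b_times]
            if condition == "associated":
                boluses += [
                    ChannelBolus(t + PAIR_DELAY, "A", bolus_amount) for t in b_times
                ]
            targets = _response_targets(
                b_times, 1.0 if condition == "associated" else 0.0
            )
            protocols.append(
                Protocol(horizon, sorted(boluses, key=lambda b: b.time), targets, condition, pid)
            )
    return ProtocolSet("clocked", protocols)


def gen_noisy_clocked(
    rng: np.random.Generator,
    n_protocols: int = 10,
    n_ticks: int = 10,
    tick_interval: float = 100.0,
    p_bolus: float = 0.5,
    p_noise: float = 0.1,
    bolus_amount: float = DEFAULT_BOLUS_AMOUNT,
) -> ProtocolSet:
    """Clocked task with pairing noise.

    With probability ``p_noise`` a stimulus tick flips its pairing: the
    control appears in the unassociated condition or is withheld in the
    associated one.  Flip positions are matched across the paired
    conditions, and the target still reflects the condition label.
    """
    protocols: list[Protocol] = []
    horizon = tick_interval * n_ticks + PAIR_DELAY
    for pid in range(n_protocols):
        ticks = tick_interval * (1 + np.arange(n_ticks))
        b_times = [float(t) for t in ticks if rng.random() < p_bolus]
        flipped = [rng.random() < p_noise for _ in b_times]
        for condition in ("unassociated", "associated"):
            paired = [
                f if condition == "unassociated" else not f for f in flipped
            ]
            boluses = [ChannelBolus(t, "B", bolus_amount) for t in b_times]
            boluses += [
                ChannelBolus(t + PAIR_DELAY, "A", bolus_amount)
                for t, a in zip(b_times, paired)
                if a
            ]
            targets = _response_targets(
                b_times, 1.0 if condition == "associated" else 0.0
            )
            protocols.append(
                Protocol(horizon, sorted(boluses, key=lambda b: b.time), targets, condition, pid)
            )
    return ProtocolSet("noisy_clocked", protocols)


def gen_nonclocked(
    rng: np.random.Generator,
    n_protocols: int = 10,
    n_events: int = 10,
    interval: tuple[float, float] = (100.0, 300.0),
    bolus_amount: float = DEFAULT_BOLUS_AMOUNT,
) -> ProtocolSet:
    """Non-clocked task: stimulus at uniform random renewal intervals.

    Both conditions see the same control-pulse rate; only the temporal
    relation to the stimulus differs.
    """
    lo, hi = interval
    protocols: list[Protocol] = []
    for pid in range(n_protocols):
        b_times = np.cumsum(rng.uniform(lo, hi, size=n_events))
        horizon = float(b_times[-1] + 2 * PAIR_DELAY)
        # independent control renewal process for the unassociated condition
        a_indep: list[float] = []
        t = float(rng.uniform(lo, hi))
        while t <= horizon:
            a_indep.append(t)
            t += float(rng.uniform(lo, hi))
        for condition in ("unassociated", "associated"):
            boluses = [ChannelBolus(float(t), "B", bolus_amount) for t in b_times]
            if condition == "associated":
                a_times = [float(t) + PAIR_DELAY for t in b_times]
            else:
                a_times = a_indep
            boluses += [ChannelBolus(t, "A", bolus_amount) for t in a_times]
            targets = _response_targets(
                b_times, 1.0 if condition == "associated" else 0.0
            )
            protocols.append(
                Protocol(horizon, sorted(boluses, key=lambda b: b.time), targets, condition, pid)
            )
    return ProtocolSet("nonclocked", protocols)


def gen_abba(
    rng: np.random.Generator,
    n_protocols: int = 10,
    horizon: float = 2000.0,
    event_rate: float = 0.025,
    refractory: float = 50.0,
    p_major: float = 0.75,
    bolus_amount: float = DEFAULT_BOLUS_AMOUNT,
    assess_after: float = 0.0,
) -> ProtocolSet:
    """Order-discrimination task: S->C pairs vs C->S pairs.

    Event start times (shared between the paired conditions) arise from a
    per-unit-time Bernoulli process at ``event_rate`` with a refractory
    gap; each event's orientation is drawn from a shared uniform variate
    so that minority ("noise") events fall in the same slots in the two
    conditions.  By default every stimulus pulse carries a response
    target; ``assess_after`` drops targets before that time, restricting
    assessment to the later part of the run once beliefs have formed.
    """
    protocols: list[Protocol] = []
    for pid in range(n_protocols):
        starts: list[float] = []
        t = 0.0
        while t < horizon - PAIR_DELAY:
            if (not starts or t - starts[-1] >= refractory) and rng.random() < event_rate:
                starts.append(t)
            t += 1.0
        orient = rng.random(len(starts))
        for condition in ("C->S", "S->C"):
            boluses: list[ChannelBolus] = []
            b_times: list[float] = []
            for t0, u in zip(starts, orient):
                # in the S->C condition the majority of events are B-then-A
                b_first = (u < p_major) == (condition == "S->C")
                first, second = ("B", "A") if b_first else ("A", "B")
                boluses.append(ChannelBolus(t0, first, bolus_amount))
                boluses.append(ChannelBolus(t0 + PAIR_DELAY, second, bolus_amount))
                b_times.append(t0 if b_first else t0 + PAIR_DELAY)
            scored = [t for t in b_times if t >= assess_after]
            targets = _response_targets(scored, 1.0 if condition == "S->C" else 0.0)
            protocols.append(
                Protocol(horizon, sorted(boluses, key=lambda b: b.time), targets, condition, pid)
            )
    return ProtocolSet("abba", protocols)


_PAIR_TYPES = ("A->A", "A->B", "B->A", "B->B")


def _pair_boluses(start: float, pair: str, amount: float) -> list[ChannelBolus]:
    first, second = pair.split("->")
    return [
        ChannelBolus(start, first, amount),
        ChannelBolus(start + PAIR_DELAY, second, amount),
    ]


def gen_2bit(bolus_amount: float = DEFAULT_BOLUS_AMOUNT) -> ProtocolSet:
    """Hand-designed exhaustive battery of four-environment protocols.

    4 protocols (one per noise-pair type) x 4 conditions (typical-pair
    type) = 16 deterministic input series.  Each series is
    [noise, typical x3, probe, noise, probe] with pairs every 100 units.
    The probe is stimulus-then-control in the "B->A" condition and
    stimulus-then-stimulus otherwise; targets require low output for the
    10 units before each probe and high (only in "B->A") or low output
    for the 20 units after it.  Errors in the "B->A" condition carry
    triple weight.
    """
    protocols: list[Protocol] = []
    starts = 100.0 * (1 + np.arange(7))
    horizon = float(starts[-1] + 3 * PAIR_DELAY)
    for noise_id, noise_pair in enumerate(_PAIR_TYPES):
        for condition in _PAIR_TYPES:
            probe = "B->A" if condition == "B->A" else "B->B"
            series = [noise_pair] + [condition] * 3 + [probe, noise_pair, probe]
            boluses: list[ChannelBolus] = []
            for t0, pair in zip(starts, series):
                boluses += _pair_boluses(float(t0), pair, bolus_amount)
            weight = 3.0 if condition == "B->A" else 1.0
            high = 1.0 if condition == "B->A" else 0.0
            targets: list[TargetWindow] = []
            for t0 in (float(starts[4]), float(starts[6])):  # probe positions
                targets.append(TargetWindow(t0 - 10.0, t0, 0.0, weight))
                targets.append(TargetWindow(t0, t0 + RESPONSE_WINDOW, high, weight))
            protocols.append(Protocol(horizon, boluses, targets, condition, noise_id))
    return ProtocolSet("twobit", protocols)


_GENERATORS: dict[str, Callable] = {
    "clocked": gen_clocked,
    "noisy_clocked": gen_noisy_clocked,
    "nonclocked": gen_nonclocked,
    "abba": gen_abba,
}


def gen_protocols(task: str, rng: np.random.Generator | None = None, **kwargs) -> ProtocolSet:
    """Dispatch to the generator for ``task`` (seeded by ``rng``)."""
    if task == "twobit":
        return gen_2bit(**kwargs)
    if task not in _GENERATORS:
        raise ValueError(f"unknown task {task!r}; choose from {TASK_NAMES}")
    if rng is None:
        raise ValueError(f"task {task!r} is stochastic and needs a generator")
    return _GENERATORS[task](rng, **kwargs)


def gen_environments(
    task: str, n_pairs: int, rng: np.random.Generator, **kwargs
) -> list[Protocol]:
    """Generate ``n_pairs`` matched condition pairs as a flat environment
    list (used for readout training/test sets)."""
    return list(gen_protocols(task, rng, n_protocols=n_pairs, **kwargs))


# ---------------------------------------------------------------------------
# simulation glue and fitness


def resolve_boluses(protocol: Protocol, net: Network) -> list[Bolus]:
    """Map channel labels to the network's input species."""
    roles = net.roles()
    channel_species = {"B": roles.stimulus, "A": roles.control}
    return [
        Bolus(b.time, channel_species[b.channel], b.amount) for b in protocol.boluses
    ]


def simulate_protocol(
    net: Network | kinetics.CompiledNetwork,
    protocol: Protocol,
    dt: float = kinetics.DEFAULT_DT,
    integrator: str = "euler",
    record_species: Sequence[str] | None = None,
    record_stride: int = 1,
    **kwargs,
) -> kinetics.Trajectory:
    cn = net if isinstance(net, kinetics.CompiledNetwork) else kinetics.CompiledNetwork(net)
    boluses = resolve_boluses(protocol, cn.net)
    if integrator == "euler":
        return kinetics.simulate_euler(
            cn,
            protocol.horizon,
            boluses,
            dt=dt,
            record_species=record_species,
            record_stride=record_stride,
            **kwargs,
        )
    if integrator == "rk":
        return kinetics.simulate_rk(
            cn,
            protocol.horizon,
            boluses,
            sample_dt=dt * record_stride,
            record_species=record_species,
            **kwargs,
        )
    raise ValueError(f"unknown integrator {integrator!r}")


def _window_error(
    output: np.ndarray, targets: Sequence[TargetWindow], dt: float
) -> tuple[float, float]:
    """Weighted squared error and total weight over in-window grid steps."""
    n_steps = len(output) - 1
    sq = 0.0
    wsum = 0.0
    for w in targets:
        i0 = int(math.floor(w.start / dt + 1e-9)) + 1
        i1 = min(int(math.floor(w.end / dt + 1e-9)), n_steps)
        if i1 < i0:
            continue
        seg = output[i0 : i1 + 1]
        sq += w.weight * float(np.sum((seg - w.value) ** 2))
        wsum += w.weight * len(seg)
    return sq, wsum


def fitness(
    net: Network,
    protocols: ProtocolSet | Sequence[Protocol],
    dt: float = kinetics.DEFAULT_DT,
) -> float:
    """Negative weighted mean square output error, pooled over protocols.

    A perfect output scores 0; a diverged simulation scores -inf.
    """
    cn = kinetics.CompiledNetwork(net)
    out_species = cn.net.roles().output
    total_sq = 0.0
    total_w = 0.0
    for protocol in protocols:
        try:
            traj = simulate_protocol(
                cn, protocol, dt=dt, record_species=[out_species]
            )
        except SimulationDiverged:
            return -math.inf
        sq, wsum = _window_error(traj.data[:, 0], protocol.targets, dt)
        total_sq += sq
        total_w += wsum
    if total_w == 0:
        return 0.0
    return -total_sq / total_w
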