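"""Ideal iterated Bayesian posteriors and the logistic belief readout.

For the tasks whose input trains decompose into discrete events (the
noisy clocked task and the order-discrimination "abba" task), an ideal
observer's belief about which environment it is in depends only on the
counts of "associated" and "unassociated" events seen so far.  With
event probabilities p1 (associated environment) and p0 (unassociated)
and prior pi, after n associated and m unassociated events

    P(X = 1 | n, m) = pi p1^n (1-p1)^m /
                      [pi p1^n (1-p1)^m + (1-pi) p0^n (1-p0)^m]

computed in log space.  The posterior is attached to the concentration
time series as a right-continuous step function that updates at each
event's completion time.

To ask how transparently a network's state encodes this belief, a
logistic readout f(x) = 1 / (1 + exp(-(w.x + b))) of the concentration
vector is fitted by (unregularised) least squares against the ideal
posterior over many training environments, and scored by the Pearson
correlation between readout and posterior pooled over all evaluated
time points of fresh test environments.  Randomly constituted networks
provide the reservoir-computing baseline for that score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from . import kinetics, tasks
from .kinetics import SimulationDiverged
from .network import Network

__all__ = [
    "BayesTaskModel",
    "Event",
    "BeliefModel",
    "extract_events",
    "posterior",
    "posterior_on_grid",
    "fit_readout",
    "fit_network_readout",
    "belief_correlation",
    "random_network_baseline",
]


@dataclass(frozen=True)
class BayesTaskModel:
    """Event statistics of a two-environment task.

    ``p1``/``p0`` are the probabilities of an *associated* event in the
    associated / unassociated environment; the prior is the proportion of
    associated environments in the training sets.
    """

    task: str
    p1: float
    p0: float
    prior: float = 0.5
    pair_delay: float = tasks.PAIR_DELAY

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < self.p1 < 1.0:
            raise ValueError("need 0 < p0 < p1 < 1")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")

    @classmethod
    def noisy_clocked(cls) -> "BayesTaskModel":
        # pairing flips with probability 0.1 per stimulus tick
        return cls(task="noisy_clocked", p1=0.9, p0=0.1)

    @classmethod
    def abba(cls) -> "BayesTaskModel":
        # 75% majority-order events per condition
        return cls(task="abba", p1=0.75, p0=0.25)

    @classmethod
    def for_task(cls, task: str) -> "BayesTaskModel":
        if task == "noisy_clocked":
            return cls.noisy_clocked()
        if task == "abba":
            return cls.abba()
        raise ValueError(f"no event model for task {task!r}")


@dataclass(frozen=True)
class Event:
    """One discrete input event with its completion time."""

    time: float  # completion time (second pulse or pairing-window expiry)
    associated: bool


def extract_events(protocol: tasks.Protocol, model: BayesTaskModel) -> list[Event]:
    """Reduce an input train to its sequence of discrete events.

    Noisy clocked: every stimulus (B) bolus is an event, associated iff a
    control (A) bolus follows within the pairing window; the event
    completes when the pairing resolves (at B-time + pair delay).
    Order-discrimination: every pulse pair is an event, associated iff
    the stimulus precedes the control; the event completes at the second
    pulse.
    """
    eps = 1e-9
    if model.task == "noisy_clocked":
        a_times = protocol.channel_times("A")
        events = []
        for tb in protocol.channel_times("B"):
            paired = bool(
                np.any((a_times > tb + eps) & (a_times <= tb + model.pair_delay + eps))
            )
            events.append(Event(time=tb + model.pair_delay, associated=paired))
        return events
    if model.task == "abba":
        bs = sorted(protocol.boluses, key=lambda b: b.time)
        events = []
        i = 0
        while i < len(bs):
            if (
                i + 1 < len(bs)
                and bs[i + 1].time - bs[i].time <= model.pair_delay + eps
            ):
                first, second = bs[i], bs[i + 1]
                events.append(
                    Event(
                        time=second.time,
                        associated=(first.channel == "B" and second.channel == "A"),
                    )
                )
                i += 2
            else:  # unpaired pulse: ignore (carries no order information)
                i += 1
        return events
    raise ValueError(f"no event model for task {model.task!r}")


def posterior(n: int, m: int, model: BayesTaskModel) -> float:
    """P(associated environment | n associated, m unassociated events)."""
    if n < 0 or m < 0:
        raise ValueError("event counts must be non-negative")
    log1 = math.log(model.prior) + n * math.log(model.p1) + m * math.log1p(-model.p1)
    log0 = (
        math.log1p(-model.prior) + n * math.log(model.p0) + m * math.log1p(-model.p0)
    )
    return float(expit(log1 - log0))


def event_posterior_series(
    protocol: tasks.Protocol, model: BayesTaskModel
) -> tuple[np.ndarray, np.ndarray]:
    """(completion times, posterior after each event), cumulative."""
    events = extract_events(protocol, model)
    times = np.array([e.time for e in events])
    post = np.empty(len(events))
    n = m = 0
    for i, e in enumerate(events):
        if e.associated:
            n += 1
        else:
            m += 1
        post[i] = posterior(n, m, model)
    return times, post


def posterior_on_grid(
    grid: np.ndarray, event_times: np.ndarray, post: np.ndarray, prior: float
) -> np.ndarray:
    """Right-continuous step-function evaluation of the posterior."""
    idx = np.searchsorted(event_times, grid, side="right")
    values = np.concatenate([[prior], post])
    return values[idx]


@dataclass
class BeliefModel:
    """Fitted logistic readout: weights keyed by species formula + bias."""

    weights: dict[str, float]
    bias: float
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = list(self.weights)

    def predict(self, data: np.ndarray, species: Sequence[str]) -> np.ndarray:
        w = np.array([self.weights.get(f, 0.0) for f in species])
        return expit(data @ w + self.bias)

    def to_dict(self) -> dict:
        return {"weights": self.weights, "bias": self.bias}


def fit_readout(
    features: np.ndarray,
    targets: np.ndarray,
    species: Sequence[str],
    max_nfev: int = 200,
) -> BeliefModel:
    """Least-squares logistic fit (Levenberg-Marquardt, no regularisation).

    ``features`` is the stacked concentration matrix over all evaluated
    time points of all training environments; ``targets`` the aligned
    ideal posterior values.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features and targets must align")
    n_feat = X.shape[1]

    def resid(params):
        return expit(X @ params[:-1] + params[-1]) - y

    def jac(params):
        f = expit(X @ params[:-1] + params[-1])
        d = (f * (1.0 - f))[:, None]
        return np.hstack([X * d, d])

    res = least_squares(
        resid, np.zeros(n_feat + 1), jac=jac, method="lm", max_nfev=max_nfev
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"readout fit failed: {res.message}")
    weights = {f: float(w) for f, w in zip(species, res.x[:-1])}
    return BeliefModel(weights=weights, bias=float(res.x[-1]), species=list(species))


def _env_series(
    cn: kinetics.CompiledNetwork,
    protocol: tasks.Protocol,
    model: BayesTaskModel,
    dt: float,
    record_stride: int,
):
    """(concentration matrix, posterior values) over post-first-event
    grid points of one environment."""
    traj = tasks.simulate_protocol(
        cn, protocol, dt=dt, record_stride=record_stride
    )
    ev_times, ev_post = event_posterior_series(protocol, model)
    if len(ev_times) == 0:
        return None
    mask = traj.times >= ev_times[0]
    post = posterior_on_grid(traj.times[mask], ev_times, ev_post, model.prior)
    return traj.data[mask], post


def fit_network_readout(
    net: Network,
    model: BayesTaskModel,
    rng: np.random.Generator,
    n_train_envs: int = 200,
    dt: float = kinetics.DEFAULT_DT,
    record_stride: int = 10,
    fit_stride: int = 10,
    train_envs: Sequence[tasks.Protocol] | None = None,
) -> BeliefModel:
    """Generate training environments, simulate, and fit the readout.

    ``n_train_envs`` environments (half associated, half unassociated)
    are drawn unless ``train_envs`` is supplied.  ``record_stride``
    subsamples the dt grid for the stored series and ``fit_stride``
    further subsamples the rows entering the least-squares fit.
    """
    if train_envs is None:
        train_envs = tasks.gen_environments(model.task, n_train_envs // 2, rng)
    cn = kinetics.CompiledNetwork(net)
    rows = []
    vals = []
    for protocol in train_envs:
        series = _env_series(cn, protocol, model, dt, record_stride)
        if series is None:
            continue
        X, post = series
        rows.append(X[::fit_stride])
        vals.append(post[::fit_stride])
    if not rows:
        raise ValueError("no events in any training environment")
    return fit_readout(np.vstack(rows), np.concatenate(vals), cn.names)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 for degenerate (constant) series."""
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def belief_correlation(
    model: BeliefModel,
    net: Network,
    task_model: BayesTaskModel,
    rng: np.random.Generator | None = None,
    n_test_envs: int = 30,
    test_envs: Sequence[tasks.Protocol] | None = None,
    dt: float = kinetics.DEFAULT_DT,
    record_stride: int = 10,
) -> tuple[float, np.ndarray]:
    """Correlation between the fitted readout and the ideal posterior on
    fresh test environments.

    Returns the Pearson correlation pooled over every evaluated time
    point of every test environment (the network's score), together with
    the per-environment correlations for boxplots.  The pooled value is
    the package's headline statistic: within a single environment the
    posterior is nearly a step function, so the informative variation --
    whether the state separates the environments -- lives *between*
    environments, which only the pooled correlation captures.
    """
    if test_envs is None:
        if rng is None:
            raise ValueError("need rng or explicit test environments")
        test_envs = tasks.gen_environments(task_model.task, n_test_envs // 2, rng)
    cn = kinetics.CompiledNetwork(net)
    cors = []
    all_readout = []
    all_post = []
    for protocol in test_envs:
        series = _env_series(cn, protocol, task_model, dt, record_stride)
        if series is None:
            continue
        X, post = series
        readout = model.predict(X, cn.names)
        cors.append(_pearson(readout, post))
        all_readout.append(readout)
        all_post.append(post)
    pooled = _pearson(np.concatenate(all_readout), np.concatenate(all_post))
    return pooled, np.array(cors)


def random_network_baseline(
    task_model: BayesTaskModel,
    rules,
    rng: np.random.Generator,
    n_networks: int = 200,
    n_mutations: int = 200,
    sigma: float = 0.03,
    n_train_envs: int = 200,
    n_test_envs: int = 30,
    dt: float = kinetics.DEFAULT_DT,
    record_stride: int = 10,
    fit_stride: int = 10,
    max_attempts_factor: int = 3,
) -> dict:
    """Readout/posterior correlation distribution for random networks.

    Each network is a random initialisation followed by ``n_mutations``
    mutations; a readout is fitted on shared training environments and
    scored on shared test environments.  Networks that diverge on any
    environment are recorded as failed and replaced (up to a cap) so the
    distribution reaches the requested size.
    """
    from .evolution import init_network, mutate

    train_envs = tasks.gen_environments(task_model.task, max(1, n_train_envs // 2), rng)
    test_envs = tasks.gen_environments(task_model.task, max(1, n_test_envs // 2), rng)
    means = []
    n_failed = 0
    attempts = 0
    max_attempts = max_attempts_factor * n_networks
    while len(means) < n_networks and attempts < max_attempts:
        attempts += 1
        net = init_network(rules, rng)
        for _ in range(n_mutations):
            net = mutate(net, sigma, rng)
        try:
            readout = fit_network_readout(
                net,
                task_model,
                rng,
                dt=dt,
                record_stride=record_stride,
                fit_stride=fit_stride,
                train_envs=train_envs,
            )
            mean_cor, _ = belief_correlation(
                readout, net, task_model, test_envs=test_envs, dt=dt,
                record_stride=record_stride,
            )
        except (SimulationDiverged, RuntimeError):
            n_failed += 1
            continue
        means.append(mean_cor)
    return {
        "correlations": np.array(means),
        "mean": float(np.mean(means)) if means else math.nan,
        "n_networks": len(means),
        "n_failed": n_failed,
    }
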