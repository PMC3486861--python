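"""Post-evolution interpretation: pruning, perturbations, statistics.

Evolved genotypes usually carry many reactions that contribute little.
Greedy backward elimination (:func:`prune`) repeatedly removes the single
reaction whose deletion harms the score least, as long as the pruned
network's mean square error stays within a tolerance (default 10%) of
the full network's; what survives is the core learning motif.

:func:`perturb_experiment` runs the matched manipulation experiments used
to test mechanistic hypotheses: transiently change one species' decay or
inflow rate and compare the output trajectory with the unperturbed
baseline on the same protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, median
from typing import Sequence

import numpy as np

from . import tasks
from .network import PARAM_RANGES, Network, NetworkError, Reaction

__all__ = ["PruneResult", "prune", "perturb_experiment", "reaction_stats"]


@dataclass
class PruneResult:
    core: Network
    removed: list[Reaction]
    full_fitness: float
    core_fitness: float
    tolerance: float

    @property
    def n_core_reactions(self) -> int:
        return len(self.core.reactions)

    def report(self) -> str:
        lines = [
            f"full network : {len(self.core.reactions) + len(self.removed)} reactions,"
            f" fitness {self.full_fitness:.5f}",
            f"pruned core  : {len(self.core.reactions)} reactions,"
            f" fitness {self.core_fitness:.5f} (tolerance {self.tolerance:.0%})",
            "core reactions:",
        ]
        lines += [f"  {r.format()}" for r in self.core.reactions]
        return "\n".join(lines)


def _drop_orphans(net: Network) -> Network:
    """Remove species with no reactions, keeping the four role species."""
    used = set()
    for rxn in net.reactions:
        used.update(rxn.lhs)
        used.update(rxn.rhs)
    keep = used | set(net.io_list[:4])
    out = net.copy()
    out.species = {f: s for f, s in out.species.items() if f in keep}
    out.io_list = [f for f in out.io_list if f in keep]
    return out


def prune(
    net: Network,
    protocols: tasks.ProtocolSet | Sequence[tasks.Protocol],
    tolerance: float = 0.10,
    dt: float = 0.01,
) -> PruneResult:
    """Greedy backward elimination of reactions.

    Each round re-evaluates every single-reaction deletion and removes
    the least harmful one (ties broken by lowest reaction index), while
    the pruned mean square error stays within ``(1 + tolerance)`` times
    the full network's MSE.  Deterministic for a fixed protocol set.
    """
    full_fitness = tasks.fitness(net, protocols, dt=dt)
    if not math.isfinite(full_fitness):
        raise ValueError("cannot prune a network that diverges on the protocols")
    budget = (1.0 + tolerance) * abs(full_fitness)
    current = net.copy()
    current_fitness = full_fitness
    removed: list[Reaction] = []
    while current.reactions:
        best_idx = None
        best_fit = -math.inf
        for idx in range(len(current.reactions)):
            trial = current.copy()
            del trial.reactions[idx]
            f = tasks.fitness(trial, protocols, dt=dt)
            if f > best_fit:
                best_fit = f
                best_idx = idx
        if best_idx is None or abs(best_fit) > budget:
            break
        removed.append(current.reactions[best_idx])
        del current.reactions[best_idx]
        current_fitness = best_fit
    return PruneResult(
        core=_drop_orphans(current),
        removed=removed,
        full_fitness=full_fitness,
        core_fitness=current_fitness,
        tolerance=tolerance,
    )


def perturb_experiment(
    net: Network,
    species: str,
    knob: str,
    value: float,
    protocols: tasks.ProtocolSet | Sequence[tasks.Protocol],
    dt: float = 0.01,
    record_species: Sequence[str] | None = None,
    record_stride: int = 1,
):
    """Baseline-vs-perturbed trajectories on matched protocols.

    ``knob`` is ``"decay"`` or ``"inflow"``; the perturbation is an
    experiment on a copy, not a mutation, so the genotype is unchanged.
    Setting a non-food species' inflow temporarily promotes it to the
    food role (inflow is only active for the food species).
    """
    if species not in net.species:
        raise NetworkError(f"unknown species {species!r}")
    param = {"decay": "decay_rate", "inflow": "food_inflow"}.get(knob)
    if param is None:
        raise ValueError("knob must be 'decay' or 'inflow'")
    lo, hi = PARAM_RANGES[param]
    if not lo <= value <= hi:
        raise NetworkError(f"{knob}={value} outside allowable range [{lo}, {hi}]")
    perturbed = net.copy()
    setattr(perturbed.species[species], param, value)
    if knob == "inflow" and perturbed.roles().food != species:
        io = perturbed.io_list
        idx = io.index(species)
        io[3], io[idx] = io[idx], io[3]
    pairs = []
    for protocol in protocols:
        base = tasks.simulate_protocol(
            net, protocol, dt=dt, record_species=record_species, record_stride=record_stride
        )
        pert = tasks.simulate_protocol(
            perturbed, protocol, dt=dt, record_species=record_species, record_stride=record_stride
        )
        pairs.append((base, pert))
    return pairs


def reaction_stats(
    nets: Sequence[Network], cores: Sequence[PruneResult] = ()
) -> dict:
    """Mean/median reaction counts for full (and pruned) networks, plus
    the connection-density distribution."""
    if not nets:
        raise ValueError("need at least one network")
    full_counts = [len(n.reactions) for n in nets]
    densities = []
    for n in nets:
        try:
            densities.append(n.connection_density())
        except NetworkError:
            pass
    out = {
        "n_networks": len(nets),
        "full_reactions_mean": mean(full_counts),
        "full_reactions_median": median(full_counts),
        "connection_density": densities,
    }
    if cores:
        core_counts = [len(c.core.reactions) for c in cores]
        out["core_reactions_mean"] = mean(core_counts)
        out["core_reactions_median"] = median(core_counts)
    return out
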