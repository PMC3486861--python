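"""Network initialisation, mutation, and the steady-state microbial GA.

The genetic algorithm is non-generational: each iteration picks two
distinct members of the population (uniformly, or adjacent on a ring in
spatial mode), evaluates both on the same fixed protocol set, and
overwrites the loser with a mutated copy of the winner.  Fitness
evaluations are cached per individual because the training protocols are
fixed for the whole run.

Mutation of a genotype with rate ``sigma``:

* every real parameter (species potentials, initial concentrations,
  decay rates, inflows; reaction favoured-rate constants) is perturbed
  by Gaussian noise with s.d. ``sigma`` times the width of its allowable
  range, reflected back into the range at the bounds;
* with probability ``5 * sigma`` a random new reaction is added;
* with probability ``5 * sigma`` a uniformly chosen reaction is deleted
  (species are never deleted, so orphans can persist);
* with probability ``sigma`` two entries of the input/output role list
  are swapped.

New reactions are built from the current chemistry: decompose one
existing species, compose two, or rearrange two (composition followed by
decomposition).  A single-atom species cannot decompose (no reaction is
added), and a composition that would exceed the maximum formula length
falls back to a rearrangement.  Product formulas not already in the
network spawn new species with uniformly initialised parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import chemistry, tasks
from .chemistry import ChemistryRules, FormulaTooLongError, IndivisibleFormulaError
from .network import INIT_RANGES, PARAM_RANGES, Network, Reaction, SpeciesSpec

__all__ = [
    "GAConfig",
    "GAResult",
    "init_network",
    "add_random_reaction",
    "mutate",
    "microbial_ga",
]

N_SEED_SPECIES = 4
SEED_FORMULA_LENGTH = 3
N_INIT_REACTION_CALLS = 20


@dataclass
class GAConfig:
    """Steady-state GA settings.

    Population size, iteration count and sigma are package defaults (the
    source experiments do not print them); see the methods note.
    """

    population_size: int = 30
    iterations: int = 20_000
    sigma: float = 0.03
    spatial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.sigma < 1.0:
            raise ValueError("sigma must be in (0, 1)")


def _uniform_species(formula: str, rng: np.random.Generator) -> SpeciesSpec:
    def draw(name: str) -> float:
        lo, hi = INIT_RANGES[name]
        return float(rng.uniform(lo, hi))

    return SpeciesSpec(
        formula=formula,
        potential=draw("potential"),
        initial_concentration=draw("initial_concentration"),
        decay_rate=draw("decay_rate"),
        food_inflow=draw("food_inflow"),
    )


def _add_species(net: Network, formula: str, rng: np.random.Generator) -> None:
    if formula not in net.species:
        net.species[formula] = _uniform_species(formula, rng)
        net.io_list.append(formula)


def add_random_reaction(
    net: Network, rng: np.random.Generator
) -> bool:
    """Attempt to add one random mass-conserving reaction in place.

    Returns True if a reaction was added (a decomposition of a
    single-atom species adds nothing).
    """
    rules = net.rules
    formulas = list(net.species)
    kind = int(rng.integers(3))
    if kind == 0:  # decompose one species
        src = formulas[int(rng.integers(len(formulas)))]
        try:
            products = chemistry.decompose(src, rules, rng)
        except IndivisibleFormulaError:
            return False
        lhs, rhs = (src,), products
    else:
        a = formulas[int(rng.integers(len(formulas)))]
        b = formulas[int(rng.integers(len(formulas)))]
        if kind == 1:  # compose two species, fall back to rearrangement
            try:
                product = chemistry.compose(a, b, rules, rng)
                lhs, rhs = (a, b), (product,)
            except FormulaTooLongError:
                lhs, rhs = (a, b), chemistry.rearrange(a, b, rules, rng)
        else:  # rearrange two species
            lhs, rhs = (a, b), chemistry.rearrange(a, b, rules, rng)
    for f in rhs:
        _add_species(net, f, rng)
    lo, hi = INIT_RANGES["k_fav"]
    net.reactions.append(Reaction(lhs=lhs, rhs=rhs, k_fav=float(rng.uniform(lo, hi))))
    return True


def init_network(rules: ChemistryRules, rng: np.random.Generator) -> Network:
    """Random genotype: 4 distinct length-3 seed species, 20 reaction-add
    attempts, fairly shuffled io list."""
    seeds = chemistry.all_canonical_formulas(rules, SEED_FORMULA_LENGTH)
    if len(seeds) < N_SEED_SPECIES:
        raise ValueError("alphabet admits fewer than 4 distinct length-3 formulas")
    if len(seeds) > N_SEED_SPECIES:
        idx = rng.choice(len(seeds), size=N_SEED_SPECIES, replace=False)
        seeds = [seeds[i] for i in sorted(idx)]
    net = Network(rules=rules, species={}, reactions=[], io_list=[])
    for f in seeds:
        _add_species(net, f, rng)
    for _ in range(N_INIT_REACTION_CALLS):
        add_random_reaction(net, rng)
    perm = rng.permutation(len(net.io_list))
    net.io_list = [net.io_list[i] for i in perm]
    return net


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a value back into [lo, hi] by reflection at the bounds."""
    width = hi - lo
    if width <= 0:
        return lo
    v = (v - lo) % (2.0 * width)
    if v > width:
        v = 2.0 * width - v
    return v + lo


def mutate(net: Network, sigma: float, rng: np.random.Generator) -> Network:
    """Return a mutated copy of ``net`` (the original is untouched)."""
    if not 0.0 < sigma < 1.0:
        raise ValueError("sigma must be in (0, 1)")
    out = net.copy()
    for spec in out.species.values():
        for name in ("potential", "initial_concentration", "decay_rate", "food_inflow"):
            lo, hi = PARAM_RANGES[name]
            v = getattr(spec, name) + rng.normal(0.0, sigma * (hi - lo))
            setattr(spec, name, _reflect(v, lo, hi))
    lo, hi = PARAM_RANGES["k_fav"]
    for rxn in out.reactions:
        rxn.k_fav = _reflect(rxn.k_fav + rng.normal(0.0, sigma * (hi - lo)), lo, hi)
    if rng.random() < 5.0 * sigma:
        add_random_reaction(out, rng)
    if rng.random() < 5.0 * sigma and out.reactions:
        del out.reactions[int(rng.integers(len(out.reactions)))]
    if rng.random() < sigma and len(out.io_list) >= 2:
        i, j = rng.choice(len(out.io_list), size=2, replace=False)
        out.io_list[i], out.io_list[j] = out.io_list[j], out.io_list[i]
    return out


@dataclass
class GAResult:
    best_network: Network
    best_fitness: float
    trace: np.ndarray  # running best evaluated fitness per iteration
    population: list[Network] = field(repr=False, default_factory=list)
    initial_best: float = math.nan


def microbial_ga(
    protocols: tasks.ProtocolSet | Sequence[tasks.Protocol],
    rules: ChemistryRules,
    cfg: GAConfig,
    fitness_fn: Callable[[Network], float] | None = None,
    dt: float = 0.01,
    log_every: int = 0,
) -> GAResult:
    """Run the steady-state microbial GA on a fixed protocol set.

    Fully reproducible from ``cfg.seed``; the trace records the best
    fitness evaluated so far at every iteration.
    """
    if fitness_fn is None:
        fitness_fn = lambda net: tasks.fitness(net, protocols, dt=dt)
    rng = np.random.default_rng(cfg.seed)
    pop = [init_network(rules, rng) for _ in range(cfg.population_size)]
    fit: list[float | None] = [None] * cfg.population_size

    def evaluate(i: int) -> float:
        if fit[i] is None:
            fit[i] = fitness_fn(pop[i])
        return fit[i]

    # initial best over the starting population (evaluated lazily below,
    # but the smoke benchmark needs a baseline)
    initial_best = max(evaluate(i) for i in range(cfg.population_size))
    best = initial_best
    trace = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        if cfg.spatial:
            i = int(rng.integers(cfg.population_size))
            j = (i + 1) % cfg.population_size
        else:
            i, j = (int(x) for x in rng.choice(cfg.population_size, size=2, replace=False))
        fi, fj = evaluate(i), evaluate(j)
        winner, loser = (i, j) if fi >= fj else (j, i)
        pop[loser] = mutate(pop[winner], cfg.sigma, rng)
        fit[loser] = None
        f_new = evaluate(loser)
        best = max(best, fi, fj, f_new)
        trace[it] = best
        if log_every and (it + 1) % log_every == 0:
            print(f"iter {it + 1}: best fitness {best:.5f}")
    evaluated = [(f, i) for i, f in enumerate(fit) if f is not None]
    best_f, best_i = max(evaluated)
    return GAResult(
        best_network=pop[best_i],
        best_fitness=best_f,
        trace=trace,
        population=pop,
        initial_best=initial_best,
    )
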