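"""Hand-built reference networks implementing the core learning motifs.

These genotypes are *reconstructions*: synthetic networks written by hand
to implement the recurring associative-learning motifs that evolution
discovers, with kinetic parameters chosen by the package authors so the
documented mechanism narrative holds (slow long-term memory decay, fast
short-term memory / control decay).  They are regression anchors for the
pruning and Bayesian analyses, not evolved genotypes.

All fixtures use the binary aggregation chemistry with maximum formula
length 4 and follow the species-label conventions of the analysed
networks: ``001`` is the long-term memory (LTM), ``0001`` the short-term
memory (STM) and ``11`` the output.
"""

from __future__ import annotations

from .chemistry import ChemistryRules
from .network import Network, Reaction, SpeciesSpec

__all__ = [
    "AGG_RULES",
    "abba_reference_network",
    "memory_readout_motif",
    "decoupled_memory_motif",
    "coincidence_motif",
    "make_fixtures",
]

AGG_RULES = ChemistryRules(kind="aggregation", alphabet_size=2, max_length=4)


def _net(species: list[SpeciesSpec], reactions: list[Reaction], io_list: list[str]) -> Network:
    net = Network(
        rules=AGG_RULES,
        species={s.formula: s for s in species},
        reactions=reactions,
        io_list=io_list,
    )
    net.validate()
    return net


def abba_reference_network() -> Network:
    """Synthetic four-reaction network for the order-discrimination task.

    Mechanism (S = stimulus ``011``, C = control ``01``, O = output
    ``11``, LTM ``001``, STM ``0001``):

    1. ``S + LTM <-> O + STM``  -- stimulus converts the slowly decaying
       long-term memory into output plus a faster-decaying short-term
       memory, so output follows the stimulus only while LTM is present.
    2. ``C + STM <-> LTM + LTM`` -- a control pulse arriving while STM
       persists (i.e. shortly *after* a stimulus) regenerates the
       long-term memory for the next event.
    3. ``C <-> 0 + 1``          -- with no STM to react with (control
       *before* stimulus), the control disintegrates instead.
    4. ``1 + O <-> 111``        -- the disintegration product scavenges
       any output, suppressing the response in the control-first
       environment.

    In the S->C environment LTM is recycled and output is sustained; in
    the C->S environment LTM is never regenerated and the scavenger
    removes what little output is made.
    """
    species = [
        #            formula  potential  init   decay  inflow
        SpeciesSpec("011", 5.0, 0.0, 0.20, 0.0),   # stimulus S
        SpeciesSpec("01", 7.0, 0.0, 0.10, 0.0),    # control C
        SpeciesSpec("11", 0.5, 0.0, 0.05, 0.0),    # output O
        SpeciesSpec("001", 2.0, 0.3, 0.002, 0.003),  # LTM (food, low inflow)
        SpeciesSpec("0001", 3.0, 0.0, 0.02, 0.0),  # STM
        SpeciesSpec("0", 1.0, 0.0, 0.10, 0.0),     # disintegration product
        SpeciesSpec("1", 1.5, 0.0, 0.03, 0.0),     # output scavenger
        SpeciesSpec("111", 0.2, 0.0, 0.30, 0.0),   # scavenged waste
    ]
    reactions = [
        Reaction(("011", "001"), ("11", "0001"), 1.0),
        Reaction(("01", "0001"), ("001", "001"), 1.0),
        Reaction(("01",), ("0", "1"), 0.2),
        Reaction(("1", "11"), ("111",), 1.0),
    ]
    io_list = ["011", "01", "11", "001", "0001", "0", "1", "111"]
    return _net(species, reactions, io_list)


def memory_readout_motif() -> Network:
    """Single reversible readout reaction plus memory regeneration.

    ``S + M <-> O``: stimulus and a slow-decaying memory molecule
    reversibly form the output; ``C + O <-> M + waste``: the control
    regenerates the memory for reuse.  The output's decay is tied to the
    motif's reversibility, which the decoupled variant improves on.
    """
    species = [
        SpeciesSpec("0", 1.5, 0.0, 0.20, 0.0),     # stimulus
        SpeciesSpec("1", 3.0, 0.0, 0.20, 0.0),     # control
        SpeciesSpec("0001", 2.0, 0.0, 0.08, 0.0),  # output
        SpeciesSpec("001", 1.5, 1.0, 0.005, 0.002),  # memory (food)
        SpeciesSpec("01", 1.0, 0.0, 0.10, 0.0),    # waste
    ]
    reactions = [
        Reaction(("0", "001"), ("0001",), 0.6),
        Reaction(("1", "0001"), ("001", "01"), 0.6),
    ]
    return _net(species, reactions, ["0", "1", "0001", "001", "01"])


def decoupled_memory_motif() -> Network:
    """Two nearly irreversible reactions decoupling output from memory.

    ``S + LTM -> O + STM`` and ``C + STM -> LTM + LTM`` with large
    potential drops, so the output's decay rate is independent of the
    short-term memory's and the control is decoupled from the output.
    """
    species = [
        SpeciesSpec("011", 4.0, 0.0, 0.20, 0.0),   # stimulus
        SpeciesSpec("01", 7.5, 0.0, 0.10, 0.0),    # control
        SpeciesSpec("11", 1.0, 0.0, 0.10, 0.0),    # output
        SpeciesSpec("001", 1.5, 1.0, 0.002, 0.005),  # LTM (food)
        SpeciesSpec("0001", 1.0, 0.0, 0.05, 0.0),  # STM
    ]
    reactions = [
        Reaction(("011", "001"), ("11", "0001"), 0.8),
        Reaction(("01", "0001"), ("001", "001"), 0.8),
    ]
    return _net(species, reactions, ["011", "01", "11", "001", "0001"])


def coincidence_motif() -> Network:
    """Stimulus/control co-occurrence initialises the long-term memory.

    ``S + C <-> LTM``: because the control decays quickly and the
    stimulus slowly, the two only co-occur when the control follows the
    stimulus -- a chemical coincidence detector.  A second reaction reads
    the memory out: stimulus plus memory yield output (and a fast-decaying
    byproduct).
    """
    species = [
        SpeciesSpec("011", 2.0, 0.0, 0.02, 0.0),   # stimulus (slow decay)
        SpeciesSpec("1", 3.0, 0.0, 0.50, 0.0),     # control (fast decay)
        SpeciesSpec("0011", 1.0, 0.0, 0.10, 0.0),  # output
        SpeciesSpec("0111", 1.5, 0.0, 0.005, 0.002),  # LTM (food)
        SpeciesSpec("111", 1.0, 0.0, 0.30, 0.0),   # readout byproduct
    ]
    reactions = [
        Reaction(("011", "1"), ("0111",), 0.6),
        Reaction(("011", "0111"), ("0011", "111"), 0.6),
    ]
    return _net(species, reactions, ["011", "1", "0011", "0111", "111"])


def make_fixtures(outdir) -> dict:
    """Write the reference genotypes (and a small protocol fixture) to
    ``outdir``; returns the mapping of name to path."""
    import os

    import numpy as np

    from . import tasks

    os.makedirs(outdir, exist_ok=True)
    nets = {
        "abba_reference": abba_reference_network(),
        "memory_readout_motif": memory_readout_motif(),
        "decoupled_memory_motif": decoupled_memory_motif(),
        "coincidence_motif": coincidence_motif(),
    }
    paths = {}
    for name, net in nets.items():
        path = os.path.join(outdir, f"{name}.json")
        net.to_json(path)
        paths[name] = path
    pset = tasks.gen_abba(np.random.default_rng(7), n_protocols=2)
    pset.seed = 7
    ppath = os.path.join(outdir, "abba_protocols.json")
    pset.save(ppath)
    paths["abba_protocols"] = ppath
    return paths
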