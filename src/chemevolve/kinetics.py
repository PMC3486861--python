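"""Deterministic simulation of a network: reversible mass-action ODEs.

Each reversible reaction is split into two directed half-reactions.  A
directed reaction with reactants R1 (+ R2) proceeds at rate
``k * [R1] (* [R2])``; it consumes its reactants and produces its
products at that rate, honouring stoichiometric multiplicity (A + A -> B
consumes two A per event).  On top of the explicit reactions every
species decays at a first-order rate (irreversibly, to unmodelled inert
waste) and the designated food species receives a constant inflow, so
the reactor is an open flow system.

Input boluses are discontinuous jumps in concentration at given times.
The workhorse integrator is explicit Euler at dt = 0.01 (the scheme used
during evolution); an adaptive Runge-Kutta integrator over the same
piecewise-smooth segments is provided for post-hoc validation.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import Network

__all__ = [
    "Bolus",
    "Trajectory",
    "SimulationDiverged",
    "CompiledNetwork",
    "derivatives",
    "simulate_euler",
    "simulate_rk",
    "atom_balance",
]

#: Divergence guard: abort a simulation once any concentration passes this.
MAX_CONCENTRATION = 1.0e6

DEFAULT_DT = 0.01


class SimulationDiverged(RuntimeError):
    """A concentration became non-finite or exceeded the divergence guard."""

    def __init__(self, time: float):
        super().__init__(f"simulation diverged at t = {time:g}")
        self.time = time


@dataclass(frozen=True)
class Bolus:
    """An instantaneous addition of ``amount`` of ``species`` at ``time``."""

    time: float
    species: str
    amount: float


@dataclass
class Trajectory:
    """Concentration time series on a regular output grid.

    ``data`` has one column per entry of ``species``; ``clamp_loss`` is
    the cumulative atom-weighted mass removed by the Euler non-negativity
    clamp (zero for well-behaved systems), used by :func:`atom_balance`.
    """

    times: np.ndarray
    data: np.ndarray
    species: list[str]
    clamp_loss: np.ndarray | None = None

    def __getitem__(self, formula: str) -> np.ndarray:
        return self.data[:, self.species.index(formula)]

    def to_frame(self):
        """Tidy (time, species, concentration) DataFrame."""
        import pandas as pd

        n = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(self.species)),
                "species": np.tile(np.array(self.species, dtype=object), n),
                "concentration": self.data.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class CompiledNetwork:
    """Flat-array view of a :class:`Network` for fast integration.

    Builds directed half-reaction arrays (reactant indices and rate
    constants with the thermodynamically derived forward/reverse split)
    and a sparse stoichiometry triplet list.  A compiled view is a
    snapshot: construct a fresh one after any genotype change.
    """

    def __init__(self, net: Network):
        self.net = net
        self.names: list[str] = list(net.species)
        self.index = {f: i for i, f in enumerate(self.names)}
        n_sp = len(self.names)

        self.y0 = np.array(
            [net.species[f].initial_concentration for f in self.names], dtype=np.float64
        )
        self.decay = np.array(
            [net.species[f].decay_rate for f in self.names], dtype=np.float64
        )
        self.wlen = np.array([float(len(f)) for f in self.names])
        self.inflow = np.zeros(n_sp)
        if len(net.io_list) >= 4:
            food = net.roles().food
            self.inflow[self.index[food]] = net.species[food].food_inflow

        kdir: list[float] = []
        r1: list[int] = []
        r2: list[int] = []
        triplets: dict[tuple[int, int], float] = {}

        def add_direction(reactants: Sequence[str], products: Sequence[str], k: float):
            j = len(kdir)
            kdir.append(k)
            r1.append(self.index[reactants[0]])
            r2.append(self.index[reactants[1]] if len(reactants) > 1 else -1)
            for s in reactants:
                key = (self.index[s], j)
                triplets[key] = triplets.get(key, 0.0) - 1.0
            for s in products:
                key = (self.index[s], j)
                triplets[key] = triplets.get(key, 0.0) + 1.0

        for rxn in net.reactions:
            kf, kr = net.rate_constants(rxn)
            add_direction(rxn.lhs, rxn.rhs, kf)
            add_direction(rxn.rhs, rxn.lhs, kr)

        self.kdir = np.array(kdir, dtype=np.float64)
        self.r1 = np.array(r1, dtype=np.int64)
        self.r2 = np.array(r2, dtype=np.int64)
        items = sorted(triplets.items())
        self.trow = np.array([k[0] for k, _ in items], dtype=np.int64)
        self.tcol = np.array([k[1] for k, _ in items], dtype=np.int64)
        self.tval = np.array([v for _, v in items], dtype=np.float64)
        # dense stoichiometry matrix for the vectorised RHS
        self.smat = np.zeros((n_sp, len(kdir)))
        self.smat[self.trow, self.tcol] = self.tval

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        rates = self.kdir * y[self.r1]
        mask = self.r2 >= 0
        rates[mask] *= y[self.r2[mask]]
        return self.smat @ rates + self.inflow - self.decay * y


def derivatives(
    net: Network, conc: Mapping[str, float] | np.ndarray
) -> dict[str, float]:
    """Instantaneous rate of change of every species at the given state."""
    cn = CompiledNetwork(net)
    if isinstance(conc, Mapping):
        y = np.array([float(conc[f]) for f in cn.names])
    else:
        y = np.asarray(conc, dtype=float)
    dy = cn.rhs(0.0, y)
    return dict(zip(cn.names, dy))


def _bolus_arrays(cn: CompiledNetwork, boluses: Iterable[Bolus], dt: float, n_steps: int):
    bs = sorted(boluses, key=lambda b: b.time)
    step = np.array([int(round(b.time / dt)) for b in bs], dtype=np.int64)
    if len(step) and (step.min() < 0 or step.max() > n_steps):
        raise ValueError("bolus time outside the simulation horizon")
    sp = np.array([cn.index[b.species] for b in bs], dtype=np.int64)
    amt = np.array([float(b.amount) for b in bs], dtype=np.float64)
    return step, sp, amt


def simulate_euler(
    net: Network | CompiledNetwork,
    horizon: float,
    boluses: Iterable[Bolus] = (),
    dt: float = DEFAULT_DT,
    record_species: Sequence[str] | None = None,
    record_stride: int = 1,
    max_conc: float = MAX_CONCENTRATION,
) -> Trajectory:
    """Explicit Euler integration on the dt grid.

    Boluses scheduled at a grid time are added to the state before that
    grid point is recorded; concentrations are clamped at zero after
    every step.  Raises :class:`SimulationDiverged` if any concentration
    exceeds ``max_conc`` or becomes non-finite.
    """
    from ._kernel import euler_loop

    if dt <= 0:
        raise ValueError("dt must be positive")
    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    n_steps = int(round(horizon / dt))
    bstep, bsp, bamt = _bolus_arrays(cn, boluses, dt, n_steps)
    rec_names = list(record_species) if record_species is not None else cn.names
    rec_idx = np.array([cn.index[f] for f in rec_names], dtype=np.int64)

    y = cn.y0.copy()
    out, closs, n_rec, status, fail_step = euler_loop(
        y,
        cn.kdir,
        cn.r1,
        cn.r2,
        cn.trow,
        cn.tcol,
        cn.tval,
        cn.decay,
        cn.inflow,
        cn.wlen,
        float(dt),
        n_steps,
        bstep,
        bsp,
        bamt,
        rec_idx,
        int(record_stride),
        float(max_conc),
    )
    if status != 0:
        raise SimulationDiverged(fail_step * dt)
    if not (np.all(np.isfinite(out[:n_rec])) and np.all(np.isfinite(y))):
        raise SimulationDiverged(n_steps * dt)
    times = np.arange(n_rec) * (dt * record_stride)
    return Trajectory(times=times, data=out[:n_rec], species=rec_names, clamp_loss=closs[:n_rec])


def simulate_rk(
    net: Network | CompiledNetwork,
    horizon: float,
    boluses: Iterable[Bolus] = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float = DEFAULT_DT,
    record_species: Sequence[str] | None = None,
    method: str = "RK45",
) -> Trajectory:
    """Adaptive Runge-Kutta integration between bolus discontinuities.

    Used post hoc to validate Euler runs.  The trajectory is sampled on
    the same regular grid as :func:`simulate_euler` so the two outputs
    are directly comparable.
    """
    from scipy.integrate import solve_ivp

    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    n_steps = int(round(horizon / sample_dt))
    grid = np.arange(n_steps + 1) * sample_dt
    bs = sorted(boluses, key=lambda b: b.time)
    jumps: dict[float, list[Bolus]] = {}
    for b in bs:
        jumps.setdefault(float(b.time), []).append(b)
    boundaries = sorted(set([0.0, float(horizon)]) | set(jumps))

    y = cn.y0.copy()
    n_rec_names = list(record_species) if record_species is not None else cn.names
    rec_idx = [cn.index[f] for f in n_rec_names]
    out = np.empty((len(grid), len(rec_idx)))
    filled = np.zeros(len(grid), dtype=bool)

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        for b in jumps.get(seg_start, []):
            y[cn.index[b.species]] += b.amount
        sel = (grid >= seg_start) & (grid < seg_end)
        # grid points at the segment start take the post-bolus state
        t_eval = grid[sel]
        if len(t_eval) and t_eval[0] == seg_start:
            out[np.nonzero(sel)[0][0]] = y[rec_idx]
            filled[np.nonzero(sel)[0][0]] = True
            t_eval = t_eval[1:]
            sel_idx = np.nonzero(sel)[0][1:]
        else:
            sel_idx = np.nonzero(sel)[0]
        if seg_end > seg_start:
            # always evaluate at the segment end so the carried state is exact
            t_eval_full = np.append(t_eval, seg_end)
            sol = solve_ivp(
                cn.rhs,
                (seg_start, seg_end),
                y,
                method=method,
                t_eval=t_eval_full,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationDiverged(seg_end)
            if len(t_eval):
                out[sel_idx] = sol.y.T[: len(t_eval), rec_idx]
                filled[sel_idx] = True
            y = sol.y[:, -1].copy()
    for b in jumps.get(boundaries[-1], []):
        y[cn.index[b.species]] += b.amount
    if not filled[-1]:
        out[-1] = y[rec_idx]
        filled[-1] = True
    out = np.clip(out, 0.0, None)  # RK can leave tiny negative round-off
    return Trajectory(times=grid, data=out, species=n_rec_names)


def atom_balance(
    net: Network,
    traj: Trajectory,
    boluses: Iterable[Bolus] = (),
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Per-time residual of the atom-count bookkeeping for an Euler run.

    The total atom count (concentration weighted by formula length) may
    change only through food inflow, boluses, first-order decay and the
    non-negativity clamp; after accounting for those the residual is zero
    up to floating-point error.  Requires a stride-1 trajectory recording
    every species.
    """
    if sorted(traj.species) != sorted(net.species):
        raise ValueError("atom_balance needs a trajectory of every species")
    cn = CompiledNetwork(net)
    order = [traj.species.index(f) for f in cn.names]
    data = traj.data[:, order]
    atoms = data @ cn.wlen
    inflow_atoms = float(cn.inflow @ cn.wlen)
    decay_atoms = data @ (cn.decay * cn.wlen)
    n = len(traj.times)
    bolus_atoms = np.zeros(n)
    for b in boluses:
        i = int(round(b.time / dt))
        if 0 <= i < n:
            bolus_atoms[i] += b.amount * len(b.species)
    clamp = traj.clamp_loss if traj.clamp_loss is not None else np.zeros(n)
    expected = np.empty(n)
    expected[0] = atoms[0]
    increments = dt * (inflow_atoms - decay_atoms[:-1]) + bolus_atoms[1:] - np.diff(clamp)
    expected[1:] = atoms[0] + np.cumsum(increments)
    return atoms - expected
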