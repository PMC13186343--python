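"""Langevin integration and the stochastic single-valent bond engine.

The integrator is a BAOAB splitting of underdamped Langevin dynamics: a
velocity half-kick with the conservative forces, a half drift, an exact
Ornstein–Uhlenbeck velocity refresh (friction ``exp(-dt/t_damp)`` plus the
matched Gaussian kick), a second half drift, and a final half-kick with the
new forces.  With the thermostat off this is exactly velocity Verlet, so
the undamped limit conserves energy to the usual O(dt²) symplectic drift.

Sticker bond creation/breaking runs once every ``bond_attempt_every`` steps
on a random stream independent of the thermostat stream, so bond statistics
are reproducible regardless of the force noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .errors import (
    InstabilityError,
    InvalidInputError,
    OverlapError,
)
from .forcefield import EnergyBreakdown, ForceFieldParams, total_energy_forces
from .polymer_setup import (
    ChainTopology,
    ComplementarityRule,
    SystemState,
    write_restart,
)
from .units import FTM2V, KB, MVV2E

__all__ = [
    "SimulationConfig",
    "BondEvent",
    "BondEventLog",
    "Trajectory",
    "RunResult",
    "init_velocities",
    "langevin_step",
    "attempt_bond_updates",
    "run",
]

THERMO_COLUMNS = [
    "step",
    "E_bond",
    "E_pair",
    "E_angle",
    "E_potential",
    "KE",
    "T_inst",
    "bonded_fraction",
]


@dataclass
class SimulationConfig:
    """Integration and output settings (real units: fs, K, g/mol)."""

    dt: float = 15.0
    T: float = 310.0
    t_damp: float | None = 500.0  # None disables the thermostat (NVE)
    mass: float = 100.0
    n_steps: int = 0
    bond_attempt_every: int = 20
    seed_thermostat: int = 12345
    seed_bonds: int = 67890
    thermo_every: int = 1000
    dump_every: int = 0
    restart_every: int = 0
    restart_prefix: str | None = None
    skin: float = 3.0

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")
        if self.bond_attempt_every < 1:
            raise InvalidInputError("bond_attempt_every must be >= 1")

    @property
    def kT(self) -> float:
        return KB * self.T


@dataclass(frozen=True)
class BondEvent:
    step: int
    kind: str  # "form" | "break"
    i: int
    j: int


class BondEventLog:
    """Chronological log of sticker bond form/break events."""

    KINDS = ("form", "break")

    def __init__(self, records: np.ndarray | None = None):
        self.records = (
            np.asarray(records, dtype=np.int64).reshape(-1, 4)
            if records is not None
            else np.empty((0, 4), np.int64)
        )

    def __len__(self):
        return self.records.shape[0]

    def __iter__(self):
        for step, kind, i, j in self.records:
            yield BondEvent(int(step), self.KINDS[kind], int(i), int(j))

    @property
    def steps(self):
        return self.records[:, 0]

    @property
    def break_steps(self):
        return self.records[self.records[:, 1] == 1, 0]

    @property
    def form_steps(self):
        return self.records[self.records[:, 1] == 0, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.records[:, 0],
                "kind": [self.KINDS[k] for k in self.records[:, 1]],
                "i": self.records[:, 2],
                "j": self.records[:, 3],
            }
        )

    @classmethod
    def concat(cls, logs):
        arrs = [lg.records for lg in logs if len(lg)]
        return cls(np.concatenate(arrs) if arrs else None)


@dataclass
class Trajectory:
    """In-memory trajectory: wrapped coordinates plus image flags per frame."""

    steps: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 3) wrapped
    images: np.ndarray  # (F, N, 3)
    box: np.ndarray  # (3,)
    dt: float  # fs per step

    @property
    def n_frames(self) -> int:
        return self.steps.size

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs."""
        return self.steps * self.dt


@dataclass
class RunResult:
    state: SystemState
    thermo: pd.DataFrame
    events: BondEventLog
    trajectory: Trajectory | None
    bond_series: np.ndarray  # bonded-sticker count at every attempt step
    rng: dict  # final PCG stream states


# ---------------------------------------------------------------------------


def init_velocities(T: float, mass: float, seed: int, n: int) -> np.ndarray:
    """Maxwell–Boltzmann velocity draw with the center-of-mass drift removed.

    Per-component variance is kB·T·ftm2v/m, so the mean kinetic energy per
    bead is (3/2) kB·T.
    """
    if T <= 0:
        raise InvalidInputError("temperature must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * T * FTM2V / mass)
    v = rng.normal(scale=sigma, size=(n, 3))
    v -= v.mean(axis=0, keepdims=True)
    return v


def _topology_arrays(topology: ChainTopology, rule: ComplementarityRule | None):
    if rule is None:
        rule = ComplementarityRule.heterotypic(topology.sticker_labels)
    comp = rule.matrix(topology.sticker_labels)
    if comp.size == 0:
        comp = np.zeros((1, 1), dtype=bool)
    bonds = topology.permanent_bonds
    angles = topology.angles
    return dict(
        bond_i=np.ascontiguousarray(bonds[:, 0]),
        bond_j=np.ascontiguousarray(bonds[:, 1]),
        ang_a=np.ascontiguousarray(angles[:, 0]),
        ang_b=np.ascontiguousarray(angles[:, 1]),
        ang_c=np.ascontiguousarray(angles[:, 2]),
        perm1=topology.perm_neighbor1,
        perm2=topology.perm_neighbor2,
        sticker_idx=topology.sticker_indices,
        stype=topology.sticker_type,
        comp=comp,
    )


def _raise_for(err: int):
    if err == _kernels.ERR_UNSTABLE:
        raise InstabilityError(
            "per-step displacement exceeded box/4 — timestep too large?"
        )
    if err == _kernels.ERR_OVERLAP:
        raise OverlapError("overlapping beads during force evaluation")
    if err == _kernels.ERR_PAIRING:
        raise InvalidInputError("pairing table asymmetry detected")


def attempt_bond_updates(
    state: SystemState,
    topology: ChainTopology,
    params: ForceFieldParams,
    rule: ComplementarityRule | None = None,
    rng: np.ndarray | int = 0,
) -> BondEventLog:
    """One stochastic bond pass (break then create) on ``state.pairing``.

    Bonded pairs at minimum-image R >= Rcut break with probability p_off;
    then unpaired complementary pairs within Rcut are visited in uniformly
    random order and bond with probability p_on, respecting valency 1.
    ``rng`` is either a PCG state vector (mutated in place) or an integer
    seed.  Returns the event log for this pass.
    """
    state.check_pairing()
    if isinstance(rng, (int, np.integer)):
        rng = _kernels.pcg_init(int(rng), stream=1)
    arrs = _topology_arrays(topology, rule)
    cap = max(16, arrs["sticker_idx"].size + 1)
    ev = np.zeros((cap, 4), dtype=np.int64)
    n_ev = _kernels._attempt_bonds(
        state.positions,
        state.box,
        state.pairing,
        arrs["sticker_idx"],
        arrs["stype"],
        arrs["comp"],
        params.Rcut_stick,
        params.p_on,
        params.p_off,
        rng,
        ev,
        0,
        True,
        state.step,
    )
    return BondEventLog(ev[:n_ev])


def _count_cadence(step0: int, n: int, every: int) -> int:
    """Number of steps s in (step0, step0+n] with s % every == 0."""
    if every <= 0 or n <= 0:
        return 0
    return (step0 + n) // every - step0 // every


def run(
    state: SystemState,
    topology: ChainTopology,
    params: ForceFieldParams,
    config: SimulationConfig,
    rule: ComplementarityRule | None = None,
    record_events: bool = True,
    sample_bond_series: bool = False,
    rng: dict | None = None,
) -> RunResult:
    """Integrate ``config.n_steps`` steps of Langevin dynamics with bond moves.

    Mutates ``state`` in place and returns a :class:`RunResult` holding the
    thermo table (a row at the initial step when aligned with the cadence,
    then one per ``thermo_every`` steps), the bond event log, the collected
    trajectory frames, the per-attempt bonded-sticker counts (when
    ``sample_bond_series``), and the final RNG stream states.

    Passing ``rng`` (as returned in a previous result or read from a
    restart) continues those streams, which makes a chunked or restarted
    run bit-identical to an uninterrupted one.
    """
    if state.n_beads != topology.n_beads:
        raise InvalidInputError("state and topology disagree on bead count")
    state.check_pairing()
    arrs = _topology_arrays(topology, rule)
    if rng is None:
        rng = {
            "thermostat": _kernels.pcg_init(config.seed_thermostat, stream=0),
            "bonds": _kernels.pcg_init(config.seed_bonds, stream=1),
        }
    rng_t = np.ascontiguousarray(rng["thermostat"], dtype=np.uint64)
    rng_b = np.ascontiguousarray(rng["bonds"], dtype=np.uint64)

    use_thermostat = config.t_damp is not None and config.T > 0
    t_damp = float(config.t_damp) if use_thermostat else np.inf
    n = state.n_beads
    n_stickers = int(arrs["sticker_idx"].size)

    thermo_rows = []
    # initial row (recomputed fresh so a zero-step run still reports energies)
    if config.thermo_every > 0 and state.step % config.thermo_every == 0:
        _, e0 = total_energy_forces(state, topology, params)
        ke0 = 0.5 * config.mass * MVV2E * float((state.velocities**2).sum())
        sat0 = (
            np.count_nonzero(state.pairing[arrs["sticker_idx"]] != -1) / n_stickers
            if n_stickers
            else 0.0
        )
        thermo_rows.append(
            [
                state.step,
                e0.E_bond,
                e0.E_pair,
                e0.E_angle,
                e0.E_potential,
                ke0,
                2.0 * ke0 / (3.0 * n * KB),
                sat0,
            ]
        )

    traj_chunks = []
    event_chunks = []
    series_chunks = []

    remaining = int(config.n_steps)
    # cap the per-chunk event buffer (S events per attempt step is an exact bound)
    if record_events and n_stickers > 0:
        max_chunk = max(
            config.bond_attempt_every,
            int(1_000_000 / n_stickers) * config.bond_attempt_every,
        )
    else:
        max_chunk = 10_000_000
    if config.restart_every > 0:
        max_chunk = min(max_chunk, config.restart_every)

    while remaining > 0:
        seg = min(remaining, max_chunk)
        if config.restart_every > 0:
            # land exactly on restart boundaries
            to_boundary = config.restart_every - state.step % config.restart_every
            seg = min(seg, to_boundary)
        n_th = _count_cadence(state.step, seg, config.thermo_every)
        n_dp = _count_cadence(state.step, seg, config.dump_every)
        n_se = (
            _count_cadence(state.step, seg, config.bond_attempt_every)
            if sample_bond_series
            else 0
        )
        n_attempts = _count_cadence(state.step, seg, config.bond_attempt_every)
        ev_cap = max(1, n_stickers * n_attempts) if record_events else 1

        thermo_buf = np.zeros((max(n_th, 1), 7))
        traj_pos = np.zeros((max(n_dp, 1), n, 3)) if n_dp else np.zeros((1, 1, 3))
        traj_img = np.zeros_like(traj_pos, dtype=np.int64)
        traj_steps = np.zeros(max(n_dp, 1), dtype=np.int64)
        series_buf = np.zeros(max(n_se, 1), dtype=np.int64)
        ev_buf = np.zeros((ev_cap, 4), dtype=np.int64)

        err, got_th, got_dp, got_se, got_ev = _kernels._run_chunk(
            state.positions,
            state.images,
            state.velocities,
            state.pairing,
            state.box,
            arrs["bond_i"],
            arrs["bond_j"],
            arrs["ang_a"],
            arrs["ang_b"],
            arrs["ang_c"],
            arrs["perm1"],
            arrs["perm2"],
            arrs["sticker_idx"],
            arrs["stype"],
            arrs["comp"],
            params.Kb,
            params.R0_bond,
            params.kappa,
            params.Ens,
            params.sigma,
            params.Rmax,
            params.Es,
            params.R0_stick,
            params.Rcut_stick,
            params.p_on,
            params.p_off,
            config.mass,
            config.dt,
            t_damp,
            config.kT,
            use_thermostat,
            state.step,
            seg,
            config.bond_attempt_every,
            config.skin,
            config.thermo_every,
            thermo_buf,
            config.dump_every if n_dp else 0,
            traj_pos,
            traj_img,
            traj_steps,
            sample_bond_series,
            series_buf,
            record_events,
            ev_buf,
            rng_t,
            rng_b,
        )
        _raise_for(err)
        state.step += seg
        for r in range(got_th):
            row = thermo_buf[r]
            thermo_rows.append(
                [
                    int(row[0]),
                    row[1],
                    row[2],
                    row[3],
                    row[4],
                    row[5],
                    2.0 * row[5] / (3.0 * n * KB),
                    row[6] / n_stickers if n_stickers else 0.0,
                ]
            )
        if got_dp:
            traj_chunks.append(
                (traj_steps[:got_dp].copy(), traj_pos[:got_dp].copy(), traj_img[:got_dp].copy())
            )
        if got_se:
            series_chunks.append(series_buf[:got_se].copy())
        if got_ev:
            event_chunks.append(ev_buf[:got_ev].copy())
        remaining -= seg
        if (
            config.restart_every > 0
            and config.restart_prefix
            and state.step % config.restart_every == 0
        ):
            write_restart(
                state,
                topology,
                f"{config.restart_prefix}_{state.step}.restart",
                rng={"thermostat": rng_t, "bonds": rng_b},
            )

    thermo = pd.DataFrame(thermo_rows, columns=THERMO_COLUMNS)
    if traj_chunks:
        trajectory = Trajectory(
            steps=np.concatenate([c[0] for c in traj_chunks]),
            positions=np.concatenate([c[1] for c in traj_chunks]),
            images=np.concatenate([c[2] for c in traj_chunks]),
            box=state.box.copy(),
            dt=config.dt,
        )
    else:
        trajectory = None
    events = BondEventLog(
        np.concatenate(event_chunks) if event_chunks else None
    )
    series = np.concatenate(series_chunks) if series_chunks else np.empty(0, np.int64)
    return RunResult(
        state=state,
        thermo=thermo,
        events=events,
        trajectory=trajectory,
        bond_series=series,
        rng={"thermostat": rng_t, "bonds": rng_b},
    )


def langevin_step(
    state: SystemState,
    topology: ChainTopology,
    params: ForceFieldParams,
    config: SimulationConfig,
    rule: ComplementarityRule | None = None,
    rng: dict | None = None,
) -> dict:
    """Advance a single integration step (no bond attempt, no output).

    Thin wrapper over the same kernel as :func:`run`, useful for stepwise
    inspection; returns the final RNG states for continuation.
    """
    one = replace(
        config, n_steps=1, thermo_every=0, dump_every=0, restart_every=0,
        bond_attempt_every=max(config.bond_attempt_every, 2_000_000_000),
    )
    res = run(
        state, topology, params, one, rule=rule, record_events=False, rng=rng
    )
    return res.rng
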