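"""Statistical-physics validation experiments.

Two headline checks of the hybrid MD/stochastic-bond scheme:

1. **Two-particle detailed balance.** Two complementary stickers diffuse in
   a strongly elongated ("pseudo-1D") periodic box and bind/unbind
   reversibly.  Sampling the bond state at every attempt step gives a 0/1
   series; counting the four frame-pair outcomes (UU, UB, BU, BB) yields
   stationary probabilities pi_U, pi_B, per-frame transition rates
   P_U->B = N_UB/N_U and P_B->U = N_BU/N_B, and the equilibrium constant
   K_eq = pi_U/pi_B.  Detailed balance requires pi_U P_U->B = pi_B P_B->U
   and Boltzmann statistics K_eq ∝ exp(-Es/kT).

2. **Phase titration.** Starting from a preformed cluster, the specific
   energy Es is titrated; time-averaged normalized ACO, sticker saturation
   and dissociation counts trace the switch-like phase boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import (
    RegressionResult,
    cluster_components,
    dissociation_series,
    linear_fit,
    sticker_saturation,
)
from .dynamics import BondEventLog, SimulationConfig, init_velocities, run
from .errors import InvalidInputError, UndefinedEquilibriumError
from .forcefield import ForceFieldParams
from .polymer_setup import (
    BlockTemplate,
    ChainTopology,
    ComplementarityRule,
    SystemState,
    build_chain,
    pack_system,
    two_component_templates,
)
from .units import KB

__all__ = [
    "TransitionCounts",
    "DetailedBalanceResult",
    "TitrationResult",
    "run_two_particle",
    "transition_stats",
    "detailed_balance_report",
    "make_preformed_cluster",
    "phase_titration",
    "free_bead_system",
    "diffusion_scan",
]


@dataclass
class TransitionCounts:
    """Counts of the four successive-frame outcomes of a 0/1 bond series."""

    N_UU: int
    N_UB: int
    N_BU: int
    N_BB: int

    @property
    def N_U(self) -> int:
        return self.N_UU + self.N_UB

    @property
    def N_B(self) -> int:
        return self.N_BB + self.N_BU


@dataclass
class DetailedBalanceResult:
    """Stationary probabilities, transition rates and equilibrium constant."""

    pi_U: float
    pi_B: float
    P_UB: float  # per-frame U -> B rate
    P_BU: float  # per-frame B -> U rate
    K_eq: float  # pi_U / pi_B
    flux_ratio: float  # (pi_U P_UB) / (pi_B P_BU); 1 under detailed balance
    flux_ratio_sigma: float  # Poisson-propagated standard error of the ratio
    well_defined: bool  # False when one of the rates is zero


@dataclass
class TitrationResult:
    es_grid_kT: np.ndarray
    aco_normalized: np.ndarray  # time-averaged, per Es
    saturation: np.ndarray
    dissociation_counts: np.ndarray  # break events per window, per Es (mean)
    threshold_kT: float | None  # Es where normalized ACO crosses 0.5
    non_equilibrated: np.ndarray  # bool flag per Es
    tables: list  # per-Es sample DataFrames (step, aco, saturation)


# ---------------------------------------------------------------------------
# Two-particle experiment
# ---------------------------------------------------------------------------


def _two_sticker_system(box):
    a = build_chain(BlockTemplate(roles=("A",), repeat_count=1))
    b = build_chain(BlockTemplate(roles=("B",), repeat_count=1))
    from .polymer_setup import _merge_topologies

    topo = _merge_topologies([(a, 1), (b, 1)])
    box = np.asarray(box, dtype=float)
    state = SystemState.empty(2, box)
    state.positions[0] = box * np.array([0.25, 0.5, 0.5])
    state.positions[1] = box * np.array([0.75, 0.5, 0.5])
    return state, topo


def run_two_particle(
    es_kT: float,
    n_frames: int,
    seed_thermostat: int = 1,
    seed_bonds: int = 2,
    box=(150.0, 15.0, 15.0),
    ens_kT: float = 0.3,
    T: float = 310.0,
    dt: float = 15.0,
    t_damp: float = 500.0,
    mass: float = 100.0,
    bond_attempt_every: int = 20,
) -> np.ndarray:
    """Bond-state series for two complementary stickers in a pseudo-1D box.

    The bond state is sampled once per attempt step (the only times it can
    change), for ``n_frames`` samples.  Returns an int8 0/1 array.  The
    elongated box accelerates the diffusive encounter cycle; its volume
    shifts the K_eq prefactor but not the Es-scaling.  The default length
    keeps the box-recurrence time of an unbound excursion short, which
    tames the heavy-tailed unbound-episode statistics that otherwise
    dominate the K_eq estimator variance at strong Es.
    """
    if es_kT < 0:
        raise InvalidInputError("Es must be nonnegative")
    state, topo = _two_sticker_system(box)
    params = ForceFieldParams.from_kT(es_kT=max(es_kT, 1e-12), ens_kT=ens_kT, temperature=T)
    state.velocities = init_velocities(T, mass, seed_thermostat, 2)
    config = SimulationConfig(
        dt=dt,
        T=T,
        t_damp=t_damp,
        mass=mass,
        n_steps=int(n_frames) * bond_attempt_every,
        bond_attempt_every=bond_attempt_every,
        seed_thermostat=seed_thermostat,
        seed_bonds=seed_bonds,
        thermo_every=0,
        dump_every=0,
    )
    res = run(
        state,
        topo,
        params,
        config,
        rule=ComplementarityRule.heterotypic(("A", "B")),
        record_events=False,
        sample_bond_series=True,
    )
    return (res.bond_series >= 2).astype(np.int8)


def transition_stats(series):
    """Transition counts and detailed-balance estimators for a 0/1 series.

    Estimators over successive frame pairs: pi_U = N_U/(N_U + N_B),
    P_U->B = N_UB/N_U, P_B->U = N_BU/N_B, K_eq = pi_U/pi_B.  Raises
    :class:`UndefinedEquilibriumError` if the series never visits one of
    the states; a zero transition rate is reported with
    ``well_defined=False`` and an infinite flux ratio.
    """
    s = np.asarray(series).astype(np.int8)
    if s.size < 2:
        raise InvalidInputError("series must contain at least 2 frames")
    a, b = s[:-1], s[1:]
    n_uu = int(np.count_nonzero((a == 0) & (b == 0)))
    n_ub = int(np.count_nonzero((a == 0) & (b == 1)))
    n_bu = int(np.count_nonzero((a == 1) & (b == 0)))
    n_bb = int(np.count_nonzero((a == 1) & (b == 1)))
    counts = TransitionCounts(N_UU=n_uu, N_UB=n_ub, N_BU=n_bu, N_BB=n_bb)
    n_u, n_b = counts.N_U, counts.N_B
    if n_u == 0 or n_b == 0:
        raise UndefinedEquilibriumError(
            "series never visits one of the states; K_eq undefined"
        )
    pi_u = n_u / (n_u + n_b)
    pi_b = n_b / (n_u + n_b)
    p_ub = n_ub / n_u
    p_bu = n_bu / n_b
    k_eq = pi_u / pi_b
    well = n_ub > 0 and n_bu > 0
    if well:
        flux_ratio = (pi_u * p_ub) / (pi_b * p_bu)  # = N_UB / N_BU
        sigma = flux_ratio * np.sqrt(1.0 / n_ub + 1.0 / n_bu)
    else:
        flux_ratio = np.inf if n_bu == 0 else 0.0
        sigma = np.nan
    return counts, DetailedBalanceResult(
        pi_U=pi_u,
        pi_B=pi_b,
        P_UB=p_ub,
        P_BU=p_bu,
        K_eq=k_eq,
        flux_ratio=flux_ratio,
        flux_ratio_sigma=sigma,
        well_defined=well,
    )


def detailed_balance_report(
    es_values_kT,
    n_frames: int,
    seed: int = 0,
    **two_particle_kwargs,
):
    """Per-Es detailed-balance statistics and the ln K_eq vs Es regression.

    Runs :func:`run_two_particle` at every Es (independent seeded streams),
    computes the estimators, and fits ln K_eq against Es (in kT).  Under
    Boltzmann statistics the fit is linear with slope near -1 per kT.
    Returns ``(DataFrame, RegressionResult)``; Es points with an undefined
    K_eq are excluded from the fit with a warning.
    """
    es_values_kT = list(es_values_kT)
    if len(es_values_kT) < 3:
        raise InvalidInputError("need at least 3 Es values")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * len(es_values_kT)) % (2**31)
    rows = []
    for k, es in enumerate(es_values_kT):
        series = run_two_particle(
            es,
            n_frames,
            seed_thermostat=int(seeds[2 * k]),
            seed_bonds=int(seeds[2 * k + 1]),
            **two_particle_kwargs,
        )
        try:
            counts, db = transition_stats(series)
        except UndefinedEquilibriumError:
            warnings.warn(f"Es = {es} kT: K_eq undefined, excluded from fit")
            continue
        rows.append(
            {
                "Es_kT": es,
                "N_UU": counts.N_UU,
                "N_UB": counts.N_UB,
                "N_BU": counts.N_BU,
                "N_BB": counts.N_BB,
                "pi_U": db.pi_U,
                "pi_B": db.pi_B,
                "P_UB": db.P_UB,
                "P_BU": db.P_BU,
                "K_eq": db.K_eq,
                "flux_ratio": db.flux_ratio,
                "flux_ratio_sigma": db.flux_ratio_sigma,
                "well_defined": db.well_defined,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["well_defined"] & (table["K_eq"] > 0)]
    if len(usable) < 3:
        raise UndefinedEquilibriumError("too few usable Es points for the fit")
    fit = linear_fit(usable["Es_kT"].to_numpy(), np.log(usable["K_eq"].to_numpy()))
    return table, fit


# ---------------------------------------------------------------------------
# Damping / diffusion experiment
# ---------------------------------------------------------------------------


def free_bead_system(n: int, box, seed: int = 0):
    """An ensemble of non-interacting single-bead chains at random positions."""
    from .polymer_setup import _merge_topologies

    c = build_chain(BlockTemplate(roles=("spacer",), repeat_count=1))
    topo = _merge_topologies([(c, n)])
    state = SystemState.empty(n, box)
    rng = np.random.default_rng(seed)
    state.positions = rng.random((n, 3)) * np.asarray(box, dtype=float)
    return state, topo


def diffusion_scan(
    t_damps=(100.0, 200.0, 500.0, 1000.0, 2000.0, 4000.0),
    n_beads: int = 100,
    n_steps: int = 200_000,
    dt: float = 10.0,
    T: float = 310.0,
    mass: float = 100.0,
    dump_every: int = 200,
    seed: int = 0,
):
    """Fit MSD = 6 D t for free beads across a range of damping times.

    For a free Langevin particle D = kT·t_damp/m, so log D against
    log t_damp is a line of slope 1 — the damping parameter acts as an
    inverse solvent viscosity.  Returns ``(DataFrame, RegressionResult)``
    with the per-damping fitted D, the analytic D, and the log-log fit.
    """
    from .analysis import free_particle_diffusion, msd_diffusion

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(3 * len(t_damps)) % (2**31)
    params = ForceFieldParams.from_kT(es_kT=1e-12, ens_kT=0.0)
    rows = []
    for k, td in enumerate(t_damps):
        # box large enough that the cell grid exists; beads never interact
        state, topo = free_bead_system(n_beads, (200.0, 200.0, 200.0), int(seeds[3 * k]))
        state.velocities = init_velocities(T, mass, int(seeds[3 * k + 1]), n_beads)
        cfg = SimulationConfig(
            dt=dt,
            T=T,
            t_damp=float(td),
            mass=mass,
            n_steps=n_steps,
            thermo_every=0,
            dump_every=dump_every,
            bond_attempt_every=2_000_000_000,
            seed_thermostat=int(seeds[3 * k + 2]),
            seed_bonds=1,
        )
        res = run(state, topo, params, cfg, record_events=False)
        msd = msd_diffusion(res.trajectory, t_damp=float(td))
        rows.append(
            {
                "t_damp": float(td),
                "D_fit": msd.D,
                "D_analytic": free_particle_diffusion(T, float(td), mass),
                "msd_r_squared": msd.fit.r_squared,
            }
        )
    table = pd.DataFrame(rows)
    loglog = (
        linear_fit(np.log(table["t_damp"].to_numpy()), np.log(table["D_fit"].to_numpy()))
        if len(table) >= 3
        else None
    )
    return table, loglog


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------


def make_preformed_cluster(
    n_chains_each: int = 20,
    box_edge: float | None = None,
    compact_edge: float | None = None,
    es_anneal_kT: float = 8.0,
    ens_kT: float = 0.3,
    anneal_steps: int = 20_000,
    seed: int = 0,
    config: SimulationConfig | None = None,
):
    """Build a bonded two-component cluster to seed a titration.

    Chains (50 beads, 10 stickers each, heterotypic A-B binding) are packed
    into a compact central region of the box — density-matched to the
    standard 400-chain/800 Å system when ``box_edge`` is not given — and
    annealed briefly at strong Es so the sticker network forms.

    Returns ``(state, topology, params, rule, config)``.
    """
    ta, tb = two_component_templates()
    ca, cb = build_chain(ta), build_chain(tb)
    n_beads = (ca.n_beads + cb.n_beads) * n_chains_each
    if box_edge is None:
        # same bead density as 20,000 beads in an 800 Å cube
        box_edge = 800.0 * (n_beads / 20_000.0) ** (1.0 / 3.0)
    if compact_edge is None:
        # ~2500 Å^3 per bead: dense enough for fast bonding, loose enough
        # for the rejection packer to succeed reliably
        compact_edge = max((n_beads * 2500.0) ** (1.0 / 3.0), 60.0)
    box = np.array([box_edge] * 3)
    cbox = np.array([compact_edge] * 3)
    state_c, topo = pack_system(
        [(ca, n_chains_each), (cb, n_chains_each)], cbox, seed=seed
    )
    # re-embed the (unwrapped) compact packing in the center of the big box
    coords = state_c.unwrapped_positions()
    coords += (box - cbox) / 2.0
    state = SystemState.empty(topo.n_beads, box)
    state.images = np.floor(coords / box).astype(np.int64)
    state.positions = coords - state.images * box
    rule = ComplementarityRule.heterotypic(("A", "B"))
    if config is None:
        config = SimulationConfig()
    config = replace(
        config,
        n_steps=anneal_steps,
        thermo_every=0,
        dump_every=0,
        seed_thermostat=seed + 101,
        seed_bonds=seed + 202,
    )
    params = ForceFieldParams.from_kT(
        es_kT=es_anneal_kT, ens_kT=ens_kT, temperature=config.T
    )
    state.velocities = init_velocities(config.T, config.mass, seed + 303, topo.n_beads)
    run(state, topo, params, config, rule=rule, record_events=False)
    return state, topo, params, rule, config


def interpolate_threshold(es_grid, aco_means, level: float = 0.5) -> float | None:
    """Es at which the normalized-ACO curve first crosses ``level`` upward.

    Linear interpolation between the bracketing grid points; ``None`` when
    the curve never crosses.
    """
    es_grid = np.asarray(es_grid, dtype=float)
    aco_means = np.asarray(aco_means, dtype=float)
    for k in range(es_grid.size - 1):
        a0, a1 = aco_means[k], aco_means[k + 1]
        if a0 < level <= a1:
            return float(es_grid[k] + (level - a0) / (a1 - a0) * (es_grid[k + 1] - es_grid[k]))
    return None


def phase_titration(
    state: SystemState,
    topology: ChainTopology,
    params: ForceFieldParams,
    rule: ComplementarityRule,
    es_grid_kT,
    steps_per_es: int,
    config: SimulationConfig,
    sample_every: int = 2_000,
    discard_fraction: float = 0.1,
    dissociation_window: int = 1_000_000,
    seed: int = 0,
) -> TitrationResult:
    """Titrate Es from a preformed cluster and trace the phase boundary.

    Every Es point restarts from the same preformed state (independent
    seeded streams), runs ``steps_per_es`` steps, and samples normalized
    ACO and sticker saturation every ``sample_every`` steps; the first
    ``discard_fraction`` of samples is discarded as equilibration before
    time-averaging.  Dissociation events are counted in windows of
    ``dissociation_window`` steps and averaged.  The threshold is the Es
    where the time-averaged normalized ACO crosses 0.5 (linear
    interpolation); an Es point whose ACO still trends over the last third
    of the run is flagged non-equilibrated.
    """
    es_grid_kT = np.asarray(list(es_grid_kT), dtype=float)
    if not np.all(np.diff(es_grid_kT) > 0):
        raise InvalidInputError("Es grid must be strictly increasing")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * es_grid_kT.size) % (2**31)
    kt = KB * config.T

    aco_mean = np.empty(es_grid_kT.size)
    sat_mean = np.empty(es_grid_kT.size)
    dis_mean = np.empty(es_grid_kT.size)
    noneq = np.zeros(es_grid_kT.size, dtype=bool)
    tables = []
    for k, es in enumerate(es_grid_kT):
        st = state.copy()
        st.step = 0
        p = replace(params, Es=es * kt)
        cfg = replace(
            config,
            n_steps=0,
            thermo_every=0,
            dump_every=0,
            restart_every=0,
            seed_thermostat=int(seeds[2 * k]),
            seed_bonds=int(seeds[2 * k + 1]),
        )
        rng = None
        samples = []
        logs = []
        done = 0
        while done < steps_per_es:
            seg = min(sample_every, steps_per_es - done)
            res = run(
                st,
                topology,
                p,
                replace(cfg, n_steps=seg),
                rule=rule,
                record_events=True,
                rng=rng,
            )
            rng = res.rng
            logs.append(res.events)
            done += seg
            cs = cluster_components(st, topology)
            samples.append(
                (st.step, cs.aco_normalized, sticker_saturation(st, topology))
            )
        tab = pd.DataFrame(samples, columns=["step", "aco_normalized", "saturation"])
        tables.append(tab)
        events = BondEventLog.concat(logs)
        n_keep = max(1, int(np.ceil(len(tab) * (1.0 - discard_fraction))))
        kept = tab.iloc[len(tab) - n_keep :]
        aco_mean[k] = kept["aco_normalized"].mean()
        sat_mean[k] = kept["saturation"].mean()
        counts = dissociation_series(
            events, window=min(dissociation_window, steps_per_es), span=steps_per_es
        )
        dis_mean[k] = counts.mean()
        last_third = tab.iloc[2 * len(tab) // 3 :]
        if len(last_third) >= 3 and np.ptp(last_third["step"].to_numpy()) > 0:
            fit = linear_fit(
                last_third["step"].to_numpy(), last_third["aco_normalized"].to_numpy()
            )
            drift = abs(fit.slope) * np.ptp(last_third["step"].to_numpy())
            noneq[k] = drift > 0.1
    threshold = interpolate_threshold(es_grid_kT, aco_mean)
    return TitrationResult(
        es_grid_kT=es_grid_kT,
        aco_normalized=aco_mean,
        saturation=sat_mean,
        dissociation_counts=dis_mean,
        threshold_kT=threshold,
        non_equilibrated=noneq,
        tables=tables,
    )
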