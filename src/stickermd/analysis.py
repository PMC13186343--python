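"""Observables: Rg, sticker saturation, cluster statistics (ACO),
dissociation kinetics, radial profiles, MSD/diffusion, regression helpers.

Cluster statistics follow the chain-graph picture: one node per chain, one
edge per active inter-chain sticker bond, connected components = clusters.
The average cluster occupancy (ACO) is the size-weighted mean cluster size

    ACO = sum_i f_i S_i = (1/N_total) sum_i n_i S_i**2,

with f_i = n_i S_i / N_total the fraction of chains living in clusters of
size S_i.  Normalizing by the chain count maps it to [1/N, 1]: 1/N for a
fully dispersed system, 1 when every chain joins a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .polymer_setup import ChainTopology, SystemState
from .units import FTM2V, KB

__all__ = [
    "ClusterStats",
    "RadialProfile",
    "MSDFit",
    "RegressionResult",
    "radius_of_gyration",
    "system_rg",
    "sticker_saturation",
    "cluster_components",
    "aco",
    "dissociation_series",
    "radial_profile",
    "msd_diffusion",
    "linear_fit",
]


@dataclass
class RegressionResult:
    """Ordinary least-squares line fit with a two-sided slope t-test."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


@dataclass
class ClusterStats:
    """Cluster-size distribution summary for one configuration."""

    sizes: np.ndarray  # distinct cluster sizes S_i (chains)
    counts: np.ndarray  # number of clusters n_i of each size
    fractions: np.ndarray  # f_i = n_i S_i / N_total
    aco: float
    aco_normalized: float
    n_total: int

    @classmethod
    def from_component_sizes(cls, component_sizes, n_total=None) -> "ClusterStats":
        component_sizes = np.asarray(component_sizes, dtype=np.int64)
        if n_total is None:
            n_total = int(component_sizes.sum())
        sizes, counts = np.unique(component_sizes, return_counts=True)
        a, a_norm = aco(component_sizes, n_total)
        return cls(
            sizes=sizes,
            counts=counts,
            fractions=counts * sizes / n_total,
            aco=a,
            aco_normalized=a_norm,
            n_total=n_total,
        )


@dataclass
class RadialProfile:
    """Shell number densities about a cluster's center of mass."""

    bin_edges: np.ndarray  # (B+1,) Å
    sticker_density: np.ndarray  # (B,) beads/Å^3
    spacer_density: np.ndarray  # (B,) beads/Å^3
    sticker_counts: np.ndarray
    spacer_counts: np.ndarray


@dataclass
class MSDFit:
    """Origin-averaged MSD curve and Einstein-relation diffusion fit."""

    lag_times: np.ndarray  # fs
    msd: np.ndarray  # Å^2
    D: float  # Å^2/fs
    fit: RegressionResult
    loglog_slope: float  # ~1 diffusive, ~2 ballistic
    fit_window: tuple


# ---------------------------------------------------------------------------
# Scalar observables
# ---------------------------------------------------------------------------


def radius_of_gyration(positions) -> float:
    """Root-mean-square distance of beads from their centroid.

    Positions must be unwrapped (image-flag corrected) coordinates; a
    single bead gives 0.
    """
    p = np.asarray(positions, dtype=float).reshape(-1, 3)
    if p.shape[0] == 0:
        raise InvalidInputError("radius_of_gyration of an empty selection")
    d = p - p.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def system_rg(state: SystemState) -> float:
    """System-wide Rg over all beads, computed on unwrapped coordinates."""
    return radius_of_gyration(state.unwrapped_positions())


def sticker_saturation(state: SystemState, topology: ChainTopology) -> float:
    """Fraction of stickers currently in the bonded state."""
    idx = topology.sticker_indices
    if idx.size == 0:
        raise InvalidInputError("system has no stickers")
    return float(np.count_nonzero(state.pairing[idx] != -1) / idx.size)


# ---------------------------------------------------------------------------
# Cluster statistics
# ---------------------------------------------------------------------------


def chain_bond_graph(state: SystemState, topology: ChainTopology) -> nx.Graph:
    """Graph with one node per chain and an edge per inter-chain sticker bond."""
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_chains))
    cid = topology.chain_ids
    for i in topology.sticker_indices:
        j = state.pairing[i]
        if j > i and cid[i] != cid[j]:
            g.add_edge(int(cid[i]), int(cid[j]))
    return g


def cluster_components(state: SystemState, topology: ChainTopology) -> ClusterStats:
    """Connected-component cluster sizes from the current pairing table.

    Intra-chain sticker bonds create no edge; an isolated chain is a
    cluster of size 1.
    """
    g = chain_bond_graph(state, topology)
    sizes = [len(c) for c in nx.connected_components(g)]
    return ClusterStats.from_component_sizes(sizes, n_total=topology.n_chains)


def aco(component_sizes, n_total: int):
    """Average cluster occupancy and its chain-count-normalized form.

    ``component_sizes`` is the multiset of cluster sizes (in chains);
    ACO = (1/N_total) * sum S_i^2 over clusters, normalized = ACO/N_total.
    """
    s = np.asarray(component_sizes, dtype=float)
    if s.size and int(s.sum()) != int(n_total):
        raise InvalidInputError(
            f"cluster sizes sum to {int(s.sum())}, expected N_total = {n_total}"
        )
    if n_total <= 0:
        raise InvalidInputError("n_total must be positive")
    a = float((s * s).sum() / n_total)
    return a, a / n_total


def dissociation_series(
    events, window: int = 1_000_000, span: int | None = None
) -> np.ndarray:
    """Break-event counts per consecutive step window.

    ``events`` is a :class:`BondEventLog` (or an array of break steps);
    ``span`` extends/limits the covered range (defaults to the last event).
    """
    if hasattr(events, "break_steps"):
        steps = np.asarray(events.break_steps)
    else:
        steps = np.asarray(events, dtype=np.int64)
    if span is None:
        span = int(steps.max()) + 1 if steps.size else window
    n_windows = max(1, int(np.ceil(span / window)))
    edges = np.arange(n_windows + 1) * window
    counts, _ = np.histogram(steps, bins=edges)
    return counts


# ---------------------------------------------------------------------------
# Spatial structure
# ---------------------------------------------------------------------------


def unwrap_cluster(
    state: SystemState, topology: ChainTopology, member_chains
) -> np.ndarray:
    """Minimum-image-consistent coordinates for one cluster's beads.

    Breadth-first traversal over backbone bonds and active sticker bonds,
    placing each newly visited bead at the minimum-image position relative
    to its parent, so a cluster spanning the periodic boundary becomes
    spatially contiguous.  Returns (member bead indices, coordinates).
    """
    member_chains = set(int(c) for c in member_chains)
    mask = np.isin(topology.chain_ids, list(member_chains))
    members = np.flatnonzero(mask)
    if members.size == 0:
        raise InvalidInputError("empty cluster selection")
    adj = {int(i): [] for i in members}
    for i, j in topology.permanent_bonds:
        if mask[i] and mask[j]:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
    for i in topology.sticker_indices:
        j = int(state.pairing[i])
        if j != -1 and mask[i] and mask[j]:
            adj[int(i)].append(j)
            adj[j].append(int(i))
    box = state.box
    pos = state.positions
    coords = np.zeros((members.size, 3))
    local = {int(b): k for k, b in enumerate(members)}
    seen = set()
    for root in members:
        root = int(root)
        if root in seen:
            continue
        coords[local[root]] = pos[root]
        seen.add(root)
        queue = [root]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb in seen:
                    continue
                d = pos[nb] - pos[cur]
                d -= box * np.round(d / box)
                coords[local[nb]] = coords[local[cur]] + d
                seen.add(nb)
                queue.append(nb)
    return members, coords


def radial_profile(
    state: SystemState,
    topology: ChainTopology,
    member_chains,
    bins: int | np.ndarray = 20,
) -> RadialProfile:
    """Sticker and spacer number densities in shells about the cluster COM."""
    members, coords = unwrap_cluster(state, topology, member_chains)
    com = coords.mean(axis=0)
    r = np.linalg.norm(coords - com, axis=1)
    if np.isscalar(bins):
        edges = np.linspace(0.0, max(r.max(), 1e-9) * 1.0000001, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    is_sticker = topology.sticker_mask[members]
    cs, _ = np.histogram(r[is_sticker], bins=edges)
    cp, _ = np.histogram(r[~is_sticker], bins=edges)
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return RadialProfile(
        bin_edges=edges,
        sticker_density=cs / shell_vol,
        spacer_density=cp / shell_vol,
        sticker_counts=cs,
        spacer_counts=cp,
    )


# ---------------------------------------------------------------------------
# Dynamics observables
# ---------------------------------------------------------------------------


def msd_diffusion(
    trajectory,
    selection=None,
    t_damp: float | None = None,
    n_lags: int = 40,
    fit_window: tuple | None = None,
) -> MSDFit:
    """Origin-averaged MSD and Einstein-relation diffusion coefficient.

    Lags are log-spaced; every frame serves as a time origin.  The
    diffusive-regime fit uses ``MSD = 6 D t`` over ``fit_window`` (fs); the
    default window starts at 10·t_damp (past the ballistic regime) when
    ``t_damp`` is given, else at a tenth of the trajectory length.  A
    log-log slope near 2 flags ballistic (non-diffusive) input.
    """
    if trajectory.n_frames < 2:
        raise InvalidInputError("trajectory must contain at least 2 frames")
    pos = trajectory.unwrapped()
    if selection is not None:
        pos = pos[:, np.asarray(selection)]
    nf = pos.shape[0]
    lags = np.unique(
        np.round(np.logspace(0, np.log10(nf - 1), n_lags)).astype(int)
    )
    lags = lags[(lags >= 1) & (lags < nf)]
    msd = np.empty(lags.size)
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[k] = float((d * d).sum(axis=2).mean())
    # frame spacing in fs
    dt_frame = float(np.diff(trajectory.steps).mean()) * trajectory.dt
    lag_t = lags * dt_frame
    if fit_window is None:
        tmin = 10.0 * t_damp if t_damp is not None else lag_t[-1] / 10.0
        fit_window = (tmin, np.inf)
    sel = (lag_t >= fit_window[0]) & (lag_t <= fit_window[1])
    if sel.sum() < 3:
        sel = np.ones_like(lag_t, dtype=bool)
    fit = linear_fit(lag_t[sel], msd[sel])
    pos_mask = msd > 0
    if pos_mask.sum() >= 3 and np.ptp(np.log(lag_t[pos_mask])) > 0:
        ll = linear_fit(np.log(lag_t[pos_mask]), np.log(msd[pos_mask]))
        loglog = ll.slope
    else:
        loglog = np.nan
    D = max(fit.slope, 0.0) / 6.0
    return MSDFit(
        lag_times=lag_t,
        msd=msd,
        D=D,
        fit=fit,
        loglog_slope=loglog,
        fit_window=(fit_window[0], min(fit_window[1], lag_t[-1])),
    )


def free_particle_diffusion(T: float, t_damp: float, mass: float) -> float:
    """Analytic Langevin free-particle diffusion coefficient kT·t_damp/m (Å²/fs)."""
    return KB * T * FTM2V * t_damp / mass


def linear_fit(x, y) -> RegressionResult:
    """Least-squares line with R² and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InvalidInputError("linear_fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise InvalidInputError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )
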