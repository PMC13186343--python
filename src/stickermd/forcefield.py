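"""Potential-energy terms, analytic forces, and neighbor search.

The force field has four terms:

* permanent backbone bonds — harmonic, ``E = Kb (R - R0)**2``;
* bending — cosine angle, ``E = kappa (1 - cos theta)`` with ``theta`` the
  deviation from a straight chain (zero energy for collinear beads);
* reversible sticker bonds — shifted harmonic well,
  ``E = Es / (R0 - Rcut)**2 * ((R - R0)**2 - (Rcut - R0)**2)`` for
  ``R < Rcut`` and zero beyond, so the well depth at ``R0`` is ``-Es`` and
  the potential vanishes continuously at the cutoff;
* non-specific cohesion — Lennard-Jones, truncated (unshifted) at ``Rmax``.

LJ exclusions follow the ``lj 0 1 1`` convention: only directly bonded
pairs (permanent 1-2 neighbors and currently bonded sticker pairs) feel no
LJ; 1-3 and 1-4 pairs interact at full strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import InvalidInputError, OverlapError
from .units import KB

__all__ = [
    "ForceFieldParams",
    "EnergyBreakdown",
    "NeighborList",
    "harmonic_bond",
    "cosine_angle",
    "lj_pair",
    "sticker_bond",
    "build_neighbor_list",
    "total_energy_forces",
]


@dataclass
class ForceFieldParams:
    """All force-field constants, in kcal/mol and Å.

    Defaults are the standard parameterization for 10 Å beads at 310 K:
    ``Kb = 3`` kcal/mol/Ų, ``R0_bond = 10`` Å, ``kappa = 2`` kcal/mol,
    ``sigma = 10`` Å, ``Rmax = 2.5 sigma``, sticker rest length
    ``R0_stick = 1.122 sigma`` and ``Rcut_stick = R0_stick + 1.5`` Å, with
    bond moves accepted deterministically (``p_on = p_off = 1``).
    """

    Kb: float = 3.0
    R0_bond: float = 10.0
    kappa: float = 2.0
    sigma: float = 10.0
    Ens: float = 0.3 * KB * 310.0
    Rmax: float = 25.0
    Es: float = 6.0 * KB * 310.0
    R0_stick: float = 11.22
    Rcut_stick: float = 12.72
    p_on: float = 1.0
    p_off: float = 1.0

    def __post_init__(self):
        if self.Rcut_stick <= self.R0_stick:
            raise InvalidInputError("Rcut_stick must exceed R0_stick")
        if self.Rmax <= self.sigma:
            raise InvalidInputError("Rmax must exceed sigma")
        for name in ("Kb", "kappa", "Ens", "Es"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be a nonnegative well depth")
        for name in ("p_on", "p_off"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_kT(
        cls, es_kT: float = 6.0, ens_kT: float = 0.3, temperature: float = 310.0, **kw
    ) -> "ForceFieldParams":
        """Build parameters with Es and Ens given in units of kT at ``temperature``."""
        kt = KB * temperature
        return cls(Es=es_kT * kt, Ens=ens_kT * kt, **kw)

    def with_es_kT(self, es_kT: float, temperature: float = 310.0) -> "ForceFieldParams":
        return replace(self, Es=es_kT * KB * temperature)


@dataclass
class EnergyBreakdown:
    """Potential-energy decomposition in kcal/mol.

    ``E_bond`` includes permanent backbone bonds and active sticker bonds;
    ``E_potential`` is always the sum of the three terms.
    """

    E_bond: float
    E_pair: float
    E_angle: float

    @property
    def E_potential(self) -> float:
        return self.E_bond + self.E_pair + self.E_angle


@dataclass
class NeighborList:
    """Half pair list (i < j) within ``Rmax + skin`` under minimum image."""

    pairs: np.ndarray  # (P, 2) int64
    rlist: float
    positions: np.ndarray = field(repr=False)  # snapshot at build time


# ---------------------------------------------------------------------------
# Closed-form terms (scalar or vectorized over separations)
# ---------------------------------------------------------------------------


def harmonic_bond(R, Kb: float, R0_bond: float):
    """Harmonic stretching energy and scalar force.

    Returns ``(E, F)`` with ``E = Kb (R - R0)**2`` and ``F = -dE/dR``.
    """
    R = np.asarray(R, dtype=float)
    dr = R - R0_bond
    return Kb * dr * dr, -2.0 * Kb * dr


def cosine_angle(theta, kappa: float):
    """Cosine bending energy and restoring torque magnitude.

    ``theta`` is the deviation from collinearity, in radians: a straight
    chain has ``theta = 0`` and zero energy.  Returns
    ``(kappa (1 - cos theta), -dE/dtheta)``.
    """
    theta = np.asarray(theta, dtype=float)
    return kappa * (1.0 - np.cos(theta)), -kappa * np.sin(theta)


def lj_pair(r, Ens: float, sigma: float, Rmax: float):
    """Truncated (unshifted) Lennard-Jones energy and scalar force.

    Zero energy and force beyond ``Rmax``; raises :class:`OverlapError` for
    numerically zero separations.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1e-6):
        raise OverlapError("zero separation in LJ pair")
    sr6 = (sigma / r) ** 6
    e = 4.0 * Ens * (sr6 * sr6 - sr6)
    f = 24.0 * Ens * (2.0 * sr6 * sr6 - sr6) / r
    inside = r <= Rmax
    return np.where(inside, e, 0.0), np.where(inside, f, 0.0)


def sticker_bond(R, Es: float, R0_stick: float, Rcut_stick: float):
    """Shifted-harmonic specific-bond energy and scalar force.

    ``E = Es/(R0-Rcut)**2 * ((R-R0)**2 - (Rcut-R0)**2)`` for ``R < Rcut``;
    zero for ``R >= Rcut``.  The well depth at ``R0_stick`` is ``-Es`` and
    the energy crosses zero exactly at the cutoff.
    """
    R = np.asarray(R, dtype=float)
    pref = Es / (R0_stick - Rcut_stick) ** 2
    well = (Rcut_stick - R0_stick) ** 2
    dr = R - R0_stick
    e = pref * (dr * dr - well)
    f = -2.0 * pref * dr
    inside = R < Rcut_stick
    return np.where(inside, e, 0.0), np.where(inside, f, 0.0)


# ---------------------------------------------------------------------------
# System-level evaluation
# ---------------------------------------------------------------------------


def build_neighbor_list(state, Rmax: float, skin: float = 3.0) -> NeighborList:
    """Half pair list of all bead pairs within ``Rmax + skin``.

    Uses linked cells when the box admits at least 3 cells per dimension
    and falls back to an exact all-pairs scan otherwise, so the result is
    always a superset of the pairs within ``Rmax`` under minimum image.
    """
    rlist = Rmax + skin
    nb_i, nb_j = _kernels._build_neighbors(
        np.ascontiguousarray(state.positions), state.box.astype(float), rlist
    )
    return NeighborList(
        pairs=np.column_stack([nb_i, nb_j]),
        rlist=rlist,
        positions=state.positions.copy(),
    )


def total_energy_forces(state, topology, params: ForceFieldParams):
    """Forces and energy breakdown for a full system configuration.

    Returns ``(forces, EnergyBreakdown)`` where ``forces`` is an (N, 3)
    array of exact negative gradients in kcal/(mol·Å).  E_bond sums the
    permanent harmonic bonds and the currently active sticker bonds; LJ is
    excluded for directly bonded pairs only.
    """
    pos = np.ascontiguousarray(state.positions)
    box = state.box.astype(float)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    if params.Ens > 0.0:
        nb_i, nb_j = _kernels._build_neighbors(pos, box, params.Rmax + 1e-9)
    else:
        nb_i = np.empty(0, np.int64)
        nb_j = np.empty(0, np.int64)
    bonds = topology.permanent_bonds
    angles = topology.angles
    eb, ep, ea, err = _kernels._compute_forces(
        pos,
        box,
        f,
        np.ascontiguousarray(bonds[:, 0]),
        np.ascontiguousarray(bonds[:, 1]),
        params.Kb,
        params.R0_bond,
        np.ascontiguousarray(angles[:, 0]),
        np.ascontiguousarray(angles[:, 1]),
        np.ascontiguousarray(angles[:, 2]),
        params.kappa,
        nb_i,
        nb_j,
        params.Ens,
        params.sigma,
        params.Rmax,
        state.pairing,
        topology.perm_neighbor1,
        topology.perm_neighbor2,
        params.Es,
        params.R0_stick,
        params.Rcut_stick,
    )
    if err == _kernels.ERR_OVERLAP:
        raise OverlapError("overlapping beads in LJ evaluation")
    return f, EnergyBreakdown(E_bond=eb, E_pair=ep, E_angle=ea)
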