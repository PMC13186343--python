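"""Chain construction, box packing, and data/restart file I/O.

A chain is defined by a :class:`BlockTemplate` — an ordered pattern of bead
roles (``"spacer"`` or a sticker-type label such as ``"A"``) repeated a
given number of times.  :func:`build_chain` expands the template into a
linear :class:`ChainTopology`; :func:`pack_system` instantiates many copies
of one or more chain types inside a periodic box as self-avoiding random
walks.

On-disk formats:

* a LAMMPS-style "molecular" data file (Atoms/Bonds/Angles sections, plus
  Masses and Coeffs) for interoperability — active sticker bonds are
  written as bond type 2 so the reversible pairing survives a round trip;
* an internal versioned text restart that restores positions, velocities,
  image flags, the pairing table, the step counter and (optionally) the
  random-stream states exactly, so a resumed run continues bit-for-bit.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import IntegrityError, InvalidInputError, PackingError, ParseError

__all__ = [
    "SPACER",
    "BlockTemplate",
    "ChainTopology",
    "ComplementarityRule",
    "SystemState",
    "build_chain",
    "pack_system",
    "two_component_templates",
    "write_data_file",
    "read_data_file",
    "write_restart",
    "read_restart",
]

SPACER = "spacer"

RESTART_MAGIC = "STICKERMD RESTART v1"


@dataclass(frozen=True)
class BlockTemplate:
    """Sticker-spacer building block repeated ``repeat_count`` times."""

    roles: tuple
    repeat_count: int

    def __post_init__(self):
        object.__setattr__(self, "roles", tuple(self.roles))
        if len(self.roles) == 0:
            raise InvalidInputError("block template must contain at least one role")
        if int(self.repeat_count) < 1:
            raise InvalidInputError("repeat_count must be >= 1")
        object.__setattr__(self, "repeat_count", int(self.repeat_count))

    @property
    def n_beads(self) -> int:
        return len(self.roles) * self.repeat_count


def two_component_templates(
    block_length: int = 5, repeats: int = 10, labels=("A", "B")
):
    """The standard two-component system: one sticker leading each block.

    With the defaults each template expands to a 50-bead chain carrying 10
    uniformly spaced stickers.
    """
    out = []
    for lab in labels:
        roles = (lab,) + (SPACER,) * (block_length - 1)
        out.append(BlockTemplate(roles=roles, repeat_count=repeats))
    return tuple(out)


class ChainTopology:
    """Beads, permanent bonds, angle triplets and chain membership.

    Holds either a single chain (output of :func:`build_chain`) or a whole
    multi-chain system (output of :func:`pack_system`).  Bonds connect
    consecutive beads within a chain only; angles are consecutive triplets.
    """

    def __init__(self, roles, chain_ids, permanent_bonds, angles):
        self.roles = list(roles)
        self.chain_ids = np.asarray(chain_ids, dtype=np.int64)
        self.permanent_bonds = np.asarray(permanent_bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
        if len(self.roles) != self.chain_ids.size:
            raise InvalidInputError("roles and chain_ids disagree on bead count")
        self._build_derived()

    def _build_derived(self):
        n = self.n_beads
        self.perm_neighbor1 = np.full(n, -1, dtype=np.int64)
        self.perm_neighbor2 = np.full(n, -1, dtype=np.int64)
        for i, j in self.permanent_bonds:
            if self.perm_neighbor1[i] == -1:
                self.perm_neighbor1[i] = j
            else:
                self.perm_neighbor2[i] = j
            if self.perm_neighbor1[j] == -1:
                self.perm_neighbor1[j] = i
            else:
                self.perm_neighbor2[j] = i
        self.sticker_mask = np.array([r != SPACER for r in self.roles], dtype=bool)
        self.sticker_indices = np.flatnonzero(self.sticker_mask).astype(np.int64)
        self.sticker_labels = sorted({r for r in self.roles if r != SPACER})
        label_code = {lab: k for k, lab in enumerate(self.sticker_labels)}
        self.sticker_type = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.roles):
            if r != SPACER:
                self.sticker_type[i] = label_code[r]

    # -- convenience -------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.roles)

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1 if self.chain_ids.size else 0

    @property
    def stickers(self) -> dict:
        """Bead-index array per sticker-type label."""
        return {
            lab: np.flatnonzero(
                [r == lab for r in self.roles]
            ).astype(np.int64)
            for lab in self.sticker_labels
        }

    def beads(self):
        """Iterate (bead index, role, chain id)."""
        for i, r in enumerate(self.roles):
            yield i, r, int(self.chain_ids[i])


@dataclass(frozen=True)
class ComplementarityRule:
    """Unordered sticker-type label pairs allowed to form a specific bond."""

    allowed: frozenset

    @classmethod
    def from_pairs(cls, pairs) -> "ComplementarityRule":
        return cls(allowed=frozenset(frozenset(p) for p in pairs))

    @classmethod
    def heterotypic(cls, labels=("A", "B")) -> "ComplementarityRule":
        """Only unlike types bind (A-B allowed, A-A and B-B forbidden)."""
        out = set()
        labels = list(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                out.add(frozenset((a, b)))
        return cls(allowed=frozenset(out))

    def allows(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.allowed

    def matrix(self, labels) -> np.ndarray:
        """Boolean compatibility matrix over ``labels`` (sorted sticker types)."""
        t = len(labels)
        m = np.zeros((t, t), dtype=bool)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                m[i, j] = self.allows(a, b)
        return m


@dataclass
class SystemState:
    """Dynamic state: wrapped positions, image flags, velocities, pairing.

    ``pairing[i]`` is the bead index of sticker i's current partner, or -1;
    the table is kept symmetric and every sticker has at most one partner
    (valency 1).  Positions are wrapped into ``[0, box)``; unwrapped
    coordinates are ``positions + images * box``.
    """

    box: np.ndarray
    positions: np.ndarray
    images: np.ndarray
    velocities: np.ndarray
    pairing: np.ndarray
    step: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.images = np.ascontiguousarray(self.images, dtype=np.int64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.pairing = np.ascontiguousarray(self.pairing, dtype=np.int64)

    @classmethod
    def empty(cls, n: int, box) -> "SystemState":
        return cls(
            box=np.asarray(box, dtype=float),
            positions=np.zeros((n, 3)),
            images=np.zeros((n, 3), dtype=np.int64),
            velocities=np.zeros((n, 3)),
            pairing=np.full(n, -1, dtype=np.int64),
            step=0,
        )

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box

    def copy(self) -> "SystemState":
        return SystemState(
            box=self.box.copy(),
            positions=self.positions.copy(),
            images=self.images.copy(),
            velocities=self.velocities.copy(),
            pairing=self.pairing.copy(),
            step=self.step,
        )

    def check_pairing(self):
        """Raise if the pairing table is asymmetric."""
        for i, j in enumerate(self.pairing):
            if j != -1 and self.pairing[j] != i:
                raise InvalidInputError(
                    f"pairing table asymmetric: {i} -> {j} but {j} -> {self.pairing[j]}"
                )


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------


def build_chain(template: BlockTemplate) -> ChainTopology:
    """Expand a block template into a single linear chain.

    The chain has ``len(roles) * repeat_count`` beads, a permanent bond
    between every pair of consecutive beads and an angle on every
    consecutive triplet.
    """
    if not isinstance(template, BlockTemplate):
        template = BlockTemplate(*template)
    roles = list(template.roles) * template.repeat_count
    n = len(roles)
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]) if n > 1 else np.empty((0, 2), np.int64)
    angles = (
        np.column_stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)])
        if n > 2
        else np.empty((0, 3), np.int64)
    )
    return ChainTopology(
        roles=roles, chain_ids=np.zeros(n, dtype=np.int64), permanent_bonds=bonds, angles=angles
    )


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------


def _merge_topologies(chain_specs) -> ChainTopology:
    roles = []
    chain_ids = []
    bonds = []
    angles = []
    offset = 0
    cid = 0
    for topo, count in chain_specs:
        if topo.n_chains != 1:
            raise InvalidInputError("pack_system expects single-chain topologies")
        for _ in range(count):
            roles.extend(topo.roles)
            chain_ids.append(np.full(topo.n_beads, cid, dtype=np.int64))
            if topo.permanent_bonds.size:
                bonds.append(topo.permanent_bonds + offset)
            if topo.angles.size:
                angles.append(topo.angles + offset)
            offset += topo.n_beads
            cid += 1
    return ChainTopology(
        roles=roles,
        chain_ids=np.concatenate(chain_ids) if chain_ids else np.empty(0, np.int64),
        permanent_bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), np.int64),
        angles=np.concatenate(angles) if angles else np.empty((0, 3), np.int64),
    )


def pack_system(
    chain_specs,
    box,
    min_separation: float = 10.0,
    seed: int = 0,
    bond_length: float = 10.0,
    max_chain_attempts: int = 400,
    max_bead_tries: int = 80,
):
    """Place chain copies in a periodic box as self-avoiding random walks.

    ``chain_specs`` is a list of ``(ChainTopology, copy_count)`` pairs.
    Consecutive beads sit at ``bond_length``; all inter-chain bead pairs
    (and intra-chain pairs more than one bond apart, slightly relaxed for
    1-3 neighbors) respect ``min_separation`` under minimum image.  The
    walk is seed-reproducible; exceeding the attempt budget raises
    :class:`PackingError`.

    Returns ``(SystemState, ChainTopology)`` — the packed state (zero
    velocities, empty pairing) and the merged multi-chain topology.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    topo = _merge_topologies(chain_specs)
    n_total = topo.n_beads
    if n_total == 0:
        raise InvalidInputError("nothing to pack")

    # coarse feasibility bound: non-overlapping spheres of radius min_sep/2
    vol = float(np.prod(box))
    sphere = (4.0 / 3.0) * np.pi * (min_separation / 2.0) ** 3
    if n_total >= 2 and (
        n_total * sphere > 0.55 * vol
        or min_separation > float(np.linalg.norm(box / 2.0))
    ):
        raise PackingError(
            f"cannot place {n_total} beads at min separation {min_separation} Å "
            f"in a {box[0]:g}x{box[1]:g}x{box[2]:g} Å box"
        )

    rng = np.random.default_rng(seed)
    placed = []  # wrapped coordinates of committed chains
    tree = None
    unwrapped_all = []

    intra3 = 0.8 * min_separation  # relaxed bound for 1-3 neighbors

    for topo_c, count in chain_specs:
        nb = topo_c.n_beads
        for _ in range(count):
            ok = False
            for _attempt in range(max_chain_attempts):
                walk = np.empty((nb, 3))
                walk[0] = rng.random(3) * box
                good = _bead_ok(walk[0], walk[:0], tree, box, min_separation, intra3)
                if not good:
                    continue
                failed = False
                for k in range(1, nb):
                    placed_bead = False
                    for _try in range(max_bead_tries):
                        v = rng.normal(size=3)
                        v /= np.linalg.norm(v)
                        cand = walk[k - 1] + bond_length * v
                        if _bead_ok(cand, walk[:k], tree, box, min_separation, intra3):
                            walk[k] = cand
                            placed_bead = True
                            break
                    if not placed_bead:
                        failed = True
                        break
                if not failed:
                    ok = True
                    break
            if not ok:
                raise PackingError(
                    f"failed to place a {nb}-bead chain after "
                    f"{max_chain_attempts} attempts (density too high?)"
                )
            unwrapped_all.append(walk)
            placed.append(walk - np.floor(walk / box) * box)
            pts = np.concatenate(placed)
            # KD-tree over committed beads, periodic in the box
            tree = cKDTree(np.mod(pts, box), boxsize=box)

    coords = np.concatenate(unwrapped_all)
    state = SystemState.empty(n_total, box)
    state.images = np.floor(coords / box).astype(np.int64)
    state.positions = coords - state.images * box
    return state, topo


def _bead_ok(cand, own_prior, tree, box, min_sep, intra3):
    """Check a candidate bead against committed chains and its own chain."""
    p = np.mod(cand, box)
    if tree is not None and tree.query_ball_point(p, min_sep, return_length=True) > 0:
        return False
    k = own_prior.shape[0]
    if k >= 2:
        d = own_prior[: k - 1] - cand  # skip the directly bonded predecessor
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        lim = np.full(k - 1, min_sep)
        lim[-1] = intra3  # 1-3 neighbor: allow moderate bending
        if np.any(r < lim):
            return False
    return True


# ---------------------------------------------------------------------------
# LAMMPS-style data file
# ---------------------------------------------------------------------------

_FLOAT = "%.17g"


def _role_types(topology: ChainTopology):
    """Stable atom-type numbering: spacer first, then sorted sticker labels."""
    labels = []
    if any(r == SPACER for r in topology.roles):
        labels.append(SPACER)
    labels.extend(topology.sticker_labels)
    return {lab: t + 1 for t, lab in enumerate(labels)}, labels


def write_data_file(state: SystemState, topology: ChainTopology, params, path, mass: float = 100.0):
    """Write a LAMMPS-style "molecular" data file.

    Bond type 1 holds the permanent backbone bonds; active sticker bonds
    are emitted as bond type 2 so the reversible pairing round-trips.
    Force-field constants go into Coeffs sections; ``p_on``/``p_off`` (which
    have no LAMMPS section) ride in the title comment.  Output is a pure
    function of the inputs, so identical inputs give byte-identical files.
    """
    if state.n_beads != topology.n_beads:
        raise InvalidInputError("state and topology disagree on bead count")
    state.check_pairing()
    type_of, labels = _role_types(topology)
    n = state.n_beads
    sticker_pairs = [
        (i, int(j)) for i, j in enumerate(state.pairing) if j > i
    ]
    n_bonds = topology.permanent_bonds.shape[0] + len(sticker_pairs)
    n_bond_types = 2
    buf = io.StringIO()
    w = buf.write
    w(
        "# stickermd data file v1 p_on=%s p_off=%s step=%d\n\n"
        % (_FLOAT % params.p_on, _FLOAT % params.p_off, state.step)
    )
    w(f"{n} atoms\n{n_bonds} bonds\n{topology.angles.shape[0]} angles\n\n")
    w(f"{len(labels)} atom types\n{n_bond_types} bond types\n1 angle types\n\n")
    for d, (lo, name) in enumerate(zip((0.0, 0.0, 0.0), ("x", "y", "z"))):
        w(f"{_FLOAT % lo} {_FLOAT % state.box[d]} {name}lo {name}hi\n")
    w("\nMasses\n\n")
    for lab in labels:
        w(f"{type_of[lab]} {_FLOAT % mass}  # {lab}\n")
    w("\nBond Coeffs  # 1: harmonic (Kb R0), 2: shifted-harmonic sticker (Es R0 Rcut)\n\n")
    w(f"1 {_FLOAT % params.Kb} {_FLOAT % params.R0_bond}\n")
    w(f"2 {_FLOAT % params.Es} {_FLOAT % params.R0_stick} {_FLOAT % params.Rcut_stick}\n")
    w("\nAngle Coeffs  # cosine (kappa)\n\n")
    w(f"1 {_FLOAT % params.kappa}\n")
    w("\nPair Coeffs  # lj/cut (Ens sigma Rmax)\n\n")
    for lab in labels:
        w(f"{type_of[lab]} {_FLOAT % params.Ens} {_FLOAT % params.sigma} {_FLOAT % params.Rmax}\n")
    w("\nAtoms  # molecular: id mol type x y z ix iy iz\n\n")
    for i in range(n):
        x, y, z = state.positions[i]
        ix, iy, iz = state.images[i]
        w(
            f"{i + 1} {topology.chain_ids[i] + 1} {type_of[topology.roles[i]]} "
            f"{_FLOAT % x} {_FLOAT % y} {_FLOAT % z} {ix} {iy} {iz}\n"
        )
    w("\nBonds\n\n")
    bid = 1
    for i, j in topology.permanent_bonds:
        w(f"{bid} 1 {i + 1} {j + 1}\n")
        bid += 1
    for i, j in sticker_pairs:
        w(f"{bid} 2 {i + 1} {j + 1}\n")
        bid += 1
    w("\nAngles\n\n")
    for a, (i, j, k) in enumerate(topology.angles, start=1):
        w(f"{a} 1 {i + 1} {j + 1} {k + 1}\n")
    w("\nVelocities\n\n")
    for i in range(n):
        vx, vy, vz = state.velocities[i]
        w(f"{i + 1} {_FLOAT % vx} {_FLOAT % vy} {_FLOAT % vz}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_data_file(path):
    """Parse a data file written by :func:`write_data_file`.

    Returns ``(SystemState, ChainTopology, ForceFieldParams)``.  Raises
    :class:`ParseError` (with the line number) on malformed content, e.g.
    a bond referencing a missing atom id.
    """
    from .forcefield import ForceFieldParams  # local import to avoid a cycle

    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError("empty data file", 1)

    header = lines[0]
    m = re.search(r"p_on=([\d.eE+-]+)\s+p_off=([\d.eE+-]+)(?:\s+step=(\d+))?", header)
    p_on, p_off = (float(m.group(1)), float(m.group(2))) if m else (1.0, 1.0)
    step = int(m.group(3)) if m and m.group(3) else 0

    counts = {}
    box = np.zeros(3)
    section = None
    sec_start = {}
    known = ("Masses", "Bond Coeffs", "Angle Coeffs", "Pair Coeffs", "Atoms", "Bonds", "Angles", "Velocities")
    for ln, raw in enumerate(lines[1:], start=2):
        stripped = raw.split("#")[0].strip()
        name = raw.strip().split("#")[0].strip()
        if name in known:
            section = name
            sec_start[name] = ln
            continue
        if section is None and stripped:
            toks = stripped.split()
            try:
                if len(toks) == 2 and toks[1] in ("atoms", "bonds", "angles"):
                    counts[toks[1]] = int(toks[0])
                elif len(toks) == 3 and toks[1] == "atom" and toks[2] == "types":
                    counts["atom types"] = int(toks[0])
                elif len(toks) == 3 and toks[2] in ("types",):
                    counts[f"{toks[1]} types"] = int(toks[0])
                elif len(toks) == 4 and toks[2].endswith("lo"):
                    d = "xyz".index(toks[2][0])
                    box[d] = float(toks[1]) - float(toks[0])
            except (ValueError, IndexError):
                raise ParseError(f"malformed header line: {raw.strip()!r}", ln)

    for need in ("atoms", "bonds", "angles"):
        if need not in counts:
            raise ParseError(f"missing '{need}' count in header", 1)
    for need in ("Atoms", "Bonds", "Angles", "Velocities", "Masses"):
        if need not in sec_start:
            raise ParseError(f"missing '{need}' section", len(lines))

    def section_body(name, expected):
        start = sec_start[name]
        rows = []
        ln = start
        for ln, raw in enumerate(lines[start:], start=start + 1):
            bare = raw.split("#")[0].strip()
            if raw.strip().split("#")[0].strip() in known and ln > start + 1:
                break
            if bare:
                rows.append((ln, bare, raw))
            if expected is not None and len(rows) == expected:
                break
        if expected is not None and len(rows) < expected:
            raise ParseError(f"'{name}' section has {len(rows)} rows, expected {expected}", ln)
        return rows

    n = counts["atoms"]
    # Masses: roles from trailing comments
    role_of_type = {}
    for ln, bare, raw in section_body("Masses", counts.get("atom types")):
        toks = bare.split()
        t = int(toks[0])
        cm = raw.split("#", 1)
        role_of_type[t] = cm[1].strip() if len(cm) == 2 and cm[1].strip() else f"type{t}"

    kb = r0b = kappa = None
    es, r0s, rcs = 0.0, 11.22, 12.72
    for ln, bare, _ in section_body("Bond Coeffs", None) if "Bond Coeffs" in sec_start else []:
        toks = bare.split()
        try:
            if int(toks[0]) == 1:
                kb, r0b = float(toks[1]), float(toks[2])
            elif int(toks[0]) == 2:
                es, r0s, rcs = float(toks[1]), float(toks[2]), float(toks[3])
        except (ValueError, IndexError):
            raise ParseError("malformed Bond Coeffs row", ln)
    if "Angle Coeffs" in sec_start:
        for ln, bare, _ in section_body("Angle Coeffs", None):
            kappa = float(bare.split()[1])
    ens = sigma = rmax = None
    if "Pair Coeffs" in sec_start:
        for ln, bare, _ in section_body("Pair Coeffs", None):
            toks = bare.split()
            ens, sigma, rmax = float(toks[1]), float(toks[2]), float(toks[3])
            break
    params = ForceFieldParams(
        Kb=kb if kb is not None else 3.0,
        R0_bond=r0b if r0b is not None else 10.0,
        kappa=kappa if kappa is not None else 2.0,
        sigma=sigma if sigma is not None else 10.0,
        Ens=ens if ens is not None else 0.0,
        Rmax=rmax if rmax is not None else 25.0,
        Es=es,
        R0_stick=r0s,
        Rcut_stick=rcs,
        p_on=p_on,
        p_off=p_off,
    )

    state = SystemState.empty(n, box)
    state.step = step
    roles = [None] * n
    chain_ids = np.zeros(n, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    for ln, bare, _ in section_body("Atoms", n):
        toks = bare.split()
        try:
            i = int(toks[0]) - 1
            if not 0 <= i < n:
                raise ValueError
            chain_ids[i] = int(toks[1]) - 1
            roles[i] = role_of_type.get(int(toks[2]), f"type{toks[2]}")
            state.positions[i] = [float(toks[3]), float(toks[4]), float(toks[5])]
            if len(toks) >= 9:
                state.images[i] = [int(toks[6]), int(toks[7]), int(toks[8])]
            seen[i] = True
        except (ValueError, IndexError):
            raise ParseError(f"malformed Atoms row: {bare!r}", ln)
    if not seen.all():
        raise ParseError("Atoms section does not cover all atom ids", sec_start["Atoms"])

    perm = []
    for ln, bare, _ in section_body("Bonds", counts["bonds"]):
        toks = bare.split()
        try:
            bt, i, j = int(toks[1]), int(toks[2]) - 1, int(toks[3]) - 1
        except (ValueError, IndexError):
            raise ParseError(f"malformed Bonds row: {bare!r}", ln)
        if not (0 <= i < n and 0 <= j < n):
            raise ParseError(f"bond references missing atom id: {bare!r}", ln)
        if bt == 2:
            state.pairing[i] = j
            state.pairing[j] = i
        else:
            perm.append((i, j))

    angles = []
    for ln, bare, _ in section_body("Angles", counts["angles"]):
        toks = bare.split()
        try:
            a, b, c = int(toks[2]) - 1, int(toks[3]) - 1, int(toks[4]) - 1
        except (ValueError, IndexError):
            raise ParseError(f"malformed Angles row: {bare!r}", ln)
        if not (0 <= a < n and 0 <= b < n and 0 <= c < n):
            raise ParseError(f"angle references missing atom id: {bare!r}", ln)
        angles.append((a, b, c))

    for ln, bare, _ in section_body("Velocities", n):
        toks = bare.split()
        try:
            i = int(toks[0]) - 1
            state.velocities[i] = [float(toks[1]), float(toks[2]), float(toks[3])]
        except (ValueError, IndexError):
            raise ParseError(f"malformed Velocities row: {bare!r}", ln)

    topo = ChainTopology(
        roles=roles,
        chain_ids=chain_ids,
        permanent_bonds=np.array(perm, dtype=np.int64).reshape(-1, 2),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
    )
    return state, topo, params


# ---------------------------------------------------------------------------
# Restart files
# ---------------------------------------------------------------------------


def write_restart(state: SystemState, topology: ChainTopology, path, rng: dict | None = None):
    """Write a versioned text restart restoring the dynamic state exactly.

    Floats use 17 significant digits so the float64 round trip is exact.
    ``rng`` may carry the PCG stream states (``{"thermostat": arr,
    "bonds": arr}``) so a resumed run continues bit-for-bit.
    """
    state.check_pairing()
    n = state.n_beads
    with open(path, "w") as fh:
        fh.write(RESTART_MAGIC + "\n")
        fh.write(f"step {state.step}\n")
        fh.write("box %s %s %s\n" % tuple(_FLOAT % v for v in state.box))
        fh.write(f"natoms {n}\n")
        fh.write(f"nchains {topology.n_chains}\n")
        fh.write("positions\n")
        for i in range(n):
            fh.write(" ".join(_FLOAT % v for v in state.positions[i]) + "\n")
        fh.write("images\n")
        for i in range(n):
            fh.write("%d %d %d\n" % tuple(state.images[i]))
        fh.write("velocities\n")
        for i in range(n):
            fh.write(" ".join(_FLOAT % v for v in state.velocities[i]) + "\n")
        fh.write("pairing\n")
        for i in range(n):
            fh.write(f"{state.pairing[i]}\n")
        if rng:
            for name in ("thermostat", "bonds"):
                if name in rng:
                    s = rng[name]
                    fh.write(f"rng_{name} {int(s[0])} {int(s[1])}\n")
        fh.write("end\n")


def read_restart(path):
    """Read a restart file; returns ``(SystemState, rng_dict)``.

    ``rng_dict`` is empty when the file carries no stream states.  A
    truncated file or one missing a required section raises
    :class:`IntegrityError`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != RESTART_MAGIC:
        raise IntegrityError("not a stickermd restart file")
    if lines[-1] != "end":
        raise IntegrityError("truncated restart file (missing 'end' marker)")
    idx = 1
    meta = {}
    while idx < len(lines) and " " in lines[idx] and lines[idx].split()[0] in ("step", "box", "natoms", "nchains"):
        toks = lines[idx].split()
        meta[toks[0]] = toks[1:]
        idx += 1
    try:
        n = int(meta["natoms"][0])
        step = int(meta["step"][0])
        box = np.array([float(v) for v in meta["box"]])
    except (KeyError, ValueError, IndexError):
        raise IntegrityError("restart header incomplete")

    state = SystemState.empty(n, box)
    state.step = step

    def read_block(name, parse, target):
        nonlocal idx
        if idx >= len(lines) or lines[idx] != name:
            raise IntegrityError(f"restart missing '{name}' section")
        idx += 1
        if idx + n > len(lines):
            raise IntegrityError(f"restart '{name}' section truncated")
        for i in range(n):
            target[i] = parse(lines[idx + i])
        idx += n

    read_block("positions", lambda s: [float(v) for v in s.split()], state.positions)
    read_block("images", lambda s: [int(v) for v in s.split()], state.images)
    read_block("velocities", lambda s: [float(v) for v in s.split()], state.velocities)
    read_block("pairing", lambda s: int(s), state.pairing)

    rng = {}
    while idx < len(lines) and lines[idx].startswith("rng_"):
        toks = lines[idx].split()
        rng[toks[0][4:]] = np.array([int(toks[1]), int(toks[2])], dtype=np.uint64)
        idx += 1
    state.check_pairing()
    return state, rng
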