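"""Broker-compatible client movers.

Each client has two layers: a broking layer (``yield_claims`` /
``configure``) that states its fold-tree and DoF requirements, and an
effector layer (``initialize`` / ``apply``) that performs sampling moves —
always through the protected conformation with its own passport, never by
touching internal state directly.  A client's ``apply`` is atomic: if a move
is rejected or errors, the conformation is left bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import selectors as sel
from .broker import (
    BrokerResult,
    ControlStrength,
    CutClaim,
    JumpClaim,
    TorsionClaim,
    VirtualResidueClaim,
)
from .dofs import DoFID
from .enforcement import ProtectedConformation
from .foldtree import downstream_set
from .geometry import RigidTransform, place_atom, stub_frame
from .kinematics import Conformation

__all__ = [
    "MoveOutcome",
    "ClientMover",
    "FragmentEntry",
    "FragmentLibrary",
    "StrandPairing",
    "StrandPairingSet",
    "RigidChunkClient",
    "FragmentInsertionClient",
    "StrandPairJumpClient",
    "CoMTrackerClient",
    "RigidBodyDockClient",
    "CCDLoopCloseClient",
    "com_tracking_update",
    "ideal_strand_transforms",
]


@dataclass(frozen=True)
class MoveOutcome:
    moved: bool
    detail: str = ""


class ClientMover:
    """Base class: a broking layer plus an effector layer.

    Subclasses override yield_claims (pure — no side effects on the
    conformation) and apply; configure stores the passport and any resolved
    indices; initialize runs once after broking, before sampling.
    """

    def __init__(self, name: str):
        self.name = name
        self.passport = None

    def yield_claims(self, conf: Conformation, rng) -> List:
        return []

    def configure(self, result: BrokerResult) -> None:
        self.passport = result.passports[self.name]

    def initialize(self, pconf: ProtectedConformation, rng) -> None:
        pass

    def apply(self, pconf: ProtectedConformation, rng) -> MoveOutcome:
        return MoveOutcome(False, "no-op")


# -- fragment insertion -----------------------------------------------------------

@dataclass(frozen=True)
class FragmentEntry:
    position: int                 # first residue of the window (1-based)
    torsions: Tuple[Tuple[float, float, float], ...]  # (phi, psi, omega) degrees

    def __post_init__(self):
        if not (3 <= len(self.torsions) <= 9):
            raise ValueError("fragment window length must be in 3..9")
        if not np.isfinite(np.asarray(self.torsions)).all():
            raise ValueError("fragment torsions must be finite")

    @property
    def length(self) -> int:
        return len(self.torsions)

    @property
    def residues(self) -> range:
        return range(self.position, self.position + self.length)


@dataclass(frozen=True)
class FragmentLibrary:
    """Torsion fragments: 3-9 residue windows of (phi, psi, omega) triples."""

    entries: Tuple[FragmentEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("fragment library is empty")

    @property
    def covered_residues(self) -> FrozenSet[int]:
        return frozenset(r for e in self.entries for r in e.residues)

    # dialect: "position length phi psi omega [phi psi omega ...]" per line
    def dump(self) -> str:
        lines = []
        for e in self.entries:
            flat = " ".join(f"{t:.4f}" for triple in e.torsions for t in triple)
            lines.append(f"{e.position} {e.length} {flat}")
        return "\n".join(lines) + "\n"

    @classmethod
    def parse(cls, text: str) -> "FragmentLibrary":
        entries = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            pos, length = int(fields[0]), int(fields[1])
            values = [float(v) for v in fields[2:]]
            if len(values) != 3 * length:
                raise ValueError(
                    f"fragment line {lineno}: expected {3 * length} torsions, got {len(values)}"
                )
            triples = tuple(tuple(values[3 * k : 3 * k + 3]) for k in range(length))
            entries.append(FragmentEntry(pos, triples))
        return cls(tuple(entries))

    @classmethod
    def read(cls, path: str) -> "FragmentLibrary":
        with open(path) as fh:
            return cls.parse(fh.read())

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.dump())


class FragmentInsertionClient(ClientMover):
    """Monte Carlo fragment insertion: claims CAN_CONTROL torsions over its
    region and, per move, writes one uniformly chosen fragment's window.

    Insertions overlapping DoFs the client was not granted (e.g. demoted under
    a rigid chunk's EXCLUSIVE claim) are rejected before any modification.
    """

    def __init__(self, name: str, library: FragmentLibrary, region=None):
        super().__init__(name)
        self.library = library
        self.region = region

    def yield_claims(self, conf, rng):
        region = self.region if self.region is not None else self.library.covered_residues
        return [TorsionClaim(region, ControlStrength.CAN_CONTROL)]

    def apply(self, pconf, rng) -> MoveOutcome:
        entry = self.library.entries[int(rng.integers(len(self.library.entries)))]
        dofs = [
            DoFID.torsion(kind, r)
            for r in entry.residues
            for kind in ("phi", "psi", "omega")
        ]
        if any(d not in self.passport.granted for d in dofs):
            return MoveOutcome(False, f"fragment at {entry.position} overlaps ungranted DoFs")
        with pconf.unlock(self.passport):
            for r, (phi, psi, omega) in zip(entry.residues, entry.torsions):
                pconf.set_torsion("phi", r, phi)
                pconf.set_torsion("psi", r, psi)
                pconf.set_torsion("omega", r, omega)
        return MoveOutcome(True, f"inserted {entry.length}-mer at {entry.position}")


# -- rigid chunk ------------------------------------------------------------------

class RigidChunkClient(ClientMover):
    """Fix a region's internal coordinates to a template: set and forget.

    Claims EXCLUSIVE torsions over the region, forbids cuts inside each
    contiguous segment, and — for discontinuous regions — pins consecutive
    segments with a fixed-geometry jump (EXCLUSIVE on all six rigid-body
    DoFs) measured from the template.  After the one-time initialize pass the
    region is guaranteed to receive no further sampling.
    """

    def __init__(self, name: str, template: Conformation, region):
        super().__init__(name)
        self.template = template
        self.region = region
        self._segments: List[Tuple[int, int]] = []
        self._jump_anchors: List[Tuple[int, int]] = []
        self._fixed: Dict[Tuple[int, int], RigidTransform] = {}

    def yield_claims(self, conf, rng):
        residues = sorted(sel.resolve(self.region, conf))
        if not residues:
            raise ValueError(f"rigid chunk {self.name!r}: empty region")
        if max(residues) > self.template.n_residues:
            raise ValueError(
                f"rigid chunk {self.name!r}: template (n={self.template.n_residues}) "
                f"missing residues up to {max(residues)}"
            )
        self._segments = _contiguous_segments(residues)
        # forbid cuts inside each segment and in the bonds flanking it: a cut
        # into the chunk would detach part of its fixed geometry
        claims: List = [
            TorsionClaim(tuple(residues), ControlStrength.EXCLUSIVE),
            CutClaim(forbidden=tuple((max(1, s - 1), e) for s, e in self._segments)),
        ]
        self._jump_anchors = []
        self._fixed = {}
        txyz = self.template.xyz
        for (s1, e1), (s2, e2) in zip(self._segments, self._segments[1:]):
            a = (s1 + e1) // 2
            b = (s2 + e2) // 2
            stub_a = stub_frame(*txyz[a - 1, 0:3])
            stub_b = stub_frame(*txyz[b - 1, 0:3])
            transform = stub_a.inverse() @ stub_b
            self._jump_anchors.append((a, b))
            self._fixed[(a, b)] = transform
            claims.append(
                JumpClaim(a, b, ControlStrength.EXCLUSIVE, fixed_transform=transform)
            )
        return claims

    def configure(self, result):
        super().configure(result)
        self._jump_numbers = {
            anchors: result.jump_number(*anchors) for anchors in self._jump_anchors
        }

    def initialize(self, pconf, rng) -> None:
        with pconf.unlock(self.passport):
            for s, e in self._segments:
                for r in range(s, e + 1):
                    for kind in ("phi", "psi", "omega"):
                        pconf.set_torsion(kind, r, self.template.get_torsion(kind, r))
            for anchors, num in self._jump_numbers.items():
                pconf.set_jump(num, self._fixed[anchors])


def _contiguous_segments(residues: Sequence[int]) -> List[Tuple[int, int]]:
    segments = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r != prev + 1:
            segments.append((start, prev))
            start = r
        prev = r
    segments.append((start, prev))
    return segments


# -- beta-strand pairing jumps -----------------------------------------------------

@dataclass(frozen=True)
class StrandPairing:
    res_i: int
    res_j: int
    orientation: str  # 'A' antiparallel, 'P' parallel
    register: int = 0

    def __post_init__(self):
        if self.orientation not in ("A", "P"):
            raise ValueError(f"orientation must be 'A' or 'P', got {self.orientation!r}")


@dataclass(frozen=True)
class StrandPairingSet:
    """Candidate strand pairings, grouped: one pairing is drawn per group per
    trajectory, plus a library of jump transforms representing observed
    strand-pair geometries."""

    groups: Tuple[Tuple[StrandPairing, ...], ...]
    transforms: Dict[str, Tuple[RigidTransform, ...]] = field(
        default_factory=lambda: ideal_strand_transforms()
    )

    def __post_init__(self):
        if not self.groups or any(not g for g in self.groups):
            raise ValueError("every pairing group must be nonempty")
        for key, lib in self.transforms.items():
            if not lib:
                raise ValueError(f"empty transform library for orientation {key!r}")
            for t in lib:
                if not t.is_orthonormal(1e-9):
                    raise ValueError("invalid strand-pair transform")

    # dialect: SELECT group headers, then "PAIRING res_i res_j orientation register"
    def dump(self) -> str:
        lines = []
        for group in self.groups:
            lines.append("SELECT")
            for p in group:
                lines.append(f"PAIRING {p.res_i} {p.res_j} {p.orientation} {p.register}")
        return "\n".join(lines) + "\n"

    @classmethod
    def parse(cls, text: str, transforms=None) -> "StrandPairingSet":
        groups: List[List[StrandPairing]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if fields[0] == "SELECT":
                groups.append([])
            elif fields[0] == "PAIRING":
                if not groups:
                    groups.append([])
                groups[-1].append(
                    StrandPairing(int(fields[1]), int(fields[2]), fields[3], int(fields[4]))
                )
            else:
                raise ValueError(f"topology line {lineno}: unrecognized record {fields[0]!r}")
        kwargs = {"transforms": transforms} if transforms else {}
        return cls(tuple(tuple(g) for g in groups), **kwargs)

    @classmethod
    def read(cls, path: str) -> "StrandPairingSet":
        with open(path) as fh:
            return cls.parse(fh.read())

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.dump())


def ideal_strand_transforms() -> Dict[str, Tuple[RigidTransform, ...]]:
    """Small idealized library of strand-pair jump transforms, one set per
    orientation, generated from ideal strand geometry (synthetic stand-in for
    a crystal-structure-derived database)."""
    anti = tuple(
        RigidTransform.from_rotvec_deg([180.0, tw, 0.0], [0.4, 4.9 + dy, 0.0])
        for tw in (-15.0, 0.0, 15.0)
        for dy in (-0.2, 0.2)
    )
    para = tuple(
        RigidTransform.from_rotvec_deg([0.0, tw, 0.0], [3.2, 4.8 + dy, 0.0])
        for tw in (-10.0, 10.0)
        for dy in (-0.2, 0.2)
    )
    return {"A": anti, "P": para}


class StrandPairJumpClient(ClientMover):
    """Pin beta-strand pairs with jumps between the paired residues' frames.

    Only one residue pair can be pinned per strand pair; a different candidate
    pair is drawn per trajectory at claim time, and apply samples the jump
    geometry from the transform library.
    """

    def __init__(self, name: str, pairing_set: StrandPairingSet):
        super().__init__(name)
        self.pairing_set = pairing_set
        self.chosen: List[StrandPairing] = []

    def yield_claims(self, conf, rng):
        self.chosen = [
            group[int(rng.integers(len(group)))] for group in self.pairing_set.groups
        ]
        return [
            JumpClaim(p.res_i, p.res_j, ControlStrength.MUST_CONTROL)
            for p in self.chosen
        ]

    def configure(self, result):
        super().configure(result)
        self._jumps = [
            (result.jump_number(p.res_i, p.res_j), p.orientation) for p in self.chosen
        ]

    def apply(self, pconf, rng) -> MoveOutcome:
        num, orientation = self._jumps[int(rng.integers(len(self._jumps)))]
        library = self.pairing_set.transforms[orientation]
        transform = library[int(rng.integers(len(library)))]
        with pconf.unlock(self.passport):
            pconf.set_jump(num, transform)
        return MoveOutcome(True, f"jump {num} <- strand-pair transform")


# -- center-of-mass tracking --------------------------------------------------------

ROOT_LABEL = "root"


def com_label(chain_id: str) -> str:
    return f"com_{chain_id}"


class CoMTrackerClient(ClientMover):
    """Track a chain's center of mass with a virtual residue.

    Claims the shared root virtual residue, a CoM virtual residue attached at
    the chain's backbone centroid, the jump root -> CoM (which docking movers
    may also claim) and the jump CoM -> chain.  Its update move re-centers the
    virtual residue on the chain's current CoM by rewriting both incident
    jumps, without moving any real atom.
    """

    def __init__(self, name: str, chain_id: str):
        super().__init__(name)
        self.chain_id = chain_id

    def yield_claims(self, conf, rng):
        label = com_label(self.chain_id)
        return [
            VirtualResidueClaim(ROOT_LABEL, ("root",)),
            VirtualResidueClaim(label, ("com", self.chain_id)),
            JumpClaim(("virtual", ROOT_LABEL), ("virtual", label), ControlStrength.MUST_CONTROL),
            JumpClaim(("virtual", label), ("chain", self.chain_id), ControlStrength.MUST_CONTROL),
        ]

    def configure(self, result):
        super().configure(result)
        self.registry = dict(result.virtual_registry)

    def apply(self, pconf, rng) -> MoveOutcome:
        moved = com_tracking_update(pconf, self.chain_id, self.passport, self.registry)
        return MoveOutcome(moved, f"CoM of chain {self.chain_id} re-centered")

    # tracking is also useful as an explicit post-move hook
    update = apply


def com_tracking_update(
    pconf: ProtectedConformation,
    chain_id: str,
    passport,
    registry: Dict[str, int],
) -> bool:
    """Move a chain's CoM virtual residue to the chain's current backbone
    centroid by rewriting its incoming and outgoing jumps; real atoms do not
    move (to floating-point precision).  Returns False if already centered."""
    chain = pconf.chain_by_id(chain_id)
    com_res = registry[com_label(chain_id)]
    xyz = pconf.xyz
    com = xyz[chain.start - 1 : chain.stop].reshape(-1, 3).mean(axis=0)

    old_stub = pconf.stub(com_res)
    if float(np.abs(old_stub.translation - com).max()) < 1e-12:
        return False
    new_stub = RigidTransform(old_stub.rotation, com)

    tree = pconf.fold_tree
    incoming = None
    outgoing = []
    for num, (s, e) in tree.jump_edges.items():
        if e == com_res:
            incoming = (num, s)
        elif s == com_res:
            outgoing.append((num, e))
    if incoming is None:
        raise ValueError(f"CoM virtual residue {com_res} has no incoming jump")

    with pconf.unlock(passport):
        num, parent = incoming
        pconf.set_jump(num, pconf.stub(parent).inverse() @ new_stub)
        for num, child in outgoing:
            pconf.set_jump(num, new_stub.inverse() @ stub_frame(*xyz[child - 1, 0:3]))
    return True


# -- rigid-body docking ---------------------------------------------------------------

class RigidBodyDockClient(ClientMover):
    """Gaussian rigid-body perturbation of one docking jump.

    For a chain docked through its CoM virtual residue, claims CAN_CONTROL on
    the root -> CoM jump; only the docked partner's subtree moves.
    """

    def __init__(
        self,
        name: str,
        chain_id: Optional[str] = None,
        rot_mag: float = 3.0,
        trans_mag: float = 0.5,
        anchors: Optional[Tuple[int, int]] = None,
    ):
        super().__init__(name)
        if (chain_id is None) == (anchors is None):
            raise ValueError("specify exactly one of chain_id or anchors")
        self.chain_id = chain_id
        self.anchors = anchors
        self.rot_mag = float(rot_mag)
        self.trans_mag = float(trans_mag)

    def _anchor_spec(self):
        if self.anchors is not None:
            return self.anchors
        return (("virtual", ROOT_LABEL), ("virtual", com_label(self.chain_id)))

    def yield_claims(self, conf, rng):
        a, b = self._anchor_spec()
        return [JumpClaim(a, b, ControlStrength.CAN_CONTROL)]

    def configure(self, result):
        super().configure(result)
        a, b = self._anchor_spec()
        if isinstance(a, tuple):
            a = result.virtual_registry[a[1]]
            b = result.virtual_registry[b[1]]
        self.jump = result.jump_number(a, b)

    def apply(self, pconf, rng) -> MoveOutcome:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, self.rot_mag) if self.rot_mag > 0 else 0.0
        dt = rng.normal(0.0, self.trans_mag, size=3) if self.trans_mag > 0 else np.zeros(3)
        delta = RigidTransform.from_rotvec_deg(axis * angle, dt)
        with pconf.unlock(self.passport):
            pconf.set_jump(self.jump, pconf.get_jump(self.jump) @ delta)
        return MoveOutcome(True, f"jump {self.jump} perturbed")


# -- CCD loop closure -----------------------------------------------------------------

class CCDLoopCloseClient(ClientMover):
    """Cyclic coordinate descent closure of the chainbreak inside a loop.

    Claims CAN_CONTROL over the loop torsions and a jump bypassing the loop
    (DOES_NOT_CONTROL on its rigid-body DoFs: the jump must exist, but this
    client never moves it) with the cut required inside the loop.  apply
    iterates analytic per-torsion rotations minimizing the deviation of the
    virtual peptide bond across the cut, touching only granted DoFs.
    """

    def __init__(self, name: str, loop: Tuple[int, int], max_iter: int = 100, tol: float = 0.05):
        super().__init__(name)
        self.loop = (int(loop[0]), int(loop[1]))
        if self.loop[0] >= self.loop[1]:
            raise ValueError("loop must span at least two residues")
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self._signs: Dict[DoFID, int] = {}

    def yield_claims(self, conf, rng):
        s, e = self.loop
        return [
            TorsionClaim(tuple(range(s, e + 1)), ControlStrength.CAN_CONTROL),
            JumpClaim(
                s - 1, e + 1, ControlStrength.DOES_NOT_CONTROL,
                cut_interval=(s, e - 1),
            ),
        ]

    def configure(self, result):
        super().configure(result)
        s, e = self.loop
        cuts = [c for c in result.fold_tree.cuts if s <= c <= e - 1]
        if not cuts:
            raise ValueError(f"loop {self.loop} of {self.name!r} contains no cut")
        self.cut = cuts[0]
        self.pivots = [
            DoFID.torsion(kind, r)
            for r in range(s, e + 1)
            for kind in ("phi", "psi")
            if DoFID.torsion(kind, r) in self.passport.granted
        ]
        if not self.pivots:
            raise ValueError(f"loop closure {self.name!r} was granted no loop torsions")
        self._signs = {}

    # -- effector -------------------------------------------------------------
    def apply(self, pconf, rng) -> MoveOutcome:
        tree = pconf.fold_tree
        it = 0
        for it in range(self.max_iter):
            if self._gap(pconf) < self.tol:
                break
            for dof in self.pivots:
                self._ccd_step(pconf, tree, dof)
        closed = self._gap(pconf) < self.tol
        return MoveOutcome(True, f"gap {self._gap(pconf):.3f} Å after {it + 1} sweeps")

    def _triplets(self, pconf) -> Tuple[np.ndarray, np.ndarray]:
        """(moving, target) 3-atom sets across the cut: the ideal continuation
        of the upstream side vs the actual downstream backbone."""
        c = self.cut
        conf = pconf._conf
        i = c - 1
        x = pconf.xyz
        n_hat = place_atom(x[i, 0], x[i, 1], x[i, 2],
                           conf.bl_c_n[i], conf.ang_ca_c_n[i], conf.psi[i])
        ca_hat = place_atom(x[i, 1], x[i, 2], n_hat,
                            conf.bl_n_ca[i + 1], conf.ang_c_n_ca[i], conf.omega[i])
        c_hat = place_atom(x[i, 2], n_hat, ca_hat,
                           conf.bl_ca_c[i + 1], conf.ang_n_ca_c[i + 1], conf.phi[i + 1])
        moving = np.array([n_hat, ca_hat, c_hat])
        target = np.array(x[i + 1, 0:3])
        return moving, target

    def _gap(self, pconf) -> float:
        moving, target = self._triplets(pconf)
        return float(np.linalg.norm(moving[0] - target[0]))

    def _objective(self, pconf) -> float:
        moving, target = self._triplets(pconf)
        return float(((moving - target) ** 2).sum())

    def _axis(self, pconf, dof: DoFID) -> Tuple[np.ndarray, np.ndarray]:
        x = pconf.xyz
        r = dof.residue - 1
        if dof.kind.name == "PHI":
            p, q = x[r, 0], x[r, 1]  # N -> CA
        else:
            p, q = x[r, 1], x[r, 2]  # CA -> C
        u = q - p
        return p, u / np.linalg.norm(u)

    def _ccd_step(self, pconf, tree, dof) -> None:
        c = self.cut
        ds = downstream_set(tree, dof)
        moving, target = self._triplets(pconf)
        moves_upstream_side = (c in ds and c + 1 not in ds) or (
            not ds and dof.residue in (c, c + 1)
        )
        moves_downstream_side = c + 1 in ds and c not in ds
        if not (moves_upstream_side or moves_downstream_side):
            # phantom torsions across the cut: psi(c)/phi(c+1) move only the
            # ideal continuation, handled as the upstream side
            if dof in (DoFID.psi(c), DoFID.phi(c + 1)):
                moves_upstream_side = True
            else:
                return
        p, u = self._axis(pconf, dof)
        if moves_upstream_side:
            rotating, fixed = moving, target
        else:
            rotating, fixed = target, moving
        # analytic single-angle optimum (classic CCD closed form)
        rv = rotating - p
        fv = fixed - p
        axial = (rv @ u)[:, None] * u
        r_perp = rv - axial
        s_perp = fv - ((fv @ u)[:, None] * u)
        a = float((r_perp * s_perp).sum())
        b = float((np.cross(np.broadcast_to(u, r_perp.shape), r_perp) * s_perp).sum())
        if abs(a) < 1e-14 and abs(b) < 1e-14:
            return
        theta = float(np.arctan2(b, a))
        theta_deg = np.degrees(theta)
        if abs(theta_deg) < 1e-9:
            return
        current = pconf.get_dof(dof)
        sign = self._signs.get(dof)
        with pconf.unlock(self.passport):
            if sign is None:
                pconf.set_dof(dof, current + theta_deg)
                obj_plus = self._objective(pconf)
                pconf.set_dof(dof, current - theta_deg)
                obj_minus = self._objective(pconf)
                sign = 1 if obj_plus <= obj_minus else -1
                self._signs[dof] = sign
                if sign == 1:
                    pconf.set_dof(dof, current + theta_deg)
            else:
                pconf.set_dof(dof, current + sign * theta_deg)
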