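"""Internal-coordinate polypeptide representation and coordinate propagation.

A :class:`Conformation` stores the molecule as backbone internal coordinates
(bond lengths, bond angles, phi/psi/omega torsions) plus one rigid transform
per jump, and converts to Cartesian coordinates by traversing its fold tree
from the root.  Atoms are backbone N, CA, C, O only; changing one degree of
freedom moves exactly the atoms downstream of it in the tree, because
upstream placement arithmetic never reads the changed value.

Torsions and angles are degrees in the public API and radians internally.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import foldtree as ft
from .dofs import DoFID, DoFKind
from .geometry import (
    RigidTransform,
    bond_angle,
    bond_length,
    dihedral,
    place_atom,
    stub_frame,
    superpose_rmsd,
)

__all__ = [
    "IDEAL",
    "TORSION_PRESETS",
    "Chain",
    "Conformation",
    "DoFID",
    "DoFKind",
    "RigidTransform",
    "build_ideal_polypeptide",
    "internal_to_cartesian",
    "cartesian_to_internal",
    "set_dof",
    "jump_transform",
    "chainbreak_deviation",
    "superpose_rmsd",
]

ATOMS = ("N", "CA", "C", "O")
ATOM_INDEX = {name: i for i, name in enumerate(ATOMS)}

# Idealized backbone geometry (Å, degrees).
IDEAL = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "N_CA_C": 111.2,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
    "CA_C_O": 120.8,
    "OMEGA": 180.0,
}

# (phi, psi) in degrees; omega is 180 for every preset.
TORSION_PRESETS = {
    "helix": (-57.0, -47.0),
    "strand": (-135.0, 135.0),
    "extended": (180.0, 180.0),
}

_D2R = np.pi / 180.0


@dataclass(frozen=True)
class Chain:
    chain_id: str
    start: int  # 1-based, inclusive
    stop: int
    virtual: bool = False

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.stop

    @property
    def residues(self) -> range:
        return range(self.start, self.stop + 1)


class Conformation:
    """Backbone internal coordinates + jumps, with a cached Cartesian image.

    Residues are indexed 1..n_residues pose-wide across chains.  Virtual
    residues carry pseudo N/CA/C/O atoms used only to define local frames;
    they are flagged and excluded from real-atom queries.
    """

    def __init__(self, chains: Sequence[Chain]):
        self.chains: List[Chain] = list(chains)
        n = self.chains[-1].stop
        if self.chains[0].start != 1 or any(
            self.chains[k].start != self.chains[k - 1].stop + 1
            for k in range(1, len(self.chains))
        ):
            raise ValueError("chains must tile residues 1..n contiguously")
        self._alloc(n)
        self.jumps: Dict[int, RigidTransform] = {}
        self.root_stub: RigidTransform = RigidTransform.identity()
        self.fold_tree: ft.FoldTree = ft.FoldTree.from_chains(
            [(c.start, c.stop) for c in self.chains]
        )
        for j in self.fold_tree.jump_edges:
            self.jumps[j] = RigidTransform.identity()
        self._xyz: Optional[np.ndarray] = None
        self._pending_virtual_stubs: Dict[int, RigidTransform] = {}
        self._saved_xyz: Optional[np.ndarray] = None

    def _alloc(self, n: int) -> None:
        self.n_residues = n
        z = lambda v: np.full(n, float(v))
        self.phi = z(180.0 * _D2R)
        self.psi = z(180.0 * _D2R)
        self.omega = z(IDEAL["OMEGA"] * _D2R)
        self.bl_n_ca = z(IDEAL["N_CA"])
        self.bl_ca_c = z(IDEAL["CA_C"])
        self.bl_c_n = z(IDEAL["C_N"])     # C(i)–N(i+1), stored on i
        self.bl_c_o = z(IDEAL["C_O"])
        self.ang_n_ca_c = z(IDEAL["N_CA_C"] * _D2R)
        self.ang_ca_c_n = z(IDEAL["CA_C_N"] * _D2R)  # CA(i)-C(i)-N(i+1)
        self.ang_c_n_ca = z(IDEAL["C_N_CA"] * _D2R)  # C(i)-N(i+1)-CA(i+1)
        self.ang_ca_c_o = z(IDEAL["CA_C_O"] * _D2R)
        self.o_offset = z(np.pi)  # dihedral(N,CA,C,O) - psi
        self.virtual = np.zeros(n, dtype=bool)

    # -- bookkeeping ---------------------------------------------------------
    def copy(self) -> "Conformation":
        return _copy.deepcopy(self)

    def chain_of(self, residue: int) -> Chain:
        for c in self.chains:
            if residue in c:
                return c
        raise ValueError(f"residue {residue} outside 1..{self.n_residues}")

    def chain_by_id(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ValueError(f"no chain with id {chain_id!r}")

    def same_chain(self, i: int, j: int) -> bool:
        return self.chain_of(i) is self.chain_of(j)

    @property
    def real_residues(self) -> np.ndarray:
        return np.flatnonzero(~self.virtual) + 1

    def add_virtual_residue(self, label: str, stub: RigidTransform) -> int:
        """Append a frame-only residue as its own single-residue chain.

        Its pseudo-backbone is placed from `stub` with ideal local geometry.
        Returns the new residue index.
        """
        # snapshot current coordinates while the existing fold tree is still
        # valid, so a later set_fold_tree can anchor jumps without moving atoms
        if self._saved_xyz is None:
            self._saved_xyz = np.array(self.xyz)
        n = self.n_residues + 1
        self.chains.append(Chain(label, n, n, virtual=True))
        for name in (
            "phi", "psi", "omega", "bl_n_ca", "bl_ca_c", "bl_c_n", "bl_c_o",
            "ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca", "ang_ca_c_o",
            "o_offset",
        ):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, _default_block(name)]))
        self.virtual = np.concatenate([self.virtual, [True]])
        self.n_residues = n
        self._invalidate()
        # caller is responsible for wiring the fold tree; record the desired
        # initial placement so jump transforms can be measured against it
        self._pending_virtual_stubs[n] = stub
        return n

    def _invalidate(self) -> None:
        self._xyz = None

    # -- fold tree -----------------------------------------------------------
    def set_fold_tree(self, tree: ft.FoldTree, keep_coords: bool = True) -> None:
        """Install a new fold tree.

        With keep_coords (default), the root stub and every jump transform are
        re-measured from the current Cartesian coordinates so that no atom
        moves; newly appended virtual residues are anchored at their recorded
        initial stubs.
        """
        violations = ft.validate(tree, self.n_residues)
        if violations:
            raise ft.FoldTreeError("; ".join(violations))
        if keep_coords:
            if self._saved_xyz is not None:
                old_xyz = self._saved_xyz
            elif self._has_placeable_tree():
                old_xyz = self.xyz
            else:
                old_xyz = None
            pending = self._pending_virtual_stubs

            def stub_of(res: int) -> RigidTransform:
                if res in pending:
                    return pending[res]
                if old_xyz is None or res > old_xyz.shape[0]:
                    return RigidTransform.identity()
                return stub_frame(*old_xyz[res - 1, 0:3])

            self.fold_tree = tree
            self.root_stub = stub_of(tree.root)
            self.jumps = {
                num: stub_of(s).inverse() @ stub_of(e)
                for num, (s, e) in tree.jump_edges.items()
            }
            self._pending_virtual_stubs = {}
            self._saved_xyz = None
        else:
            self.fold_tree = tree
            self.jumps = {num: RigidTransform.identity() for num in tree.jump_edges}
        self._invalidate()

    def _has_placeable_tree(self) -> bool:
        return ft.validate(self.fold_tree, self.n_residues) == []

    # -- DoF access -----------------------------------------------------------
    def _torsion_array(self, kind: DoFKind) -> np.ndarray:
        return {DoFKind.PHI: self.phi, DoFKind.PSI: self.psi, DoFKind.OMEGA: self.omega}[kind]

    def get_dof(self, dof: DoFID) -> float:
        """Current value: degrees for torsions; Å or degrees for jump rb components."""
        if dof.is_torsion:
            self._check_residue(dof.residue)
            return float(self._torsion_array(dof.kind)[dof.residue - 1] / _D2R)
        return float(self._jump(dof.jump).rb_vector()[dof.rb - 1])

    def set_dof(self, dof: DoFID, value: float) -> None:
        if dof.is_torsion:
            self._check_residue(dof.residue)
            self._torsion_array(dof.kind)[dof.residue - 1] = float(value) * _D2R
        else:
            rb = self._jump(dof.jump).rb_vector()
            rb[dof.rb - 1] = float(value)
            self.jumps[dof.jump] = RigidTransform.from_rb_vector(rb)
        self._invalidate()

    def get_torsion(self, name: str, residue: int) -> float:
        return self.get_dof(DoFID.torsion(name, residue))

    def set_torsion(self, name: str, residue: int, degrees: float) -> None:
        self.set_dof(DoFID.torsion(name, residue), degrees)

    def get_jump(self, jump: int) -> RigidTransform:
        return self._jump(jump)

    def set_jump(self, jump: int, transform: RigidTransform) -> None:
        self._jump(jump)
        if not transform.is_orthonormal(1e-6):
            raise ValueError("jump transform rotation is not orthonormal")
        self.jumps[jump] = transform
        self._invalidate()

    def _jump(self, jump: int) -> RigidTransform:
        try:
            return self.jumps[jump]
        except KeyError:
            raise KeyError(f"no jump numbered {jump} in conformation") from None

    def _check_residue(self, residue: int) -> None:
        if not (1 <= residue <= self.n_residues):
            raise KeyError(f"residue {residue} outside 1..{self.n_residues}")

    def all_dofs(self) -> List[DoFID]:
        dofs = [
            DoFID.torsion(k, r)
            for r in range(1, self.n_residues + 1)
            for k in ("phi", "psi", "omega")
        ]
        for j in sorted(self.jumps):
            dofs.extend(DoFID.jump_rb(j, rb) for rb in range(1, 7))
        return dofs

    # -- Cartesian cache -------------------------------------------------------
    @property
    def xyz(self) -> np.ndarray:
        """(n_residues, 4, 3) array of N, CA, C, O coordinates (Å)."""
        if self._xyz is None:
            self._xyz = internal_to_cartesian(self)
        return self._xyz

    def atom(self, residue: int, name: str) -> np.ndarray:
        return self.xyz[residue - 1, ATOM_INDEX[name]]

    def stub(self, residue: int) -> RigidTransform:
        x = self.xyz
        return stub_frame(*x[residue - 1, 0:3])

    def real_atom_coords(self) -> np.ndarray:
        """(n_real * 4, 3) coordinates of non-virtual residues' atoms."""
        return self.xyz[~self.virtual].reshape(-1, 3)


def _default_block(name: str) -> np.ndarray:
    defaults = {
        "phi": 180.0 * _D2R, "psi": 180.0 * _D2R, "omega": IDEAL["OMEGA"] * _D2R,
        "bl_n_ca": IDEAL["N_CA"], "bl_ca_c": IDEAL["CA_C"], "bl_c_n": IDEAL["C_N"],
        "bl_c_o": IDEAL["C_O"],
        "ang_n_ca_c": IDEAL["N_CA_C"] * _D2R, "ang_ca_c_n": IDEAL["CA_C_N"] * _D2R,
        "ang_c_n_ca": IDEAL["C_N_CA"] * _D2R, "ang_ca_c_o": IDEAL["CA_C_O"] * _D2R,
        "o_offset": np.pi,
    }
    return np.array([defaults[name]])


# -- construction -------------------------------------------------------------

def build_ideal_polypeptide(
    n: int,
    chain_spec: Optional[Sequence[int]] = None,
    torsion_preset: Union[str, Sequence[Tuple[float, float, float]]] = "extended",
    chain_ids: Optional[Sequence[str]] = None,
) -> Conformation:
    """Ideal-geometry polypeptide with preset torsions and a linear fold tree
    per chain (multi-chain systems get default chain-connecting jumps)."""
    if n < 2:
        raise ValueError("polypeptide needs at least 2 residues")
    lengths = list(chain_spec) if chain_spec is not None else [n]
    if any(l <= 0 for l in lengths):
        raise ValueError("chain lengths must be positive")
    if sum(lengths) != n:
        raise ValueError(f"chain lengths {lengths} do not sum to n={n}")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + k) for k in range(len(lengths))]
    chains = []
    start = 1
    for cid, length in zip(chain_ids, lengths):
        chains.append(Chain(cid, start, start + length - 1))
        start += length
    conf = Conformation(chains)
    if isinstance(torsion_preset, str):
        try:
            phi, psi = TORSION_PRESETS[torsion_preset]
        except KeyError:
            raise ValueError(f"unknown torsion preset {torsion_preset!r}") from None
        conf.phi[:] = phi * _D2R
        conf.psi[:] = psi * _D2R
        conf.omega[:] = IDEAL["OMEGA"] * _D2R
    else:
        triples = list(torsion_preset)
        if len(triples) != n:
            raise ValueError("explicit torsion list must have one (phi,psi,omega) per residue")
        for i, (phi, psi, omega) in enumerate(triples):
            conf.phi[i] = phi * _D2R
            conf.psi[i] = psi * _D2R
            conf.omega[i] = omega * _D2R
    # separate chains in space so default multi-chain builds do not overlap
    for k, num in enumerate(sorted(conf.jumps), start=1):
        conf.jumps[num] = RigidTransform(np.eye(3), np.array([0.0, 18.0 * k, 0.0]))
    return conf


# -- internal <-> Cartesian ----------------------------------------------------

def internal_to_cartesian(conf: Conformation) -> np.ndarray:
    """Cartesian coordinates generated by traversing the fold tree from the root.

    Deterministic: identical internal coordinates give bit-identical output.
    """
    tree = conf.fold_tree
    steps = ft.placement_steps(tree)
    n = conf.n_residues
    xyz = np.full((n, 4, 3), np.nan)

    def place_residue_from_stub(res: int, stub: RigidTransform) -> None:
        i = res - 1
        ca = stub.translation.copy()
        x, y = stub.rotation[:, 0], stub.rotation[:, 1]
        c = ca + conf.bl_ca_c[i] * x
        theta = conf.ang_n_ca_c[i]
        nn = ca + conf.bl_n_ca[i] * (np.cos(theta) * x + np.sin(theta) * y)
        xyz[i, 0] = nn
        xyz[i, 1] = ca
        xyz[i, 2] = c

    for step in steps:
        if step[0] == "root":
            place_residue_from_stub(step[1], conf.root_stub)
        elif step[0] == "fwd":
            i = step[1] - 1  # source residue (0-based)
            j = step[2] - 1
            nn = place_atom(
                xyz[i, 0], xyz[i, 1], xyz[i, 2],
                conf.bl_c_n[i], conf.ang_ca_c_n[i], conf.psi[i],
            )
            ca = place_atom(
                xyz[i, 1], xyz[i, 2], nn,
                conf.bl_n_ca[j], conf.ang_c_n_ca[i], conf.omega[i],
            )
            c = place_atom(
                xyz[i, 2], nn, ca,
                conf.bl_ca_c[j], conf.ang_n_ca_c[j], conf.phi[j],
            )
            xyz[j, 0], xyz[j, 1], xyz[j, 2] = nn, ca, c
        elif step[0] == "bwd":
            i = step[1] - 1  # source residue
            j = step[2] - 1  # j == i - 1
            c = place_atom(
                xyz[i, 2], xyz[i, 1], xyz[i, 0],
                conf.bl_c_n[j], conf.ang_c_n_ca[j], conf.phi[i],
            )
            ca = place_atom(
                xyz[i, 1], xyz[i, 0], c,
                conf.bl_ca_c[j], conf.ang_ca_c_n[j], conf.omega[j],
            )
            nn = place_atom(
                xyz[i, 0], c, ca,
                conf.bl_n_ca[j], conf.ang_n_ca_c[j], conf.psi[j],
            )
            xyz[j, 0], xyz[j, 1], xyz[j, 2] = nn, ca, c
        else:  # jump
            _, num, src, dst = step
            src_stub = stub_frame(*xyz[src - 1, 0:3])
            place_residue_from_stub(dst, src_stub @ conf._jump(num))

    # carbonyl oxygens: local to each residue (psi + stored offset)
    for i in range(n):
        xyz[i, 3] = place_atom(
            xyz[i, 0], xyz[i, 1], xyz[i, 2],
            conf.bl_c_o[i], conf.ang_ca_c_o[i],
            conf.psi[i] + conf.o_offset[i],
        )
    return xyz


def cartesian_to_internal(coords: np.ndarray, topology: Conformation) -> Conformation:
    """Measure internal coordinates from Cartesian coordinates.

    `topology` supplies chain layout and fold tree; its internal coordinate
    values are ignored.  Returns a new Conformation that round-trips:
    internal_to_cartesian(result) reproduces `coords` (backbone exactly,
    oxygens via the stored per-residue offset).

    Raises ValueError on missing atoms (NaNs) or collinear triples.
    """
    coords = np.asarray(coords, dtype=float)
    conf = topology.copy()
    n = conf.n_residues
    if coords.shape != (n, 4, 3):
        raise ValueError(f"expected coordinates of shape ({n}, 4, 3), got {coords.shape}")
    if np.isnan(coords).any():
        bad = sorted(set(np.argwhere(np.isnan(coords))[:, 0] + 1))
        raise ValueError(f"missing atoms in residues {bad[:10]}")
    N, CA, C, O = (coords[:, k] for k in range(4))
    for i in range(n):
        conf.bl_n_ca[i] = bond_length(N[i], CA[i])
        conf.bl_ca_c[i] = bond_length(CA[i], C[i])
        conf.bl_c_o[i] = bond_length(C[i], O[i])
        conf.ang_n_ca_c[i] = bond_angle(N[i], CA[i], C[i])
        conf.ang_ca_c_o[i] = bond_angle(CA[i], C[i], O[i])
        r = i + 1
        intra_chain = r < n and conf.same_chain(r, r + 1)
        if intra_chain:
            conf.bl_c_n[i] = bond_length(C[i], N[i + 1])
            conf.ang_ca_c_n[i] = bond_angle(CA[i], C[i], N[i + 1])
            conf.ang_c_n_ca[i] = bond_angle(C[i], N[i + 1], CA[i + 1])
            conf.psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
            conf.omega[i] = dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
            conf.phi[i + 1] = dihedral(C[i], N[i + 1], CA[i + 1], C[i + 1])
        else:
            # psi is unconstrained by a following residue; anchor it to the
            # carbonyl oxygen so the oxygen round-trips with offset pi
            conf.psi[i] = dihedral(N[i], CA[i], C[i], O[i]) - np.pi
        conf.o_offset[i] = _wrap(dihedral(N[i], CA[i], C[i], O[i]) - conf.psi[i])
    # root stub and jump transforms from coordinates
    stubs = {}

    def stub_of(res: int) -> RigidTransform:
        if res not in stubs:
            stubs[res] = stub_frame(N[res - 1], CA[res - 1], C[res - 1])
        return stubs[res]

    conf.root_stub = stub_of(conf.fold_tree.root)
    for num, (s, e) in conf.fold_tree.jump_edges.items():
        conf.jumps[num] = stub_of(s).inverse() @ stub_of(e)
    conf._invalidate()
    return conf


def _wrap(angle: float) -> float:
    return float((angle + np.pi) % (2 * np.pi) - np.pi)


# -- spec operations as module-level functions --------------------------------

def set_dof(conf: Conformation, dof: DoFID, value) -> Conformation:
    """Set one degree of freedom (torsion in degrees, or one rb component).

    Only atoms downstream of the DoF in the fold tree move; upstream atoms
    are bit-identical because their placement never reads the changed value.
    """
    if isinstance(value, RigidTransform):
        if dof.is_torsion:
            raise TypeError("RigidTransform value only valid for jump DoFs")
        conf.set_jump(dof.jump, value)
    else:
        conf.set_dof(dof, float(value))
    return conf


def jump_transform(conf: Conformation, jump: int) -> RigidTransform:
    """Stub-to-stub transform of a jump, measured from current coordinates."""
    s, e = conf.fold_tree.jump_anchors(jump)
    return conf.stub(s).inverse() @ conf.stub(e)


def chainbreak_deviation(conf: Conformation, cut_position: int) -> Tuple[float, Tuple[float, float]]:
    """Deviation of the virtual peptide bond across a cut from ideal geometry.

    Returns (|C(i)-N(i+1)| - ideal C-N| in Å, (two bond-angle gaps in degrees)).
    Zero iff the geometry across the cut is chemically continuous.
    """
    if not conf.fold_tree.is_cut(cut_position):
        raise ValueError(f"position {cut_position} is not a cut in the fold tree")
    i = cut_position - 1
    x = conf.xyz
    dist_gap = abs(bond_length(x[i, 2], x[i + 1, 0]) - conf.bl_c_n[i])
    a1 = abs(bond_angle(x[i, 1], x[i, 2], x[i + 1, 0]) - conf.ang_ca_c_n[i]) / _D2R
    a2 = abs(bond_angle(x[i, 2], x[i + 1, 0], x[i + 1, 1]) - conf.ang_c_n_ca[i]) / _D2R
    return dist_gap, (a1, a2)
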