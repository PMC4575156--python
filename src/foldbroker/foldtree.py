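"""The fold tree: a rooted, directed, acyclic residue graph.

The fold tree fixes the direction in which internal-coordinate changes
propagate into Cartesian space.  Edges are either PEPTIDE edges (coordinates
extend residue by residue along the chain, in either sequence direction) or
numbered jump edges (the downstream residue's local frame is placed rigidly
from the upstream residue's frame).  Every consecutive-residue adjacency not
covered by a peptide edge is a *cut*; for a connected tree the number of cuts
always equals the number of jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .dofs import DoFID, DoFKind

PEPTIDE = "PEPTIDE"

__all__ = [
    "PEPTIDE",
    "Edge",
    "FoldTree",
    "FoldTreeError",
    "NoLegalCutError",
    "validate",
    "downstream_set",
    "random_cut_placement",
    "placement_steps",
]


class FoldTreeError(ValueError):
    pass


class NoLegalCutError(FoldTreeError):
    pass


@dataclass(frozen=True, order=True)
class Edge:
    start: int
    stop: int
    label: object  # PEPTIDE or a positive jump number

    def __post_init__(self):
        if self.label != PEPTIDE and (not isinstance(self.label, int) or self.label < 1):
            raise FoldTreeError(f"edge label must be PEPTIDE or a positive jump number, got {self.label!r}")

    @property
    def is_jump(self) -> bool:
        return self.label != PEPTIDE


@dataclass(frozen=True)
class FoldTree:
    """Edge set + root + cut list.  Immutable; construct a new tree to change it."""

    edges: Tuple[Edge, ...]
    root: int
    cuts: Tuple[int, ...] = ()

    def __post_init__(self):
        edges = tuple(
            e if isinstance(e, Edge) else Edge(*e) for e in self.edges
        )
        # deterministic serialization order: by start residue, jumps after
        # peptide edges at the same start, jumps by number
        edges = tuple(
            sorted(edges, key=lambda e: (e.start, e.is_jump, e.label if e.is_jump else 0, e.stop))
        )
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "cuts", tuple(sorted(self.cuts)))

    # -- queries -----------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return max(max(e.start, e.stop) for e in self.edges) if self.edges else self.root

    @property
    def jump_edges(self) -> Dict[int, Tuple[int, int]]:
        return {e.label: (e.start, e.stop) for e in self.edges if e.is_jump}

    @property
    def n_jumps(self) -> int:
        return sum(1 for e in self.edges if e.is_jump)

    def jump_anchors(self, jump: int) -> Tuple[int, int]:
        try:
            return self.jump_edges[jump]
        except KeyError:
            raise FoldTreeError(f"no jump numbered {jump} in fold tree") from None

    def jump_number(self, a: int, b: int) -> Optional[int]:
        """Jump number between residues a, b in either direction, or None."""
        for num, (s, e) in self.jump_edges.items():
            if {s, e} == {a, b}:
                return num
        return None

    def peptide_adjacencies(self) -> Set[int]:
        """All i such that the i -> i+1 peptide connection is an edge."""
        adj: Set[int] = set()
        for e in self.edges:
            if not e.is_jump:
                lo, hi = min(e.start, e.stop), max(e.start, e.stop)
                adj.update(range(lo, hi))
        return adj

    def is_cut(self, position: int) -> bool:
        return position in self.cuts

    # -- serialization -----------------------------------------------------
    def serialize(self) -> str:
        lines = [f"EDGE {e.start} {e.stop} {e.label}" for e in self.edges]
        lines.append(f"ROOT {self.root}")
        lines.append("CUTS " + " ".join(str(c) for c in self.cuts))
        return "\n".join(lines) + "\n"

    @classmethod
    def deserialize(cls, text: str) -> "FoldTree":
        edges: List[Edge] = []
        root = None
        cuts: Tuple[int, ...] = ()
        for line in text.splitlines():
            fields = line.split()
            if not fields:
                continue
            if fields[0] == "EDGE":
                label = fields[3] if fields[3] == PEPTIDE else int(fields[3])
                edges.append(Edge(int(fields[1]), int(fields[2]), label))
            elif fields[0] == "ROOT":
                root = int(fields[1])
            elif fields[0] == "CUTS":
                cuts = tuple(int(c) for c in fields[1:])
            else:
                raise FoldTreeError(f"unrecognized fold tree line: {line!r}")
        if root is None:
            raise FoldTreeError("serialized fold tree lacks a ROOT line")
        return cls(tuple(edges), root, cuts)

    @classmethod
    def linear(cls, n: int, root: int = 1) -> "FoldTree":
        """Single-chain tree folding outward from the root."""
        edges = []
        if root > 1:
            edges.append(Edge(root, 1, PEPTIDE))
        if root < n:
            edges.append(Edge(root, n, PEPTIDE))
        return cls(tuple(edges), root, ())

    @classmethod
    def from_chains(cls, chain_ranges: Sequence[Tuple[int, int]]) -> "FoldTree":
        """Default multi-chain tree: each chain linear, chains attached to the
        first residue by numbered jumps; chain boundaries are cuts."""
        edges = []
        cuts = []
        for k, (start, stop) in enumerate(chain_ranges):
            if stop > start:
                edges.append(Edge(start, stop, PEPTIDE))
            if k > 0:
                edges.append(Edge(chain_ranges[0][0], start, k))
                cuts.append(start - 1)
        return cls(tuple(edges), chain_ranges[0][0], tuple(cuts))


# -- placement program ------------------------------------------------------

def placement_steps(tree: FoldTree) -> List[tuple]:
    """Ordered atomic placement steps implied by the tree.

    Steps are ('root', r), ('fwd', i, i+1), ('bwd', i, i-1) or
    ('jump', number, src, dst).  Each step's source residue is placed by an
    earlier step.  Raises FoldTreeError on trees that revisit or strand
    residues (use :func:`validate` for diagnostic messages).
    """
    unit: List[tuple] = []
    for e in tree.edges:
        if e.is_jump:
            unit.append(("jump", e.label, e.start, e.stop))
        elif e.stop > e.start:
            unit.extend(("fwd", i, i + 1) for i in range(e.start, e.stop))
        else:
            unit.extend(("bwd", i, i - 1) for i in range(e.start, e.stop, -1))
    placed = {tree.root}
    steps: List[tuple] = [("root", tree.root)]
    pending = sorted(unit, key=_step_key)
    while pending:
        progress = False
        rest = []
        for step in pending:
            src, dst = step[-2], step[-1]
            if src in placed:
                if dst in placed:
                    raise FoldTreeError(
                        f"two coordinate propagation paths reach residue {dst}"
                    )
                placed.add(dst)
                steps.append(step)
                progress = True
            else:
                rest.append(step)
        if not progress:
            raise FoldTreeError(
                "fold tree is disconnected or cyclic; unreachable steps: "
                + ", ".join(map(str, rest[:5]))
            )
        pending = rest
    return steps


def _step_key(step):
    order = {"fwd": 0, "bwd": 1, "jump": 2}
    return (order[step[0]], step[-2], step[-1])


# -- validation -------------------------------------------------------------

def validate(tree: FoldTree, n_residues: int) -> List[str]:
    """All invariant violations of `tree` for a system of `n_residues`.

    Empty list means the tree is a valid coordinate-propagation map:
    connected, acyclic, single-rooted, covering residues 1..n, with jump
    numbers consecutive from 1 and the cut list exactly the set of broken
    consecutive adjacencies (hence |cuts| == |jumps|).
    """
    violations: List[str] = []
    if not (1 <= tree.root <= n_residues):
        violations.append(f"root {tree.root} outside residue range 1..{n_residues}")

    # residues touched by edges
    touched: Set[int] = {tree.root}
    for e in tree.edges:
        if e.start == e.stop:
            violations.append(f"degenerate edge at residue {e.start}")
        lo, hi = min(e.start, e.stop), max(e.start, e.stop)
        if lo < 1 or hi > n_residues:
            violations.append(f"edge {e.start}->{e.stop} outside residue range")
        touched.update((e.start, e.stop))
        if not e.is_jump:
            touched.update(range(lo, hi + 1))

    missing = set(range(1, n_residues + 1)) - touched
    if missing:
        violations.append(f"residues not covered by any edge: {sorted(missing)[:10]}")

    # incoming-path counts at unit-step granularity
    incoming: Dict[int, int] = {}
    for e in tree.edges:
        if e.is_jump:
            incoming[e.stop] = incoming.get(e.stop, 0) + 1
        else:
            step = 1 if e.stop > e.start else -1
            for i in range(e.start, e.stop, step):
                incoming[i + step] = incoming.get(i + step, 0) + 1
    if incoming.get(tree.root, 0) > 0:
        violations.append(f"root residue {tree.root} has an incoming edge")
    orphans = [
        r for r in sorted(touched)
        if r != tree.root and incoming.get(r, 0) == 0 and 1 <= r <= n_residues
    ]
    if orphans:
        violations.append(f"multiple roots: residues {orphans[:10]} have no incoming edge")
    for r, k in sorted(incoming.items()):
        if k > 1:
            violations.append(f"two valid coordinate propagation paths lead to residue {r}")

    # cycles: a connected cover of n residues with every residue having exactly
    # one incoming step is a tree; cycles manifest as unreachable residues.
    if not violations:
        try:
            placement_steps(tree)
        except FoldTreeError as err:
            violations.append(f"cycle: {err}")

    # jump numbering
    jumps = [e.label for e in tree.edges if e.is_jump]
    if len(set(jumps)) != len(jumps):
        violations.append("duplicate jump numbers")
    if jumps and sorted(set(jumps)) != list(range(1, len(set(jumps)) + 1)):
        violations.append(f"jump numbers not consecutive from 1: {sorted(set(jumps))}")

    # cut bookkeeping: cuts are exactly the broken adjacencies
    adj = tree.peptide_adjacencies()
    broken = {i for i in range(1, n_residues) if i not in adj}
    declared = set(tree.cuts)
    if declared - broken:
        violations.append(f"declared cuts not broken in the tree: {sorted(declared - broken)}")
    if broken - declared:
        violations.append(f"broken adjacencies missing from cut list: {sorted(broken - declared)}")
    if not violations and len(tree.cuts) != len(jumps):
        violations.append(
            f"cut/jump count mismatch: {len(tree.cuts)} cuts vs {len(jumps)} jumps"
        )
    return violations


# -- downstream sets --------------------------------------------------------

def downstream_set(tree: FoldTree, dof: DoFID) -> Set[int]:
    """Residues whose backbone (N, CA, C) atoms move when `dof` changes.

    Derived from the placement dependency graph: an atom moves if its
    placement reads the DoF or references a moved atom.  The pivot residue is
    included when one of its own N/CA/C atoms moves (e.g. phi moves the
    residue's own C); a psi/omega pivot moves only later-placed residues.
    """
    steps = placement_steps(tree)
    placed_by: Dict[int, tuple] = {}
    for step in steps:
        placed_by[step[-1]] = step

    if dof.kind is DoFKind.JUMP_RB:
        if dof.jump not in tree.jump_edges:
            raise FoldTreeError(f"no jump numbered {dof.jump} in fold tree")
    else:
        if not (1 <= dof.residue <= tree.n_residues):
            raise FoldTreeError(f"residue {dof.residue} not on fold tree")

    # moved[residue] = set of that residue's moved backbone atoms ('N','CA','C')
    moved: Dict[int, Set[str]] = {}

    def mark(res: int, atoms: Iterable[str]):
        moved.setdefault(res, set()).update(atoms)

    for step in steps:
        kind = step[0]
        if kind == "root":
            continue
        dst = step[-1]
        src = step[-2]
        src_moved = moved.get(src, set())
        if kind == "jump":
            reads_dof = dof.kind is DoFKind.JUMP_RB and dof.jump == step[1]
            # jump placement reads the full source stub (N, CA, C)
            if reads_dof or src_moved:
                mark(dst, ("N", "CA", "C"))
        elif kind == "fwd":
            # N(dst) <- psi(src); CA(dst) <- omega(src); C(dst) <- phi(dst)
            n_m = (dof == DoFID.psi(src)) or bool(src_moved & {"N", "CA", "C"})
            ca_m = n_m or (dof == DoFID.omega(src)) or bool(src_moved & {"CA", "C"})
            c_m = ca_m or (dof == DoFID.phi(dst))
            atoms = set()
            if n_m:
                atoms.add("N")
            if ca_m:
                atoms.add("CA")
            if c_m:
                atoms.add("C")
            if atoms:
                mark(dst, atoms)
        elif kind == "bwd":
            # C(dst) <- phi(src); CA(dst) <- omega(dst); N(dst) <- psi(dst)
            c_m = (dof == DoFID.phi(src)) or bool(src_moved & {"N", "CA", "C"})
            ca_m = c_m or (dof == DoFID.omega(dst))
            n_m = ca_m or (dof == DoFID.psi(dst))
            atoms = set()
            if c_m:
                atoms.add("C")
            if ca_m:
                atoms.add("CA")
            if n_m:
                atoms.add("N")
            if atoms:
                mark(dst, atoms)
    # the pivot residue's own placed-later atoms: handled above only via
    # fwd/bwd steps into it; for a forward-placed pivot, phi moves its C
    if dof.is_torsion and dof.kind is DoFKind.PHI:
        step = placed_by.get(dof.residue)
        if step is not None and step[0] == "fwd":
            mark(dof.residue, ("C",))
        if step is not None and step[0] == "root":
            # root residue's phi moves its own C only in backward context; as
            # tree root nothing upstream exists, so nothing moves via phi
            pass
    return set(moved)


# -- cut placement ----------------------------------------------------------

def random_cut_placement(
    segments: Sequence[Tuple[int, int]],
    forbidden: Set[int],
    rng,
) -> int:
    """Uniformly random allowed cut position.

    `segments` are inclusive (start, stop) position intervals; a position i
    means the i -> i+1 peptide connection.  Reproducible for a seeded
    numpy Generator `rng`.
    """
    allowed = sorted(
        {p for start, stop in segments for p in range(start, stop + 1)} - set(forbidden)
    )
    if not allowed:
        intervals = ", ".join(f"[{s},{e}]" for s, e in segments)
        raise NoLegalCutError(
            f"no legal cutpoint in segments {intervals}; forbidden positions: "
            f"{_format_intervals(sorted(forbidden))}"
        )
    return int(allowed[int(rng.integers(len(allowed)))])


def _format_intervals(positions: List[int]) -> str:
    if not positions:
        return "(none)"
    spans = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        spans.append((start, prev))
        start = prev = p
    spans.append((start, prev))
    return ", ".join(f"[{s},{e}]" if s != e else f"[{s}]" for s, e in spans)
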