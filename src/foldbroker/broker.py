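"""The Broker: collect claims from client movers, build one consensus fold
tree satisfying all of them, and issue per-client DoF passports.

Broking runs in three phases, because later fold-tree properties depend on
earlier ones (a jump cannot link residues that do not yet exist):

1. sequence changes — virtual residues are appended, in claim order;
2. topology — jumps are wired in and, for every cycle a jump (or chain
   boundary) would create, exactly one cut is placed, randomized per seed
   and honoring every claim's forbidden/required cut regions;
3. DoF accessibility — each scalar degree of freedom is granted per the
   control-strength matrix, or broking fails naming the two clients that
   conflict and the DoF they conflict at.

On success the input conformation is wrapped in a protected conformation and
each client receives a passport; on any failure the input is untouched and no
passports exist.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np

from . import foldtree as ft
from . import selectors as sel
from .dofs import DoFID, jump_dofs
from .enforcement import Passport, ProtectedConformation
from .geometry import RigidTransform
from .kinematics import Conformation

__all__ = [
    "ControlStrength",
    "BrokingError",
    "AccessConflictError",
    "TorsionClaim",
    "JumpClaim",
    "CutClaim",
    "VirtualResidueClaim",
    "ResidueElement",
    "JumpElement",
    "CutElement",
    "DoFElement",
    "BrokerResult",
    "Broker",
    "expand_jump_claim",
    "resolve_access",
    "build_consensus_tree",
]


class ControlStrength(enum.IntEnum):
    """How strongly a client needs a DoF, totally ordered weakest to strongest."""

    DOES_NOT_CONTROL = 0
    CAN_CONTROL = 1
    MUST_CONTROL = 2
    EXCLUSIVE = 3


class BrokingError(RuntimeError):
    pass


class AccessConflictError(BrokingError):
    def __init__(self, dof: DoFID, client_a: str, strength_a, client_b: str, strength_b):
        self.dof = dof
        self.clients = (client_a, client_b)
        super().__init__(
            f"broking failed: movers {client_a!r} ({strength_a.name}) and "
            f"{client_b!r} ({strength_b.name}) conflict at DoF {dof}"
        )


# -- claims (human-level) ------------------------------------------------------

Anchor = Union[int, Tuple[str, str]]  # residue index, ("virtual", label) or ("chain", id)


@dataclass(frozen=True)
class TorsionClaim:
    """Access request for phi/psi/omega over a residue region."""

    residues: object  # selector spec (Selector, expression string, or iterable)
    strength: ControlStrength
    kinds: Tuple[str, ...] = ("phi", "psi", "omega")
    owner: Optional[str] = None


@dataclass(frozen=True)
class JumpClaim:
    """Request for a jump between two anchors; expands to six rigid-body DoF
    elements, one jump element and one cut element."""

    anchor_a: Anchor
    anchor_b: Anchor
    strength: ControlStrength
    fixed_transform: Optional[RigidTransform] = None
    cut_interval: Optional[Tuple[int, int]] = None  # required cut region, if any
    owner: Optional[str] = None


@dataclass(frozen=True)
class CutClaim:
    """Forbid (or fix) cut placement in residue-position intervals."""

    forbidden: Tuple[Tuple[int, int], ...] = ()
    fixed: Optional[int] = None
    owner: Optional[str] = None


@dataclass(frozen=True)
class VirtualResidueClaim:
    """Request a frame-only residue: attach = ("com", chain_id) or ("root",).

    Claims with the same label from different clients are merged; the first
    attachment rule wins and later conflicting rules are an error.
    """

    label: str
    attach: Tuple
    owner: Optional[str] = None


Claim = Union[TorsionClaim, JumpClaim, CutClaim, VirtualResidueClaim]


# -- elements (machine-level) ---------------------------------------------------

@dataclass(frozen=True)
class ResidueElement:
    owner: str
    label: str
    attach: Tuple


@dataclass(frozen=True)
class JumpElement:
    owner: str
    anchor_a: Anchor
    anchor_b: Anchor
    fixed_transform: Optional[RigidTransform] = None
    cut_interval: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class CutElement:
    owner: str
    forbidden: Tuple[Tuple[int, int], ...] = ()
    fixed: Optional[int] = None


@dataclass(frozen=True)
class DoFElement:
    """An access request for one scalar DoF.  For jump DoFs claimed before the
    topology phase resolves jump numbers, `dof` is None and `jump_anchors`/`rb`
    identify the pending DoF."""

    owner: str
    strength: ControlStrength
    dof: Optional[DoFID] = None
    jump_anchors: Optional[Tuple[Anchor, Anchor]] = None
    rb: int = 0


def expand_jump_claim(claim: JumpClaim) -> List[object]:
    """Machine-level expansion of one jump claim: exactly six DoF elements
    (rb1..rb6 at the claim's control strength), one jump element, one cut
    element."""
    if claim.owner is None:
        raise BrokingError("jump claim has no owner; register it through a client")
    anchors = (claim.anchor_a, claim.anchor_b)
    elements: List[object] = [
        DoFElement(claim.owner, claim.strength, jump_anchors=anchors, rb=rb)
        for rb in range(1, 7)
    ]
    elements.append(
        JumpElement(claim.owner, claim.anchor_a, claim.anchor_b,
                    claim.fixed_transform, claim.cut_interval)
    )
    elements.append(CutElement(claim.owner))
    return elements


# -- access resolution ----------------------------------------------------------

def resolve_access(
    claimants_by_dof: Dict[DoFID, List[Tuple[str, ControlStrength]]],
) -> Dict[DoFID, FrozenSet[str]]:
    """Grant DoF access per the control-strength matrix.

    EXCLUSIVE x (EXCLUSIVE | MUST_CONTROL) fails; EXCLUSIVE demotes every
    CAN_CONTROL claimant; DOES_NOT_CONTROL is never granted; in all other
    cases every claimant is granted.  More than two claimants are resolved
    pairwise.  Raises AccessConflictError naming both movers and the DoF.
    """
    grants: Dict[DoFID, FrozenSet[str]] = {}
    for dof in sorted(claimants_by_dof):
        # one effective strength per client: its strongest claim on this DoF
        strengths: Dict[str, ControlStrength] = {}
        for owner, s in claimants_by_dof[dof]:
            if owner not in strengths or s > strengths[owner]:
                strengths[owner] = s
        exclusive = sorted(o for o, s in strengths.items() if s is ControlStrength.EXCLUSIVE)
        must = sorted(o for o, s in strengths.items() if s is ControlStrength.MUST_CONTROL)
        can = sorted(o for o, s in strengths.items() if s is ControlStrength.CAN_CONTROL)
        if len(exclusive) >= 2:
            raise AccessConflictError(
                dof, exclusive[0], ControlStrength.EXCLUSIVE,
                exclusive[1], ControlStrength.EXCLUSIVE,
            )
        if exclusive and must:
            raise AccessConflictError(
                dof, exclusive[0], ControlStrength.EXCLUSIVE,
                must[0], ControlStrength.MUST_CONTROL,
            )
        if exclusive:
            granted = frozenset(exclusive)
        else:
            granted = frozenset(must) | frozenset(can)
        grants[dof] = granted
    return grants


# -- consensus tree construction -------------------------------------------------

def build_consensus_tree(
    n_residues: int,
    chain_ranges: Sequence[Tuple[int, int]],
    jump_elements: Sequence[JumpElement],
    cut_elements: Sequence[CutElement],
    seed: int,
    root: int = 1,
    anchor_resolver=None,
) -> Tuple[ft.FoldTree, Dict[FrozenSet[int], int]]:
    """Build the one fold tree that satisfies all topology elements.

    Every cycle created by a claimed jump is broken by exactly one cut, drawn
    uniformly among allowed positions (seeded per jump, so the result does not
    depend on client registration order).  Chains left unconnected by claims
    are attached to the root by automatic jumps.  Returns the validated tree
    and the anchor-pair -> jump-number map.
    """
    resolve_anchor = anchor_resolver or (lambda a: int(a))

    graph = nx.Graph()
    graph.add_nodes_from(range(1, n_residues + 1))
    for start, stop in chain_ranges:
        for i in range(start, stop):
            graph.add_edge(i, i + 1, kind="pep")

    forbidden: Dict[int, Set[str]] = {}
    for ce in cut_elements:
        for lo, hi in ce.forbidden:
            for p in range(lo, hi + 1):
                forbidden.setdefault(p, set()).add(ce.owner)
    fixed_cuts = sorted({ce.fixed for ce in cut_elements if ce.fixed is not None})
    for p in fixed_cuts:
        if graph.has_edge(p, p + 1):
            graph.remove_edge(p, p + 1)

    # deduplicate jump elements per anchor pair, merging constraints
    resolved: Dict[FrozenSet[int], JumpElement] = {}
    order: List[FrozenSet[int]] = []
    for je in jump_elements:
        a = resolve_anchor(je.anchor_a)
        b = resolve_anchor(je.anchor_b)
        if a == b:
            raise BrokingError(
                f"jump claim of {je.owner!r} has identical anchors ({a})"
            )
        key = frozenset((a, b))
        je = replace(je, anchor_a=a, anchor_b=b)
        if key in resolved:
            prev = resolved[key]
            if (
                prev.fixed_transform is not None
                and je.fixed_transform is not None
                and prev.fixed_transform.distance(je.fixed_transform) > 1e-9
            ):
                raise BrokingError(
                    f"movers {prev.owner!r} and {je.owner!r} claim the same jump "
                    f"{tuple(sorted(key))} with different fixed geometries"
                )
            if prev.fixed_transform is None and je.fixed_transform is not None:
                resolved[key] = replace(prev, fixed_transform=je.fixed_transform)
        else:
            resolved[key] = je
            order.append(key)

    # canonical processing order: independent of registration order
    order.sort(key=lambda k: tuple(sorted(k)))

    directed_anchors: Dict[FrozenSet[int], Tuple[int, int]] = {}
    for key in order:
        je = resolved[key]
        a, b = je.anchor_a, je.anchor_b
        if nx.has_path(graph, a, b):
            path = nx.shortest_path(graph, a, b)
            candidates = sorted(
                min(u, v)
                for u, v in zip(path, path[1:])
                if graph.edges[u, v]["kind"] == "pep"
            )
            if not candidates:
                raise BrokingError(
                    f"jump {tuple(sorted(key))} of {je.owner!r} closes a cycle "
                    "containing no breakable peptide connection"
                )
            if je.cut_interval is not None:
                lo, hi = je.cut_interval
                candidates = [p for p in candidates if lo <= p <= hi]
                if not candidates:
                    raise BrokingError(
                        f"jump {tuple(sorted(key))} of {je.owner!r} requires a cut "
                        f"in [{lo},{hi}] but no breakable position lies there"
                    )
            allowed = [p for p in candidates if p not in forbidden]
            if not allowed:
                blockers = sorted(
                    {o for p in candidates for o in forbidden.get(p, ())}
                )
                raise BrokingError(
                    f"no legal cutpoint for the cycle closed by jump "
                    f"{tuple(sorted(key))}: candidate interval "
                    f"[{candidates[0]},{candidates[-1]}] is fully forbidden by "
                    f"movers {blockers}"
                )
            rng = np.random.default_rng([seed, min(key), max(key)])
            cut = ft.random_cut_placement([(p, p) for p in allowed], set(), rng)
            graph.remove_edge(cut, cut + 1)
        graph.add_edge(a, b, kind="jump")
        directed_anchors[key] = (a, b)

    # attach any components not reachable from the root
    auto_keys: List[FrozenSet[int]] = []
    comps = sorted(nx.connected_components(graph), key=min)
    root_comp = next(c for c in comps if root in c)
    for comp in comps:
        if comp is root_comp:
            continue
        anchor = min(comp)
        key = frozenset((root, anchor))
        graph.add_edge(root, anchor, kind="jump")
        directed_anchors[key] = (root, anchor)
        auto_keys.append(key)

    # direct the tree away from the root and compress peptide runs
    parent = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(graph.neighbors(u), reverse=True):
            if v not in parent:
                parent[v] = u
                stack.append(v)

    up_steps = set()
    down_steps = set()
    jump_pairs: List[Tuple[int, int]] = []
    for v, u in parent.items():
        if u is None:
            continue
        if graph.edges[u, v]["kind"] == "pep":
            (up_steps if v == u + 1 else down_steps).add(u)
        else:
            jump_pairs.append((u, v))

    edges: List[ft.Edge] = []
    for steps, step in ((up_steps, 1), (down_steps, -1)):
        for start in sorted(steps):
            if start - step in steps:
                continue
            stop = start
            while stop in steps:
                stop += step
            edges.append(ft.Edge(start, stop, ft.PEPTIDE))

    # jump numbering: claimed jumps in canonical anchor order, then automatics
    numbered: Dict[FrozenSet[int], int] = {}
    claimed_keys = [k for k in sorted(order, key=lambda k: tuple(sorted(k)))]
    for num, key in enumerate(claimed_keys + sorted(auto_keys, key=min), start=1):
        numbered[key] = num
    for u, v in jump_pairs:
        edges.append(ft.Edge(u, v, numbered[frozenset((u, v))]))

    cuts = tuple(
        i
        for i in range(1, n_residues)
        if not (graph.has_edge(i, i + 1) and graph.edges[i, i + 1]["kind"] == "pep")
    )
    tree = ft.FoldTree(tuple(edges), root, cuts)
    violations = ft.validate(tree, n_residues)
    if violations:  # pragma: no cover - internal consistency guard
        raise BrokingError("broker produced an invalid fold tree: " + "; ".join(violations))
    return tree, numbered


# -- the broker -------------------------------------------------------------------

@dataclass
class BrokerResult:
    """The contract among all client movers produced by one broking round."""

    fold_tree: ft.FoldTree
    passports: Dict[str, Passport]
    virtual_registry: Dict[str, int]
    jump_map: Dict[FrozenSet[int], int]
    grants: Dict[DoFID, FrozenSet[str]]
    pconf: ProtectedConformation
    fixed_jump_transforms: Dict[int, RigidTransform] = field(default_factory=dict)

    def jump_number(self, anchor_a: int, anchor_b: int) -> int:
        return self.jump_map[frozenset((anchor_a, anchor_b))]


class Broker:
    """Registers client movers, runs the broking process, enforces the result."""

    def __init__(self, named_selectors: Optional[Dict[str, sel.Selector]] = None):
        self._clients: List[object] = []
        self._broked = False
        self.named_selectors = named_selectors or {}

    def register(self, client) -> None:
        if self._broked:
            raise BrokingError("cannot register clients after broking has run")
        name = getattr(client, "name", None)
        if not name:
            raise BrokingError("client movers must have a nonempty .name")
        if client in self._clients or any(
            getattr(c, "name", None) == name for c in self._clients
        ):
            raise BrokingError(f"duplicate client {name!r}")
        self._clients.append(client)

    @property
    def clients(self) -> Tuple[object, ...]:
        return tuple(self._clients)

    def broke(self, conformation: Conformation, seed: int) -> BrokerResult:
        """Run the three broking phases and return the brokered contract.

        All-or-nothing: on any conflict the input conformation is unmodified
        and no passports are issued.
        """
        self._broked = True
        seed = int(seed) & 0x7FFFFFFF
        work = conformation.copy()
        work.named_selectors = self.named_selectors

        # collect claims; per-client rng is derived from (seed, client name) so
        # per-trajectory choices do not depend on registration order
        claims: List[Claim] = []
        for client in self._clients:
            rng = np.random.default_rng([seed, zlib.crc32(client.name.encode())])
            for claim in client.yield_claims(work, rng):
                if claim.owner is None:
                    claim = replace(claim, owner=client.name)
                claims.append(claim)

        # phase 1: sequence changes (virtual residues, appended in claim order)
        registry: Dict[str, int] = {}
        attach_rules: Dict[str, Tuple] = {}
        root_label: Optional[str] = None
        for claim in claims:
            if not isinstance(claim, VirtualResidueClaim):
                continue
            if claim.label in attach_rules:
                if attach_rules[claim.label] != claim.attach:
                    raise BrokingError(
                        f"virtual residue {claim.label!r} claimed with conflicting "
                        f"attachment rules {attach_rules[claim.label]} and {claim.attach}"
                    )
                continue
            attach_rules[claim.label] = claim.attach
            stub = _attach_stub(work, claim.attach)
            registry[claim.label] = work.add_virtual_residue(claim.label, stub)
            if claim.attach[0] == "root":
                root_label = claim.label

        # phase 2: fold tree topology
        jump_elements: List[JumpElement] = []
        cut_elements: List[CutElement] = []
        pending_dofs: List[DoFElement] = []
        for claim in claims:
            if isinstance(claim, JumpClaim):
                for el in expand_jump_claim(claim):
                    if isinstance(el, JumpElement):
                        jump_elements.append(el)
                    elif isinstance(el, CutElement):
                        cut_elements.append(el)
                    else:
                        pending_dofs.append(el)
            elif isinstance(claim, CutClaim):
                cut_elements.append(
                    CutElement(claim.owner, tuple(claim.forbidden), claim.fixed)
                )

        root = registry[root_label] if root_label else 1

        def resolve_anchor(anchor: Anchor) -> int:
            if isinstance(anchor, int):
                if not (1 <= anchor <= work.n_residues):
                    raise BrokingError(f"jump anchor {anchor} outside residue range")
                return anchor
            kind, name = anchor
            if kind == "virtual":
                if name not in registry:
                    raise BrokingError(f"jump anchored at unknown virtual residue {name!r}")
                return registry[name]
            if kind == "chain":
                chain = work.chain_by_id(name)
                return (chain.start + chain.stop) // 2
            raise BrokingError(f"unresolvable jump anchor {anchor!r}")

        tree, jump_map = build_consensus_tree(
            work.n_residues,
            [(c.start, c.stop) for c in work.chains],
            jump_elements,
            cut_elements,
            seed,
            root=root,
            anchor_resolver=resolve_anchor,
        )

        # phase 3: DoF accessibility
        claimants: Dict[DoFID, List[Tuple[str, ControlStrength]]] = {}
        for claim in claims:
            if isinstance(claim, TorsionClaim):
                residues = sel.resolve(claim.residues, work, self.named_selectors)
                for r in sorted(residues):
                    for kind in claim.kinds:
                        dof = DoFID.torsion(kind, r)
                        claimants.setdefault(dof, []).append((claim.owner, claim.strength))
        for el in pending_dofs:
            a = resolve_anchor(el.jump_anchors[0])
            b = resolve_anchor(el.jump_anchors[1])
            num = jump_map[frozenset((a, b))]
            dof = DoFID.jump_rb(num, el.rb)
            claimants.setdefault(dof, []).append((el.owner, el.strength))

        grants = resolve_access(claimants)

        # success: mutate only the working copy from here on
        work.set_fold_tree(tree, keep_coords=True)
        token = object()
        passports = {
            client.name: Passport(
                owner=client.name,
                granted=frozenset(
                    dof for dof, owners in grants.items() if client.name in owners
                ),
                token=token,
            )
            for client in self._clients
        }
        pconf = ProtectedConformation(work, token=token, grants=grants)

        fixed: Dict[int, RigidTransform] = {}
        for je in jump_elements:
            if je.fixed_transform is not None:
                a = resolve_anchor(je.anchor_a)
                b = resolve_anchor(je.anchor_b)
                fixed[jump_map[frozenset((a, b))]] = je.fixed_transform

        result = BrokerResult(
            fold_tree=tree,
            passports=passports,
            virtual_registry=registry,
            jump_map=jump_map,
            grants=grants,
            pconf=pconf,
            fixed_jump_transforms=fixed,
        )
        # communicate brokered results back to each client
        for client in self._clients:
            configure = getattr(client, "configure", None)
            if configure is not None:
                configure(result)
        return result


def _attach_stub(conf: Conformation, attach: Tuple) -> RigidTransform:
    kind = attach[0]
    if kind == "com":
        chain = conf.chain_by_id(attach[1])
        if chain.start > chain.stop:
            raise BrokingError(f"chain {attach[1]!r} is empty")
        xyz = conf.xyz[chain.start - 1 : chain.stop]  # all backbone atoms
        return RigidTransform(np.eye(3), xyz.reshape(-1, 3).mean(axis=0))
    if kind == "root":
        xyz = conf.xyz[~conf.virtual].reshape(-1, 3)
        return RigidTransform(np.eye(3), xyz.mean(axis=0))
    if kind == "fixed":
        return attach[1]
    raise BrokingError(f"unknown virtual-residue attachment rule {attach!r}")
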