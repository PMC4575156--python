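"""Programmatic generation of all test inputs.

The three canonical fixtures emulate the constraint topology of three
protocol archetypes at toy scale — (1) ab initio folding with a rigid chunk
and beta-strand pairing jumps, (2) domain-insertion modeling with a
discontinuous fixed host, (3) multibody docking through center-of-mass
virtual residues with loop closure.  They emulate constraint topology, not
the structures of real proteins; same spec + seed gives a byte-identical
fixture.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .clients import (
    FragmentEntry,
    FragmentLibrary,
    StrandPairing,
    StrandPairingSet,
)
from .kinematics import Conformation, build_ideal_polypeptide
from .pdbio import write_pdb

__all__ = ["Fixture", "make_vignette1_fixture", "make_vignette2_fixture", "make_vignette3_fixture"]


@dataclass
class Fixture:
    """A generated test input set: structure, optional template/fragments/
    pairings, and a declarative protocol config referencing the files that
    ``write`` produces."""

    name: str
    conformation: Conformation
    config: Dict
    template: Optional[Conformation] = None
    fragments: Optional[FragmentLibrary] = None
    pairings: Optional[StrandPairingSet] = None

    def write(self, outdir: str) -> Dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {"config": os.path.join(outdir, "config.yaml")}
        paths["pdb"] = os.path.join(outdir, "structure.pdb")
        write_pdb(self.conformation, paths["pdb"])
        if self.template is not None:
            paths["template"] = os.path.join(outdir, "template.pdb")
            write_pdb(self.template, paths["template"])
        if self.fragments is not None:
            paths["fragments"] = os.path.join(outdir, "fragments.frag")
            self.fragments.write(paths["fragments"])
        if self.pairings is not None:
            paths["topology"] = os.path.join(outdir, "topology.top")
            self.pairings.write(paths["topology"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=False)
        return paths


def _harvest_fragments(
    conf: Conformation, positions, rng, jitter_deg: float = 15.0
) -> FragmentLibrary:
    """Fragment windows harvested from a structure: the native torsions of
    each window plus one jittered variant (3-9 residue windows)."""
    entries: List[FragmentEntry] = []
    lengths = (3, 4, 5, 6, 7, 8, 9)
    for k, pos in enumerate(positions):
        length = lengths[k % len(lengths)]
        if pos + length - 1 > conf.n_residues:
            length = 3
        native = tuple(
            (
                conf.get_torsion("phi", r),
                conf.get_torsion("psi", r),
                conf.get_torsion("omega", r),
            )
            for r in range(pos, pos + length)
        )
        entries.append(FragmentEntry(pos, native))
        jitter = rng.uniform(-jitter_deg, jitter_deg, size=(length, 2))
        perturbed = tuple(
            (phi + jitter[i, 0], psi + jitter[i, 1], omega)
            for i, (phi, psi, omega) in enumerate(native)
        )
        entries.append(FragmentEntry(pos, perturbed))
    return FragmentLibrary(tuple(entries))


def make_vignette1_fixture(seed: int) -> Fixture:
    """76-residue single-chain toy: helix at 23-34 (strand elsewhere), a rigid
    chunk covering residues 17-40 fixed from a template, fragments harvested
    from the structure itself, and two candidate terminal strand pairings."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 1])
    conf = build_ideal_polypeptide(76, torsion_preset="strand")
    for r in range(23, 35):
        conf.set_torsion("phi", r, -57.0)
        conf.set_torsion("psi", r, -47.0)
    template = conf.copy()
    fragments = _harvest_fragments(conf, range(1, 69, 3), rng)
    pairings = StrandPairingSet(
        ((StrandPairing(3, 70, "A", 0), StrandPairing(4, 69, "A", 0)),)
    )
    config = {
        "inputs": {
            "pdb": "structure.pdb",
            "template": "template.pdb",
            "fragments": "fragments.frag",
            "topology": "topology.top",
        },
        "selectors": {"chunk_region": "range(17,40)"},
        "clients": [
            {"type": "rigid_chunk", "name": "chunk", "region": "chunk_region",
             "template": "template.pdb"},
            {"type": "fragment_insertion", "name": "frag", "fragments": "fragments.frag"},
            {"type": "strand_jumps", "name": "strand", "topology": "topology.top"},
        ],
        "schedule": {"cycles": 500, "temperature": [2.0, 0.5], "n_struct": 1,
                     "weights": {"chunk": 0.0, "frag": 4.0, "strand": 1.0}},
        "score": {"clash": 1.0, "chainbreak": 1.0},
    }
    return Fixture("vignette1", conf, config, template, fragments, pairings)


def make_vignette2_fixture(seed: int) -> Fixture:
    """Domain-insertion toy: an 80-residue chain whose host domain is the two
    discontinuous segments 1-20 and 61-80 (helical, fixed from a template and
    pinned by one fixed jump); the 21-60 insert starts extended and is folded
    by fragment insertion and one strand-pairing jump.  Cuts can fall only in
    the insert."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2])
    torsions = []
    for r in range(1, 81):
        if r <= 20 or r >= 61:
            torsions.append((-57.0, -47.0, 180.0))
        else:
            torsions.append((-135.0, 135.0, 180.0))
    template = build_ideal_polypeptide(80, torsion_preset=torsions)
    conf = template.copy()
    for r in range(21, 61):
        conf.set_torsion("phi", r, 180.0)
        conf.set_torsion("psi", r, 180.0)
    fragments = _harvest_fragments(template, range(21, 53, 3), rng)
    pairings = StrandPairingSet(((StrandPairing(25, 55, "A", 0),),))
    config = {
        "inputs": {
            "pdb": "structure.pdb",
            "template": "template.pdb",
            "fragments": "fragments.frag",
            "topology": "topology.top",
        },
        "selectors": {"host": "or(range(1,20),range(61,80))", "insert": "range(21,60)"},
        "clients": [
            {"type": "rigid_chunk", "name": "host_chunk", "region": "host",
             "template": "template.pdb"},
            {"type": "fragment_insertion", "name": "frag", "fragments": "fragments.frag"},
            {"type": "strand_jumps", "name": "strand", "topology": "topology.top"},
        ],
        "schedule": {"cycles": 500, "temperature": [2.0, 0.5], "n_struct": 1,
                     "weights": {"host_chunk": 0.0, "frag": 4.0, "strand": 1.0}},
        "score": {"clash": 1.0, "chainbreak": 1.0},
    }
    return Fixture("vignette2", conf, config, template, fragments, pairings)


def make_vignette3_fixture(seed: int) -> Fixture:
    """Three-chain docking toy (chains H, L, C): each chain is docked through
    a center-of-mass virtual residue to a root virtual residue (a star fold
    tree); the two H-chain loops are bypassed by jumps, interrupted by cuts,
    and closed by CCD."""
    conf = build_ideal_polypeptide(
        75, chain_spec=[30, 25, 20], chain_ids=["H", "L", "C"], torsion_preset="helix"
    )
    loops = [(10, 15), (20, 25)]
    config = {
        "inputs": {"pdb": "structure.pdb"},
        "selectors": {
            "antigen": "chain(C)",
            "antibody": "or(chain(H),chain(L))",
        },
        "clients": (
            [{"type": "com_tracker", "name": f"com_{c}", "chain": c} for c in "HLC"]
            + [{"type": "dock", "name": f"dock_{c}", "chain": c,
                "rot_mag": 3.0, "trans_mag": 0.5} for c in "HLC"]
            + [{"type": "ccd_loop", "name": f"loop_{s}_{e}", "loop": [s, e],
                "max_iter": 50, "tol": 0.05} for s, e in loops]
        ),
        "schedule": {"cycles": 300, "temperature": [2.0, 0.5], "n_struct": 1,
                     "weights": {"com_H": 1, "com_L": 1, "com_C": 1,
                                 "dock_H": 3, "dock_L": 3, "dock_C": 3,
                                 "loop_10_15": 2, "loop_20_25": 2}},
        "score": {"clash": 1.0, "chainbreak": 1.0},
    }
    return Fixture("vignette3", conf, config)


FIXTURES = {
    "vignette1": make_vignette1_fixture,
    "vignette2": make_vignette2_fixture,
    "vignette3": make_vignette3_fixture,
}


class StaticClaimClient:
    """Minimal client mover that yields a fixed list of claims (fuzz/testing)."""

    def __init__(self, name: str, claims):
        self.name = name
        self.claims = list(claims)
        self.passport = None

    def yield_claims(self, conf, rng):
        return list(self.claims)

    def configure(self, result):
        self.passport = result.passports[self.name]

    def initialize(self, pconf, rng):
        pass

    def apply(self, pconf, rng):
        from .clients import MoveOutcome

        return MoveOutcome(False, "static client")


def random_claim_system(rng) -> Tuple[Conformation, List[StaticClaimClient]]:
    """A random toy system plus a random, typically resolvable, claim set:
    chains of 20-100 residues, optional exclusive chunk regions, torsion
    claims and jump claims.  Used by fold-tree fuzzing."""
    from .broker import ControlStrength, CutClaim, JumpClaim, TorsionClaim

    n = int(rng.integers(20, 101))
    n_chains = int(rng.integers(1, 4))
    if n_chains == 1:
        lengths = [n]
    else:
        bounds = sorted(rng.choice(np.arange(8, n - 7), size=n_chains - 1, replace=False))
        bounds = [0] + [int(b) for b in bounds] + [n]
        lengths = [bounds[k + 1] - bounds[k] for k in range(n_chains)]
        if min(lengths) < 4:
            lengths = [n]
    conf = build_ideal_polypeptide(n, chain_spec=lengths, torsion_preset="strand")

    clients: List[StaticClaimClient] = []
    if rng.random() < 0.5:
        lo = int(rng.integers(2, n - 8))
        hi = min(n - 1, lo + int(rng.integers(4, 12)))
        clients.append(
            StaticClaimClient(
                "chunk",
                [
                    TorsionClaim(tuple(range(lo, hi + 1)), ControlStrength.EXCLUSIVE),
                    CutClaim(forbidden=((lo, hi - 1),)),
                ],
            )
        )
    for k in range(int(rng.integers(0, 3))):
        lo = int(rng.integers(1, n - 4))
        hi = min(n, lo + int(rng.integers(3, 20)))
        clients.append(
            StaticClaimClient(
                f"frag{k}",
                [TorsionClaim(tuple(range(lo, hi + 1)), ControlStrength.CAN_CONTROL)],
            )
        )
    for k in range(int(rng.integers(0, 3))):
        a = int(rng.integers(1, n - 5))
        b = int(rng.integers(a + 4, n + 1))
        strength = ControlStrength.MUST_CONTROL if rng.random() < 0.7 else ControlStrength.CAN_CONTROL
        clients.append(StaticClaimClient(f"jump{k}", [JumpClaim(a, b, strength)]))
    return conf, clients
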