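"""Declarative protocol configuration: YAML -> clients + schedule + score.

A config document has blocks ``inputs`` (file paths, relative to the config
file), ``selectors`` (named residue selectors), ``clients`` (ordered client
mover definitions), ``schedule`` and ``score``.
"""

from __future__ import annotations

import os
from typing import Dict, List, Tuple

import yaml

from . import selectors as sel
from .clients import (
    CCDLoopCloseClient,
    CoMTrackerClient,
    FragmentInsertionClient,
    RigidBodyDockClient,
    RigidChunkClient,
    StrandPairingSet,
    FragmentLibrary,
)
from .kinematics import Conformation
from .pdbio import read_pdb
from .sampling import Protocol, ToyScore

__all__ = ["load_protocol", "build_protocol"]


class ConfigError(ValueError):
    pass


def load_protocol(config_path: str) -> Tuple[Protocol, Conformation]:
    """Load a YAML protocol config; paths are resolved against its directory."""
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    return build_protocol(config, base_dir=os.path.dirname(os.path.abspath(config_path)))


def build_protocol(config: Dict, base_dir: str = ".") -> Tuple[Protocol, Conformation]:
    def path(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base_dir, p)

    inputs = config.get("inputs", {})
    if "pdb" not in inputs:
        raise ConfigError("config must name an input PDB under inputs.pdb")
    start = read_pdb(path(inputs["pdb"]))

    named = {
        name: sel.parse_selector(expr)
        for name, expr in (config.get("selectors") or {}).items()
    }
    # make named selectors resolvable against the loaded structure
    start.named_selectors = named

    clients: List[object] = []
    for block in config.get("clients", []):
        ctype = block.get("type")
        name = block.get("name")
        if not ctype or not name:
            raise ConfigError(f"client block needs type and name: {block}")
        if ctype == "rigid_chunk":
            template = read_pdb(path(block["template"]))
            clients.append(RigidChunkClient(name, template, block["region"]))
        elif ctype == "fragment_insertion":
            library = FragmentLibrary.read(path(block["fragments"]))
            clients.append(FragmentInsertionClient(name, library, block.get("region")))
        elif ctype == "strand_jumps":
            from .clients import StrandPairJumpClient

            pairings = StrandPairingSet.read(path(block["topology"]))
            clients.append(StrandPairJumpClient(name, pairings))
        elif ctype == "com_tracker":
            clients.append(CoMTrackerClient(name, block["chain"]))
        elif ctype == "dock":
            clients.append(
                RigidBodyDockClient(
                    name,
                    chain_id=block.get("chain"),
                    rot_mag=block.get("rot_mag", 3.0),
                    trans_mag=block.get("trans_mag", 0.5),
                )
            )
        elif ctype == "ccd_loop":
            clients.append(
                CCDLoopCloseClient(
                    name,
                    tuple(block["loop"]),
                    max_iter=block.get("max_iter", 100),
                    tol=block.get("tol", 0.05),
                )
            )
        else:
            raise ConfigError(f"unknown client type {ctype!r}")

    schedule = config.get("schedule", {})
    score_cfg = config.get("score", {})
    score = ToyScore(
        clash=score_cfg.get("clash", 1.0),
        chainbreak=score_cfg.get("chainbreak", 1.0),
        pair=score_cfg.get("pair", 0.0),
        pairs=score_cfg.get("pairs", ()),
    )
    temperature = schedule.get("temperature", 1.0)
    if isinstance(temperature, list):
        temperature = tuple(temperature)
    protocol = Protocol(
        clients=clients,
        cycles=int(schedule.get("cycles", 1000)),
        temperature=temperature,
        weights=schedule.get("weights"),
        n_struct=int(schedule.get("n_struct", 1)),
        score=score,
        named_selectors=named,
    )
    return protocol, start
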