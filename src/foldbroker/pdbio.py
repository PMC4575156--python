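"""Minimal PDB reader/writer: ATOM records, backbone atoms, chain IDs.

Fields follow PDB v3.3 fixed columns.  HETATM records, alternate locations
and insertion codes are rejected with a clear error; the writer emits TER
between chains and skips virtual residues (they carry no physical atoms).
"""

from __future__ import annotations

from typing import List, Optional, TextIO, Union

import numpy as np

from .foldtree import FoldTree
from .kinematics import ATOMS, Chain, Conformation, cartesian_to_internal

__all__ = ["read_pdb", "write_pdb", "PDBFormatError"]


class PDBFormatError(ValueError):
    pass


def write_pdb(conf: Conformation, path_or_handle: Union[str, TextIO]) -> None:
    """Write backbone ATOM records for all non-virtual residues."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            write_pdb(conf, fh)
        return
    fh = path_or_handle
    xyz = conf.xyz
    serial = 0
    prev_chain: Optional[str] = None
    out_res = 0
    for chain in conf.chains:
        if chain.virtual:
            continue
        if prev_chain is not None:
            fh.write("TER\n")
        prev_chain = chain.chain_id
        for res in chain.residues:
            out_res += 1
            for k, name in enumerate(ATOMS):
                serial += 1
                x, y, z = xyz[res - 1, k]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {pdb_name} GLY {chain.chain_id:1s}{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{name[0]:>2s}\n"
                )
    fh.write("TER\nEND\n")


def read_pdb(path_or_handle: Union[str, TextIO]) -> Conformation:
    """Read a backbone-only PDB file into a Conformation.

    Residues are renumbered pose-wide 1..n in file order; the fold tree is the
    default per-chain linear tree with chain-connecting jumps.  Internal
    coordinates are measured from the file's Cartesian coordinates.
    """
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_pdb(fh)
    fh = path_or_handle

    # (chain_id, resseq) in order of appearance -> {atom: xyz}
    residues: List[tuple] = []
    atom_map = {}
    for lineno, line in enumerate(fh, start=1):
        rec = line[:6]
        if rec == "HETATM":
            raise PDBFormatError(f"line {lineno}: HETATM records are not supported")
        if rec != "ATOM  ":
            continue
        altloc = line[16]
        if altloc not in (" ", ""):
            raise PDBFormatError(f"line {lineno}: alternate locations are not supported")
        icode = line[26]
        if icode not in (" ", ""):
            raise PDBFormatError(f"line {lineno}: insertion codes are not supported")
        name = line[12:16].strip()
        if name not in ATOMS:
            continue  # side-chain atoms are ignored
        chain_id = line[21]
        resseq = int(line[22:26])
        key = (chain_id, resseq)
        if key not in atom_map:
            residues.append(key)
            atom_map[key] = {}
        atom_map[key][name] = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )

    if not residues:
        raise PDBFormatError("no ATOM records found")
    # group consecutive residues by chain
    chains: List[Chain] = []
    start = 1
    for idx, (chain_id, _) in enumerate(residues, start=1):
        if not chains or chains[-1].chain_id != chain_id:
            if chains:
                chains[-1] = Chain(chains[-1].chain_id, chains[-1].start, idx - 1)
            chains.append(Chain(chain_id, idx, idx))
            start = idx
    chains[-1] = Chain(chains[-1].chain_id, chains[-1].start, len(residues))
    if len({c.chain_id for c in chains}) != len(chains):
        raise PDBFormatError("chain IDs must form contiguous blocks")

    n = len(residues)
    coords = np.full((n, 4, 3), np.nan)
    for i, key in enumerate(residues):
        atoms = atom_map[key]
        missing = [a for a in ATOMS if a not in atoms]
        if missing:
            raise PDBFormatError(
                f"residue {key[1]} of chain {key[0]} missing backbone atoms: {missing}"
            )
        for k, name in enumerate(ATOMS):
            coords[i, k] = atoms[name]
    topology = Conformation(chains)
    return cartesian_to_internal(coords, topology)
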