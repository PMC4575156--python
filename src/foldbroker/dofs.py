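"""Identifiers for scalar degrees of freedom.

A DoF is one sampled scalar: a backbone torsion (phi/psi/omega of a residue)
or one of the six rigid-body components of a jump (rb1-rb3 translation in Å,
rb4-rb6 rotation-vector components in degrees).  Each rigid-body component is
brokered and access-controlled separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class DoFKind(enum.IntEnum):
    PHI = 0
    PSI = 1
    OMEGA = 2
    JUMP_RB = 3


@dataclass(frozen=True, order=True)
class DoFID:
    """Unique, totally ordered identifier of one scalar degree of freedom."""

    kind: DoFKind
    residue: int = 0        # 1-based residue index; 0 for jump DoFs
    jump: int = 0           # jump number; 0 for torsions
    rb: int = 0             # rb index 1..6; 0 for torsions

    def __post_init__(self) -> None:
        if self.kind is DoFKind.JUMP_RB:
            if self.jump < 1 or not (1 <= self.rb <= 6):
                raise ValueError(f"invalid jump DoF: jump={self.jump} rb={self.rb}")
        else:
            if self.residue < 1:
                raise ValueError(f"invalid torsion DoF: residue={self.residue}")

    @classmethod
    def phi(cls, residue: int) -> "DoFID":
        return cls(DoFKind.PHI, residue=residue)

    @classmethod
    def psi(cls, residue: int) -> "DoFID":
        return cls(DoFKind.PSI, residue=residue)

    @classmethod
    def omega(cls, residue: int) -> "DoFID":
        return cls(DoFKind.OMEGA, residue=residue)

    @classmethod
    def jump_rb(cls, jump: int, rb: int) -> "DoFID":
        return cls(DoFKind.JUMP_RB, jump=jump, rb=rb)

    @classmethod
    def torsion(cls, name: str, residue: int) -> "DoFID":
        return cls(DoFKind[name.upper()], residue=residue)

    @property
    def is_torsion(self) -> bool:
        return self.kind is not DoFKind.JUMP_RB

    def __str__(self) -> str:
        if self.kind is DoFKind.JUMP_RB:
            return f"jump({self.jump}).rb{self.rb}"
        return f"{self.kind.name.lower()}({self.residue})"


def torsion_dofs(residues, kinds=("phi", "psi", "omega")):
    """All torsion DoFIDs of the given kinds over an iterable of residues."""
    return [DoFID.torsion(k, r) for r in residues for k in kinds]


def jump_dofs(jump: int):
    """The six rigid-body DoFIDs of a jump."""
    return [DoFID.jump_rb(jump, rb) for rb in range(1, 7)]
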