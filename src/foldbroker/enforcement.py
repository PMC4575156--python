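"""Passport-based access control over degree-of-freedom modification.

After broking, the conformation is wrapped in a :class:`ProtectedConformation`
that refuses any DoF change not covered by the passport on top of its unlock
stack, and refuses fold-tree replacement outright.  Reads pass through
unchanged.  An :class:`Unlock` is strictly stack-scoped: a client pushes its
passport for the duration of one sampling call and only the top passport is
ever consulted — one membership check per modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional

import numpy as np

from .dofs import DoFID, jump_dofs
from .geometry import RigidTransform
from .kinematics import Conformation, chainbreak_deviation, jump_transform

__all__ = [
    "Passport",
    "Unlock",
    "ProtectedConformation",
    "AuthorizationError",
    "FoldTreeFrozenError",
    "with_unlock",
]


class AuthorizationError(PermissionError):
    pass


class FoldTreeFrozenError(RuntimeError):
    pass


@dataclass(frozen=True)
class Passport:
    """Per-client record of granted DoFs, immutable after broking."""

    owner: str
    granted: FrozenSet[DoFID]
    token: object  # identifies the broking round that issued it

    def __contains__(self, dof: DoFID) -> bool:
        return dof in self.granted


class Unlock:
    """Stack-scoped credential: pushes the passport on entry, pops on exit
    (including error paths).  Only the top of the stack authorizes."""

    def __init__(self, pconf: "ProtectedConformation", passport: Passport):
        if passport.token is not pconf.token:
            raise AuthorizationError(
                f"passport of {passport.owner!r} was issued by a different broking round"
            )
        self._pconf = pconf
        self._passport = passport
        self.active = False

    def __enter__(self) -> "Unlock":
        self._pconf._stack.append(self._passport)
        self.active = True
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        popped = self._pconf._stack.pop()
        assert popped is self._passport, "unlock stack corrupted"
        self.active = False


def with_unlock(pconf: "ProtectedConformation", passport: Passport, action):
    """Run `action()` with `passport` active; returns the action's value.

    The passport is pushed before and popped after the action, on success and
    on error alike.
    """
    with Unlock(pconf, passport):
        return action()


class ProtectedConformation:
    """Conformation wrapper that requires a valid passport for modification.

    The fold tree is never replaced after broking; a DoF granted to nobody is
    immutable for the whole trajectory.  Read access is always permitted.
    """

    def __init__(
        self,
        conformation: Conformation,
        token: object,
        grants: Optional[Dict[DoFID, FrozenSet[str]]] = None,
    ):
        self._conf = conformation
        self.token = token
        self.grants = grants or {}
        self._stack: list[Passport] = []
        self.auth_checks = 0  # instrumentation: one passport lookup per modification

    # -- authorization -------------------------------------------------------
    def _authorize(self, dof: DoFID) -> None:
        self.auth_checks += 1
        if not self._stack:
            raise AuthorizationError(
                f"modification of {dof} with no active unlock; "
                f"granted to: {self._granted_to(dof)}"
            )
        top = self._stack[-1]
        if dof not in top:  # the single passport lookup
            raise AuthorizationError(
                f"mover {top.owner!r} is not granted {dof}; "
                f"granted to: {self._granted_to(dof)}"
            )

    def _granted_to(self, dof: DoFID) -> str:
        owners = sorted(self.grants.get(dof, ()))
        return ", ".join(repr(o) for o in owners) if owners else "(nobody)"

    def unlock(self, passport: Passport) -> Unlock:
        return Unlock(self, passport)

    # -- guarded modification --------------------------------------------------
    def set_dof(self, dof: DoFID, value: float) -> None:
        self._authorize(dof)
        self._conf.set_dof(dof, value)

    def set_torsion(self, name: str, residue: int, degrees: float) -> None:
        self.set_dof(DoFID.torsion(name, residue), degrees)

    def set_jump(self, jump: int, transform: RigidTransform) -> None:
        """Setting a whole jump requires all six of its rigid-body DoFs."""
        for dof in jump_dofs(jump):
            self._authorize(dof)
        self._conf.set_jump(jump, transform)

    def set_fold_tree(self, tree) -> None:
        raise FoldTreeFrozenError(
            "the consensus fold tree is frozen after broking; "
            "re-broker to change the topology"
        )

    # -- pass-through reads ------------------------------------------------------
    @property
    def fold_tree(self):
        return self._conf.fold_tree

    @property
    def n_residues(self) -> int:
        return self._conf.n_residues

    @property
    def chains(self):
        return tuple(self._conf.chains)

    @property
    def virtual(self) -> np.ndarray:
        return self._conf.virtual

    @property
    def xyz(self) -> np.ndarray:
        return self._conf.xyz

    def atom(self, residue: int, name: str) -> np.ndarray:
        return self._conf.atom(residue, name)

    def stub(self, residue: int):
        return self._conf.stub(residue)

    def chain_by_id(self, chain_id: str):
        return self._conf.chain_by_id(chain_id)

    def get_dof(self, dof: DoFID) -> float:
        return self._conf.get_dof(dof)

    def get_torsion(self, name: str, residue: int) -> float:
        return self._conf.get_torsion(name, residue)

    def get_jump(self, jump: int) -> RigidTransform:
        return self._conf.get_jump(jump)

    def jump_transform(self, jump: int) -> RigidTransform:
        return jump_transform(self._conf, jump)

    def chainbreak_deviation(self, cut: int):
        return chainbreak_deviation(self._conf, cut)

    def real_atom_coords(self) -> np.ndarray:
        return self._conf.real_atom_coords()

    def copy_conformation(self) -> Conformation:
        """Detached copy of the wrapped conformation (for output/analysis)."""
        return self._conf.copy()

    # -- driver-level trajectory bookkeeping --------------------------------------
    # Snapshot/restore implement Metropolis rejection at the protocol level;
    # they restore the exact pre-move state and are not a client-facing
    # modification path.
    def snapshot(self) -> Conformation:
        return self._conf.copy()

    def restore(self, snap: Conformation) -> None:
        self._conf = snap.copy()
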