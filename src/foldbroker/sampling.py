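"""Metropolis Monte Carlo protocol driver over brokered clients.

The driver re-brokers per output model (so cut placement is re-randomized per
model), runs a one-time client initialize pass, then cycles: pick a client by
weight, let it apply one move through the protected conformation, score, and
Metropolis-accept.  Rejected moves restore the conformation bit-exactly.
The score is a deliberately simple surrogate — a CA clash term, a chainbreak
term and an optional residue-pair restraint — adequate for exercising the
sampling machinery, with no physical calibration claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .broker import Broker
from .enforcement import ProtectedConformation
from .kinematics import Conformation

__all__ = ["ToyScore", "Protocol", "metropolis_accept", "run_protocol"]


class ToyScore:
    """Weighted sum of nonnegative terms evaluated on (protected) conformations.

    clash: sum over non-neighbor real CA pairs of (4 - d)^2 for d < 4 Å.
    chainbreak: over intra-chain cuts, squared distance gap plus squared
        angle gaps (radians) of the virtual peptide bond.
    pair: harmonic (d - target)^2 on declared CA-CA residue pairs.
    """

    CLASH_RADIUS = 4.0

    def __init__(
        self,
        clash: float = 1.0,
        chainbreak: float = 1.0,
        pair: float = 0.0,
        pairs: Sequence[Tuple[int, int]] = (),
        pair_target: float = 5.0,
    ):
        self.weights = {"clash": float(clash), "chainbreak": float(chainbreak), "pair": float(pair)}
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("score weights must be nonnegative")
        self.pairs = tuple((int(i), int(j)) for i, j in pairs)
        self.pair_target = float(pair_target)

    def terms(self, conf) -> Dict[str, float]:
        xyz = conf.xyz
        virtual = conf.virtual
        real = np.flatnonzero(~virtual)
        ca = xyz[real, 1]
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        seq = (real + 1)
        sep = np.abs(seq[:, None] - seq[None, :])
        mask = (sep >= 2) & (d < self.CLASH_RADIUS)
        iu = np.triu(mask, k=1)
        clash = float(((self.CLASH_RADIUS - d[iu]) ** 2).sum())

        chainbreak = 0.0
        tree = conf.fold_tree
        for cut in tree.cuts:
            ci = cut - 1
            if virtual[ci] or virtual[ci + 1]:
                continue
            chains = conf.chains
            same_chain = any(cut in c and (cut + 1) in c for c in chains)
            if not same_chain:
                continue
            dist, (a1, a2) = conf.chainbreak_deviation(cut) if hasattr(conf, "chainbreak_deviation") else _cbdev(conf, cut)
            chainbreak += dist ** 2 + np.radians(a1) ** 2 + np.radians(a2) ** 2

        pair = 0.0
        for i, j in self.pairs:
            dij = float(np.linalg.norm(xyz[i - 1, 1] - xyz[j - 1, 1]))
            pair += (dij - self.pair_target) ** 2

        return {"clash": clash, "chainbreak": chainbreak, "pair": pair}

    def __call__(self, conf) -> float:
        terms = self.terms(conf)
        return float(sum(self.weights[k] * v for k, v in terms.items()))


def _cbdev(conf, cut):
    from .kinematics import chainbreak_deviation

    return chainbreak_deviation(conf, cut)


def metropolis_accept(delta_score: float, temperature: float, rng) -> bool:
    """Accept iff delta <= 0 or rng.random() < exp(-delta/temperature)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_score <= 0:
        return True
    if np.isinf(delta_score):
        return False
    return bool(rng.random() < np.exp(-delta_score / temperature))


@dataclass
class Protocol:
    """Declarative MC protocol: ordered clients, schedule, score, outputs."""

    clients: List[object]
    cycles: int = 1000
    temperature: Union[float, Tuple[float, float]] = 1.0  # constant or (start, end) linear
    weights: Optional[Dict[str, float]] = None  # per-client-name; default uniform
    n_struct: int = 1
    score: ToyScore = field(default_factory=ToyScore)
    named_selectors: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        w = self._weight_vector()
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("weights must be nonnegative with at least one positive")

    def _weight_vector(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.clients))
        return np.array([float(self.weights.get(c.name, 0.0)) for c in self.clients])

    def temperature_at(self, cycle: int) -> float:
        if isinstance(self.temperature, (tuple, list)):
            start, end = self.temperature
            if self.cycles <= 1:
                return float(end)
            frac = cycle / (self.cycles - 1)
            return float(start + (end - start) * frac)
        return float(self.temperature)


@dataclass
class ModelRecord:
    conformation: Conformation
    fold_tree_text: str
    row: Dict[str, float]


def run_protocol(
    protocol: Protocol,
    start_conformation: Conformation,
    seed: int,
) -> Tuple[List[Conformation], pd.DataFrame]:
    """Run the protocol: per model, re-broker (re-randomizing cuts), initialize
    clients, and run the Metropolis loop.  Fully reproducible per seed."""
    models: List[Conformation] = []
    rows: List[Dict] = []
    for m in range(protocol.n_struct):
        model_seed = int(np.random.default_rng([int(seed) & 0x7FFFFFFF, m]).integers(2 ** 31))
        broker = Broker(named_selectors=protocol.named_selectors)
        for client in protocol.clients:
            broker.register(client)
        result = broker.broke(start_conformation, model_seed)
        pconf = result.pconf
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, m, 1])
        for client in protocol.clients:
            client.initialize(pconf, rng)

        weights = protocol._weight_vector()
        probs = weights / weights.sum()
        score0 = protocol.score(pconf)
        current = score0
        accepted = 0
        for cycle in range(protocol.cycles):
            client = protocol.clients[int(rng.choice(len(protocol.clients), p=probs))]
            snap = pconf.snapshot()
            outcome = client.apply(pconf, rng)
            if not outcome.moved:
                continue
            trial = protocol.score(pconf)
            if metropolis_accept(trial - current, protocol.temperature_at(cycle), rng):
                current = trial
                accepted += 1
            else:
                pconf.restore(snap)

        final_conf = pconf.copy_conformation()
        models.append(final_conf)
        terms = protocol.score.terms(final_conf)
        row = {
            "model": m,
            "seed": model_seed,
            "initial_score": score0,
            "final_score": current,
            "accepted_moves": accepted,
            "cycles": protocol.cycles,
        }
        row.update({f"term_{k}": v for k, v in terms.items()})
        rows.append(row)
    return models, pd.DataFrame(rows)
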