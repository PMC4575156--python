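# foldbroker

Combining several constrained sampling strategies in one macromolecular
Monte Carlo simulation is hard not because any single constraint is hard,
but because the constraints interact. In internal-coordinate modeling the
interaction is concentrated in two shared resources: the **fold tree** — the
rooted, directed, acyclic residue graph that decides how a torsion change
propagates into Cartesian space — and the set of **degrees of freedom**
(DoFs: backbone φ/ψ/ω torsions and the six rigid-body components of each
jump) that each sampling module is allowed to touch. A β-strand-pairing
module needs a jump between paired residues; a rigid-region module needs its
torsions never sampled by anyone; a docking module needs the rigid-body DoFs
between chains; and every jump forces a compensating cut in the peptide
chain, whose placement all of them constrain at once.

`foldbroker` is a self-contained, desk-scale Python implementation of a
*broker* architecture for this problem:

1. **Claims.** Each sampling module (a *client mover*) states its
   requirements as declarative claims: torsion regions with a *control
   strength* (`exclusive` > `must control` > `can control` > `does not
   control`), jumps between anchors (a jump claim expands to six rigid-body
   DoF elements, one jump element and one cut element), forbidden or
   required cut regions, and virtual residues (e.g. a chain's center of
   mass, or a global root).
2. **Broking.** The `Broker` expands claims to machine-level elements in
   three phases — sequence changes, fold-tree topology, DoF accessibility —
   builds a single **consensus fold tree** (placing one uniformly random cut
   per cycle a jump creates, re-randomized per model), and resolves DoF
   access by a fixed pairwise matrix: two `exclusive`/`must` claims on the
   same DoF abort broking with an error naming both movers and the DoF;
   `exclusive` demotes `can control`; `does not control` is never granted.
3. **Enforcement.** On success the conformation is wrapped in a
   `ProtectedConformation` and each client receives a `Passport` of granted
   DoFs. A client activates its passport with a stack-scoped `Unlock` for
   the duration of one move; every modification checks exactly the top
   passport and fails fast otherwise. The fold tree is frozen until the next
   broking round.

The kinematics layer underneath stores the molecule as backbone internal
coordinates (ideal bond lengths/angles, φ/ψ/ω in degrees) and converts to
Cartesian coordinates by fold-tree traversal, so constraints like "this jump
pins these two residues' relative geometry" hold exactly, by construction,
rather than being pushed by a score penalty.

Shipped client movers: rigid chunk (set-and-forget template regions,
including discontinuous regions pinned by a fixed jump), torsion-fragment
insertion, β-strand-pairing jumps sampled from a transform library,
center-of-mass tracking virtual residues, rigid-body docking, and CCD loop
closure. A Metropolis MC driver with a deliberately simple score (CA clash +
chainbreak + optional pair restraints) exercises them; three toy fixtures
reproduce the constraint topology of ab initio folding with a fixed chunk,
domain-insertion modeling, and star-topology multibody docking.

## Worked example

Generate the ab initio-style fixture (76-residue toy, rigid chunk over
residues 17–40, fragments, two candidate strand pairings) and run the
brokered protocol:

```bash
foldbroker fixtures vignette1 --seed 2 --out demo
foldbroker run demo/config.yaml --seed 3 --out demo/models --dump-foldtree
```

which prints the consensus fold tree and the per-model score table:

```
EDGE 1 43 PEPTIDE
EDGE 4 69 1
EDGE 69 44 PEPTIDE
EDGE 69 76 PEPTIDE
ROOT 1
CUTS 43
 model       seed  initial_score  final_score  accepted_moves  cycles  term_clash  term_chainbreak  term_pair
     0 1742692732   5.471258e-25     0.608941             127     500         0.0         0.608941        0.0
```

Reading the tree: this trajectory drew the strand pairing (4, 69), so jump 1
pins residues 4 and 69; the compensating cut landed at position 43 (the
43→44 peptide bond), outside the chunk's forbidden region 16–40; residues
44–69 fold *backward* from the jump anchor. The score table shows 127 of 500
fragment/strand moves accepted and the remaining chainbreak term at the cut
(closable by the CCD client; this config does not include one). Re-running
with the same seeds reproduces both bit-for-bit; a different seed yields a
different pairing choice and cut. After any run, every torsion in 17–40
equals the template exactly — the chunk's exclusive grant makes re-sampling
impossible rather than merely discouraged.

The same `run` command accepts the `vignette2` (domain insertion) and
`vignette3` (H/L/C multibody docking with CoM virtual residues and loop
closure) fixtures. The library API mirrors the CLI: see
`foldbroker.broker.Broker`, `foldbroker.clients`, and
`foldbroker.sampling.run_protocol`.

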