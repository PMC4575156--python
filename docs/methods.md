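# Methods

## Model

A polypeptide is represented in internal coordinates: per residue, the
backbone torsions φ, ψ, ω (degrees in the public API, radians in storage),
bond lengths N–CA, CA–C, C–N(+1), C=O, and the bond angles N-CA-C,
CA-C-N(+1), C(−1)-N-CA, CA-C-O. Atoms are restricted to backbone N, CA, C, O
— sufficient for every behavior the architecture demonstrates; side-chain
kinematics are out of scope. Residues are numbered 1..n pose-wide across
chains. Idealized geometry constants (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, C=O 1.231 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°, CA-C-O
120.8°; ω default 180°) are standard textbook values; any self-consistent
set would serve, since all guarantees are internal to the representation.

Cartesian coordinates are generated by traversing the **fold tree** from its
root. Within a peptide edge each atom is placed from the three preceding
atoms by its bond length, bond angle and torsion (NeRF chain extension);
peptide edges may run toward either terminus, and backward edges consume the
same stored torsions with the reference atoms reversed. Across a **jump**
edge, the downstream residue's stub frame equals the upstream stub composed
with the jump's rigid transform. A *stub frame* is the orthonormal frame
built from a residue's N, CA, C: origin at CA, x toward C, y the component
of N−CA orthogonal to x. Carbonyl oxygens are placed locally from their own
residue's frame at dihedral ψ + offset (offset π by default, measured on PDB
input so foreign oxygens round-trip).

Because placement is a pure, deterministic function of the internal
coordinates along the path from the root, two properties hold *bit-exactly*
rather than approximately: atoms upstream of a changed DoF do not move
(their placement arithmetic never reads the changed value), and re-deriving
coordinates from scratch reproduces the cache. The per-jump six rigid-body
DoFs are parameterized as rb1–rb3 = translation (Å) and rb4–rb6 =
rotation-vector components (degrees); setting one component recomposes the
transform. This keeps the six scalars independent at the cost of the usual
rotation-vector singularity at 180°, which toy-scale perturbation moves do
not approach.

## Fold tree and cuts

A fold tree is valid when it is connected, acyclic, single-rooted, covers
all residues, numbers jumps consecutively from 1, and lists as cuts exactly
the consecutive-residue adjacencies not covered by a peptide edge. For any
spanning tree this forces |cuts| = |jumps|; chain boundaries and
virtual-residue boundaries are cuts bridged by (automatic or claimed)
jumps, so the count decomposes as cycle-breaking cuts + (chains − 1)
boundary cuts. `validate` returns all violations rather than raising, and
`downstream_set` computes the exact residue set whose N/CA/C placement
transitively depends on a DoF — the same dependency walk the coordinate
builder uses, so the two cannot disagree (a brute-force coordinate-motion
test confirms this).

Cut placement: when a claimed jump closes a cycle, the breakable positions
are the peptide bonds on the tree path between its anchors; the broker
intersects them with every claim's required region, removes all forbidden
positions, and draws uniformly. The draw is seeded per (seed, anchor pair),
which makes the consensus tree independent of client registration order; a
fresh seed per output model re-randomizes cuts per model. If no legal
position remains, broking fails naming the interval and the forbidding
movers.

## Broking and enforcement

Claims expand to elements in three phases (virtual residues; topology; DoF
access), because a jump cannot reference residues that do not yet exist.
Virtual residues are appended after real residues in claim order; claims on
the same label merge (conflicting attachment rules are an error). Duplicate
jump claims on one anchor pair merge into one jump edge, each claimant
receiving its own six DoF-access elements. Access resolution applies the
pairwise control-strength matrix; with more than two claimants, any
`exclusive`×(`exclusive`|`must`) pair aborts and one `exclusive` demotes all
`can` claimants. Broking is all-or-nothing: it operates on a copy, so on any
failure the input conformation is untouched and no passports exist.

Enforcement is deliberately minimal: one membership test against the
passport on top of the unlock stack per modification (an instrumentation
counter verifies this). Only the top passport is consulted — an inner unlock
does not union with outer ones. Reads always pass through. A DoF granted to
nobody is immutable for the whole trajectory, which is what makes the rigid
chunk's set-and-forget guarantee a guarantee. Fold-tree replacement on a
protected conformation is always refused, even with an identical tree — a
silent no-op would mask protocol bugs. The Metropolis driver's
snapshot/restore used for move rejection is a protocol-level mechanism, not
a client-facing modification path.

## Client movers

* **Rigid chunk** — claims `exclusive` torsions over its region, forbids
  cuts inside each contiguous segment *and in the bonds flanking it* (a cut
  into the chunk would detach part of its fixed geometry), and pins
  consecutive segments of a discontinuous region with a fixed-geometry jump
  (`exclusive` on all six rb DoFs) measured between the segment-midpoint
  stubs of the template. Template torsions are written once, inside the
  chunk's own unlock, in a post-broking initialize pass.
* **Fragment insertion** — `can control` over its region; each move writes
  one uniformly chosen 3–9-residue (φ, ψ, ω) window. Windows overlapping any
  ungranted DoF are rejected before any write, so moves are atomic.
* **Strand-pairing jumps** — one `must control` jump claim per pairing
  group, anchored at a candidate residue pair drawn uniformly per trajectory
  at claim time (only one pair can be pinned per strand pair; trajectory-level
  re-drawing covers the rest of pair space across an ensemble). Moves set
  the jump to a transform drawn from a small idealized
  parallel/antiparallel library generated from ideal strand geometry — a
  synthetic stand-in for a crystal-structure-derived database. The pinned
  frames are the paired residues' N/CA/C stubs.
* **CoM tracking** — claims a shared root virtual residue, a per-chain CoM
  virtual (at the unweighted mean of the chain's backbone atoms — masses add
  nothing to the invariant being demonstrated), and `must control` on the
  root→CoM and CoM→chain jumps. Its update re-centers the virtual by
  rewriting the incoming jump and recomputing every outgoing jump against
  current child stubs, so no real atom moves (≤1e-9 Å; in practice ~1e-13).
  Note a pure rigid-body dock carries the CoM virtual along with its chain,
  so only internal (backbone) motion makes the update non-trivial.
* **Rigid-body docking** — `can control` on the root→CoM jump (compatible
  with the tracker's `must`); perturbations compose a rotation about a
  uniform random axis with N(0, rot_mag°) magnitude and N(0, trans_mag Å)
  translation components onto the jump in the downstream frame.
* **CCD loop closure** — `can control` over the loop torsions plus a
  `does not control` jump claim bypassing the loop with the cut required
  inside it (the jump must exist for connectivity; nobody samples it).
  Closure is cyclic coordinate descent: per pivot torsion, the classic
  closed-form optimal rotation angle about the torsion axis minimizing the
  squared distance between the ideal continuation of the upstream side
  (three pseudo-atoms N̂, ĈA, Ĉ built from the cut residue with current
  ψ/ω/φ) and the actual downstream backbone. The mapping from a rotation
  about the axis to a signed torsion increment depends on the fold
  direction at the pivot; the sign is calibrated once per pivot by a probe
  step and cached. Default tolerance 0.05 Å on the chainbreak distance,
  100 sweeps maximum.

## Monte Carlo driver and toy score

Per output model the driver re-brokers (new cuts, new per-trajectory pairing
choices), initializes clients, then cycles: draw a client by configured
weight, apply one move, Metropolis-accept on the score at the scheduled
temperature (constant or linear start→end), restoring the exact pre-move
state on rejection. Everything derives from one integer seed; identical
seeds give bit-identical models. The score is an uncalibrated surrogate in
arbitrary units with kT = temperature: a soft CA–CA repulsion, (4 − d)² for
d < 4 Å excluding sequence neighbors i, i±1, chosen for smoothness and
speed; a chainbreak term summing squared distance and squared angle gaps of
the virtual peptide bond across each intra-chain cut; and an optional
harmonic CA-pair restraint. It stands in for a physical energy function
only to exercise the sampling machinery; no claim about real-protein
energetics is made or tested.

## Synthetic fixtures and what passing tests show

All test inputs are generated programmatically. The three fixtures emulate
the *constraint topology* of three protocol archetypes — (1) a 76-residue
chain with a fixed chunk at 17–40, self-harvested fragments and two
candidate terminal strand pairings; (2) an 80-residue domain-insertion toy
whose discontinuous host (1–20 ∪ 61–80) is pinned by one fixed jump with
cuts confined to the 21–60 insert; (3) a three-chain (H/L/C) star-topology
docking toy with CoM virtuals and two cut-interrupted H-chain loops. They
are ideal-geometry constructs, not models of real proteins: fragment
libraries are native windows plus ±15° jitter, strand-pair transforms are
idealized, and scores are toy. Passing tests therefore demonstrate the
architectural guarantees — consensus-tree validity, access control,
coordinate-propagation correctness, guarantee preservation through
sampling — and say nothing about structure-prediction accuracy on real
data.

Default problem sizes (20–100-residue fuzz systems, 500-cycle trajectories,
1,000-broking uniformity sweeps) keep the full validation suite at desk
scale; all scale linearly if enlarged.

## Numerical choices and limitations

Coordinates are recomputed from the root on each read after a modification
(O(n) per move at these sizes) rather than incrementally patched; this is
what makes upstream atoms bit-identical and the cache trivially coherent.
Bit-exactness claims (`bit-identical upstream atoms`, `rejected moves
restore exactly`) rely on deterministic placement order, which the fold
tree fixes. Tolerances: 1e-9 Å for jump-pin and CoM invariants, 1e-6° for
round-trip torsions, 1e-12° for the rigid-chunk guarantee (exact value
storage; the comparison tolerance only absorbs degree/radian conversion).
Degenerate inputs (collinear stub atoms, missing backbone atoms, empty cut
intervals) raise immediately with named positions. Known limitations:
residue-level (not atom-level) fold trees; no re-broking mid-trajectory; no
thread safety across concurrent unlocks; rotation-vector jump
parameterization is singular at exactly 180°; the six rb DoFs of one jump
may be granted to different clients (brokered separately by design), which
is permitted but untested beyond the access matrix.
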