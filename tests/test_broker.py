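import itertools

import numpy as np
import pytest

from foldbroker import DoFID, build_ideal_polypeptide, validate
from foldbroker.broker import (
    AccessConflictError,
    Broker,
    BrokingError,
    ControlStrength,
    CutClaim,
    CutElement,
    DoFElement,
    JumpClaim,
    JumpElement,
    TorsionClaim,
    VirtualResidueClaim,
    build_consensus_tree,
    expand_jump_claim,
    resolve_access,
)
from foldbroker.fixtures import StaticClaimClient, random_claim_system

CS = ControlStrength


def client(name, *claims):
    return StaticClaimClient(name, claims)


class TestExpandJumpClaim:
    def test_single_claim_yields_six_dof_one_jump_one_cut(self):
        elements = expand_jump_claim(JumpClaim(5, 20, CS.CAN_CONTROL, owner="x"))
        dofs = [e for e in elements if isinstance(e, DoFElement)]
        assert len(dofs) == 6
        assert sorted(e.rb for e in dofs) == [1, 2, 3, 4, 5, 6]
        assert all(e.strength is CS.CAN_CONTROL for e in dofs)
        assert len([e for e in elements if isinstance(e, JumpElement)]) == 1
        assert len([e for e in elements if isinstance(e, CutElement)]) == 1

    def test_two_claims_expand_additively(self):
        a = expand_jump_claim(JumpClaim(5, 20, CS.MUST_CONTROL, owner="x"))
        b = expand_jump_claim(JumpClaim(30, 40, CS.MUST_CONTROL, owner="y"))
        both = a + b
        assert len([e for e in both if isinstance(e, DoFElement)]) == 12
        assert len([e for e in both if isinstance(e, JumpElement)]) == 2
        assert len([e for e in both if isinstance(e, CutElement)]) == 2

    def test_fixed_geometry_claim_carries_exclusive_strength(self):
        from foldbroker import RigidTransform

        claim = JumpClaim(5, 20, CS.EXCLUSIVE, fixed_transform=RigidTransform.identity(), owner="x")
        dofs = [e for e in expand_jump_claim(claim) if isinstance(e, DoFElement)]
        assert all(e.strength is CS.EXCLUSIVE for e in dofs)

    def test_unowned_claim_is_rejected(self):
        with pytest.raises(BrokingError, match="owner"):
            expand_jump_claim(JumpClaim(5, 20, CS.CAN_CONTROL))


class TestResolveAccess:
    DOF = DoFID.psi(12)

    @pytest.mark.parametrize(
        "sa, sb",
        list(itertools.combinations_with_replacement(list(CS), 2)),
        ids=lambda s: s.name if isinstance(s, CS) else None,
    )
    def test_every_unordered_pair_matches_the_control_matrix(self, sa, sb):
        claimants = {self.DOF: [("A", sa), ("B", sb)]}
        fails = {sa, sb} == {CS.EXCLUSIVE} or (
            CS.EXCLUSIVE in (sa, sb) and CS.MUST_CONTROL in (sa, sb)
        )
        if fails:
            with pytest.raises(AccessConflictError) as err:
                resolve_access(claimants)
            message = str(err.value)
            assert "'A'" in message and "'B'" in message and "psi(12)" in message
            return
        grants = resolve_access(claimants)[self.DOF]
        for owner, s in (("A", sa), ("B", sb)):
            other = sb if owner == "A" else sa
            if s is CS.DOES_NOT_CONTROL:
                expect = False
            elif s is CS.CAN_CONTROL and other is CS.EXCLUSIVE:
                expect = False  # demoted by the exclusive claimant
            else:
                expect = True
            assert (owner in grants) == expect, (sa, sb, owner)

    def test_three_claimants_resolved_pairwise(self):
        dof = DoFID.phi(3)
        grants = resolve_access({dof: [("A", CS.EXCLUSIVE), ("B", CS.CAN_CONTROL), ("C", CS.CAN_CONTROL)]})
        assert grants[dof] == frozenset({"A"})
        with pytest.raises(AccessConflictError):
            resolve_access({dof: [("A", CS.EXCLUSIVE), ("B", CS.CAN_CONTROL), ("C", CS.MUST_CONTROL)]})

    def test_same_client_claims_collapse_to_strongest(self):
        dof = DoFID.phi(3)
        grants = resolve_access({dof: [("A", CS.DOES_NOT_CONTROL), ("A", CS.CAN_CONTROL)]})
        assert grants[dof] == frozenset({"A"})

    def test_strength_ordering(self):
        assert CS.DOES_NOT_CONTROL < CS.CAN_CONTROL < CS.MUST_CONTROL < CS.EXCLUSIVE


class TestBuildConsensusTree:
    def test_single_jump_gets_one_cut_between_anchors(self):
        for seed in range(100):
            tree, jump_map = build_consensus_tree(
                40, [(1, 40)], [JumpElement("x", 5, 20)], [], seed=seed
            )
            assert validate(tree, 40) == []
            assert jump_map[frozenset((5, 20))] == 1
            assert len(tree.cuts) == 1
            assert 5 <= tree.cuts[0] <= 19

    def test_no_jumps_single_chain_gives_linear_tree(self):
        tree, jump_map = build_consensus_tree(30, [(1, 30)], [], [], seed=0)
        assert validate(tree, 30) == []
        assert tree.cuts == ()
        assert tree.n_jumps == 0
        assert jump_map == {}

    def test_forbidden_interval_confines_cuts(self):
        cuts = set()
        for seed in range(1000):
            tree, _ = build_consensus_tree(
                40,
                [(1, 40)],
                [JumpElement("x", 5, 30)],
                [CutElement("chunk", forbidden=((17, 40),))],
                seed=seed,
            )
            cuts.add(tree.cuts[0])
        assert cuts <= set(range(5, 17))
        assert len(cuts) > 5  # and the allowed region is actually explored

    def test_identical_anchors_rejected(self):
        with pytest.raises(BrokingError, match="identical anchors"):
            build_consensus_tree(40, [(1, 40)], [JumpElement("x", 7, 7)], [], seed=0)

    def test_fully_forbidden_cycle_names_the_blocking_movers(self):
        with pytest.raises(BrokingError, match="chunk"):
            build_consensus_tree(
                40,
                [(1, 40)],
                [JumpElement("x", 5, 30)],
                [CutElement("chunk", forbidden=((1, 40),))],
                seed=0,
            )


class TestBrokerLifecycle:
    def test_register_after_broking_is_an_error(self):
        conf = build_ideal_polypeptide(20, torsion_preset="helix")
        broker = Broker()
        broker.register(client("a", TorsionClaim("all", CS.CAN_CONTROL)))
        broker.broke(conf, 1)
        with pytest.raises(BrokingError, match="after broking"):
            broker.register(client("b"))

    def test_zero_clients_gives_linear_tree_and_no_passports(self):
        conf = build_ideal_polypeptide(20, torsion_preset="helix")
        result = Broker().broke(conf, 1)
        assert validate(result.fold_tree, 20) == []
        assert result.fold_tree.n_jumps == 0
        assert result.passports == {}

    def test_duplicate_client_rejected(self):
        broker = Broker()
        c = client("dup")
        broker.register(c)
        with pytest.raises(BrokingError, match="duplicate"):
            broker.register(c)
        with pytest.raises(BrokingError, match="duplicate"):
            broker.register(client("dup"))


class TestBroke:
    def test_overlapping_exclusive_chunks_conflict_names_both(self):
        conf = build_ideal_polypeptide(40, torsion_preset="helix")
        broker = Broker()
        broker.register(client("chunkA", TorsionClaim(tuple(range(10, 26)), CS.EXCLUSIVE)))
        broker.register(client("chunkB", TorsionClaim(tuple(range(20, 31)), CS.EXCLUSIVE)))
        with pytest.raises(AccessConflictError) as err:
            broker.broke(conf, 1)
        assert "chunkA" in str(err.value) and "chunkB" in str(err.value)

    def test_conflict_leaves_input_untouched_and_issues_no_passports(self):
        conf = build_ideal_polypeptide(40, torsion_preset="helix")
        before = np.array(conf.xyz)
        broker = Broker()
        a = client("chunkA", TorsionClaim(tuple(range(10, 26)), CS.EXCLUSIVE))
        b = client("chunkB", TorsionClaim(tuple(range(20, 31)), CS.EXCLUSIVE))
        broker.register(a)
        broker.register(b)
        with pytest.raises(AccessConflictError):
            broker.broke(conf, 1)
        assert np.array_equal(conf.xyz, before)
        assert conf.n_residues == 40
        assert a.passport is None and b.passport is None

    def test_com_star_topology(self):
        conf = build_ideal_polypeptide(
            45, chain_spec=[20, 15, 10], chain_ids=["H", "L", "C"], torsion_preset="helix"
        )
        broker = Broker()
        for cid in "HLC":
            broker.register(
                client(
                    f"com_{cid}",
                    VirtualResidueClaim("root", ("root",)),
                    VirtualResidueClaim(f"com_{cid}", ("com", cid)),
                    JumpClaim(("virtual", "root"), ("virtual", f"com_{cid}"), CS.MUST_CONTROL),
                    JumpClaim(("virtual", f"com_{cid}"), ("chain", cid), CS.MUST_CONTROL),
                )
            )
        result = broker.broke(conf, 3)
        assert result.pconf.n_residues == 49  # 45 real + root + 3 CoM virtuals
        assert result.fold_tree.root == result.virtual_registry["root"]
        assert validate(result.fold_tree, 49) == []
        assert result.fold_tree.n_jumps == 6
        # broking added virtual residues but moved no real atom
        assert np.abs(result.pconf.xyz[:45] - conf.xyz).max() < 1e-9

    def test_jumps_never_reference_missing_virtuals(self):
        # phase ordering: a jump claim against a virtual label resolves because
        # the residue-addition phase ran first
        conf = build_ideal_polypeptide(20, torsion_preset="helix")
        broker = Broker()
        broker.register(
            client(
                "tracker",
                VirtualResidueClaim("root", ("root",)),
                JumpClaim(("virtual", "root"), 10, CS.MUST_CONTROL),
            )
        )
        result = broker.broke(conf, 2)
        root = result.virtual_registry["root"]
        assert result.fold_tree.jump_anchors(1) in ((root, 10), (10, root))

    def test_registration_order_does_not_change_trees_or_grants(self):
        conf = build_ideal_polypeptide(60, torsion_preset="strand")
        claim_sets = {
            "chunk": (
                TorsionClaim(tuple(range(17, 41)), CS.EXCLUSIVE),
                CutClaim(forbidden=((17, 39),)),
            ),
            "frag": (TorsionClaim("all", CS.CAN_CONTROL),),
            "pair": (JumpClaim(3, 55, CS.MUST_CONTROL),),
            "pair2": (JumpClaim(10, 50, CS.MUST_CONTROL),),
        }

        def broke(order):
            broker = Broker()
            for name in order:
                broker.register(client(name, *claim_sets[name]))
            return broker.broke(conf, 5)

        ref = broke(["chunk", "frag", "pair", "pair2"])
        for order in (["pair2", "pair", "frag", "chunk"], ["frag", "pair", "chunk", "pair2"]):
            other = broke(order)
            assert other.fold_tree == ref.fold_tree
            assert other.grants == ref.grants
            assert other.jump_map == ref.jump_map


class TestBrokeredTreeFuzz:
    def test_random_resolvable_claim_sets_always_produce_valid_trees(self):
        rng = np.random.default_rng(2024)
        successes = 0
        attempts = 0
        while successes < 200 and attempts < 2000:
            attempts += 1
            conf, clients = random_claim_system(rng)
            broker = Broker()
            for c in clients:
                broker.register(c)
            try:
                result = broker.broke(conf, int(rng.integers(2 ** 31)))
            except BrokingError:
                continue  # unresolvable set: rejection is the correct outcome
            successes += 1
            n = result.pconf.n_residues
            assert validate(result.fold_tree, n) == []
            # broken adjacencies (incl. chain boundaries) == jumps
            assert len(result.fold_tree.cuts) == result.fold_tree.n_jumps
            # every granted DoF exists on the consensus tree
            jumps = set(result.fold_tree.jump_edges)
            for passport in result.passports.values():
                for dof in passport.granted:
                    if not dof.is_torsion:
                        assert dof.jump in jumps
                    else:
                        assert 1 <= dof.residue <= n
        assert successes == 200
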