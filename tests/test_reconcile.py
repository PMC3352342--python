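import numpy as np
import pytest

from flavicophy.reconcile import (
    EventCount,
    ReconciliationError,
    best_codivergence,
    best_noncodivergence,
    brute_force_reconcile,
    count_events,
    reconcile,
)
from flavicophy.simulate import simulate_cophylogeny
from flavicophy.trees import (
    AssociationMap,
    PhyloTree,
    TreeNode,
    parse_newick,
    prune_to_group,
    write_newick,
)
from conftest import random_instance, random_tree


def bijective(virus, host):
    vl = sorted(virus.leaf_labels())
    hl = sorted(host.leaf_labels())
    return AssociationMap.from_pairs(zip(vl, hl))


class TestExamples:
    def test_perfect_congruence_three_taxa(self):
        virus = parse_newick("((a,b),c);")
        host = parse_newick("((A,B),C);")
        assoc = AssociationMap.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
        sols = reconcile(virus, host, assoc)
        assert sols.event_vectors == [(2, 0, 0, 0)]
        assert sols[0].nce == 0

    def test_incongruent_three_taxa_matches_oracle(self):
        virus = parse_newick("((a,c),b);")
        host = parse_newick("((A,B),C);")
        assoc = AssociationMap.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
        assert (
            reconcile(virus, host, assoc).event_vectors
            == brute_force_reconcile(virus, host, assoc).event_vectors
        )

    def test_identical_cherries(self):
        virus = parse_newick("(a,b);")
        host = parse_newick("(A,B);")
        assoc = AssociationMap.from_pairs([("a", "A"), ("b", "B")])
        assert brute_force_reconcile(virus, host, assoc).event_vectors == [(1, 0, 0, 0)]

    def test_same_host_cherry_is_forced_duplication(self):
        virus = parse_newick("(a,b);")
        host = parse_newick("((A,B),C);")
        assoc = AssociationMap.from_pairs([("a", "A"), ("b", "A")])
        assert brute_force_reconcile(virus, host, assoc).event_vectors == [(0, 1, 0, 0)]
        assert reconcile(virus, host, assoc).event_vectors == [(0, 1, 0, 0)]

    def test_unmapped_leaf_error_names_label(self):
        virus = parse_newick("(a,b);")
        host = parse_newick("(A,B);")
        assoc = AssociationMap.from_pairs([("a", "A")])
        with pytest.raises(ReconciliationError, match="'b'"):
            reconcile(virus, host, assoc)

    def test_unknown_host_error(self):
        virus = parse_newick("(a,b);")
        host = parse_newick("(A,B);")
        assoc = AssociationMap.from_pairs([("a", "A"), ("b", "Z")])
        with pytest.raises(ReconciliationError, match="'Z'"):
            reconcile(virus, host, assoc)

    def test_brute_force_size_cap(self):
        rng = np.random.default_rng(0)
        virus = random_tree([f"v{i}" for i in range(9)], rng)
        host = parse_newick("(A,B);")
        assoc = AssociationMap.from_pairs((v, "A") for v in virus.leaf_labels())
        with pytest.raises(ReconciliationError):
            brute_force_reconcile(virus, host, assoc)


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self, rng):
        """The DP's Pareto front equals exhaustive enumeration's (light
        version; the full 100-instance run lives in the acceptance suite)."""
        for _ in range(25):
            nv = int(rng.integers(4, 7))
            nh = int(rng.integers(4, 6))
            virus, host, assoc = random_instance(rng, nv, nh)
            assert (
                reconcile(virus, host, assoc).event_vectors
                == brute_force_reconcile(virus, host, assoc).event_vectors
            )


class TestInvariantsAndCounts:
    def test_congruence_limit(self, rng):
        for n in (4, 6, 8):
            host = random_tree([f"H{i}" for i in range(n)], rng)
            virus = parse_newick(write_newick(host).replace("H", "v"))
            assoc = AssociationMap.from_pairs(
                (f"v{i}", f"H{i}") for i in range(n)
            )
            sols = reconcile(virus, host, assoc)
            assert sols.max_ce == n - 1
            assert sols.min_nce == 0

    def test_event_conservation_and_recount(self, rng):
        for _ in range(10):
            virus, host, assoc = random_instance(rng, 6, 5)
            for sol in reconcile(virus, host, assoc):
                n_internal = virus.n_leaves - 1
                c = sol.counts
                assert c.n_codivergence + c.n_duplication + c.n_switch == n_internal
                assert count_events(sol) == c

    def test_recount_detects_tampered_event_map(self, rng):
        virus, host, assoc = random_instance(rng, 5, 5)
        sol = reconcile(virus, host, assoc)[0]
        v = next(iter(sol.event_map))
        sol.event_map[v] = (
            "duplication" if sol.event_map[v] != "duplication" else "codivergence"
        )
        with pytest.raises(ReconciliationError):
            count_events(sol)

    def test_scalar_summaries_match_frontier(self, rng):
        for _ in range(10):
            virus, host, assoc = random_instance(rng, 6, 5)
            sols = reconcile(virus, host, assoc)
            assert best_codivergence(virus, host, assoc) == sols.max_ce
            assert best_noncodivergence(virus, host, assoc) == sols.min_nce

    def test_unmapped_host_leaf_only_adds_losses(self, rng):
        """Grafting a host leaf with no associated virus cannot change the
        best CE or the best duplication+switch total; losses may grow."""
        for seed in range(8):
            r = np.random.default_rng(seed)
            virus, host, assoc = random_instance(r, 5, 4)
            sols = reconcile(virus, host, assoc)
            # graft an extra host leaf onto a random edge
            host2 = host.copy()
            nodes = [n for n in host2.postorder() if n.parent is not None]
            target = nodes[r.integers(len(nodes))]
            parent = target.parent
            joint = TreeNode(children=[target, TreeNode(label="EXTRA")])
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            host2 = PhyloTree(host2.root)
            sols2 = reconcile(virus, host2, assoc)
            assert sols2.max_ce == sols.max_ce
            assert min(
                s.counts.n_duplication + s.counts.n_switch for s in sols2
            ) == min(s.counts.n_duplication + s.counts.n_switch for s in sols)
            assert min(s.counts.n_loss for s in sols2) >= min(
                s.counts.n_loss for s in sols
            )

    def test_regrafting_a_leaf_never_increases_max_ce(self, rng):
        for seed in range(8):
            r = np.random.default_rng(seed)
            n = 6
            host = random_tree([f"H{i}" for i in range(n)], r)
            virus = parse_newick(write_newick(host).replace("H", "v"))
            assoc = AssociationMap.from_pairs((f"v{i}", f"H{i}") for i in range(n))
            base = best_codivergence(virus, host, assoc)
            assert base == n - 1
            # move one leaf: prune it out, re-insert as sister of another leaf
            moved = f"v{r.integers(n)}"
            rest = [l for l in virus.leaf_labels() if l != moved]
            sub = prune_to_group(virus, rest)
            other = rest[r.integers(len(rest))]
            nwk = parse_newick(
                write_newick(sub).replace(other, f"({other},{moved})")
            )
            assert best_codivergence(nwk, host, assoc) <= base

    def test_true_history_recovered_when_optimal(self):
        """Pure-codivergence simulations: the generator's recorded history is
        the (unique) optimum the reconciler finds."""
        for seed in range(5):
            sim = simulate_cophylogeny(n_hosts=7, seed=seed)
            sols = reconcile(sim.virus_tree, sim.host_tree, sim.assoc)
            assert sols.event_vectors == [sim.true_events.as_tuple()]
            assert sim.true_events.as_tuple() == (6, 0, 0, 0)


class TestEventCount:
    def test_nce_is_dup_plus_switch_plus_loss(self):
        c = EventCount(3, 1, 2, 4)
        assert c.nce == 7

    def test_negative_counts_rejected(self):
        with pytest.raises(ReconciliationError):
            EventCount(-1, 0, 0, 0)
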