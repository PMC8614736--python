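"""Consensus, K2P, neighbor joining, ML-PTP delimitation, primer matching."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from barcodegap import errors
from barcodegap.seqdelim import (
    SATURATED,
    DistanceMatrix,
    PrimerPair,
    _PtpTree,
    consensus,
    k2p,
    k2p_matrix,
    match_primer,
    midpoint_root,
    nj,
    partition_summary,
    primer_match,
    ptp_delimit,
    reverse_complement,
    tree_path_distances,
)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def random_binary_tree(labels, rng, lengths):
    """Random topology over labels; branch lengths drawn from `lengths`."""
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(lengths(rng))
        b.edge.length = float(lengths(rng))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    t = dendropy.Tree(taxon_namespace=tns)
    t.seed_node = nodes[0]
    t.is_rooted = True
    return t


def enumerate_delimitations(view):
    """All antichain states of a rooted tree (independent brute force)."""
    def rec(i):
        states = [frozenset([i])]
        if view.children[i]:
            for combo in itertools.product(*(rec(c)
                                             for c in view.children[i])):
                states.append(frozenset().union(*combo))
        return states
    return rec(view.root)


def leaf_partition(view, state):
    return frozenset(frozenset(view.leaves_under(i)) for i in state)


def partition_of(result):
    clusters = {}
    for leaf, cid in result.assignment.items():
        clusters.setdefault(cid, set()).add(leaf)
    return frozenset(frozenset(v) for v in clusters.values())


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_single_sequence_returns_itself(self):
        assert consensus(["ACGTACGT"]) == "ACGTACGT"

    def test_tie_resolved_to_ambiguity_code(self):
        assert consensus(["ACGT", "ACGA"]) == "ACGW"

    def test_all_gap_column_dropped(self):
        assert consensus(["AC-T", "AC-T"]) == "ACT"

    def test_majority_wins_above_threshold(self):
        assert consensus(["ACGT", "ACGT", "ACGA"]) == "ACGT"

    def test_three_way_tie_covers_all(self):
        assert consensus(["A", "C", "G"]) == "V"

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seqs = ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(4)]
            if all(set(col) == {"-"} or "-" not in col
                   for col in zip(*seqs)):
                continue
            c = consensus(seqs)
            assert consensus([c]) == c

    def test_empty_set_rejected(self):
        with pytest.raises(errors.ValidationError):
            consensus([])


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p01_q01(self):
        # 10% transitions, 10% transversions over 20 sites:
        # K = -0.5 ln((1 - 0.3) sqrt(0.8)) = 0.23419...
        a = "ACGTACGTACGTACGTACGT"
        #    transitions at 0,1 (A->G, C->T); transversions at 2,3 (G->T, T->G)
        b = "GTTGACGTACGTACGTACGT"
        val = k2p(a, b)
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.1)
                                   * math.sqrt(1 - 2 * 0.1))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.2341, abs=5e-5)

    def test_saturation_at_half_transitions(self):
        # P = 0.5, Q = 0 -> log argument 0 -> saturated
        a = "AAAA"
        b = "GGAA"
        assert k2p(a, b) == SATURATED

    def test_symmetry_and_gap_exclusion(self):
        a, b = "AC-TANGT", "ACGTA-GA"
        assert k2p(a, b) == k2p(b, a)
        # gap/ambiguity sites excluded pairwise: 6 comparable sites remain,
        # one of which (T/A) is a transversion
        q = 1 / 6
        assert k2p(a, b) == pytest.approx(
            -0.5 * math.log((1 - q) * math.sqrt(1 - 2 * q)), abs=1e-12)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(errors.ValidationError):
            k2p("NNNN", "ACGT")

    def test_matrix_collects_saturated_pairs(self):
        dm = k2p_matrix({"a": "AAAA", "b": "GGAA", "c": "AAAA"})
        assert ("a", "b") in dm.undefined_pairs
        assert dm.d[0, 2] == 0.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_two_taxa_edge_totals_distance(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = nj(dm)
        back = tree_path_distances(tree)
        assert back.d[0, 1] == pytest.approx(3.0, abs=1e-12)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        labels = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            m[i, j] = m[j, i] = d[(a, b)]
        tree = nj(DistanceMatrix(labels, m))
        back = tree_path_distances(tree)
        for (i, a), (j, b) in itertools.combinations(
                enumerate(back.labels), 2):
            assert back.d[i, j] == pytest.approx(d[(a, b)], abs=1e-9)
        # split AB|CD present
        clades = {frozenset(l.taxon.label for l in nd.leaf_iter())
                  for nd in tree.preorder_node_iter() if not nd.is_leaf()}
        assert (frozenset({"A", "B"}) in clades
                or frozenset({"C", "D"}) in clades)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_matrices_recovered_exactly(self, n_leaves):
        """NJ is exact on additive matrices: path distances on the output
        tree equal the input for random trees of every size tested."""
        rng = np.random.default_rng(n_leaves)
        for _ in range(25):
            labels = [f"L{i}" for i in range(n_leaves)]
            t = random_binary_tree(labels, rng,
                                   lambda r: r.uniform(0.5, 3.0))
            dm = tree_path_distances(t)
            back = tree_path_distances(nj(dm))
            assert back.labels == dm.labels
            np.testing.assert_allclose(back.d, dm.d, atol=1e-9)

    def test_agrees_with_dendropy_nj(self):
        """Independent cross-check against dendropy's NJ on a random
        non-additive matrix: identical topologies (bipartition sets)."""
        rng = np.random.default_rng(9)
        labels = [f"T{i}" for i in range(7)]
        base = rng.uniform(0.2, 1.0, size=(7, 7))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0.0)
        mine = nj(DistanceMatrix(labels, m))

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(m[i, j]) for j in range(7))
            for i in range(7))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        theirs = pdm.nj_tree()

        def bipartitions(tree):
            tree.encode_bipartitions()
            all_taxa = frozenset(t.label for t in tree.taxon_namespace)
            out = set()
            for e in tree.preorder_edge_iter():
                if e.bipartition is None or e.head_node is None:
                    continue
                side = frozenset(t.label for t in e.bipartition.leafset_taxa(
                    tree.taxon_namespace))
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(min(side, all_taxa - side, key=sorted))
            return out

        assert bipartitions(mine) == bipartitions(theirs)

    def test_saturated_pairs_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, np.inf],
                                                  [np.inf, 0.0]]),
                            undefined_pairs={("a", "b")})
        with pytest.raises(errors.SaturationError):
            nj(dm)


# ---------------------------------------------------------------------------
# ML-PTP
# ---------------------------------------------------------------------------

class TestPtp:
    def test_matches_exhaustive_enumeration_small_trees(self):
        """The search equals brute-force ML over all delimitations for
        random trees with 3..8 leaves."""
        rng = np.random.default_rng(21)
        for trial in range(30):
            n = int(rng.integers(3, 9))
            t = random_binary_tree(
                [f"L{i}" for i in range(n)], rng,
                lambda r: float(r.choice([r.exponential(0.004),
                                          r.exponential(0.4)])))
            view = _PtpTree(t)
            best, best_ll = None, -math.inf
            for st in enumerate_delimitations(view):
                ll = view.loglik(st)
                if ll > best_ll + 1e-12:
                    best, best_ll = st, ll
            res = ptp_delimit(t, seed=trial, collapse_if_null=False)
            assert res.log_likelihood == pytest.approx(best_ll, abs=1e-9)
            assert partition_of(res) == leaf_partition(view, best)

    def test_two_clade_tree_gives_two_clusters(self):
        within = "A1:0.003,A2:0.003"
        within_b = "B1:0.003,B2:0.003"
        s = (f"((({within}):0.002,A3:0.003):0.6,"
             f"(({within_b}):0.002,B3:0.003):0.6);")
        res = ptp_delimit(tree_from_newick(s), seed=0)
        part = partition_of(res)
        assert part == frozenset({frozenset({"A1", "A2", "A3"}),
                                  frozenset({"B1", "B2", "B3"})})

    def test_star_like_tree_prefers_null(self):
        s = "((A:0.3,B:0.3):0.3,(C:0.3,D:0.3):0.3);"
        res = ptp_delimit(tree_from_newick(s), seed=0)
        assert res.null_preferred
        assert res.n_clusters == 1

    def test_isolated_long_branch_is_own_cluster(self):
        s = "((A:0.001,B:0.001):0.5,C:0.5);"
        res = ptp_delimit(tree_from_newick(s), seed=0,
                          collapse_if_null=False)
        part = partition_of(res)
        assert frozenset({"C"}) in part
        assert frozenset({"A", "B"}) in part

    def test_zero_length_tree_rejected(self):
        s = "((A:0,B:0):0,C:0);"
        with pytest.raises(errors.DegenerateInputError):
            ptp_delimit(tree_from_newick(s))

    def test_unrooted_input_midpoint_rooted(self):
        s = "(A:0.001,B:0.001,(C:0.002,D:0.002):0.9);"
        res = ptp_delimit(tree_from_newick(s), seed=0,
                          collapse_if_null=False)
        assert set(res.assignment) == {"A", "B", "C", "D"}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        t = random_binary_tree([f"L{i}" for i in range(12)], rng,
                               lambda r: r.exponential(0.1))
        a = ptp_delimit(t, seed=5)
        b = ptp_delimit(t, seed=5)
        assert a.assignment == b.assignment


class TestPartitionSummary:
    def make_partition(self, clusters):
        assignment = {}
        for cid, leaves in enumerate(clusters, start=1):
            for leaf in leaves:
                assignment[leaf] = cid
        from barcodegap.seqdelim import SpeciesPartition
        return SpeciesPartition(assignment, len(clusters), 0.0, 0.0,
                                0.0, 0.0, False)

    def test_perfect_partition_100(self):
        truth = {"a1": "A", "a2": "A", "b1": "B"}
        p = self.make_partition([["a1", "a2"], ["b1"]])
        s = partition_summary(p, truth)
        assert s.percent_separated == 100.0
        assert not s.merges and not s.splits

    def test_merge_counting_rule(self):
        # 38 species, two fused -> 36/38 separated with one merge pair
        truth = {}
        clusters = []
        for i in range(36):
            truth[f"s{i}_1"] = f"Sp{i}"
            clusters.append([f"s{i}_1"])
        truth["x_1"], truth["y_1"] = "SpX", "SpY"
        clusters.append(["x_1", "y_1"])
        s = partition_summary(self.make_partition(clusters), truth)
        assert s.n_species == 38 and s.n_separated == 36
        assert s.percent_separated == pytest.approx(100 * 36 / 38)
        assert s.merges == [("SpX", "SpY")]

    def test_oversplit_species_not_separated(self):
        truth = {"a1": "A", "a2": "A"}
        p = self.make_partition([["a1"], ["a2"]])
        s = partition_summary(p, truth)
        assert s.n_separated == 0 and s.splits == ["A"]

    def test_missing_leaf_rejected(self):
        p = self.make_partition([["a1"]])
        with pytest.raises(errors.TaxonLookupError):
            partition_summary(p, {})


# ---------------------------------------------------------------------------
# primer matching
# ---------------------------------------------------------------------------

class TestPrimerMatch:
    def test_exact_substring_found(self):
        hit = match_primer("TTGGTCAACAAATCAA", "GGTCAACAAATC")
        assert hit.found and hit.mismatches == 0 and hit.positions == [2]

    def test_iupac_n_matches_any(self):
        hit = match_primer("CATGCA", "ATGN")
        assert hit.found and hit.positions == [1] and hit.mismatches == 0

    def test_mismatch_budget_enforced(self):
        rng = np.random.default_rng(13)
        target = "".join(rng.choice(list("ACGT"), 80))
        primer = target[20:40]
        # mutate max_mismatch + 1 positions to incompatible bases
        mutated = list(primer)
        for pos in (2, 7, 11, 15):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
                mutated[pos]]
        bad = "".join(mutated)
        # brute-force best mismatch count over all offsets
        best = min(sum(a != b for a, b in zip(bad, target[o:o + 20]))
                   for o in range(len(target) - 19))
        assert best == 4
        assert not match_primer(target, bad, max_mismatch=3).found
        assert match_primer(target, bad, max_mismatch=4).found

    def test_pair_requires_both_ends(self):
        pair = PrimerPair("ACGTACGT", "TTTTCCCC", "toy")
        # forward present; reverse primer must match the reverse complement
        target = "ACGTACGT" + "A" * 20 + reverse_complement("TTTTCCCC")
        res = primer_match(target, pair, max_mismatch=0)
        assert res.found
        res2 = primer_match("ACGTACGT" + "A" * 20 + "GGGGTTTT",
                            pair, max_mismatch=0)
        assert res2.forward.found

    def test_primer_longer_than_target(self):
        hit = match_primer("ACGT", "ACGTACGT")
        assert not hit.found and hit.mismatches is None

    def test_invalid_primer_characters_rejected(self):
        with pytest.raises(errors.ValidationError):
            PrimerPair("ACGU", "ACGT")
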