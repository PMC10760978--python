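"""Neighbor joining, Newick round-trips, haplotype collapsing and the
minimum-spanning network."""

import itertools

import dendropy
import numpy as np
import pytest

from barcodekit import phylo, simdata, alignio
from barcodekit.barcodegap import DistanceMatrix, distance_matrix
from barcodekit.phylo import (
    HaplotypeSet,
    collapse_haplotypes,
    from_newick,
    neighbor_joining,
    parsimony_network,
    random_binary_tree,
    to_newick,
    tree_distance_matrix,
)
from conftest import make_alignment
from oracles import brute_min_spanning_weight


def _dm(ids, entries):
    n = len(ids)
    m = np.zeros((n, n))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return DistanceMatrix(ids=list(ids), snp_percent=m,
                          comparable_sites=np.ones((n, n), dtype=int))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = _dm("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0})
        tree = neighbor_joining(dm)
        hub = [n for n in tree.nodes if n.startswith("#")]
        assert len(hub) == 1
        limbs = tree.adj[hub[0]]
        assert limbs == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_recovery(self):
        """Distances additive on ((A:1,B:2):1,(C:3,D:4)) recover the AB|CD
        split and the generating branch lengths."""
        entries = {
            (0, 1): 3.0,  # A-B
            (0, 2): 5.0,  # A-C: 1+1+3
            (0, 3): 6.0,
            (1, 2): 6.0,
            (1, 3): 7.0,
            (2, 3): 7.0,
        }
        tree = neighbor_joining(_dm("ABCD", entries))
        assert tree.has_clade({"A", "B"}) and tree.has_clade({"C", "D"})
        paths = tree.leaf_path_lengths(floor_at_zero=False)
        for (x, y), v in entries.items():
            assert paths[("ABCD"[x], "ABCD"[y])] == pytest.approx(v)

    def test_label_permutation_gives_isomorphic_tree(self):
        entries = {(0, 1): 2.0, (0, 2): 7.0, (0, 3): 7.5, (1, 2): 7.3,
                   (1, 3): 7.8, (2, 3): 1.0}
        t1 = neighbor_joining(_dm(["w", "x", "y", "z"], entries))
        # relabel w<->z, x<->y: distances permuted accordingly
        perm = {0: 3, 1: 2, 2: 1, 3: 0}
        entries2 = {
            tuple(sorted((perm[i], perm[j]))): v for (i, j), v in entries.items()
        }
        t2 = neighbor_joining(_dm(["w", "x", "y", "z"], entries2))
        relabel = {"w": "z", "x": "y", "y": "x", "z": "w"}
        splits2 = {
            frozenset(relabel[l] for l in s) for s in t2.splits()
        }
        canon2 = set()
        leaves = frozenset(t1.leaves)
        for s in splits2:
            canon2.add(s if "w" not in s else leaves - s)
        canon1 = set()
        for s in t1.splits():
            canon1.add(s if "w" not in s else leaves - s)
        assert canon1 == canon2

    def test_missing_distance_rejected_with_pair(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        dm = DistanceMatrix(ids=["a", "b", "c"], snp_percent=m,
                            comparable_sites=np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            neighbor_joining(dm)

    def test_consistency_on_random_additive_matrices(self, rng):
        """NJ recovers the generating topology from exact additive distances
        (checked by split-set identity for n up to 8)."""
        for _ in range(40):
            n = int(rng.integers(4, 9))
            labels = [f"t{k}" for k in range(n)]
            truth = random_binary_tree(labels, rng)
            recovered = neighbor_joining(tree_distance_matrix(truth))
            assert recovered.splits() == truth.splits()


class TestNewick:
    def test_three_taxon_fixed_output(self):
        dm = _dm("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0})
        assert to_newick(neighbor_joining(dm)) == (
            "(A:0.000000,B:2.000000,C:4.000000);"
        )

    def test_round_trip_is_byte_identical(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree([f"t{k}" for k in range(n)], rng)
            text = to_newick(tree)
            assert to_newick(from_newick(text)) == text

    def test_negative_lengths_floored_in_output_only(self):
        dm = _dm("ABC", {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 4.0})
        tree = neighbor_joining(dm)
        hub = [n for n in tree.nodes if n.startswith("#")][0]
        assert tree.adj[hub]["A"] < 0  # kept in the tree object
        assert "-" not in to_newick(tree).replace("-", "", 0)
        assert ":-" not in to_newick(tree)

    def test_leaf_name_with_space_is_quoted(self):
        dm = _dm(["taxon one", "B", "C"],
                 {(0, 1): 2.0, (0, 2): 2.0, (1, 2): 2.0})
        text = to_newick(neighbor_joining(dm))
        assert "'taxon one'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"taxon one", "B", "C"}

    def test_newick_parses_with_dendropy(self, rng):
        tree = random_binary_tree([f"t{k}" for k in range(6)], rng)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick",
                                   preserve_underscores=True)
        assert len(parsed.leaf_nodes()) == 6

    def test_midpoint_rooting_balances_longest_path(self):
        dm = _dm("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0})
        rooted = phylo.midpoint_root(neighbor_joining(dm))
        # longest path B..C has length 6; each side of #root gets 3
        dists = {}
        for leaf in ("B", "C"):
            seen = {"#root": 0.0}
            stack = ["#root"]
            while stack:
                cur = stack.pop()
                for nb, ln in rooted.adj[cur].items():
                    if nb not in seen:
                        seen[nb] = seen[cur] + max(0.0, ln)
                        stack.append(nb)
            dists[leaf] = seen[leaf]
        assert dists["B"] == pytest.approx(3.0)
        assert dists["C"] == pytest.approx(3.0)


class TestCollapseHaplotypes:
    def test_identical_rows_collapse_to_one(self):
        rows = {f"s|{k}": "ACGT" for k in range(5)}
        haps = collapse_haplotypes(make_alignment(rows))
        assert len(haps.haplotypes) == 1
        assert haps.haplotypes[0].multiplicity == 5
        assert haps.haplotypes[0].label == "s|0"

    def test_forced_two_haplotype_example(self):
        rows = {"a": "ACGT", "b": "ACGA", "c": "ACGT"}
        haps = collapse_haplotypes(make_alignment(rows))
        assert sorted(h.multiplicity for h in haps.haplotypes) == [1, 2]
        assert haps.pairwise_steps[0, 1] == 1

    def test_n_matches_anything(self):
        rows = {"a": "ACGT", "b": "ACGN"}
        haps = collapse_haplotypes(make_alignment(rows))
        assert len(haps.haplotypes) == 1

    def test_multiplicities_sum_to_record_count(self, trimmed_alignment):
        haps = collapse_haplotypes(trimmed_alignment)
        assert sum(h.multiplicity for h in haps.haplotypes) == len(
            trimmed_alignment.ids
        )

    def test_no_two_output_haplotypes_mergeable(self, rng):
        """Greedy merging leaves no pair of representatives compatible under
        the N-wildcard rule (random sets with Ns)."""
        for _ in range(30):
            n, L = int(rng.integers(2, 8)), int(rng.integers(3, 12))
            rows = {
                f"r{k}": "".join(
                    rng.choice(list("ACGTN"), size=L, p=[0.3, 0.3, 0.15, 0.15, 0.1])
                )
                for k in range(n)
            }
            haps = collapse_haplotypes(make_alignment(rows))
            for i, j in itertools.combinations(range(len(haps.haplotypes)), 2):
                assert haps.pairwise_steps[i, j] >= 1


class TestParsimonyNetwork:
    def _haps(self, steps, k):
        mat = np.zeros((k, k), dtype=int)
        for (i, j), v in steps.items():
            mat[i, j] = mat[j, i] = v
        hs = [
            phylo.Haplotype(sequence="A" * 4, multiplicity=1,
                            member_ids=(f"h{i}",), label=f"h{i}")
            for i in range(k)
        ]
        return HaplotypeSet(haplotypes=hs, pairwise_steps=mat)

    def test_unique_mst_no_ties(self):
        haps = self._haps({(0, 1): 1, (0, 2): 1, (1, 2): 2}, 3)
        net = parsimony_network(haps)
        assert sorted((a, b) for a, b, _ in net.edges) == [("h0", "h1"), ("h0", "h2")]
        assert len(net.components) == 1
        assert net.spanning_weight == 2

    def test_all_ties_triangle_keeps_every_edge(self):
        haps = self._haps({(0, 1): 1, (0, 2): 1, (1, 2): 1}, 3)
        net = parsimony_network(haps)
        assert len(net.edges) == 3
        assert net.spanning_weight == 2

    def test_step_limit_splits_into_singletons(self):
        haps = self._haps({(0, 1): 5, (0, 2): 5, (1, 2): 2}, 3)
        net = parsimony_network(haps, step_limit=1)
        assert net.edges == []
        assert net.components == [["h0"], ["h1"], ["h2"]]

    def test_invalid_step_limit_rejected(self):
        haps = self._haps({(0, 1): 1}, 2)
        with pytest.raises(ValueError):
            parsimony_network(haps, step_limit=0)

    def test_forest_weight_matches_exhaustive_search(self, rng):
        for _ in range(40):
            k = int(rng.integers(2, 8))
            steps = {
                (i, j): int(rng.integers(1, 9))
                for i, j in itertools.combinations(range(k), 2)
            }
            net = parsimony_network(self._haps(steps, k))
            assert net.spanning_weight == brute_min_spanning_weight(k, steps)

    def test_networkx_mst_weight_cross_check(self, rng):
        import networkx as nx

        for _ in range(10):
            k = int(rng.integers(3, 10))
            steps = {
                (i, j): int(rng.integers(1, 12))
                for i, j in itertools.combinations(range(k), 2)
            }
            net = parsimony_network(self._haps(steps, k))
            g = nx.Graph()
            for (i, j), w in steps.items():
                g.add_edge(i, j, weight=w)
            ref = sum(
                d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)
            )
            assert net.spanning_weight == ref


class TestEndToEnd:
    def test_star_genus_single_component_when_limit_allows(self):
        cfg = simdata.SimConfig(
            n_species=4, seqs_per_species=3, seq_length=400,
            intra_divergence=0.004, inter_divergence=0.03, seed=8,
        )
        seqset, _ = simdata.simulate_genus(cfg)
        aln = alignio.trim_and_degap(alignio.alignment_from_seqset(seqset))
        haps = collapse_haplotypes(aln)
        max_steps = int(haps.pairwise_steps.max())
        net = parsimony_network(haps, step_limit=max_steps)
        assert len(net.components) == 1

    def test_divergent_clade_recovered_as_subtree(self):
        """An 8-species genus with a 3-species high-divergence clade yields
        an NJ tree containing that clade's individuals as one subtree."""
        cfg = simdata.SimConfig(
            n_species=8, seqs_per_species=3, seq_length=1200,
            intra_divergence=0.005, inter_divergence=0.03, seed=77,
        )
        seqset, _, clade_species = simdata.simulate_clade_genus(
            cfg, clade_size=3, clade_divergence=0.08
        )
        aln = alignio.trim_and_degap(alignio.alignment_from_seqset(seqset))
        tree = neighbor_joining(distance_matrix(aln))
        clade_leaves = {
            r.id for r in seqset if r.species in clade_species
        }
        assert tree.has_clade(clade_leaves)
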