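"""Evidence-matrix assembly, Dollo reconstruction, support collapse, summaries."""

import numpy as np
import pytest

from helpers_oracles import (
    dollo_oracle_all_patterns,
    rooted_shapes,
    shape_to_newick,
)
from orthofuzz.errors import ValidationError
from orthofuzz.formats_io import SupportTree
from orthofuzz.frb import HomologyCall
from orthofuzz.matrix_phylo import (
    CellTier,
    build_matrix,
    collapse_low_support,
    dollo_reconstruct,
    forward_simulate,
    summarize_matrix,
)
from orthofuzz.model_reconciliation import RefinementTier
from orthofuzz.read_evidence import ConsistencyVerdict


def call(gene, sp, members=("m",)):
    return HomologyCall(seed_gene=gene, species=sp, members=tuple(members))


def verdict(gene, sp, supported=True):
    return ConsistencyVerdict(
        seed_gene=gene, species=sp, supported=supported,
        z_like=0.0, reference_median=20.0, reference_mad=1.0,
    )


class TestBuildMatrix:
    def test_best_case_wins_over_refinement(self):
        m = build_matrix(
            [call("g1", "sp1")],
            {("g1", "sp1"): RefinementTier.MAJOR_REFINEMENT},
            [],
            genes=["g1"],
            species=["sp1"],
        )
        assert m.at["g1", "sp1"] is CellTier.PUBLISHED_OK

    def test_read_only_evidence(self):
        m = build_matrix([], {}, [verdict("g1", "sp1")], genes=["g1"], species=["sp1"])
        assert m.at["g1", "sp1"] is CellTier.READ_ONLY

    def test_unsupported_verdict_is_no_evidence(self):
        m = build_matrix([], {}, [verdict("g1", "sp1", supported=False)],
                         genes=["g1"], species=["sp1"])
        assert m.at["g1", "sp1"] is CellTier.ABSENT

    def test_no_evidence_absent(self):
        m = build_matrix([], {}, [], genes=["g1"], species=["sp1"])
        assert m.at["g1", "sp1"] is CellTier.ABSENT

    def test_conflicting_duplicates_rejected(self):
        tiers = [
            (("g1", "sp1"), RefinementTier.MINOR_REFINEMENT),
            (("g1", "sp1"), RefinementTier.MAJOR_REFINEMENT),
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            build_matrix([], tiers, [], genes=["g1"], species=["sp1"])

    def test_stream_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(4)]
        species = [f"sp{j}" for j in range(3)]
        calls = [call(g, s) for g in genes[:2] for s in species]
        tiers = {(g, s): RefinementTier.MINOR_REFINEMENT for g in genes[1:3] for s in species}
        verdicts = [verdict(g, s) for g in genes[2:] for s in species[:1]]
        ref = build_matrix(calls, tiers, verdicts, genes=genes, species=species)
        for _ in range(4):
            shuffled_calls = [calls[i] for i in rng.permutation(len(calls))]
            shuffled_verdicts = [verdicts[i] for i in rng.permutation(len(verdicts))]
            again = build_matrix(shuffled_calls, tiers, shuffled_verdicts,
                                 genes=genes, species=species)
            assert again.equals(ref)


class TestDollo:
    def test_present_everywhere_gain_at_root(self):
        tree = SupportTree.from_newick("((A,B),(C,D));")
        recon = dollo_reconstruct({l: 1 for l in "ABCD"}, tree)
        assert recon.gain_leaves == frozenset("ABCD")
        assert recon.n_losses == 0

    def test_single_presence_leaf(self):
        tree = SupportTree.from_newick("((A,B),(C,D));")
        recon = dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0}, tree)
        assert recon.gain_leaves == frozenset("A")
        assert recon.n_losses == 0

    def test_no_presence_empty_history(self):
        tree = SupportTree.from_newick("((A,B),C);")
        recon = dollo_reconstruct({}, tree)
        assert recon.gain_leaves is None and recon.n_losses == 0

    def test_maximal_absent_subtrees(self):
        tree = SupportTree.from_newick("(((A,B),(C,D)),(E,F));")
        pattern = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0, "F": 1}
        recon = dollo_reconstruct(pattern, tree)
        assert recon.gain_leaves == frozenset("ABCDEF")
        assert set(recon.loss_edges) == {frozenset("CD"), frozenset("E")}

    def test_forward_resimulation_roundtrip(self, rng):
        """Replaying (gain, losses) must reproduce the input pattern exactly."""
        for _ in range(30):
            n = int(rng.integers(2, 10))
            labels = [f"T{i}" for i in range(n)]
            nodes = labels[:]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [
                    f"({nodes[i]},{nodes[j]})"
                ]
            tree = SupportTree.from_newick(nodes[0] + ";")
            pattern = {l: int(rng.random() < 0.6) for l in labels}
            recon = dollo_reconstruct(pattern, tree)
            assert forward_simulate(recon, tree) == pattern

    def test_adding_presence_moves_gain_rootward(self):
        tree = SupportTree.from_newick("(((A,B),C),(D,E));")
        small = dollo_reconstruct({"A": 1, "B": 1}, tree)
        grown = dollo_reconstruct({"A": 1, "B": 1, "D": 1}, tree)
        assert small.gain_leaves <= grown.gain_leaves

    def test_matches_exhaustive_minimisation_small(self):
        """n_losses equals brute-force single-gain/any-loss minimisation (<=5 leaves)."""
        for n in range(2, 6):
            for shape in rooted_shapes(n, binary_only=True):
                newick, labels = shape_to_newick(shape)
                tree = SupportTree.from_newick(newick)
                oracle = dollo_oracle_all_patterns(shape)
                for bits in range(1, 1 << n):
                    pattern = {lab: (bits >> i) & 1 for i, lab in enumerate(labels)}
                    recon = dollo_reconstruct(pattern, tree)
                    assert recon.n_losses == oracle[bits], (newick, bits)


class TestCollapse:
    def test_threshold_semantics_at_fifty(self):
        tree = SupportTree.from_newick("(((A,B)49,C)50,(D,E)90);")
        out = collapse_low_support(tree, 50.0)
        bips = out.bipartitions()
        assert frozenset("AB") not in bips          # support 49 -> contracted
        assert frozenset("ABC") in bips             # support 50 -> retained
        assert frozenset("DE") in bips
        assert set(out.leaf_labels()) == set("ABCDE")

    def test_threshold_zero_identity(self):
        tree = SupportTree.from_newick("(((A,B)10,C)5,(D,E)1);")
        out = collapse_low_support(tree, 0.0)
        assert out.bipartitions() == tree.bipartitions()

    def test_unsupported_edges_retained(self):
        tree = SupportTree.from_newick("(((A,B),C)90,(D,E)90);")
        out = collapse_low_support(tree, 50.0)
        assert frozenset("AB") in out.bipartitions()

    def test_fractional_supports_rescaled_with_warning(self):
        tree = SupportTree.from_newick("(((A,B)0.4,C)0.9,D);")
        with pytest.warns(UserWarning, match="rescaling"):
            out = collapse_low_support(tree, 50.0)
        bips = out.bipartitions()
        assert frozenset("AB") not in bips and frozenset("ABC") in bips

    def test_random_trees_bipartition_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 13))
            labels = [f"T{i}" for i in range(n)]
            nodes = labels[:]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                sup = int(rng.integers(0, 101))
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [
                    f"({nodes[i]},{nodes[j]}){sup}"
                ]
            tree = SupportTree.from_newick(nodes[0] + ";")
            threshold = float(rng.integers(0, 101))
            expected = {
                SupportTree.leaf_set(nd)
                for nd in tree.dtree.preorder_node_iter()
                if nd.parent_node is not None
                and not nd.is_leaf()
                and not (
                    (s := SupportTree.node_support(nd)) is not None and s < threshold
                )
            }
            out = collapse_low_support(tree, threshold)
            assert out.bipartitions() == expected
            assert set(out.leaf_labels()) == set(labels)


class TestSummaries:
    def test_all_published_fraction_one(self):
        m = build_matrix(
            [call(g, s) for g in ["g1", "g2"] for s in ["sp1", "sp2"]],
            {}, [], genes=["g1", "g2"], species=["sp1", "sp2"],
        )
        summary = summarize_matrix(m)
        assert summary.at["all", "frac_pub"] == 1.0
        assert summary.at["all", "frac_genome_dependent"] == 0.0

    def test_half_read_only_genome_dependent(self):
        m = build_matrix(
            [call("g1", "sp1"), call("g1", "sp2")],
            {},
            [verdict("g2", "sp1"), verdict("g2", "sp2")],
            genes=["g1", "g2"],
            species=["sp1", "sp2"],
        )
        summary = summarize_matrix(m)
        assert summary.at["all", "frac_genome_dependent"] == 0.5

    def test_random_matrix_counting_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        species = [f"sp{j}" for j in range(4)]
        tiers = list(CellTier)
        import pandas as pd

        cells = {
            sp: [tiers[int(rng.integers(0, len(tiers)))] for _ in genes] for sp in species
        }
        matrix = pd.DataFrame(cells, index=genes)
        groups = {sp: ("left" if i < 2 else "right") for i, sp in enumerate(species)}
        summary = summarize_matrix(matrix, groups)
        for grp in ("left", "right"):
            cols = [sp for sp in species if groups[sp] == grp]
            flat = [matrix.at[g, sp] for sp in cols for g in genes]
            for tier in CellTier:
                from orthofuzz.matrix_phylo import TIER_CODES

                assert summary.at[grp, f"n_{TIER_CODES[tier].lower()}"] == flat.count(tier)
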