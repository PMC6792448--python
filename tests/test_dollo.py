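"""Dollo reconstruction: optimality, conservation identity, oracle parity."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from domevol import (
    brute_force_oracle,
    enumerate_rooted_topologies,
    parse_newick,
    reconstruct_all,
    reconstruct_domain,
    simulate_yule_tree,
    stem_content,
    write_reconstruction,
)
from domevol.matrix import PresenceMatrix
import pandas as pd


class TestReconstructDomain:
    def test_one_loss_pattern(self, four_tip_tree):
        h = reconstruct_domain(four_tip_tree, {"A", "B", "C"}, "d")
        assert h.gain_node == "N0"
        assert h.loss_branches == frozenset({"D"})
        assert h.present_nodes == frozenset({"N0", "N1", "N2", "A", "B", "C"})

    def test_single_tip_gain_no_losses(self, four_tip_tree):
        h = reconstruct_domain(four_tip_tree, {"A"})
        assert h.gain_node == "A"
        assert h.n_losses == 0
        assert h.present_nodes == frozenset({"A"})

    def test_full_presence(self, four_tip_tree):
        h = reconstruct_domain(four_tip_tree, {"A", "B", "C", "D"})
        assert h.gain_node == four_tip_tree.root
        assert h.n_losses == 0
        assert h.present_nodes == frozenset(four_tip_tree.nodes)

    def test_empty_pattern_rejected(self, four_tip_tree):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_domain(four_tip_tree, set())

    def test_gain_node_is_mrca(self, four_tip_tree):
        h = reconstruct_domain(four_tip_tree, {"C", "D"})
        assert h.gain_node == "N2"
        assert h.present_nodes == frozenset({"N2", "C", "D"})

    def test_losses_are_maximal_lost_clades(self):
        # entire (C,D) clade lost: one event on its stem, not two
        tree = parse_newick("(((A,B),(C,D)),E);")
        h = reconstruct_domain(tree, {"A", "B", "E"})
        assert h.n_losses == 1


class TestReconstructAll:
    def test_tallies(self, four_tip_tree, four_tip_matrix):
        recon = reconstruct_all(four_tip_tree, four_tip_matrix)
        s = recon.summary
        assert s.gains["N0"] == 2 and s.gains["A"] == 1
        assert s.losses["D"] == 1
        assert sum(s.losses.values()) == 1
        assert sum(s.gains.values()) == 3
        assert recon.skipped == []

    def test_all_absent_domain_skipped(self, four_tip_tree):
        frame = pd.DataFrame(
            {"gone": [0, 0, 0, 0], "there": [1, 0, 0, 0]},
            index=pd.Index(list("ABCD"), name="taxon"),
        )
        recon = reconstruct_all(four_tip_tree, PresenceMatrix(frame))
        assert recon.skipped == ["gone"]
        assert len(recon.histories) == 1

    def test_empty_matrix(self, four_tip_tree):
        frame = pd.DataFrame(
            index=pd.Index(list("ABCD"), name="taxon"), columns=[]
        )
        recon = reconstruct_all(four_tip_tree, PresenceMatrix(frame))
        assert recon.histories == []
        assert all(v == 0 for v in recon.summary.content.values())

    def test_matrix_taxon_not_in_tree_named(self, four_tip_tree):
        frame = pd.DataFrame(
            {"d": [1, 1]}, index=pd.Index(["A", "Zoo"], name="taxon")
        )
        with pytest.raises(ValueError, match="Zoo"):
            reconstruct_all(four_tip_tree, PresenceMatrix(frame))
        recon = reconstruct_all(
            four_tip_tree, PresenceMatrix(frame),
            prune_missing=True, allow_absent_tips=True,
        )
        assert recon.histories[0].gain_node == "A"

    def test_missing_tip_requires_flag(self, four_tip_tree):
        frame = pd.DataFrame(
            {"d": [1, 1, 1]}, index=pd.Index(["A", "B", "C"], name="taxon")
        )
        with pytest.raises(ValueError, match="D"):
            reconstruct_all(four_tip_tree, PresenceMatrix(frame))

    def test_stem_content_identity_printed_scale(self):
        # content bookkeeping at the scale the full analysis reports
        assert stem_content(5715, 399, 181) == 5497


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "pattern, expected",
        [({"A", "B", "C"}, (1, "N0")),
         ({"A", "C"}, (2, "N0")),
         ({"A", "B", "C", "D"}, (0, "N0")),
         ({"A"}, (0, "A"))],
    )
    def test_examples(self, four_tip_tree, pattern, expected):
        assert brute_force_oracle(four_tip_tree, pattern) == expected

    def test_size_bound_enforced(self):
        tree = simulate_yule_tree(20, 0)
        with pytest.raises(ValueError, match="12"):
            brute_force_oracle(tree, {tree.tips[0]})

    def test_oracle_equivalence_exhaustive_five_tips(self):
        """On every rooted binary 5-tip topology and every pattern, the
        direct reconstruction matches the exhaustive minimum."""
        tips = ["A", "B", "C", "D", "E"]
        for tree in enumerate_rooted_topologies(tips):
            for r in range(1, len(tips) + 1):
                for pattern in itertools.combinations(tips, r):
                    pattern = frozenset(pattern)
                    h = reconstruct_domain(tree, pattern)
                    losses, gain = brute_force_oracle(tree, pattern)
                    assert h.n_losses == losses
                    assert h.gain_node == gain

    def test_oracle_on_polytomy(self):
        tree = parse_newick("(A,B,C,D);")
        assert brute_force_oracle(tree, {"A", "B"}) == (2, tree.root)
        h = reconstruct_domain(tree, {"A", "B"})
        assert h.n_losses == 2 and h.gain_node == tree.root


class TestProperties:
    @given(seed=st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_conservation_identity_random(self, seed):
        import numpy as np

        tree = simulate_yule_tree(15, seed)
        rng = np.random.default_rng(seed)
        tips = list(tree.tips)
        frame = pd.DataFrame(
            rng.integers(0, 2, size=(len(tips), 30)),
            index=pd.Index(tips, name="taxon"),
            columns=[f"d{i}" for i in range(30)],
        )
        recon = reconstruct_all(tree, PresenceMatrix(frame))
        recon.summary.check_conservation()  # raises on violation
        n_present = int((frame.sum(axis=0) > 0).sum())
        assert sum(recon.summary.gains.values()) == n_present

    def test_full_clade_presence_implies_ancestral_presence(self, four_tip_tree):
        h = reconstruct_domain(four_tip_tree, {"C", "D", "A"})
        assert "N2" in h.present_nodes  # all tips below N2 possess

    def test_taxon_deletion_never_moves_gain_rootward(self):
        tree = simulate_yule_tree(10, 3)
        tips = list(tree.tips)
        pattern = set(tips[:6])
        h_full = reconstruct_domain(tree, pattern)
        for drop in list(pattern):
            reduced = pattern - {drop}
            if not reduced:
                continue
            h = reconstruct_domain(tree, reduced)
            assert tree.is_descendant(h.gain_node, h_full.gain_node)

    def test_permutation_invariance_of_tallies(self, four_tip_tree,
                                               four_tip_matrix):
        base = reconstruct_all(four_tip_tree, four_tip_matrix).summary
        shuffled = PresenceMatrix(
            four_tip_matrix.counts.iloc[::-1, ::-1]
        )
        other = reconstruct_all(four_tip_tree, shuffled).summary
        assert base.gains == other.gains
        assert base.losses == other.losses
        assert base.content == other.content


class TestWriteReconstruction:
    def test_round_trip_artifacts(self, tmp_path, four_tip_tree,
                                  four_tip_matrix):
        recon = reconstruct_all(four_tip_tree, four_tip_matrix)
        paths = write_reconstruction(recon, tmp_path / "out")
        node_rows = (paths["node_summary"]).read_text().splitlines()
        assert node_rows[0].startswith("node\t")
        assert len(node_rows) == 1 + len(four_tip_tree.nodes)
        # root row: losses 0 by construction
        root_row = [r for r in node_rows[1:] if r.startswith("N0\t")][0]
        assert root_row.split("\t")[4] == "0"
        annotated = parse_newick((paths["annotated_tree"]).read_text())
        assert annotated.tips == four_tip_tree.tips
        assert any("+" in lab for lab in annotated.internal_labels.values())

    def test_empty_reconstruction_headers_only(self, tmp_path, four_tip_tree):
        frame = pd.DataFrame(
            index=pd.Index(list("ABCD"), name="taxon"), columns=[]
        )
        recon = reconstruct_all(four_tip_tree, PresenceMatrix(frame))
        paths = write_reconstruction(recon, tmp_path / "out")
        assert len(paths["domain_histories"].read_text().splitlines()) == 1
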