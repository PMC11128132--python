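"""Binary scores, RF candidate ranking, minimal combinations and curation."""

from itertools import combinations

import numpy as np
import pytest

from stquant.markers import (
    MarkerEntry,
    MarkerPanel,
    apply_curation,
    binary_scores,
    fbeta_score_binary,
    minimal_combination,
    rank_candidates_rf,
)


@pytest.fixture
def three_cluster_expr():
    # 3 clusters x 4 spots; gene columns with known medians per cluster
    labels = np.repeat([0, 1, 2], 4)
    X = np.zeros((12, 3))
    X[labels == 0, 0] = 2.0  # exclusive to target
    X[:, 1] = 1.0  # equal everywhere
    X[labels == 0, 2] = 2.0  # medians 2 / 1 / 0
    X[labels == 1, 2] = 1.0
    return X, labels


class TestBinaryScores:
    def test_hand_values(self, three_cluster_expr):
        X, labels = three_cluster_expr
        s = binary_scores(X, labels, target=0)
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.0)
        assert s[2] == pytest.approx(0.75)  # 1 - mean(0.5, 0)

    def test_zero_target_median_scores_zero(self):
        labels = np.repeat([0, 1], 3)
        X = np.zeros((6, 1))
        X[labels == 1, 0] = 5.0
        assert binary_scores(X, labels, 0)[0] == 0.0

    def test_rescale_invariance(self, three_cluster_expr):
        X, labels = three_cluster_expr
        np.testing.assert_allclose(
            binary_scores(X, labels, 0), binary_scores(X * 7.3, labels, 0)
        )

    def test_single_cluster_error(self):
        with pytest.raises(ValueError, match="two clusters"):
            binary_scores(np.ones((4, 2)), np.zeros(4), 0)


class TestRankCandidates:
    def _planted(self, seed, n=120, g=30):
        rng = np.random.default_rng(seed)
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        X = rng.poisson(3, size=(n, g)).astype(float)
        X[labels == 1, 7] += 50.0  # perfectly separating gene
        return X, labels

    def test_planted_gene_ranks_first(self):
        for seed in range(5):
            X, labels = self._planted(seed)
            ranked = rank_candidates_rf(
                X, labels, 1, [f"g{i}" for i in range(30)], n_trees=100, seed=seed
            )
            assert ranked[0] == "g7"

    def test_deterministic_given_seed(self):
        X, labels = self._planted(0)
        genes = [f"g{i}" for i in range(30)]
        a = rank_candidates_rf(X, labels, 1, genes, n_trees=50, seed=3)
        b = rank_candidates_rf(X, labels, 1, genes, n_trees=50, seed=3)
        assert a == b

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_candidates_rf(np.ones((4, 2)), np.zeros(4), 0, ["a", "b"])


class TestMinimalCombination:
    def test_perfect_single_marker(self, three_cluster_expr):
        X, labels = three_cluster_expr
        genes, fb = minimal_combination(["g0"], X, labels, 0, ["g0", "g1", "g2"])
        assert genes == ["g0"] and fb == pytest.approx(1.0)

    def test_conjunction_needed(self):
        # A positive in clusters {1,2}, B in {1,3}; target 1 needs both
        labels = np.repeat([1, 2, 3], 4)
        A = np.where(np.isin(labels, [1, 2]), 1.0, 0.0)
        B = np.where(np.isin(labels, [1, 3]), 1.0, 0.0)
        X = np.column_stack([A, B])
        genes, fb = minimal_combination(["A", "B"], X, labels, 1, ["A", "B"])
        assert sorted(genes) == ["A", "B"] and fb == pytest.approx(1.0)
        _, fb_a = minimal_combination(["A"], X, labels, 1, ["A", "B"])
        _, fb_b = minimal_combination(["B"], X, labels, 1, ["A", "B"])
        assert fb_a < 1.0 and fb_b < 1.0

    def test_never_worse_than_best_single(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 60)
        X = rng.poisson(4, size=(60, 6)).astype(float)
        genes = [f"g{i}" for i in range(6)]
        _, fb = minimal_combination(genes, X, labels, 0, genes, max_genes=3)
        singles = [minimal_combination([g], X, labels, 0, genes)[1] for g in genes]
        assert fb >= max(singles) - 1e-12

    def test_matches_exhaustive_oracle(self):
        """Search equals brute force over all subsets for <= 6 candidates."""
        from stquant.markers import _stump_threshold

        rng = np.random.default_rng(1)
        for trial in range(5):
            labels = rng.integers(0, 3, 45)
            X = rng.poisson(3, size=(45, 6)).astype(float)
            genes = [f"g{i}" for i in range(6)]
            got_genes, got_fb = minimal_combination(
                genes, X, labels, 0, genes, max_genes=3
            )
            truth = labels == 0
            above = np.array(
                [X[:, j] > _stump_threshold(X[:, j], truth.astype(int)) for j in range(6)]
            )
            best = (-1.0, None)
            for k in (1, 2, 3):
                for combo in combinations(range(6), k):
                    fb = fbeta_score_binary(np.all(above[list(combo)], 0), truth, 0.5)
                    if fb > best[0] + 1e-9:
                        best = (fb, combo)
            assert got_fb == pytest.approx(best[0], abs=1e-9)
            assert len(got_genes) <= len(best[1])

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            minimal_combination([], np.ones((4, 1)), np.array([0, 0, 1, 1]), 0, ["a"])


class TestCuration:
    def _panel(self, genes, ct="T_ILC"):
        return MarkerPanel(entries={ct: MarkerEntry(genes=list(genes), fbeta=0.9)})

    def test_crossexpression_removal(self):
        panel = self._panel(["Cx3cr1", "Cd3e", "Trac"])
        out = apply_curation(
            panel, ["Cx3cr1", "Cd3e", "Trac"], crossexpr={"Cx3cr1": "microglia"}
        )
        e = out.entries["T_ILC"]
        assert e.status["Cx3cr1"] == "removed-crossexpression"
        assert e.reasons["Cx3cr1"] == "microglia"
        assert e.active_genes == ["Cd3e", "Trac"]

    def test_blocklist_pattern(self):
        panel = self._panel(["Rpl13", "Cd8a"])
        out = apply_curation(panel, ["Rpl13", "Cd8a"], blocklist=["Rpl*", "Rps*"])
        assert out.entries["T_ILC"].status["Rpl13"] == "removed-blocklist"

    def test_absent_gene_removed(self):
        panel = self._panel(["Cd8a", "NotHere"])
        out = apply_curation(panel, ["Cd8a"])
        assert out.entries["T_ILC"].status["NotHere"] == "removed-absent"

    def test_ubiquitous_gene_flagged_not_removed(self):
        rng = np.random.default_rng(0)
        expr = (rng.uniform(size=(100, 2)) < [0.9, 0.2]).astype(float)
        panel = self._panel(["dense", "sparse"])
        out = apply_curation(
            panel, ["dense", "sparse"], max_detect_frac=0.5, expr=expr
        )
        e = out.entries["T_ILC"]
        assert e.flagged == ["dense"]
        assert e.status["dense"] == "active"

    def test_empty_entry_error_names_cell_type(self):
        panel = self._panel(["Rpl1"], ct="B_cells")
        with pytest.raises(ValueError, match="B_cells"):
            apply_curation(panel, ["Rpl1"], blocklist=["Rpl*"])

    def test_panel_round_trip(self, tmp_path):
        panel = self._panel(["Cd8a", "Trac"])
        apply_curation(panel, ["Cd8a", "Trac"])
        panel.write_json(tmp_path / "p.json")
        back = MarkerPanel.read_json(tmp_path / "p.json")
        assert back.gene_sets() == panel.gene_sets()
        panel.write_tsv(tmp_path / "p.tsv")
        assert (tmp_path / "p.tsv").read_text().startswith("cell_type\tgene")
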