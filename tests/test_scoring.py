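"""Module scores, per-mouse aggregation and Wilcoxon group comparison."""

import numpy as np
import pandas as pd
import pytest

from stquant.prep_integrate import log_normalize
from stquant.scoring import (
    SignatureTable,
    _expression_bins,
    aggregate_scores,
    compare_groups,
    module_score,
    score_signatures,
    wilcoxon_rank_sum,
)
from stquant.segment import RegionAssignment, label_regions, majority_vote_names
from stquant.simdata import reactive_glia_signature


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        X = np.full((10, 48), 3.0)
        s = module_score(X, ["g1", "g2"], gene_ids=[f"g{i}" for i in range(48)])
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_self_control_bin_of_one(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.uniform(size=20), rng.uniform(size=20) + 10])
        s = module_score(X, ["hi"], gene_ids=["lo", "hi"], n_bins=2, n_ctrl=5)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)  # controls = the gene itself

    def test_equal_frequency_bins(self):
        rng = np.random.default_rng(1)
        bins = _expression_bins(rng.uniform(size=101), 24)
        sizes = np.bincount(bins)
        assert sizes.max() - sizes.min() <= 1

    def test_absent_genes_warn_empty_error(self):
        X = np.ones((5, 4))
        ids = list("abcd")
        with pytest.warns(UserWarning, match="absent"):
            module_score(X, ["a", "zz"], gene_ids=ids)
        with pytest.raises(ValueError, match="no signature genes"):
            module_score(X, ["zz"], gene_ids=ids)

    def test_planted_signature_sign_stable(self, tiny_study, tiny_spec):
        """Planted white-matter TG signature scores higher inside the region
        across independent control draws."""
        study, truth = tiny_study
        norm = log_normalize(study.counts)
        sig = reactive_glia_signature(tiny_spec)
        tg = (study.obs["group"] == "TG").to_numpy()
        wm = (truth.region == "white matter").to_numpy()
        for seed in range(20):
            s = module_score(
                norm.values, sig, gene_ids=study.shared_genes, seed=seed
            )
            assert s[tg & wm].mean() > s[tg & ~wm].mean()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(30, 100))
        ids = [f"g{i}" for i in range(100)]
        a = module_score(X, ["g5", "g6"], gene_ids=ids, seed=9)
        b = module_score(X, ["g5", "g6"], gene_ids=ids, seed=9)
        np.testing.assert_array_equal(a, b)


class TestAggregate:
    def _mini_study(self):
        class Study:
            obs = pd.DataFrame(
                {
                    "slide_id": ["s1"] * 3 + ["s2"] * 3,
                    "barcode": [f"b{i}" for i in range(6)],
                    "mouse_id": ["m1"] * 3 + ["m2"] * 3,
                    "group": ["WT"] * 3 + ["TG"] * 3,
                    "plane": ["coronal"] * 6,
                }
            )

        return Study()

    def test_hand_means(self):
        study = self._mini_study()
        scores = pd.DataFrame({"sig": [0.7, 0.2, 0.4, 1.0, 2.0, 3.0]})
        ra = RegionAssignment(
            cluster_id=np.array([0, 1, 1, 0, 0, 0]),
            region_name_map={0: "wm", 1: "ctx"},
            resolution=0.15,
            n_clusters=2,
        )
        table = aggregate_scores(scores, ra, study)
        agg = table.aggregates.set_index(["mouse_id", "region"])
        assert agg.loc[("m1", "wm"), "mean_score"] == pytest.approx(0.7)
        assert agg.loc[("m1", "wm"), "n_spots"] == 1
        assert agg.loc[("m1", "ctx"), "mean_score"] == pytest.approx(0.3)
        assert agg.loc[("m2", "wm"), "mean_score"] == pytest.approx(2.0)
        # m2 has no ctx spots -> no row, not zero
        assert ("m2", "ctx") not in agg.index

    def test_matches_brute_force_groupby(self, tiny_study):
        study, truth = tiny_study
        norm = log_normalize(study.counts, gene_ids=study.shared_genes)
        scores = score_signatures(
            norm, {"sig": study.shared_genes[40:50]}, obs_index=study.obs.index,
            seed=0,
        )
        names = majority_vote_names(
            np.zeros(study.n_spots, dtype=int), truth.region.to_numpy()
        )
        ra = RegionAssignment(
            cluster_id=np.zeros(study.n_spots, dtype=int),
            region_name_map=names, resolution=0.15, n_clusters=1,
        )
        table = aggregate_scores(scores, ra, study)
        # independent oracle: explicit loops
        for row in table.aggregates.itertuples():
            mask = (study.obs["mouse_id"] == row.mouse_id).to_numpy()
            expected = scores.loc[mask, "sig"].mean()
            assert abs(row.mean_score - expected) < 1e-12


class TestCompareGroups:
    def test_exact_wilcoxon_matches_enumeration_property(self):
        """Exact rank-sum p equals full enumeration for any tie-free split
        with n_A + n_B <= 8."""
        from hypothesis import given, settings, strategies as st

        from stquant.validation import exact_wilcoxon_p

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(
            vals=st.lists(
                st.integers(min_value=0, max_value=10**6),
                min_size=2, max_size=8, unique=True,
            ),
            data=st.data(),
        )
        def check(vals, data):
            na = data.draw(st.integers(min_value=1, max_value=len(vals) - 1))
            a = np.array(vals[:na], dtype=float)
            b = np.array(vals[na:], dtype=float)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(exact_wilcoxon_p(a, b), abs=1e-12)

        check()

    def test_exact_p_hand_case(self):
        _, p = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.100)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum(np.array([1.0, 1, 1]), np.array([1.0, 1, 1]))
        assert p == 1.0

    def test_bonferroni_arithmetic_and_direction(self):
        agg = pd.DataFrame(
            {
                "mouse_id": [f"m{i}" for i in range(12)],
                "group": ["TG"] * 3 + ["WT"] * 3 + ["TG"] * 3 + ["WT"] * 3,
                "region": ["wm"] * 6 + ["ctx"] * 6,
                "signature": ["sig"] * 12,
                "mean_score": [4, 5, 6, 1, 2, 3, 1, 2, 3, 4, 5, 6],
                "n_spots": [5] * 12,
            }
        )
        table = SignatureTable(spot_scores=pd.DataFrame(), aggregates=agg)
        cmp = compare_groups(table, "TG", "WT")
        rows = cmp.rows.set_index("region")
        assert cmp.family_size == 2
        for region in ("wm", "ctx"):
            assert rows.loc[region, "p_adjusted"] == pytest.approx(
                min(1.0, 2 * rows.loc[region, "p_raw"])
            )
        assert rows.loc["wm", "direction"] == 1
        assert rows.loc["ctx", "direction"] == -1

    def test_explicit_family_size(self):
        agg = pd.DataFrame(
            {
                "mouse_id": list("abcdef"),
                "group": ["TG"] * 3 + ["WT"] * 3,
                "region": ["wm"] * 6,
                "signature": ["sig"] * 6,
                "mean_score": [4.0, 5, 6, 1, 2, 3],
                "n_spots": [5] * 6,
            }
        )
        table = SignatureTable(spot_scores=pd.DataFrame(), aggregates=agg)
        cmp = compare_groups(table, "TG", "WT", family=5)
        row = cmp.rows.iloc[0]
        assert row["family_m"] == 5
        assert row["p_adjusted"] == pytest.approx(min(1.0, 5 * row["p_raw"]))

    def test_region_missing_one_group_skipped(self):
        agg = pd.DataFrame(
            {
                "mouse_id": ["m1", "m2"],
                "group": ["TG", "TG"],
                "region": ["wm", "wm"],
                "signature": ["sig", "sig"],
                "mean_score": [1.0, 2.0],
                "n_spots": [3, 3],
            }
        )
        table = SignatureTable(spot_scores=pd.DataFrame(), aggregates=agg)
        assert len(compare_groups(table, "TG", "WT").rows) == 0
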