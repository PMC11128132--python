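"""Normalization, vst HVGs, feature ranking, scaling, PCA and RPCA anchors."""

import numpy as np
import pytest
import scipy.sparse as sp

from stquant.io_spatial import assemble_study
from stquant.prep_integrate import (
    embed_pca,
    integrate_rpca,
    log_normalize,
    rank_integration_features,
    scale_and_regress,
    select_hvg_vst,
    vst_standardized_variance,
)
from stquant.simdata import default_brain_spec, simulate_study

from conftest import make_slide


class TestLogNormalize:
    def test_closed_form(self):
        counts = np.zeros((1, 2), dtype=int)
        counts[0] = [5, 4995]  # total 5000
        norm = log_normalize(counts, scale_factor=10000)
        assert norm.values[0, 0] == pytest.approx(np.log1p(10.0))

    def test_zero_count_maps_to_zero(self):
        norm = log_normalize(np.array([[0, 3]]))
        assert norm.values[0, 0] == 0.0

    def test_expm1_row_sums_equal_scale_factor(self, tiny_study):
        study, _ = tiny_study
        norm = log_normalize(study.counts[:200], scale_factor=10000.0)
        rowsums = np.asarray(np.expm1(norm.values.todense()).sum(axis=1)).ravel()
        np.testing.assert_allclose(rowsums, 10000.0, atol=1e-8)

    def test_zero_total_spot_flagged(self):
        norm = log_normalize(np.array([[0, 0], [1, 1]]))
        assert norm.zero_total.tolist() == [True, False]
        assert norm.values[0].nnz == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_normalize(np.array([[-1, 2]]))


class TestHvgVst:
    def test_constant_gene_zero_variance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, size=(50, 10))
        X[:, 3] = 7  # constant
        sv = vst_standardized_variance(X)
        assert sv[3] == 0.0
        top = select_hvg_vst(X, [f"g{i}" for i in range(10)], n_top=9)
        assert "g3" not in top

    def test_planted_high_dispersion_recovered(self):
        """20 overdispersed genes among 500 dominate the top-20 HVGs."""
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, g = 400, 500
            mean = rng.lognormal(np.log(2), 0.5, g)
            r = np.full(g, 20.0)
            r[:20] = 0.15  # high dispersion
            lam = rng.gamma(r, mean / r, size=(n, g))
            X = rng.poisson(lam)
            top = select_hvg_vst(X, [f"g{i}" for i in range(g)], n_top=20)
            hits.append(len(set(top) & {f"g{i}" for i in range(20)}))
        assert min(hits) >= 18

    def test_n_top_larger_than_genes_warns(self):
        with pytest.warns(UserWarning, match="returning all"):
            out = select_hvg_vst(np.random.default_rng(0).poisson(3, (20, 5)),
                                 list("abcde"), n_top=10)
        assert len(out) == 5


class TestIntegrationFeatures:
    def test_slide_frequency_is_primary_key(self):
        genes = ["x", "y", "z"]
        lists = [["x", "y"], ["x", "y"], ["x", "y"], ["x", "y"], ["x"]]
        assert rank_integration_features(lists, genes, 3) == ["x", "y"]

    def test_median_rank_breaks_ties(self):
        # X ranks {3,5,7} (median 5), Y ranks {1,9,9} (median 9) -> X first
        genes = list("abcdefghijXY")
        fill = [g for g in genes if g not in "XY"]

        def with_rank(rx, ry):
            lst = list(fill)
            lst.insert(rx - 1, "X")
            lst.insert(ry - 1 if ry - 1 <= len(lst) else len(lst), "Y")
            return lst

        lists = [with_rank(3, 1), with_rank(5, 9), with_rank(7, 9)]
        ranked = rank_integration_features(lists, genes, len(genes))
        assert ranked.index("X") < ranked.index("Y")


class TestScaleRegress:
    def test_gene_linear_in_covariate_zeroed(self):
        cov = np.arange(30.0)
        Y = np.column_stack([2 * cov + 5, np.random.default_rng(0).normal(size=30)])
        out = scale_and_regress(Y, covariate=cov)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(5, (100, 20)).astype(float)
        cov = Y.sum(axis=1)
        out = scale_and_regress(Y, covariate=cov)
        for j in range(20):
            if out[:, j].std() > 0:
                assert abs(np.corrcoef(out[:, j], cov)[0, 1]) < 1e-8

    def test_unit_variance_and_zero_mean(self):
        rng = np.random.default_rng(2)
        out = scale_and_regress(rng.normal(size=(200, 5)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_gene_zero_column(self):
        Y = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        out = scale_and_regress(Y)
        assert np.all(out[:, 0] == 0.0)

    def test_clip(self):
        y = np.zeros(300)
        y[0] = 1000.0  # standardized outlier far beyond the clip value
        out = scale_and_regress(y[:, None], clip=10.0)
        assert out.max() == 10.0


class TestPca:
    def test_axis_aligned_variance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(scale=10, size=200), rng.normal(scale=0.01, size=200)])
        emb = embed_pca(X, n_pcs=2)
        assert abs(emb.components[0, 0]) > 0.999
        assert emb.explained_variance_ratio[0] > 0.999

    def test_variances_non_increasing_and_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 20))
        emb1 = embed_pca(X, n_pcs=10)
        emb2 = embed_pca(X, n_pcs=10)
        assert np.all(np.diff(emb1.explained_variance) <= 1e-12)
        np.testing.assert_array_equal(emb1.coordinates, emb2.coordinates)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        emb = embed_pca(X, n_pcs=3)
        for row in emb.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_n_pcs_too_large(self):
        with pytest.raises(ValueError, match="n_pcs"):
            embed_pca(np.zeros((5, 3)), n_pcs=4)


class TestRpca:
    def _two_slide_study(self, seed=0):
        spec = default_brain_spec("tiny", planted_effect=1.0).with_(
            n_slides_per_group=1, batch_sigma=0.0
        )
        return simulate_study(spec, seed=seed)

    def test_identical_query_gets_no_correction(self):
        study, _ = self._two_slide_study(seed=2)
        # make the TG slide a bit-identical copy of the WT slide
        wt = study.slides[0]
        import dataclasses

        tg = dataclasses.replace(wt, slide_id="TG_s0", group="TG", mouse_id="m2")
        twin = assemble_study([wt, tg])
        features = twin.shared_genes[:100]
        corrected, anchors = integrate_rpca(twin, {"WT"}, features=features)
        F = np.asarray(log_normalize(twin.counts).values[:, :100].todense())
        assert np.max(np.abs(corrected - F)) < 1e-6
        assert "TG_s0" in anchors
        assert anchors["TG_s0"].pairs["score"].between(0, 1).all()

    def test_constant_shift_recovered(self):
        """Query = reference + delta on 10 genes: correction ~ -delta."""
        study, _ = self._two_slide_study(seed=3)
        features = study.shared_genes[:100]
        F = np.asarray(log_normalize(study.counts).values[:, :100].todense())
        qmask = (study.obs["group"] == "TG").to_numpy()
        delta = 0.8
        F_shift = F.copy()
        F_shift[np.ix_(qmask, np.arange(10))] += delta
        corrected, _ = integrate_rpca(
            study, {"WT"}, features=features, feature_matrix=F_shift
        )
        correction = corrected[qmask] - F_shift[qmask]
        mean_corr = correction[:, :10].mean()
        assert mean_corr == pytest.approx(-delta, rel=0.10)

    def test_no_reference_error(self):
        study, _ = self._two_slide_study()
        with pytest.raises(ValueError, match="no reference"):
            integrate_rpca(study, {"XX"}, features=study.shared_genes[:50])

    def test_too_few_spots_error(self):
        s1 = make_slide(slide_id="a", n_spots=3, n_genes=30, group="WT", seed=1)
        s2 = make_slide(slide_id="b", n_spots=3, n_genes=30, group="TG", seed=2)
        study = assemble_study([s1, s2])
        with pytest.raises(ValueError, match="fewer than k_anchor"):
            integrate_rpca(study, {"WT"}, features=study.shared_genes[:10])
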