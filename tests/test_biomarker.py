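import numpy as np
import pandas as pd
import pytest

from methylclass import (BetaMatrix, EigengeneMarkerSelector,
                         compute_eigengenes, eigengene_score, get_scheme,
                         rank_markers, rank_markers_for_scheme, select_top_k,
                         simulate_panel, split_by_chromosome)

from conftest import random_beta_matrix, small_config


def _eig(bm, k=1, labels=None):
    return compute_eigengenes(bm, k, labels=labels)


class TestComputeEigengenes:
    def test_rank_one_matrix_first_component_explains_everything(self):
        u = np.array([0.1, 0.3, 0.5, 0.7])
        v = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
        bm = BetaMatrix(pd.DataFrame(
            np.outer(u, v), index=[f"cg{i}" for i in range(4)],
            columns=[f"S{j}" for j in range(5)]))
        eigs = _eig(bm, 1)
        assert eigs[0].explained_variance_ratio > 0.99

    def test_scores_match_brute_force_covariance_eigendecomposition(self, rng):
        bm = random_beta_matrix(rng, 12, 7)
        eigs = _eig(bm, 3)
        # oracle: eigen-decompose the sample covariance of probe-centered data
        X = bm.values.T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k, eig in enumerate(eigs):
            expected = Xc @ V[:, order[k]]
            got = eig.scores.to_numpy()
            sign = np.sign(expected @ got)
            np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_distinct_components_uncorrelated(self, rng):
        bm = random_beta_matrix(rng, 20, 10)
        e1, e2 = _eig(bm, 2)
        r = np.corrcoef(e1.scores, e2.scores)[0, 1]
        assert abs(r) < 1e-10

    def test_sign_oriented_by_first_class(self, small_panel):
        scheme = get_scheme("SC_vs_PC")
        labels = scheme.labels(small_panel.samples)
        eigs = compute_eigengenes(small_panel.matrix, 1, labels=labels)
        indicator = (labels.loc[small_panel.matrix.sample_ids] == "SC"
                     ).to_numpy(float)
        assert np.corrcoef(eigs[0].scores, indicator)[0, 1] >= 0

    def test_too_many_components_rejected(self, rng):
        bm = random_beta_matrix(rng, 5, 4)
        with pytest.raises(ValueError, match="n_components"):
            compute_eigengenes(bm, 5)


class TestEigengeneScore:
    def test_probe_equal_to_eigengene_scores_one(self, rng):
        bm = random_beta_matrix(rng, 8, 6)
        eig = _eig(bm, 1)[0]
        data = bm.data.copy()
        e = eig.scores.to_numpy()
        data.iloc[0] = (e - e.min()) / (e.max() - e.min())  # affine copy of E
        scores = eigengene_score(BetaMatrix(data), eig)
        assert scores.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_probe_scores_zero(self, rng):
        bm = random_beta_matrix(rng, 8, 6)
        data = bm.data.copy()
        data.iloc[2] = 0.5
        eig = _eig(BetaMatrix(data), 1)[0]
        scores = eigengene_score(BetaMatrix(data), eig)
        assert scores.iloc[2] == 0.0

    def test_matches_hand_rolled_pearson(self, rng):
        bm = random_beta_matrix(rng, 4, 6)
        eig = _eig(bm, 1)[0]
        scores = eigengene_score(bm, eig)
        e = eig.scores.to_numpy()
        for i, probe in enumerate(bm.probe_ids):
            x = bm.values[i]
            xc, ec = x - x.mean(), e - e.mean()
            expected = abs((xc * ec).sum()
                           / np.sqrt((xc ** 2).sum() * (ec ** 2).sum()))
            assert scores[probe] == pytest.approx(expected, abs=1e-12)

    def test_sample_mismatch_rejected(self, rng):
        bm = random_beta_matrix(rng, 8, 6)
        eig = _eig(bm, 1)[0]
        other = BetaMatrix(bm.data.iloc[:, :4])
        with pytest.raises(ValueError, match="samples"):
            eigengene_score(other, eig)

    def test_invariant_to_consistent_sample_permutation(self, rng):
        bm = random_beta_matrix(rng, 10, 8)
        eig = _eig(bm, 1)[0]
        base = eigengene_score(bm, eig)
        perm = list(rng.permutation(bm.sample_ids))
        permuted = eigengene_score(bm.select_samples(perm), eig)
        pd.testing.assert_series_equal(base, permuted)

    def test_invariant_to_affine_probe_rescaling(self, rng):
        bm = random_beta_matrix(rng, 10, 8)
        eig = _eig(bm, 1)[0]
        base = eigengene_score(bm, eig)
        data = bm.data.copy()
        data.iloc[0] = 0.2 + 0.5 * data.iloc[0]
        rescaled = eigengene_score(BetaMatrix(data), eig)
        assert rescaled.iloc[0] == pytest.approx(base.iloc[0], abs=1e-12)


class TestRankMarkers:
    def test_planted_loci_recovered_with_high_recall(self):
        panel = simulate_panel(small_config(
            n_probes=2000, n_sc=30, n_ipsc=15, n_esc=15, n_x_probes=100,
            n_informative_scpc=50, n_informative_escipsc=60,
            n_informative_stage=30, seed=17))
        ranking = rank_markers_for_scheme(panel.matrix, panel.annotation,
                                          panel.samples,
                                          get_scheme("SC_vs_PC"))
        planted = set(panel.truth.probes_of("sc_pc_marker"))
        hits = sum(p in planted for p in ranking.top(60))
        assert hits >= 45

    def test_table_shape_and_ordering(self, small_panel):
        ranking = rank_markers_for_scheme(
            small_panel.matrix, small_panel.annotation, small_panel.samples,
            get_scheme("SC_vs_PC"))
        t = ranking.to_table1_format()
        assert list(t.columns) == ["ID", "Chr", "MapInfo", "Symbol",
                                   "Ranking"]
        scores = t["Ranking"].to_numpy()
        assert (np.diff(scores) <= 0).all()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_all_annotated_probes_ranked_minus_y(self, small_panel):
        matrix, ann = small_panel.matrix, small_panel.annotation.copy()
        ann.iloc[:5, ann.columns.get_loc("chromosome")] = "Y"
        eigs = compute_eigengenes(matrix, 1)
        ranking = rank_markers(matrix, ann, None, eigs)
        assert len(ranking) == matrix.shape[0] - 5

    def test_unannotated_probes_excluded(self, small_panel):
        ann = small_panel.annotation.iloc[10:]
        eigs = compute_eigengenes(small_panel.matrix, 1)
        ranking = rank_markers(small_panel.matrix, ann, None, eigs)
        assert len(ranking) == small_panel.matrix.shape[0] - 10

    def test_dominates_random_ranking_in_recall(self):
        # eigengene ranking must beat random ordering at every panel size
        panel = simulate_panel(small_config(n_probes=600, n_sc=20,
                                            n_ipsc=10, n_esc=10, seed=29))
        ranking = rank_markers_for_scheme(panel.matrix, panel.annotation,
                                          panel.samples,
                                          get_scheme("SC_vs_PC"))
        planted = set(panel.truth.probes_of("sc_pc_marker"))
        ranked = ranking.probe_ids
        rng = np.random.default_rng(0)
        for k in (10, 30, 60, 100):
            recall = sum(p in planted for p in ranked[:k])
            random_recalls = [
                sum(p in planted for p in rng.permutation(ranked)[:k])
                for _ in range(20)]
            assert recall > np.mean(random_recalls)


class TestSplitAndSelect:
    def test_split_partitions_preserving_order(self, small_panel):
        ranking = rank_markers_for_scheme(
            small_panel.matrix, small_panel.annotation, small_panel.samples,
            get_scheme("ESC_vs_iPSC"))
        autosomal, x_group = split_by_chromosome(ranking)
        assert len(autosomal) + len(x_group) == len(ranking)
        assert (autosomal.table["chrom_group"] == "autosomal").all()
        assert (x_group.table["chrom_group"] == "X").all()
        for part in (autosomal, x_group):
            scores = part.table["score"].to_numpy()
            assert (np.diff(scores) <= 0).all()

    def test_no_x_probes_gives_empty_x_group(self, rng):
        bm = random_beta_matrix(rng, 12, 6)
        ann = pd.DataFrame({"chromosome": "2",
                            "position": np.arange(12) + 1, "symbol": ""},
                           index=bm.probe_ids)
        ranking = rank_markers(bm, ann, None, compute_eigengenes(bm, 1))
        _, x_group = split_by_chromosome(ranking)
        assert len(x_group) == 0

    def test_top_k_prefix_property(self, small_panel):
        ranking = rank_markers_for_scheme(
            small_panel.matrix, small_panel.annotation, small_panel.samples,
            get_scheme("SC_vs_PC"))
        for k in (1, 5, 20):
            assert select_top_k(ranking, k) == \
                select_top_k(ranking, k + 1)[:k]
        assert select_top_k(ranking, len(ranking)) == ranking.probe_ids

    def test_k_out_of_range_rejected(self, small_panel):
        ranking = rank_markers_for_scheme(
            small_panel.matrix, small_panel.annotation, small_panel.samples,
            get_scheme("SC_vs_PC"))
        for bad in (0, len(ranking) + 1):
            with pytest.raises(ValueError, match="out of range"):
                select_top_k(ranking, bad)


class TestEigengeneMarkerSelectorEstimator:
    def test_selects_planted_features_and_composes_with_sklearn(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(4)
        n, p, informative = 60, 200, 10
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, size=(n, p))
        X[:, :informative] += y[:, None] * 2.0
        sel = EigengeneMarkerSelector(k=informative).fit(X, y)
        assert set(sel.get_support(indices=True)) == set(range(informative))
        pipe = make_pipeline(EigengeneMarkerSelector(k=informative),
                             LogisticRegression())
        assert pipe.fit(X, y).score(X, y) == 1.0

    def test_get_params_round_trip(self):
        sel = EigengeneMarkerSelector(k=7, components=(2, 3))
        params = sel.get_params()
        assert params == {"k": 7, "components": (2, 3)}
        clone = EigengeneMarkerSelector(**params)
        assert clone.get_params() == params
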