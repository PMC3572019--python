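import itertools

import numpy as np
import pandas as pd
import pytest

from methylclass import (ClassifierSpec, PLATEAU_NOT_REACHED, SweepResult,
                         cohens_kappa, cross_platform_predict, detect_plateau,
                         get_scheme, marker_sweep, rank_markers_for_scheme,
                         repeated_split_evaluate, simulate_panel,
                         simulate_second_platform)

from conftest import small_config


def _kappa_oracle(t, p):
    """Brute-force contingency-table kappa."""
    n = len(t)
    classes = sorted(set(t) | set(p))
    table = {(a, b): 0 for a in classes for b in classes}
    for a, b in zip(t, p):
        table[(a, b)] += 1
    p_o = sum(table[(c, c)] for c in classes) / n
    p_e = sum((sum(table[(c, b)] for b in classes) / n)
              * (sum(table[(a, c)] for a in classes) / n)
              for c in classes)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


class TestCohensKappa:
    def test_identical_sequences_give_one(self):
        assert cohens_kappa(list("aabb"), list("aabb")) == 1.0
        assert cohens_kappa(["a"] * 5, ["a"] * 5) == 1.0  # p_e = 1 case

    def test_balanced_confusion_example(self):
        # confusion [[4,1],[1,4]]: p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        t = list("aaaaabbbbb")
        p = list("aaaabbbbba")
        assert cohens_kappa(t, p) == pytest.approx(0.6)

    def test_exhaustive_agreement_with_contingency_oracle(self):
        # every pair of 2-class label vectors up to length 8
        for n in range(1, 9):
            for t in itertools.product("ab", repeat=n):
                for p in itertools.product("ab", repeat=n):
                    assert cohens_kappa(t, p) == pytest.approx(
                        _kappa_oracle(t, p), abs=1e-12)

    def test_matches_sklearn_on_random_vectors(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(50):
            t = rng.choice(["a", "b"], size=30)
            p = rng.choice(["a", "b"], size=30)
            if len(set(t)) == 1 and len(set(p)) == 1 and t[0] == p[0]:
                continue  # sklearn returns nan for the constant case
            assert cohens_kappa(t, p) == pytest.approx(
                cohen_kappa_score(t, p), abs=1e-12)

    def test_random_shuffles_average_to_zero(self, rng):
        t = np.array(["a"] * 12 + ["b"] * 8, dtype=object)
        kappas = []
        for _ in range(1000):
            p = rng.permutation(t)
            kappas.append(cohens_kappa(t, p))
        assert abs(np.mean(kappas)) < 0.05

    def test_symmetric_under_relabeling(self, rng):
        t = rng.choice(["a", "b"], size=25)
        p = rng.choice(["a", "b"], size=25)
        swap = {"a": "b", "b": "a"}
        relabeled = cohens_kappa([swap[x] for x in t], [swap[x] for x in p])
        assert cohens_kappa(t, p) == pytest.approx(relabeled, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a", "b"], ["a"])


@pytest.fixture(scope="module")
def panel_and_ranking():
    panel = simulate_panel(small_config(n_probes=600, n_sc=20, n_ipsc=10,
                                        n_esc=10, seed=21))
    scheme = get_scheme("SC_vs_PC")
    ranking = rank_markers_for_scheme(panel.matrix, panel.annotation,
                                      panel.samples, scheme)
    return panel, scheme, ranking


class TestRepeatedSplitEvaluate:
    def test_strong_panel_perfect_at_three_markers(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        for kind in ("NNET", "SVM"):
            res = repeated_split_evaluate(panel.matrix, labels,
                                          ranking.top(3),
                                          ClassifierSpec(kind), n_reps=20,
                                          seed=5)
            accs, kappas = zip(*res)
            assert np.mean(accs) == pytest.approx(1.0)
            assert np.mean(kappas) == pytest.approx(1.0)

    def test_shuffled_labels_null_kappa(self, panel_and_ranking, rng):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
        res = repeated_split_evaluate(panel.matrix, shuffled, ranking.top(3),
                                      ClassifierSpec("SVM"), n_reps=30,
                                      seed=5)
        _, kappas = zip(*res)
        assert -0.1 < np.mean(kappas) < 0.1

    def test_fixed_seed_reproducible(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        kw = dict(n_reps=1, seed=123)
        r1 = repeated_split_evaluate(panel.matrix, labels, ranking.top(5),
                                     ClassifierSpec("NNET"), **kw)
        r2 = repeated_split_evaluate(panel.matrix, labels, ranking.top(5),
                                     ClassifierSpec("NNET"), **kw)
        assert r1 == r2

    def test_tiny_class_rejected_with_advice(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples).iloc[:22]  # 20 SC + 2 PC
        with pytest.raises(ValueError, match="train fraction"):
            repeated_split_evaluate(panel.matrix, labels, ranking.top(3),
                                    ClassifierSpec("SVM"), n_reps=2, seed=0)

    def test_mean_metrics_invariant_to_class_relabeling(self,
                                                        panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        swapped = labels.map({"SC": "PC", "PC": "SC"})
        r1 = repeated_split_evaluate(panel.matrix, labels, ranking.top(3),
                                     ClassifierSpec("SVM"), n_reps=10,
                                     seed=9)
        r2 = repeated_split_evaluate(panel.matrix, swapped, ranking.top(3),
                                     ClassifierSpec("SVM"), n_reps=10,
                                     seed=9)
        assert np.mean([a for a, _ in r1]) == pytest.approx(
            np.mean([a for a, _ in r2]))
        assert np.mean([k for _, k in r1]) == pytest.approx(
            np.mean([k for _, k in r2]))


class TestMarkerSweep:
    def test_sweep_reaches_perfect_accuracy(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        sweep = marker_sweep(panel.matrix, labels, ranking, [1, 3, 5, 10, 20],
                             [ClassifierSpec("NNET"), ClassifierSpec("SVM")],
                             n_reps=10, seed=2)
        for kind in ("NNET", "SVM"):
            assert sweep.mean_accuracy(kind, 20) == pytest.approx(1.0)
        summary = sweep.summary()
        assert len(summary) == 10
        assert summary["mean_accuracy"].between(0, 1).all()
        assert summary["mean_kappa"].between(-1, 1).all()

    def test_single_point_sweep(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        sweep = marker_sweep(panel.matrix, labels, ranking, [len(ranking)],
                             [ClassifierSpec("SVM")], n_reps=3, seed=2)
        assert list(sweep.replicates) == [("SVM", len(ranking))]
        assert len(sweep.replicates[("SVM", len(ranking))]) == 3

    def test_null_data_sweep_kappa_near_zero(self):
        # replicate kappas within one cohort share its chance structure, so
        # the null is averaged over independent pure-noise panels as well
        scheme = get_scheme("SC_vs_PC")
        means = {3: [], 10: []}
        for seed in (31, 32, 33, 34, 35):
            null_panel = simulate_panel(small_config(
                n_probes=300, n_sc=20, n_ipsc=10, n_esc=10, seed=seed,
                delta_scpc=0.0, delta_escipsc=0.0, delta_stage=0.0,
                sex_shift=0.0, sex_escape_shift=0.0))
            ranking = rank_markers_for_scheme(null_panel.matrix,
                                              null_panel.annotation,
                                              null_panel.samples, scheme)
            sweep = marker_sweep(null_panel.matrix,
                                 scheme.labels(null_panel.samples), ranking,
                                 [3, 10], [ClassifierSpec("SVM")], n_reps=8,
                                 seed=4)
            for k in means:
                means[k].append(sweep.mean_kappa("SVM", k))
        for k, values in means.items():
            assert abs(np.mean(values)) < 0.15

    def test_oversized_k_rejected(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        with pytest.raises(ValueError, match="exceeds"):
            marker_sweep(panel.matrix, scheme.labels(panel.samples), ranking,
                         [len(ranking) + 1], [ClassifierSpec("SVM")],
                         n_reps=1, seed=0)

    def test_whole_sweep_bit_reproducible(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        kw = dict(n_reps=4, seed=77)
        s1 = marker_sweep(panel.matrix, labels, ranking, [2, 5],
                          [ClassifierSpec("NNET")], **kw)
        s2 = marker_sweep(panel.matrix, labels, ranking, [2, 5],
                          [ClassifierSpec("NNET")], **kw)
        assert s1.replicates == s2.replicates


def _sweep_from_curve(accs):
    ks = list(range(1, len(accs) + 1))
    reps = {("SVM", k): [(a, a)] for k, a in zip(ks, accs)}
    return SweepResult(replicates=reps, model_kinds=["SVM"], k_values=ks,
                       n_reps=1, train_frac=0.7, seed=0)


class TestDetectPlateau:
    def test_constant_curve_plateaus_at_first_k(self):
        sweep = _sweep_from_curve([0.9] * 8)
        assert detect_plateau(sweep, "SVM") == 1

    def test_steadily_rising_curve_never_plateaus(self):
        sweep = _sweep_from_curve(list(np.linspace(0.5, 0.99, 8)))
        assert detect_plateau(sweep, "SVM") == PLATEAU_NOT_REACHED

    def test_rise_then_flat(self):
        sweep = _sweep_from_curve([0.6, 0.8, 0.95, 1.0, 1.0, 1.0, 1.0, 1.0,
                                   1.0])
        assert detect_plateau(sweep, "SVM") == 4

    def test_synthetic_sweep_plateaus_by_thirty_markers(self,
                                                        panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        sweep = marker_sweep(panel.matrix, labels, ranking,
                             [1, 2, 3, 5, 10, 15, 20, 25, 30, 40, 50],
                             [ClassifierSpec("SVM")], n_reps=10, seed=6)
        plateau = detect_plateau(sweep, "SVM")
        assert plateau != PLATEAU_NOT_REACHED and plateau <= 30

    def test_too_few_points_rejected(self):
        sweep = _sweep_from_curve([0.9, 0.9])
        with pytest.raises(ValueError, match="window"):
            detect_plateau(sweep, "SVM")


class TestCrossPlatformPredict:
    def test_resubstitution_gives_all_ones(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        result = cross_platform_predict(
            panel.matrix, labels, panel.matrix, labels, ranking,
            [5, 10], ClassifierSpec("SVM"), n_reps=10, seed=3)
        assert all(v == 1.0 for v in result["quantiles"].values())

    def test_second_platform_strong_markers_predict_perfectly(
            self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        test_matrix, test_samples = simulate_second_platform(
            panel, probe_keep_fraction=0.5, extra_noise_sd=0.05, seed=8)
        result = cross_platform_predict(
            panel.matrix, scheme.labels(panel.samples), test_matrix,
            scheme.labels(test_samples), ranking, [10, 20],
            ClassifierSpec("SVM"), n_reps=20, seed=3)
        assert all(v == 1.0 for v in result["quantiles"].values())
        # only the overlap is used, and it is reported
        for k, detail in result["per_k"].items():
            assert detail["overlap"] <= k

    def test_empty_overlap_rejected(self, panel_and_ranking):
        panel, scheme, ranking = panel_and_ranking
        labels = scheme.labels(panel.samples)
        import pandas as pd
        from methylclass import BetaMatrix
        foreign = BetaMatrix(pd.DataFrame(
            np.full((3, len(labels)), 0.5), index=["zz1", "zz2", "zz3"],
            columns=labels.index))
        with pytest.raises(ValueError, match="overlap"):
            cross_platform_predict(panel.matrix, labels, foreign, labels,
                                   ranking, [5], ClassifierSpec("SVM"),
                                   n_reps=2, seed=0)
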