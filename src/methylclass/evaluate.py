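"""Repeated random-subsampling evaluation of marker panels.

The protocol: for a given marker set, draw many random stratified 70/30
train/test splits, fit each model on the training part, and record test-set
accuracy and Cohen's kappa per replicate.  Sweeping the marker count over
rank-order prefixes of a :class:`~methylclass.biomarker.MarkerRanking` traces
the accuracy-vs-panel-size curve, whose plateau gives the working panel size.
A separate protocol scores a fixed trained panel on an independent cohort
(e.g. a different array platform) by repeatedly subsampling 90% of the test
samples, reporting the accuracy quantiles.

Every replicate's seed derives deterministically from the master seed plus
its (model, marker count, replicate) coordinates, so any cell of a sweep can
be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker import MarkerRanking, select_top_k
from .classify import ClassifierSpec, predict, train
from .io import BetaMatrix

logger = logging.getLogger("methylclass")

_MODEL_CODE = {"NNET": 1, "SVM": 2}
PLATEAU_NOT_REACHED = -1


def cohens_kappa(true_labels, predicted_labels) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate and p_e the agreement expected from
    the two label sequences' marginal frequencies.  Two identical constant
    sequences (p_e = 1) return 1.0 by convention.
    """
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label sequences must be equal-length 1-D")
    if t.size == 0:
        raise ValueError("label sequences must be non-empty")
    n = t.size
    p_o = float(np.mean(t == p))
    classes = np.unique(np.concatenate([t, p]))
    p_e = sum(float(np.mean(t == c)) * float(np.mean(p == c))
              for c in classes)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def replicate_seed(master_seed: int, model_kind: str, k: int, rep: int) -> int:
    """Deterministic per-replicate seed from the (model, k, replicate) cell."""
    ss = np.random.SeedSequence(
        [int(master_seed), _MODEL_CODE[model_kind], int(k), int(rep)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stratified_split(labels: np.ndarray, train_frac: float,
                      rng: np.random.Generator,
                      stratify: bool = True) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    if stratify:
        train_idx = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            n_train = int(round(train_frac * len(idx)))
            train_idx.append(idx[:n_train])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:int(round(train_frac * n))])
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return train_idx, test_idx


def _check_split_feasible(labels: np.ndarray, train_frac: float) -> None:
    for c in np.unique(labels):
        n_c = int((labels == c).sum())
        n_train = int(round(train_frac * n_c))
        if n_train < 2 or n_c - n_train < 2:
            raise ValueError(
                f"class {c!r} has {n_c} samples: a {train_frac:.0%} split "
                "leaves <2 samples in one partition; use more samples or a "
                "different train fraction")


def repeated_split_evaluate(matrix: BetaMatrix, labels: pd.Series,
                            marker_list: list[str], spec: ClassifierSpec,
                            n_reps: int = 200, train_frac: float = 0.7,
                            seed: int = 0, stratify: bool = True
                            ) -> list[tuple[float, float]]:
    """Replicate (accuracy, kappa) pairs over repeated random splits.

    Each replicate draws a stratified ``train_frac`` split of the samples
    carrying labels, trains ``spec`` on the training part (with a
    replicate-derived seed) and scores the held-out part.
    """
    labels = pd.Series(labels)
    sample_ids = [s for s in matrix.sample_ids if s in labels.index]
    sub = matrix.select_samples(sample_ids)
    y = labels.loc[sample_ids].to_numpy(dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    _check_split_feasible(y, train_frac)
    features = sub.select_probes(marker_list).features()  # samples x markers

    results = []
    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, spec.model_kind, len(marker_list), rep)
        rng = np.random.default_rng(rep_seed)
        train_idx, test_idx = _stratified_split(y, train_frac, rng,
                                                stratify=stratify)
        model = train(features.iloc[train_idx],
                      pd.Series(y[train_idx], index=features.index[train_idx]),
                      spec.with_seed(rep_seed))
        yhat = predict(model, features.iloc[test_idx]).to_numpy(dtype=object)
        y_test = y[test_idx]
        acc = float(np.mean(yhat == y_test))
        results.append((acc, cohens_kappa(y_test, yhat)))
    return results


@dataclass
class SweepResult:
    """Replicate accuracies/kappas per (model kind, marker count)."""

    replicates: dict[tuple[str, int], list[tuple[float, float]]]
    model_kinds: list[str]
    k_values: list[int]
    n_reps: int
    train_frac: float
    seed: int

    def mean_accuracy(self, model_kind: str, k: int) -> float:
        return float(np.mean([a for a, _ in self.replicates[(model_kind, k)]]))

    def mean_kappa(self, model_kind: str, k: int) -> float:
        return float(np.mean([kp for _, kp in self.replicates[(model_kind, k)]]))

    def summary(self) -> pd.DataFrame:
        rows = [{"model": m, "k": k,
                 "mean_accuracy": self.mean_accuracy(m, k),
                 "mean_kappa": self.mean_kappa(m, k),
                 "n_reps": len(self.replicates[(m, k)])}
                for m in self.model_kinds for k in self.k_values]
        return pd.DataFrame(rows)


def marker_sweep(matrix: BetaMatrix, labels: pd.Series,
                 ranking: MarkerRanking, k_values: list[int],
                 specs: list[ClassifierSpec], n_reps: int = 200,
                 train_frac: float = 0.7, seed: int = 0,
                 stratify: bool = True) -> SweepResult:
    """Run the repeated-split protocol at every marker count in ``k_values``.

    Marker sets are rank-order prefixes of ``ranking``.
    """
    k_values = sorted(int(k) for k in k_values)
    if k_values and k_values[-1] > len(ranking):
        raise ValueError(f"max k={k_values[-1]} exceeds ranking size "
                         f"{len(ranking)}")
    replicates = {}
    for spec in specs:
        for k in k_values:
            markers = select_top_k(ranking, k)
            replicates[(spec.model_kind, k)] = repeated_split_evaluate(
                matrix, labels, markers, spec, n_reps=n_reps,
                train_frac=train_frac, seed=seed, stratify=stratify)
    return SweepResult(replicates=replicates,
                       model_kinds=[s.model_kind for s in specs],
                       k_values=k_values, n_reps=n_reps,
                       train_frac=train_frac, seed=seed)


def detect_plateau(sweep: SweepResult, model_kind: str,
                   epsilon: float = 0.005, window: int = 5) -> int:
    """Smallest marker count from which mean accuracy stops moving.

    Returns the first k whose next ``window`` evaluated marker counts all
    have mean accuracy within ``epsilon`` of k's, or
    :data:`PLATEAU_NOT_REACHED` if the curve never stabilizes.
    """
    ks = sweep.k_values
    if len(ks) < window:
        raise ValueError(f"need at least window={window} sweep points")
    acc = np.array([sweep.mean_accuracy(model_kind, k) for k in ks])
    for i in range(len(ks) - window):
        if np.all(np.abs(acc[i + 1:i + 1 + window] - acc[i]) < epsilon):
            return ks[i]
    return PLATEAU_NOT_REACHED


def cross_platform_predict(train_matrix: BetaMatrix, train_labels: pd.Series,
                           test_matrix: BetaMatrix, test_labels: pd.Series,
                           ranking: MarkerRanking, k_range: list[int],
                           spec: ClassifierSpec, n_reps: int = 200,
                           test_frac: float = 0.9, seed: int = 0) -> dict:
    """Prediction profiling on an independent cohort.

    For each marker count k, the top-k markers are intersected with the test
    cohort's probes, the model is trained once on the *full* training matrix
    over that overlap, and ``n_reps`` random subsamples of ``test_frac`` of
    the test samples are scored.  Returns the pooled accuracy quantiles
    (0/25/50/75/100%) plus per-k detail.
    """
    train_labels = pd.Series(train_labels)
    test_labels = pd.Series(test_labels)
    train_ids = [s for s in train_matrix.sample_ids if s in train_labels.index]
    test_ids = [s for s in test_matrix.sample_ids if s in test_labels.index]
    y_test_all = test_labels.loc[test_ids].to_numpy(dtype=object)

    all_accuracies = []
    per_k = {}
    for k in k_range:
        top = select_top_k(ranking, k)
        overlap = [p for p in top if p in test_matrix.probe_ids]
        if not overlap:
            raise ValueError(f"no overlap between top-{k} markers and the "
                             "test cohort's probes")
        logger.info("cross_platform_predict: k=%d, overlap=%d", k,
                    len(overlap))
        features_train = (train_matrix.select_samples(train_ids)
                          .select_probes(overlap).features())
        model = train(features_train, train_labels.loc[train_ids],
                      spec.with_seed(replicate_seed(seed, spec.model_kind,
                                                    k, 0)))
        features_test = (test_matrix.select_samples(test_ids)
                         .select_probes(overlap).features())
        accs = []
        n_take = max(1, int(round(test_frac * len(test_ids))))
        for rep in range(n_reps):
            rng = np.random.default_rng(
                replicate_seed(seed, spec.model_kind, k, rep + 1))
            take = np.sort(rng.choice(len(test_ids), size=n_take,
                                      replace=False))
            yhat = predict(model, features_test.iloc[take]).to_numpy(object)
            accs.append(float(np.mean(yhat == y_test_all[take])))
        per_k[k] = {"overlap": len(overlap), "accuracies": accs}
        all_accuracies.extend(accs)

    qs = np.percentile(all_accuracies, [0, 25, 50, 75, 100])
    return {"quantiles": {"0%": qs[0], "25%": qs[1], "50%": qs[2],
                          "75%": qs[3], "100%": qs[4]},
            "per_k": per_k}
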