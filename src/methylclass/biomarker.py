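"""Eigengene-score marker selection.

An *eigengene* is the sample-score vector of a principal component of the
probe-centered beta matrix: a one-dimensional summary of a dominant axis of
variation across samples.  Each probe i is scored by

    score(i) = max_k | Cor(x_i, E_k) |

the absolute Pearson correlation between the probe's methylation vector x_i
and each supplied eigengene E_k; probes are ranked by this score.  Ranking by
correlation with a variance axis (instead of by differential methylation)
de-duplicates correlated probes' evidence and is robust to the heavy class
imbalance typical of public methylation cohorts.

For the somatic-vs-pluripotent comparison the first component carries the
separation; for ESC vs iPSC the separation is spread over two components,
and the resulting markers split naturally into an autosomal and an
X-chromosome group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import BetaMatrix, LabelScheme

logger = logging.getLogger("methylclass")

#: default components per comparison scheme (1-based indices).  The
#: decomposition runs on the comparison's own samples, so the comparison's
#: axis is a leading component; ESC vs iPSC uses two components because its
#: markers occupy two variance axes (an autosomal and an X-linked group).
DEFAULT_COMPONENTS: dict[str, tuple[int, ...]] = {
    "SC_vs_PC": (1,),
    "ESC_vs_iPSC": (1, 2),
    "F_vs_M_iPSC": (1,),
    "fetal_vs_adult_SC": (1,),
}


@dataclass
class Eigengene:
    """One principal component's sample scores.

    ``component_index`` is 1-based; ``scores`` is indexed by sample ID and has
    zero mean (probes are centered before the decomposition); distinct
    components' scores are orthogonal.
    """

    component_index: int
    scores: pd.Series
    explained_variance_ratio: float


def compute_eigengenes(matrix: BetaMatrix, n_components: int,
                       labels: pd.Series | None = None) -> list[Eigengene]:
    """Top principal-component sample scores of the probe-centered matrix.

    Sign convention: when ``labels`` (a binary class series over the samples)
    is given, each eigengene is oriented so its correlation with the
    first-class indicator is non-negative; otherwise the entry of largest
    magnitude is made positive.
    """
    n_probes, n_samples = matrix.shape
    if n_samples < 2 or n_probes < 2:
        raise ValueError("need >=2 probes and >=2 samples")
    if n_components > min(n_probes, n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)="
            f"{min(n_probes, n_samples)}")
    X = matrix.values.T  # samples x probes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s  # samples x components
    total_var = float((s ** 2).sum())
    if total_var <= 0:
        raise ValueError("matrix has zero variance; no components")

    indicator = None
    if labels is not None:
        labels = pd.Series(labels).loc[matrix.sample_ids]
        first = pd.unique(labels)[0]
        indicator = (labels == first).to_numpy(float)
        indicator = indicator - indicator.mean()

    out = []
    for k in range(n_components):
        e = scores[:, k]
        if indicator is not None and float(indicator @ e) < 0:
            e = -e
        elif indicator is None and e[np.argmax(np.abs(e))] < 0:
            e = -e
        out.append(Eigengene(
            component_index=k + 1,
            scores=pd.Series(e, index=matrix.sample_ids),
            explained_variance_ratio=float(s[k] ** 2) / total_var,
        ))
    return out


def eigengene_score(matrix: BetaMatrix, eigengene: Eigengene) -> pd.Series:
    """|Pearson correlation| of every probe vector with an eigengene.

    Constant (zero-variance) probes score 0 by convention.
    """
    e = eigengene.scores
    if not e.index.equals(matrix.sample_ids):
        if set(e.index) != set(matrix.sample_ids):
            raise ValueError("eigengene samples do not match the matrix")
        e = e.loc[matrix.sample_ids]
    X = matrix.values
    ec = e.to_numpy() - e.to_numpy().mean()
    e_norm = np.linalg.norm(ec)
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(Xc, axis=1)
    denom = x_norm * e_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc @ ec) / denom, 0.0)
    return pd.Series(np.abs(r), index=matrix.probe_ids, name="score")


@dataclass
class MarkerRanking:
    """Probes ordered by eigengene score (descending, probe-ID tiebreak).

    ``table`` columns: score, component_index, chromosome, position, symbol,
    chrom_group ('autosomal' or 'X'); indexed by probe ID.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return select_top_k(self, k)

    def to_table1_format(self) -> pd.DataFrame:
        """Five-column table: ID, Chr, MapInfo, Symbol, Ranking."""
        return pd.DataFrame({
            "ID": self.table.index,
            "Chr": self.table["chromosome"].to_numpy(),
            "MapInfo": self.table["position"].to_numpy(),
            "Symbol": self.table["symbol"].to_numpy(),
            "Ranking": self.table["score"].to_numpy(),
        })


def rank_markers(matrix: BetaMatrix, annotation: pd.DataFrame,
                 scheme: LabelScheme | None,
                 components: list[Eigengene]) -> MarkerRanking:
    """Rank all annotated probes by their best eigengene score.

    Each probe gets score = max over the supplied eigengenes of
    |Cor(x_i, E_k)| and the 1-based index of the maximizing component.
    Probes without annotation are excluded (count logged); Y-chromosome
    probes are excluded (sex-linked dosage confound).  ``scheme`` is carried
    for bookkeeping only; restrict the matrix to the scheme's samples before
    calling if a per-comparison decomposition is wanted.
    """
    if not components:
        raise ValueError("at least one eigengene required")
    scores = pd.concat([eigengene_score(matrix, e) for e in components], axis=1)
    comp_idx = np.array([e.component_index for e in components])
    best = scores.to_numpy().argmax(axis=1)
    best_score = scores.to_numpy()[np.arange(len(scores)), best]

    table = pd.DataFrame({
        "score": best_score,
        "component_index": comp_idx[best],
    }, index=matrix.probe_ids)

    known = table.index.intersection(annotation.index)
    n_missing = len(table) - len(known)
    if n_missing:
        logger.info("rank_markers: %d probes lack annotation and were "
                    "excluded", n_missing)
    table = table.loc[known]
    table["chromosome"] = annotation.loc[known, "chromosome"]
    table["position"] = annotation.loc[known, "position"]
    table["symbol"] = annotation.loc[known, "symbol"]
    n_y = int((table["chromosome"] == "Y").sum())
    if n_y:
        logger.info("rank_markers: excluded %d Y-chromosome probes", n_y)
    table = table[table["chromosome"] != "Y"]
    table["chrom_group"] = np.where(table["chromosome"] == "X", "X",
                                    "autosomal")
    table = (table.rename_axis("probe_id")
             .sort_values(["score", "probe_id"], ascending=[False, True],
                          kind="stable"))
    return MarkerRanking(table=table)


def split_by_chromosome(ranking: MarkerRanking
                        ) -> tuple[MarkerRanking, MarkerRanking]:
    """Partition a ranking into its autosomal and X-chromosome groups."""
    t = ranking.table
    return (MarkerRanking(t[t["chrom_group"] == "autosomal"].copy()),
            MarkerRanking(t[t["chrom_group"] == "X"].copy()))


def select_top_k(ranking: MarkerRanking, k: int) -> list[str]:
    """First k probe IDs in rank order."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range [1, {len(ranking)}]")
    return list(ranking.table.index[:k])


def rank_markers_for_scheme(matrix: BetaMatrix, annotation: pd.DataFrame,
                            samples: pd.DataFrame, scheme: LabelScheme,
                            components: tuple[int, ...] | None = None
                            ) -> MarkerRanking:
    """End-to-end ranking for a named comparison.

    Restricts the matrix to the scheme's samples, computes the needed
    eigengenes there (signs oriented by the scheme's first class), and ranks
    every annotated probe.
    """
    if components is None:
        components = DEFAULT_COMPONENTS.get(scheme.name, (1,))
    labels = scheme.labels(samples)
    sub = matrix.select_samples([s for s in matrix.sample_ids
                                 if s in labels.index])
    if len(pd.unique(labels.loc[sub.sample_ids])) < 2:
        raise ValueError(f"scheme {scheme.name}: both classes required")
    eigs = compute_eigengenes(sub, max(components),
                              labels=labels.loc[sub.sample_ids])
    chosen = [eigs[k - 1] for k in components]
    return rank_markers(sub, annotation, scheme, chosen)


class EigengeneMarkerSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn feature selector ranking features by eigengene score.

    ``fit`` centers the features, computes the requested principal-component
    sample scores, scores each feature by its best |Pearson correlation| with
    them, and stores the rank order; ``transform`` keeps the top ``k``
    features.  ``y`` (optional binary labels) only orients component signs.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Best absolute correlation per feature.
    ranking_ : ndarray of shape (n_features,)
        Feature indices in decreasing score order.
    support_ : boolean mask of the selected features.
    """

    def __init__(self, k: int = 20, components: tuple[int, ...] = (1,)):
        self.k = k
        self.components = components

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=2)
        if self.k < 1 or self.k > X.shape[1]:
            raise ValueError(f"k={self.k} out of range")
        n_comp = max(self.components)
        if n_comp > min(X.shape):
            raise ValueError("component index exceeds matrix rank bound")
        Xc = X - X.mean(axis=0, keepdims=True)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        E = (U * s)[:, [c - 1 for c in self.components]]
        Ec = E - E.mean(axis=0, keepdims=True)
        e_norm = np.linalg.norm(Ec, axis=0)
        x_norm = np.linalg.norm(Xc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(Xc.T @ Ec) / np.outer(x_norm, e_norm)
        corr = np.nan_to_num(corr, nan=0.0)
        self.scores_ = corr.max(axis=1)
        self.component_index_ = np.array(self.components)[corr.argmax(axis=1)]
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_[:self.k]] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return X[:, self.ranking_[:self.k]]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return self.ranking_[:self.k] if indices else self.support_
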