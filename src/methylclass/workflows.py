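"""End-to-end benchmark workflows on synthetic panels.

Each workflow generates a panel under stated study conditions, ranks markers
by eigengene score, and evaluates both discriminant models with repeated
stratified 70/30 splits, returning per-model mean test accuracy and mean
Cohen's kappa.  These are the canonical demonstrations of the system:
somatic-vs-pluripotent discrimination with a small top-ranked panel, and
female-vs-male iPSC discrimination from X-linked markers.
"""

from __future__ import annotations

import numpy as np

from .classify import ClassifierSpec
from .evaluate import repeated_split_evaluate
from .biomarker import rank_markers_for_scheme
from .io import get_scheme
from .simulate import SimulationConfig, simulate_panel

MODEL_KINDS = ("NNET", "SVM")


def _evaluate_panel(panel, scheme_name: str, top_k: int, n_reps: int,
                    seed: int) -> dict[str, dict[str, float]]:
    scheme = get_scheme(scheme_name)
    ranking = rank_markers_for_scheme(panel.matrix, panel.annotation,
                                      panel.samples, scheme)
    labels = scheme.labels(panel.samples)
    markers = ranking.top(top_k)
    out: dict[str, dict[str, float]] = {}
    for kind in MODEL_KINDS:
        res = repeated_split_evaluate(panel.matrix, labels, markers,
                                      ClassifierSpec(kind), n_reps=n_reps,
                                      train_frac=0.7, seed=seed)
        accs, kappas = zip(*res)
        out[kind] = {"mean_accuracy": float(np.mean(accs)),
                     "mean_kappa": float(np.mean(kappas))}
    return out


def sc_vs_pc_benchmark(seed: int = 1, n_reps: int = 50, top_k: int = 20
                       ) -> dict[str, dict[str, float]]:
    """Somatic vs pluripotent discrimination on the flagship panel.

    2000 probes, 60 SC + 30 iPSC + 30 ESC samples, 100 informative loci at
    mean-beta difference 0.3, concentration 30; top ``top_k`` markers ranked
    by |Cor(x_i, E)| against the first principal component.
    """
    panel = simulate_panel(SimulationConfig(seed=seed))
    return _evaluate_panel(panel, "SC_vs_PC", top_k, n_reps, seed)


def sex_benchmark_config(seed: int = 1) -> SimulationConfig:
    """Study conditions for the X-linked sex comparison: an all-iPSC cohort
    (40 F + 40 M), 200 X probes of 2000, male X means near 0.15 and female
    means shifted fully toward 0.5."""
    return SimulationConfig(
        n_sc=0, n_esc=0, n_ipsc=80,
        n_x_probes=200, male_x_mean=0.15, sex_shift=0.35,
        x_inactivated_fraction=1.0, seed=seed)


def sex_discrimination_benchmark(seed: int = 1, n_reps: int = 50,
                                 top_k: int = 2
                                 ) -> dict[str, dict[str, float]]:
    """Female vs male iPSC discrimination from the top X-linked markers."""
    panel = simulate_panel(sex_benchmark_config(seed))
    return _evaluate_panel(panel, "F_vs_M_iPSC", top_k, n_reps, seed)
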