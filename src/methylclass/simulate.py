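"""Synthetic methylation panels with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a bimodal (hypo/hyper) background of beta values, sampled from Beta
  distributions in a mean/concentration parameterization so every draw stays
  in [0, 1];
* planted informative loci whose group mean beta differs between somatic
  (SC) and pluripotent (iPSC + ESC) cells, and — more weakly and over more
  loci — between ESC and iPSC, the latter split into an autosomal and an
  X-chromosome group;
* X-inactivation structure: a fraction of X probes (subject to full
  X-inactivation) shift strongly toward intermediate values in female
  samples, the rest (escape-like) shift mildly; male X probes sit near the
  unmethylated mode.  The somatic/pluripotent axis stays the dominant
  variance component, as in real cohorts;
* fetal/adult somatic-stage loci;
* optional additive batch effects on the logit scale.

Every generated panel carries a :class:`TruthTable` recording each probe's
role and the planted group means, so recovery of markers, batch effects and
outliers can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import BetaMatrix

CATEGORY_NULL = "null"
CATEGORY_SCPC = "sc_pc_marker"
CATEGORY_ESCIPSC_AUTO = "esc_ipsc_autosomal"
CATEGORY_ESCIPSC_X = "esc_ipsc_X"
CATEGORY_SEX = "sex_marker"
CATEGORY_STAGE = "stage_marker"

OUTLIER_KINDS = ("sex_mislabel", "unimodal", "distance")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic methylation panel.

    Defaults mirror a moderately sized multi-batch microarray cohort: a
    strong somatic/pluripotent axis (effect 0.3 at 100 of 2000 loci), a
    weaker and more diffuse ESC/iPSC axis (0.15 at 150 loci, one third on
    the X chromosome), X-linked sex structure on a 5% X-probe quota (30%
    of X probes fully inactivated in females, the rest escape-like), and
    Beta-distributed observation noise with concentration 30 (per-probe SD
    around 0.05-0.09).
    """

    n_probes: int = 2000
    n_sc: int = 60
    n_ipsc: int = 30
    n_esc: int = 30
    n_x_probes: int = 100
    n_informative_scpc: int = 100
    n_informative_escipsc: int = 150
    escipsc_x_fraction: float = 1 / 3
    delta_scpc: float = 0.3
    delta_escipsc: float = 0.15
    n_informative_stage: int = 80
    delta_stage: float = 0.2
    hypo_mean: float = 0.1
    hyper_mean: float = 0.9
    hyper_fraction: float = 0.5
    male_x_mean: float = 0.20
    sex_shift: float = 0.30
    x_inactivated_fraction: float = 0.30
    sex_escape_shift: float = 0.075
    concentration: float = 30.0
    batches: tuple[str, ...] = ("batch1",)
    batch_shifts: dict = field(default_factory=dict)  # batch -> logit shift
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sc, self.n_ipsc, self.n_esc) < 0 or self.n_probes < 1:
            raise ValueError("counts must be non-negative, n_probes >= 1")
        n_esc_x = int(round(self.escipsc_x_fraction
                            * self.n_informative_escipsc))
        if n_esc_x > self.n_x_probes:
            raise ValueError("more planted X loci than X probes")
        planted_auto = (self.n_informative_scpc
                        + (self.n_informative_escipsc - n_esc_x)
                        + self.n_informative_stage)
        if planted_auto > self.n_probes - self.n_x_probes:
            raise ValueError("more informative loci than autosomal probes")
        for d in (self.delta_scpc, self.delta_escipsc):
            if not 0 <= d < 1:
                raise ValueError("effect sizes must lie in [0, 1)")


@dataclass
class TruthTable:
    """Planted structure of a simulated panel."""

    categories: pd.Series            # probe -> category
    group_means: pd.DataFrame        # probes x (SC, iPSC, ESC)
    stage_offset: pd.Series          # added for fetal somatic samples
    sex_offset: pd.Series            # added per probe for female samples
    is_x: pd.Series                  # probe -> bool
    concentration: float

    def probes_of(self, category: str) -> list[str]:
        return list(self.categories.index[self.categories == category])


@dataclass
class Panel:
    """A simulated cohort: matrix + annotation + samples + ground truth."""

    matrix: BetaMatrix
    annotation: pd.DataFrame
    samples: pd.DataFrame
    truth: TruthTable
    config: SimulationConfig


def _toward_interior(base: np.ndarray, delta: float) -> np.ndarray:
    """Shift means by exactly ``delta``, away from the nearer boundary."""
    return np.where(base + delta <= 0.98, base + delta, base - delta)


def _mean_matrix(truth: TruthTable, samples: pd.DataFrame) -> np.ndarray:
    """Per-probe, per-sample planted means for an arbitrary sample table."""
    probes = truth.group_means.index
    means = np.empty((len(probes), len(samples)))
    gm = truth.group_means
    sex_off = truth.sex_offset.to_numpy()
    stage_off = truth.stage_offset.to_numpy()
    for j, (sid, row) in enumerate(samples.iterrows()):
        m = gm[row["cell_type"]].to_numpy().copy()
        if row["sex"] == "F":
            m = np.clip(m + sex_off, 0.02, 0.98)
        if row["cell_type"] == "SC" and row["stage"] == "fetal":
            m = np.clip(m + stage_off, 0.02, 0.98)
        means[:, j] = m
    return means


def _draw_betas(means: np.ndarray, concentration: float,
                rng: np.random.Generator) -> np.ndarray:
    a = means * concentration
    b = (1.0 - means) * concentration
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    counter = 0
    for cell_type, n in (("SC", config.n_sc), ("iPSC", config.n_ipsc),
                         ("ESC", config.n_esc)):
        for i in range(n):
            rows.append({
                "sample_id": f"S{counter:03d}",
                "cell_type": cell_type,
                "sex": "F" if i % 2 == 0 else "M",
                "stage": (("fetal" if i % 2 == 0 else "adult")
                          if cell_type == "SC" else "unknown"),
                "batch": config.batches[counter % len(config.batches)],
                "platform": "platform1",
            })
            counter += 1
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_panel(config: SimulationConfig | None = None) -> Panel:
    """Generate a full synthetic panel from the study conditions."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")

    # chromosome assignment: an X quota, the rest autosomal
    perm = rng.permutation(n)
    x_idx = np.sort(perm[:config.n_x_probes])
    is_x = np.zeros(n, dtype=bool)
    is_x[x_idx] = True
    chroms = rng.integers(1, 23, size=n).astype(str)
    chroms[is_x] = "X"
    annotation = pd.DataFrame({
        "chromosome": chroms,
        "position": rng.integers(1, 150_000_000, size=n),
        "symbol": [f"GENE{i:04d}" for i in range(n)],
    }, index=probe_ids)

    # baseline means: bimodal autosomal background, hypomethylated X
    base = np.where(rng.random(n) < config.hyper_fraction,
                    config.hyper_mean, config.hypo_mean)
    base = np.clip(base + rng.uniform(-0.05, 0.05, size=n), 0.02, 0.98)
    base[is_x] = np.clip(config.male_x_mean
                         + rng.uniform(-0.07, 0.07, size=is_x.sum()),
                         0.02, 0.98)

    # planted loci (disjoint categories)
    categories = np.full(n, CATEGORY_NULL, dtype=object)
    categories[is_x] = CATEGORY_SEX  # all X probes carry the sex structure
    auto_idx = rng.permutation(np.flatnonzero(~is_x))
    n_esc_x = int(round(config.escipsc_x_fraction
                        * config.n_informative_escipsc))
    n_esc_auto = config.n_informative_escipsc - n_esc_x
    cursor = 0
    scpc_idx = auto_idx[cursor:cursor + config.n_informative_scpc]
    cursor += config.n_informative_scpc
    esc_auto_idx = auto_idx[cursor:cursor + n_esc_auto]
    cursor += n_esc_auto
    stage_idx = auto_idx[cursor:cursor + config.n_informative_stage]
    esc_x_idx = rng.permutation(x_idx)[:n_esc_x]
    categories[scpc_idx] = CATEGORY_SCPC
    categories[esc_auto_idx] = CATEGORY_ESCIPSC_AUTO
    categories[esc_x_idx] = CATEGORY_ESCIPSC_X
    categories[stage_idx] = CATEGORY_STAGE

    group_means = pd.DataFrame({ct: base.copy()
                                for ct in ("SC", "iPSC", "ESC")},
                               index=probe_ids)
    # SC vs PC: shift both pluripotent groups together
    shifted = _toward_interior(base[scpc_idx], config.delta_scpc)
    group_means.iloc[scpc_idx,
                     group_means.columns.get_indexer(["iPSC", "ESC"])] = \
        np.column_stack([shifted, shifted])
    # ESC vs iPSC: shift iPSC only
    for idx in (esc_auto_idx, esc_x_idx):
        group_means.iloc[idx, group_means.columns.get_loc("iPSC")] = \
            _toward_interior(base[idx], config.delta_escipsc)

    stage_offset = np.zeros(n)
    stage_offset[stage_idx] = np.where(base[stage_idx] <= 0.5,
                                       config.delta_stage,
                                       -config.delta_stage)

    # X-inactivation: a subset of X probes gains the full female shift,
    # the rest (escape-like) a mild one
    sex_offset = np.zeros(n)
    n_strong = int(round(config.x_inactivated_fraction * len(x_idx)))
    strong = rng.permutation(x_idx)[:n_strong]
    sex_offset[is_x] = config.sex_escape_shift
    sex_offset[strong] = config.sex_shift

    truth = TruthTable(
        categories=pd.Series(categories, index=probe_ids, name="category"),
        group_means=group_means,
        stage_offset=pd.Series(stage_offset, index=probe_ids),
        sex_offset=pd.Series(sex_offset, index=probe_ids),
        is_x=pd.Series(is_x, index=probe_ids),
        concentration=config.concentration,
    )

    samples = _sample_table(config)
    means = _mean_matrix(truth, samples)
    values = _draw_betas(means, config.concentration, rng)

    # additive batch effects on the logit scale
    shifts = np.array([config.batch_shifts.get(b, 0.0)
                       for b in samples["batch"]])
    if np.any(shifts != 0.0):
        values = expit(logit(np.clip(values, 1e-6, 1 - 1e-6))
                       + shifts[None, :])

    matrix = BetaMatrix(pd.DataFrame(values, index=probe_ids,
                                     columns=samples.index))
    return Panel(matrix=matrix, annotation=annotation, samples=samples,
                 truth=truth, config=config)


def simulate_second_platform(panel: Panel, probe_keep_fraction: float = 0.8,
                             extra_noise_sd: float = 0.05, seed: int = 0
                             ) -> tuple[BetaMatrix, pd.DataFrame]:
    """Fresh samples from the same truth on a reduced, noisier probe set.

    Emulates an independent validation cohort on a different platform: a
    random ``probe_keep_fraction`` of the probes is retained, fresh samples
    (same group sizes as the original panel) are drawn from the planted
    means, and logit-scale Gaussian noise of SD ``extra_noise_sd`` is added.
    """
    if not 0 < probe_keep_fraction <= 1:
        raise ValueError("probe_keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = panel.config.n_probes
    n_keep = int(round(probe_keep_fraction * n))
    keep = np.sort(rng.permutation(n)[:n_keep])
    probes = panel.truth.group_means.index[keep]

    samples = _sample_table(panel.config)
    samples.index = pd.Index(["T" + s[1:] for s in samples.index],
                             name="sample_id")
    samples["platform"] = "platform2"
    means = _mean_matrix(panel.truth, samples)[keep, :]
    values = _draw_betas(means, panel.config.concentration, rng)
    if extra_noise_sd > 0:
        values = expit(logit(np.clip(values, 1e-6, 1 - 1e-6))
                       + rng.normal(0.0, extra_noise_sd, size=values.shape))
    matrix = BetaMatrix(pd.DataFrame(values, index=probes,
                                     columns=samples.index))
    return matrix, samples


def simulate_outliers(panel: Panel, kinds: set[str] | tuple[str, ...] = (),
                      seed: int = 0) -> tuple[Panel, dict[str, str]]:
    """Inject one labeled outlier per requested kind.

    * ``sex_mislabel`` — a female sample's recorded sex is flipped to M
      (its data keep the female X pattern);
    * ``unimodal``     — a sample's betas are replaced by Uniform(0.3, 0.7)
      (a degenerate, non-bimodal array);
    * ``distance``     — a sample is shifted by +0.3 on every probe.

    Returns the modified panel and a mapping kind -> injected sample ID.
    Distinct samples are used for the three kinds.
    """
    kinds = set(kinds)
    unknown = kinds - set(OUTLIER_KINDS)
    if unknown:
        raise ValueError(f"unknown outlier kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    data = panel.matrix.data.copy()
    samples = panel.samples.copy()
    injected: dict[str, str] = {}
    used: set[str] = set()

    def pick(candidates) -> str:
        for sid in candidates:
            if sid not in used:
                used.add(sid)
                return sid
        raise ValueError("not enough samples to inject outliers")

    if "sex_mislabel" in kinds:
        sid = pick(samples.index[samples["sex"] == "F"])
        samples.loc[sid, "sex"] = "M"
        injected["sex_mislabel"] = sid
    if "unimodal" in kinds:
        # keep the recorded-female X pattern plausible: a mid-beta flood has
        # mean X beta ~0.5, inside the female window
        sid = pick(samples.index[samples["sex"] == "F"])
        data[sid] = rng.uniform(0.3, 0.7, size=len(data))
        injected["unimodal"] = sid
    if "distance" in kinds:
        sid = pick(samples.index[samples["sex"] == "M"])
        data[sid] = np.clip(data[sid] + 0.3, 0.0, 1.0)
        injected["distance"] = sid

    new_panel = replace(panel, matrix=BetaMatrix(data), samples=samples)
    return new_panel, injected
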