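"""Sample-level quality control.

Three outlier checks run on the raw (unnormalized) beta matrix, before any
normalization or marker selection:

1. **X-chromosome distribution** — in female cells X-inactivation pushes
   X-probe betas toward intermediate values, while male X probes sit near the
   unmethylated mode.  A sample whose recorded sex contradicts its mean X beta
   is flagged; with unknown sex, a robust (MAD-based) outlier rule is applied
   within the sample's cell-type group.
2. **CpG methylation distribution** — genome-wide beta distributions are
   bimodal (hypo/hyper).  The fraction of probes in the extreme bins
   (beta < 0.3 or beta > 0.7) is computed per sample; samples far below the
   cohort median are degenerate/unimodal arrays and are flagged.
3. **Distance to group centre** — within each cell-type group, the Euclidean
   distance of each sample's beta vector to the group mean; samples beyond
   mean + k.SD of within-group distances are flagged.

All checks are sample-wise and deterministic; no probe is removed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger("methylclass")

#: consistency constant making MAD comparable to a standard deviation
_MAD_SCALE = 1.4826

FLAG_COLUMNS = ("x_chrom_fail", "cpg_dist_fail", "distance_fail")


@dataclass
class QcReport:
    """Per-sample QC statistics and flags; covers every input sample."""

    stats: pd.DataFrame  # mean_x_beta, extreme_fraction, distance, distance_z + flags
    pass_ids: list[str]

    @property
    def n_flagged(self) -> int:
        return int(self.stats[list(FLAG_COLUMNS)].any(axis=1).sum())

    def counts(self) -> dict[str, int]:
        return {c: int(self.stats[c].sum()) for c in FLAG_COLUMNS}


def _robust_z(values: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); zero when the MAD vanishes."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        return np.zeros_like(values, dtype=float)
    return (values - med) / (_MAD_SCALE * mad)


def qc_x_chromosome(matrix: BetaMatrix, annotation: pd.DataFrame,
                    samples: pd.DataFrame,
                    female_window: tuple[float, float] = (0.30, 0.70),
                    male_max: float = 0.30,
                    n_mads: float = 3.0) -> pd.DataFrame:
    """Flag samples whose X-probe beta pattern contradicts their recorded sex.

    Returns a DataFrame (indexed by sample) with ``mean_x_beta`` and
    ``x_chrom_fail``.
    """
    x_probes = annotation.index[annotation["chromosome"] == "X"]
    x_probes = x_probes.intersection(matrix.probe_ids)
    if len(x_probes) < 10:
        raise ValueError(
            f"insufficient X probes: {len(x_probes)} found, >=10 required")
    mean_x = matrix.data.loc[x_probes].mean(axis=0)
    samples = samples.loc[matrix.sample_ids]
    mx = mean_x.to_numpy()
    sex = samples["sex"].to_numpy()
    flags = np.zeros(len(sex), dtype=bool)

    lo, hi = female_window
    is_f = sex == "F"
    is_m = sex == "M"
    flags[is_f] = (mx[is_f] < lo) | (mx[is_f] > hi)
    flags[is_m] = mx[is_m] >= male_max

    unknown = ~(is_f | is_m)
    if unknown.any():
        cell_types = samples["cell_type"].to_numpy()
        for ct in np.unique(cell_types[unknown]):
            idx = np.flatnonzero(unknown & (cell_types == ct))
            flags[idx] = np.abs(_robust_z(mx[idx])) > n_mads

    return pd.DataFrame({"mean_x_beta": mean_x,
                         "x_chrom_fail": pd.Series(flags,
                                                   index=matrix.sample_ids)})


def qc_cpg_distribution(matrix: BetaMatrix, low: float = 0.3,
                        high: float = 0.7, n_mads: float = 3.0) -> pd.DataFrame:
    """Flag degenerate (unimodal) arrays by their extreme-bin fraction.

    The statistic is f = P(beta < low) + P(beta > high) per sample; a sample is
    flagged when f falls more than ``n_mads`` scaled MADs below the cohort
    median.
    """
    if matrix.shape[0] < 100:
        raise ValueError(
            f"qc_cpg_distribution requires >=100 probes, got {matrix.shape[0]}")
    values = matrix.values
    with np.errstate(invalid="ignore"):
        f = (np.nanmean(values < low, axis=0) + np.nanmean(values > high, axis=0))
    f = pd.Series(f, index=matrix.sample_ids, name="extreme_fraction")
    med = float(np.median(f))
    mad = float(np.median(np.abs(f - med)))
    # strict inequality: an exactly-typical cohort (deviation 0, MAD 0) passes
    flags = (med - f) > n_mads * _MAD_SCALE * mad
    return pd.DataFrame({"extreme_fraction": f, "cpg_dist_fail": flags})


def qc_distance_outlier(matrix: BetaMatrix, samples: pd.DataFrame,
                        k: float = 2.0) -> pd.DataFrame:
    """Flag within-group Euclidean-distance outliers.

    Distance of each sample's beta vector to its cell-type group mean; flag
    when distance > mean + k.SD of the group's distances.  Groups with fewer
    than 3 samples are skipped with a warning.
    """
    samples = samples.loc[matrix.sample_ids]
    cell_types = samples["cell_type"].to_numpy()
    n = len(cell_types)
    dist = np.full(n, np.nan)
    z = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    for ct in np.unique(cell_types):
        idx = np.flatnonzero(cell_types == ct)
        if len(idx) < 3:
            warnings.warn(
                f"cell-type group {ct!r} has {len(idx)} samples; "
                "distance check skipped", UserWarning)
            continue
        block = matrix.values[:, idx]
        centre = block.mean(axis=1, keepdims=True)
        d = np.sqrt(((block - centre) ** 2).sum(axis=0))
        mu, sd = d.mean(), d.std(ddof=1)
        dist[idx] = d
        z[idx] = (d - mu) / sd if sd > 0 else 0.0
        if np.isfinite(k):
            flags[idx] = d > mu + k * sd
    return pd.DataFrame({"distance": dist, "distance_z": z,
                         "distance_fail": flags}, index=matrix.sample_ids)


def apply_qc(matrix: BetaMatrix, annotation: pd.DataFrame,
             samples: pd.DataFrame,
             female_window: tuple[float, float] = (0.30, 0.70),
             male_max: float = 0.30,
             n_mads: float = 3.0,
             distance_k: float = 2.0) -> tuple[BetaMatrix, QcReport]:
    """Run all three checks and drop samples failing any of them.

    The order of surviving samples is preserved.  Raises if every sample is
    flagged (an empty matrix is never returned).
    """
    x_res = qc_x_chromosome(matrix, annotation, samples,
                            female_window=female_window, male_max=male_max,
                            n_mads=n_mads)
    cpg_res = qc_cpg_distribution(matrix, n_mads=n_mads)
    dist_res = qc_distance_outlier(matrix, samples, k=distance_k)
    stats = pd.concat([x_res, cpg_res, dist_res], axis=1)
    any_flag = stats[list(FLAG_COLUMNS)].any(axis=1)
    pass_ids = [s for s in matrix.sample_ids if not any_flag[s]]
    report = QcReport(stats=stats, pass_ids=pass_ids)
    for check, count in report.counts().items():
        logger.info("QC %s: %d sample(s) flagged", check, count)
    if not pass_ids:
        raise ValueError("QC flagged every sample; refusing to return an "
                         "empty matrix")
    return matrix.select_samples(pass_ids), report
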