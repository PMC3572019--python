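"""Beta-value <-> discrete methylation-percentage conversion.

Array betas are continuous in [0, 1]; classical assays (bisulfite
conversion counting, sequencing read counts) report discrete methylation
percentages.  The two scales are linked by a fixed monotone step table so the
discriminant system accepts either kind of measurement.  The inverse map
(percentage back to a representative beta) takes the midpoint of each table
cell and interpolates linearly between levels, which is what sequencing-count
import uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix

# (beta lower bound, percentage), descending.  Top level requires beta
# strictly above 0.90; betas strictly below 0.17 map to 0.
CONVERSION_PAIRS: tuple[tuple[float, int], ...] = (
    (0.90, 100),  # strict: beta > 0.90
    (0.90, 90),
    (0.85, 80),
    (0.80, 70),
    (0.75, 60),
    (0.70, 40),
    (0.60, 25),
    (0.55, 20),
    (0.50, 10),
    (0.40, 5),
    (0.30, 2),
    (0.17, 1),
    (0.17, 0),    # strict: beta < 0.17
)

#: half-open interval lower edges and their percentages, ascending
_EDGES = np.array([0.17, 0.30, 0.40, 0.50, 0.55, 0.60, 0.70, 0.75, 0.80,
                   0.85, 0.90])
_LEVELS = np.array([1, 2, 5, 10, 20, 25, 40, 60, 70, 80, 90])

#: representative beta per percentage level: the midpoint of its table cell
#  (100 lives on (0.90, 1.0] -> 0.95; 0 lives on [0, 0.17) -> 0.085; the
#  90 cell is the single point {0.90})
PERCENT_LEVELS = np.array([0, 1, 2, 5, 10, 20, 25, 40, 60, 70, 80, 90, 100])
REPRESENTATIVE_BETA = np.array([0.085, 0.235, 0.35, 0.45, 0.525, 0.575,
                                0.65, 0.725, 0.775, 0.825, 0.875, 0.90,
                                0.95])


def beta_to_percentage(beta) -> int | np.ndarray:
    """Map beta value(s) to the discrete percentage scale.

    Interval semantics: beta > 0.90 -> 100; each listed lower edge v owns the
    half-open cell [v, next edge) (0.90 itself -> 90); beta < 0.17 -> 0.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        bad = arr[np.nonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))][0] \
            if arr.ndim else arr
        raise ValueError(f"beta value {bad} outside [0, 1]")
    idx = np.searchsorted(_EDGES, arr, side="right")  # 0 -> below 0.17
    out = np.where(idx == 0, 0, _LEVELS[np.maximum(idx - 1, 0)])
    out = np.where(arr > 0.90, 100, out)
    if np.ndim(beta) == 0:
        return int(out)
    return out.astype(int)


def percentage_to_beta(percentage) -> float | np.ndarray:
    """Representative beta for percentage value(s), interpolating between
    table-cell midpoints for percentages that fall between listed levels."""
    arr = np.asarray(percentage, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentage outside [0, 100]")
    out = np.interp(arr, PERCENT_LEVELS, REPRESENTATIVE_BETA)
    if np.ndim(percentage) == 0:
        return float(out)
    return out


def convert_matrix(matrix: BetaMatrix) -> pd.DataFrame:
    """Elementwise beta -> percentage on a whole matrix.

    Missing entries stay missing; the result is an integer DataFrame on the
    same probe/sample axes (float with NaN if the input had missing values).
    """
    values = matrix.values
    mask = np.isnan(values)
    filled = np.where(mask, 0.0, values)
    conv = beta_to_percentage(filled).astype(float)
    conv[mask] = np.nan
    frame = pd.DataFrame(conv, index=matrix.probe_ids,
                         columns=matrix.sample_ids)
    if not mask.any():
        frame = frame.astype(int)
    return frame


def counts_to_beta(methylated: int, total: int) -> float:
    """Convert sequencing read counts at a site to the beta scale.

    The observed percentage p = 100 * methylated / total is pushed through
    the inverse conversion curve (cell midpoints, linear interpolation):
    p = 100 -> 0.95, p = 0 -> 0.085.
    """
    if total < 1:
        raise ValueError("total read count must be >= 1")
    if not 0 <= methylated <= total:
        raise ValueError("methylated count must lie in [0, total]")
    return percentage_to_beta(100.0 * methylated / total)
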