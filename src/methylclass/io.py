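"""Domain containers and delimited-text readers/writers.

The central exchange object is :class:`BetaMatrix`, a probes x samples matrix
of methylation beta values (methylated fraction estimates in [0, 1], possibly
missing).  Probe annotations and sample metadata travel as validated pandas
DataFrames; all joins downstream are by probe/sample identifier, never by
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylclass")

#: chromosome tokens accepted in probe annotations
CHROMOSOMES: frozenset[str] = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

CELL_TYPES = ("SC", "iPSC", "ESC")

_CELL_TYPE_ALIASES = {ct.lower(): ct for ct in CELL_TYPES}
_SEX_ALIASES = {"f": "F", "female": "F", "m": "M", "male": "M"}
_STAGE_ALIASES = {"fetal": "fetal", "adult": "adult"}


class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1], NaN = missing.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by probe ID, columns by sample ID.  IDs must be unique;
        every non-missing entry must lie in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        values = data.to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(values) & ((values < 0.0) | (values > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self._data = data.astype(float)
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)

    # -- basic accessors ---------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying probes x samples DataFrame."""
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def probe_ids(self) -> pd.Index:
        return self._data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self._data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def n_missing(self) -> int:
        return int(self._data.isna().to_numpy().sum())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self._data.copy())

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        """Subset to the given probes, in the given order (by ID)."""
        missing = [p for p in probe_ids if p not in self._data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self._data.loc[list(probe_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self._data[list(sample_ids)])

    def features(self) -> pd.DataFrame:
        """Samples x probes view, the orientation classifiers consume."""
        return self._data.T

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


def normalize_chromosome(token: str) -> str:
    """Normalize a chromosome token: strip a 'chr' prefix, upper-case X/Y."""
    tok = str(token).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok.lower() in ("x", "y"):
        tok = tok.upper()
    if tok not in CHROMOSOMES:
        raise ValueError(f"unknown chromosome: {token!r}")
    return tok


def read_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    """Read a probes x samples beta-value table.

    First column holds probe IDs, header row holds sample IDs; empty cells are
    treated as missing.  Non-numeric cells and values outside [0, 1] are
    rejected with the offending row/column named.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = {}
    for col in raw.columns:
        stripped = raw[col].str.strip() if raw[col].dtype == object else raw[col]
        conv = pd.to_numeric(stripped, errors="coerce")
        bad = conv.isna() & stripped.notna() & (stripped != "")
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric value {raw.loc[probe, col]!r} at probe "
                f"{probe!r}, sample {col!r}"
            )
        numeric[col] = conv
    frame = pd.DataFrame(numeric, index=raw.index)
    return BetaMatrix(frame)


def write_beta_matrix(matrix: BetaMatrix, path, delimiter: str = "\t",
                      decimals: int = 6) -> None:
    """Write a beta matrix as delimited text (6 decimals by default)."""
    matrix.data.to_csv(path, sep=delimiter, float_format=f"%.{decimals}f",
                       index_label="probe_id")


def read_annotation(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe annotation table with columns ID, Chr, MapInfo, Symbol.

    Returns a DataFrame indexed by probe ID with columns ``chromosome``
    (normalized token), ``position`` (1-based) and ``symbol``.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    colmap = {c.lower(): c for c in raw.columns}
    for required in ("id", "chr", "mapinfo"):
        if required not in colmap:
            raise ValueError(f"annotation is missing required column: {required!r}")
    ann = pd.DataFrame({
        "chromosome": raw[colmap["chr"]].map(normalize_chromosome),
        "position": pd.to_numeric(raw[colmap["mapinfo"]]).astype(int),
        "symbol": raw[colmap["symbol"]].fillna("") if "symbol" in colmap else "",
    })
    ann.index = pd.Index(raw[colmap["id"]].astype(str).str.strip(), name="probe_id")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID in annotation: {dup!r}")
    if (ann["position"] < 0).any():
        raise ValueError("annotation positions must be non-negative")
    return ann


def write_annotation(annotation: pd.DataFrame, path, delimiter: str = "\t") -> None:
    out = pd.DataFrame({
        "ID": annotation.index,
        "Chr": annotation["chromosome"].to_numpy(),
        "MapInfo": annotation["position"].to_numpy(),
        "Symbol": annotation["symbol"].to_numpy(),
    })
    out.to_csv(path, sep=delimiter, index=False)


def _normalize_token(value, aliases: dict, default: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    key = str(value).strip().lower()
    if key in ("", "na", "nan", "unknown", "none"):
        return default
    if key not in aliases:
        raise ValueError(f"unrecognized token {value!r}")
    return aliases[key]


def read_samples(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample metadata table.

    Required columns: ``sample_id``, ``cell_type`` (SC/iPSC/ESC, any case).
    Optional: ``sex`` (F/M), ``stage`` (fetal/adult), ``batch``, ``platform``;
    missing optional fields default to "unknown" / a single batch/platform.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    for required in ("sample_id", "cell_type"):
        if required not in raw.columns:
            raise ValueError(f"sample table is missing required column: {required!r}")
    table = pd.DataFrame(index=pd.Index(raw["sample_id"].astype(str).str.strip(),
                                        name="sample_id"))
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r}")
    table["cell_type"] = [
        _normalize_token(v, _CELL_TYPE_ALIASES, default="")
        for v in raw["cell_type"]
    ]
    if (table["cell_type"] == "").any():
        missing = table.index[(table["cell_type"] == "").to_numpy()][0]
        raise ValueError(f"cell_type missing for sample {missing!r}")
    table["sex"] = (
        [_normalize_token(v, _SEX_ALIASES, "unknown") for v in raw["sex"]]
        if "sex" in raw.columns else "unknown"
    )
    table["stage"] = (
        [_normalize_token(v, _STAGE_ALIASES, "unknown") for v in raw["stage"]]
        if "stage" in raw.columns else "unknown"
    )
    table["batch"] = (raw["batch"].fillna("batch1").astype(str).to_numpy()
                      if "batch" in raw.columns else "batch1")
    table["platform"] = (raw["platform"].fillna("platform1").astype(str).to_numpy()
                         if "platform" in raw.columns else "platform1")
    return table


def write_samples(samples: pd.DataFrame, path, delimiter: str = "\t") -> None:
    samples.to_csv(path, sep=delimiter, index_label="sample_id")


def impute_missing(matrix: BetaMatrix, max_missing_frac: float = 0.2
                   ) -> tuple[BetaMatrix, int]:
    """Drop probes with > ``max_missing_frac`` missing values, impute the rest.

    Remaining missing entries are replaced by the probe median.  Returns the
    completed matrix and the number of dropped probes (also logged).
    """
    data = matrix.data
    frac = data.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("impute_missing: dropped %d probes with >%d%% missing",
                    n_dropped, int(100 * max_missing_frac))
    data = data.loc[keep]
    if data.empty:
        raise ValueError("all probes dropped by missingness filter")
    medians = data.median(axis=1)
    data = data.T.fillna(medians).T
    return BetaMatrix(data), n_dropped


# ---------------------------------------------------------------------------
# Label schemes: binary comparisons over the sample table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelScheme:
    """A binary comparison defined on the sample table.

    ``mask`` selects the in-scope samples, ``label`` maps each selected row to
    one of exactly two classes.  ``classes[0]`` is the reference class used to
    orient eigengene signs.
    """

    name: str
    classes: tuple[str, str]
    mask_fn: Callable[[pd.DataFrame], pd.Series] = field(repr=False)
    label_fn: Callable[[pd.DataFrame], pd.Series] = field(repr=False)

    def mask(self, samples: pd.DataFrame) -> pd.Series:
        return self.mask_fn(samples).astype(bool)

    def labels(self, samples: pd.DataFrame) -> pd.Series:
        """Class label per in-scope sample (indexed by sample_id)."""
        sub = samples.loc[self.mask(samples)]
        lab = self.label_fn(sub).astype(str)
        got = set(lab.unique())
        if not got <= set(self.classes):
            raise ValueError(f"scheme {self.name}: unexpected labels {got}")
        return lab


SCHEMES: dict[str, LabelScheme] = {
    "SC_vs_PC": LabelScheme(
        name="SC_vs_PC", classes=("SC", "PC"),
        mask_fn=lambda s: s["cell_type"].isin(CELL_TYPES),
        label_fn=lambda s: s["cell_type"].map(
            lambda ct: "SC" if ct == "SC" else "PC"),
    ),
    "ESC_vs_iPSC": LabelScheme(
        name="ESC_vs_iPSC", classes=("ESC", "iPSC"),
        mask_fn=lambda s: s["cell_type"].isin(["ESC", "iPSC"]),
        label_fn=lambda s: s["cell_type"],
    ),
    "F_vs_M_iPSC": LabelScheme(
        name="F_vs_M_iPSC", classes=("F", "M"),
        mask_fn=lambda s: (s["cell_type"] == "iPSC") & s["sex"].isin(["F", "M"]),
        label_fn=lambda s: s["sex"],
    ),
    "fetal_vs_adult_SC": LabelScheme(
        name="fetal_vs_adult_SC", classes=("fetal", "adult"),
        mask_fn=lambda s: (s["cell_type"] == "SC")
        & s["stage"].isin(["fetal", "adult"]),
        label_fn=lambda s: s["stage"],
    ),
}


def get_scheme(name: str) -> LabelScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown label scheme {name!r}; known: {sorted(SCHEMES)}") from None
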