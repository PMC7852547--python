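"""CSV dialect shared by the calibration and main-experiment tables.

Both tables are plain UTF-8 CSV with a ``.`` decimal separator and columns

``strain_id, combination_id, density_cells_ml, count1, count2, count3``

plus ``time_min`` for the main experiment (absent or ignored for noise
calibration) and an optional ``assay_id`` distinguishing replicate assays of
the same strain combination at different starting densities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["count1", "count2", "count3"]
BASE_COLUMNS = ["strain_id", "combination_id", "density_cells_ml", *COUNT_COLUMNS]


def read_observations(path, require_time: bool = False) -> pd.DataFrame:
    """Read a triplicate-count table and append the derived ``cv`` column (percent).

    Parameters
    ----------
    path : str or file-like
        CSV file in the dialect above.
    require_time : bool
        If True, a ``time_min`` column must be present (main-experiment table).

    Raises
    ------
    ValueError
        If a required column is missing; the message names the column.
    """
    df = pd.read_csv(path)
    required = list(BASE_COLUMNS) + (["time_min"] if require_time else [])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    counts = df[COUNT_COLUMNS].to_numpy(float)
    if (counts < 0).any():
        raise ValueError("negative counts are not valid cell densities")
    df = df.copy()
    df["cv"] = triplicate_cv(counts)
    return df


def triplicate_cv(counts: np.ndarray) -> np.ndarray:
    """Row-wise CV (percent, n-1 denominator) of an (n, 3) count array.

    Rows with zero mean get NaN rather than raising; callers decide whether
    such degenerate rows are dropped or are an error.
    """
    counts = np.asarray(counts, float)
    mean = counts.mean(axis=1)
    sd = counts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return cv


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
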