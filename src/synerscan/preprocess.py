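"""Expression preprocessing: log transform, variability filter, row scaling.

The clustering input is prepared the way Cluster 3.0 prepares it: genes
(rows) whose across-sample standard deviation exceeds a threshold are
retained, then each row is centered and scaled to unit sum of squares.
The SD filter uses a strict inequality (``SD > threshold``) and, by
default, the sample (n-1) denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass
class PreprocessParams:
    """Settings for the filtering/normalization stage.

    ``sd_threshold`` defaults to 0.7 log2 units; ``center`` is the row
    statistic subtracted before scaling; ``scale_rows`` divides each row by
    its root sum of squares; ``sd_ddof`` selects the SD denominator
    (1 = sample, 0 = population).
    """

    pseudocount: float = 0.0
    sd_threshold: float = 0.7
    center: str = "mean"
    scale_rows: bool = True
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.sd_threshold < 0:
            raise ValueError("sd_threshold must be >= 0")
        if self.center not in ("mean", "median"):
            raise ValueError("center must be 'mean' or 'median'")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2(value + pseudocount) for a linear-scale matrix."""
    if matrix.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = np.log2(matrix.values.to_numpy() + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        "log2",
    )


def row_sd(matrix: ExpressionMatrix, ddof: int = 1) -> pd.Series:
    """Across-sample standard deviation per gene."""
    if matrix.n_samples < 2:
        raise ValueError("row SD needs >= 2 samples")
    return matrix.values.std(axis=1, ddof=ddof)


def sd_filter(
    matrix: ExpressionMatrix, sd_threshold: float = 0.7, ddof: int = 1
) -> ExpressionMatrix:
    """Keep exactly the rows whose SD strictly exceeds the threshold.

    Operates on log2 values; rows with SD equal to the threshold are
    excluded (the boundary is out).
    """
    if matrix.scale != "log2":
        raise ValueError("sd_filter expects a log2-scale matrix")
    sds = row_sd(matrix, ddof=ddof)
    keep = sds > sd_threshold
    if not keep.any():
        raise ValueError(
            f"no rows pass SD > {sd_threshold}; max row SD is {sds.max():.4g}"
        )
    return ExpressionMatrix(matrix.values.loc[keep].copy(), "log2")


def center_and_normalize(
    matrix: ExpressionMatrix, params: PreprocessParams | None = None
) -> ExpressionMatrix:
    """Center each row, then (optionally) scale it to unit sum of squares.

    Rows that are all zero after centering (constant rows) pass through
    unscaled with a warning — there is no direction to normalize.
    """
    if matrix.scale != "log2":
        raise ValueError("center_and_normalize expects a log2-scale matrix")
    params = params or PreprocessParams()
    values = matrix.values.to_numpy(dtype=float).copy()
    if params.center == "mean":
        centers = values.mean(axis=1)
    else:
        centers = np.median(values, axis=1)
    values -= centers[:, None]
    if params.scale_rows:
        norms = np.sqrt((values**2).sum(axis=1))
        degenerate = norms == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} constant row(s) left unscaled "
                "(zero norm after centering)"
            )
        norms[degenerate] = 1.0
        values /= norms[:, None]
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        "log2",
    )


def preprocess(matrix: ExpressionMatrix, params: PreprocessParams | None = None) -> ExpressionMatrix:
    """Full preparation: log2 if needed, SD filter, center + normalize."""
    params = params or PreprocessParams()
    if matrix.scale == "linear":
        matrix = log2_transform(matrix, params.pseudocount)
    filtered = sd_filter(matrix, params.sd_threshold, ddof=params.sd_ddof)
    return center_and_normalize(filtered, params)
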