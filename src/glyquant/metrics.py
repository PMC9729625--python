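"""Benchmark metrics for replicate quantitation matrices.

A replicate matrix is a pandas DataFrame with quantified entities as rows,
replicate runs as columns and NaN for missing values. PMVL is the proportion
of rows affected by missingness, PMVT the proportion of missing cells;
Pearson correlation is computed on pairwise-complete rows, and the robust
standard deviation of a log2-ratio vector is half the distance between its
84.13th and 15.87th percentiles (equal to the ordinary SD for a normal
distribution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pmvl(m: pd.DataFrame, strict: bool = False) -> float:
    """Proportion of rows with missing values.

    By default a row counts if it has one or more missing cells; with
    ``strict=True`` only rows with two or more missing cells count (the
    alternative literal reading of "more than one").
    """
    if len(m) == 0:
        raise ValueError("replicate matrix has no rows")
    missing_per_row = m.isna().sum(axis=1)
    threshold = 2 if strict else 1
    return float((missing_per_row >= threshold).mean())


def pmvt(m: pd.DataFrame) -> float:
    """Proportion of missing cells among all quantitation cells."""
    if m.size == 0:
        raise ValueError("replicate matrix has no cells")
    return float(m.isna().to_numpy().mean())


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation after pairwise-complete deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("fewer than 2 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def robust_sd(r: np.ndarray) -> float:
    """Half the distance between the 84.13% and 15.87% percentiles of R."""
    r = np.asarray(r, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) < 2:
        raise ValueError("need at least 2 ratios")
    hi, lo = np.percentile(r, [84.13, 15.87])
    return float((hi - lo) / 2.0)
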