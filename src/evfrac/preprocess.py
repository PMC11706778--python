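"""Protein filtering and variance-stabilizing normalization.

Filtering keeps proteins quantified in at least half the donors of at
least one density fraction, so proteins expressed selectively in one or
two fractions survive. Normalization calibrates each sample to a common
scale and applies a generalized-log (glog) transform whose offset is
chosen to flatten the mean-SD trend across proteins; sample medians are
aligned exactly afterwards.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import IntensityMatrix


def filter_proteins(
    m: IntensityMatrix, min_obs_frac: float = 0.5
) -> Tuple[IntensityMatrix, pd.Index]:
    """Keep proteins observed in >= ceil(min_obs_frac * n_donors) donors
    of at least one fraction.

    Returns the filtered matrix and the dropped accessions. Idempotent:
    re-filtering the result drops nothing.
    """
    mask = m.mask
    keep = pd.Series(False, index=m.accessions)
    for fraction in sorted(m.design["fraction"].unique()):
        cols = m.fraction_columns(fraction)
        need = math.ceil(min_obs_frac * len(cols))
        keep |= mask[cols].sum(axis=1) >= need
    dropped = m.accessions[~keep]
    return m.subset(m.accessions[keep]), dropped


def _mean_sd_trend(values: pd.DataFrame) -> float:
    """|Spearman| between per-protein observed mean and SD (0 if undefined)."""
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    ok = means.notna() & sds.notna()
    if ok.sum() < 3 or sds[ok].nunique() == 1 or means[ok].nunique() == 1:
        return 0.0
    rho = spearmanr(means[ok], sds[ok]).statistic
    return float(abs(rho)) if np.isfinite(rho) else 0.0


def _glog2(y: np.ndarray, lam: float) -> np.ndarray:
    """Generalized log2: log2((y + sqrt(y^2 + lam^2)) / 2); identity with
    plain log2 at lam = 0."""
    return np.log2((y + np.sqrt(y * y + lam * lam)) / 2.0)


def vsn_normalize(
    m: IntensityMatrix, trend_tolerance: float = 0.05
) -> IntensityMatrix:
    """Variance-stabilizing normalization of a log2 intensity matrix.

    Per sample: scale the linear-scale intensities to a common median,
    glog-transform with an offset lambda selected (over a quantile grid,
    including 0) to minimize the |Spearman| correlation between
    per-protein mean and SD, then shift so every sample median equals the
    grand median exactly. The transform is strictly monotone within each
    sample and never touches the missingness mask. If the input trend is
    already <= `trend_tolerance`, only calibration and median alignment
    are applied.
    """
    if len(m.samples) < 2:
        raise ValueError("normalization requires at least 2 samples")
    empty = [s for s in m.samples if m.values[s].isna().all()]
    if empty:
        raise ValueError(f"samples with no observed values: {empty}")

    linear = np.power(2.0, m.values)
    sample_medians = linear.median(axis=0, skipna=True)
    target = float(sample_medians.median())
    calibrated = linear * (target / sample_medians)

    input_trend = _mean_sd_trend(m.values)
    lam = 0.0
    if input_trend > trend_tolerance:
        flat = calibrated.to_numpy().ravel()
        flat = flat[np.isfinite(flat)]
        grid = [0.0] + list(np.quantile(flat, [0.05, 0.10, 0.25, 0.50, 0.75]))
        best = input_trend
        for candidate in grid:
            trend = _mean_sd_trend(
                pd.DataFrame(
                    _glog2(calibrated.to_numpy(), candidate),
                    index=m.values.index,
                    columns=m.values.columns,
                )
            )
            if trend < best:
                best, lam = trend, candidate

    out = pd.DataFrame(
        _glog2(calibrated.to_numpy(), lam),
        index=m.values.index,
        columns=m.values.columns,
    )
    med = out.median(axis=0, skipna=True)
    out = out - med + float(med.median())
    return replace(m, values=out, normalized=True)
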