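"""Moderated differential-enrichment testing across fraction groups.

A cell-means model is fitted per protein over the three fraction groups
(F1-3, F4-6, F7-8). Residual variances are shrunk toward a common prior
by empirical Bayes: the prior degrees of freedom d0 and prior variance
s0^2 are estimated by moment-matching of log s^2 against a scaled-F law,

    z_g = log s_g^2,
    E[z_g] = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2),
    Var[z_g] = psi'(d_g/2) + psi'(d0/2),

and each protein's posterior variance is the precision-weighted blend
(d0 s0^2 + d_g s_g^2) / (d0 + d_g). Moderated t statistics divide the
pairwise group contrasts by the posterior standard error with d0 + d_g
degrees of freedom; the moderated F for any group difference is the
one-way statistic with the pooled variance replaced by the posterior
variance (equivalently, the mean squared moderated t over an orthogonal
contrast basis). Multiple testing uses Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .design import GROUPS
from .matrix import IntensityMatrix

#: Pairwise contrasts tested across the three fraction groups.
CONTRASTS = (
    (GROUPS[1], GROUPS[0]),  # F4-6 vs F1-3
    (GROUPS[2], GROUPS[0]),  # F7-8 vs F1-3
    (GROUPS[2], GROUPS[1]),  # F7-8 vs F4-6
)


def contrast_name(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def fit_group_model(
    m: IntensityMatrix,
    groups: Sequence[str] = GROUPS,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-protein cell-means fit over the fraction groups.

    Uses the observed values only, so the same routine serves both the
    imputed matrix (no missing cells) and the unimputed analysis. A
    protein is ``testable`` when every group carries at least
    `min_per_group` observations; untestable proteins keep NaN statistics.

    Returns a DataFrame with per-group means and counts, the pooled
    residual variance ``s2`` and its degrees of freedom ``df``
    (n_observed - n_groups).
    """
    values = m.values.to_numpy(dtype=float)
    out = pd.DataFrame(index=m.accessions)
    rss = np.zeros(len(out))
    n_total = np.zeros(len(out))
    testable = np.ones(len(out), dtype=bool)
    for group in groups:
        cols = [m.values.columns.get_loc(s) for s in m.group_columns(group)]
        block = values[:, cols]
        n = np.sum(~np.isnan(block), axis=1)
        total = np.nansum(block, axis=1)
        mean = np.where(n > 0, total / np.where(n > 0, n, 1), np.nan)
        resid = block - mean[:, None]
        rss += np.nansum(resid * resid, axis=1)
        n_total += n
        testable &= n >= min_per_group
        out[f"mean_{group}"] = mean
        out[f"n_{group}"] = n
    df = n_total - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, rss / np.where(df > 0, df, 1), np.nan)
    out["s2"] = np.where(testable, s2, np.nan)
    out["df"] = np.where(testable, df, 0).astype(int)
    out["testable"] = testable
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x -= step
        x = max(x, 1e-12)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Fits a scaled-F law to the sample variances via the log-variance
    moments; returns ``d0 = inf`` when the observed spread of log s^2 is
    no larger than expected from the chi-square sampling noise alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to fit the prior")
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def ebayes_moderate(
    fit: pd.DataFrame,
    groups: Sequence[str] = GROUPS,
    d0: Optional[float] = None,
    s02: Optional[float] = None,
) -> pd.DataFrame:
    """Add shrunken variances and moderated t/F statistics to a fit.

    `d0` and `s02` override the moment-matched prior when given (d0 = 0
    reproduces ordinary statistics; d0 = inf forces every posterior
    variance to s0^2).
    """
    fit = fit.copy()
    testable = fit["testable"].to_numpy()
    s2 = fit["s2"].to_numpy(dtype=float)
    df = fit["df"].to_numpy(dtype=float)

    if d0 is None or s02 is None:
        est_d0, est_s02 = estimate_prior(s2[testable], df[testable])
        d0 = est_d0 if d0 is None else d0
        s02 = est_s02 if s02 is None else s02

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df.copy()
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    s2_post = np.where(testable, s2_post, np.nan)
    fit["d0"] = d0
    fit["s02"] = s02
    fit["s2_post"] = s2_post
    fit["df_total"] = np.where(testable, df_total, np.nan)

    df_eval = np.where(np.isinf(df_total), 1e9, df_total)

    for a, b in CONTRASTS:
        diff = fit[f"mean_{a}"] - fit[f"mean_{b}"]
        na = fit[f"n_{a}"].to_numpy(dtype=float)
        nb = fit[f"n_{b}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
            t = diff.to_numpy() / se
        p = 2.0 * sps.t.sf(np.abs(t), df_eval)
        name = contrast_name(a, b)
        fit[f"logFC_{name}"] = diff
        fit[f"t_{name}"] = np.where(testable, t, np.nan)
        fit[f"p_t_{name}"] = np.where(testable, p, np.nan)

    # moderated F: one-way statistic with the posterior variance
    k = len(groups)
    n_mat = fit[[f"n_{g}" for g in groups]].to_numpy(dtype=float)
    mean_mat = fit[[f"mean_{g}" for g in groups]].to_numpy(dtype=float)
    n_sum = n_mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(n_mat * mean_mat, axis=1) / n_sum
        between = np.nansum(n_mat * (mean_mat - grand[:, None]) ** 2, axis=1)
        f_stat = between / ((k - 1) * s2_post)
    p_f = sps.f.sf(f_stat, k - 1, df_eval)
    fit["F"] = np.where(testable, f_stat, np.nan)
    fit["p_F"] = np.where(testable, p_f, np.nan)
    return fit


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate untouched."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    if ok.sum():
        adjusted[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adjusted


def run_contrasts(
    m: IntensityMatrix,
    alpha: float = 0.05,
    min_per_group: int = 2,
    d0: Optional[float] = None,
    s02: Optional[float] = None,
) -> pd.DataFrame:
    """Full moderated pipeline: fit, shrink, BH-adjust, flag significance.

    Significance is judged on the BH-adjusted moderated-F p-value at
    `alpha`, with no fold-change cutoff.
    """
    fit = fit_group_model(m, min_per_group=min_per_group)
    fit = ebayes_moderate(fit, d0=d0, s02=s02)
    fit["adj_p_F"] = bh_adjust(fit["p_F"].to_numpy())
    fit["significant"] = fit["adj_p_F"] < alpha
    fit.loc[fit["adj_p_F"].isna(), "significant"] = False
    return fit
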