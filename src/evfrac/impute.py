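"""Hybrid MNAR/MAR classification and imputation of missing intensities.

Each missing cell is classified by where its protein sits within the
density fraction the cell belongs to: a protein with no observed value in
that fraction, or whose mean observed intensity there falls below the
fraction's log2 cutoff, is treated as censored (missing not at random,
MNAR); otherwise the cell is treated as a sporadic dropout (missing at
random, MAR). MNAR cells are filled by left-shifted Gaussian draws from
the tail of the sample's observed distribution; MAR cells by k-nearest-
neighbour averaging over protein rows.

The per-fraction cutoffs determined for the real study are the module
defaults; a single global cutoff (e.g. the simulation-derived 12) can be
built with :meth:`CutoffSet.uniform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .matrix import IntensityMatrix

#: Missingness labels assigned by the classifier.
MNAR = "MNAR"
MAR = "MAR"

#: Manually determined per-fraction log2 intensity cutoffs for the real
#: density-fractionated study (fraction -> cutoff).
DEFAULT_FRACTION_CUTOFFS: Dict[int, float] = {
    1: 14.9,
    2: 14.7,
    3: 14.9,
    4: 14.3,
    5: 14.6,
    6: 14.5,
    7: 15.3,
    8: 15.2,
}


@dataclass(frozen=True)
class CutoffSet:
    """Per-fraction log2-intensity MNAR cutoffs.

    Classification compares a protein's mean observed intensity *within a
    fraction* against that fraction's cutoff.
    """

    cutoffs: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_CUTOFFS)
    )

    def __post_init__(self) -> None:
        for fraction, value in self.cutoffs.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite cutoff for fraction {fraction}")

    @classmethod
    def uniform(cls, value: float, fractions: Iterable[int] = range(1, 9)) -> "CutoffSet":
        return cls(cutoffs={f: float(value) for f in fractions})

    def __getitem__(self, fraction: int) -> float:
        try:
            return self.cutoffs[fraction]
        except KeyError:
            raise KeyError(f"no MNAR cutoff defined for fraction {fraction}") from None


def classify_missingness(m: IntensityMatrix, cutoffs: CutoffSet) -> pd.DataFrame:
    """Label every missing cell MNAR or MAR.

    For each protein x fraction with at least one missing cell: if the
    protein has no observed value in that fraction, all its missing cells
    there are MNAR with basis ``absent-in-fraction``; otherwise the mean
    observed intensity within the fraction decides — below the fraction
    cutoff is MNAR, at or above is MAR.

    Returns a DataFrame with one row per missing cell: protein, sample,
    fraction, label, basis (the fraction mean, NaN when absent).
    """
    values = m.values
    records = []
    for fraction in sorted(m.design["fraction"].unique()):
        cutoff = cutoffs[fraction]
        cols = m.fraction_columns(fraction)
        block = values[cols]
        missing = block.isna()
        any_missing = missing.any(axis=1)
        if not any_missing.any():
            continue
        frac_mean = block.mean(axis=1, skipna=True)
        for protein in block.index[any_missing]:
            mean = frac_mean.loc[protein]
            if np.isnan(mean):
                label, basis = MNAR, np.nan
            elif mean < cutoff:
                label, basis = MNAR, float(mean)
            else:
                label, basis = MAR, float(mean)
            for sample in block.columns[missing.loc[protein]]:
                records.append(
                    {
                        "protein": protein,
                        "sample": sample,
                        "fraction": fraction,
                        "label": label,
                        "basis": basis,
                    }
                )
    return pd.DataFrame(
        records, columns=["protein", "sample", "fraction", "label", "basis"]
    )


def impute_mnar(
    m: IntensityMatrix,
    classification: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    seed: Optional[int] = None,
) -> IntensityMatrix:
    """Fill MNAR cells with draws from the sample's low-intensity tail.

    Each MNAR cell in sample ``s`` is drawn from
    ``N(mu_s - shift * sigma_s, (width * sigma_s)^2)`` where ``mu_s`` and
    ``sigma_s`` are the mean and SD of the observed values of that sample.
    Observed cells are untouched; deterministic given `seed`.
    """
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    mnar = classification[classification["label"] == MNAR]
    for sample, cells in mnar.groupby("sample", sort=True):
        observed = m.values[sample].dropna()
        if len(observed) < 3:
            raise ValueError(
                f"sample {sample} has {len(observed)} observed values; "
                "need >= 3 to estimate the censoring tail"
            )
        mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(mu - shift * sigma, width * sigma, size=len(cells))
        out.loc[cells["protein"].to_numpy(), sample] = draws
    return replace(m, values=out)


def impute_mar(
    m: IntensityMatrix,
    classification: pd.DataFrame,
    k: int = 10,
) -> Tuple[IntensityMatrix, pd.DataFrame]:
    """Fill MAR cells by averaging the k nearest protein rows.

    Neighbour distance is Euclidean over jointly observed samples
    (nan-aware); for each MAR cell the imputed value is the mean of the
    same cell position across the k nearest rows that carry a value
    there. Rows with no eligible neighbour fall back to the protein's
    within-fraction-group mean; the returned report lists those cells.
    """
    mar = classification[classification["label"] == MAR]
    if mar.empty:
        return replace(m, values=m.values.copy()), pd.DataFrame(
            columns=["protein", "sample", "fallback"]
        )

    values = m.values.to_numpy()
    index = m.values.index
    col_of = {s: i for i, s in enumerate(m.values.columns)}
    row_of = {p: i for i, p in enumerate(index)}
    group_cols = {
        g: [col_of[s] for s in m.group_columns(g)]
        for g in m.design["group"].unique()
    }
    group_of_sample = dict(zip(m.design["sample"], m.design["group"]))

    need_rows = np.array(sorted({row_of[p] for p in mar["protein"]}))
    # distances from rows needing imputation to all rows, nan-aware
    dist = nan_euclidean_distances(values[need_rows], values)
    dist[np.arange(len(need_rows)), need_rows] = np.inf  # exclude self
    order = np.argsort(dist, axis=1)
    pos_of_need = {r: i for i, r in enumerate(need_rows)}

    out = values.copy()
    fallbacks = []
    for cells_protein, cells in mar.groupby("protein", sort=False):
        row = row_of[cells_protein]
        ranked = order[pos_of_need[row]]
        ranked = ranked[np.isfinite(dist[pos_of_need[row]][ranked])]
        for _, cell in cells.iterrows():
            col = col_of[cell["sample"]]
            donors = ranked[~np.isnan(values[ranked, col])][:k]
            if donors.size:
                out[row, col] = float(np.mean(values[donors, col]))
            else:
                cols = group_cols[group_of_sample[cell["sample"]]]
                out[row, col] = float(np.nanmean(values[row, cols]))
                fallbacks.append(
                    {
                        "protein": cells_protein,
                        "sample": cell["sample"],
                        "fallback": "fraction-group mean",
                    }
                )
    frame = pd.DataFrame(out, index=index, columns=m.values.columns)
    report = pd.DataFrame(fallbacks, columns=["protein", "sample", "fallback"])
    return replace(m, values=frame), report


def hybrid_impute(
    m: IntensityMatrix,
    cutoffs: Optional[CutoffSet] = None,
    shift: float = 1.8,
    width: float = 0.3,
    k: int = 10,
    seed: Optional[int] = None,
) -> Tuple[IntensityMatrix, pd.DataFrame, dict]:
    """Classify missing cells and impute MNAR then MAR.

    Returns the fully imputed matrix (no missing cells), the per-cell
    classification, and a JSON-ready report with label counts per
    fraction, fallback count and the seed used.
    """
    cutoffs = cutoffs or CutoffSet()
    classification = classify_missingness(m, cutoffs)
    step1 = impute_mnar(m, classification, shift=shift, width=width, seed=seed)
    imputed, fallback_report = impute_mar(step1, classification, k=k)

    counts: Dict[str, Dict[str, int]] = {}
    if not classification.empty:
        tally = (
            classification.groupby(["fraction", "label"]).size().unstack(fill_value=0)
        )
        counts = {
            str(f): {lab: int(n) for lab, n in row.items()}
            for f, row in tally.iterrows()
        }
    report = {
        "n_missing": int(len(classification)),
        "n_mnar": int((classification["label"] == MNAR).sum()) if len(classification) else 0,
        "n_mar": int((classification["label"] == MAR).sum()) if len(classification) else 0,
        "cells_per_fraction": counts,
        "n_mar_fallback": int(len(fallback_report)),
        "seed": seed,
    }
    return imputed, classification, report
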