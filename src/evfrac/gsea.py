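"""Single-sample gene-set enrichment (ssGSEA) and gene-set filtering.

The ssGSEA score of a set in a sample is the running difference between
the rank-weighted empirical CDF of the in-set genes and the unweighted
ECDF of the out-of-set genes, summed over the gene list ordered by
decreasing expression; ranks enter with exponent alpha (default 0.25).
Scores depend on within-sample ranks only, so any monotone per-sample
transform of the expression leaves them unchanged.

Set collections are filtered before scoring: 5-50 detected members, no
directionality-modifier names, and no pair of surviving sets with an
overlap coefficient above 0.25.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt
from scipy.stats import rankdata

from .matrix import IntensityMatrix
from .stats import run_contrasts

#: Name fragments marking directional gene sets, matched case-insensitively.
DEFAULT_DIRECTIONAL_PATTERNS = (
    "upregulation of",
    "downregulation of",
    "up-regulation of",
    "down-regulation of",
    "positive regulation of",
    "negative regulation of",
)


@dataclass
class GeneSetCollection:
    """Named gene/protein sets, e.g. read from a GMT file."""

    sets: Dict[str, List[str]]
    source: Optional[str] = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate ids")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated gene ids)."""
    sets = {name: list(dict.fromkeys(genes)) for name, genes in _gseapy_read_gmt(str(path)).items()}
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            fh.write("\t".join([name, "na", *members]) + "\n")


def overlap_coefficient(a: Iterable[str], b: Iterable[str]) -> float:
    """|A n B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def filter_gene_sets(
    sets: GeneSetCollection,
    detected_ids: Iterable[str],
    min_size: int = 5,
    max_size: int = 50,
    max_overlap: float = 0.25,
    name_patterns: Sequence[str] = DEFAULT_DIRECTIONAL_PATTERNS,
    scores: Optional[Mapping[str, float]] = None,
) -> GeneSetCollection:
    """Apply the detection-size, directionality and overlap filters.

    Sets are restricted to detected ids and kept only with `min_size` to
    `max_size` surviving members; sets whose names contain a directional
    modifier are dropped; among pairs with overlap coefficient above
    `max_overlap`, the greedy pass keeps the higher-priority set.
    Priority is the ascending `scores` value when given (e.g. a
    moderated-F p-value per set), otherwise larger detected size, with
    set name as the final tie-break.
    """
    detected = set(detected_ids)
    patterns = [re.compile(re.escape(p), re.IGNORECASE) for p in name_patterns]

    trimmed: Dict[str, List[str]] = {}
    for name, members in sets:
        if any(p.search(name) for p in patterns):
            continue
        present = [g for g in members if g in detected]
        if min_size <= len(present) <= max_size:
            trimmed[name] = present

    if scores is not None:
        order = sorted(trimmed, key=lambda n: (scores.get(n, np.inf), n))
    else:
        order = sorted(trimmed, key=lambda n: (-len(trimmed[n]), n))

    kept: Dict[str, List[str]] = {}
    for name in order:
        if all(
            overlap_coefficient(trimmed[name], members) <= max_overlap
            for members in kept.values()
        ):
            kept[name] = trimmed[name]
    # restore the collection's original ordering among survivors
    ordered = {name: trimmed[name] for name, _ in sets if name in kept}
    return GeneSetCollection(sets=ordered, source=sets.source)


def ssgsea_scores(
    m: IntensityMatrix | pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA enrichment scores, gene sets x samples.

    Per sample, genes are ordered by decreasing expression and the score
    accumulates (weighted in-set ECDF - out-set ECDF) along that order,
    with in-set weights |rank|^alpha. With `normalize`, all scores are
    divided by (max - min) over the whole matrix.
    """
    expr = m.values if isinstance(m, IntensityMatrix) else m
    genes = expr.index
    scores = pd.DataFrame(index=list(sets.sets), columns=expr.columns, dtype=float)

    membership = {}
    for name, members in sets:
        in_set = genes.isin(members)
        if not in_set.any():
            raise ValueError(f"gene set {name!r} has no members in the matrix")
        membership[name] = in_set

    n = len(genes)
    for sample in expr.columns:
        x = expr[sample].to_numpy(dtype=float)
        ranks = rankdata(x)  # 1 = lowest expression
        order = np.argsort(-x, kind="stable")
        weights = np.abs(ranks[order]) ** alpha
        for name, in_set in membership.items():
            tags = in_set[order]
            n_in = int(tags.sum())
            if n_in == n:
                raise ValueError(f"gene set {name!r} covers every gene in the matrix")
            p_in = np.cumsum(np.where(tags, weights, 0.0))
            p_in /= p_in[-1]
            p_out = np.cumsum(~tags) / (n - n_in)
            scores.loc[name, sample] = float(np.sum(p_in - p_out))

    if normalize:
        spread = float(scores.to_numpy().max() - scores.to_numpy().min())
        if spread > 0:
            scores /= spread
    return scores


def scale_rows(scores: pd.DataFrame) -> pd.DataFrame:
    """Row z-scaling for display: each row to mean 0, SD 1."""
    centered = scores.sub(scores.mean(axis=1), axis=0)
    sd = scores.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant enrichment row cannot be z-scaled")
    return centered.div(sd, axis=0)


def run_ssgsea_contrasts(
    scores: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 5e-4,
) -> pd.DataFrame:
    """Moderated testing of enrichment scores across fraction groups.

    The score matrix is pushed through the same moderated-F pipeline as
    the protein intensities, at the stricter default threshold used for
    gene sets (adjusted p < 5e-4).
    """
    m = IntensityMatrix(values=scores, design=design)
    return run_contrasts(m, alpha=alpha)
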