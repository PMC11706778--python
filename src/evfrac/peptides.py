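"""Tau peptide coverage track: N-to-C ordering, near-duplicate merging,
intensity summation and region annotation.

Peptide coordinates are 1-based inclusive residue spans on the longest
(2N4R, 441-residue) tau isoform. Peptides sharing most of their span —
missed-cleavage extensions and modified forms — are merged into one group
when neither is more than 50% unique from its sorted neighbour; group
intensities are summed on the linear scale and reported on log2.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

TAU_2N4R_LENGTH = 441

#: Printed landmark regions of 2N4R tau (name, start, end).
DEFAULT_REGIONS: Tuple[Tuple[str, int, int], ...] = (
    ("extreme N terminus", 6, 23),
    ("Tau13 epitope", 2, 18),
    ("HT7 epitope", 159, 163),
    ("repeat region", 242, 370),
    ("TauC epitope", 242, 411),
)


def _validate_span(start: int, end: int, protein_length: int = TAU_2N4R_LENGTH) -> None:
    if not (1 <= start <= end <= protein_length):
        raise ValueError(
            f"span [{start}, {end}] outside protein of length {protein_length}"
        )


def uniqueness(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """Fraction of b's residues not covered by a (directional)."""
    _validate_span(*a)
    _validate_span(*b)
    overlap = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    length_b = b[1] - b[0] + 1
    return (length_b - overlap) / length_b


def pair_uniqueness(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """Symmetric uniqueness: the minimum of the two directions."""
    return min(uniqueness(a, b), uniqueness(b, a))


def merge_near_duplicates(
    peptides: pd.DataFrame,
    threshold: float = 0.5,
    protein_length: int = TAU_2N4R_LENGTH,
) -> pd.DataFrame:
    """Merge near-duplicate peptides into ordered coverage groups.

    `peptides` needs columns ``start`` and ``end`` plus per-sample log2
    intensity columns; any other columns are ignored. Peptides are sorted
    N to C (by start, ties by end) and walked in order: a peptide joins
    the open group when its symmetric uniqueness against the group's
    anchor (first, most N-terminal member) is at or below `threshold`;
    otherwise it opens a new group and becomes its anchor. Group
    intensity is the sum of the members' linear-scale intensities,
    reported on log2; missing member intensities contribute nothing.

    Returns one row per group: group, start (min), end (max),
    n_peptides, members (list of row labels), then the sample columns.
    """
    meta_cols = {"start", "end", "accession", "modified", "missed_cleavage"}
    sample_cols = [c for c in peptides.columns if c not in meta_cols]
    table = peptides.sort_values(["start", "end"], kind="stable")
    for start, end in zip(table["start"], table["end"]):
        _validate_span(int(start), int(end), protein_length)

    group_ids: List[int] = []
    current = 0
    anchor = None
    for start, end in zip(table["start"], table["end"]):
        span = (int(start), int(end))
        if anchor is None:
            anchor = span
        elif pair_uniqueness(anchor, span) > threshold:
            current += 1
            anchor = span
        group_ids.append(current)
    table = table.assign(_group=group_ids)

    records = []
    for gid, block in table.groupby("_group", sort=True):
        linear = np.power(2.0, block[sample_cols].to_numpy(dtype=float))
        summed = np.nansum(linear, axis=0)
        record = {
            "group": int(gid),
            "start": int(block["start"].min()),
            "end": int(block["end"].max()),
            "n_peptides": int(len(block)),
            "members": list(block.index),
        }
        record.update(dict(zip(sample_cols, np.log2(summed))))
        records.append(record)
    return pd.DataFrame(records)


def annotate_regions(
    track: pd.DataFrame,
    regions: Sequence[Tuple[str, int, int]] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Label each peptide group with every overlapping landmark region."""
    track = track.copy()
    labels = []
    for start, end in zip(track["start"], track["end"]):
        hits = [
            name
            for name, r_start, r_end in regions
            if start <= r_end and end >= r_start
        ]
        labels.append(hits)
    track["regions"] = labels
    return track


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide TSV (accession, start, end, flags, sample columns)."""
    table = pd.read_csv(path, sep="\t")
    for col in ("start", "end"):
        if col not in table.columns:
            raise ValueError(f"peptide table lacks column {col!r}")
        table[col] = table[col].astype(int)
    return table
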