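"""Log2 LFQ intensity matrices with an explicit missingness mask.

The central container is :class:`IntensityMatrix`: a proteins (or peptides)
x samples table of log2 label-free quantification intensities, where NaN
marks a missing cell, together with the sample design. Zero intensities in
raw exports are read as missing (DIA search software writes both ``0`` and
empty cells for non-quantified precursors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class IntensityMatrix:
    """Proteins/peptides x samples log2 intensities plus design metadata.

    Attributes
    ----------
    values
        DataFrame indexed by accession with one column per sample; NaN
        encodes a missing cell.
    design
        Sample design table (columns ``sample``, ``donor``, ``fraction``,
        ``group``); every column of `values` must appear in it.
    normalized
        Whether variance-stabilizing normalization has been applied.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        design_samples = list(self.design["sample"])
        matrix_samples = list(self.values.columns)
        extra = set(matrix_samples) - set(design_samples)
        if extra:
            raise ValueError(f"samples absent from design: {sorted(extra)}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate accessions: {list(dupes[:5])}")
        # keep design restricted and ordered to the matrix columns
        if design_samples != matrix_samples:
            design = self.design.set_index("sample").loc[matrix_samples].reset_index()
            object.__setattr__(self, "design", design)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a value is observed."""
        return self.values.notna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return replace(self, values=self.values.copy(), design=self.design.copy())

    def subset(self, accessions) -> "IntensityMatrix":
        return replace(self, values=self.values.loc[accessions].copy())

    def group_columns(self, group: str) -> list[str]:
        return list(self.design.loc[self.design["group"] == group, "sample"])

    def fraction_columns(self, fraction: int) -> list[str]:
        return list(self.design.loc[self.design["fraction"] == fraction, "sample"])


def read_lfq_table(path, design: pd.DataFrame, raw: bool = False) -> IntensityMatrix:
    """Read a TSV intensity table (first column = accession).

    Zero and empty cells become missing. With ``raw=True`` the values are
    log2-transformed after zero-masking. Sample columns must match the
    design; offenders are named in the error.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[1] == 0:
        raise ValueError(f"no sample columns found in {path}")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique()
        raise ValueError(f"duplicate accessions in {path}: {list(dupes[:5])}")
    unknown = set(table.columns) - set(design["sample"])
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    values = table.astype(float)
    values = values.where(values != 0.0)
    if raw:
        values = np.log2(values)
    return IntensityMatrix(values=values, design=design)


def write_lfq_table(m: IntensityMatrix, path) -> None:
    """Write the matrix as TSV; missing cells become empty fields."""
    out = m.values.copy()
    out.index.name = out.index.name or "accession"
    out.to_csv(path, sep="\t", na_rep="")
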