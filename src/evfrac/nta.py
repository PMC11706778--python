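"""Nanoparticle tracking analysis (NTA) post-processing.

Instrument exports give per-size-bin particle concentrations on a 5-nm
grid for each technical replicate, measured after dilution. The pipeline
multiplies concentrations back up by the dilution factor, optionally
scales to particles per mg of source tissue, aggregates replicates (mean
for per-mg concentration figures, sum of counts for mode estimation) and
summarizes the size distribution by its mode, percentile diameters
(D10/D50/D90) and the mass fraction above a diameter threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BIN_WIDTH_NM = 5.0


@dataclass
class SizeDistribution:
    """Binned particle concentration vs diameter for one measurement."""

    bin_centers_nm: np.ndarray
    concentration: np.ndarray
    dilution: Optional[float] = None
    tissue_mg: Optional[float] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        self.bin_centers_nm = np.asarray(self.bin_centers_nm, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.bin_centers_nm.shape != self.concentration.shape:
            raise ValueError("bin grid and concentrations differ in length")
        diffs = np.diff(self.bin_centers_nm)
        if len(diffs) and not np.allclose(diffs, BIN_WIDTH_NM):
            raise ValueError("bins must be strictly increasing on a 5-nm grid")
        if np.any(self.concentration < 0):
            raise ValueError("negative concentrations")
        if self.dilution is not None and self.dilution <= 0:
            raise ValueError(f"dilution must be positive, got {self.dilution}")

    @property
    def total(self) -> float:
        return float(self.concentration.sum())


def read_nta_csv(path) -> list[SizeDistribution]:
    """Read a tidy NTA export (bin_center_nm, concentration, replicate,
    dilution) into one SizeDistribution per replicate."""
    table = pd.read_csv(path)
    required = {"bin_center_nm", "concentration", "replicate", "dilution"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"NTA export lacks columns: {sorted(missing)}")
    out = []
    for rep, block in table.groupby("replicate", sort=True):
        block = block.sort_values("bin_center_nm")
        dilution = block["dilution"].unique()
        if len(dilution) != 1:
            raise ValueError(f"replicate {rep} has mixed dilution factors")
        out.append(
            SizeDistribution(
                bin_centers_nm=block["bin_center_nm"].to_numpy(),
                concentration=block["concentration"].to_numpy(),
                dilution=float(dilution[0]),
                replicate=int(rep),
            )
        )
    return out


def normalize_dilution(d: SizeDistribution) -> SizeDistribution:
    """Multiply each bin by the dilution factor; clears the metadata."""
    if d.dilution is None:
        return replace(d)
    return replace(d, concentration=d.concentration * d.dilution, dilution=None)


def scale_per_mg(d: SizeDistribution, tissue_mg: float) -> SizeDistribution:
    """Scale to particles per ml per mg of source tissue."""
    if tissue_mg <= 0:
        raise ValueError(f"tissue mass must be positive, got {tissue_mg}")
    return replace(d, concentration=d.concentration / tissue_mg, tissue_mg=tissue_mg)


def aggregate_replicates(
    ds: Sequence[SizeDistribution], method: str = "mean"
) -> SizeDistribution:
    """Element-wise mean (concentration figures) or sum (mode estimation)
    of technical replicates on identical bin grids."""
    if not ds:
        raise ValueError("no replicates to aggregate")
    grid = ds[0].bin_centers_nm
    for d in ds[1:]:
        if not np.array_equal(d.bin_centers_nm, grid):
            raise ValueError("replicates have different bin grids")
    stack = np.vstack([d.concentration for d in ds])
    if method == "mean":
        agg = stack.mean(axis=0)
    elif method == "sum":
        agg = stack.sum(axis=0)
    else:
        raise ValueError(f"method must be 'mean' or 'sum', got {method!r}")
    return SizeDistribution(
        bin_centers_nm=grid.copy(),
        concentration=agg,
        dilution=ds[0].dilution,
        tissue_mg=ds[0].tissue_mg,
    )


def mode_diameter(d: SizeDistribution) -> float:
    """Bin center of the maximum; ties break toward the smaller diameter."""
    if d.total == 0:
        raise ValueError("empty distribution has no mode")
    return float(d.bin_centers_nm[int(np.argmax(d.concentration))])


def percentile_diameters(d: SizeDistribution, q: Sequence[float]) -> np.ndarray:
    """Diameters below which the given percentages of particles fall.

    Bin mass is treated as uniform within each 5-nm bin and the cumulative
    distribution is linearly interpolated inside the crossing bin, so D10
    of a uniform distribution on [0, 100] nm is exactly 10 nm.
    """
    total = d.total
    if total == 0:
        raise ValueError("empty distribution has no percentiles")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 100)):
        raise ValueError("percentiles must be in [0, 100]")
    lo_edges = d.bin_centers_nm - BIN_WIDTH_NM / 2.0
    cum = np.concatenate([[0.0], np.cumsum(d.concentration)]) / total
    out = np.empty_like(q)
    for i, frac in enumerate(q / 100.0):
        j = int(np.searchsorted(cum, frac, side="left"))
        j = min(max(j, 1), len(cum) - 1)
        mass = cum[j] - cum[j - 1]
        if mass == 0:
            out[i] = lo_edges[j - 1]
        else:
            out[i] = lo_edges[j - 1] + (frac - cum[j - 1]) / mass * BIN_WIDTH_NM
    return out


def size_band_fraction(d: SizeDistribution, threshold_nm: float) -> float:
    """Percentage of particle mass at diameters above `threshold_nm`.

    Uses the same uniform-within-bin convention as the percentiles.
    """
    total = d.total
    if total == 0:
        raise ValueError("empty distribution")
    lo_edges = d.bin_centers_nm - BIN_WIDTH_NM / 2.0
    hi_edges = d.bin_centers_nm + BIN_WIDTH_NM / 2.0
    covered = np.clip((hi_edges - threshold_nm) / BIN_WIDTH_NM, 0.0, 1.0)
    return float(100.0 * np.sum(d.concentration * covered) / total)
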