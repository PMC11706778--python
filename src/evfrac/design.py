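"""Sample design for the density-gradient fractionation layout.

Samples are donor x fraction combinations named ``<donor>_F<fraction>``.
Fractions 1 (lightest) through 8 (densest) are analysed in three groups:
F1-3, F4-6 and F7-8.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

#: Fraction-group labels, a deterministic function of the fraction number.
GROUP_F13 = "F1-3"
GROUP_F46 = "F4-6"
GROUP_F78 = "F7-8"
GROUPS = (GROUP_F13, GROUP_F46, GROUP_F78)

DEFAULT_DONORS = ("A", "B", "C", "D", "E", "F", "G", "H")
#: Donors retained in fraction 8 (three donors yielded too little dense
#: material and their fraction-8 samples are excluded from the design).
DEFAULT_FRACTION8_DONORS = ("B", "C", "D", "G", "H")


def fraction_group(fraction: int) -> str:
    """Map a fraction number (1-8) to its analysis group."""
    if 1 <= fraction <= 3:
        return GROUP_F13
    if 4 <= fraction <= 6:
        return GROUP_F46
    if 7 <= fraction <= 8:
        return GROUP_F78
    raise ValueError(f"fraction must be in 1..8, got {fraction}")


def sample_name(donor: str, fraction: int) -> str:
    return f"{donor}_F{fraction}"


def make_design(
    donors: Sequence[str] = DEFAULT_DONORS,
    fractions: Iterable[int] = range(1, 9),
    fraction8_donors: Sequence[str] = DEFAULT_FRACTION8_DONORS,
) -> pd.DataFrame:
    """Build the full study design table.

    Returns a DataFrame with columns ``sample``, ``donor``, ``fraction``
    and ``group``, ordered by fraction then donor. Fraction 8 is restricted
    to `fraction8_donors`.
    """
    rows = []
    for fraction in fractions:
        frac_donors = fraction8_donors if fraction == 8 else donors
        for donor in frac_donors:
            rows.append(
                {
                    "sample": sample_name(donor, fraction),
                    "donor": donor,
                    "fraction": fraction,
                    "group": fraction_group(fraction),
                }
            )
    return pd.DataFrame(rows)


def read_design(path) -> pd.DataFrame:
    """Read a design CSV with columns sample,donor,fraction (group derived)."""
    design = pd.read_csv(path)
    required = {"sample", "donor", "fraction"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design file lacks columns: {sorted(missing)}")
    design["fraction"] = design["fraction"].astype(int)
    design["group"] = design["fraction"].map(fraction_group)
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design[["sample", "donor", "fraction"]].to_csv(path, index=False)
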