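"""Synthetic density-fractionation studies with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a log2 LFQ intensity matrix over 8 donors x 8 density fractions
(fraction 8 restricted to 5 donors), per-protein means and standard
deviations drawn from study-scale hyperparameters, a subset of proteins
differentially enriched in one of the three fraction groups, and two
missingness mechanisms — intensity-dependent censoring (MNAR) and uniform
dropout (MAR) — with per-cell ground-truth labels.

MNAR cells are censored independently with a logistic probability in
intensity that saturates at 1 deep in the low tail (expected censored
fraction matched to the configured rate); MAR cells are an exact-count
uniform sample from the remainder. Everything is deterministic given
``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import GROUPS, make_design
from .matrix import IntensityMatrix

#: Truth codes for per-cell missingness bookkeeping.
OBSERVED = "observed"
MNAR = "MNAR"
MAR = "MAR"


@dataclass
class SimulationConfig:
    """Parameters of a synthetic fractionation study.

    The defaults reproduce the study-scale simulation used to design and
    benchmark the hybrid imputation strategy: 6,105 proteins across 61
    samples (8 donors x fractions 1-7, 5 donors x fraction 8) with 3,000
    differentially enriched proteins and mixed MNAR/MAR missingness whose
    censoring regime ends near log2 intensity 12.
    """

    n_proteins: int = 6105
    n_donors: int = 8
    fractions: Sequence[int] = tuple(range(1, 9))
    n_donors_fraction8: int = 5
    n_dep: int = 3000
    #: DEP log2 shifts are |N(mean, sd)| with a random sign, applied to the
    #: samples of one randomly chosen fraction group. Density fractions
    #: enrich organelle- and vesicle-selective proteins strongly, so the
    #: default effects are large (median ~3.5 log2 units).
    dep_effect_mean: float = 3.5
    dep_effect_sd: float = 1.0
    #: Hyperparameters of the per-protein moments (log2 units): protein
    #: means ~ N(mean_of_means, sd_of_means), protein SDs ~ N(sd_mean,
    #: sd_sd) truncated below at 0.05. The small within-protein SD
    #: relative to the between-protein spread makes intensity censoring
    #: near block-wise per protein, as in fraction-selective expression.
    mean_of_means: float = 10.6
    sd_of_means: float = 2.2
    sd_mean: float = 0.2
    sd_sd: float = 0.05
    #: Alternatively, copy per-protein (mean, SD) pairs from an empirical
    #: log2 matrix by resampling its rows.
    empirical_matrix: Optional[pd.DataFrame] = None
    #: Fractions of all cells made missing by each mechanism.
    mnar_rate: float = 0.15
    mar_rate: float = 0.012
    #: Intensity quantile of the complete matrix anchoring the logistic
    #: censoring curve, and its steepness (log2 units).
    mnar_censor_quantile: float = 0.17
    mnar_steepness: float = 0.10
    seed: int = 2023

    def validate(self) -> None:
        if self.n_dep > self.n_proteins:
            raise ValueError(
                f"n_dep ({self.n_dep}) exceeds n_proteins ({self.n_proteins})"
            )
        for name in ("mnar_rate", "mar_rate", "mnar_censor_quantile"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.mnar_rate + self.mar_rate > 0.95:
            raise ValueError(
                "mnar_rate + mar_rate > 0.95 would leave the matrix unusably sparse"
            )
        if self.n_donors_fraction8 > self.n_donors:
            raise ValueError("n_donors_fraction8 cannot exceed n_donors")

    def make_design(self) -> pd.DataFrame:
        donors = [chr(ord("A") + i) for i in range(self.n_donors)]
        # mirror the real study: fraction-8 exclusions are specific donors
        excluded = ("A", "F", "E")
        f8 = [d for d in donors if d not in excluded]
        if len(f8) > self.n_donors_fraction8:
            f8 = f8[: self.n_donors_fraction8]
        while len(f8) < self.n_donors_fraction8:
            f8.append(donors[len(f8)])
        return make_design(donors=donors, fractions=self.fractions, fraction8_donors=f8)


@dataclass
class SimulatedStudy:
    """A synthetic study plus its ground truth.

    ``complete`` holds the noise-free-of-missingness matrix, ``observed``
    the matrix after missingness injection (identical until
    :func:`inject_missingness` is applied). ``dep_labels`` records which
    proteins are differentially enriched, in which fraction group and with
    which signed log2 effect; ``missingness_truth`` labels every cell as
    observed/MNAR/MAR.
    """

    complete: IntensityMatrix
    observed: IntensityMatrix
    dep_labels: pd.DataFrame
    missingness_truth: pd.DataFrame
    config: SimulationConfig

    @property
    def dep_accessions(self) -> pd.Index:
        return self.dep_labels.index[self.dep_labels["is_dep"]]

    def truth_counts(self) -> pd.Series:
        return self.missingness_truth.stack().value_counts()


def _draw_protein_moments(config: SimulationConfig, rng: np.random.Generator):
    if config.empirical_matrix is not None:
        emp = config.empirical_matrix
        means = emp.mean(axis=1).to_numpy()
        sds = emp.std(axis=1, ddof=1).to_numpy()
        ok = np.isfinite(means) & np.isfinite(sds)
        idx = rng.integers(0, ok.sum(), size=config.n_proteins)
        return means[ok][idx], np.maximum(sds[ok][idx], 0.05)
    means = rng.normal(config.mean_of_means, config.sd_of_means, config.n_proteins)
    sds = np.maximum(rng.normal(config.sd_mean, config.sd_sd, config.n_proteins), 0.05)
    return means, sds


def simulate_complete_matrix(config: SimulationConfig) -> SimulatedStudy:
    """Draw the complete (missingness-free) study.

    Each protein's values are N(mean_p, sd_p); DEP proteins additionally
    receive a signed |N(dep_effect_mean, dep_effect_sd)| log2 shift in all
    samples of one randomly chosen fraction group.
    """
    config.validate()
    seed_complete, _ = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seed_complete)
    design = config.make_design()
    n_samples = len(design)
    accessions = pd.Index(
        [f"P{i:05d}" for i in range(config.n_proteins)], name="accession"
    )

    means, sds = _draw_protein_moments(config, rng)
    values = rng.normal(
        means[:, None], sds[:, None], size=(config.n_proteins, n_samples)
    )

    dep_idx = rng.choice(config.n_proteins, size=config.n_dep, replace=False)
    dep_groups = rng.integers(0, len(GROUPS), size=config.n_dep)
    signs = rng.choice([-1.0, 1.0], size=config.n_dep)
    magnitudes = np.abs(
        rng.normal(config.dep_effect_mean, config.dep_effect_sd, size=config.n_dep)
    )
    effects = signs * magnitudes

    group_of_sample = design["group"].to_numpy()
    for row, g, eff in zip(dep_idx, dep_groups, effects):
        values[row, group_of_sample == GROUPS[g]] += eff

    dep_labels = pd.DataFrame(
        {"is_dep": False, "group": pd.NA, "effect_log2": np.nan}, index=accessions
    )
    dep_labels.iloc[dep_idx, 0] = True
    dep_labels.iloc[dep_idx, 1] = [GROUPS[g] for g in dep_groups]
    dep_labels.iloc[dep_idx, 2] = effects

    frame = pd.DataFrame(values, index=accessions, columns=design["sample"].to_list())
    complete = IntensityMatrix(values=frame, design=design)
    truth = pd.DataFrame(
        OBSERVED, index=accessions, columns=frame.columns, dtype=object
    )
    return SimulatedStudy(
        complete=complete,
        observed=complete.copy(),
        dep_labels=dep_labels,
        missingness_truth=truth,
        config=config,
    )


def mnar_censor_probability(
    flat: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Per-cell logistic censoring probability with matched expected mass.

    ``p(x) = 1 / (1 + exp((x - x0 - delta) / s))`` with ``x0`` the
    `mnar_censor_quantile` quantile of the values and ``delta`` solved by
    bisection so that ``mean(p) == mnar_rate``.
    """
    x0 = float(np.quantile(flat, config.mnar_censor_quantile))
    s = config.mnar_steepness

    def mean_p(delta: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.mean(1.0 / (1.0 + np.exp((flat - x0 - delta) / s))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < config.mnar_rate:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((flat - x0 - delta) / s))


def inject_missingness(
    study: SimulatedStudy, config: Optional[SimulationConfig] = None
) -> SimulatedStudy:
    """Inject MNAR and MAR missing cells.

    Sampling scheme (deterministic given the config seed; child stream 1 of
    ``SeedSequence(seed)``):

    1. MNAR: each cell with log2 value ``x`` is censored independently
       with probability ``p(x) = 1 / (1 + exp((x - x0 - delta) / s))``,
       where ``x0`` is the `mnar_censor_quantile` quantile of the complete
       matrix, ``s = mnar_steepness``, and the shift ``delta`` is solved
       so the expected censored fraction equals `mnar_rate`. The
       probability saturates at 1 deep in the low-intensity tail, so
       proteins far below the censoring band lose entire fraction groups.
       Censoring draws are ``rng.random(n_cells) < p``.
    2. MAR: permute the remaining cell indices and take the first
       ``round(mar_rate * n_cells)``.
    """
    config = config or study.config
    config.validate()
    _, seed_missing = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seed_missing)

    values = study.complete.values.to_numpy().copy()
    n_cells = values.size
    n_mar = int(round(config.mar_rate * n_cells))

    flat = values.ravel()
    truth = np.full(n_cells, OBSERVED, dtype=object)

    if config.mnar_rate > 0:
        p = mnar_censor_probability(flat, config)
        mnar_cells = rng.random(n_cells) < p
        truth[mnar_cells] = MNAR

    if n_mar > 0:
        remaining = np.flatnonzero(truth == OBSERVED)
        mar_cells = remaining[rng.permutation(remaining.size)[:n_mar]]
        truth[mar_cells] = MAR

    observed_values = flat.copy()
    observed_values[truth != OBSERVED] = np.nan
    shape = values.shape
    observed_frame = pd.DataFrame(
        observed_values.reshape(shape),
        index=study.complete.values.index,
        columns=study.complete.values.columns,
    )
    truth_frame = pd.DataFrame(
        truth.reshape(shape),
        index=study.complete.values.index,
        columns=study.complete.values.columns,
    )
    observed = replace(study.complete, values=observed_frame)
    return replace(study, observed=observed, missingness_truth=truth_frame)


def simulate_study(config: Optional[SimulationConfig] = None) -> SimulatedStudy:
    """Complete matrix plus injected missingness in one call."""
    config = config or SimulationConfig()
    return inject_missingness(simulate_complete_matrix(config))


# ---------------------------------------------------------------------------
# Fixture generators for the peptide-mapping and NTA stages
# ---------------------------------------------------------------------------

def simulate_peptide_table(
    protein_length: int = 441,
    n_peptides: int = 30,
    design: Optional[pd.DataFrame] = None,
    near_duplicate_prob: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a tau-like peptide table with spans on a 441-residue protein.

    Emulates tryptic peptide quantification: base peptides with random
    spans, plus near-duplicates (missed cleavages extending a span, or
    modified forms sharing a span). Columns: accession, start, end,
    modified, missed_cleavage, then one log2 intensity per sample.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = make_design()
    samples = list(design["sample"])
    rows = []
    while len(rows) < n_peptides:
        length = int(rng.integers(7, 26))
        start = int(rng.integers(1, protein_length - length + 1))
        end = start + length - 1
        rows.append((start, end, False, False))
        if len(rows) < n_peptides and rng.random() < near_duplicate_prob:
            if rng.random() < 0.5:
                # missed cleavage: extended span sharing the start
                ext = int(rng.integers(3, 13))
                rows.append((start, min(end + ext, protein_length), False, True))
            else:
                rows.append((start, end, True, False))
    rows = rows[:n_peptides]
    records = []
    for i, (start, end, modified, missed) in enumerate(rows):
        if not (1 <= start <= end <= protein_length):
            raise ValueError(f"peptide span [{start}, {end}] outside protein")
        base = rng.normal(14.0, 1.5)
        intensities = rng.normal(base, 0.5, size=len(samples))
        suffix = "_mod" if modified else ("_mc" if missed else "")
        records.append(
            {
                "accession": f"pep_{start:03d}_{end:03d}_{i:02d}{suffix}",
                "start": start,
                "end": end,
                "modified": modified,
                "missed_cleavage": missed,
                **dict(zip(samples, intensities)),
            }
        )
    columns = ["accession", "start", "end", "modified", "missed_cleavage", *samples]
    table = pd.DataFrame.from_records(records, columns=columns)
    return table.sort_values(["start", "end"], kind="stable").reset_index(drop=True)


def simulate_nta_readings(
    law: str = "lognormal",
    median_nm: float = 130.0,
    sigma_log: float = 0.45,
    lo_nm: float = 0.0,
    hi_nm: float = 100.0,
    n_particles: int = 20000,
    dilution: float = 1e5,
    replicates: int = 3,
    bin_width: float = 5.0,
    max_nm: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate raw NTA exports on a 5-nm bin grid.

    Returns a tidy DataFrame (bin_center_nm, concentration, replicate,
    dilution) mimicking an instrument export: the reported concentration is
    the diluted one, so downstream dilution normalization multiplies it
    back up. ``law`` is one of ``lognormal`` (median `median_nm`, log-SD
    `sigma_log`), ``uniform`` on [lo_nm, hi_nm], or ``point`` at
    `median_nm`.
    """
    if dilution <= 0:
        raise ValueError(f"dilution must be positive, got {dilution}")
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, max_nm + bin_width, bin_width)
    centers = edges[:-1] + bin_width / 2.0
    frames = []
    for rep in range(1, replicates + 1):
        if law == "lognormal":
            sizes = rng.lognormal(np.log(median_nm), sigma_log, n_particles)
        elif law == "uniform":
            sizes = rng.uniform(lo_nm, hi_nm, n_particles)
        elif law == "point":
            sizes = np.full(n_particles, median_nm)
        else:
            raise ValueError(f"unknown size law: {law!r}")
        counts, _ = np.histogram(np.clip(sizes, 0, max_nm - 1e-9), bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "bin_center_nm": centers,
                    "concentration": counts / dilution,
                    "replicate": rep,
                    "dilution": dilution,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
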