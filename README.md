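# evfrac

Analysis pipeline for label-free (LFQ) proteomics of density-fractionated
brain extracellular vesicles (EVs), built around a **hybrid MNAR/MAR
missing-value imputation strategy** with simulation-calibrated intensity
cutoffs. The package is aimed at proteomics analysts working with
density-gradient EV preparations (eight donors x eight fractions here),
where the interesting proteins are exactly the ones that vanish from some
fractions — and are therefore destroyed by naive missing-data handling.

It provides, as a library plus a thin `evfrac` command line:

* **Synthetic studies with ground truth** (`evfrac.simulate`): log2
  intensity matrices with planted differentially enriched proteins (DEPs),
  intensity-censored (MNAR) and random (MAR) missing cells, plus peptide
  and nanoparticle-tracking fixtures — every downstream stage is testable
  without any deposited data.
* **Preprocessing** (`evfrac.preprocess`): fraction-aware protein
  filtering and variance-stabilizing normalization.
* **Hybrid imputation** (`evfrac.impute`): each missing cell is classified
  per fraction — a protein absent from a fraction, or whose mean observed
  intensity there falls below the fraction's log2 cutoff, is MNAR and
  imputed from the sample's low tail (`N(mu - 1.8 sigma, (0.3 sigma)^2)`);
  the rest are MAR and imputed by k-nearest-neighbour protein rows.
* **Moderated statistics** (`evfrac.stats`): empirical-Bayes shrunken
  variances `s2_post = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)` with moment-matched
  prior (d0, s0^2), moderated t for pairwise group contrasts and moderated
  F across the three fraction groups, Benjamini-Hochberg control
  (verified against R/limma in the test suite).
* **Calibration** (`evfrac.calibration`): the missingness-vs-intensity
  curve, automatic MNAR cutoff selection at the bottom of its decline, and
  the hybrid / unimputed / complete-case benchmark on simulated truth.
* **ssGSEA** (`evfrac.gsea`): rank-weighted single-sample enrichment
  scores with the study's set filters (5-50 detected genes, no directional
  names, <=25% overlap coefficient).
* **Tau peptide mapping** (`evfrac.peptides`) and **NTA size summaries**
  (`evfrac.nta`).

## Worked example

```python
from evfrac import (SimulationConfig, simulate_study, missingness_curve,
                    select_cutoff, compare_strategies)

study = simulate_study(SimulationConfig(seed=2023))   # 6,105 x 61, 3,000 DEPs
cutoff = select_cutoff(missingness_curve(study))
print(f"selected MNAR cutoff: {cutoff:.3f} log2 units")
print(compare_strategies(study, cutoff=12.0, seed=2024)
      [["capture_pct", "accuracy_pct", "n_called"]].round(2))
```

prints

```
selected MNAR cutoff: 12.125 log2 units
               capture_pct  accuracy_pct  n_called
strategy
hybrid               93.67         97.54      2881
unimputed            66.23         96.74      2054
complete_case        24.77         96.49       770
```

Reading: of the 3,000 planted DEPs, hybrid imputation followed by the
moderated-F pipeline recovers 93.7% at BH-adjusted p < 0.05 with ~98%
precision; testing only the observed values recovers 66%, because proteins
censored out of entire fraction groups cannot be fitted; restricting to
proteins with no missing values at all recovers just 25%. The selected
cutoff (~12.1) is where the fraction of truly-censored cells among missing
cells falls below 5% along the protein-mean intensity axis.

Imputing a real table instead:

```bash
evfrac preprocess intensities.tsv design.csv --out normalized.tsv
evfrac impute normalized.tsv design.csv --seed 1 --out-prefix run
evfrac test run_imputed.tsv design.csv --out contrasts.tsv
```

`impute` uses the study's per-fraction cutoffs (F1 14.9 ... F8 15.2) unless
`--cutoffs` supplies a YAML mapping.

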