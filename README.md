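# qcindex

A tested, reusable pipeline for building a **Quality-of-Care Index (QCI)**
from burden-of-disease tables of the kind exported by the Global Burden of
Disease (GBD) results tool — incidence, prevalence, deaths, YLLs, YLDs and
DALYs for a single cause (the motivating application is lip and oral cavity
cancer) by country, year, sex and 5-year age group.

The package is aimed at epidemiologists and health-systems researchers who
want a transparent, reproducible implementation of composite care-quality
scoring, complete with a synthetic-data generator whose hidden care-quality
gradient makes every pipeline stage checkable against ground truth.

## The method

Four ratio indices summarise the quality of cancer care per analysis unit
(counts summed within the unit first):

| index | definition | reading |
|---|---|---|
| PIR | prevalence / incidence | survival duration among cases |
| MIR | deaths / incidence | case fatality — lower is better |
| DPR | DALYs / prevalence | burden per prevalent case |
| YLR | YLLs / YLDs | mortality share of the burden — lower is better |

Each index is z-standardised and the four are unified by the first
principal component of their 4×4 correlation matrix. The component's sign
is anchored so the MIR loading is negative (falling back to YLR if the MIR
loading vanishes), making higher scores mean better care; the oriented
score is then min–max rescaled over the fitting set so that

```
QCI = 100 · (s − s_min) / (s_max − s_min)  ∈ [0, 100],
```

with the fitting-set extrema hitting 0 and 100 exactly. Derived analyses:
the **gender disparity ratio** GDR = QCI_male / QCI_female, classified into
the bands ≤ 0.5, (0.5, 0.95], (0.95, 1.05] (optimal), (1.05, 1.5], > 1.5;
**age-standardised** figures using world-standard population weights;
**six-sigma outlier detection** (values outside (μ − 3σ, μ + 3σ)); and a
**validation regression** of QCI on health-system covariates with a
per-country random intercept, whose predictions are correlated with a
reference access-and-quality series.

## Worked example

```python
import numpy as np
from qcindex import RunConfig, SyntheticConfig, run_pipeline
from qcindex.disparity import rank_locations

cfg = RunConfig(
    synthetic=SyntheticConfig(n_countries=20, year_start=1990,
                              year_end=2017, seed=42),
    out_dir="demo_run")
bundle = run_pipeline(cfg)

print("PC1 explained share: %.3f" % bundle.scorer.explained_share_[0])
print("PC1 loadings (pir, mir, dpr, ylr):",
      np.round(bundle.scorer.loadings_, 3))

asr = bundle.qci_scores
both_2017 = asr[(asr.age_group == "age-standardised")
                & (asr.sex == "both") & (asr.year == 2017)]
print(rank_locations(both_2017, 2017, "descending")
      .head(3)[["rank", "location", "qci"]].to_string(index=False))

gdr_2017 = bundle.gdr[bundle.gdr.year == 2017]
print("optimal-GDR countries in 2017: %d / %d"
      % (gdr_2017.optimal.sum(), len(gdr_2017)))
print("validation Pearson r vs reference index: %.2f"
      % bundle.validation["pearson_r"])
```

prints

```
PC1 explained share: 0.963
PC1 loadings (pir, mir, dpr, ylr): [ 0.5 -0.5 -0.5 -0.5]
 rank    location       qci
    1 Country-001 98.940344
    2 Country-002 98.744787
    3 Country-010 98.350544
optimal-GDR countries in 2017: 20 / 20
validation Pearson r vs reference index: 0.92
```

The first principal component carries 96% of the four indices' variance
and loads positively on survival duration (PIR) and negatively on case
fatality (MIR), burden per case (DPR) and the mortality share (YLR) —
higher QCI therefore means longer survival and lower fatality. The ranked
list shows the best-scoring synthetic countries in the final year; every
country's male and female scores sit inside the optimal parity band; and
the mixed-model predictions correlate at r = 0.92 with the (synthetic)
reference access-and-quality series.

The same run is available from the shell:

```bash
qcindex run --seed 42 --out-dir demo_run
qcindex report demo_run
```

which writes `qci_scores.csv`, `gdr.csv`, `region_summary.csv`
(age-standardised DALY rate and QCI per income and development stratum at
the period ends with percent changes), `outliers.csv`, `trend_by_sex.csv`,
`validation.json` and a JSON run manifest.

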