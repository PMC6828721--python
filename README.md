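# aquarisk

Probabilistic human health-risk assessment of potentially toxic metals (Pb,
Cr, Ni, Fe, Mn, Al) in groundwater, for environmental scientists and
risk assessors working with well/borehole monitoring data.  The package
covers the full chain such studies run: descriptive statistics and
guideline-exceedance accounting, US EPA-style dose equations, Monte Carlo
uncertainty propagation with percentile and exceedance reporting,
rank-correlation sensitivity shares, correlation/principal-factor source
apportionment, and inverse-distance-weighted (IDW) concentration surfaces.
A synthetic-data generator emulates a two-district, two-source sampling
design (36 locations × 3 replicates = 108 samples), so every stage is
testable without field data.

## The model

Chronic daily intake (µg/kg·day) for the two exposure routes:

    CDI_ing = C · IR_w · EF_r · ED / (BW · AT_r)
    CDI_derm = C · SA · K_p · EF_r · ED · ET · CF / (BW · AT_r)

with `C` the concentration in water (µg/L), `IR_w` intake (L/day), `EF_r`
exposure frequency (days/year), `ED` exposure duration (years), `BW` body
weight (kg), `AT_r` averaging time (days; `ED·365` for non-carcinogenic
endpoints, `70·365` for carcinogenic), `SA` skin area (cm²), `K_p` dermal
permeability (cm/h), `ET` exposure time (h/day), `CF` = 0.001 L/cm³.

Risk metrics:

    HQ   = CDI / RfD            (hazard quotient; HQ > 1 flags concern)
    LTCR = CDI[mg/kg·day] · SF  (lifetime cancer risk; acceptable 1e-6..1e-4)

Monte Carlo simulation draws the concentration (and optionally any exposure
factor) from configurable distributions, pushes n joint draws through the
equations, and reports mean, SD, the 90/95/99/99.9th percentiles and the
fraction of the simulated population above a threshold.  Sensitivity shares
are signed squared-Spearman contributions; source apportionment
eigen-decomposes the parameter correlation matrix into principal factors
with variable- and observation-contribution accounting.

## Worked example

Propagate a lognormal Pb concentration (mean 56 µg/L, sd 25) through the
adult ingestion hazard quotient (`examples/02_monte_carlo_hazard.py`):

```
simulated HQ mean 1.093, sd 0.488  (n = 10000)
   50.0th percentile : 0.996
   90.0th percentile : 1.724
   95.0th percentile : 2.001
   99.0th percentile : 2.699
   99.9th percentile : 3.755
share of population with HQ > 1 : 49.60%
```

The mean hazard quotient sits just above 1 and roughly half of the simulated
population exceeds the safety threshold — the distribution-based answer that
a single point calculation would hide.  The other scripts in `examples/`
walk through the dose arithmetic, the synthetic study design and guideline
violations, the sensitivity tornado, factor-based source attribution, and
IDW mapping, each printing a few annotated numbers.

A full report bundle (summary CSV, risk tables, tornado rows, factor CSVs,
`.asc` rasters, manifest) comes from the CLI:

```sh
aquarisk all --seed 7 --n 10000 --out report/
```

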