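# sepsisburden

Subnational sepsis burden from official registries: age-standardized
incidence and mortality, excess-of-mortality mapping, and multiple-cause
bias correction.

## The problem

Global and national sepsis estimates do not tell a health ministry *where*
sepsis is killing people that the health system is failing to catch.
Countries with complete civil registration (Chile is the motivating case)
publish death records, hospital discharges and population projections at
the third administrative level (comunas). This package turns those tables
into comuna-level answers:

* **ASIR / ASMR** — sepsis-related age-standardized incidence (live
  discharges) and mortality rates per 100,000, by direct standardization
  to a reference-year age structure, with Fay–Feuer gamma/chi-squared
  confidence intervals under a Poisson count model:

  `ASR = 1e5 · Σ_a w_a d_a / n_a`,  `Var = 1e10 · Σ_a w_a² d_a / n_a²`

* **EM = ASMR / ASIR** — the excess-of-mortality ratio per geography ×
  age group × ICD-10 code. `EM > 1` flags strata where sepsis deaths
  outpace recorded sepsis incidence — where sepsis is *not being
  contained*; strata with mortality but zero recorded incidence get a
  **warning** label (EM is undefined there), and results are ranked by the
  magnitude of the excess.

* **λ = ASR_MCOD / ASR_SCOD** — a correction ratio computed on an external
  registry that publishes all death-certificate lines (A–D), quantifying
  how much a single-cause (underlying-cause-only) reading undercounts
  sepsis; applied multiplicatively to single-cause rates. Relative bias is
  reported as `100·(1 − 1/λ)`.

* **Quality machinery** — variable-wise completeness audit with a
  chi-square goodness-of-fit test for non-random missingness, Monte Carlo
  probabilistic sensitivity analysis with Spearman rank attribution, and
  pairwise Z-tests between geographies with p-value matrices.

Sepsis is identified from editable ICD-10 code lists (explicit sepsis,
infection, organ dysfunction — seeded from the GBD groupings of Rudd et
al. 2020): explicit-or-implicit on single-cause records, explicit-on-any-line
on multiple-cause records.

A bundled synthetic registry generator emits all three registry dialects
from a declared ground truth (Poisson event counts, configurable
secondary-line fraction and missingness), so the entire pipeline is
testable without downloading anything.

## Worked example

The headline classification — a comuna reported with ASMR 41.6 and ASIR
27.8 per 100,000:

```python
>>> from sepsisburden import compute_em
>>> r = compute_em(41.6, 27.8)
>>> print(f"EM = {r.em:.3f}  state = {r.state}")
EM = 1.496  state = excess
```

Mortality exceeds incidence by a factor of ~1.5: sepsis is not being
contained there.

The full pipeline on the bundled synthetic registry (8 comunas, one year,
known truth):

```sh
sepsisburden all --data scratch/data --out scratch/out --seed 1
```

writes rate tables, EM tables, the λ table, PSA and Z-test results, and
rendered heatmaps. The ranking of not-contained strata
(`scratch/out/em_ranking.csv`):

```
age_group,code,geography,em,asmr,state
40-59,J180,01103,4.333333333,337.037037,excess
60+,A419,01102,4,425,excess
60+,K659,03102,,67.30769231,warning
40-59,N390,02103,,62.96296296,warning
60+,J960,03102,,38.46153846,warning
```

Two excess cells (bronchopneumonia J18.0 in comuna 01103 at ages 40–59;
septicemia A41.9 in comuna 01102 at 60+) and three warning cells — exactly
the departures planted by the generator. The λ table from the synthetic
multiple-cause registry (true secondary-line fraction 0.25, so expected
bias is 25%):

```
sex,year,asr_mcod,asr_scod,lam,relative_bias_pct
female,2022,116.1057692,86.84615385,1.336913198,25.20082816
female,2023,113.1442308,84.89423077,1.332767018,24.96813121
male,2022,115.25,87.30769231,1.320044053,24.24495244
male,2023,112.375,83.86538462,1.339944967,25.37006931
```

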