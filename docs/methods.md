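# Methods

`sepsisburden` quantifies the subnational burden of sepsis from official
registries: death records and hospital discharges coded in ICD-10, plus
population projections. This note documents the statistical model, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical corner cases.

## Record model and harmonization

Each event (death or live discharge) is reduced to: year, sex, age, region
and comuna of residency, and one or more ICD-10 codes. ICD-10 codes are
normalized to a canonical 3/4-character form (uppercase, dot-free, trailing
"X" placeholder trimmed); structurally invalid codes send the whole row to
a reject log with a reason token, so every reader satisfies
`rows_in = records_out + rejects`.

Age arrives as a (unit, magnitude) pair — years, months, days or hours —
and is recoded into five analysis bins: `<1`, `1–19`, `20–39`, `40–59`,
`60+`. The top bin is closed at 60 (a sixty-year-old is `60+`). Sub-year
units always map to `<1`; registries use them only for infants.
Column names, sex and age-unit codebooks, delimiters, encodings and
geography sentinels vary across sources and are therefore configuration
(YAML), not code. Geography codes are opaque strings: leading zeros are
data, and region↔comuna containment comes from a lookup file.

Multiple-cause death records carry four certificate lines (A–D), each with
up to five asterisk-demarcated code slots. The parser returns codes in
certificate order, preserves duplicates, skips malformed slots non-fatally,
and truncates lines with more than five slots (logging the anomaly);
output length is bounded by 20.

## Sepsis definition

Code lists (explicit sepsis / infection / organ dysfunction) ship as
editable YAML seeded from the GBD sepsis ICD-10 groupings (Rudd et al.,
2020). Entries are dot-free prefixes: a 3-character entry covers its
4-character children; a 4-character entry matches only itself. Matching
precedence is explicit > infection > organ dysfunction; precedence affects
only the label, never the sepsis/not-sepsis boolean.

* **Single-cause (SCOD) rule** — used where only the underlying cause of
  death / primary cause of hospitalization is available: a record is
  sepsis-related if its one code is explicit, or implicitly via an
  infection *or* an organ-dysfunction code. The literal "or" is the
  default; a stricter explicit-only mode exists for sensitivity analyses.
* **Multiple-cause (MCOD) rule** — a record is sepsis-related iff an
  explicit code appears on any line. Implicit categories are deliberately
  not used here; with all lines visible, infection and dysfunction codes
  co-occur too freely to remain specific. The rule is order-invariant.

## Rates

Crude rates are `1e5 · d / n` with annual population projections as the
person-years denominator (no mid-year interpolation — the projections are
already annual averages). Direct standardization uses weights `w_a` from a
reference projection year (default 2025):

```
ASR  = 1e5  · Σ_a w_a · d_a / n_a
Var  = 1e10 · Σ_a w_a² · d_a / n_a²
```

The variance model is Poisson on counts — the standard model behind the
gamma interval for directly standardized rates. Two standardization modes:

* `matched` (default): each geography is standardized to its **own**
  reference-year age structure; appropriate when each geography's rate is
  read on its own.
* `national`: one common structure for all geographies; required whenever
  rates or variances are compared across geographies, so the pairwise
  Z-tests always use it.

Confidence intervals are Fay–Feuer gamma/chi-squared intervals: the lower
bound is the `α/2` quantile of a gamma distribution with the ASR's first
two moments; the upper bound is the `1−α/2` quantile after shifting the
moments by the largest single-count contribution `max_a 1e5·w_a/n_a`. With
a single age group this reduces exactly to the chi-square interval for a
Poisson count, which is the oracle used in the tests. A zero rate pins the
lower bound at 0; the upper bound then comes from the shift term alone.

When a table is stratified *by* age group, "standardization" degenerates
to the age-specific rate (weight 1 on that group) — this is what the
per-age excess analyses use.

## Excess of mortality

`EM = ASMR / ASIR` per stratum, with four states: `excess` (ASIR > 0 and
EM > 1; EM exactly 1 is *contained* — the operator is strictly ">"),
`contained`, `warning` (ASIR = 0 with ASMR > 0: EM is undefined, but
mortality with no recorded incidence is the strongest signal), and
`silent` (0/0, kept distinct so matrices can tell no-signal from
contained). The warning rule fires on any positive ASMR by default; a
stricter variant requiring ASMR > 1 (`warning_mode="gt1"`) exists because
the two readings cannot be reconciled from available sources — the default
follows the division-by-zero rationale, which any positive ASMR triggers.
Rankings list excess cells by descending EM, then warnings by descending
ASMR; heatmap matrices contain excess cells only (yellow→red scale).

EM is scale-invariant, and invariant to the choice of standard population
exactly when age-specific rate ratios are constant across ages.

## Correction ratio λ

Single-cause registries miss sepsis mentioned off the underlying line. On
an external registry publishing all lines, `λ(sex, year) =
ASR_MCOD / ASR_SCOD` where the SCOD side applies the explicit rule to the
underlying cause (line A, first slot) only — this pairing guarantees the
SCOD-positive set is nested in the MCOD-positive set, hence λ ≥ 1.
Relative bias defaults to the shortfall against the multiple-cause rate,
`100·(1 − 1/λ)` ("vs-mcod", consistent with "underestimation");
`100·(λ − 1)` is available as `vs-scod` since both conventions circulate.
Applying λ scales the rate and its CI bounds; λ's own sampling uncertainty
is *not* propagated — a documented limitation, corrected rates carry the
uncorrected interval geometry.

## Sensitivity and uncertainty

**PSA.** Expected events `rate × population / 1e5` are recomputed under
Monte Carlo perturbation of both inputs (default 10,000 iterations):
population truncated-normal with cv 0.05 (projections carry small relative
error), event counts Poisson around the observed expectation (matching the
rate-variance model); both laws configurable. Attribution is the Spearman
rank correlation of each input's draws against the output; a zero-variance
input is reported as undefined rather than 0. A single top-level seed
makes runs bit-reproducible.

**Z-tests.** `z = (ASR₁ − ASR₂)/√(Var₁ + Var₂)` with a two-sided normal
p-value, expanded into symmetric matrices over all geography pairs with
the share of significant pairs. Raw p-values by default (no multiplicity
adjustment, matching how "significant combinatorial differences" are
usually quoted); Holm can be applied downstream.

## Completeness audit

"Missing" (structurally empty) and "undetermined" (present-but-sentinel,
e.g. comuna `99999` ignored / `88888` foreign national) are counted
separately; completeness below 99.95% flags a variable for a Pearson
chi-square goodness-of-fit test of missing counts against the
proportional-to-group-size null, with per-group `(O−E)²/E` contributions
reported so favored groups are identifiable. Groups for the test default
to decadal age bins. Variables whose missingness masks coincide exactly
are reported untestable (no test can distinguish them). Zero expected
count with nonzero observed raises a structured error advising group
merging. Incomplete rows are excluded, never imputed.

## Synthetic registries

The generator emits the exact dialects the readers consume, from a
declared truth: a geography tree (default 3 regions × 8 comunas, 100,000
inhabitants each with comuna-varying age structures), true ASIR/ASMR
surfaces per comuna × age × code (6 sepsis codes + chapter-spanning
background codes), a secondary-line fraction `f` for the multiple-cause
registry, and a missingness spec. Event counts are Poisson
(`rate·n/1e5`); the multiple-cause registry places the sepsis code on
line B behind a background underlying cause with probability `f`, so the
expected correction ratio is `λ = 1/(1−f)` and expected vs-MCOD bias is
`100·f`%. Default `f = 0.25` and ≈47,500 sepsis deaths across two sexes ×
two years give λ recovery within fractions of a point.

The default single-year scenario is deliberately sharp: baseline cells
have incidence roughly ten-fold mortality (contained), two planted excess
cells have mortality five-fold incidence with expected counts ≥ 15 on
both sides, three planted warning cells have zero incidence and expected
mortality counts ≥ 12, and designated silent cells are zero/zero. With
that separation the probability that any cell's recovered state differs
from the declared one is < 1e-4, so recovery tests can demand exact set
equality. What passing these tests shows is that the pipeline recovers a
truth *of the kind the analysis assumes* (independent Poisson cells,
stable coding, closed population); it says nothing about coding drift,
migration, cohort effects or within-person event correlation, none of
which the generator emulates.

Simulation sizes used by the test suite and the acceptance script (5,000
replicates for interval coverage and test calibration, 2,000 for the
missingness test, 10,000 PSA iterations, ~190,000 multiple-cause rows)
were chosen so the whole suite completes in well under a minute of
simulation time while leaving Monte Carlo error far inside the asserted
tolerances.

## Numerical choices

* Gamma quantiles, chi-square tails and normal tails come from
  `scipy.stats`; no saddlepoint or continuity corrections.
* `alpha` applies two-sided everywhere; CI width is monotone in `alpha`.
* Zero-event strata produce ASR 0 with CI lower bound 0.
* A stratum with events in an age group of zero population is an error
  (inconsistent inputs), as is a stratum with zero total population.
* λ cells with zero SCOD rate are marked incomputable and excluded from
  summaries with a warning rather than raising.
* CSV outputs are UTF-8, "." decimal, `%.10g` floats; reports round rates
  to one decimal, machine outputs keep full precision. Every output
  directory carries `RUN_INFO.json` (package version + seed) and the full
  `run_config.yaml`.

## Known limitations

* λ is a country-level point correction; no uncertainty propagation and
  no age-specific λ.
* The discharge-side λ (MCODi/SCODi) is implemented and exercised on
  synthetic data, but real open-access discharge registries rarely carry
  usable secondary-cause fields.
* No indirect standardization, no trend fitting, no spatial smoothing,
  no choropleth cartography — per-geography tables and matrix heatmaps
  are the outputs.
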