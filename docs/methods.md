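# Methods

## The index model

The Quality of Care Index treats care quality as a latent construct whose
observable footprint is the *relationship* among burden measures, not their
levels. A health system that diagnoses early and treats effectively turns
incident cases into long-lived prevalent cases (high prevalence/incidence),
prevents deaths among the incident (low mortality-to-incidence), and shifts
the burden mix from mortality to morbidity (low YLL/YLD, low
DALY/prevalence). All four ratios are scale-free: multiplying every measure
of a stratum by a common constant — a different underlying disease burden —
changes none of them, so the index compares *management* of the disease, not
its magnitude.

The composite is the first principal component of the four ratios. Key
assumptions: (i) one dominant axis of variation exists among the ratios and
it is the care-quality axis — checked via the explained-variance fraction
stored on every fitted model; (ii) quality enters approximately linearly on
the standardized ratio scale; (iii) the strata in the fitting frame span the
quality range of interest, since the 0–100 anchors are that frame's extremes.

### Standardization

Correlation-matrix PCA (z-scoring each ratio, sample sd with ddof = 1) is
the default. The four ratios live on very different scales — YLL/YLD
commonly exceeds 10 while MIR is below 1 — so covariance PCA would be
dominated by whichever ratio happens to have the largest spread.
Covariance mode (`standardize=False`) and a natural-log pre-transform
(`log_transform=True`, useful for heavy-tailed YLL/YLD) are available and are
recorded in the fitted model so scoring always applies the same
preprocessing as fitting. In correlation mode the index is invariant to any
positive affine rescaling of an individual ratio column.

### Orientation

A principal component's sign is arbitrary. The orientation rule pins it to
the mortality-to-incidence ratio: the sign is chosen so the oriented MIR
loading is ≤ 0, making "higher index = better care" a structural guarantee
rather than a convention (raising a stratum's MIR, everything else fixed,
can then never raise its score). When the MIR loading is exactly zero the
decision falls through YLL/YLD, then DALY/prevalence, then the negated
prevalence/incidence loading (the one ratio where higher is better); all
four zero is an error. If the top two eigenvalues are numerically tied
(gap ≤ 1e-9 relative), the component with the larger |MIR| loading is
selected deterministically and the model records `eigen_tie_broken`.

### Rescaling and fit frames

Scores are min–max rescaled to [0, 100] using the extremes of the fitting
frame, which are stored in the model; within one fit, scores are therefore
comparable across years and locations. The default pipeline fits on the
both-sexes, age-standardized strata and scores sex-specific strata against
that same model, so sex differences are measured on a common scale.
Out-of-frame strata may score below 0 or above 100; they are flagged
(`in_frame=False`) rather than silently clamped, with clamping available by
flag. `fit_scope ∈ {pooled, per_sex, per_age}` refits per subgroup instead;
note that per-sex refitting rescales each sex to its own [0, 100] and
therefore erases between-sex level differences — the pooled frame is the
right choice when the GDR is the quantity of interest.

## Secondary-measure policy

A stratum enters the ratio table only if all six measures are present and
the three denominators (incidence, prevalence, YLD) are strictly positive.
Everything else is excluded with a per-stratum reason (`zero_incidence`,
`zero_prevalence`, `zero_yld`, `missing_measure`); an exclusion summary is a
one-call tally. Epsilon-imputation of zero denominators exists behind
`zero_policy="epsilon"` but is off by default — imputed near-zero
denominators produce extreme ratio outliers that silently distort the PCA
loadings. A run in which *no* stratum survives is a hard error.

## Gender disparity ratio

GDR = female QCI / male QCI per (location, year, age group), computed from
full-precision scores and rounded (1 decimal) only for reporting; dividing
already-rounded scores would inject up to about ±0.002 of spurious
disparity. The ratio is undefined — skipped and logged, not set to 0 or ∞ —
when either sex is missing, when the male score is 0, or when either score
is negative (below the fitting frame). Downstream summaries report the skip
count.

## SDI quintiles

Rank mode computes the 20/40/60/80th percentile boundaries over locations in
a reference year (default: the latest year present) so each location keeps
one quintile label across years; ties are broken by stable location-name
order, making assignment invariant to input row order and to any strictly
monotone transform of SDI. Fixed-cutpoint mode applies four user-supplied
boundaries, for replicating published cut-offs.

## Age standardization

Direct standardization: the weighted sum of age-specific rates under a
reference age structure whose weights sum to 1 (tolerance 1e-9). Age bins
follow the 5-year GBD convention (0–4 … 90–94, open-ended 95+),
configurable. The default reference standard is equal weights across the
configured bins; any standard can be supplied, since published
age-standardized rates depend on the chosen standard population.

## The synthetic generator

The generator emulates the statistical structure of a GBD-style extract: a
latent per-location care quality q ~ Beta(2, 2), an SDI that is a monotone
affine link of q plus truncated Gaussian noise (sd 0.05), and six measures
per stratum and 5-year age bin:

- incidence: logistic-in-age baseline (scale 300 per 100,000, half-maximum
  at age 65, slope 12 years) — rare in the young, plateauing in old age;
- deaths = incidence × MIR(q), MIR linear from 0.9 (q = 0) to 0.1 (q = 1);
- prevalence = incidence × duration(q), duration linear from 1 to 10 years;
- YLD = prevalence × disability weight (0.2);
- YLL = deaths × residual life expectancy, declining linearly from 85 years
  at age 0 to 2 years at the top bin;
- DALY = YLL + YLD, formed after every aggregation step (sex-combined and
  age-standardized rows included) so the identity holds exactly row-by-row.

Multiplicative log-normal noise (sd 0.1 on the log scale) is applied per
measure from per-measure substreams of a single seed, so adding a measure
never shifts another's draws and a fixed seed is bit-reproducible. Noise is
shared across the sexes by default: with `sex_effect = 1` female and male
rows are identical and the GDR null is exact; `independent_sex_noise=True`
adds sex-specific sampling noise instead. `sex_effect` multiplies female
latent quality, and a linear `year_trend` can drift quality over years.

Default study conditions: 100 locations, the single year 2019, seed 42,
noise sd 0.1. At that size the full pipeline runs in about a second; tests
that need tighter Monte-Carlo behaviour use 200 locations.

What the generator does *not* emulate — and hence what passing tests do not
show about real extracts: realistic burden magnitudes for any actual cancer,
age-dependence of care quality, correlated errors across measures coming
from a shared estimation model, uncertainty intervals, or non-monotone
SDI–quality relationships. Recovery results on synthetic data demonstrate
that the pipeline's machinery is correct, not that one principal component
suffices for any particular real disease.

## Numerical choices

- PCA is computed by full SVD on the standardized matrix (scikit-learn
  backend); tests verify agreement with a dense symmetric eigendecomposition
  of the correlation matrix to 1e-8.
- Degenerate inputs fail loudly: < 3 strata, a zero-variance ratio column
  (named in the error), zero raw-score spread, all-zero loadings.
- Reported scores and GDRs are rounded to 1 decimal in CSV outputs; full
  precision is kept in memory and in the serialized model (17 significant
  digits).
- CLI exit codes: 0 success, 2 config error, 3 data error, 4 degenerate
  math.

## Known limitations

- The explained-variance fraction is reported, not enforced; a first
  component carrying, say, 40% of the variance still yields an index, and
  judging its adequacy is left to the analyst.
- Regional or global aggregates can be formed either by (population-weighted)
  averaging of location scores or by refitting on aggregate-level rates; the
  two are not equivalent and the package supports both without asserting
  either as canonical.
- Rates are assumed per 100,000 throughout; count-based inputs are out of
  scope (ratios of counts and of rates coincide only when the stratum
  population cancels).
- No uncertainty propagation: the index is a point estimate per stratum.
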