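# Methods

## The model

The network scale-up method (NSUM) estimates the size of a hidden
population from a general-population survey in which each respondent *i*
reports the number `m_i` of hidden-population members they know. If a
respondent's personal network of size `c_i` were a uniform sample of the
reference population of size `t`, the fraction of hidden members in the
network would estimate their population fraction, giving the crude
estimator

    e = (Σ_i m_i / Σ_i c_i) · t .

Here the hidden population is female sex workers (FSWs), the reference
population is adult women (t = 406,916), and the degrees are fixed
per-gender values borrowed from a prior known-population study:
`c = 90` for male and `120` for female respondents. The package does not
estimate degrees from the survey; they are configuration inputs.

Two multiplicative corrections address the estimator's standard
assumption violations:

- **Visibility factor (VF)** — transparency barrier: a respondent knows an
  FSW acquaintance's status only with probability `v`; the crude count is
  thinned by `v`, so the estimate is multiplied by `VF = 1/v`. The
  detection probability adopted from the external correction-factor study
  is 0.35–0.55; the point value is the reciprocal of the midpoint,
  `VF = 1/0.45 ≈ 2.222`. (Its common printed rounding is 2.22; the
  reciprocal form is what reproduces the downstream estimates, so the
  reciprocal is the default.)
- **Popularity factor (PF)** — barrier effect: hidden-population members
  have networks `ρ` times the general average (`ρ` = 0.67–0.87), so fewer
  respondents reach them; the estimate is multiplied by `PF = 1/ρ`, point
  `1/0.77 ≈ 1.299`.

Both are pure multipliers, so `e_adjusted = e · VF · PF` independent of
order; the singly-adjusted values are reported for table-style output.
Prevalence is `e_adjusted / t` scaled to a chosen denominator (default per
1000).

The companion sample-size formula `n = z² p (1−p) / d²`, inflated for
nonresponse (default multiplicatively by `1 + nr`; division by `1 − nr`
available), documents the survey design the defaults emulate
(p = 0.015, d = 0.008, 95% confidence, 10% nonresponse → 976).

## Uncertainty

The printed aggregates support two interval constructions, both percentile
bands of replicate estimates with an explicit `(low, high)` percentile
parameter (default 2.5/97.5):

- **Monte Carlo (parametric).** Per replicate, `Σm* ~ Poisson(Σm)` and
  `Σc* ~ Poisson(Σc)` (a sum of per-respondent Poisson degrees is exactly
  one aggregate Poisson draw, so the aggregate draw is used; zero draws of
  `Σc*` are redrawn — they carry no information and are vanishingly rare
  at realistic totals). When factor sampling is on (default),
  `VF* ~ U(1/0.55, 1/0.35)` and `PF* ~ U(1/0.87, 1/0.67)`; otherwise the
  point factors are used. With fixed factors the relative half-width
  follows the Poisson-ratio delta approximation
  `1.96·sqrt(1/Σm + 1/Σc) ≈ 9.4%` at the default aggregates, which the
  tests use as an independent band. Sampling the factors roughly triples
  the width — materially wider than intervals published from comparable
  analyses, which is why the tests validate the procedure's properties
  (unbiased replicate mean, Poisson replicate distribution) rather than
  pinning printed bounds.
- **Bootstrap (nonparametric).** Respondents are resampled with
  replacement, gender-stratified by default because degrees are
  gender-specific (so the denominator is invariant and only the numerator
  resamples); pooled resampling is available by flag. Resampling is
  realised as multinomial count vectors in blocks of 1000 replicates, so
  replicate sums are dot products and memory stays flat.

Both take a single integer seed feeding one `numpy` generator per call;
the seed is recorded in the result and identical seeds give bit-identical
results. Default replicate count is 10,000.

## Synthetic surveys and parameter recovery

The generator emulates the study design and the two distortions the
corrections exist for. For a truth with hidden count `k_true`, each
respondent of gender `g` draws

    m_true ~ Binomial(c_g, p),   p = (k_true / t) · ρ
    m      ~ Binomial(m_true, v)

Binomial rather than Poisson counts are deliberate: degrees are small
integers and `p` is tiny, so the Poisson model assumed by the Monte Carlo
interval is an accurate limit of — but not identical to — the generative
process, and the tests probe exactly that agreement. Default truth mirrors
the study: t = 406,916, 495/505 respondents, degrees 90/120, v = 0.45,
ρ = 0.77, `k_true = 4850` (chosen so the expected report total,
`0.45 · 0.77 · (k_true/t) · Σc ≈ 437`, sits at the observed scale of 434).
Demographic columns (respondent and alter) are drawn independently per
record from the study's published marginal frequencies; no joint
demographic structure, network topology, homophily or recall error is
emulated, so passing recovery tests demonstrate correctness of the
estimator chain under the model's own assumptions, not robustness to real
field data.

`recover_parameters` repeats generate → estimate → correct (with the
oracle reciprocals `VF = 1/v`, `PF = 1/ρ`) and reports mean and relative
bias plus the empirical coverage of the fixed-factor Monte Carlo interval
for `k_true`. At the study scale the adjusted estimator is unbiased to
within Monte Carlo error (|relative bias| well under 5% at 200
simulations); dropping the corrections under v = 0.45 reproduces the
expected 55% underestimate.

`force_total_reports` pins a simulated survey to a published aggregate
total by adding/removing single reports at seeded-random respondents —
used to rebuild the study's exact headline numbers on record-level data.

## Numerical and design choices

- All chained estimates are kept at full precision; rounding (counts to
  integers, prevalence to 2 decimals) happens only at report time.
- Percentages in demographic tables are computed at full precision with a
  configurable denominator: `all` records (default, matching how the
  source tables were computed) or `nonmissing` only.
- Sensitivity rows are recomputed from scratch per scale rather than via
  the exact reciprocal law `e(s) = e(1)/s`; the law then serves as an
  internal consistency check. Both genders' degrees scale together by
  default, with per-gender switches.
- The reproduction of published aggregates from counts
  (`NetworkScaleUp.from_counts`) allocates reports one at a time over
  respondents (seeded-random order); any allocation reproduces the point
  estimates exactly, but resampling intervals do depend on it.
- Report JSON is schema-versioned, key-sorted, and free of timestamps so
  regeneration from the same inputs and seed is byte-identical.

## Problem sizes

Defaults run the Monte Carlo and bootstrap at 10,000 replicates (well
under a second each at n = 1000). The validation experiments use 200
simulated surveys for bootstrap coverage (1000 bootstrap replicates each)
and 200 simulations for parameter recovery (1000 Monte Carlo replicates
each) — sizes at which the binomial/Poisson Monte Carlo error is a few
tenths of a percent, comfortably below the 5% recovery criterion.

## Known limitations

- Degrees, `t` and the correction factors are externally supplied; no
  known-population or summation degree estimation is implemented.
- The generator shares the analysis model's structure (up to the
  binomial/Poisson distinction), so recovery tests cannot detect shared
  misspecification such as recall error or non-uniform mixing.
- The uncertainty intervals propagate sampling and stated factor
  uncertainty only; degree misspecification is addressed separately (and
  only deterministically) by the sensitivity scan.
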