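# Methods

## The model

All three estimation pathways share the von Bertalanffy growth curve

    L(t) = L∞ · (1 − e^(−K·(t − t0))) + ε,   ε ~ Normal(0, σ)

with lengths in mm and ages in decimal years. `L∞` (mm) is the mean
asymptotic length, `K` (1/yr) the Brody coefficient governing how fast
the curve approaches it, `t0` (yr) the nominal age at zero length — a
curve-shifting parameter with no biological meaning — and `σ` (mm) the
SD of additive observation error. Internally everything is mm;
centimetre-resolution monitoring data are converted on ingest. Elapsed
times given as dates are converted at 365.25 days per year.

The three pathways differ in what they observe:

1. **Age-at-length** (`nls.fit_vbgm_nls`, `bayes` with `model="vBGM"`):
   scale-derived decimal ages and lengths; all of (L∞, K, t0, σ) are
   estimated.
2. **Mark-recapture increments** (`fit_fabens_nls`, `model="Fabens"`):
   the Fabens reparameterisation
   `L_r = L_m + (L∞ − L_m)(1 − e^(−K·Δt)) + ε` predicts the recapture
   length from the marking length and the elapsed time; only (L∞, K, σ)
   appear — no individual ages, no t0. Mean growth declines linearly
   with length under this model.
3. **Length-frequency** (`elefan`): a non-seasonal curve is fitted to
   the modal progression of binned catches (ELEFAN, below); the
   calendar anchor `t_anchor ∈ [0, 1)` plays the role of t0.

Ages from scale readings are the pooled arithmetic mean of all
(reader × scale) annulus counts, plus the fraction of the year elapsed
since the nominal April 1 hatching date (fraction counted from the most
recent anniversary on or before capture, so it is always in [0, 1)).
Cohort classes are `floor(age)`, matching the "0+ … 7+" labelling.

## Frequentist fitting

Levenberg–Marquardt least squares with analytic residual Jacobians.
The von Bertalanffy SSE surface is multimodal under weak designs, so
fits multi-start from `L∞ = 1.1·max(length)`, `K ∈ {0.1, 0.3, 0.6}`,
`t0 = 0` (plus any user start) and keep the lowest SSE. Parameters are
deliberately unconstrained by default: on samples lacking old fish the
asymptote legitimately runs away, and hiding that behind box
constraints would mask a data problem (a bounded mode exists for
production use). Convergence tolerance is 1e−8 on the relative SSE
change, 500 iteration-equivalents per start. A fit is flagged
non-converged when the optimizer fails or when any parameter's Wald SE
exceeds twice its estimate — the signature of an unidentifiable design
such as recapture intervals all near zero.

95% intervals: profile likelihood by default (the profiled SSE compared
against an F(1, n−p) cut-off, inverted by bracketing + Brent), falling
back to Wald t-intervals with a recorded warning when the profile
cannot be bracketed. Both methods are exposed; on zero-residual data
intervals collapse to the point estimate.

## Bayesian fitting

Priors for L∞, K (and t0 for the age-based model) are normal with mean
and sample SD taken column-wise from a packaged table of eleven
published growth studies of the species from other European regions
(means: L∞ 445.50 mm, K 0.286/yr, t0 0.171 yr). L∞ and K are truncated
positive; t0 is untruncated because published values include negatives.
The column-SD reading of "spread across studies" is one of two
defensible choices; the prior builder accepts any table, so a wider
prior is one argument away. σ gets a weakly informative
half-Normal(0, 50 mm) prior. The Fabens model ignores the t0 column.

Sampling is an adaptive random-walk Metropolis written for this
package: a joint Gaussian proposal whose per-parameter scales follow
running posterior variances (Welford) and whose global scale is tuned
by Robbins–Monro toward ≈0.30 acceptance, adapting during burn-in only
so the post-burn-in chain is a valid fixed-kernel MCMC. The default
schedule is 50,000 iterations, 25,000 burn-in, thinning 10 — exactly
2,500 retained draws per chain — with 4 chains. Split-R̂ and ESS are
computed via arviz; R̂ > 1.05 surfaces as a warning, not an error.
Point estimates are posterior medians (means also reported); intervals
are equal-tailed quantiles.

## ELEFAN

Per-fish lengths are binned to 10-mm classes (`[mid − w/2, mid + w/2)`,
lower-inclusive, midpoints on the (j+½)·w grid). Each date's histogram
is restructured with the moving-average ratio recipe: (1) MA over 5
bins, edge windows averaging over the bins that exist (so a flat
histogram scores zero everywhere); (2) score = count/MA − 1 where
MA > 0, else 0; (3) isolated-peak de-emphasis by `1 − nz/(w−1)` with nz
the zero-count bins among the w−1 nearest neighbours; (4) negatives
rescaled so positive and negative sums cancel per date, floored at −1.
Because rescaling can push values through the floor, a short
fixed-point loop (rescale the non-floored negatives, floor, repeat)
keeps both the floor and the zero-sum contract exact; when the positive
sum exceeds the total negative capacity the zero-sum contract is
unattainable and the negatives simply saturate at −1.

A candidate (L∞, K, t_anchor) defines one cohort curve per birth year,
`L(t) = L∞(1 − e^(−K(t − (year + t_anchor))))`. Birth years extend
*before* the survey span, back to the age at which a curve reaches the
top occupied bin (older fish would otherwise be untraceable), and each
curve is followed only until it reaches min(top bin edge, 0.95·L∞):
past that point the whole family piles into the same asymptotic bins,
carrying no cohort information while accumulating trough penalties.
The (date, bin) cells crossed by the family are deduplicated; ESP
credits each peak (maximal run of positive bins within a date) once
with its full summed score when any curve crosses it — once across the
whole family, which is what guarantees ESP ≤ ASP — and adds the scores
of crossed non-positive cells. ASP is the summed score of all peaks;
the fitness is the canonical Rn = 10^(ESP/ASP)/10 ∈ (0, 1].

Optimisation is a real-coded genetic algorithm: tournament selection
(size 3), BLX-0.5 blend crossover (p = 0.8), Gaussian mutation
(p = 0.1 per gene, SD 10% of the parameter range), elitism of one —
hence a non-decreasing best fitness. Defaults: population 50,
100 generations; search box `L∞ ∈ (0.8, 1.5)·Lmax`, `K ∈ (0.01, 1)`,
`t_anchor ∈ [0, 1)`. Bootstrap intervals resample fish (not bins)
within each sampling date with replacement, rebin, and rerun the GA per
replicate (default B = 200; the analysis driver uses B = 100 with a
reduced 30×40 GA per replicate); intervals are equal-tailed
percentiles, widened if needed to include the full-data point estimate.
Replicates without peaks are dropped with a warning; more than 20%
drops is an error.

## Synthetic data

The generators emulate a nine-year river monitoring programme on an
alpine grayling population and are the test bed for every estimator.

* **Age-at-length** (n = 122): integer ages on 0..7 with truncated
  geometric weights (decay 0.65/yr — most fish aged 0–3), plus the
  April→mid-September fraction; lengths on the curve plus
  Normal(0, σ = 35 mm), redrawn positive. The 35-mm σ reproduces the
  very wide within-cohort ranges such data show (ageing error folded
  into length spread).
* **Mark-recapture** (n = 121): marking lengths uniform on
  (119, 503) mm truncated below L∞, elapsed times uniform on
  (0.09, 1.01) yr, recapture lengths from the Fabens expectation plus
  Normal(0, σ = 15 mm).
* **Length-frequency**: 25 sampling events from autumn 2013 to spring
  2022 (spring/summer/autumn most years, winter events in 2019 and
  2021, only summer in 2020). Each living cohort (hatched April 1,
  ages to 20) contributes Poisson-many fish with lengths
  Normal(cohort mean, 15 mm), abundance 600 recruits/yr thinned by
  annual survival 0.6, capture probability 0.12 scaled by logistic
  size selectivity (50% at 80 mm, slope 15 mm) so the catch is
  dominated by 100–300 mm fish and >400 mm fish are rare; lengths are
  rounded to the centimetre. Survival 0.6 (not lower) keeps the upper
  length classes occupied at all, as real surveys of this population
  are; the expected total catch is ≈1,840 fish.

What the generators do **not** emulate: ageing error as a separate
process (it is folded into σ), individual growth heterogeneity beyond
the cohort SD, tag loss, movement between river sections, year-effect
recruitment pulses, and seasonal growth oscillation. Passing recovery
tests therefore show the estimators are correct *given the model*, not
that the model captures every feature of field data.

## Known limitations

* Under slow growth (K ≈ 0.12) with catches dominated by ages 0–4, the
  Rn surface has a long ridge along constant L∞·K: curves that stop
  early (small L∞) avoid the sparsely sampled upper-length region,
  while overshooting curves (large L∞, small K) thread noise peaks in
  the merged old-age hump. Point estimates then ride this ridge — the
  same mechanism field studies report when large fish are scarce — and
  should be read together with the bootstrap intervals, which are
  honest about it. The GA recovers cleanly when cohorts are tight and
  growth fast (see the test suite's clean-survey recovery test).
* Profile CIs assume a locally quadratic-enough SSE; on pathological
  fits they fall back to Wald with a warning.
* The Metropolis sampler is adequate for these 3–4 parameter
  posteriors; it makes no claim to efficiency on stiffer models.
* The length-frequency reader accepts per-fish rows only; pre-binned
  matrices go through the matrix CSV reader.
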