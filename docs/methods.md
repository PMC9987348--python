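# Methods

## Model

Over an observed vocabulary of N types ranked 1..N by descending frequency,
the Zipf–Mandelbrot probability mass function is

    p(r) = (r + β)^(−α) / Σ_{r'=1..N} (r' + β)^(−α)

with exponent α > 0 (steeper decay for larger α) and shift β ≥ 0 (flattens
the very top ranks; β = 0 recovers classic Zipf). The PMF is computed in
log space (`log-sum-exp` normalisation), so it is exact to 1e−12 for any
parameters the package accepts, including exponents in the hundreds where
linear-space computation underflows.

## Estimation

Parameters are estimated by maximum likelihood under a multinomial over the
observed ranks: `LL(α, β) = Σ_r f_obs(r) · log p(r)` with N equal to the
number of observed types. No unseen-type correction is applied — the object
being fitted is the observed rank-frequency distribution, not an underlying
infinite lexicon. The optimizer is bounded L-BFGS-B with a fixed multi-start
schedule (α₀ ∈ {0.8, 1.2, 1.6, 3, 10, 50} × β₀ ∈ {0.1, 1, 10, 100}), bounds
α ∈ (0.05, 200], β ∈ [0, 1000] (per-POS fits on function words genuinely
reach α ≈ 130, β ≈ 476), and ftol 1e−12. The relative tolerance is set
tighter than strictly needed because corpus log-likelihoods are O(1e7) and
a looser relative tolerance would leave β imprecise. The fit is
deterministic given the schedule; tests verify equality with an exhaustive
grid-search oracle within one grid step on small instances (the optimizer
restricted to the oracle's search box, since exactly geometric count
sequences push the unconstrained likelihood up the α, β → ∞ ridge where the
model degenerates toward a geometric distribution).

Ranks are assigned by descending count with ties broken by a seeded uniform
permutation within each tie block. Because tied words share a count, the
rank→frequency vector — and therefore every fitted parameter — is invariant
to the tie-break seed; the seed is recorded in outputs for audit anyway.

## Goodness of fit

The headline statistic is the Pearson correlation between the observed and
the expected frequency vectors (expected = PMF × token total), not between
frequency and rank; the same correlation on log-log scale is reported
alongside, restricted to ranks with positive observed frequency.

**Degenerate fits.** When α·log(1+β) exceeds ~708.4, the unnormalised
weights (r+β)^(−α) underflow normal double precision; any linear-space
pipeline then assigns probability one to rank 1 and zero elsewhere, and the
observed/expected correlation stops being meaningful. Fits in this regime
(and any fit with p(1) > 1 − 1e−9) are flagged `degenerate=True` and report
no correlations — this mirrors how such fits behave in practice for
preposition distributions with tiny vocabularies, while the package's own
PMF remains mathematically correct in log space. The flag never triggers
for α ≤ 2 with β ≤ 1000.

**Split-half estimator.** To decouple rank from frequency, each token is
assigned independently to half A or half B with probability 1/2; ranks are
computed from half A and frequencies of the rank-ordered words are taken
from half B. Words missing from one half are dropped by default and the
intersection is re-ranked consecutively (configurable to zero-fill
instead — the choice is not settled in the literature). The resulting
rank-frequency pairs are not monotone, so the fit runs on the raw pairs
rather than through the ranking invariant.

**Clauset-style alternative.** As a cross-check diagnostic (not the
headline method, which presumes a *near*-power-law rather than a true one),
a discrete power-law is fitted over frequency values: for each candidate
threshold x_min among observed values, the exponent is estimated by MLE
with Hurwitz-zeta normalisation and the tail KS distance measured; the
returned fit minimises the KS distance. Candidates whose tail holds fewer
than 10 values are skipped. The value-domain formulation is standard; a
rank-domain variant is not implemented.

## Subsampling and development

Conversationally continuous samples concatenate whole transcripts in
ordering-key order (lexicographic corpus/path by default; the original
file order is not recoverable from published tables) until a target size is
reached; transcripts are never split mid-file. Stability curves draw random
continuous samples (transcripts shuffled per replicate, each read from the
beginning) of 5k..100k tokens, ten replicates per size by default.

Age bins tile child age in six-month steps; a transcript's age is the
target child's age at recording, bins pool all corpora of a language by
simple token-weighted pooling, and bins below 50,000 tokens are summarized
but not fitted (below that size the exponent estimate is still visibly
rising with sample size). Age trends are mixed-effects regressions of the
per-bin response (α or Pearson r) on bin start age in months, centred, with
a by-language random intercept and age slope, simplifying on convergence
failure (intercept-only, then OLS; the structure actually used is named in
the output). p-values are Wald approximations.

## Part of speech

Tokens are classified per occurrence by their aligned `%mor` category code
(exact codes, no subcategory absorption; the default profile maps
n/v/adj/prep, editable per language). Tag/token alignment is positional;
utterances whose morphology tier does not align are skipped and counted.
Mistagged types are removed via plain-text exclusion lists — the surrogate
for manual cleaning by native speakers — and never reassigned to another
category; the error rate is excluded types over types extracted.
Categories with fewer than 10 types are summarized but not fitted.

## Synthetic corpora

The generator draws tokens i.i.d. from the Zipf–Mandelbrot PMF over a fixed
vocabulary (rank r ↦ word "w…r", injective, so the true rank is
recoverable), packs them into utterances (geometric length, mean 6 — a
plumbing choice nothing downstream depends on) and transcripts (default
2,000 tokens) with `@ID` headers carrying a configurable age schedule,
optionally emits a child speaker (default 10% of utterances) to exercise
adult filtering, and optionally emits `%mor` tiers from a per-category
(α, β, vocabulary, token-share) profile. Default generating parameters
(α = 1.38, β = 9.86) are the cross-language means reported for
child-directed speech; a uniform-distribution generator provides the
baseline condition used in lab learning studies. All randomness flows from
the single spec seed.

What a green test establishes, and what it does not: the generator matches
the analyses' *distributional* assumptions exactly (i.i.d. sampling from
the fitted family), so recovery tests validate the estimation machinery,
not the linguistics. Real speech is bursty, repetitive (variation sets,
frequent frames) and topic-dependent; none of that is modelled, and fits
on real corpora inherit whatever dependence structure those properties
induce.

## Numerical choices and edge cases

- PMF normalisation error < 1e−12 up to N = 10^6 (log-sum-exp).
- Empty frequency tables cannot be ranked or summarized (error); empty
  token streams yield empty tables.
- Fractional counts are accepted throughout (relative-frequency lists).
- Uniform-ish inputs fit with α near the lower bound and low/absent
  correlations — reported, not raised.
- ANOVA requires ≥ 2 groups and some within-group variance; the F statistic
  is undefined otherwise (error).
- Unknown speaker roles are kept (conservative inclusion of adults);
  sibling/playmate roles are excluded by default with a config switch,
  since the literature specifies only that child utterances were removed.
- Word forms are lower-cased before counting by default (sentence-initial
  capitalisation would otherwise split types); configurable off.
- Repetition markers (`[x N]`) are stripped, not expanded.

## Known limitations

- CHAT support is a pragmatic subset (headers, main tiers, %mor); overlap
  markers, timing and phonological tiers are ignored.
- Orthographic word definition: "dog" and "dog's" are distinct types, which
  inflates type counts more in morphologically rich languages.
- The split-half intersection rule slightly biases toward well-attested
  words in small corpora.
- Mixed-model denominator degrees of freedom use the Wald approximation,
  not Satterthwaite/Kenward-Roger.
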