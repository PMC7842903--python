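# Methods

`predread` implements a complete pipeline for estimating word
predictability from two kinds of sources — human cloze responses and
corpus-trained language models — and for quantifying what each source
contributes to eye-fixation durations during sentence reading.  This note
documents the models, the estimation choices, and what the synthetic data
do and do not establish.

## Probability sources

### Cloze aggregation

In the cumulative cloze task every participant guesses each word of a
sentence in turn, seeing the actual word after each guess.  The lexical
probability of a target is the share of guesses matching it exactly
(orthographic match after lower-casing and Unicode NFC).  Because
probabilities are analysed on the logit scale, the two boundary cases are
smoothed symmetrically for a word with n guesses:

* zero matches → 1/(2n) (flagged `smoothed`);
* all matches → 1 − 1/(2n).

The lower replacement is the standard treatment for zero cloze
probabilities; the upper cap is its mirror image, required because the
logit is undefined at 1.  Sentence-initial words receive no cloze record
at all — with no context the task is uninformative about them — and this
is enforced in the aggregation layer, not left to analysis code.

### Kneser-Ney n-gram model

The corpus-based reference model is an interpolated Kneser-Ney n-gram with
a single fixed absolute discount d (default 0.75, the conventional value;
count-of-count estimated discounts are deliberately out of scope).  The
highest order uses raw counts, lower orders use continuation counts, and
the recursion bottoms out in a uniform distribution over the vocabulary
plus one unknown-word (UNK) bucket, so every conditional distribution is
strictly positive and sums to one.  Vocabulary is capped to the most
frequent forms; everything else maps to UNK.  Sentences are padded with
begin markers; begin markers are never predicted.

Models serialize to ARPA.  Interpolated KN admits an exact backoff
representation (stored probabilities are the interpolated ones, backoff
weights are the interpolation weights), so a written-and-reloaded model
reproduces the original distributions to floating-point precision; the
test suite verifies this, and separately checks the trained model against
a brute-force oracle coded directly from the defining equations.

Evaluation follows the usual two metrics: accuracy (the target is the
argmax of the predicted distribution; ties break to the lexicographically
smallest form for determinism) and perplexity exp(−mean log p).
Sentence-initial tokens and punctuation are excluded from scoring.

External models (e.g. a neural language model) plug in through a
JSON-lines table of per-position distributions (top-K mass plus an
explicit tail mass); nothing downstream distinguishes them from the
built-in n-gram.

### Morphosyntactic probabilities

Both sources define a probability mass function over candidate
continuations, and all derived probabilities are computed identically from
that mass:

* word-class probability — total mass on candidates sharing a word class
  with the target;
* feature probability (gender/number/case for nouns; tense plus number and
  person or gender for finite verbs, depending on tense) — total mass on
  candidates matching the target's feature value *within the same word
  class*: a noun's singular does not match a verb's singular, because noun
  and verb feature probabilities are meaningful only class-internally.

Morphological ambiguity is handled permissively: an ambiguous form matches
if any of its readings does, with no mass splitting.  Feature
probabilities use the full candidate mass as denominator by default; a
`renormalize_within_class` flag divides by the class-matching mass
instead.  The unnormalized default is the single most result-sensitive
choice in this layer and is therefore exposed as a flag rather than a
constant.  Zero/one-boundary handling reuses the cloze smoothing rule on
the cloze side and a fixed floor of 1e-9 on the corpus side.  Truncated
corpus distributions treat the tail mass as non-matching.

All comparisons happen on the half-logit scale q = 0.5·ln(p/(1−p)), for
both sources alike.  Pearson correlations are computed on logits (with or
without the smoothed-zero records); Spearman correlations on raw
probabilities with smoothed zeros included, since only ranks matter there.
The cumulative-correlation curve reports the Pearson coefficient over all
words whose cloze probability lies below a moving threshold, always
excluding smoothed zeros; points supported by fewer than three pairs are
omitted.

## Reading measures

Four measures are derived per (participant, word) from the fixation
sequence of a trial: first fixation duration (FFD), gaze duration (GD,
the sum of first-pass fixations), total reading time (TT, the sum of all
fixations), and single fixation duration (SFD, defined only when the word
received exactly one fixation in the whole trial).  The first pass is the
maximal initial run of consecutive fixations on the word starting at its
first fixation; it ends as soon as any other word is fixated, regardless
of direction.  This is the standard convention; other conventions exist,
and this one is fixed here explicitly.

Exclusion rules operate in two stages: the correlation stage drops
sentence-initial words; the eye-tracking stage additionally drops
sentence-final words (end-of-sentence wrap-up).  Applied to a 144-sentence
stimulus set of 1,362 words these rules leave 1,218 and 1,074 words
respectively — an exact bookkeeping identity the acceptance script
recomputes.

The analysis table pairs each included word's measures with the duration
predictors: centered-and-scaled word length and log10 frequency-per-million
(floor 0.5 per million) for the previous, current, and next word; logit
probabilities of those three words per source; incoming saccade amplitude,
landing position, and a base-form flag for the current word; word-class
probabilities for the current and next word; and feature probabilities for
the current word.  Neighbour predictors are taken at the raw sentence
positions — exclusions apply to the dependent word, not its neighbours.
One consequence is handled explicitly: a word at position 2 would need the
cloze probability of the sentence-initial word, which by construction does
not exist, so such rows are dropped for every source alike (keeping the
cloze and corpus model rows identical for later comparisons).  Any other
missing predictor is treated as a data defect and raises an error naming
the word.

## Duration models

Each model regresses log duration on one tier of predictors with crossed
varying intercepts for participants, sentences, and words (words grouped
by form, so repeated forms share an intercept).  Tiers are strictly
nested: baseline (lexical probabilities plus covariates) ⊂ word-class ⊂
one of three feature tiers fitted on the relevant subsets — noun targets,
present/future finite verbs (which mark person), or past-tense finite
verbs (which mark gender).  Predictors that are constant on a subset
(e.g. the base-form flag among finite verbs) are dropped from that design
rather than allowed to make it singular.

### Estimation

The contract for a fit is: coefficient estimates with 95% intervals,
variance components, per-row residuals, and pointwise predictive density
contributions.  The estimation backend is a maximum-likelihood crossed
random-intercepts Gaussian LMM written for this package: the marginal
covariance is handled through the Woodbury identity, so each likelihood
evaluation costs O(q³) in the total number of group levels (a few hundred
here) rather than anything in the number of rows; the three or four
variance parameters are optimized by Nelder-Mead on the log scale, with
fixed effects profiled out by GLS.  Intervals are Wald 95% intervals from
(X'V⁻¹X)⁻¹; group effects are BLUPs.  The procedure is deterministic —
identical data and specification reproduce identical estimates to machine
precision — which the suite asserts directly.  With the row counts used
here (thousands of rows, ≥ 10 levels per factor) Wald intervals are well
calibrated; the suite's null simulations measure ≈ 95% empirical coverage.

Residuals are conditional (observation minus fixed effects and BLUPs) and
live on the log scale, consistent with the lognormal likelihood.

### k-fold comparison

Two specifications sharing a dependent measure are compared on the
intersection of their usable rows, partitioned into k (default 10) seeded
random folds at the row level.  Each model is refitted k times (fold
refits warm-start from the full-data variance estimates) and scored on its
held-out rows by the plug-in predictive density: conditional on BLUPs for
group levels seen in training, with the group variance added to the
predictive variance for unseen levels.  The criterion difference is
reported on the deviance scale, ΔIC = −2·Δelpd (negative favours model A),
together with the raw elpd difference; the standard error is the usual
√(n·var) of the pointwise differences, and |ΔIC/SE| ≥ 2 is flagged as a
reliable difference.  Identical specifications tie at exactly zero.

### Residual complementarity

To ask whether two probability sources explain the same variance, the
residuals of a model fitted with one source become the dependent variable
of a second model whose predictors are the other source's probability
columns for the same tier (three lexical columns at baseline, five with
word class, eight with features), keeping the same varying intercepts.  A
complementary predictor is "reliable" when its 95% interval excludes
zero.  Zero-variance predictors are reported as degenerate with a zero
estimate rather than entering the design.

## Synthetic data

The generator produces a complete, internally consistent study from one
root seed (independent named substreams per stage, byte-identical
regeneration):

* **Lexicon** — pseudo-word forms tagged with one or (at rate 0.15) two
  morphological readings; class mixture approximating written-corpus
  shares (37% nouns, 14% adjectives, 15% finite verbs, …).
* **Stimuli** — 144 sentences of 5–13 words (uniform, mean 9) sampled from
  a first-order Markov chain over the lexicon.  A first-order chain is
  used deliberately: its exact conditional distributions are storable and
  queryable, giving every later stage a ground truth to be checked
  against.
* **Cloze** — per non-initial word, 20 + negative-binomial (mean 27,
  r = 2) guesses clipped to 151 — i.e. 20–151 with mean ≈ 47, with the
  overdispersion that self-selected participation produces — drawn from
  the true distribution, optionally reweighted by exp(−bias·length) to
  emulate the avoidance of long words in typed responses.
* **Corpus source** — each true distribution resampled from a Dirichlet
  with concentration parameter c (default 200): mean-preserving estimation
  error that vanishes as c → ∞, plus a small explicit tail bucket.
* **Reading** — per word, the first-pass gaze duration is lognormal:
  log GD = intercept (5.4 ≈ 221 ms) + Σβ·x + participant + sentence + word
  intercepts (SDs 0.12/0.06/0.08) + residual (SD 0.30), with a default
  true predictability effect β_q = −0.05 log-ms per logit unit on the
  cloze scale.  GD is realized as one or two consecutive fixations
  (refixation probability increasing with word length); an optional
  revisit is inserted after the next word's completed first pass and
  contributes to total time only.  Skipping probability increases with
  predictability, the empirically observed direction.  Landing positions
  are uniform within the word; saccade amplitudes are character distances
  between consecutive fixation locations.  These oculomotor rules are test
  scaffolding with documented parameters, not claims about eye-movement
  control.

### What the synthetic data show — and what they do not

Passing the suite establishes that the *computations* are correct: the
n-gram equals an independent oracle, the probability derivations are
source-symmetric, the measures match hand-traced definitions, the
hierarchical model recovers known coefficients with calibrated intervals,
and the comparison machinery detects an independently injected second
probability source while staying silent when none exists.  It does not
establish linguistic claims: the sentences are not grammatical, cloze
response biases beyond word length are absent, and the corpus distortion
is mean-preserving in probability space — one visible consequence is that
the synthetic cumulative-correlation curve *rises* with the threshold,
whereas real cloze/corpus data can show the opposite shape; that shape
depends on how estimation error varies with predictability, which the
default generator does not try to imitate.

## Numerical choices

* KN discount 0.75 everywhere; tokenization = lower-case, punctuation
  split into separate tokens and excluded from evaluation.
* Argmax ties break lexicographically; fold assignment is row-level and
  seeded; all generator substreams derive from one root seed.
* Optimizer: Nelder-Mead, xatol 1e-5, fatol 1e-7 on the negative log
  likelihood — two orders tighter than any quantity reported.
* Corpus-side probability floor 1e-9; cloze-side smoothing 1/(2n) and cap
  1 − 1/(2n).
* Logit uses the 0.5 factor for both sources, so the two scales remain
  directly comparable.

## Known limitations

* The duration models are estimated by maximum likelihood with Wald
  intervals rather than full posterior inference; with the group and row
  counts used here the difference is negligible for estimates and interval
  coverage, but genuinely weak-data regimes (a factor with two or three
  levels) would warrant a Bayesian treatment.
* Variance-component estimates at their boundary (a factor contributing
  nothing) are reported as very small positive numbers, not flagged
  specially.
* The k-fold predictive density is a plug-in approximation: it ignores
  estimation uncertainty in the BLUPs and fixed effects.  Comparisons are
  therefore slightly anti-conservative in absolute terms, but both models
  in a pair are treated identically.
* No morphological analyser is bundled; lexica are static TSV files, and
  context-free ambiguity is preserved rather than resolved in context.
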