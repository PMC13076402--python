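# Methods

`affectnorm` estimates word valence — the positivity/negativity of a
word's affective meaning, expressed on a seven-point scale from −3
(very negative) to +3 (very positive) — for words that no human has
rated, by reading it off the geometry of a word-embedding space. This
note documents the models, the default parameters and why they are
what they are, the synthetic data the package tests itself on, and the
numerical choices a maintainer would want written down.

## Estimators

**Semantic orientation.** Given a vector space model (VSM) and label
lists `l_p` (i prototypically positive words) and `l_n` (j
prototypically negative words), the raw score of a target word w is

    raw(w) = (1/i) Σ_p cos(w, l_p) − (1/j) Σ_n cos(w, l_n),

the difference of mean cosine similarities to the two anchor sets. The
seven-point value is `3 · raw(w)` clipped to [−3, 3]. Note the
difference of two means of cosines is mathematically bounded by
[−2, 2], not [−1, 1]; in practice scores rarely leave [−1, 1] because
a word cannot be simultaneously anti-aligned with one pole and
aligned with the other across many anchors. Clipping (with a warning,
and a count of clip events in batch mode) keeps the map total while
preserving the published scale bound. Words on the label lists are
still scorable as targets — there is no self-exclusion, so an anchor
word's own pole mean contains cos(w, w) = 1. This matters for
evaluation design (see "Held-out evaluation" below).

**kNN extrapolation.** The alternative estimator assigns w the
unweighted mean human rating of its k nearest rated words by cosine
(the target itself never counts as its own neighbour; ties in
similarity are broken by vocabulary order for determinism). k
defaults to 30 — a middle value for word-level semantic-norm
extrapolation, exposed as a flag since the method's originators tuned
k per dataset. A similarity-weighted mean is available behind
`weighted=True`, default off: the unweighted mean is the plainest
reading of the method and keeps the estimate inside the neighbours'
rating range.

Both estimators use exact-match vocabulary lookup. Subword
composition for out-of-vocabulary words (a property of some embedding
training tools, not of the vectors themselves) is not reimplemented;
OOV targets go to a skip report, OOV anchors are dropped from their
pole with a warning, and an entirely unresolvable pole is an error.
Case-folding fallback exists (`VectorStore.resolve`) but is off by
default because German nouns are capitalized and folding conflates
distinct lemmas.

## Label-list extraction

Anchors are drawn from a rating summary by rank averaging: rank words
by mean valence descending (1 = most positive) and independently by
natural-log word frequency descending (1 = most frequent), with
midranks for ties; average the two ranks; the k = 60 best form the
positive list. Frequency enters so that anchors are words whose
vectors are well estimated (frequent words have more training
evidence), not merely extreme ones.

The negative list has two modes because the procedure's published
description fixes only the positive pole:

* `literal` (default): the k *worst* average ranks. This is the
  verbatim "top and bottom k" reading, but since the frequency
  ranking is shared, the bottom of the averaged list favours words
  that are both negative and *rare*.
* `mirrored`: re-rank with valence ascending (1 = most negative),
  keep the frequency ranking as is, take the k best. This treats the
  negative pole symmetrically to the positive one — most negative
  *and* most frequent.

Ties exactly at a cutoff break alphabetically; the whole extraction
is deterministic. Lists are drawn only from words with a positive
entry in the frequency table (missing-frequency words are dropped
with a warning, never imputed), and an overlap between the two lists
(possible on degenerate, nearly-tied summaries) is a hard error
prompting a larger vocabulary.

The database manipulations used in the robustness analyses are
first-class operations: `subset_small` (uniform random m-word
subsample, seeded), `subset_bias` (drop words with mean valence below
a cutoff, default −1 — an artificial positivity bias; the boundary
value is kept), and their composition.

## Rating panels and reliability

Rating databases are long-format (rater, word, response) tables on a
bounded integer scale with an explicit unknown marker. Cleaning
applies, in a single pass with all fractions computed on the incoming
database: first remove words marked unknown by more than 50% of their
raters, then remove raters whose modal response exceeds 60% of their
known answers or who knew fewer than 50% of their assigned words.
The pass is not iterated to a fixed point — the rules are applied
once, in this order, so one final count results.

Responses on a child 5-point scale are mapped onto [−3, 3] by the
affine map r ↦ −3 + (r − min)·6/(max − min); unknowns pass through
untouched and never enter any mean.

Reliability of the per-word mean ratings is the one-way
random-effects, average-measure intraclass correlation computed from
the one-way ANOVA decomposition over words:
ICC = (MSB − MSW)/MSB. The one-way (rather than two-way) family is
the right model for panels in which each rater sees a different
random word subset, so rater cannot be crossed with word; the
average-measure form is used because the object whose reliability
matters is the word *mean*, and for unbalanced panels the mean number
of ratings per word is absorbed through MSB. Spearman–Brown
(`k·r / (1 + (k−1)·r)`) extrapolates a reliability to a k-fold longer
panel, and `disattenuate` divides an observed correlation by
`sqrt(rel_x · rel_y)`, clipping to ±1 with a warning. Evaluation
corrects *correlations* (treating computed norms as error-free, so
only the human-rating reliability enters as 1/sqrt(rel)); rescaling
the ratings themselves is deliberately not done — both operations are
exposed, correction-of-correlations is the default because it leaves
the rating scale intact. Sample SDs use the n−1 denominator
throughout.

## The lexical-decision validation model

Word-level mean reaction times validate a norm set by asking whether
it reproduces the *functional form* of the valence effect on lexical
processing. RTs are modelled on the natural-log scale (log-normal RTs;
natural log so that exp(intercept) is a milliseconds prediction) in
two OLS steps:

* Step 1 — controls: z-scored word length (letters), z-scored
  log(frequency per million + 1), z-scored OLD20;
* Step 2 — adds z-scored valence and its square. The square is built
  from the z-scored valence and left unscaled, so "valence 2 SD above
  the mean" is literally z = 2 and the contrast arithmetic stays
  transparent.

Frequency is log-transformed before scaling (+1 guards zero
frequencies) because word-frequency effects on RT are
logarithmic. The Step-2 variance increment is tested with
F = (ΔR²/q) / ((1 − R²_full)/(n − p_full)), q = 2, df = (2, n − 6).
Accuracy is carried in the dataset but never modelled.

OLD20 — the mean Levenshtein distance from a word to its 20 nearest
orthographic neighbours in a reference lexicon — is computed with
edit distances from edlib (global alignment, unit costs), the word
itself excluded; lexica smaller than 21 entries error unless
`allow_fewer` is set, in which case all available neighbours are
averaged.

Contrasts at valence z ∈ {−2, 0, +2} (controls at their means) are
c(z) = b_lin·z + b_quad·z², with standard errors from the coefficient
covariance (the contrast is linear in the coefficients, so the delta
method is exact), and predictions back-transformed by exponentiation.
`compare_effect_shapes` lines up several norm conditions against a
reference fit on the same words and flags a condition as "captures
quadratic positivity effect" when its quadratic term is reliably
negative, its −2 SD contrast is not significant, and its +2 SD
contrast is significantly negative (faster) — the signature of a
positivity effect without a negativity effect.

## The synthetic world

The generator produces everything the pipeline consumes without any
restricted corpus: a lexicon of unique random lowercase strings of
3–10 letters (so Levenshtein structure is non-degenerate), a true
valence per word, Zipf frequencies, an embedding, rater panels, and
RT data. All generators are pure functions of (parameters, seed).

**Embedding model.** Each word's vector is

    v_w = signal · (val_w / 3) · u  +  c · g  +  ε,

with u a random unit "valence axis", g a fixed unit direction
orthogonal to u shared by all words, and ε isotropic Gaussian noise
(sd `noise_sd` per coordinate). The shared component (default
c = 0.5) deserves explanation: real distributional spaces are not
isotropic — their mean pairwise cosine is positive (all words share
common-frequency directions; "hubness"). Without it, a near-neutral
anchor word would be, on average, *orthogonal* to everything, and the
central mechanism by which positivity-biased label lists distort
norms — near-neutral negative anchors being over-similar to all
words, inflating the negative term and shifting the whole estimate
distribution leftward — could not arise. With c = 0.5 the mean
pairwise cosine is ≈ 0.1, realistic for word2vec-family spaces, and
the mechanism reproduces qualitatively.

Defaults mirror the study conditions: 600 words (the order of the
evaluation intersection), 50 dimensions (the child-space
dimensionality), signal 1, noise 0.2. True valence is uniform on
[−3, 3] ("full") or uniform on [−1, 3] ("positivity_biased", the
right-shifted child-vocabulary case). Frequencies are Zipf with
exponent 1, permuted at random so frequency and valence are
independent by construction. The canonical test world is
`canonical_world()` = these defaults at seed 42, regenerated
bit-for-bit rather than shipped as a rendered file.

**Rating panels.** Each of `n_raters` (default 100) raters receives a
random subset of `items_per_rater` (default 90) words; the response
is true valence plus Gaussian rater noise (default sd 0.6 on the
[−3, 3] scale), affinely mapped to the requested integer scale
(default the 5-point child scale), rounded to the nearest point,
clipped, with unknowns injected at `unknown_rate` (default 5% in the
paperlike preset). The defaults give ≈ 15 ratings per word, the
coverage of the child rating study, and a panel ICC in the high .90s
— the simulated raters are better behaved than real children, which
is fine for the pipeline tests (reliability enters the analyses as a
measured quantity, not an assumption).

**RT data.** log RT = b0 + b1·z(length) + b2·z(log freq) +
b3·z(OLD20) + b4·z(val) + b5·z(val)² + N(0, σ). The default
coefficients are the adult human-rating values (6.353, 0.020, −0.023,
0.001, −0.010, −0.006 on the natural-log scale) and σ = 0.05, chosen
so the simulated coefficient standard errors at n = 535 (~0.002–
0.003) match the magnitude of the published adult fits. Lengths are
the lexicon's own letter counts; OLD20 is computed from the synthetic
lexicon and cached on the world (it depends only on the lexicon, so
replications that resample residual noise reuse it).

**What the synthetic world does not emulate** — and hence what
passing tests do not show about real data: semantic clustering
(valence is the *only* planted structure; real spaces entangle
valence with topic, concreteness, register), German morphology and
compounding, non-linear valence geometry (the planted axis makes
orientation scores monotone in truth by construction; the real
question of whether cosines track valence at all is untestable here),
heavy-tailed rater behaviour, and item-level RT variance structure.
The synthetic bias-propagation effect is also much smaller than the
published real-data drop (r ≈ .74 → .44), precisely because a planted
linear axis is forgiving: truncated anchors still point the right
way. The package demonstrates the *mechanism* and the *machinery*,
not the real-world effect sizes.

## Held-out evaluation

Because the orientation estimator does not self-exclude, anchor words
partially score themselves, and anchors are by construction extreme
on the rated summary. Recovery correlations on the synthetic world
are therefore reported on held-out words (targets not on the label
list) wherever the question is "does the estimator generalize":
with no planted signal the all-words correlation stays spuriously
positive (~0.13–0.24) through this leak alone, while the held-out
correlation is ~0 as it should be. Comparisons *between* label
conditions (full vs biased) are made on the full shared word set so
both conditions score identical words.

## Numerical choices and degenerate inputs

* Cosines are computed on raw vectors with cached norms; zero vectors
  are rejected at store construction.
* KDE mode counting (`distribution_summary`) uses a Gaussian kernel,
  Silverman bandwidth, and a fixed 512-point grid over [min, max];
  boundary-monotone densities count as one mode; zero-variance input
  reports sd 0, skewness 0, one mode.
* A perfect Step-2 fit (zero residual variance) reports F = ∞, p = 0
  rather than dividing by zero.
* `extract_labels` sorts the eligible vocabulary alphabetically
  before stable-sorting on rank averages, which is what makes the
  cutoff tie-break alphabetical and the output order-independent.
* Exclusion reports satisfy n_after = n_before − |removed| for words
  and raters by construction, and the operation is invariant to input
  row order.
* Seeds: every generator takes an explicit integer seed; nothing
  reads global RNG state.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
worlds at the study's own scale: 600-word/50-d worlds for the
recovery and bias analyses, 535 words for the RT regressions (100
replications for coefficient recovery, 500 for the null calibration
of the increment test, 200 for the shape-flag power check), 50-word
stores for estimator-vs-oracle agreement, and 50 random lexica for
OLD20-vs-oracle agreement. These sizes keep every oracle exhaustive
and every simulation replicable in seconds while matching the n at
which the published analyses operate.

## Known limitations

* Real-data results require resources that cannot ship with a
  package: embeddings trained on large licensed corpora and the
  published German rating and lexical-decision databases. The package
  reproduces the procedures and their qualitative behaviour on
  synthetic worlds; users supply their own vector files and rating
  tables for real analyses.
* Embedding training is out of scope: the package consumes word2vec
  text files, it does not produce them.
* The ICC variant is a documented choice (one-way, average-measure);
  panels collected under a fully crossed design would justify a
  two-way model instead.
* `literal` negative-pole extraction demonstrably favours rare
  negative words (see the six-word worked example, where a rare
  positive word can even land on the negative list); `mirrored` mode
  is the remedy but changes the published procedure, hence is not
  the default.
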