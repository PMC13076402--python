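# affectnorm

Bootstrapping affective word norms — valence, here — from semantic
vector spaces, for research on word processing in children and
adults.

Developmental psycholinguistics needs valence norms for far more
words than child rating studies can cover: existing child databases
span a few hundred words, while analyses of reading behaviour need
norms for whole vocabularies. `affectnorm` implements the standard
bootstrapping route and everything around it:

* **Semantic orientation** (Turney–Littman): the estimated valence of
  a word *w* is the difference of its mean cosine similarity to
  prototypically positive and negative *label words* in an embedding
  space,

  ```
  rating(w) = (1/i) Σₚ cos(w, lₚ) − (1/j) Σₙ cos(w, lₙ),
  ```

  rescaled to the seven-point scale [−3, 3]; plus the **Bestgen kNN**
  alternative (mean human rating of the k nearest rated neighbours).
* **Label-list extraction** from rating databases by the rank-average
  rule (valence rank + log-frequency rank), with literal and mirrored
  negative-pole modes, and the size/bias manipulations (random
  subsampling, positivity-bias truncation) used to probe what drives
  norm quality.
* **Rating-panel tooling**: long-format ingestion with unknown
  markers, word/rater exclusion rules, 5→7-point rescaling, one-way
  average-measure ICC, Spearman–Brown, disattenuation.
* **Evaluation**: correlation grids of every VSM × label-source
  combination against human references (optionally disattenuated),
  norm-table intercorrelations, distribution summaries with KDE mode
  counting.
* **Lexical-decision validation**: OLD20, the two-step blocked
  log-RT regression with linear + quadratic valence, the variance-
  increment F test, ±2 SD contrasts back-transformed to ms, and
  side-by-side shape comparison of norm conditions against a human
  reference.
* A **synthetic-world generator** (lexicon, embedding with a planted
  valence axis, rater panels, RT data) so the whole pipeline is
  testable without restricted corpora.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

`examples/bootstrap_norms.py` builds the canonical 600-word synthetic
world, simulates a child rating panel over it (~15 ratings/word on a
5-point scale), extracts 60+60 labels, and scores every word:

```
$ python examples/bootstrap_norms.py
words scored:            600
positive anchor example: 'ffynlhqta' (rated +2.70)
negative anchor example: 'lgdvci' (rated -2.80)
r(estimate, true valence), all words: 0.945
r(estimate, true valence), held-out:  0.932
```

The held-out correlation (words not on the label list) is the honest
recovery number: the orientation score, anchored only in 120
panel-rated words, reconstructs the planted valence of the other 480.

`examples/bias_manipulations.py` shows the mechanism that makes
child-derived label lists problematic — truncating the label source's
negative range (as child vocabularies implicitly do) drags the whole
estimate distribution leftward and degrades recovery, while merely
shrinking the database does not:

```
label source      r(truth)  est. mean  est. sd  modes
full                 0.945     +0.024    0.892      3
small (n=300)        0.943     -0.000    0.699      3
bias (>= -1)         0.942     -0.024    0.531      3
small + bias         0.939     -0.039    0.511      2
```

The other examples cover reliability estimation
(`rating_reliability.py`), the two estimators side by side
(`knn_vs_orientation.py`), the RT validation regression
(`ldt_regression.py`), and the full VSM × label-source design matrix
(`design_matrix.py`).

## Command line

A thin CLI wraps the library:

```sh
affectnorm simulate --preset paperlike --seed 42 --out world/
affectnorm extract-labels --ratings world/ratings.csv \
    --freqs world/frequencies.tsv --k 60 --out labels.json
affectnorm estimate --vectors world/vectors.txt --labels labels.json \
    --estimator tl --out norms.tsv
affectnorm evaluate --norms norms.tsv --ratings world/ratings.csv
affectnorm ldt --data world/ldt.tsv --out report.json
affectnorm run-matrix --config config.yaml --out out/
```

File formats are plain text throughout: word2vec-dialect vectors
(optionally gzipped), CSV/TSV rating and frequency tables, JSON label
lists.

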