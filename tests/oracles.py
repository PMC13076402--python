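"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so
they share no code path with what they check.
"""

import numpy as np


def cosine_naive(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.dot(a, b) / (np.sqrt(np.dot(a, a)) * np.sqrt(np.dot(b, b))))


def tl_naive(store, word, positive, negative):
    """Orientation score by per-pair cosine loops."""
    w = store.vector(word)
    pos = [cosine_naive(w, store.vector(p)) for p in positive]
    neg = [cosine_naive(w, store.vector(n)) for n in negative]
    return sum(pos) / len(pos) - sum(neg) / len(neg)


def knn_naive(store, word, means, k):
    """kNN extrapolation by exhaustive sort over all rated words."""
    sims = []
    for i, cand in enumerate(sorted(means,
                                    key=lambda c: store.words.index(c))):
        if cand == word:
            continue
        sims.append((-cosine_naive(store.vector(word), store.vector(cand)),
                     store.words.index(cand), cand))
    sims.sort()
    chosen = [c for _, _, c in sims[:k]]
    return float(np.mean([means[c] for c in chosen]))


def levenshtein_dp(a, b):
    """Textbook dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def old20_naive(word, lexicon, k=20):
    dists = sorted(levenshtein_dp(word, w) for w in lexicon if w != word)
    return float(np.mean(dists[:k]))


def ols_normal_equations(X, y):
    """Coefficients, R^2 and SEs straight from the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / ss_tot
    return beta, np.sqrt(np.diag(cov)), r2, cov


def anova_icc1k(groups):
    """Average-measure one-way ICC from explicit sums of squares.

    ``groups``: list of per-word response arrays.
    """
    allvals = np.concatenate(groups)
    grand = allvals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    msb = ssb / (len(groups) - 1)
    msw = ssw / (len(allvals) - len(groups))
    return (msb - msw) / msb


def pearson_naive(x, y):
    """Textbook covariance-formula correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
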