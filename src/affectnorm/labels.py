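"""Label-list extraction and rating-database manipulations.

Anchor ("label") lists of prototypically positive and negative words
are drawn from a rating summary by a rank-average rule: words are
ranked once by mean valence (descending) and once by log word
frequency (descending), the two ranks are averaged, and the k words
with the best (smallest) average rank form the positive list.  The
negative list is either the k words with the *worst* average rank
(``literal``) or the k best under a mirrored valence ranking
(``mirrored`` — most negative first, frequency ranked as before).

Also provided: the database manipulations used to probe what drives
norm quality — random down-sampling to a target size and truncation of
the negative valence range (an artificial positivity bias).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ratings import RatingSummary

__all__ = [
    "LabelList",
    "extract_labels",
    "subset_small",
    "subset_bias",
    "subset_small_bias",
    "load_frequencies",
    "save_labels",
    "load_labels",
]


@dataclass
class LabelList:
    """k positive + k negative prototype words with provenance."""

    positive: list[str]
    negative: list[str]
    k: int
    source: str = "synthetic"
    negative_mode: str = "literal"

    def __post_init__(self) -> None:
        if len(self.positive) != self.k or len(self.negative) != self.k:
            raise ValueError("positive and negative lists must both have length k")
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative lists overlap")


def load_frequencies(path) -> pd.Series:
    """Read a TSV ``word<TAB>freq_per_million`` into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["word", "freq_pm"]
    return df.set_index("word")["freq_pm"].astype(float)


def _as_freq_series(freqs) -> pd.Series:
    if isinstance(freqs, pd.Series):
        return freqs.astype(float)
    return pd.Series(freqs, dtype=float)


def extract_labels(summary: RatingSummary, freqs, k: int = 60,
                   negative_mode: str = "literal",
                   source: str | None = None) -> LabelList:
    """Rank-average selection of k positive and k negative label words.

    Only words present in both the summary and the frequency table with
    positive frequency are eligible; others are dropped with a warning.
    Ties get midranks; a tie exactly at the cutoff is broken
    alphabetically.
    """
    if negative_mode not in ("literal", "mirrored"):
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    freqs = _as_freq_series(freqs)
    means = summary.table["mean"]
    eligible = means.index.intersection(freqs.index[freqs > 0])
    n_dropped = len(means) - len(eligible)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} word(s) lack a positive frequency and are "
            "ineligible as labels"
        )
    if len(eligible) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} eligible words, have {len(eligible)}"
        )
    words = sorted(eligible)  # alphabetical base order fixes tie-breaks
    val = means.loc[words].to_numpy(dtype=float)
    logf = np.log(freqs.loc[words].to_numpy(dtype=float))

    r_val_desc = rankdata(-val, method="average")
    r_freq = rankdata(-logf, method="average")

    avg_pos = (r_val_desc + r_freq) / 2.0
    positive = _take_smallest(words, avg_pos, k)

    if negative_mode == "literal":
        negative = _take_smallest(words, -avg_pos, k)
    else:  # mirrored: rerank with the most negative word first
        r_val_asc = rankdata(val, method="average")
        avg_neg = (r_val_asc + r_freq) / 2.0
        negative = _take_smallest(words, avg_neg, k)

    if set(positive) & set(negative):
        raise ValueError(
            "positive and negative lists overlap; enlarge the vocabulary "
            "or reduce k"
        )
    return LabelList(positive, negative, k,
                     source=source or summary.name,
                     negative_mode=negative_mode)


def _take_smallest(words: list[str], key: np.ndarray, k: int) -> list[str]:
    # words is alphabetically sorted, stable sort => alphabetical tie-break
    order = np.argsort(key, kind="stable")[:k]
    return [words[i] for i in order]


def subset_small(summary: RatingSummary, m: int, seed: int) -> RatingSummary:
    """Uniform random m-word subset of a summary, reproducible from seed."""
    if m > len(summary):
        raise ValueError(f"cannot draw {m} words from {len(summary)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(summary), size=m, replace=False)
    tab = summary.table.iloc[np.sort(idx)]
    return _rebuild(summary, tab, f"{summary.name}+small{m}")


def subset_bias(summary: RatingSummary, min_rating: float = -1.0) -> RatingSummary:
    """Positivity-biased summary: keep words with mean valence >= min_rating."""
    tab = summary.table[summary.table["mean"] >= min_rating]
    if len(tab) == 0:
        raise ValueError(f"no words with mean >= {min_rating}")
    return _rebuild(summary, tab, f"{summary.name}+bias{min_rating:g}")


def subset_small_bias(summary: RatingSummary, m: int, min_rating: float = -1.0,
                      seed: int = 0) -> RatingSummary:
    """Truncate the negative range, then down-sample to m words."""
    return subset_small(subset_bias(summary, min_rating), m, seed)


def _rebuild(summary: RatingSummary, tab: pd.DataFrame, name: str) -> RatingSummary:
    means = tab["mean"].to_numpy()
    return RatingSummary(
        table=tab,
        grand_mean=float(means.mean()),
        grand_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        name=name,
        reliability=summary.reliability,
    )


def save_labels(labels: LabelList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(labels), fh, ensure_ascii=False, indent=2)


def load_labels(path) -> LabelList:
    with open(path, encoding="utf-8") as fh:
        return LabelList(**json.load(fh))
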