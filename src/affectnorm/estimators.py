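"""Valence-norm estimators over a vector store.

Two extrapolation routes from a handful of human-rated words to the
whole vocabulary:

* semantic orientation (Turney & Littman): the mean cosine similarity
  of a target word to the positive anchors minus its mean cosine to
  the negative anchors,

      raw(w) = (1/i) Σ_p cos(w, l_p) − (1/j) Σ_n cos(w, l_n),

  rescaled onto the seven-point rating scale as 3·raw clipped to
  [−3, 3];
* k-nearest-neighbour extrapolation (Bestgen): the mean human rating
  of the k rated words closest to the target in embedding space —
  already on the rating scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import VectorStore
from .labels import LabelList
from .ratings import RatingSummary

__all__ = [
    "NormTable",
    "tl_raw",
    "rescale_norm",
    "knn_estimate",
    "estimate_table",
]

DEFAULT_KNN_K = 30


@dataclass
class NormTable:
    """Estimated valence per word with provenance.

    ``table``: DataFrame indexed by word with columns ``raw`` and
    ``rescaled`` (the seven-point value in [−3, 3]).  ``skipped`` lists
    requested words that could not be scored (out of vocabulary).
    """

    table: pd.DataFrame
    vsm: str
    labels_source: str
    estimator: str  # "tl" | "knn"
    k: int | None = None
    skipped: list[str] = field(default_factory=list)

    @property
    def words(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def rescaled_of(self, word: str) -> float:
        return float(self.table.loc[word, "rescaled"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["estimator"] = self.estimator
        out["vsm"] = self.vsm
        out["labels_source"] = self.labels_source
        out.to_csv(path, sep="\t", index_label="word")


def _resolve_pole(store: VectorStore, pole: list[str], which: str) -> list[str]:
    present = [w for w in pole if w in store]
    if not present:
        raise ValueError(f"no {which} label word is in the vocabulary")
    if len(present) < len(pole):
        warnings.warn(
            f"{len(pole) - len(present)} {which} label word(s) out of "
            "vocabulary; pole mean uses the remainder"
        )
    return present


def tl_raw(store: VectorStore, word: str, labels: LabelList) -> float:
    """Semantic-orientation score of `word`: mean cos to positive anchors
    minus mean cos to negative anchors.  Unresolvable anchors are dropped
    (with a warning); a fully unresolvable pole is an error."""
    pos = _resolve_pole(store, labels.positive, "positive")
    neg = _resolve_pole(store, labels.negative, "negative")
    return float(store.cosines_to(word, pos).mean()
                 - store.cosines_to(word, neg).mean())


def rescale_norm(raw: float) -> float:
    """Map a raw orientation score onto the seven-point scale: 3·raw,
    clipped to [−3, 3] (with a warning when |raw| > 1)."""
    if abs(raw) > 1:
        warnings.warn(f"raw score {raw:.4f} outside [-1, 1]; clipping")
    return float(np.clip(3.0 * raw, -3.0, 3.0))


def knn_estimate(store: VectorStore, word: str, summary: RatingSummary,
                 k: int = DEFAULT_KNN_K, weighted: bool = False) -> float:
    """Mean rated valence of the k rated words nearest to `word` by cosine.

    The target itself never counts as its own neighbour.  With
    ``weighted`` the mean is similarity-weighted instead of unweighted.
    """
    neighbours = store.nearest_rated(word, summary.words, k)
    means = np.array([summary.mean_of(w) for w, _ in neighbours])
    if not weighted:
        return float(means.mean())
    sims = np.array([s for _, s in neighbours])
    w = np.clip(sims, 0.0, None)
    if w.sum() == 0:
        return float(means.mean())
    return float((w * means).sum() / w.sum())


def estimate_table(store: VectorStore, words: list[str], labels_or_summary,
                   estimator: str = "tl", k: int | None = None,
                   weighted: bool = False) -> NormTable:
    """Batch estimation: one row per resolvable word, input order kept.

    Out-of-vocabulary words go to the skip report; zero resolvable
    words is an error.
    """
    if len(words) == 0:
        raise ValueError("empty word list")
    if estimator == "tl":
        if not isinstance(labels_or_summary, LabelList):
            raise TypeError("tl estimator needs a LabelList")
        labels = labels_or_summary
        source = labels.source
    elif estimator == "knn":
        if not isinstance(labels_or_summary, RatingSummary):
            raise TypeError("knn estimator needs a RatingSummary")
        summary = labels_or_summary
        source = summary.name
        if k is None:
            k = DEFAULT_KNN_K
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    seen = set()
    resolvable, skipped = [], []
    for w in words:
        if w in seen:
            continue
        seen.add(w)
        (resolvable if w in store else skipped).append(w)
    if not resolvable:
        raise ValueError(
            f"no requested word is in the vocabulary (skipped {len(skipped)})"
        )

    raws, rescaled = [], []
    if estimator == "tl":
        pos = _resolve_pole(store, labels.positive, "positive")
        neg = _resolve_pole(store, labels.negative, "negative")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-word clip warnings batched
            n_clip = 0
            for w in resolvable:
                raw = float(store.cosines_to(w, pos).mean()
                            - store.cosines_to(w, neg).mean())
                raws.append(raw)
                if abs(raw) > 1:
                    n_clip += 1
                rescaled.append(float(np.clip(3.0 * raw, -3.0, 3.0)))
        if n_clip:
            warnings.warn(f"{n_clip} raw score(s) outside [-1, 1] were clipped")
    else:
        for w in resolvable:
            est = knn_estimate(store, w, summary, k=k, weighted=weighted)
            raws.append(est)
            rescaled.append(est)

    tab = pd.DataFrame({"raw": raws, "rescaled": rescaled},
                       index=pd.Index(resolvable, name="word"))
    return NormTable(
        table=tab,
        vsm=store.name,
        labels_source=source,
        estimator=estimator,
        k=k if estimator == "knn" else None,
        skipped=skipped,
    )
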