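"""Rating databases: ingestion, cleaning, rescaling, and reliability.

A rating database is a long-format table of (rater, word, response)
triples on a bounded integer scale — e.g. a 5-point smiley scale used
with children, or the 7-point −3…+3 scale common in adult affective-norm
studies.  Raters may mark a word as *unknown*; unknown responses are
preserved (they drive the exclusion rules) but never enter means or
reliability estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RatingDatabase",
    "RatingSummary",
    "ExclusionReport",
    "load_ratings",
    "apply_exclusions",
    "rescale_responses",
    "summarize",
    "compute_icc",
    "spearman_brown",
    "disattenuate",
]


@dataclass
class RatingDatabase:
    """Long-format rater x word responses on a bounded scale.

    ``responses`` has columns ``rater_id``, ``word``, ``response`` where
    ``response`` is a float (scale points are integers on ingestion but
    rescaling produces fractional values) and NaN marks *unknown*.
    """

    responses: pd.DataFrame
    scale_min: float
    scale_max: float
    name: str = "ratings"

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"degenerate scale [{self.scale_min}, {self.scale_max}]"
            )
        req = {"rater_id", "word", "response"}
        missing = req - set(self.responses.columns)
        if missing:
            raise ValueError(f"responses missing columns {sorted(missing)}")
        dup = self.responses.duplicated(subset=["rater_id", "word"])
        if dup.any():
            row = self.responses[dup].iloc[0]
            raise ValueError(
                f"duplicate response for rater {row['rater_id']!r}, "
                f"word {row['word']!r}"
            )
        vals = self.responses["response"].to_numpy(dtype=float)
        known = vals[~np.isnan(vals)]
        bad = (known < self.scale_min) | (known > self.scale_max)
        if bad.any():
            v = known[bad][0]
            raise ValueError(
                f"response {v} outside scale [{self.scale_min}, {self.scale_max}]"
            )

    @property
    def raters(self) -> list[str]:
        return sorted(self.responses["rater_id"].unique())

    @property
    def words(self) -> list[str]:
        return sorted(self.responses["word"].unique())

    @property
    def n_raters(self) -> int:
        return self.responses["rater_id"].nunique()

    @property
    def n_words(self) -> int:
        return self.responses["word"].nunique()


@dataclass
class RatingSummary:
    """Per-word mean/sd/n plus panel-level statistics.

    ``table`` is indexed by word with columns ``mean``, ``sd``, ``n``.
    ``reliability`` is the estimated reliability of the word means
    (e.g. a one-way average-measure ICC), or None when unknown.
    """

    table: pd.DataFrame
    grand_mean: float
    grand_sd: float
    name: str = "ratings"
    reliability: float | None = None

    @property
    def words(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def mean_of(self, word: str) -> float:
        return float(self.table.loc[word, "mean"])

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={"mean": "mean", "sd": "sd", "n": "n"})
        out.to_csv(path, sep="\t", index_label="word")

    @classmethod
    def from_means(cls, means: dict[str, float], name: str = "ratings",
                   reliability: float | None = None) -> "RatingSummary":
        """Build a summary directly from word -> mean (sd/n unavailable)."""
        tab = pd.DataFrame(
            {"mean": pd.Series(means, dtype=float)}
        )
        tab["sd"] = np.nan
        tab["n"] = 1
        vals = tab["mean"].to_numpy()
        return cls(
            table=tab,
            grand_mean=float(np.mean(vals)),
            grand_sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            name=name,
            reliability=reliability,
        )


@dataclass
class ExclusionReport:
    words_removed_unknown: list[str] = field(default_factory=list)
    raters_removed_uniform: list[str] = field(default_factory=list)
    raters_removed_lowknowledge: list[str] = field(default_factory=list)
    n_words_before: int = 0
    n_words_after: int = 0
    n_raters_before: int = 0
    n_raters_after: int = 0


def load_ratings(path, scale_min: int, scale_max: int,
                 unknown_marker: str = "?", name: str | None = None,
                 sep: str | None = None) -> RatingDatabase:
    """Read a long-format rating CSV/TSV with header rater_id,word,response.

    Responses equal to ``unknown_marker`` are stored as unknown (NaN);
    anything else must parse as a number within [scale_min, scale_max].
    Raises on duplicate (rater, word) pairs and out-of-scale responses,
    naming the offending row.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    req = {"rater_id", "word", "response"}
    if not req <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(req)}, got {list(df.columns)}"
        )
    raw = df["response"].astype(str).str.strip()
    resp = np.full(len(df), np.nan)
    for i, v in enumerate(raw):
        if v == unknown_marker:
            continue
        try:
            resp[i] = float(v)
        except ValueError:
            raise ValueError(
                f"{path} row {i + 2}: unparseable response {v!r}"
            ) from None
        if not (scale_min <= resp[i] <= scale_max):
            raise ValueError(
                f"{path} row {i + 2}: response {v} outside scale "
                f"[{scale_min}, {scale_max}]"
            )
    out = pd.DataFrame(
        {
            "rater_id": df["rater_id"].astype(str),
            "word": df["word"].astype(str),
            "response": resp,
        }
    )
    return RatingDatabase(out, float(scale_min), float(scale_max),
                          name=name or str(path))


def apply_exclusions(db: RatingDatabase, word_unknown_gt: float = 0.5,
                     rater_uniform_gt: float = 0.6,
                     rater_known_lt: float = 0.5,
                     ) -> tuple[RatingDatabase, ExclusionReport]:
    """Drop unknown-heavy words, then uniform or low-knowledge raters.

    Single pass: all fractions are computed on the database as given.
    Words marked unknown by a fraction of their raters strictly greater
    than ``word_unknown_gt`` go first; then raters whose modal response
    share (among their known answers) exceeds ``rater_uniform_gt``, or
    who knew a fraction of their assigned words strictly below
    ``rater_known_lt``.
    """
    if len(db.responses) == 0:
        raise ValueError("empty rating database")
    df = db.responses
    unknown = df["response"].isna()

    word_unknown_frac = unknown.groupby(df["word"]).mean()
    bad_words = sorted(word_unknown_frac[word_unknown_frac > word_unknown_gt].index)

    def modal_share(resp: pd.Series) -> float:
        known = resp.dropna()
        if known.empty:
            return 0.0
        return known.value_counts().iloc[0] / len(known)

    # Single pass on the pre-exclusion data: modal share among known
    # answers; known share relative to everything the rater was asked.
    per_rater = df.groupby("rater_id")["response"]
    uniform_frac = per_rater.apply(modal_share)
    known_frac = per_rater.apply(lambda r: r.notna().mean())
    bad_uniform = sorted(uniform_frac[uniform_frac > rater_uniform_gt].index)
    bad_lowknow = sorted(known_frac[known_frac < rater_known_lt].index)
    bad_raters = set(bad_uniform) | set(bad_lowknow)

    keep = ~df["word"].isin(bad_words) & ~df["rater_id"].isin(bad_raters)
    out = df[keep].reset_index(drop=True)
    report = ExclusionReport(
        words_removed_unknown=bad_words,
        raters_removed_uniform=bad_uniform,
        raters_removed_lowknowledge=bad_lowknow,
        n_words_before=db.n_words,
        n_words_after=out["word"].nunique(),
        n_raters_before=db.n_raters,
        n_raters_after=out["rater_id"].nunique(),
    )
    if report.n_words_after == 0:
        raise ValueError("exclusion removed every word")
    if report.n_raters_after == 0:
        raise ValueError("exclusion removed every rater")
    return replace(db, responses=out), report


def rescale_responses(db: RatingDatabase, target_min: float = -3.0,
                      target_max: float = 3.0) -> RatingDatabase:
    """Affinely map responses onto [target_min, target_max]; NaN unchanged."""
    if target_min >= target_max:
        raise ValueError(f"degenerate target scale [{target_min}, {target_max}]")
    span = db.scale_max - db.scale_min
    scaled = target_min + (db.responses["response"] - db.scale_min) * (
        (target_max - target_min) / span
    )
    out = db.responses.copy()
    out["response"] = scaled
    return replace(db, responses=out, scale_min=float(target_min),
                   scale_max=float(target_max))


def summarize(db: RatingDatabase, reliability: float | None = None) -> RatingSummary:
    """Per-word mean/sd/n over known responses; grand stats over word means.

    Words with zero known responses are dropped with a warning.  sd uses
    the n−1 denominator (NaN for single-rating words).
    """
    if len(db.responses) == 0:
        raise ValueError("empty rating database")
    known = db.responses.dropna(subset=["response"])
    all_words = set(db.responses["word"])
    lost = sorted(all_words - set(known["word"]))
    if lost:
        warnings.warn(
            f"{len(lost)} word(s) had no known responses and were dropped: "
            f"{lost[:5]}{'...' if len(lost) > 5 else ''}"
        )
    g = known.groupby("word")["response"]
    tab = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    tab = tab.sort_index()
    means = tab["mean"].to_numpy()
    return RatingSummary(
        table=tab,
        grand_mean=float(means.mean()),
        grand_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        name=db.name,
        reliability=reliability,
    )


def compute_icc(db: RatingDatabase) -> float:
    """One-way random-effects, average-measure reliability of word means.

    From the one-way ANOVA decomposition over words (targets):
    ICC = (MSB − MSW) / MSB, where MSB is the between-word and MSW the
    within-word mean square.  For unbalanced panels the average-measure
    form absorbs the mean number of ratings per word through MSB.
    Unknown responses are ignored.
    """
    known = db.responses.dropna(subset=["response"])
    counts = known.groupby("word")["response"].size()
    usable = counts[counts >= 2]
    if len(usable) < 2:
        raise ValueError(
            "reliability undefined: need >= 2 words with >= 2 ratings each"
        )
    sub = known[known["word"].isin(usable.index)]
    x = sub["response"].to_numpy(dtype=float)
    grand = x.mean()
    g = sub.groupby("word")["response"]
    means = g.mean()
    ns = g.size()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((sub["response"] - sub["word"].map(means)) ** 2).sum())
    df_b = len(ns) - 1
    df_w = len(sub) - len(ns)
    if df_w == 0:
        raise ValueError("reliability undefined: no within-word replication")
    msb = ssb / df_b
    msw = ssw / df_w
    if msb == 0:
        return 0.0
    return (msb - msw) / msb


def spearman_brown(r1: float, k: float) -> float:
    """Spearman–Brown prophecy: reliability of a test lengthened k-fold."""
    if k <= 0:
        raise ValueError(f"length factor k must be positive, got {k}")
    if not (0 <= r1 <= 1):
        raise ValueError(f"unit reliability must lie in [0, 1], got {r1}")
    return k * r1 / (1 + (k - 1) * r1)


def disattenuate(r_obs: float, rel_x: float, rel_y: float = 1.0) -> float:
    """Correct an observed correlation for unreliability in x and/or y.

    r_true = r_obs / sqrt(rel_x * rel_y), clipped to [−1, 1] with a
    warning if the correction overshoots the bound.
    """
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be positive")
    if rel_x > 1 or rel_y > 1:
        raise ValueError("reliabilities cannot exceed 1")
    r = r_obs / np.sqrt(rel_x * rel_y)
    if abs(r) > 1:
        warnings.warn(
            f"disattenuated correlation {r:.4f} clipped to +/-1"
        )
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)
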