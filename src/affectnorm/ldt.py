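"""Lexical-decision analyses: OLD20 and the blocked valence regression.

Word-level mean reaction times from a lexical decision task are
modelled in two steps on the natural-log scale: Step 1 enters the
lexical control variables (word length, log frequency, OLD20, each
z-scored); Step 2 adds a linear and a quadratic valence term (the
quadratic computed from the z-scored valence).  The variance increment
of Step 2 is tested with F = (ΔR²/q) / ((1 − R²_full)/(n − p_full)).
Predicted RTs at valence = −2/0/+2 SD are back-transformed to
milliseconds, and contrasts against the neutral point carry
delta-method standard errors from the coefficient covariance.

OLD20 is the mean Levenshtein distance from a word to its 20 nearest
orthographic neighbours in a reference lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LDTDataset",
    "BlockedRegressionResult",
    "compute_old20",
    "prepare_design",
    "fit_blocked",
    "valence_contrasts",
    "compare_effect_shapes",
]

CONTROLS = ["length", "log_freq", "old20"]
VALENCE_TERMS = ["valence_z", "valence_z_sq"]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def compute_old20(word: str, lexicon, n_neighbors: int = 20,
                  allow_fewer: bool = False) -> float:
    """Mean Levenshtein distance to the nearest orthographic neighbours.

    The word itself (distance 0) is excluded.  With fewer than
    ``n_neighbors`` other lexicon entries the call errors unless
    ``allow_fewer`` is set, in which case all entries are averaged.
    """
    others = [w for w in lexicon if w != word]
    if len(others) < n_neighbors and not allow_fewer:
        raise ValueError(
            f"lexicon has only {len(others)} entries besides {word!r}; "
            f"need {n_neighbors} (or allow_fewer=True)"
        )
    dists = np.sort([levenshtein(word, w) for w in others])
    return float(dists[: n_neighbors].mean())


@dataclass
class LDTDataset:
    """Word-level lexical decision data with covariates.

    ``table`` indexed by word with columns ``mean_rt`` (ms), ``accuracy``,
    ``length``, ``freq_pm``, ``old20``, ``valence``.  Accuracy is carried
    for description but never modelled.
    """

    table: pd.DataFrame
    group: str = "children"

    def __post_init__(self) -> None:
        req = {"mean_rt", "accuracy", "length", "freq_pm", "old20", "valence"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"LDT table missing columns {sorted(missing)}")
        t = self.table
        if (t["mean_rt"] <= 0).any():
            raise ValueError("mean_rt must be positive")
        if ((t["accuracy"] < 0) | (t["accuracy"] > 1)).any():
            raise ValueError("accuracy must lie in [0, 1]")
        if (t["length"] < 1).any():
            raise ValueError("length must be >= 1")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path, group: str = "children",
                 lexicon: list[str] | None = None) -> "LDTDataset":
        """Read TSV ``word  mean_rt  accuracy  length  freq_pm  [old20]``;
        OLD20 is computed from ``lexicon`` when the column is absent."""
        df = pd.read_csv(path, sep="\t").set_index("word")
        if "old20" not in df.columns:
            if lexicon is None:
                raise ValueError(f"{path} lacks old20 and no lexicon given")
            df["old20"] = [compute_old20(w, lexicon) for w in df.index]
        if "valence" not in df.columns:
            df["valence"] = np.nan
        return cls(df, group=group)

    def with_valence(self, values: pd.Series, drop_missing: bool = True
                     ) -> "LDTDataset":
        """Copy of the dataset with the valence column replaced (e.g. by
        computed norms); words without a value are dropped by default."""
        tab = self.table.copy()
        tab["valence"] = values.reindex(tab.index)
        if drop_missing:
            tab = tab.dropna(subset=["valence"])
        return LDTDataset(tab, group=self.group)


@dataclass
class DesignMatrix:
    X1: pd.DataFrame       # intercept + controls
    X2: pd.DataFrame       # + valence terms
    y: pd.Series           # log RT
    scaling: pd.DataFrame  # mean/sd used for each z-score
    words: pd.Index


@dataclass
class BlockedRegressionResult:
    step1: pd.DataFrame  # b, se, t, p per coefficient
    step2: pd.DataFrame
    r2_step1: float
    r2_step2: float
    delta_r2: float
    f_increment: float
    df_increment: tuple[int, int]
    p_increment: float
    n: int
    cov_step2: pd.DataFrame
    scaling: pd.DataFrame
    group: str = ""
    condition: str = "human"
    words: pd.Index | None = field(default=None, repr=False)


def prepare_design(data: LDTDataset) -> DesignMatrix:
    """Build the two-step design: log RT on z-scored length, log
    frequency, OLD20 and valence, plus the square of z-scored valence
    (itself left unscaled so ±2 SD contrasts stay transparent)."""
    t = data.table
    if t[["length", "freq_pm", "old20", "valence"]].isna().any().any():
        raise ValueError("missing covariate values")
    y = np.log(t["mean_rt"].astype(float))
    raw = pd.DataFrame(
        {
            "length": t["length"].astype(float),
            "log_freq": np.log(t["freq_pm"].astype(float) + 1.0),
            "old20": t["old20"].astype(float),
            "valence": t["valence"].astype(float),
        },
        index=t.index,
    )
    scaling = pd.DataFrame({"mean": raw.mean(), "sd": raw.std(ddof=1)})
    zero = scaling.index[scaling["sd"] == 0]
    if len(zero):
        raise ValueError(f"zero variance in predictor {zero[0]!r}")
    z = (raw - scaling["mean"]) / scaling["sd"]
    X1 = pd.DataFrame({"const": 1.0}, index=t.index)
    X1["length"] = z["length"]
    X1["log_freq"] = z["log_freq"]
    X1["old20"] = z["old20"]
    X2 = X1.copy()
    X2["valence_z"] = z["valence"]
    X2["valence_z_sq"] = z["valence"] ** 2
    return DesignMatrix(X1=X1, X2=X2, y=y, scaling=scaling, words=t.index)


def fit_blocked(design: DesignMatrix, group: str = "",
                condition: str = "human") -> BlockedRegressionResult:
    """OLS for both steps plus the Step-2 variance-increment F test."""
    n = len(design.y)
    p_full = design.X2.shape[1]
    if n <= p_full + 1:
        raise ValueError(f"too few observations (n={n})")
    fit1 = sm.OLS(design.y, design.X1).fit()
    fit2 = sm.OLS(design.y, design.X2).fit()
    if fit2.df_resid <= 0 or np.linalg.matrix_rank(design.X2) < p_full:
        raise ValueError("rank-deficient design")
    r2_1, r2_2 = float(fit1.rsquared), float(fit2.rsquared)
    delta = r2_2 - r2_1
    q = len(VALENCE_TERMS)
    df2 = n - p_full
    denom = (1.0 - r2_2) / df2
    if denom <= 0:  # perfect fit: zero residual variance
        f_inc = np.inf if delta > 0 else 0.0
    else:
        f_inc = (delta / q) / denom
    p_inc = float(stats.f.sf(f_inc, q, df2))

    def coef_table(fit) -> pd.DataFrame:
        return pd.DataFrame(
            {"b": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
        )

    return BlockedRegressionResult(
        step1=coef_table(fit1),
        step2=coef_table(fit2),
        r2_step1=r2_1,
        r2_step2=r2_2,
        delta_r2=delta,
        f_increment=float(f_inc),
        df_increment=(q, df2),
        p_increment=p_inc,
        n=n,
        cov_step2=pd.DataFrame(
            fit2.cov_params(), index=fit2.params.index, columns=fit2.params.index
        ),
        scaling=design.scaling,
        group=group,
        condition=condition,
        words=design.words,
    )


def valence_contrasts(result: BlockedRegressionResult,
                      z_points=(-2.0, 0.0, 2.0)) -> pd.DataFrame:
    """Predicted RT (ms, controls at their means) and contrast vs the
    neutral point at the given valence z-scores.

    The contrast c(z) = b_lin·z + b_quad·z² is a linear function of the
    coefficients, so its SE comes straight from the coefficient
    covariance (delta method on the log scale)."""
    params = result.step2["b"]
    cov = result.cov_step2
    if cov is None:
        raise ValueError("coefficient covariance unavailable")
    rows = []
    names = list(params.index)
    for z in z_points:
        cvec = pd.Series(0.0, index=names)
        cvec["valence_z"] = z
        cvec["valence_z_sq"] = z * z
        contrast = float(cvec @ params)
        se = float(np.sqrt(cvec @ cov @ cvec))
        pred_log = float(params["const"] + contrast)
        if z == 0:
            t = 0.0
            p = 1.0
        else:
            t = contrast / se
            p = float(2 * stats.t.sf(abs(t), result.df_increment[1]))
        rows.append(
            {"z": z, "rt_ms": float(np.exp(pred_log)), "b": contrast,
             "se": se, "t": t, "p": p}
        )
    return pd.DataFrame(rows).set_index("z")


def captures_quadratic_positivity(result: BlockedRegressionResult,
                                  alpha: float = 0.05) -> bool:
    """True when the fit shows the human-rating signature: a reliably
    negative quadratic term, no reliable negativity contrast at −2 SD,
    and a reliably negative (faster) contrast at +2 SD."""
    quad = result.step2.loc["valence_z_sq"]
    contr = valence_contrasts(result)
    neg = contr.loc[-2.0]
    pos = contr.loc[2.0]
    return bool(
        quad["b"] < 0 and quad["p"] < alpha
        and neg["p"] >= alpha
        and pos["b"] < 0 and pos["p"] < alpha
    )


def compare_effect_shapes(results: list[BlockedRegressionResult],
                          reference: BlockedRegressionResult,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Side-by-side valence effects for several norm conditions against
    the human-rating reference, all fitted on the same words.

    One row per condition (reference first): linear and quadratic b with
    significance flags and the qualitative "captures quadratic
    positivity effect" flag."""
    ref_words = set(reference.words)
    for res in results:
        if set(res.words) != ref_words:
            raise ValueError(
                f"condition {res.condition!r} fitted on different words "
                "than the reference"
            )
    rows = []
    for res in [reference] + list(results):
        lin = res.step2.loc["valence_z"]
        quad = res.step2.loc["valence_z_sq"]
        rows.append(
            {
                "condition": res.condition,
                "b_linear": float(lin["b"]),
                "p_linear": float(lin["p"]),
                "sig_linear": bool(lin["p"] < alpha),
                "b_quadratic": float(quad["b"]),
                "p_quadratic": float(quad["p"]),
                "sig_quadratic": bool(quad["p"] < alpha),
                "captures_quadratic_positivity":
                    captures_quadratic_positivity(res, alpha=alpha),
            }
        )
    return pd.DataFrame(rows).set_index("condition")
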