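"""Comparing computed norms with human ratings.

Pearson correlations on the word intersection (optionally corrected
for the unreliability of the human ratings), pairwise intercorrelation
matrices between norm tables, and moment/mode summaries of valence
distributions (bimodality is assessed by counting local maxima of a
Gaussian KDE with Silverman bandwidth on a fixed grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import NormTable
from .ratings import RatingSummary, disattenuate

__all__ = [
    "EvaluationGrid",
    "correlate",
    "intercorrelation",
    "distribution_summary",
    "build_grid",
]

_KDE_GRID = 512


@dataclass
class EvaluationGrid:
    """Label-source x VSM grid of correlations against one reference."""

    table: pd.DataFrame  # rows: label source, columns: VSM
    reference: str
    n_words: pd.DataFrame  # same layout, intersection sizes

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="labels")

    def max_cell(self) -> tuple[str, str, float]:
        """(label source, vsm, r) of the best cell."""
        r = self.table.stack()
        (src, vsm) = r.idxmax()
        return src, vsm, float(r.max())


def correlate(norms: NormTable, summary: RatingSummary,
              reliability: float | None = None) -> tuple[float, int]:
    """Pearson r between rescaled norms and per-word rating means.

    Computed on the word intersection; with ``reliability`` given the r
    is disattenuated by 1/sqrt(reliability) (the computed norms are
    treated as error-free, only the human ratings carry measurement
    error).  Returns (r, n).
    """
    common = norms.table.index.intersection(summary.table.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"word intersection too small ({n} < 3)")
    x = norms.table.loc[common, "rescaled"].to_numpy(dtype=float)
    y = summary.table.loc[common, "mean"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance on one side of the correlation")
    r = float(stats.pearsonr(x, y).statistic)
    if reliability is not None:
        r = disattenuate(r, reliability, 1.0)
    return r, n


def intercorrelation(tables: list[NormTable]) -> pd.DataFrame:
    """Pairwise Pearson r between norm tables on their common words."""
    if len(tables) < 2:
        raise ValueError("need at least two norm tables")
    common = tables[0].table.index
    for t in tables[1:]:
        common = common.intersection(t.table.index)
    if len(common) < 3:
        raise ValueError(f"common word intersection too small ({len(common)})")
    names = [f"{t.vsm}-{t.labels_source}" for t in tables]
    mat = np.eye(len(tables))
    vals = [t.table.loc[common, "rescaled"].to_numpy(dtype=float) for t in tables]
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            r = float(stats.pearsonr(vals[i], vals[j]).statistic)
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


def distribution_summary(values) -> tuple[float, float, float, int]:
    """(mean, sd, skewness, n_modes) of a valence distribution.

    Moment-based mean/sd/skewness; n_modes counts local maxima of a
    Gaussian KDE (Silverman bandwidth) evaluated on a 512-point grid
    over [min, max].  A zero-variance sample reports sd 0, skewness 0
    and a single mode.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need >= 3 finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return mean, 0.0, 0.0, 1
    skew = float(stats.skew(x))
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), _KDE_GRID)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    n_modes = int(interior.sum())
    if n_modes == 0:  # monotone density: the boundary maximum is the mode
        n_modes = 1
    return mean, sd, skew, n_modes


def build_grid(norm_tables: dict[tuple[str, str], NormTable],
               reference: RatingSummary,
               reliability: float | None = None) -> EvaluationGrid:
    """Assemble a label-source x VSM correlation grid on one shared
    word intersection across all cells."""
    if not norm_tables:
        raise ValueError("no norm tables supplied")
    common = reference.table.index
    for t in norm_tables.values():
        common = common.intersection(t.table.index)
    if len(common) < 3:
        raise ValueError("shared word intersection too small")
    sources = sorted({src for src, _ in norm_tables})
    vsms = sorted({vsm for _, vsm in norm_tables})
    r_tab = pd.DataFrame(np.nan, index=sources, columns=vsms)
    n_tab = pd.DataFrame(0, index=sources, columns=vsms)
    y = reference.table.loc[common, "mean"].to_numpy(dtype=float)
    for (src, vsm), t in norm_tables.items():
        x = t.table.loc[common, "rescaled"].to_numpy(dtype=float)
        r = float(stats.pearsonr(x, y).statistic)
        if reliability is not None:
            r = disattenuate(r, reliability, 1.0)
        r_tab.loc[src, vsm] = r
        n_tab.loc[src, vsm] = len(common)
    return EvaluationGrid(table=r_tab, reference=reference.name, n_words=n_tab)
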