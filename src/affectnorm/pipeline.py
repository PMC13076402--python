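"""End-to-end orchestration of the VSM x label-source design matrix.

Given embedding files (one per vector-space tag) and rating databases
(one per label-source tag), the pipeline extracts a label list from
every rating source, computes a norm table for every (VSM, source)
cell, and correlates each table with every rating summary serving as a
reference — the full factorial design comparing where the semantic
space comes from against where the anchor words come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import estimators, evaluation, labels as labels_mod, ratings as ratings_mod
from .embeddings import read_vectors

logger = logging.getLogger("affectnorm")

__all__ = ["PipelineConfig", "RatingSourceConfig", "run_design_matrix"]


@dataclass
class RatingSourceConfig:
    path: str
    scale_min: float = 1
    scale_max: float = 5
    unknown_marker: str = "?"
    apply_exclusions: bool = False
    rescale: bool = True          # map onto the seven-point scale
    reliability: float | None = None  # overrides the panel ICC if set


@dataclass
class PipelineConfig:
    vectors: dict[str, str]
    ratings: dict[str, RatingSourceConfig]
    frequencies: str
    estimator: str = "tl"
    knn_k: int = estimators.DEFAULT_KNN_K
    label_k: int = 60
    negative_mode: str = "literal"
    disattenuate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("configure at least one vector space")
        if not self.ratings:
            raise ValueError("configure at least one rating source")
        for tag, path in self.vectors.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"vectors[{tag}]: {path}")
        for tag, src in self.ratings.items():
            if not Path(src.path).exists():
                raise FileNotFoundError(f"ratings[{tag}]: {src.path}")
        if not Path(self.frequencies).exists():
            raise FileNotFoundError(f"frequencies: {self.frequencies}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["ratings"] = {
            tag: RatingSourceConfig(**spec) if isinstance(spec, dict)
            else RatingSourceConfig(path=spec)
            for tag, spec in raw["ratings"].items()
        }
        return cls(**raw)


@dataclass
class DesignMatrixResult:
    norm_tables: dict[tuple[str, str], estimators.NormTable]
    grids: dict[str, evaluation.EvaluationGrid]  # per reference tag
    summaries: dict[str, ratings_mod.RatingSummary]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_summary(tag: str, src: RatingSourceConfig
                  ) -> ratings_mod.RatingSummary:
    db = ratings_mod.load_ratings(
        src.path, src.scale_min, src.scale_max,
        unknown_marker=src.unknown_marker, name=tag,
    )
    if src.apply_exclusions:
        db, report = ratings_mod.apply_exclusions(db)
        logger.info(
            "%s: exclusions removed %d word(s), %d rater(s)", tag,
            report.n_words_before - report.n_words_after,
            report.n_raters_before - report.n_raters_after,
        )
    reliability = src.reliability
    if reliability is None:
        try:
            reliability = ratings_mod.compute_icc(db)
            logger.info("%s: panel ICC %.3f", tag, reliability)
        except ValueError:
            logger.info("%s: reliability unavailable (no replication)", tag)
    if src.rescale:
        db = ratings_mod.rescale_responses(db, -3.0, 3.0)
    return ratings_mod.summarize(db, reliability=reliability)


def run_design_matrix(config: PipelineConfig, out_dir=None
                      ) -> DesignMatrixResult:
    """Run every VSM x label-source cell and evaluate against every
    rating source as reference.

    A failing cell is logged and skipped; the remaining cells continue.
    With ``out_dir`` the norm tables and grids are written as TSV.
    """
    stores = {tag: read_vectors(path, name=tag)
              for tag, path in config.vectors.items()}
    freqs = labels_mod.load_frequencies(config.frequencies)
    summaries = {tag: _load_summary(tag, src)
                 for tag, src in config.ratings.items()}

    label_lists: dict[str, labels_mod.LabelList] = {}
    failures: dict[tuple[str, str], str] = {}
    for tag, summary in summaries.items():
        try:
            label_lists[tag] = labels_mod.extract_labels(
                summary, freqs, k=config.label_k,
                negative_mode=config.negative_mode, source=tag,
            )
            logger.info("labels[%s]: k=%d mode=%s", tag, config.label_k,
                        config.negative_mode)
        except ValueError as exc:
            for vsm in stores:
                failures[(tag, vsm)] = f"label extraction failed: {exc}"
            logger.error("labels[%s]: %s", tag, exc)

    norm_tables: dict[tuple[str, str], estimators.NormTable] = {}
    for src_tag, lab in label_lists.items():
        for vsm_tag, store in stores.items():
            # score every word any reference summary can evaluate
            words = sorted(
                {w for s in summaries.values() for w in s.words if w in store}
            )
            try:
                if config.estimator == "tl":
                    tab = estimators.estimate_table(store, words, lab, "tl")
                else:
                    tab = estimators.estimate_table(
                        store, words, summaries[src_tag], "knn", k=config.knn_k
                    )
                norm_tables[(src_tag, vsm_tag)] = tab
                if tab.skipped:
                    logger.info("norms[%s/%s]: %d word(s) skipped (OOV)",
                                src_tag, vsm_tag, len(tab.skipped))
            except (ValueError, KeyError) as exc:
                failures[(src_tag, vsm_tag)] = str(exc)
                logger.error("norms[%s/%s]: %s", src_tag, vsm_tag, exc)

    grids: dict[str, evaluation.EvaluationGrid] = {}
    for ref_tag, ref in summaries.items():
        rel = ref.reliability if config.disattenuate else None
        try:
            grids[ref_tag] = evaluation.build_grid(norm_tables, ref, rel)
        except ValueError as exc:
            logger.error("grid[%s]: %s", ref_tag, exc)

    result = DesignMatrixResult(norm_tables=norm_tables, grids=grids,
                                summaries=summaries, failures=failures)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (src, vsm), tab in norm_tables.items():
            tab.to_tsv(out / f"norms_{vsm}_{src}.tsv")
        for ref, grid in grids.items():
            grid.to_tsv(out / f"grid_ref-{ref}.tsv")
        if len(norm_tables) >= 2:
            inter = evaluation.intercorrelation(list(norm_tables.values()))
            inter.to_csv(out / "intercorrelations.tsv", sep="\t")
    return result
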