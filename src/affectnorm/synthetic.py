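"""Self-contained synthetic worlds for exercising the whole pipeline.

A world is a lexicon of random letter strings with a latent "true"
valence per word on the seven-point scale [−3, 3], Zipf-like
frequencies, and an embedding in which valence is planted along a
single axis:

    vector(w) = signal · (valence_w / 3) · u  +  c · g  +  ε,

with ``u`` the unit valence axis, ``g`` a fixed unit direction shared
by every word (real distributional spaces have a positive mean pairwise
cosine; this component reproduces it, and with it the mechanism by
which near-neutral negative anchors inflate the negative term of the
orientation score), and ε isotropic Gaussian noise.

On top of a world the module simulates rater panels (random item
assignment, per-rater noise, Likert rounding, unknown responses) and
word-level lexical-decision RTs from a linear+quadratic valence model
on the log scale.  Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import VectorStore, write_vectors
from .ldt import LDTDataset, compute_old20
from .ratings import RatingDatabase

__all__ = [
    "SyntheticWorld",
    "gen_world",
    "gen_rating_panel",
    "gen_ldt",
    "canonical_world",
    "PAPERLIKE",
    "write_world",
]

# Canonical study-scale parameters: a 600-word lexicon in a 50-d space
# (the child-space dimensionality), unit signal with moderate noise, a
# panel sized to yield ~15 ratings per word on a 5-point child scale,
# and RT coefficients matching the adult human-rating fit.
PAPERLIKE = {
    "world": dict(n_words=600, dim=50, signal=1.0, noise_sd=0.2,
                  valence_dist="full"),
    "panel": dict(n_raters=100, items_per_rater=90, rater_noise_sd=0.6,
                  scale=(1, 5), unknown_rate=0.05),
    "ldt": dict(coefs=(6.353, 0.020, -0.023, 0.001, -0.010, -0.006),
                resid_sd=0.05),
    "label_k": 60,
}


@dataclass
class SyntheticWorld:
    words: list[str]
    true_valence: np.ndarray  # [−3, 3]
    freq_pm: np.ndarray
    axis: np.ndarray          # unit valence direction u
    common: np.ndarray        # unit shared direction g (orthogonal to u)
    signal: float
    noise_sd: float
    common_strength: float
    valence_dist: str
    seed: int
    _old20: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_words(self) -> int:
        return len(self.words)

    def valence_series(self) -> pd.Series:
        return pd.Series(self.true_valence, index=self.words)

    def freq_series(self) -> pd.Series:
        return pd.Series(self.freq_pm, index=self.words)

    def old20(self) -> np.ndarray:
        """OLD20 of every word against the world's own lexicon (cached)."""
        if self._old20 is None:
            self._old20 = np.array(
                [compute_old20(w, self.words, allow_fewer=True)
                 for w in self.words]
            )
        return self._old20


def _random_lexicon(rng: np.random.Generator, n_words: int,
                    min_len: int = 3, max_len: int = 10) -> list[str]:
    letters = np.array(list(string.ascii_lowercase))
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n_words:
        length = int(rng.integers(min_len, max_len + 1))
        w = "".join(rng.choice(letters, size=length))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def gen_world(n_words: int = 600, dim: int = 50, signal: float = 1.0,
              noise_sd: float = 0.2, valence_dist: str = "full",
              seed: int = 0, zipf_exponent: float = 1.0,
              common_strength: float = 0.5,
              ) -> tuple[SyntheticWorld, VectorStore]:
    """Generate a synthetic lexicon + embedding with a planted valence axis.

    ``valence_dist``: "full" draws true valence uniformly on [−3, 3];
    "positivity_biased" truncates the negative range at −1, mimicking
    the right-shifted valence distributions of child-directed
    vocabularies.  Frequencies follow a Zipf law (per-million, randomly
    permuted against valence).
    """
    if n_words < 10:
        raise ValueError("need n_words >= 10")
    if dim < 2:
        raise ValueError("need dim >= 2")
    if signal < 0 or noise_sd < 0:
        raise ValueError("signal and noise_sd must be >= 0")
    if valence_dist not in ("full", "positivity_biased"):
        raise ValueError(f"unknown valence_dist {valence_dist!r}")
    rng = np.random.default_rng(seed)
    words = _random_lexicon(rng, n_words)
    if valence_dist == "full":
        val = rng.uniform(-3.0, 3.0, size=n_words)
    else:
        val = rng.uniform(-1.0, 3.0, size=n_words)

    u = rng.normal(size=dim)
    u /= np.linalg.norm(u)
    g = rng.normal(size=dim)
    g -= (g @ u) * u
    g /= np.linalg.norm(g)

    eps = rng.normal(0.0, noise_sd, size=(n_words, dim)) if noise_sd > 0 \
        else np.zeros((n_words, dim))
    vectors = (signal * (val / 3.0))[:, None] * u \
        + common_strength * g + eps
    # guard against the measure-zero chance of an exactly zero vector
    norms = np.linalg.norm(vectors, axis=1)
    vectors[norms == 0] += 1e-8 * u

    ranks = rng.permutation(n_words) + 1
    freq_pm = 1000.0 / ranks.astype(float) ** zipf_exponent

    world = SyntheticWorld(
        words=words, true_valence=val, freq_pm=freq_pm, axis=u, common=g,
        signal=signal, noise_sd=noise_sd, common_strength=common_strength,
        valence_dist=valence_dist, seed=seed,
    )
    store = VectorStore(words, vectors, name=f"synthetic(seed={seed})")
    return world, store


def gen_rating_panel(world: SyntheticWorld, n_raters: int = 100,
                     items_per_rater: int = 90, rater_noise_sd: float = 0.6,
                     scale: tuple[int, int] = (1, 5),
                     unknown_rate: float = 0.0, seed: int = 0,
                     ) -> RatingDatabase:
    """Simulate a rating panel over the world's words.

    Each rater receives a random subset of the lexicon; the response is
    the true valence plus Gaussian rater noise (on the [−3, 3] scale),
    affinely mapped onto the requested integer scale, rounded to the
    nearest scale point and clipped.  Unknown responses are injected at
    ``unknown_rate``.
    """
    smin, smax = int(scale[0]), int(scale[1])
    if smin >= smax:
        raise ValueError(f"invalid scale {scale}")
    if items_per_rater > world.n_words:
        raise ValueError("items_per_rater exceeds lexicon size")
    if not (0 <= unknown_rate < 1):
        raise ValueError("unknown_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    width = len(str(n_raters))
    for r in range(n_raters):
        rater = f"r{r:0{width}d}"
        items = rng.choice(world.n_words, size=items_per_rater, replace=False)
        latent = world.true_valence[items] + rng.normal(
            0.0, rater_noise_sd, size=items_per_rater
        )
        mapped = smin + (latent + 3.0) * (smax - smin) / 6.0
        resp = np.clip(np.rint(mapped), smin, smax)
        unknown = rng.random(items_per_rater) < unknown_rate
        resp = np.where(unknown, np.nan, resp)
        for i, v in zip(items, resp):
            rows.append((rater, world.words[i], v))
    df = pd.DataFrame(rows, columns=["rater_id", "word", "response"])
    return RatingDatabase(df, float(smin), float(smax),
                          name=f"panel(seed={seed})")


def gen_ldt(world: SyntheticWorld,
            coefs=(6.353, 0.020, -0.023, 0.001, -0.010, -0.006),
            resid_sd: float = 0.05, seed: int = 0,
            group: str = "adults") -> LDTDataset:
    """Simulate word-level lexical-decision RTs from the world.

    log RT = b0 + b1·z(length) + b2·z(log freq) + b3·z(OLD20)
           + b4·z(valence) + b5·z(valence)² + N(0, resid_sd).

    Lengths are the lexicon's own letter counts (3–10), OLD20 comes
    from the synthetic lexicon, and the default coefficients are the
    adult human-rating values on the natural-log scale.
    """
    if resid_sd < 0:
        raise ValueError("resid_sd must be >= 0")
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (6,):
        raise ValueError("coefs must be 6 values (b0..b5)")
    rng = np.random.default_rng(seed)

    length = np.array([len(w) for w in world.words], dtype=float)
    log_freq = np.log(world.freq_pm + 1.0)
    old20 = world.old20()
    val = world.true_valence

    def z(x):
        return (x - x.mean()) / x.std(ddof=1)

    zl, zf, zo, zv = z(length), z(log_freq), z(old20), z(val)
    log_rt = (coefs[0] + coefs[1] * zl + coefs[2] * zf + coefs[3] * zo
              + coefs[4] * zv + coefs[5] * zv ** 2)
    if resid_sd > 0:
        log_rt = log_rt + rng.normal(0.0, resid_sd, size=world.n_words)

    acc = np.clip(rng.normal(0.95, 0.03, size=world.n_words), 0.0, 1.0)
    tab = pd.DataFrame(
        {
            "mean_rt": np.exp(log_rt),
            "accuracy": acc,
            "length": length.astype(int),
            "freq_pm": world.freq_pm,
            "old20": old20,
            "valence": val,
        },
        index=pd.Index(world.words, name="word"),
    )
    return LDTDataset(tab, group=group)


def canonical_world(seed: int = 42) -> tuple[SyntheticWorld, VectorStore]:
    """The repository's canonical test world: 600 words, 50 dimensions,
    signal 1, noise 0.2, full valence range, regenerated bit-for-bit
    from its frozen parameters and seed."""
    return gen_world(seed=seed, **PAPERLIKE["world"])


def write_world(world: SyntheticWorld, store: VectorStore, outdir,
                panel: RatingDatabase | None = None,
                ldt: LDTDataset | None = None) -> dict[str, Path]:
    """Render a world to the pipeline's on-disk formats: word2vec text
    vectors, a long-format ratings CSV, a frequency TSV, an LDT TSV and
    the true valence for reference."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["vectors"] = out / "vectors.txt"
    write_vectors(store, paths["vectors"])
    paths["frequencies"] = out / "frequencies.tsv"
    world.freq_series().rename("freq_pm").to_csv(
        paths["frequencies"], sep="\t", index_label="word"
    )
    paths["true_valence"] = out / "true_valence.tsv"
    world.valence_series().rename("valence").to_csv(
        paths["true_valence"], sep="\t", index_label="word"
    )
    if panel is not None:
        paths["ratings"] = out / "ratings.csv"
        export = panel.responses.copy()
        export["response"] = export["response"].map(
            lambda v: "?" if pd.isna(v) else f"{v:g}"
        )
        export.to_csv(paths["ratings"], index=False)
    if ldt is not None:
        paths["ldt"] = out / "ldt.tsv"
        ldt.table.to_csv(paths["ldt"], sep="\t", index_label="word")
    return paths
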