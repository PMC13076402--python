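"""Word-vector stores in the word2vec text dialect.

The store is the semantic-similarity substrate for both norm
estimators: valence is read off cosine similarities between a target
word and anchor words.  Vectors are static (one vector per surface
form); a word absent from the file is out-of-vocabulary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VectorStore",
    "read_vectors",
    "write_vectors",
    "cosine",
    "nearest_rated",
]


@dataclass
class VectorStore:
    """An ordered vocabulary mapped to d-dimensional real vectors."""

    words: list[str]
    vectors: np.ndarray  # shape (|vocab|, d)
    name: str = "vsm"
    _index: dict[str, int] = field(init=False, repr=False)
    _norms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.words):
            raise ValueError("vectors must be |vocab| x d")
        if self.vectors.shape[1] < 1:
            raise ValueError("dimension must be >= 1")
        self._index = {}
        for i, w in enumerate(self.words):
            if w in self._index:
                raise ValueError(f"duplicate word {w!r}")
            self._index[w] = i
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite vector entries")
        self._norms = np.linalg.norm(self.vectors, axis=1)
        zero = np.flatnonzero(self._norms == 0)
        if zero.size:
            raise ValueError(f"zero vector for word {self.words[zero[0]]!r}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in vocabulary") from None

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity between two in-vocabulary words."""
        ia, ib = self._index_of(a), self._index_of(b)
        num = float(self.vectors[ia] @ self.vectors[ib])
        return num / float(self._norms[ia] * self._norms[ib])

    def cosines_to(self, word: str, others: list[str]) -> np.ndarray:
        """Vectorized cosine of `word` against a list of words."""
        i = self._index_of(word)
        idx = np.array([self._index_of(o) for o in others], dtype=int)
        num = self.vectors[idx] @ self.vectors[i]
        return num / (self._norms[idx] * self._norms[i])

    def nearest_rated(self, word: str, candidates, k: int
                      ) -> list[tuple[str, float]]:
        """The k candidates most cosine-similar to `word`, descending.

        The word itself is never its own neighbour.  Ties are broken by
        vocabulary order.  Candidates missing from the vocabulary are
        ignored; fewer than k resolvable candidates is an error.
        """
        i = self._index_of(word)
        cand_idx = sorted(
            self._index[c] for c in set(candidates)
            if c in self._index and self._index[c] != i
        )
        if len(cand_idx) < k:
            raise ValueError(
                f"only {len(cand_idx)} resolvable candidates for k={k}"
            )
        cand_idx = np.array(cand_idx, dtype=int)
        sims = (self.vectors[cand_idx] @ self.vectors[i]) / (
            self._norms[cand_idx] * self._norms[i]
        )
        # stable sort on -sim keeps vocabulary order within ties
        order = np.argsort(-sims, kind="stable")[:k]
        return [(self.words[cand_idx[j]], float(sims[j])) for j in order]

    def resolve(self, word: str, casefold: bool = False) -> str | None:
        """Vocabulary form of `word`, or None if out-of-vocabulary.

        Lookup is exact by default (German nouns are capitalized, so
        folding can conflate distinct lemmas); with ``casefold`` a
        lower-cased fallback is tried when the exact form is absent.
        """
        if word in self._index:
            return word
        if casefold and word.lower() in self._index:
            return word.lower()
        return None

    def _index_of(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in vocabulary") from None


def cosine(store: VectorStore, a: str, b: str) -> float:
    """Cosine similarity between two words of a store."""
    return store.cosine(a, b)


def nearest_rated(store: VectorStore, word: str, candidates, k: int):
    """k nearest candidates to `word` by cosine; see VectorStore.nearest_rated."""
    return store.nearest_rated(word, candidates, k)


def read_vectors(path, name: str | None = None) -> VectorStore:
    """Read a word2vec-dialect text file (optionally gzipped).

    First line: ``n_words n_dims``; then one word and n_dims
    whitespace-separated reals per line.  Header/body mismatches,
    ragged rows, duplicates and zero vectors are hard errors.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        n_words, n_dims = int(header[0]), int(header[1])
        words: list[str] = []
        mat = np.empty((n_words, n_dims))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split()
            if len(parts) != n_dims + 1:
                raise ValueError(
                    f"{path} line {lineno}: expected {n_dims} values, "
                    f"got {len(parts) - 1}"
                )
            if len(words) >= n_words:
                raise ValueError(f"{path}: more rows than header promises")
            words.append(parts[0])
            mat[len(words) - 1] = [float(v) for v in parts[1:]]
    if len(words) != n_words:
        raise ValueError(
            f"{path}: header promises {n_words} words, found {len(words)}"
        )
    return VectorStore(words, mat, name=name or str(path))


def write_vectors(store: VectorStore, path) -> None:
    """Write a store in the word2vec text dialect (gzip if path ends .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(store)} {store.dim}\n")
        for w, vec in zip(store.words, store.vectors):
            fh.write(w + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")
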