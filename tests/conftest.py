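import numpy as np
import pandas as pd
import pytest

from affectnorm import ratings as ratings_mod
from affectnorm import synthetic as syn
from affectnorm.embeddings import VectorStore


@pytest.fixture(scope="session")
def canonical():
    """The canonical synthetic test world (600 words, 50-d, seed 42)."""
    return syn.canonical_world()


@pytest.fixture(scope="session")
def canonical_summary(canonical):
    """Rescaled rating summary from a study-scale panel over the world."""
    world, _ = canonical
    panel = syn.gen_rating_panel(world, seed=43, **syn.PAPERLIKE["panel"])
    return ratings_mod.summarize(ratings_mod.rescale_responses(panel))


@pytest.fixture
def tiny_store():
    """Four words in 3-d with hand-friendly geometry."""
    vecs = np.array(
        [
            [1.0, 0.0, 0.0],   # ex
            [0.0, 1.0, 0.0],   # ey
            [1.0, 1.0, 0.0],   # diag
            [0.0, 0.0, 2.0],   # ez2
        ]
    )
    return VectorStore(["ex", "ey", "diag", "ez2"], vecs, name="tiny")


def make_panel(rows, scale=(1, 5), name="panel"):
    """Build a RatingDatabase from (rater, word, response) triples;
    None marks unknown."""
    df = pd.DataFrame(rows, columns=["rater_id", "word", "response"])
    df["response"] = df["response"].astype(float)
    return ratings_mod.RatingDatabase(df, float(scale[0]), float(scale[1]),
                                      name=name)
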