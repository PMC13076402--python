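"""Probe what degrades norm quality: database size vs positivity bias.

Recomputes norms after (a) randomly shrinking the label-source
database and (b) truncating its negative valence range at -1 — the
positivity bias typical of child-directed vocabularies — and compares
recovery correlations and the shape of the estimate distribution.
"""

import warnings

import numpy as np

import affectnorm as an
from affectnorm import evaluation as ev
from affectnorm import labels as lb
from affectnorm import synthetic as syn

warnings.filterwarnings("ignore", category=UserWarning)

world, store = syn.canonical_world()
panel = syn.gen_rating_panel(world, seed=43, **syn.PAPERLIKE["panel"])
summary = an.summarize(an.rescale_responses(panel))
truth = world.valence_series()

conditions = {
    "full": summary,
    "small (n=300)": lb.subset_small(summary, 300, seed=1),
    "bias (>= -1)": lb.subset_bias(summary, -1.0),
    "small + bias": lb.subset_small_bias(summary, 300, -1.0, seed=1),
}

print(f"{'label source':16s} {'r(truth)':>9s} {'est. mean':>10s} "
      f"{'est. sd':>8s} {'modes':>6s}")
for name, src in conditions.items():
    labels = an.extract_labels(src, world.freq_series(), k=60)
    tab = an.estimate_table(store, world.words, labels, "tl")
    r = np.corrcoef(tab.table["rescaled"], truth.loc[tab.words])[0, 1]
    mean, sd, _, modes = ev.distribution_summary(tab.table["rescaled"])
    print(f"{name:16s} {r:9.3f} {mean:+10.3f} {sd:8.3f} {modes:6d}")
print()
print("Shrinking the database at random barely matters; truncating its")
print("negative range lowers the recovery correlation and shifts the")
print("whole estimate distribution leftward, because near-neutral")
print("negative anchors are over-similar to every word and inflate the")
print("negative term of the orientation score.")
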