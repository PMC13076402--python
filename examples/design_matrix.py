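"""Run the full VSM x label-source design matrix.

Writes two synthetic vector spaces (a low-noise and a high-noise one,
standing in for large- vs small-corpus training) and two rating
sources (a clean and a noisy panel) to disk, then runs every
combination: labels from each source, norms in each space, evaluated
against each source as reference.
"""

import tempfile
import warnings
from pathlib import Path

from affectnorm import synthetic as syn
from affectnorm.pipeline import PipelineConfig, RatingSourceConfig, run_design_matrix

warnings.filterwarnings("ignore", category=UserWarning)

tmp = Path(tempfile.mkdtemp(prefix="affectnorm_"))
world, store_good = syn.gen_world(n_words=200, dim=16, noise_sd=0.15, seed=31)
_, store_noisy = syn.gen_world(n_words=200, dim=16, noise_sd=0.8, seed=31)
panel_clean = syn.gen_rating_panel(world, n_raters=60, items_per_rater=60,
                                   rater_noise_sd=0.4, seed=32)
panel_noisy = syn.gen_rating_panel(world, n_raters=60, items_per_rater=60,
                                   rater_noise_sd=1.2, seed=33)
a = syn.write_world(world, store_good, tmp / "a", panel=panel_clean)
b = syn.write_world(world, store_noisy, tmp / "b", panel=panel_noisy)

config = PipelineConfig(
    vectors={"GOOD": str(a["vectors"]), "NOISY": str(b["vectors"])},
    ratings={
        "clean": RatingSourceConfig(path=str(a["ratings"])),
        "noisy": RatingSourceConfig(path=str(b["ratings"])),
    },
    frequencies=str(a["frequencies"]),
    label_k=30,
)
result = run_design_matrix(config, out_dir=tmp / "out")

for ref, grid in result.grids.items():
    print(f"correlations against reference '{ref}' "
          f"(disattenuated by its ICC):")
    print(grid.table.round(3).to_string())
    print()
src, vsm, r = result.grids["clean"].max_cell()
print(f"best cell: labels '{src}' in space '{vsm}' (r = {r:.3f})")
print(f"artifacts written under {tmp / 'out'}")
print()
print("Rows are label sources, columns vector spaces. The low-noise")
print("space dominates regardless of label source - the analogue of a")
print("large adult-trained space beating a small child-specific one.")
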