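#!/usr/bin/env python
"""Generate the synthetic rat-head cohort: 16 base subjects (10 train /
3 validation / 3 test) on the canonical 96x16x16 macrovoxel grid.

Writes results/run/phantoms.h5 and prints the material composition of the
cohort.  Subsequent scripts (02-04) consume the same working directory.
"""

import os
import sys

import h5py
import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from mrtdose.cli import RunConfig, run_stage  # noqa: E402

WORKDIR = os.path.join(os.path.dirname(__file__), "..", "results", "run")

CONFIG = RunConfig(
    seed=1,
    workdir=WORKDIR,
    n_bases={"train": 10, "val": 3, "test": 3},
    n_samples={"train": 120, "val": 30, "test": 3},
    engine={"n_filters": 16, "batch_size": 1, "learning_rate": 2.5e-3,
            "levels": 4, "patience": 18, "max_epochs": 18,
            "adam_beta2": 0.99, "weight_ema": 0.998},
)


def main() -> None:
    run_stage("generate", CONFIG)
    with h5py.File(CONFIG.path("phantoms.h5"), "r") as fh:
        print(f"wrote {CONFIG.path('phantoms.h5')}")
        for pid, grp in fh["phantoms"].items():
            labels = grp["labels"][()]
            frac = np.bincount(labels.ravel(), minlength=3) / labels.size
            print(
                f"  {pid} [{grp.attrs['partition']:>5}] "
                f"air {frac[0]:.2f}  water {frac[1]:.2f}  bone {frac[2]:.2f}  "
                f"tumor voxels {int(grp['tumor_mask'][()].sum())}"
            )


if __name__ == "__main__":
    main()
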