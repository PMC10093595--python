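#!/usr/bin/env python
"""Train the independent peak and valley dose engines on the high-noise
dataset (16 filters, batch 8, Adam/MAE, early stopping on validation MAE).

Writes results/run/models/{peak,valley}.npz and training_history.json, and
prints the per-channel learning curves' endpoints.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
sys.path.insert(0, os.path.dirname(__file__))
CONFIG = __import__("01_build_phantoms").CONFIG
from mrtdose.cli import run_stage  # noqa: E402


def main() -> None:
    run_stage("train", CONFIG)
    with open(CONFIG.path("training_history.json")) as fh:
        histories = json.load(fh)
    for channel, hist in histories.items():
        print(
            f"{channel:>6}: {len(hist['val_mae'])} epochs, best epoch "
            f"{hist['best_epoch']} with validation MAE {min(hist['val_mae']):.5f} "
            f"(first epoch {hist['val_mae'][0]:.5f})"
        )


if __name__ == "__main__":
    main()
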