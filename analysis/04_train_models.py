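#!/usr/bin/env python
"""Train per-target relevance models from each label source.

For every data item with more than 3 positive training labels, screens
feature groups (keep iff pooled CV AUROC > 0.55), compares the six
(imputation x classifier) candidates by cross-validation, and refits the
winner on the full training set — once with manual-selection labels and
once with gaze-derived labels.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, WORKDIR, study_config

from gazerel.pipeline import stage_train


def main() -> None:
    cfg = study_config()
    frames = []
    for source in ("manual", "gaze"):
        counts = stage_train(cfg, WORKDIR, source)
        manifest = pd.read_csv(WORKDIR / "models" / source / "training_manifest.csv")
        manifest.insert(0, "source", source)
        frames.append(manifest)
        print(f"{source}: {counts['models_trained']} models trained "
              f"({counts['eligible_targets']} eligible targets)")
        by_clf = manifest.groupby(["classifier", "imputation"]).size()
        print(by_clf.to_string())
    RESULTS.mkdir(exist_ok=True)
    pd.concat(frames).to_csv(RESULTS / "training_manifest.csv", index=False)
    print(f"training manifest written to {RESULTS / 'training_manifest.csv'}")


if __name__ == "__main__":
    main()
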