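#!/usr/bin/env python
"""Featurize the cases and build the two imputation variants.

Each predictor variable becomes its fixed feature group (35 per lab/vital,
31 per ventilator setting, 9 per medication, 4 per culture/procedure, 2
per intake-output, 1 per atemporal variable); constant and duplicate
columns are dropped on the training matrix, then missing values are filled
two ways (median/mode and regression), giving the two training data sets
the model selection chooses between.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, WORKDIR, study_config

from gazerel.pipeline import stage_featurize


def main() -> None:
    cfg = study_config()
    counts = stage_featurize(cfg, WORKDIR)
    print(f"training matrix: {counts['train_rows']} rows x "
          f"{counts['full_width']} features "
          f"({counts['retained_width']} after dropping constants/duplicates)")
    print(f"evaluation matrix: {counts['eval_rows']} rows")
    schema = json.loads((WORKDIR / "features" / "schema.json").read_text())
    print(f"constant features removed: {len(schema['removed_constant'])}; "
          f"duplicate classes merged: {len(schema['duplicate_classes'])}")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "feature_schema.json").write_text(json.dumps(
        {k: schema[k] for k in ("removed_constant", "duplicate_classes")},
        indent=2,
    ))


if __name__ == "__main__":
    main()
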