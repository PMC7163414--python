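#!/usr/bin/env python
"""Quality-control the sessions and derive both label sets.

Discards sessions with incomplete gaze capture or a skipped selection
task, accumulates per-item gaze dwell over the dynamic layout, and labels
every present data item: positive by gaze when total dwell >= 250 ms,
positive by manual selection when its checkbox was ticked.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, WORKDIR, study_config

from gazerel.pipeline import stage_label


def main() -> None:
    cfg = study_config()
    counts = stage_label(cfg, WORKDIR)
    qc = pd.read_csv(WORKDIR / "labels" / "qc.csv")
    for split in ("train", "eval"):
        sub = qc[qc["split"] == split]
        print(f"{split}: {len(sub)} sessions reviewed, "
              f"{int((~sub['valid']).sum())} discarded by QC, "
              f"{int(sub['valid'].sum())} usable")
    labels = pd.read_csv(WORKDIR / "labels" / "labels.csv")
    rate = (
        labels.groupby("source")["label"].apply(lambda s: (s == "positive").mean())
    )
    print("positive-label rate by source:")
    print(rate.to_string())
    RESULTS.mkdir(exist_ok=True)
    qc.to_csv(RESULTS / "session_qc.csv", index=False)
    print(f"QC table written to {RESULTS / 'session_qc.csv'}")


if __name__ == "__main__":
    main()
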