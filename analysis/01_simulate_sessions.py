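#!/usr/bin/env python
"""Simulate the study cohorts and review sessions.

Generates 178 training cases (one reviewed session each) and 18 evaluation
cases reviewed by 4 reviewers apiece, each session consisting of a ~60 Hz
gaze stream over a scrolling element layout plus checkbox selections, all
driven by a latent logistic relevance model with known coefficients.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, WORKDIR, study_config

from gazerel.pipeline import stage_simulate


def main() -> None:
    cfg = study_config()
    counts = stage_simulate(cfg, WORKDIR)
    print(f"simulated {counts['train_cases']} training cases "
          f"and {counts['eval_cases']} evaluation cases "
          f"({counts['sessions']} sessions total)")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cohort_manifest.csv").write_bytes(
        (WORKDIR / "sim" / "cohort.csv").read_bytes()
    )
    print(f"cohort manifest copied to {RESULTS / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
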