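#!/usr/bin/env python
"""Compare manual-selection and gaze-derived models on the evaluation set.

Scores each pair of models on the usable evaluation sessions (manual
selection is the gold standard), computes per-pair AUROCs with paired
bootstrap 95% CIs, flags pairs whose AUROC-difference CI excludes zero,
and runs a paired Wilcoxon signed-rank test across all pairs.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, WORKDIR, study_config

from gazerel.pipeline import stage_evaluate


def main() -> None:
    cfg = study_config()
    report = stage_evaluate(cfg, WORKDIR)
    s = report.summary()
    print(f"{s['n_pairs']} model pairs evaluated")
    print(f"mean AUROC: manual {s['mean_auroc_manual']:.3f}, "
          f"gaze {s['mean_auroc_gaze']:.3f}")
    print(f"paired Wilcoxon signed-rank: W+={s['wilcoxon_statistic']:.1f}, "
          f"P={s['wilcoxon_p']:.3f}")
    print(f"significantly better pairs: manual {s['n_significant_manual']}, "
          f"gaze {s['n_significant_gaze']}, "
          f"no difference {s['n_not_significant']}")
    RESULTS.mkdir(exist_ok=True)
    for name in ("report.csv", "scatter.csv", "summary.json"):
        (RESULTS / f"comparison_{name}").write_bytes(
            (WORKDIR / "eval" / name).read_bytes()
        )
    print(f"comparison tables written to {RESULTS}/comparison_*")


if __name__ == "__main__":
    main()
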