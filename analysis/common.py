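"""Shared study configuration for the numbered analysis scripts.

The training batch is 178 reviewed sessions and the evaluation batch is
18 cases x 4 reviewers, with session-loss rates sized so that roughly a
quarter of training sessions fail QC. Heavy pipeline artifacts go to
scratch/; the scripts copy only small summary tables into results/.
"""

from pathlib import Path

from gazerel.config import RunConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_COUNTS = {
    "vitals": 3,
    "ventilator": 2,
    "labs": 5,
    "medications": 3,
    "procedures": 1,
    "cultures": 1,
    "intake_output": 1,
    "demographics": 6,
    "diagnosis": 1,
}


def study_config(seed: int = 1) -> RunConfig:
    sim = SimConfig(
        n_cases=178,
        seed=seed,
        variable_counts=dict(STUDY_COUNTS),
        p_gaze_incomplete=0.18,
        p_selection_skipped=0.08,
    )
    return RunConfig(sim=sim, n_eval_cases=18, reviewers_per_case=4,
                     bootstrap_b=2000, seed=seed)
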