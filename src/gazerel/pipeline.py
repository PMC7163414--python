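"""End-to-end study orchestration.

Stages: ``simulate`` (cohorts + review sessions) -> ``label`` (QC, dwell,
gaze/manual labels) -> ``featurize`` (matrices + preprocessing variants) ->
``train`` (per-target model selection, once per label source) ->
``evaluate`` (paired AUROC comparison against the manual gold standard).

Each stage writes its outputs plus a JSON manifest (config hash, seed,
input checksums, row counts) under a fixed directory layout, and is
deterministic given (config, seed): a rerun with an unchanged config
reproduces identical text outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from gazerel.config import RunConfig, SimConfig
from gazerel.errors import InputError
from gazerel import io as gio
from gazerel.evaluation import ComparisonReport, build_report
from gazerel.features import (
    FeatureMatrix,
    FeatureSchema,
    assemble_matrix,
    deduplicate_features,
    impute_median_mode,
    impute_regression,
    remove_constant_features,
)
from gazerel.gaze import (
    ABSENT,
    POSITIVE,
    LabelSet,
    compute_dwell,
    derive_gaze_labels,
    derive_manual_labels,
    qc_session,
)
from gazerel.modeling import (
    TrainedModel,
    default_screening_learner,
    eligible_targets,
    predict_relevance,
    screen_feature_groups,
    select_and_train,
)
from gazerel.simulate import SessionSim, generate_cohort, simulate_session, true_relevance

logger = logging.getLogger(__name__)

STAGES = ("simulate", "label", "featurize", "train", "evaluate")


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(8)
    names = ("train_cohort", "eval_cohort", "train_sessions", "eval_sessions",
             "screen", "select", "bootstrap", "spare")
    return {name: int(s % 2**31) for name, s in zip(names, state)}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: RunConfig,
                    inputs: list[Path], counts: dict[str, int]) -> None:
    doc = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {str(p.relative_to(outdir)): _checksum(p) for p in inputs if p.exists()},
        "counts": counts,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(doc, sort_keys=True, indent=2))


def _require_artifact(path: Path, produced_by: str) -> None:
    if not path.exists():
        raise InputError(
            f"missing upstream artifact {path}; run the '{produced_by}' stage first"
        )


# ---------------------------------------------------------------- simulate


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate training and evaluation cohorts and their review sessions.

    The training split has one reviewer session per case; the evaluation
    split has ``reviewers_per_case`` sessions per case (the evaluation unit
    is a case x reviewer session). One latent relevance model, drawn with
    the training cohort, drives every session.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    sim_dir = outdir / "sim"
    (sim_dir / "cases").mkdir(parents=True, exist_ok=True)
    (sim_dir / "sessions").mkdir(parents=True, exist_ok=True)

    train_cfg = dataclasses.replace(config.sim, seed=seeds["train_cohort"])
    train_cases, model = generate_cohort(train_cfg)
    eval_cfg = dataclasses.replace(
        config.sim, n_cases=config.n_eval_cases, seed=seeds["eval_cohort"]
    )
    eval_cases, _ = generate_cohort(eval_cfg)
    eval_cases = [
        dataclasses.replace(c, case_id=f"eval_{c.case_id}") for c in eval_cases
    ]

    index_rows = []
    selections: dict[str, set[str] | None] = {}
    truth: dict[str, dict] = {}

    def emit(case, session_id: str, seed: int) -> None:
        relevance = true_relevance(case, model)
        sess = simulate_session(case, relevance, config.sim, seed)
        gio.write_gaze_csv(sess.gaze_stream, sim_dir / "sessions" / f"{session_id}.gaze.csv")
        gio.write_layout_jsonl(
            sess.layout_stream, sim_dir / "sessions" / f"{session_id}.layout.jsonl"
        )
        selections[session_id] = sess.manual_selections
        truth[session_id] = {
            "intended_dwell_ms": sess.intended_dwell_ms,
            "relevant_draw": {k: bool(v) for k, v in sess.relevant_draw.items()},
            "qc_flags": sorted(sess.qc_flags),
        }

    train_sess_ss = np.random.SeedSequence(seeds["train_sessions"])
    for case, child in zip(train_cases, train_sess_ss.spawn(len(train_cases))):
        gio.write_case(case, sim_dir / "cases" / f"{case.case_id}.json")
        sid = case.case_id
        emit(case, sid, int(child.generate_state(1)[0] % 2**31))
        index_rows.append({"session_id": sid, "case_id": case.case_id, "split": "train"})

    n_eval_sessions = len(eval_cases) * config.reviewers_per_case
    eval_sess_ss = np.random.SeedSequence(seeds["eval_sessions"])
    children = iter(eval_sess_ss.spawn(n_eval_sessions))
    for case in eval_cases:
        gio.write_case(case, sim_dir / "cases" / f"{case.case_id}.json")
        for r in range(config.reviewers_per_case):
            sid = f"{case.case_id}_r{r}"
            emit(case, sid, int(next(children).generate_state(1)[0] % 2**31))
            index_rows.append({"session_id": sid, "case_id": case.case_id, "split": "eval"})

    idx = pd.DataFrame(index_rows, columns=["session_id", "case_id", "split"])
    idx.to_csv(sim_dir / "sessions.csv", index=False)
    gio.write_cohort_manifest(train_cases + eval_cases, sim_dir / "cohort.csv")
    gio.write_selections_csv(selections, sim_dir / "selections.csv")
    skipped = sorted(sid for sid, sel in selections.items() if sel is None)
    (sim_dir / "selections_recorded.json").write_text(
        json.dumps({"skipped_sessions": skipped}, sort_keys=True)
    )
    gio.write_relevance_model(model, sim_dir / "relevance_model.json")
    (sim_dir / "truth.json").write_text(json.dumps(truth, sort_keys=True))

    counts = {
        "train_cases": len(train_cases),
        "eval_cases": len(eval_cases),
        "sessions": len(index_rows),
    }
    _write_manifest(outdir, "simulate", config, [sim_dir / "sessions.csv"], counts)
    return counts


def _load_sessions(outdir: Path) -> tuple[pd.DataFrame, dict[str, SessionSim]]:
    sim_dir = outdir / "sim"
    _require_artifact(sim_dir / "sessions.csv", "simulate")
    idx = pd.read_csv(sim_dir / "sessions.csv")
    sel_df = pd.read_csv(sim_dir / "selections.csv")
    skipped = set(
        json.loads((sim_dir / "selections_recorded.json").read_text())["skipped_sessions"]
    )
    sel_by_session: dict[str, set[str]] = {
        sid: set(grp["item_id"]) for sid, grp in sel_df.groupby("case_id")
    }
    sessions: dict[str, SessionSim] = {}
    for row in idx.itertuples():
        sid = row.session_id
        gaze = gio.read_gaze_csv(sim_dir / "sessions" / f"{sid}.gaze.csv")
        layout = gio.read_layout_jsonl(sim_dir / "sessions" / f"{sid}.layout.jsonl")
        manual = None if sid in skipped else sel_by_session.get(sid, set())
        sessions[sid] = SessionSim(
            case_id=row.case_id,
            gaze_stream=gaze,
            layout_stream=layout,
            manual_selections=manual,
        )
    return idx, sessions


# ------------------------------------------------------------------ label


def stage_label(config: RunConfig, outdir: Path) -> dict:
    """QC every session, accumulate dwell, and derive both label sets."""
    idx, sessions = _load_sessions(outdir)
    sim_dir = outdir / "sim"
    label_dir = outdir / "labels"
    label_dir.mkdir(parents=True, exist_ok=True)

    case_items: dict[str, set[str]] = {}
    for cid in idx["case_id"].unique():
        case = gio.read_case(sim_dir / "cases" / f"{cid}.json")
        case_items[cid] = case.present_items()

    qc_rows, label_rows = [], []
    dwells: dict[str, dict[str, float]] = {}
    for row in idx.itertuples():
        sid, cid = row.session_id, row.case_id
        sess = sessions[sid]
        report = qc_session(sess, config.min_valid_fraction)
        qc_rows.append(
            {
                "session_id": sid,
                "split": row.split,
                "valid": report.valid,
                "reasons": ";".join(report.reasons),
                "valid_sample_fraction": round(report.valid_sample_fraction, 6),
            }
        )
        if not report.valid:
            continue
        present = case_items[cid]
        dwell = compute_dwell(sess.gaze_stream, sess.layout_stream, config.max_gap_ms)
        dwells[sid] = dwell.dwell_ms
        gaze_labels = derive_gaze_labels(dwell, present, config.dwell_threshold_ms)
        manual_labels = derive_manual_labels(sess.manual_selections, present)
        for ls in (gaze_labels, manual_labels):
            for item, lab in sorted(ls.labels.items()):
                label_rows.append(
                    {"case_id": sid, "item_id": item, "label": lab, "source": ls.source}
                )

    pd.DataFrame(
        qc_rows,
        columns=["session_id", "split", "valid", "reasons", "valid_sample_fraction"],
    ).to_csv(label_dir / "qc.csv", index=False)
    gio.write_dwell_csv(dwells, label_dir / "dwell.csv")
    gio.write_labels_csv(label_rows, label_dir / "labels.csv")

    n_valid = sum(1 for r in qc_rows if r["valid"])
    counts = {
        "sessions": len(qc_rows),
        "sessions_passing_qc": n_valid,
        "sessions_discarded": len(qc_rows) - n_valid,
        "label_rows": len(label_rows),
    }
    _write_manifest(
        outdir, "label", config,
        [sim_dir / "sessions.csv", label_dir / "labels.csv"], counts,
    )
    return counts


# -------------------------------------------------------------- featurize


def _train_fill_values(train_df: pd.DataFrame, nominal: set[str]) -> pd.Series:
    fills = {}
    for col in train_df.columns:
        observed = train_df[col].dropna()
        if observed.empty:
            fills[col] = 0.0
        elif col in nominal:
            counts = observed.value_counts()
            top = counts[counts == counts.max()]
            fills[col] = float(min(top.index))
        else:
            fills[col] = float(observed.median())
    return pd.Series(fills)


def stage_featurize(config: RunConfig, outdir: Path) -> dict:
    """Build fixed-width matrices and the two imputation variants.

    Training rows are the QC-passing training sessions (one per case);
    evaluation rows are the QC-passing evaluation sessions, whose features
    come from the underlying case. Constant removal and deduplication are
    fit on the training matrix; evaluation rows are restricted to the
    retained columns and filled with training-set medians/modes in both
    variants (imputation statistics never leak from evaluation data).
    """
    label_dir = outdir / "labels"
    _require_artifact(label_dir / "qc.csv", "label")
    sim_dir = outdir / "sim"
    qc = pd.read_csv(label_dir / "qc.csv")
    idx = pd.read_csv(sim_dir / "sessions.csv")
    valid = set(qc.loc[qc["valid"], "session_id"])

    schema = FeatureSchema.from_counts(config.sim.variable_counts)
    cases = {
        cid: gio.read_case(sim_dir / "cases" / f"{cid}.json")
        for cid in idx["case_id"].unique()
    }

    def session_matrix(split: str) -> FeatureMatrix:
        rows = idx[(idx["split"] == split) & idx["session_id"].isin(valid)]
        cohort = [cases[cid] for cid in rows["case_id"]]
        fm = assemble_matrix(cohort, schema)
        fm.values.index = list(rows["session_id"])
        return fm

    train_fm = session_matrix("train")
    eval_fm = session_matrix("eval")

    train_fm, removed = remove_constant_features(train_fm)
    train_fm, dup_classes = deduplicate_features(train_fm)
    kept_cols = list(train_fm.values.columns)
    eval_df = eval_fm.values[kept_cols]

    train_median = impute_median_mode(train_fm)
    train_regression = impute_regression(train_fm)
    fills = _train_fill_values(train_fm.values, schema.nominal_columns())
    eval_filled = eval_df.fillna(fills)

    feat_dir = outdir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    gio.write_matrix_csv(train_fm.values, feat_dir / "train_raw.csv")
    gio.write_matrix_csv(train_median.values, feat_dir / "train_median.csv")
    gio.write_matrix_csv(train_regression.values, feat_dir / "train_regression.csv")
    gio.write_matrix_csv(eval_filled, feat_dir / "eval.csv")
    (feat_dir / "schema.json").write_text(
        json.dumps(
            {
                "schema": schema.to_dict(),
                "retained_columns": kept_cols,
                "removed_constant": removed,
                "duplicate_classes": dup_classes,
            },
            sort_keys=True,
        )
    )
    counts = {
        "train_rows": len(train_fm.values),
        "eval_rows": len(eval_filled),
        "full_width": schema.width,
        "retained_width": len(kept_cols),
    }
    _write_manifest(outdir, "featurize", config, [feat_dir / "schema.json"], counts)
    return counts


def _load_matrices(outdir: Path, schema: FeatureSchema):
    feat_dir = outdir / "features"
    _require_artifact(feat_dir / "train_median.csv", "featurize")
    med = FeatureMatrix(gio.read_matrix_csv(feat_dir / "train_median.csv"), schema)
    reg = FeatureMatrix(gio.read_matrix_csv(feat_dir / "train_regression.csv"), schema)
    ev = FeatureMatrix(gio.read_matrix_csv(feat_dir / "eval.csv"), schema)
    return med, reg, ev


def _labelsets(labels_df: pd.DataFrame, source: str, split_sessions: set[str]) -> dict[str, LabelSet]:
    sub = labels_df[(labels_df["source"] == source) & labels_df["case_id"].isin(split_sessions)]
    out: dict[str, LabelSet] = {}
    for sid, grp in sub.groupby("case_id"):
        out[sid] = LabelSet(source=source, labels=dict(zip(grp["item_id"], grp["label"])))
    return out


# ------------------------------------------------------------------ train


def stage_train(config: RunConfig, outdir: Path, source: str) -> dict:
    """Screen, select, and train one relevance model per eligible target."""
    if source not in ("manual", "gaze"):
        raise InputError(f"source must be manual or gaze, got {source!r}")
    label_dir = outdir / "labels"
    _require_artifact(label_dir / "labels.csv", "label")
    seeds = _stage_seeds(config.seed)
    schema = FeatureSchema.from_counts(config.sim.variable_counts)
    med, reg, _ = _load_matrices(outdir, schema)

    idx = pd.read_csv(outdir / "sim" / "sessions.csv")
    train_sessions = set(idx.loc[idx["split"] == "train", "session_id"]) & set(med.values.index)
    labels_df = gio.read_labels_csv(label_dir / "labels.csv")
    labelsets = _labelsets(labels_df, source, train_sessions)
    universe = schema.time_series_variables()
    specs = eligible_targets(labelsets, universe, config.min_positives)

    model_dir = outdir / "models" / source
    model_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for spec in specs:
        rows = [sid for sid in med.values.index if labelsets[sid].get(spec.item_id) != ABSENT]
        y = pd.Series(
            [1 if labelsets[sid].get(spec.item_id) == POSITIVE else 0 for sid in rows],
            index=rows,
        )
        med_sub = FeatureMatrix(med.values.loc[rows], schema)
        reg_sub = FeatureMatrix(reg.values.loc[rows], schema)
        kept = {}
        for imp, fm in (("median", med_sub), ("regression", reg_sub)):
            kept[imp], _scores = screen_feature_groups(
                fm, y, config.screen_auroc_threshold, config.cv_folds,
                learner=default_screening_learner(
                    seeds["screen"], config.screen_rf_n_estimators
                ),
                seed=seeds["screen"],
            )
        model = select_and_train(
            med_sub, reg_sub, y, kept, spec.item_id, source,
            cv=config.cv_folds, seed=seeds["select"],
            rf_n_estimators=config.rf_n_estimators,
        )
        with (model_dir / f"{spec.item_id}.pkl").open("wb") as fh:
            pickle.dump(model, fh)
        (model_dir / f"{spec.item_id}.json").write_text(
            json.dumps(model.sidecar(), sort_keys=True, indent=2)
        )
        manifest_rows.append(
            {
                "item_id": spec.item_id,
                "n_positive": spec.n_positive,
                "n_negative": spec.n_negative,
                "n_absent": spec.n_absent,
                "imputation": model.config.imputation if model.config else "",
                "classifier": model.config.classifier if model.config else "fallback",
                "n_features": len(model.feature_columns),
            }
        )
    pd.DataFrame(
        manifest_rows,
        columns=["item_id", "n_positive", "n_negative", "n_absent",
                 "imputation", "classifier", "n_features"],
    ).to_csv(model_dir / "training_manifest.csv", index=False)
    counts = {"eligible_targets": len(specs), "models_trained": len(manifest_rows)}
    _write_manifest(outdir, f"train_{source}", config,
                    [model_dir / "training_manifest.csv"], counts)
    return counts


# --------------------------------------------------------------- evaluate


def stage_evaluate(config: RunConfig, outdir: Path) -> ComparisonReport:
    """Score both model families on the evaluation sessions and compare.

    The gold standard is always the manual selection labels of the
    evaluation sessions; per target, sessions where the item is absent are
    excluded from scoring.
    """
    seeds = _stage_seeds(config.seed)
    schema = FeatureSchema.from_counts(config.sim.variable_counts)
    _, _, eval_fm = _load_matrices(outdir, schema)
    label_dir = outdir / "labels"
    labels_df = gio.read_labels_csv(label_dir / "labels.csv")
    idx = pd.read_csv(outdir / "sim" / "sessions.csv")
    eval_sessions = set(idx.loc[idx["split"] == "eval", "session_id"]) & set(eval_fm.values.index)
    gold = _labelsets(labels_df, "manual", eval_sessions)

    models: dict[str, dict[str, TrainedModel]] = {}
    for source in ("manual", "gaze"):
        model_dir = outdir / "models" / source
        _require_artifact(model_dir / "training_manifest.csv", f"train --source {source}")
        models[source] = {}
        for pkl in sorted(model_dir.glob("*.pkl")):
            with pkl.open("rb") as fh:
                m: TrainedModel = pickle.load(fh)
            models[source][m.item_id] = m

    shared = sorted(set(models["manual"]) & set(models["gaze"]))
    target_data = {}
    for item in shared:
        rows = [sid for sid in eval_fm.values.index if gold.get(sid) and gold[sid].get(item) != ABSENT]
        if not rows:
            continue
        y = np.array([1 if gold[sid].get(item) == POSITIVE else 0 for sid in rows])
        sub = FeatureMatrix(eval_fm.values.loc[rows], schema)
        sm = predict_relevance(models["manual"][item], sub)
        sg = predict_relevance(models["gaze"][item], sub)
        target_data[item] = (sm, sg, y)

    report = build_report(
        target_data, b=config.bootstrap_b, alpha=config.alpha, seed=seeds["bootstrap"]
    )
    eval_dir = outdir / "eval"
    eval_dir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(eval_dir / "report.csv", index=False, float_format="%.6f")
    (eval_dir / "summary.json").write_text(
        json.dumps(report.summary(), sort_keys=True, indent=2)
    )
    # scatter data for the manual-vs-gaze AUROC figure
    scatter = report.to_frame()[
        ["item_id", "auroc_manual", "ci_manual_lo", "ci_manual_hi",
         "auroc_gaze", "ci_gaze_lo", "ci_gaze_hi", "significant"]
    ]
    scatter.to_csv(eval_dir / "scatter.csv", index=False, float_format="%.6f")
    _write_manifest(outdir, "evaluate", config, [eval_dir / "report.csv"],
                    {"pairs_evaluated": len(report.pairs)})
    return report


# ------------------------------------------------------------- dispatcher


def run_stage(stage: str, config: RunConfig, outdir: Path, source: str | None = None):
    """Run one named stage; non-initial stages check their upstream outputs."""
    outdir = Path(outdir)
    if stage == "simulate":
        return stage_simulate(config, outdir)
    if stage == "label":
        return stage_label(config, outdir)
    if stage == "featurize":
        return stage_featurize(config, outdir)
    if stage == "train":
        return stage_train(config, outdir, source or "manual")
    if stage == "evaluate":
        return stage_evaluate(config, outdir)
    raise InputError(f"unknown stage {stage!r}; expected one of {STAGES}")


def run_all(config: RunConfig, outdir: Path) -> ComparisonReport:
    """Execute the whole study end to end and return the comparison report."""
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_label(config, outdir)
    stage_featurize(config, outdir)
    stage_train(config, outdir, "manual")
    stage_train(config, outdir, "gaze")
    return stage_evaluate(config, outdir)
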