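"""End-to-end orchestration: normalize, split, three-stage gene selection,
five base learners, top-3 majority vote, evaluation.

All feature selection is fit on the training split only; the test split's
values are content-hashed before selection and verified untouched before the
final evaluation. A ``selection_before_split`` flag reproduces the literal
select-then-split ordering for replication studies (it leaks test information
into selection and is off by default).

Every source of randomness derives its seed deterministically from the global
seed, so identical configurations give identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boruta as boruta_mod
from . import imrmr as imrmr_mod
from . import ssa as ssa_mod
from .dataset_io import (
    ExpressionDataset,
    load_expression_table,
    minmax_normalize,
    stratified_split,
    write_split_membership,
)
from .ensemble import EnsembleModel, predict_ensemble, votes_frame
from .errors import ConfigError, PipelineError
from .learners import LEARNER_IDS, rank_learners, train_base_learners
from .metrics import MetricsReport, compute_metrics, macro_ovr_auc
from .synthetic_data import SyntheticSpec, generate_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_ablation"]

STAGES = ("boruta", "imrmr", "ssa", "ensemble")


@dataclass
class PipelineConfig:
    """One input source (a delimited table or a synthetic spec) plus stage configs."""

    input_path: str = None
    label_column: str = "class"
    delimiter: str = ","
    synthetic: SyntheticSpec = None
    ratio: float = 0.85
    boruta: boruta_mod.BorutaConfig = field(default_factory=boruta_mod.BorutaConfig)
    imrmr: imrmr_mod.IMRMRConfig = field(default_factory=imrmr_mod.IMRMRConfig)
    ssa: ssa_mod.SSAConfig = field(default_factory=ssa_mod.SSAConfig)
    learner_hyperparameters: dict = field(default_factory=dict)
    sweep_alpha: bool = False
    skip_stages: tuple = ()
    selection_before_split: bool = False
    seed: int = 0
    out_dir: str = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_path or synthetic must be set")
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages to skip: {sorted(unknown)}")
        if not 0 < self.ratio < 1:
            raise ConfigError("ratio must be in (0, 1)")


@dataclass
class PipelineReport:
    feature_counts: dict              # stage -> gene count, non-increasing
    selected_genes: dict              # stage -> gene id list
    learner_accuracies: dict          # learner_id -> training CV accuracy
    top3: list
    test_metrics: dict                # learner_id / "ensemble" -> MetricsReport
    ensemble_auc: float
    alpha_used: float
    ssa_trace: list
    seeds: dict
    runtimes: dict                    # stage -> seconds
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["test_metrics"] = {k: v.to_dict() for k, v in self.test_metrics.items()}
        out.pop("runtimes")  # wall-clock varies run to run; kept out of the canonical JSON
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _stage_seeds(seed: int) -> dict:
    words = np.random.SeedSequence(seed).generate_state(6)
    names = ("synthetic", "split", "boruta", "ssa", "learners", "spare")
    return {k: int(w % 2**31) for k, w in zip(names, words)}


def _hash_values(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()


def _load_input(config: PipelineConfig, seeds: dict) -> ExpressionDataset:
    if config.input_path is not None:
        return load_expression_table(config.input_path, config.label_column, config.delimiter)
    spec = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
    dataset, _ = generate_dataset(spec)
    return dataset


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full (or ablated) pipeline and return the report.

    Stage feature counts are non-increasing along the pipeline; an empty
    post-stage gene set aborts with the stage name.
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    runtimes = {}
    t0 = time.perf_counter()

    dataset = _load_input(config, seeds)

    if config.selection_before_split:
        # literal ordering: selection sees the whole dataset (leaks test data)
        work = dataset
        split = None
    else:
        split = stratified_split(dataset, config.ratio, seeds["split"])
        work = split.train

    if split is None:
        split = stratified_split(dataset, config.ratio, seeds["split"])
    train, test, _ = minmax_normalize(split.train, split.test)
    test_hash = _hash_values(test.values)
    runtimes["prepare"] = time.perf_counter() - t0

    selection = train if not config.selection_before_split else minmax_normalize(work)[0]
    feature_counts = {"input": dataset.n_genes}
    selected_genes = {}
    current_ids = list(train.gene_ids)

    # --- stage 1: shadow-feature filter ---------------------------------
    alpha_used = config.imrmr.alpha
    ssa_trace = []
    if "boruta" not in config.skip_stages:
        t = time.perf_counter()
        bcfg = dataclasses.replace(config.boruta, seed=seeds["boruta"])
        bres = boruta_mod.run_boruta(selection.subset_genes(current_ids), bcfg)
        current_ids = bres.selected_ids
        runtimes["boruta"] = time.perf_counter() - t
        if not current_ids:
            raise PipelineError("stage boruta left an empty gene set")
        feature_counts["boruta"] = len(current_ids)
        selected_genes["boruta"] = list(current_ids)

    # --- stage 2: relevance/redundancy ranking --------------------------
    if "imrmr" not in config.skip_stages:
        t = time.perf_counter()
        icfg = config.imrmr
        subset = selection.subset_genes(current_ids)
        if config.sweep_alpha:
            alpha_used, _ = imrmr_mod.sweep_alpha(subset, icfg)
            icfg = dataclasses.replace(icfg, alpha=alpha_used)
        ires = imrmr_mod.imrmr_select(subset, icfg)
        alpha_used = ires.alpha_used
        current_ids = ires.selected_ids
        runtimes["imrmr"] = time.perf_counter() - t
        if not current_ids:
            raise PipelineError("stage imrmr left an empty gene set")
        feature_counts["imrmr"] = len(current_ids)
        selected_genes["imrmr"] = list(current_ids)

    # --- stage 3: salp-swarm wrapper -------------------------------------
    if "ssa" not in config.skip_stages:
        t = time.perf_counter()
        scfg = dataclasses.replace(config.ssa, seed=seeds["ssa"])
        subset = selection.subset_genes(current_ids)
        sres = ssa_mod.run_ssa(subset.values, subset.encoded_labels, scfg)
        current_ids = [g for g, m in zip(current_ids, sres.mask) if m]
        ssa_trace = list(map(float, sres.trace))
        runtimes["ssa"] = time.perf_counter() - t
        if not current_ids:
            raise PipelineError("stage ssa left an empty gene set")
        feature_counts["ssa"] = len(current_ids)
        selected_genes["ssa"] = list(current_ids)

    if test_hash != _hash_values(test.values):
        raise PipelineError("test split was modified during feature selection")

    # --- base learners, ranking, ensemble, evaluation --------------------
    t = time.perf_counter()
    train_sel = train.subset_genes(current_ids)
    test_sel = test.subset_genes(current_ids)
    y_train = train_sel.encoded_labels
    y_test = test_sel.encoded_labels
    fits = train_base_learners(
        train_sel.values, y_train, seed=seeds["learners"],
        hyperparameters=config.learner_hyperparameters,
    )
    accuracies = {lid: f.cv_accuracy for lid, f in fits.items()}
    macro_f1 = {lid: f.macro_f1 for lid, f in fits.items()}
    ranking = rank_learners(accuracies, k=3, macro_f1=macro_f1)
    runtimes["learners"] = time.perf_counter() - t

    test_metrics: dict[str, MetricsReport] = {}
    classes = sorted(set(np.unique(y_train)) | set(np.unique(y_test)))
    for lid in LEARNER_IDS:
        pred = fits[lid].model.predict(test_sel.values)
        test_metrics[lid] = compute_metrics(y_test, pred, classes=classes)

    ensemble_auc = float("nan")
    top3 = []
    if "ensemble" not in config.skip_stages:
        top3 = ranking.top_ids
        model = EnsembleModel(
            members=[(lid, fits[lid].model) for lid in top3],
            feature_mask=np.ones(len(current_ids), dtype=bool),
            gene_ids=current_ids,
            label_mapping={i: c for i, c in enumerate(train.class_names)},
        )
        pred = predict_ensemble(model, test_sel.values)
        test_metrics["ensemble"] = compute_metrics(y_test, pred, classes=classes)
        # per-class score = fraction of members voting for the class
        votes = np.stack([fits[lid].model.predict(test_sel.values) for lid in top3])
        scores = np.stack([(votes == c).mean(axis=0) for c in classes], axis=1)
        try:
            ensemble_auc = macro_ovr_auc(y_test, scores, classes=classes)
        except Exception:
            ensemble_auc = float("nan")

    report = PipelineReport(
        feature_counts=feature_counts,
        selected_genes=selected_genes,
        learner_accuracies=accuracies,
        top3=list(top3),
        test_metrics=test_metrics,
        ensemble_auc=ensemble_auc,
        alpha_used=alpha_used,
        ssa_trace=ssa_trace,
        seeds=seeds,
        runtimes=runtimes,
        config_echo={
            "ratio": config.ratio,
            "seed": config.seed,
            "skip_stages": list(config.skip_stages),
            "sweep_alpha": config.sweep_alpha,
        },
    )
    if config.out_dir:
        _write_artifacts(report, split, config)
    return report


def _write_artifacts(report: PipelineReport, split, config: PipelineConfig) -> None:
    from pathlib import Path

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / "report.json")
    rows = []
    for name, rep in report.test_metrics.items():
        frame = rep.to_frame()
        frame.insert(0, "model", name)
        rows.append(frame)
    pd.concat(rows).to_csv(out / "metrics.csv", index=False)
    for stage, genes in report.selected_genes.items():
        (out / f"selected_{stage}.txt").write_text("\n".join(map(str, genes)) + "\n")
    if report.ssa_trace:
        pd.DataFrame(
            {"iteration": range(1, len(report.ssa_trace) + 1), "best_fitness": report.ssa_trace}
        ).to_csv(out / "ssa_trace.csv", index=False)
    write_split_membership(split, out / "split.csv")


def run_ablation(config: PipelineConfig, stages_to_skip) -> dict:
    """Run the full pipeline and a variant skipping ``stages_to_skip``.

    Returns ``{"full": report, "ablated": report, "table": DataFrame}`` where
    the table compares test accuracy and gene counts between the variants.
    """
    stages_to_skip = tuple(stages_to_skip)
    unknown = set(stages_to_skip) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages to skip: {sorted(unknown)}")
    full = run_pipeline(dataclasses.replace(config, skip_stages=()))
    ablated = run_pipeline(dataclasses.replace(config, skip_stages=stages_to_skip))
    rows = []
    for name, rep in (("full", full), ("ablated", ablated)):
        final_count = list(rep.feature_counts.values())[-1]
        for model, met in rep.test_metrics.items():
            rows.append(
                {"variant": name, "model": model, "test_accuracy": met.ACC,
                 "final_gene_count": final_count}
            )
    return {"full": full, "ablated": ablated, "table": pd.DataFrame(rows)}
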