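"""End-to-end pipeline: simulate/load -> validate -> split -> impute ->
scale/pad -> resample (train only) -> train -> evaluate.

The stage order enforces leak-freedom: the stratified 80/20 split happens
first, the imputer and scaler are fitted on the training split only, and
SMOTEENN resampling touches only training patients.  Every artifact is
stamped with a hash of the configuration and the global seed, and one
global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .evaluate import (evaluation_report, round2, worked_example_confusion,
                       one_vs_all_metrics)
from .impute import ImputerConfig, fit_autoencoder_imputer, impute
from .model import CostMatrix, ModelConfig, RNNLRModel
from .resample import FeatureTable, smoteenn
from .schema import Cohort, read_cohort, validate_cohort, write_cohort
from .sequences import PaddedSequenceSet, build_sequences, fit_scaler
from .simulate import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_worked_example",
           "stage_seed", "sequence_set_from_flat"]

log = logging.getLogger("rnnlr")

_STAGES = ("simulate", "split", "impute", "scale", "resample", "train")


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented fan-out of the global seed to one per-stage seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class PipelineConfig:
    cohort_path: str | None = None      # read a cohort CSV ...
    simulate: SimConfig | None = None   # ... or draw one (exactly one set)
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    phenotype_cost: float = 200.0
    split_fraction: float = 0.80        # training share
    resample: bool = True
    k_smote: int = 5
    k_enn: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if (self.cohort_path is None) == (self.simulate is None):
            raise ValueError("set exactly one of cohort_path / simulate")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if "imputer" in raw:
            raw["imputer"] = ImputerConfig(
                **{**raw["imputer"],
                   "hidden": tuple(raw["imputer"].get("hidden", (32, 16)))})
        if "model" in raw:
            m = dict(raw["model"])
            if "head_widths" in m:
                m["head_widths"] = tuple(m["head_widths"])
            raw["model"] = ModelConfig(**m)
        return cls(**raw)

    def canonical(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def _subset_cohort(cohort: Cohort, idx: np.ndarray) -> Cohort:
    sub = Cohort([cohort.patients[i] for i in idx], cohort.panel,
                 cohort.class_order)
    return sub.copy()


def stratified_split(cohort: Cohort, train_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified patient-level split; returns (train_idx, test_idx)."""
    y = [p.outcome for p in cohort.patients]
    idx = np.arange(len(cohort))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


def sequence_set_from_flat(flat: np.ndarray, labels: np.ndarray,
                           template: PaddedSequenceSet,
                           ids: list[str]) -> PaddedSequenceSet:
    """Rebuild a padded sequence set from per-patient flattened vectors.

    A slot counts as real when any of its features is nonzero (synthetic
    SMOTE patients inherit an interpolated notion of padding).
    """
    n_slots = template.sequences.shape[1]
    n_feat = template.sequences.shape[2]
    seqs = flat[:, :n_slots * n_feat].reshape(-1, n_slots, n_feat)
    statics = flat[:, n_slots * n_feat:]
    pad_mask = (np.abs(seqs) > 0).any(axis=2)
    return PaddedSequenceSet(seqs, statics, pad_mask, labels, ids,
                             template.feature_names, template.static_names)


class StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; write reports/checkpoints/logs into ``outdir``.

    Returns the artifact dictionary (cohort, splits, results, report).
    Any stage failure raises :class:`StageError` naming the stage; partial
    outputs already written are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    art: dict = {"stamp": stamp}

    def stage(name):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage '{name}' failed: {exc}") from exc
        return _Ctx()

    with stage("load"):
        if config.simulate is not None:
            sim = dataclasses.replace(
                config.simulate, seed=stage_seed(config.seed, "simulate"))
            cohort, truth = generate_cohort(sim)
            art["ground_truth"] = truth
            write_cohort(cohort, outdir / "cohort.csv")
        else:
            cohort = read_cohort(config.cohort_path)
        art["cohort"] = cohort

    with stage("validate"):
        violations = validate_cohort(cohort)
        if violations:
            raise ValueError(f"{len(violations)} validation violation(s); "
                             f"first: {violations[0]}")

    with stage("split"):
        train_idx, test_idx = stratified_split(
            cohort, config.split_fraction, stage_seed(config.seed, "split"))
        train_cohort = _subset_cohort(cohort, train_idx)
        test_cohort = _subset_cohort(cohort, test_idx)
        art["train_patient_ids"] = [p.patient_id for p in train_cohort.patients]
        art["test_patient_ids"] = [p.patient_id for p in test_cohort.patients]

    with stage("impute"):
        imp_cfg = dataclasses.replace(
            config.imputer, seed=stage_seed(config.seed, "impute"))
        imputer = fit_autoencoder_imputer(train_cohort, imp_cfg)
        train_cohort = impute(imputer, train_cohort)
        test_cohort = impute(imputer, test_cohort)

    with stage("sequences"):
        scaler = fit_scaler(train_cohort)
        train_set = build_sequences(train_cohort, scaler)
        test_set = build_sequences(test_cohort, scaler)
        art["scaler"] = scaler

    with stage("resample"):
        if config.resample:
            table = FeatureTable(train_set.flat_features(), train_set.labels)
            resampled = smoteenn(table, config.k_smote, config.k_enn,
                                 seed=stage_seed(config.seed, "resample"))
            ids = [f"S{i:06d}" if s else f"O{i:06d}"
                   for i, s in enumerate(resampled.synthetic)]
            fit_set = sequence_set_from_flat(resampled.X, resampled.y,
                                             train_set, ids)
        else:
            fit_set = train_set
    art["train_set"], art["test_set"], art["fit_set"] = train_set, test_set, fit_set

    with stage("train"):
        mdl_cfg = dataclasses.replace(
            config.model, seed=stage_seed(config.seed, "train"))
        cost = CostMatrix.default(config.phenotype_cost)
        model = RNNLRModel(fit_set, mdl_cfg, cost)
        results = model.fit(val_set=test_set)
        results.history.to_csv(outdir / "learning_curve.csv", index=False)
        results.save(outdir / "model.npz")
        art["results"] = results

    with stage("evaluate"):
        labels, probs = results.predict(test_set)
        report = evaluation_report(test_set.labels, labels, probs,
                                   cohort.class_order)
        report.extras.update(stamp)
        (outdir / "report.json").write_text(report.to_json())
        report.rendered().to_csv(outdir / "report.csv")
        pd.DataFrame({
            "patient_id": test_set.patient_ids,
            "actual": [cohort.class_order[i] for i in test_set.labels],
            "predicted": [cohort.class_order[i] for i in labels],
            **{f"p_{c}": probs[:, i]
               for i, c in enumerate(cohort.class_order)},
        }).to_csv(outdir / "predictions.csv", index=False)
        art["report"] = report
    return art


def reproduce_worked_example() -> pd.DataFrame:
    """Per-class precision/recall/F (2 decimals) of the bundled held-out
    confusion matrix of the published predictor."""
    cm = worked_example_confusion()
    rows = {}
    for i, label in enumerate(cm.class_order):
        p, r, f = one_vs_all_metrics(cm, i)
        rows[label] = {"precision": round2(p), "recall": round2(r),
                       "f_measure": round2(f)}
    return pd.DataFrame.from_dict(rows, orient="index")
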