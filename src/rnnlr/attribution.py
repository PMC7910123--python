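"""Grouped Shapley-style attribution over clinical indicators, recurrent
embedding units, and latent-regulator columns.

A model-agnostic permutation-sampling Shapley estimator is applied at two
layers of the fitted model:

* at the classifier-head input, where the 64 temporal-embedding units
  ("RNN unit j") and the 8 columns of the combined-effect block ("hidden
  j", the j-th column of the latent regulator) are the features;
* at the raw input, where each laboratory analyte (as a block across the
  three record slots) and each static patient feature is a clinical
  indicator attributed through the full network.

For each random feature ordering the estimator switches features from the
baseline (dataset means) to the instance value and records the marginal
change in the model score (the predicted probability mass on the two
complication phenotypes); attributions telescope, so their sum equals
``f(instance) - f(baseline)`` for every sampled permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from .model import RNNLRResults
from .nn import softmax_probs
from .sequences import PaddedSequenceSet

__all__ = ["FeatureGrouping", "AttributionReport", "sampled_shapley",
           "attribute_model"]

GROUPS = ("clinical_indicator", "rnn_unit", "latent_regulator")


@dataclass(frozen=True)
class FeatureGrouping:
    """Display name -> group label for every attributable feature."""

    groups: dict[str, str]

    def __post_init__(self):
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group label(s): {bad}")


@dataclass
class AttributionReport:
    """Per-feature mean absolute attribution, sorted descending."""

    table: pd.DataFrame  # columns: feature, group, mean_abs_attribution, rank

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.head(n)


def sampled_shapley(predict_fn, instance: np.ndarray, baseline: np.ndarray,
                    n_permutations: int = 200, seed: int = 0,
                    groups: list[list[int]] | None = None) -> np.ndarray:
    """Permutation-sampling Shapley values for a scalar-valued function.

    ``predict_fn`` maps a batch (m, d) to scores (m,).  ``groups`` lets a
    block of vector entries move together as one feature; default is one
    feature per entry.  For each permutation the marginal contributions
    telescope to ``f(instance) - f(baseline)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    instance = np.asarray(instance, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if groups is None:
        groups = [[i] for i in range(instance.size)]
    rng = np.random.default_rng(seed)
    phi = np.zeros(len(groups))
    for _ in range(n_permutations):
        order = rng.permutation(len(groups))
        # batch of prefix states: row t has the first t groups switched on
        states = np.tile(baseline, (len(groups) + 1, 1))
        current = baseline.copy()
        for t, g in enumerate(order, start=1):
            current[groups[g]] = instance[groups[g]]
            states[t] = current
        scores = np.asarray(predict_fn(states), dtype=float)
        phi[order] += scores[1:] - scores[:-1]
    return phi / n_permutations


def _complication_score_from_logits(logits: Tensor) -> np.ndarray:
    probs = softmax_probs(logits).data
    return probs[:, 1] + probs[:, 2]  # P(AHE) + P(HRS)


def _head_forward(results: RNNLRResults, head_inputs: np.ndarray) -> np.ndarray:
    p = results.model.params
    cfg = results.config
    x = Tensor(head_inputs)
    n_dense = len(cfg.head_widths) + 1
    for i in range(1, n_dense + 1):
        x = x @ p[f"Wd{i}"] + p[f"bd{i}"]
        if i < n_dense:
            x = x.relu()
    return _complication_score_from_logits(x)


def _embeddings(results: RNNLRResults, data: PaddedSequenceSet) -> np.ndarray:
    """Head-input matrix [D | D@H | statics] for every patient."""
    m = results.model
    cfg, p = m.config, m.params
    h = [None] * cfg.rnn_layers
    for t in range(data.sequences.shape[1]):
        inp = Tensor(data.sequences[:, t, :])
        for layer in range(cfg.rnn_layers):
            pre = inp @ p[f"Wx{layer}"] + p[f"bh{layer}"]
            if h[layer] is not None:
                pre = pre + h[layer] @ p[f"Wh{layer}"]
            h[layer] = pre.tanh()
            inp = h[layer]
    D = (h[-1] @ p["Wproj"] + p["bproj"]).data
    r = cfg.latent_size
    DH = (D.reshape(-1, r) @ p["H"].data).reshape(len(D), r * r)
    return np.hstack([D, DH, data.statics])


def default_grouping(results: RNNLRResults,
                     data: PaddedSequenceSet) -> FeatureGrouping:
    r = results.config.latent_size
    groups: dict[str, str] = {}
    for j in range(r * r):
        groups[f"RNN unit {j + 1}"] = "rnn_unit"
    for j in range(r):
        groups[f"hidden {j + 1}"] = "latent_regulator"
    for nm in data.feature_names:
        if nm != "day_frac":
            groups[nm] = "clinical_indicator"
    for nm in data.static_names:
        groups[nm] = "clinical_indicator"
    return FeatureGrouping(groups)


def attribute_model(results: RNNLRResults, data: PaddedSequenceSet,
                    grouping: FeatureGrouping | None = None,
                    n_permutations: int = 20, seed: int = 0,
                    max_instances: int = 50) -> AttributionReport:
    """Mean |Shapley| per feature over the dataset, ranked descending.

    Baselines are dataset means (of head inputs for the embedding/regulator
    features, of raw inputs for clinical indicators).  At most
    ``max_instances`` patients are attributed (deterministic subsample) to
    bound the permutation budget.
    """
    if len(data) == 0:
        raise ValueError("cannot attribute an empty dataset")
    if grouping is None:
        grouping = default_grouping(results, data)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(data))
    if len(idx) > max_instances:
        idx = np.sort(rng.choice(idx, size=max_instances, replace=False))
    r = results.config.latent_size
    emb = r * r

    # --- head layer: 64 D units + 8 latent-regulator column blocks -------
    head = _embeddings(results, data)
    head_base = head.mean(axis=0)
    head_groups = [[j] for j in range(emb)] \
        + [[emb + j + r * i for i in range(r)] for j in range(r)]
    # column j of D@H sits at positions emb + j, emb + j + r, ... (row-major)
    head_names = [f"RNN unit {j + 1}" for j in range(emb)] \
        + [f"hidden {j + 1}" for j in range(r)]

    # --- raw layer: analytes as slot-blocks + statics ---------------------
    n_feat = data.sequences.shape[2]
    n_slots = data.sequences.shape[1]
    flat = np.hstack([data.sequences.reshape(len(data), -1), data.statics])
    raw_base = flat.mean(axis=0)
    raw_groups, raw_names = [], []
    for a, nm in enumerate(data.feature_names):
        if nm == "day_frac":
            continue
        raw_groups.append([t * n_feat + a for t in range(n_slots)])
        raw_names.append(nm)
    for s, nm in enumerate(data.static_names):
        raw_groups.append([n_slots * n_feat + s])
        raw_names.append(nm)

    def raw_fn(states: np.ndarray) -> np.ndarray:
        seqs = states[:, :n_slots * n_feat].reshape(-1, n_slots, n_feat)
        statics = states[:, n_slots * n_feat:]
        fake = PaddedSequenceSet(seqs, statics,
                                 np.ones((len(states), n_slots), dtype=bool),
                                 np.zeros(len(states), dtype=int),
                                 ["_"] * len(states), data.feature_names,
                                 data.static_names)
        probs = results.class_probabilities(fake)
        return probs[:, 1] + probs[:, 2]

    acc: dict[str, list[float]] = {nm: [] for nm in head_names + raw_names}
    for i in idx:
        phi_head = sampled_shapley(
            lambda s: _head_forward(results, s), head[i], head_base,
            n_permutations, seed=int(rng.integers(2 ** 31)), groups=head_groups)
        for nm, v in zip(head_names, phi_head):
            acc[nm].append(abs(v))
        phi_raw = sampled_shapley(
            raw_fn, flat[i], raw_base, n_permutations,
            seed=int(rng.integers(2 ** 31)), groups=raw_groups)
        for nm, v in zip(raw_names, phi_raw):
            acc[nm].append(abs(v))

    rows = [{"feature": nm, "group": grouping.groups.get(nm, "clinical_indicator"),
             "mean_abs_attribution": float(np.mean(vals))}
            for nm, vals in acc.items()]
    table = pd.DataFrame(rows).sort_values(
        "mean_abs_attribution", ascending=False, kind="stable",
        ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return AttributionReport(table)
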