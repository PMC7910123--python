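"""Canonical evaluation protocols for the package's own validation studies.

These functions bundle the study conditions under which the package
validates itself on synthetic cohorts (sizes, prevalence, epoch budgets —
rationale in the methods note):

* worked-example metrics on the bundled published confusion matrix;
* counting identities of the published cohort shape;
* brute-force oracle agreement for the arithmetic primitives;
* null-signal control and signal-recovery studies (full pipeline);
* latent-regulator ablation (paired, with vs frozen-at-zero H);
* the masked-holdout imputation benchmark (nested 20%/30% masks).

Every function takes a single integer seed and derives all internal
randomness from it.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from .evaluate import confusion, one_vs_all_metrics, roc_auc_ova, round2, \
    worked_example_confusion
from .impute import (ImputerConfig, MaskHoldout, fit_autoencoder_imputer,
                     impute, mask_lab_values, mean_impute, nrmse)
from .model import CostMatrix, ModelConfig, RNNLRModel, expected_cost
from .pipeline import PipelineConfig, run_pipeline
from .resample import FeatureTable, enn, smote
from .sequences import build_sequences, fit_scaler
from .simulate import SimConfig, generate_cohort
from .attribution import sampled_shapley
from .schema import ClinicalRecord, Cohort, PatientHistory, default_panel

#: Prevalence used by the stochastic property studies: enough minority
#: cases for stable one-vs-all AUC estimates at desk-scale cohort sizes.
STUDY_PREVALENCE = (0.70, 0.12, 0.18)

#: Epoch budgets for the property studies (full default is 100).
NULL_EPOCHS = 30
SIGNAL_EPOCHS = 60


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(k,))
               .generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Exact checks
# ---------------------------------------------------------------------------

def worked_example_metrics() -> dict:
    """Rendered one-vs-all metric cells of the bundled confusion matrix."""
    cm = worked_example_confusion()
    out = {}
    for i, label in enumerate(cm.class_order):
        p, r, f = one_vs_all_metrics(cm, i)
        key = label.lower()
        out[f"{key}_precision"] = round2(p)
        out[f"{key}_recall"] = round2(r)
        out[f"{key}_f_measure"] = round2(f)
    out["row_sums"] = cm.row_sums().tolist()
    return out


def counting_identities() -> dict:
    """Record and padded-slot totals of the published record-count
    distribution (3665/1951/929 patients with 1/2/3 records)."""
    panel = default_panel()
    labs = {a.name: a.midpoint for a in panel}
    patients = []
    i = 0
    for n_rec, count in ((1, 3665), (2, 1951), (3, 929)):
        for _ in range(count):
            records = [ClinicalRecord(d, dict(labs)) for d in range(n_rec)]
            patients.append(PatientHistory(
                patient_id=f"P{i:05d}", inpatient_id=f"I{i:05d}", sex=0,
                age=60, dgtm=1, comorbidities=frozenset(),
                operation_category=0, pneumonia=False, uti=False, ssi=False,
                records=records, outcome="neither"))
            i += 1
    cohort = Cohort(patients, panel)
    ds = build_sequences(cohort, fit_scaler(cohort))
    return {
        "n_patients": len(cohort),
        "raw_records": cohort.n_records,
        "padded_slots": int(ds.sequences.shape[0] * ds.sequences.shape[1]),
        "real_slots": int(ds.pad_mask.sum()),
    }


def oracle_checks(seed: int = 0) -> dict:
    """Max deviations between package primitives and brute-force oracles."""
    rng = np.random.default_rng(seed)
    out = {}

    # expected cost vs explicit sum, 1000 random triples
    dev = 0.0
    for _ in range(1000):
        p = rng.dirichlet(np.ones(3))
        k = int(rng.integers(0, 3))
        c = rng.uniform(0, 300, (3, 3))
        np.fill_diagonal(c, 0)
        brute = sum(c[k, i] * p[i] for i in range(3))
        dev = max(dev, abs(expected_cost(p, k, CostMatrix(c)) - brute))
    out["expected_cost_max_dev"] = dev

    # one-vs-all metrics vs pair counting, 100 random label sets
    dev = 0.0
    for _ in range(100):
        y = rng.integers(0, 3, 30)
        yhat = rng.integers(0, 3, 30)
        cm = confusion(y, yhat)
        for k in range(3):
            tp = np.sum((y == k) & (yhat == k))
            fp = np.sum((y != k) & (yhat == k))
            fn = np.sum((y == k) & (yhat != k))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, r, _ = one_vs_all_metrics(cm, k)
            dev = max(dev, abs(p - (tp / (tp + fp) if tp + fp else 0.0)),
                      abs(r - (tp / (tp + fn) if tp + fn else 0.0)))
    out["ova_metrics_max_dev"] = float(dev)

    # AUC vs O(n^2) all-pairs with ties
    dev = 0.0
    for _ in range(10):
        n = int(rng.integers(50, 200))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 1)
        probs = np.zeros((n, 3))
        probs[:, 1] = s
        pos, neg = s[y == 1], s[y == 0]
        brute = float(sum((p > q) + 0.5 * (p == q)
                          for p in pos for q in neg) / (len(pos) * len(neg)))
        dev = max(dev, abs(roc_auc_ova(y, probs, 1) - brute))
    out["auc_max_dev"] = dev

    # SMOTE convexity: synthetic points on same-class segments (n <= 50)
    X = rng.normal(size=(40, 3))
    y = np.array([0] * 30 + [1] * 10)
    res = smote(FeatureTable(X, y), k_neighbors=3, seed=seed)
    minority = X[y == 1]
    worst = 0.0
    for s in res.X[res.synthetic]:
        best = np.inf
        for i in range(len(minority)):
            for j in range(len(minority)):
                if i == j:
                    continue
                d = minority[j] - minority[i]
                u = np.clip((s - minority[i]) @ d / (d @ d), 0, 1)
                best = min(best, np.linalg.norm(minority[i] + u * d - s))
        worst = max(worst, best)
    out["smote_convexity_max_dev"] = worst

    # ENN vs brute-force kNN vote on <= 20 points
    X = rng.normal(size=(18, 2))
    y = rng.integers(0, 2, 18)
    kept = {tuple(r) for r in enn(FeatureTable(X, y), k=3).X}
    mism = 0
    for i in range(18):
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        votes = y[np.argsort(d, kind="stable")[:3]]
        c0, c1 = (votes == 0).sum(), (votes == 1).sum()
        keep = (c0 != c1) and ((c1 > c0) == (y[i] == 1))
        mism += keep != (tuple(X[i]) in kept)
    out["enn_rule_mismatches"] = mism

    # sampled Shapley vs closed form on an additive function
    w = rng.normal(size=5)
    inst, base = rng.normal(size=5), rng.normal(size=5)
    phi = sampled_shapley(lambda x: x @ w, inst, base, n_permutations=1,
                          seed=seed)
    out["shapley_additive_max_dev"] = float(
        np.max(np.abs(phi - w * (inst - base))))
    return out


# ---------------------------------------------------------------------------
# Pipeline studies
# ---------------------------------------------------------------------------

def _study_config(n: int, beta: float, epochs: int, sim_seed: int,
                  pipe_seed: int, use_h: bool = True) -> PipelineConfig:
    return PipelineConfig(
        simulate=SimConfig(n_patients=n, prevalence=STUDY_PREVALENCE,
                           signal_strength=beta, missing_rate=0.10,
                           seed=sim_seed),
        model=ModelConfig(epochs=epochs, use_latent_regulator=use_h),
        imputer=ImputerConfig(epochs=100),
        seed=pipe_seed)


def null_signal_study(seed: int, n_seeds: int = 5, n: int = 2000) -> dict:
    """Zero-signal cohorts: per-class test AUC averaged over seeds."""
    import tempfile
    aucs = []
    for k in range(n_seeds):
        cfg = _study_config(n, 0.0, NULL_EPOCHS, _sub_seed(seed, k),
                            _sub_seed(seed, 100 + k))
        with tempfile.TemporaryDirectory() as tmp:
            art = run_pipeline(cfg, tmp)
        aucs.append(art["report"].per_class["auc"].to_numpy())
    mean = np.mean(aucs, axis=0)
    return {"auc_neither": float(mean[0]), "auc_ahe": float(mean[1]),
            "auc_hrs": float(mean[2])}


def signal_recovery_study(seed: int, n_seeds: int = 5, n: int = 4000) -> dict:
    """High-signal cohorts vs shuffled-label baseline (mean one-vs-all AUC)."""
    import tempfile
    gains, signal_aucs, baseline_aucs = [], [], []
    for k in range(n_seeds):
        cfg = _study_config(n, 3.0, SIGNAL_EPOCHS, _sub_seed(seed, k),
                            _sub_seed(seed, 200 + k))
        with tempfile.TemporaryDirectory() as tmp:
            art = run_pipeline(cfg, tmp)
        signal = art["report"].per_class["auc"].mean()
        # shuffled-label baseline: same features, permuted training labels
        fit_set, test_set = art["fit_set"], art["test_set"]
        rng = np.random.default_rng(_sub_seed(seed, 300 + k))
        shuffled = fit_set.subset(np.arange(len(fit_set)))
        shuffled.labels = rng.permutation(shuffled.labels)
        res = RNNLRModel(shuffled, art["results"].config,
                         art["results"].cost).fit()
        probs = res.class_probabilities(test_set)
        base = np.mean([roc_auc_ova(test_set.labels, probs, c)
                        for c in range(3)])
        signal_aucs.append(signal)
        baseline_aucs.append(base)
        gains.append(signal - base)
    return {"mean_auc_signal": float(np.mean(signal_aucs)),
            "mean_auc_shuffled": float(np.mean(baseline_aucs)),
            "mean_auc_gain": float(np.mean(gains))}


def regulator_ablation_study(seed: int, n_seeds: int = 5,
                             n: int = 2000) -> dict:
    """Paired mean test AUC: latent regulator enabled vs frozen at zero."""
    import tempfile
    with_h, without_h = [], []
    for k in range(n_seeds):
        sim_seed, pipe_seed = _sub_seed(seed, k), _sub_seed(seed, 400 + k)
        for use_h, acc in ((True, with_h), (False, without_h)):
            cfg = _study_config(n, 3.0, SIGNAL_EPOCHS, sim_seed, pipe_seed,
                                use_h=use_h)
            with tempfile.TemporaryDirectory() as tmp:
                art = run_pipeline(cfg, tmp)
            acc.append(art["report"].per_class["auc"].mean())
    return {"mean_auc_with_regulator": float(np.mean(with_h)),
            "mean_auc_frozen_regulator": float(np.mean(without_h)),
            "mean_auc_difference": float(np.mean(with_h) - np.mean(without_h))}


# ---------------------------------------------------------------------------
# Imputation benchmark
# ---------------------------------------------------------------------------

def nested_mask_pair(cohort: Cohort, seed: int,
                     frac_small: float = 0.2,
                     frac_large: float = 0.3) -> tuple[MaskHoldout, MaskHoldout]:
    """Nested masked holdouts: the small-fraction holdout is a random
    subset of the large one (variance-reduced pairing of the protocol)."""
    hold_large = mask_lab_values(cohort, frac_large, seed)
    rng = np.random.default_rng(seed + 1)
    n_small = round(len(hold_large.holdout) * frac_small / frac_large)
    keep = set(rng.choice(len(hold_large.holdout), size=n_small,
                          replace=False).tolist())
    small_cohort = cohort.copy()
    pid = {p.patient_id: i for i, p in enumerate(small_cohort.patients)}
    holdout = []
    for j, (p, ri, nm, v) in enumerate(hold_large.holdout):
        if j in keep:
            small_cohort.patients[pid[p]].records[ri].labs.pop(nm)
            holdout.append((p, ri, nm, v))
    return MaskHoldout(small_cohort, holdout), hold_large


def imputation_benchmark(seed: int, n_seeds: int = 10,
                         n_monotone: int = 150, n_ordering: int = 800) -> dict:
    """The masked-holdout protocol checks.

    Monotone sanity: mean-imputer NRMSE on nested 30% vs 20% masks over
    ``n_seeds`` small cohorts.  Ordering: autoencoder vs mean imputer on
    correlated cohorts, paired per seed, with a one-sided sign test.
    """
    e20, e30 = [], []
    for k in range(n_seeds):
        cohort, _ = generate_cohort(SimConfig(
            n_patients=n_monotone, prevalence=STUDY_PREVALENCE,
            missing_rate=0.10, seed=_sub_seed(seed, k)))
        h20, h30 = nested_mask_pair(cohort, _sub_seed(seed, 500 + k))
        e20.append(nrmse(mean_impute(h20.cohort), h20, cohort))
        e30.append(nrmse(mean_impute(h30.cohort), h30, cohort))

    wins = 0
    ae_errs, mean_errs = [], []
    for k in range(n_seeds):
        s = _sub_seed(seed, 600 + k)
        cohort, _ = generate_cohort(SimConfig(
            n_patients=n_ordering, prevalence=STUDY_PREVALENCE,
            missing_rate=0.10, seed=s))
        hold = mask_lab_values(cohort, 0.2, s)
        ae = impute(fit_autoencoder_imputer(
            hold.cohort, ImputerConfig(seed=s)), hold.cohort)
        ae_err = nrmse(ae, hold, cohort)
        mean_err = nrmse(mean_impute(hold.cohort), hold, cohort)
        ae_errs.append(ae_err)
        mean_errs.append(mean_err)
        wins += ae_err < mean_err
    sign_p = binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
    return {
        "mean_imputer_nrmse_20": float(np.mean(e20)),
        "mean_imputer_nrmse_30": float(np.mean(e30)),
        "autoencoder_nrmse_20": float(np.mean(ae_errs)),
        "mean_imputer_nrmse_20_large": float(np.mean(mean_errs)),
        "autoencoder_wins": int(wins),
        "sign_test_p": float(sign_p),
    }


def determinism_check(seed: int, outdir_a, outdir_b) -> bool:
    """Same config + seed twice: byte-identical reports."""
    cfg = PipelineConfig(
        simulate=SimConfig(n_patients=250, prevalence=STUDY_PREVALENCE,
                           missing_rate=0.10, seed=0),
        model=ModelConfig(epochs=4), imputer=ImputerConfig(epochs=40),
        seed=seed)
    run_pipeline(cfg, outdir_a)
    run_pipeline(cfg, outdir_b)
    from pathlib import Path
    names = ("report.json", "report.csv", "learning_curve.csv")
    return all((Path(outdir_a) / n).read_bytes() ==
               (Path(outdir_b) / n).read_bytes() for n in names)
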