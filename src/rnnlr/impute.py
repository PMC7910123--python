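"""Missing laboratory value imputation and its masking/NRMSE benchmark.

The primary imputer is a denoising autoencoder over per-record lab vectors:
records are standardised per analyte on observed statistics, missing cells
are initialised at the analyte mean, and a symmetric bottleneck network is
trained to reconstruct the observed entries only.  Patients with similar
observed profiles land close in the bottleneck, so their values inform each
other's missing cells.  Mean and k-nearest-neighbour imputers are provided
as protocol baselines, and :func:`nrmse` implements the masked-holdout
error measure (RMSE over held-out cells divided by the mean of the complete
reference data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .nn import Adam, glorot
from .schema import Cohort

__all__ = [
    "MaskHoldout", "ImputerConfig", "AutoencoderImputer",
    "mask_lab_values", "fit_autoencoder_imputer", "impute",
    "mean_impute", "knn_impute", "nrmse",
]


# ---------------------------------------------------------------------------
# Cohort <-> record-matrix plumbing
# ---------------------------------------------------------------------------

def cohort_lab_matrix(cohort: Cohort) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flatten records to an (n_records, n_analytes) matrix, NaN = missing."""
    names = [a.name for a in cohort.panel]
    rows, index = [], []
    for pi, p in enumerate(cohort.patients):
        for ri, r in enumerate(p.records):
            rows.append([r.labs.get(nm, np.nan) for nm in names])
            index.append((pi, ri))
    return np.asarray(rows, dtype=float), index


def _matrix_to_cohort(cohort: Cohort, matrix: np.ndarray,
                      index: list[tuple[int, int]]) -> Cohort:
    """Write a fully observed matrix back; originally observed cells kept."""
    out = cohort.copy()
    names = [a.name for a in cohort.panel]
    lows = np.array([a.valid_range[0] for a in cohort.panel])
    highs = np.array([a.valid_range[1] for a in cohort.panel])
    clipped = np.clip(matrix, lows, highs)
    for row, (pi, ri) in zip(clipped, index):
        rec = out.patients[pi].records[ri]
        for j, nm in enumerate(names):
            if nm not in rec.labs:
                rec.labs[nm] = float(row[j])
    return out


# ---------------------------------------------------------------------------
# Masking protocol
# ---------------------------------------------------------------------------

@dataclass
class MaskHoldout:
    """A cohort with extra cells blanked plus the ground-truth holdout."""

    cohort: Cohort
    holdout: list[tuple[str, int, str, float]]  # (patient_id, rec idx, analyte, truth)


def mask_lab_values(cohort: Cohort, fraction: float, seed: int) -> MaskHoldout:
    """Blank a uniform random ``fraction`` of the *observed* lab cells.

    Exactly ``round(fraction * n_observed)`` cells are removed, sampled
    without replacement; deterministic per seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    cells = [(pi, ri, nm)
             for pi, p in enumerate(cohort.patients)
             for ri, r in enumerate(p.records)
             for nm in (a.name for a in cohort.panel) if nm in r.labs]
    if not cells:
        raise ValueError("cohort has no observed lab cells to mask")
    rng = np.random.default_rng(seed)
    n_mask = round(fraction * len(cells))
    picks = rng.choice(len(cells), size=n_mask, replace=False)
    masked = cohort.copy()
    holdout = []
    for c in sorted(picks):
        pi, ri, nm = cells[c]
        truth = masked.patients[pi].records[ri].labs.pop(nm)
        holdout.append((cohort.patients[pi].patient_id, ri, nm, truth))
    return MaskHoldout(masked, holdout)


# ---------------------------------------------------------------------------
# Autoencoder imputer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputerConfig:
    """Bottleneck widths are mirrored into a symmetric decoder."""

    hidden: tuple[int, ...] = (32, 16)
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer widths must be positive")


class AutoencoderImputer:
    """Symmetric reconstruction network over standardised lab records."""

    def __init__(self, config: ImputerConfig = ImputerConfig()):
        self.config = config
        self.panel_names: list[str] | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.params: list[Tensor] | None = None

    # -- internals -------------------------------------------------------
    def _widths(self, d: int) -> list[int]:
        h = list(self.config.hidden)
        return [d] + h + h[-2::-1] + [d]  # mirror: d 32 16 32 d

    def _forward(self, x: Tensor) -> Tensor:
        out = x
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            out = out @ self.params[2 * i] + self.params[2 * i + 1]
            if i < n_layers - 1:
                out = out.relu()
        return out

    def fit(self, cohort: Cohort) -> "AutoencoderImputer":
        matrix, _ = cohort_lab_matrix(cohort)
        if matrix.shape[0] < 2:
            raise ValueError("autoencoder imputer needs at least 2 records")
        self.panel_names = [a.name for a in cohort.panel]
        obs = ~np.isnan(matrix)
        mean = np.nanmean(np.where(obs, matrix, np.nan), axis=0)
        for j, a in enumerate(cohort.panel):
            if not obs[:, j].any():
                warnings.warn(f"analyte {a.name} has no observed values; "
                              "falling back to panel-range midpoint", stacklevel=2)
                mean[j] = a.midpoint
        std = np.where(obs.any(axis=0),
                       np.nanstd(np.where(obs, matrix, np.nan), axis=0), 1.0)
        std = np.where(std > 0, std, 1.0)
        self.mean_, self.std_ = mean, std

        x = (np.where(obs, matrix, mean) - mean) / std  # missing -> 0 (mean)
        rng = np.random.default_rng(self.config.seed)
        widths = self._widths(x.shape[1])
        self.params = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            self.params += [glorot(rng, fan_in, fan_out),
                            Tensor(np.zeros(fan_out), requires_grad=True)]
        opt = Adam(self.params, lr=self.config.learning_rate)
        mask = Tensor(obs.astype(float))
        target = Tensor(x)
        xin = Tensor(x)
        n_obs = obs.sum()
        for _ in range(self.config.epochs):
            opt.zero_grad()
            recon = self._forward(xin)
            err = (recon - target) * mask
            loss = (err * err).sum() / n_obs  # observed entries only
            loss.backward()
            opt.step()
        return self

    def transform_matrix(self, matrix: np.ndarray) -> np.ndarray:
        obs = ~np.isnan(matrix)
        x = (np.where(obs, matrix, self.mean_) - self.mean_) / self.std_
        recon = self._forward(Tensor(x)).data * self.std_ + self.mean_
        return np.where(obs, matrix, recon)


def fit_autoencoder_imputer(masked: Cohort,
                            config: ImputerConfig = ImputerConfig()) -> AutoencoderImputer:
    return AutoencoderImputer(config).fit(masked)


def impute(imputer: AutoencoderImputer, masked: Cohort) -> Cohort:
    """Fill every missing lab cell; observed cells are never altered.

    Imputed values are clipped to the panel's clinical ranges so the output
    passes range validation.
    """
    if imputer.panel_names != [a.name for a in masked.panel]:
        raise ValueError("imputer was fitted on a different analyte panel")
    matrix, index = cohort_lab_matrix(masked)
    return _matrix_to_cohort(masked, imputer.transform_matrix(matrix), index)


# ---------------------------------------------------------------------------
# Baseline imputers
# ---------------------------------------------------------------------------

def mean_impute(masked: Cohort) -> Cohort:
    """Per-analyte observed mean (panel midpoint if nothing observed)."""
    matrix, index = cohort_lab_matrix(masked)
    obs = ~np.isnan(matrix)
    mean = np.where(obs.any(axis=0), np.nanmean(matrix, axis=0),
                    [a.midpoint for a in masked.panel])
    filled = np.where(obs, matrix, mean)
    return _matrix_to_cohort(masked, filled, index)


def knn_impute(masked: Cohort, k: int = 5) -> Cohort:
    """Average of the k nearest complete-case records (Euclidean distance on
    standardised analytes observed in the focal record); falls back to the
    observed mean with a warning when no complete record exists."""
    if k < 1:
        raise ValueError("k must be >= 1")
    matrix, index = cohort_lab_matrix(masked)
    obs = ~np.isnan(matrix)
    mean = np.where(obs.any(axis=0), np.nanmean(matrix, axis=0),
                    [a.midpoint for a in masked.panel])
    std = np.where(obs.any(axis=0), np.nanstd(matrix, axis=0), 1.0)
    std = np.where(std > 0, std, 1.0)
    z = (matrix - mean) / std
    complete = obs.all(axis=1)
    filled = np.where(obs, matrix, mean)
    if not complete.any():
        warnings.warn("no complete-case records; falling back to mean imputation",
                      stacklevel=2)
        return _matrix_to_cohort(masked, filled, index)
    donors = z[complete]
    donor_raw = matrix[complete]
    for i in np.flatnonzero(~obs.all(axis=1)):
        shared = obs[i]
        if not shared.any():
            continue  # nothing observed: keep mean fill
        d = np.sqrt(((donors[:, shared] - z[i, shared]) ** 2).sum(axis=1))
        kk = min(k, len(d))
        nn = np.argsort(d, kind="stable")[:kk]
        filled[i, ~shared] = donor_raw[nn][:, ~shared].mean(axis=0)
    return _matrix_to_cohort(masked, filled, index)


# ---------------------------------------------------------------------------
# NRMSE
# ---------------------------------------------------------------------------

def nrmse(imputed: Cohort, holdout: MaskHoldout, reference: Cohort,
          per_analyte: bool = True) -> float:
    """Normalised RMSE over held-out cells.

    Default: per-analyte RMSE divided by that analyte's mean in the complete
    reference data, averaged (unweighted) across analytes with at least one
    holdout cell.  ``per_analyte=False`` computes one global RMSE divided by
    the global reference mean (the analytes span four orders of magnitude,
    which makes the global ratio hard to interpret; it is provided for
    completeness).
    """
    pid_to_patient = {p.patient_id: p for p in imputed.patients}
    by_analyte: dict[str, list[tuple[float, float]]] = {}
    for pid, ri, nm, truth in holdout.holdout:
        rec = pid_to_patient[pid].records[ri]
        if nm not in rec.labs:
            raise ValueError(f"holdout cell ({pid}, {ri}, {nm}) is not imputed")
        by_analyte.setdefault(nm, []).append((rec.labs[nm], truth))

    ref_vals: dict[str, list[float]] = {a.name: [] for a in reference.panel}
    for p in reference.patients:
        for r in p.records:
            for nm, v in r.labs.items():
                ref_vals[nm].append(v)

    if not per_analyte:
        pairs = [pv for vals in by_analyte.values() for pv in vals]
        pred = np.array([p for p, _ in pairs])
        true = np.array([t for _, t in pairs])
        gmean = np.mean([v for nm in by_analyte for v in ref_vals[nm]])
        return float(np.sqrt(np.mean((pred - true) ** 2)) / gmean)

    ratios = []
    for nm, pairs in by_analyte.items():
        ref_mean = np.mean(ref_vals[nm]) if ref_vals[nm] else 0.0
        if ref_mean == 0.0:
            warnings.warn(f"analyte {nm} has zero reference mean; excluded "
                          "from NRMSE", stacklevel=2)
            continue
        pred = np.array([p for p, _ in pairs])
        true = np.array([t for _, t in pairs])
        ratios.append(np.sqrt(np.mean((pred - true) ** 2)) / ref_mean)
    if not ratios:
        raise ValueError("no analyte contributed to NRMSE")
    return float(np.mean(ratios))
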