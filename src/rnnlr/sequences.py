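"""Fixed-length, zero-padded, min-max-scaled model inputs.

Every patient contributes a length-3 sequence of per-record feature vectors
(scaled labs plus a within-window time feature).  Patients with fewer than
3 records have their real records placed in the *trailing* slots in day
order and the leading slots filled with zeros; after min-max scaling to
[0, 1] on the training cohort, a zero pad sits near the feature minima
rather than at a mid-range value.  Static patient features (sex, scaled
age, scaled prior-hospitalisation count, comorbidity flags, operation
one-hot, complication flags) are kept separate and injected at the
classifier head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schema import (CHARLSON_CATEGORIES, N_OPERATION_CATEGORIES, WINDOW_DAYS,
                     Cohort)

__all__ = ["Scaler", "PaddedSequenceSet", "fit_scaler", "build_sequences"]

SEQ_LEN = WINDOW_DAYS  # 3 slots per patient


@dataclass
class Scaler:
    """Per-feature (min, max) from training data; training min->0, max->1.

    Test values may map outside [0, 1]; that is intentional (no clipping).
    """

    bounds: dict[str, tuple[float, float]]

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[name]
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)


@dataclass
class PaddedSequenceSet:
    sequences: np.ndarray   # (n, SEQ_LEN, F)
    statics: np.ndarray     # (n, S)
    pad_mask: np.ndarray    # (n, SEQ_LEN) bool, True = real record
    labels: np.ndarray      # (n,) class codes
    patient_ids: list[str]
    feature_names: list[str]
    static_names: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "PaddedSequenceSet":
        idx = np.asarray(idx)
        return PaddedSequenceSet(
            self.sequences[idx], self.statics[idx], self.pad_mask[idx],
            self.labels[idx], [self.patient_ids[i] for i in idx],
            self.feature_names, self.static_names)

    def flat_features(self) -> np.ndarray:
        """Per-patient flattened vector: 3 record slots then statics."""
        n = len(self)
        return np.hstack([self.sequences.reshape(n, -1), self.statics])

    def save_npz(self, path) -> None:
        np.savez(path, sequences=self.sequences, statics=self.statics,
                 pad_mask=self.pad_mask, labels=self.labels,
                 patient_ids=np.array(self.patient_ids),
                 feature_names=np.array(self.feature_names),
                 static_names=np.array(self.static_names))

    @classmethod
    def load_npz(cls, path) -> "PaddedSequenceSet":
        z = np.load(path, allow_pickle=False)
        return cls(z["sequences"], z["statics"], z["pad_mask"], z["labels"],
                   [str(s) for s in z["patient_ids"]],
                   [str(s) for s in z["feature_names"]],
                   [str(s) for s in z["static_names"]])


def fit_scaler(cohort: Cohort) -> Scaler:
    """Min-max bounds for every lab analyte plus age and dgtm.

    Fit on the *training* cohort only.  A constant feature gets bounds
    (min, min + 1) with a warning, mapping all its values to 0.
    """
    bounds: dict[str, tuple[float, float]] = {}
    pools: dict[str, list[float]] = {a.name: [] for a in cohort.panel}
    for p in cohort.patients:
        for r in p.records:
            for nm, v in r.labs.items():
                pools[nm].append(v)
    pools["age"] = [float(p.age) for p in cohort.patients]
    pools["dgtm"] = [float(p.dgtm) for p in cohort.patients]
    for nm, vals in pools.items():
        if not vals:
            raise ValueError(f"feature {nm} has no observed values")
        lo, hi = min(vals), max(vals)
        if lo == hi:
            warnings.warn(f"feature {nm} is constant; using (min, min + 1)",
                          stacklevel=2)
            hi = lo + 1.0
        bounds[nm] = (lo, hi)
    return Scaler(bounds)


def build_sequences(cohort: Cohort, scaler: Scaler) -> PaddedSequenceSet:
    """Zero-pad each patient to SEQ_LEN slots of scaled record features.

    Per-record features: scaled labs in panel order, then day_offset divided
    by the window length.  Requires a fully imputed cohort.
    """
    names = [a.name for a in cohort.panel]
    feature_names = names + ["day_frac"]
    static_names = (["sex", "age", "dgtm"]
                    + [f"cm_{c}" for c in CHARLSON_CATEGORIES]
                    + [f"op_{j}" for j in range(N_OPERATION_CATEGORIES)]
                    + ["pneumonia", "uti", "ssi"])
    class_index = {label: i for i, label in enumerate(cohort.class_order)}

    n, F, S = len(cohort), len(feature_names), len(static_names)
    sequences = np.zeros((n, SEQ_LEN, F))
    statics = np.zeros((n, S))
    pad_mask = np.zeros((n, SEQ_LEN), dtype=bool)
    labels = np.zeros(n, dtype=int)
    ids = []
    for i, p in enumerate(cohort.patients):
        ids.append(p.patient_id)
        labels[i] = class_index[p.outcome]
        offset = SEQ_LEN - len(p.records)  # real records fill trailing slots
        for j, r in enumerate(p.records):
            slot = offset + j
            pad_mask[i, slot] = True
            for a, nm in enumerate(names):
                if nm not in r.labs:
                    raise ValueError(
                        f"patient {p.patient_id} record {j} is missing {nm}; "
                        "impute the cohort before building sequences")
                sequences[i, slot, a] = scaler.transform(nm, r.labs[nm])
            sequences[i, slot, F - 1] = r.day_offset / WINDOW_DAYS
        statics[i, 0] = p.sex
        statics[i, 1] = scaler.transform("age", float(p.age))
        statics[i, 2] = scaler.transform("dgtm", float(p.dgtm))
        for c_i, c in enumerate(CHARLSON_CATEGORIES):
            statics[i, 3 + c_i] = float(c in p.comorbidities)
        statics[i, 3 + len(CHARLSON_CATEGORIES) + p.operation_category] = 1.0
        statics[i, S - 3:] = [float(p.pneumonia), float(p.uti), float(p.ssi)]
    return PaddedSequenceSet(sequences, statics, pad_mask, labels, ids,
                             feature_names, static_names)
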