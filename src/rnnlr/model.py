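"""Cost-sensitive recurrent phenotype predictor with a latent regulator.

The model maps each patient's padded 3-slot record sequence through a stack
of Elman (tanh) recurrent layers; the final hidden state is projected to an
8x8 temporal embedding ``D`` of the patient's disease progression.  A
global trainable 8x8 parameter matrix ``H`` — the latent regulator — is
learned jointly with the network to absorb progression variation that the
short observed window cannot express.  The classifier head consumes
``flatten(D)``, the combined effect ``flatten(D @ H)``, and the static
patient features, through three ReLU dense layers to the 3-class logits.
``H`` is shared across patients and fixed at prediction time; its per-epoch
Frobenius-norm movement is recorded as a convergence trace.

Class imbalance is handled by cost-sensitive training: a K x K
misclassification cost matrix ``c(k, i)`` (zero diagonal) either reweights
the cross-entropy of each instance by its true-class row cost, or is
minimised directly as the expected cost ``sum_i c(k, i) p_i``.

Usage follows the statsmodels convention::

    model = RNNLRModel(train_set, config, cost)
    res = model.fit(val_set)
    print(res.summary())
    labels, probs = res.predict(test_set)
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from .nn import Adam, dropout_mask, glorot, logsumexp_rows, softmax_probs
from .schema import CLASS_ORDER
from .sequences import PaddedSequenceSet

__all__ = ["ModelConfig", "CostMatrix", "LatentRegulator", "RNNLRModel",
           "RNNLRResults", "expected_cost", "training_loss"]

K_CLASSES = 3


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs c[k, i] = cost of predicting i when truth is k."""

    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.shape != (K_CLASSES, K_CLASSES):
            raise ValueError(f"cost matrix must be {K_CLASSES}x{K_CLASSES}")
        if (c < 0).any():
            raise ValueError("costs must be non-negative")
        if np.diag(c).any():
            raise ValueError("cost matrix diagonal must be zero")

    @classmethod
    def default(cls, phenotype_cost: float = 200.0) -> "CostMatrix":
        """Off-diagonal cost ``phenotype_cost`` on the AHE and HRS rows
        (missing a true complication is expensive), 1 on the neither row."""
        c = np.array([[0.0, 1.0, 1.0],
                      [phenotype_cost, 0.0, phenotype_cost],
                      [phenotype_cost, phenotype_cost, 0.0]])
        return cls(c)

    def class_weights(self) -> np.ndarray:
        """Row cost mass per true class: w_k = sum_{i != k} c(k, i) / (K - 1)."""
        return self.c.sum(axis=1) / (K_CLASSES - 1)


@dataclass(frozen=True)
class ModelConfig:
    learning_rate: float = 0.01       # gamma
    latent_size: int = 8              # H is latent_size x latent_size
    drop_rate: float = 0.2
    rnn_layers: int = 8
    units_per_layer: int = 16
    weight_decay: float = 0.005       # lambda, coupled L2 in Adam
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    loss_mode: str = "weighted_ce"    # or "expected_cost"
    head_widths: tuple[int, int, int] = (128, 64, 32)
    lr_schedule: str = "cosine"       # anneal gamma -> 0; or "constant"
    tolerance: float = 1e-4           # H convergence tolerance (Frobenius)
    use_latent_regulator: bool = True  # False: H frozen at zero (ablation)
    mask_aware: bool = False          # skip state updates on padded slots

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.drop_rate < 1:
            raise ValueError("drop_rate must be in [0, 1)")
        if self.loss_mode not in ("weighted_ce", "expected_cost"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class LatentRegulator:
    """The fitted H matrix with its convergence bookkeeping."""

    H: np.ndarray
    deltas: list[float] = field(default_factory=list)  # per-epoch ||dH||_F
    tolerance: float = 1e-4

    @property
    def i_min(self) -> int | None:
        """First (1-based) epoch whose Frobenius delta fell below tolerance."""
        for i, d in enumerate(self.deltas, start=1):
            if d < self.tolerance:
                return i
        return None


# ---------------------------------------------------------------------------
# Cost-sensitive objectives
# ---------------------------------------------------------------------------

def expected_cost(probs: np.ndarray, true_class: int, cost: CostMatrix) -> float:
    """Expected misclassification cost sum_i c(k, i) * p_i of one simplex row."""
    p = np.asarray(probs, dtype=float)
    return float(cost.c[true_class] @ p)


def training_loss(logits: Tensor, labels: np.ndarray, cost: CostMatrix,
                  mode: str = "weighted_ce") -> Tensor:
    """Differentiable batch loss.

    ``weighted_ce``: mean over instances of w_k * (-log p_k) with
    w_k = sum_{i != k} c(k, i) / (K - 1) — plain mean cross-entropy when all
    off-diagonal costs are 1.  ``expected_cost``: mean of
    sum_i c(k, i) * p_i, the smooth expected-cost surrogate.
    """
    n = len(labels)
    onehot = np.zeros((n, K_CLASSES))
    onehot[np.arange(n), labels] = 1.0
    if mode == "weighted_ce":
        lse = logsumexp_rows(logits)
        logp_true = (logits * Tensor(onehot)).sum(axis=1, keepdims=True) - lse
        w = cost.class_weights()[labels][:, None]
        return -(Tensor(w) * logp_true).mean()
    if mode == "expected_cost":
        probs = softmax_probs(logits).clip_min(1e-12)
        rows = cost.c[labels]  # (n, K) constant per-instance cost rows
        return (probs * Tensor(rows)).sum(axis=1, keepdims=True).mean()
    raise ValueError(f"unknown loss mode {mode!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class RNNLRModel:
    """Recurrent latent-regulator classifier bound to a training set."""

    def __init__(self, train_set: PaddedSequenceSet,
                 config: ModelConfig = ModelConfig(),
                 cost: CostMatrix | None = None):
        self.train_set = train_set
        self.config = config
        self.cost = cost if cost is not None else CostMatrix.default()
        self.n_features = train_set.sequences.shape[2]
        self.n_statics = train_set.statics.shape[1]
        self.class_order = CLASS_ORDER
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- construction ----------------------------------------------------
    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        r, u = cfg.latent_size, cfg.units_per_layer
        emb = r * r
        p: dict[str, Tensor] = {}
        fan_in = self.n_features
        for layer in range(cfg.rnn_layers):
            p[f"Wx{layer}"] = glorot(rng, fan_in, u)
            # orthogonal recurrent matrices keep signal conditioned through
            # the deep stack (tanh Elman cells degrade with Glorot here)
            q, _ = np.linalg.qr(rng.standard_normal((u, u)))
            p[f"Wh{layer}"] = Tensor(q, requires_grad=True)
            p[f"bh{layer}"] = Tensor(np.zeros(u), requires_grad=True)
            fan_in = u
        p["Wproj"] = glorot(rng, u, emb)
        p["bproj"] = Tensor(np.zeros(emb), requires_grad=True)
        p["H"] = Tensor(0.1 * rng.standard_normal((r, r)),
                        requires_grad=cfg.use_latent_regulator)
        if not cfg.use_latent_regulator:
            p["H"].data[:] = 0.0  # frozen ablation: combined-effect block dead
        widths = [emb + emb + self.n_statics, *cfg.head_widths, K_CLASSES]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]), start=1):
            p[f"Wd{i}"] = glorot(rng, a, b)
            p[f"bd{i}"] = Tensor(np.zeros(b), requires_grad=True)
        self.params = p

    def trainable(self) -> list[Tensor]:
        return [t for t in self.params.values() if t.requires_grad]

    # -- forward ---------------------------------------------------------
    def _forward(self, sequences: np.ndarray, statics: np.ndarray,
                 pad_mask: np.ndarray | None = None,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        """Batch logits; dropout active only when ``drop_rng`` is given."""
        cfg, p = self.config, self.params
        n, T, _ = sequences.shape
        h = [None] * cfg.rnn_layers
        for t in range(T):
            inp = Tensor(sequences[:, t, :])
            for layer in range(cfg.rnn_layers):
                pre = inp @ p[f"Wx{layer}"] + p[f"bh{layer}"]
                if h[layer] is not None:
                    pre = pre + h[layer] @ p[f"Wh{layer}"]
                new = pre.tanh()
                if cfg.mask_aware and pad_mask is not None:
                    m = pad_mask[:, t].astype(float)[:, None]
                    new = new * Tensor(m) if h[layer] is None else \
                        new * Tensor(m) + h[layer] * Tensor(1.0 - m)
                h[layer] = new
                inp = new
            # h carries over to the next time step per layer
        D = h[-1] @ p["Wproj"] + p["bproj"]  # (n, r*r) temporal embedding
        r = cfg.latent_size
        DH = (D.reshape(n * r, r) @ p["H"]).reshape(n, r * r)
        x = concat([D, DH, Tensor(np.asarray(statics, dtype=float))], axis=1)
        if drop_rng is not None and cfg.drop_rate > 0:
            x = x * Tensor(dropout_mask(drop_rng, x.shape, cfg.drop_rate))
        n_dense = len(cfg.head_widths) + 1
        for i in range(1, n_dense + 1):
            x = x @ p[f"Wd{i}"] + p[f"bd{i}"]
            if i < n_dense:
                x = x.relu()
        return x

    # -- fitting ---------------------------------------------------------
    def _epoch_lr(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch; cosine anneals to 0 at the end."""
        cfg = self.config
        if cfg.lr_schedule == "constant":
            return cfg.learning_rate
        return cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * epoch / cfg.epochs))

    def fit(self, val_set: PaddedSequenceSet | None = None,
            verbose: bool = False) -> "RNNLRResults":
        cfg = self.config
        train = self.train_set
        if len(np.unique(train.labels)) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(cfg.seed + 1)  # batching/dropout stream
        opt = Adam(self.trainable(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        n = len(train)
        deltas: list[float] = []
        history: list[dict] = []
        H_prev = self.params["H"].data.copy()
        for epoch in range(1, cfg.epochs + 1):
            lr = self._epoch_lr(epoch)
            order = rng.permutation(n)
            total, batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                logits = self._forward(train.sequences[idx], train.statics[idx],
                                       train.pad_mask[idx], drop_rng=rng)
                loss = training_loss(logits, train.labels[idx], self.cost,
                                     cfg.loss_mode)
                loss.backward()
                opt.step(lr=lr)
                total += float(loss.data)
                batches += 1
            H_now = self.params["H"].data
            deltas.append(float(np.linalg.norm(H_now - H_prev)))
            H_prev = H_now.copy()
            row = {"epoch": epoch, "lr": lr, "train_loss": total / batches,
                   "H_delta": deltas[-1]}
            if val_set is not None:
                row.update(self._val_metrics(val_set))
            history.append(row)
            if verbose:
                print(f"epoch {epoch:4d}  loss {row['train_loss']:.4f}  "
                      f"|dH| {deltas[-1]:.2e}")
        latent = LatentRegulator(self.params["H"].data.copy(), deltas,
                                 cfg.tolerance)
        return RNNLRResults(self, latent, pd.DataFrame(history))

    def _val_metrics(self, val_set: PaddedSequenceSet) -> dict:
        from .evaluate import roc_auc_ova
        probs = self.predict_proba(val_set)
        out = {"val_expected_cost": float(np.mean(
            [expected_cost(probs[i], val_set.labels[i], self.cost)
             for i in range(len(val_set))]))}
        aucs = []
        for k in range(K_CLASSES):
            if 0 < (val_set.labels == k).sum() < len(val_set):
                aucs.append(roc_auc_ova(val_set.labels, probs, k))
        out["val_mean_auc"] = float(np.mean(aucs)) if aucs else float("nan")
        return out

    # -- inference -------------------------------------------------------
    def predict_proba(self, data: PaddedSequenceSet) -> np.ndarray:
        logits = self._forward(data.sequences, data.statics, data.pad_mask)
        return np.asarray(softmax_probs(logits).data)


class RNNLRResults:
    """Fitted-model container: estimates, convergence trace, diagnostics."""

    def __init__(self, model: RNNLRModel, latent: LatentRegulator,
                 history: pd.DataFrame):
        self.model = model
        self.latent = latent
        self.history = history
        self.config = model.config
        self.cost = model.cost
        self.class_order = model.class_order

    # -- prediction ------------------------------------------------------
    def class_probabilities(self, data: PaddedSequenceSet) -> np.ndarray:
        """Row-stochastic (n, K) phenotype probabilities; dropout disabled."""
        return self.model.predict_proba(data)

    def predict(self, data: PaddedSequenceSet,
                decision_rule: str = "argmax") -> tuple[np.ndarray, np.ndarray]:
        """Labels and probabilities under the chosen decision rule.

        ``argmax``: most probable class (ties -> lowest class index).
        ``min_expected_cost``: argmin_i sum_k p_k c(k, i) (ties -> lowest).
        """
        probs = self.class_probabilities(data)
        if decision_rule == "argmax":
            labels = probs.argmax(axis=1)
        elif decision_rule == "min_expected_cost":
            decision_costs = probs @ self.cost.c  # column i: predict-i cost
            labels = decision_costs.argmin(axis=1)
        else:
            raise ValueError(f"unknown decision rule {decision_rule!r}")
        return labels, probs

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        n_params = sum(t.data.size for t in self.model.params.values())
        buf = io.StringIO()
        w = buf.write
        w("Cost-sensitive recurrent phenotype model (latent regulator)\n")
        w("=" * 62 + "\n")
        w(f"classes:             {', '.join(self.class_order)}\n")
        w(f"recurrent stack:     {cfg.rnn_layers} layers x "
          f"{cfg.units_per_layer} tanh units\n")
        w(f"temporal embedding:  {cfg.latent_size}x{cfg.latent_size}\n")
        w(f"latent regulator:    "
          f"{'enabled' if cfg.use_latent_regulator else 'frozen at zero'}\n")
        w(f"loss mode:           {cfg.loss_mode} "
          f"(class weights {np.round(self.cost.class_weights(), 2).tolist()})\n")
        w(f"parameters:          {n_params}\n")
        w(f"epochs / batch:      {cfg.epochs} / {cfg.batch_size}\n")
        w(f"learning rate:       {cfg.learning_rate} ({cfg.lr_schedule})\n")
        w(f"weight decay:        {cfg.weight_decay}\n")
        final = self.history["train_loss"].iloc[-1]
        w(f"final train loss:    {final:.4f}\n")
        i_min = self.latent.i_min
        w(f"H convergence:       first epoch < {self.latent.tolerance:g}: "
          f"{i_min if i_min is not None else 'not reached'}; "
          f"final |dH|_F = {self.latent.deltas[-1]:.2e}\n")
        if "val_mean_auc" in self.history:
            w(f"final val mean AUC:  {self.history['val_mean_auc'].iloc[-1]:.3f}\n")
        return buf.getvalue()

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: t.data for name, t in self.model.params.items()}
        arrays["_H_deltas"] = np.asarray(self.latent.deltas)
        meta = {"config": asdict(self.config),
                "cost": self.cost.c.tolist(),
                "class_order": list(self.class_order),
                "n_features": self.model.n_features,
                "n_statics": self.model.n_statics,
                "history": self.history.to_dict(orient="list")}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "RNNLRResults":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["head_widths"] = tuple(cfg_dict["head_widths"])
        cfg = ModelConfig(**cfg_dict)
        dummy = PaddedSequenceSet(
            np.zeros((1, 3, meta["n_features"])),
            np.zeros((1, meta["n_statics"])),
            np.ones((1, 3), dtype=bool), np.zeros(1, dtype=int), ["_"],
            [f"f{i}" for i in range(meta["n_features"])],
            [f"s{i}" for i in range(meta["n_statics"])])
        model = RNNLRModel(dummy, cfg, CostMatrix(np.asarray(meta["cost"])))
        for name, t in model.params.items():
            t.data = z[name].astype(float)
        latent = LatentRegulator(model.params["H"].data.copy(),
                                 [float(d) for d in z["_H_deltas"]],
                                 cfg.tolerance)
        history = pd.DataFrame(meta["history"])
        return cls(model, latent, history)
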