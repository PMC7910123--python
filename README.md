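# rnnlr — cost-sensitive recurrent phenotype prediction with a latent regulator

`rnnlr` predicts rare, severe complication phenotypes after surgery for an
acute disease — acute hepatic encephalopathy (AHE) and hepatorenal syndrome
(HRS) after peritonitis surgery — from the short, heterogeneous and highly
imbalanced laboratory record sequences available in the first three days
after the operation.  It is aimed at clinical-informatics researchers who
want a fully testable, end-to-end reference implementation of this class of
model without access to the proprietary hospital data such models are
usually built on: a synthetic cohort generator with known ground truth
stands in for the real registry.

## The model

Each patient contributes up to three timestamped lab records (18 analytes),
zero-padded to a fixed length-3 sequence with the real records in the
trailing slots.  The sequence passes through a stack of 8 Elman (tanh)
recurrent layers of 16 units; the final hidden state is projected to an
8×8 temporal embedding **D** of the patient's disease progression.  A
global trainable 8×8 parameter matrix **H** — the *latent regulator* — is
learned jointly with the network and absorbs progression variation that the
short observed window cannot express; the classifier head consumes
flatten(D) ⊕ flatten(D·H) ⊕ static features through three ReLU dense
layers and a softmax over the classes {neither, AHE, HRS}.  H is shared
across patients and fixed at prediction time; its per-epoch Frobenius
movement ‖H⁽ᵉ⁾ − H⁽ᵉ⁻¹⁾‖_F is recorded as a convergence trace.

Class imbalance (≈0.6% AHE, ≈2.7% HRS in the emulated cohort) is handled
twice: SMOTEENN resampling of the training split, and cost-sensitive
training with a misclassification cost matrix c(k, i) (zero diagonal,
cost 200 on the true-AHE and true-HRS rows).  The default loss reweights
the cross-entropy of each instance by its true-class row cost
w_k = Σ_{i≠k} c(k, i)/(K−1); the expected cost Σᵢ c(k, i)·pᵢ is available
both as an alternative loss and as a prediction-time decision rule
argminᵢ Σₖ pₖ·c(k, i).

Around the model the package implements the full protocol: a validated
cohort schema (flat CSV, one row per record), a denoising-autoencoder lab
imputer benchmarked by masked-holdout NRMSE against mean/kNN baselines,
min-max scaling + zero padding, first-principles SMOTE and
edited-nearest-neighbour cleaning, one-against-all evaluation
(precision/recall/F/AUC, PR curves, repeated-trial paired t-tests), and
permutation-sampling Shapley attribution grouped into clinical indicators,
RNN embedding units and latent-regulator columns.

## Worked example

```python
from rnnlr import (PipelineConfig, SimConfig, ModelConfig, run_pipeline)

config = PipelineConfig(
    simulate=SimConfig(n_patients=1200, prevalence=(0.70, 0.12, 0.18),
                       signal_strength=3.0, seed=0),
    model=ModelConfig(epochs=100),
    seed=7)
art = run_pipeline(config, "runs/demo")
print(art["report"].rendered())
```

prints the held-out one-against-all table (2-decimal rendering):

```
         precision  recall  f_measure   auc
neither       0.00    0.00       0.00  0.63
AHE           0.14    0.56       0.22  0.63
HRS           0.26    0.79       0.39  0.70
```

With cost 200 on missing a true complication, the decision rule trades
essentially all `neither` precision for phenotype recall — the AUC columns
show the probabilistic ranking is far better than chance, while the
thresholded labels are deliberately alarm-biased.  The same pipeline is
available from the shell (`rnnlr run`, `rnnlr simulate`, `rnnlr impute`,
`rnnlr train`, `rnnlr predict`, `rnnlr evaluate`, `rnnlr attribute`).

The bundled published confusion matrix runs through the same metric stack
with:

```bash
rnnlr reproduce-table
#          precision  recall  f_measure
# neither       0.98    0.85       0.91
# AHE           0.21    0.42       0.28
# HRS           0.08    0.40       0.13
```

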