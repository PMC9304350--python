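# dynamilc

Interpretable deep learning on multivariate ICA time-course dynamics:
self-supervised window↔sequence pretraining, attention-LSTM
classification, post hoc saliency, and two validation procedures that
test whether the saliency means anything.

## Who this is for

Computational neuroimaging groups who classify patients vs controls from
resting-state fMRI **ICA time courses** (C components × T time points per
subject, typically 53 × ~140) and want the model itself to say *which*
parts of the signal dynamics carried the decision — then to verify that
claim quantitatively rather than by eyeballing saliency maps.

## What's inside

* **whole-MILC network** — a parameter-shared LSTM encoder (hidden 256)
  with additive attention turns each sliding 53 × 20 window into a local
  embedding **z**; a top LSTM (hidden 200) with attention turns the window
  sequence into a context embedding **c**; a bilinear critic
  f(z, c) = φ(z)ᵀc scores window/sequence pairs.
* **Self-supervised pretraining** — InfoNCE over minibatches of unlabeled
  subjects: L = −Σᵢ Σₜ log [exp f(zₜⁱ, cⁱ) / Σₖ exp f(zₜⁱ, cᵏ)], a lower
  bound on the mutual information between a window and its own sequence.
  The learned representations transfer into small labeled studies
  ("w/ pretraining" vs "w/o pretraining").
* **Attribution** — integrated gradients (and smoothgrad-IG) of the
  predicted-class logit, computed on the stride-1 windowed input and
  averaged over overlapping windows into one C × T saliency map per
  subject.
* **RAR (Retain And Retrain)** — keep only the top-5% salient cells, zero
  the rest, recompute Pearson FNC, retrain an independent RBF SVM
  (grid-searched, inner 3-fold CV), and compare ξ(Xᴹ | g_i) against the
  random-permutation baseline ξ(Xᴹ | gᴿ) on identical folds.
* **Temporal statistics** — per-time-point counts of top-5% cells
  ("temporal density") and the earth mover's distance to a uniform
  density, quantifying whether discriminative activity is temporally
  focal (spiky) or diffuse; Wilcoxon rank tests for group contrasts.
* **Synthetic cohort generator** — AR(1)-latent subjects with planted
  connectivity shifts and/or focal events plus exact ground-truth masks,
  so the whole pipeline is testable end to end without any data download.

All numerics run on NumPy with a small built-in reverse-mode autodiff
tape; no GPU or deep-learning framework is required.

## Worked example

```python
import numpy as np
import dynamilc as dm
from dynamilc import experiments as ex
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

# cohort of 50 patients + 50 controls with a planted focal event
spec = dm.CohortSpec(n_per_class=50, seed=101)
records, truth = dm.generate_cohort(spec)
labels = np.array([r.label for r in records])

folds = list(StratifiedKFold(5, shuffle=True, random_state=0)
             .split(np.zeros(len(records)), labels))
model = ex.train_cohort_model(records, folds[0][0], seed=5)
probs = dm.subject_probabilities(model, [records[i] for i in folds[0][1]])
print("test AUC", round(roc_auc_score(labels[folds[0][1]], probs), 3))

saliency = ex.cohort_saliency(model, records, steps=16)
print(ex.saliency_precision(saliency, truth, range(50, 100)))
rar = ex.rar_experiment(records, saliency, seed=7)
print("xi(salient)", round(rar["xi_salient"], 3),
      "xi(random)", round(rar["xi_random"], 3), "p", rar["p_value"])
```

Output from this exact script:

```
test AUC 0.8
{'precision': 0.1001078167115903, 'chance': 0.016172506738544475, 'ratio': 6.19}
xi(salient) 0.982 xi(random) 0.605 p 0.0006337625600278512
```

Reading: the fine-tuned model separates the synthetic patients from
controls (AUC 0.80 on the held-out fold); the top-5% IG cells hit the
planted ground-truth cells 6.2× more often than chance; and an
independent SVM trained on just those 5% retained cells nearly matches
full-data performance (ξ = 0.98) while the same SVM on randomly retained
cells collapses (ξ = 0.60) — i.e. the saliency maps point at the cells
that actually carry the class signal.

## Command-line interface

```bash
dynamilc simulate --n 50 --seed 0 --out cohort.h5
dynamilc pretrain --cohort pool.h5 --epochs 10 --out pre.h5
dynamilc finetune --cohort cohort.h5 --checkpoint pre.h5 --mode pretrained --out model.h5
dynamilc cv --cohort cohort.h5 --sizes 15,25 --k 5 --repeats 10 --out cv.csv
dynamilc attribute --cohort cohort.h5 --checkpoint model.h5 --method ig --out-dir out/
dynamilc rar --cohort cohort.h5 --mask-dir out/ --out rar.csv
dynamilc temporal --saliency-dir out/ --cohort cohort.h5 --out emd.csv
```

## Scope

The package starts from ICA time courses: raw fMRI preprocessing, group
ICA and component curation are upstream and out of scope, as are
brain-space renderings (edge lists are exported instead).
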