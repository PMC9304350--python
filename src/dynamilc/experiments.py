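"""End-to-end study drivers: train → attribute → validate on synthetic cohorts.

These functions tie the pipeline together at the cohort scale used for the
package's reproducibility checks: a focal-event cohort for RAR and
saliency-localization validation, a flat-profile twin for the temporal-EMD
contrast, and a pretraining-transfer comparison at small sample size.
Every function takes a single integer seed from which all randomness is
derived.  Problem sizes and epoch counts are the package defaults chosen
for single-CPU runs; they can be raised for larger studies.
"""

from __future__ import annotations

import numpy as np

from .attribution import random_importance, saliency_map, select_top_fraction
from .cohort import TimecourseRecord
from .network import MilcModel
from .rar import apply_retain_mask, compare_estimators, rar_auc
from .synthetic import CohortSpec, generate_cohort, generate_pretraining_pool
from .temporal import emd_to_uniform, temporal_density, wilcoxon_rank
from .training import TrainConfig, cross_validate, finetune, pretrain

__all__ = [
    "train_cohort_model",
    "cohort_saliency",
    "rar_experiment",
    "saliency_precision",
    "temporal_emd_experiment",
    "pretraining_transfer_experiment",
]

# study-condition defaults for the reproduction experiments
FOCAL_SPEC = dict(n_per_class=50, effect_type="focal_event")
TRAIN_EPOCHS = 6
TRAIN_LR = 1e-3
TRAIN_WEIGHT_DECAY = 1e-2
IG_STEPS = 16


def _seed(base: int, *parts) -> int:
    return int(np.random.SeedSequence([int(base), *map(int, parts)]).generate_state(1)[0] % (2**31))


def train_cohort_model(
    records,
    train_idx,
    seed: int,
    epochs: int = TRAIN_EPOCHS,
    learning_rate: float = TRAIN_LR,
    weight_decay: float = TRAIN_WEIGHT_DECAY,
    pretrained: MilcModel | None = None,
    freeze_encoder: bool = False,
) -> MilcModel:
    """Fine-tune a fresh whole-MILC model on the given training subjects."""
    model = MilcModel(n_components=records[0].n_components, seed=seed)
    mode = "finetune_from_pretrained" if pretrained is not None else "finetune_from_scratch"
    cfg = TrainConfig(batch_size=8, epochs=epochs, learning_rate=learning_rate,
                      weight_decay=weight_decay, seed=seed, mode=mode,
                      freeze_encoder=freeze_encoder)
    finetune(model, [records[i] for i in train_idx], cfg, pretrained=pretrained)
    return model


def cohort_saliency(model: MilcModel, records, steps: int = IG_STEPS, method: str = "ig"):
    """Assembled IG saliency maps for every subject."""
    return [saliency_map(model, r, method=method, steps=steps) for r in records]


def rar_experiment(
    records,
    saliency_maps,
    retain_fraction: float = 0.05,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
):
    """ξ(X^M | IG) vs ξ(X^M | g^R) on identical folds.

    Every subject's data is reduced to its top-fraction cells — once by the
    model's saliency map, once by a subject-specific random permutation —
    and an RBF SVM on masked-FNC features is retrained per fold and repeat.
    """
    labels = [r.label for r in records]
    masked_sal, masked_rand = [], []
    for i, (rec, sal) in enumerate(zip(records, saliency_maps)):
        masked_sal.append(apply_retain_mask(rec, select_top_fraction(sal, retain_fraction)))
        est = random_importance(rec.data.shape, seed=_seed(seed, 1, i))
        masked_rand.append(apply_retain_mask(rec, select_top_fraction(est, retain_fraction)))
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_seed(seed, 2) % (2**31))
    fold_list = list(skf.split(np.zeros(len(records)), labels))
    rep_s = rar_auc(masked_sal, labels, folds=fold_list, repeats=repeats,
                    seed=_seed(seed, 3), estimator_tag="g_i", retain_fraction=retain_fraction)
    rep_r = rar_auc(masked_rand, labels, folds=fold_list, repeats=repeats,
                    seed=_seed(seed, 3), estimator_tag="g_R", retain_fraction=retain_fraction)
    comparison = compare_estimators(rep_s, rep_r)
    comparison["report_salient"] = rep_s
    comparison["report_random"] = rep_r
    return comparison


def saliency_precision(saliency_maps, truth, patient_slice, p: float = 0.05) -> dict:
    """Precision of the top-p cells against the planted ground truth (patients)."""
    precisions = []
    for i in patient_slice:
        mask = select_top_fraction(saliency_maps[i], p).mask
        planted = truth.masks[i]
        if planted.sum() == 0:
            continue
        precisions.append((mask & planted).sum() / mask.sum())
    precision = float(np.mean(precisions))
    chance = float(truth.planted_fraction)
    return {"precision": precision, "chance": chance, "ratio": precision / chance}


def temporal_emd_experiment(spiky_maps, flat_maps, p: float = 0.05) -> dict:
    """EMD-to-uniform distributions of the two temporal profiles + rank-sum test."""
    emd_spiky = [emd_to_uniform(temporal_density(s, p)) for s in spiky_maps]
    emd_flat = [emd_to_uniform(temporal_density(s, p)) for s in flat_maps]
    stat, pval = wilcoxon_rank(emd_spiky, emd_flat)
    return {
        "emd_spiky_mean": float(np.mean(emd_spiky)),
        "emd_flat_mean": float(np.mean(emd_flat)),
        "statistic": stat,
        "p_value": pval,
        "emd_spiky": emd_spiky,
        "emd_flat": emd_flat,
    }


def pretraining_transfer_experiment(
    seed: int,
    pool_size: int = 64,
    pretrain_epochs: int = 12,
    n_per_class: int = 40,
    train_per_class: int = 15,
    repeats: int = 10,
    epochs: int = 3,
    pretrained_lr: float = 3e-4,
    cohort_spec: dict | None = None,
) -> dict:
    """Fine-tuning at small n, initialized from the pretrained checkpoint vs scratch.

    Pretrains once on an unlabeled pool, then repeats a balanced 15-per-class
    fine-tune with both initializations on fresh subsamples, scoring AUC on
    the untouched remainder of the cohort each time.  The pretrained arm
    fine-tunes at a lower learning rate (standard transfer practice: large
    steps would destroy the transferred representation before the fresh head
    settles); the scratch arm uses the package's fine-tuning default.
    """
    from sklearn.metrics import roc_auc_score

    from .training import subject_probabilities

    pool = generate_pretraining_pool(pool_size, seed=_seed(seed, 10))
    pre = MilcModel(n_components=53, seed=_seed(seed, 11))
    _, history = pretrain(pool, pre, TrainConfig(
        batch_size=16, epochs=pretrain_epochs, learning_rate=1e-3, seed=_seed(seed, 12)))

    spec_fields = dict(FOCAL_SPEC, n_per_class=n_per_class, seed=_seed(seed, 13))
    spec_fields.update(cohort_spec or {})
    records, _ = generate_cohort(CohortSpec(**spec_fields))
    labels = np.array([r.label for r in records])

    auc_pre, auc_scratch = [], []
    for rep in range(repeats):
        rng = np.random.default_rng(_seed(seed, 14, rep))
        train_idx = np.concatenate([
            rng.choice(np.where(labels == c)[0], size=train_per_class, replace=False)
            for c in (0, 1)
        ])
        test_idx = np.setdiff1d(np.arange(len(records)), train_idx)
        test = [records[i] for i in test_idx]
        for mode, bucket in (("finetune_from_pretrained", auc_pre),
                             ("finetune_from_scratch", auc_scratch)):
            from_pre = mode == "finetune_from_pretrained"
            model = train_cohort_model(
                records, train_idx, seed=_seed(seed, 15, rep), epochs=epochs,
                learning_rate=pretrained_lr if from_pre else TRAIN_LR,
                pretrained=pre if from_pre else None,
            )
            p1 = subject_probabilities(model, test)
            bucket.append(roc_auc_score(labels[test_idx], p1))
    stat, pval = wilcoxon_rank(auc_pre, auc_scratch, paired=True)
    return {
        "auc_pretrained_mean": float(np.mean(auc_pre)),
        "auc_scratch_mean": float(np.mean(auc_scratch)),
        "auc_pretrained": auc_pre,
        "auc_scratch": auc_scratch,
        "signed_rank_statistic": stat,
        "signed_rank_p": pval,
        "pretraining_history": history,
    }
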