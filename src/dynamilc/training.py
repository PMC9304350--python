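"""Contrastive pretraining, supervised fine-tuning and the CV harness.

Pretraining maximizes a mutual-information lower bound between each
window embedding z_t^i and the whole-sequence context embeddings c^k of
the subjects in the minibatch (InfoNCE): the positive pair is the
window's own sequence, the negatives are the other sequences in the
batch, and the loss is

    L = − Σ_i Σ_t log( exp f(z_t^i, c^i) / Σ_k exp f(z_t^i, c^k) ).

Pretraining accuracy is the fraction of held-out (window, sequence)
pairs whose own sequence wins the argmax over the batch.

Fine-tuning trains the whole network end-to-end with cross-entropy on
the two-logit head, either from a pretrained checkpoint (encoder, top
network and φ transferred; fresh head) or from random initialization.
The cross-validation harness subsamples progressively larger balanced
training sets from the train folds, repeats each cell with its own seed,
and scores AUC on the untouched test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax as np_softmax
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor, logsumexp
from .cohort import SlidingWindowSpec, TimecourseRecord, make_windows, normalize_timecourses
from .network import MilcModel

__all__ = [
    "TrainConfig",
    "CVResult",
    "infonce_loss",
    "pretrain",
    "finetune",
    "cross_validate",
    "subject_probabilities",
]

PRETRAIN_STRIDE = 10
DOWNSTREAM_STRIDE = 1


@dataclass
class TrainConfig:
    """Optimization settings; every stochastic choice flows from `seed`."""

    batch_size: int = 16
    epochs: int = 10
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    weight_decay: float = 0.0  # decoupled (AdamW-style)
    freeze_encoder: bool = False  # fine-tune top network + head only (transfer mode)
    seed: int = 0
    device: str = "cpu"
    mode: str = "pretrain"  # pretrain | finetune_from_pretrained | finetune_from_scratch

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch_size, epochs must be positive; learning_rate >= 0")
        if self.mode not in ("pretrain", "finetune_from_pretrained", "finetune_from_scratch"):
            raise ValueError(f"unknown mode {self.mode!r}")


class _Adam:
    """Adaptive-moment gradient descent on the model's parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            if g is None:
                continue
            g = g.astype(self.params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.wd:
                self.params[k] -= self.lr * self.wd * self.params[k]


# ---------------------------------------------------------------------------
# InfoNCE
# ---------------------------------------------------------------------------

def infonce_loss(scores: np.ndarray) -> float:
    """InfoNCE loss −Σ_i Σ_t log softmax_k S[i,t,k] at k=i for S (N, T, N).

    Computed with a stable log-sum-exp; equals N·T·ln N when all scores are
    equal, and approaches 0 as the positive scores dominate.
    """
    S = np.asarray(scores, dtype=np.float64)
    if S.ndim != 3 or S.shape[0] != S.shape[2]:
        raise ValueError("scores must be (N, T, N)")
    N = S.shape[0]
    if N < 2:
        raise ValueError("InfoNCE needs at least two sequences (one negative)")
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite scores")
    m = S.max(axis=2, keepdims=True)
    lse = np.log(np.exp(S - m).sum(axis=2)) + m[..., 0]
    pos = S[np.arange(N)[:, None], np.arange(S.shape[1])[None, :], np.arange(N)[:, None]]
    return float((lse - pos).sum())


def _infonce_loss_t(S: Tensor, owner: np.ndarray) -> Tensor:
    """Tape version: S is (M, N) window-vs-sequence scores, owner[m] = positive column."""
    lse = logsumexp(S, axis=1)
    pos = S[np.arange(S.shape[0]), owner]
    return (lse - pos).sum()


# ---------------------------------------------------------------------------
# shared data plumbing
# ---------------------------------------------------------------------------

def _window_stack(records: Sequence[TimecourseRecord], model: MilcModel, stride: int):
    """Normalize records and window them; requires a common window count."""
    spec = SlidingWindowSpec(window_length=model.config["window_length"], stride=stride)
    stacks = [make_windows(normalize_timecourses(r), spec).windows for r in records]
    n_windows = {s.shape[0] for s in stacks}
    if len(n_windows) != 1:
        raise ValueError("records in one batch must share the same window count")
    return np.stack(stacks).astype(model.dtype), n_windows.pop()


def _batch_scores(model: MilcModel, pt, windows: np.ndarray, n_windows: int):
    """Forward a (B, nw, C, L) batch to pair scores (B·nw, B) and contexts."""
    B = windows.shape[0]
    flat = Tensor(windows.reshape(B * n_windows, *windows.shape[2:]))
    z = model._encode_windows_t(pt, flat)
    c = model._encode_sequence_t(pt, z.reshape(B, n_windows, z.shape[1]))
    S = model._scores_t(pt, z, c)
    owner = np.repeat(np.arange(B), n_windows)
    return S, owner, c


def subject_probabilities(
    model: MilcModel,
    records: Sequence[TimecourseRecord],
    stride: int = DOWNSTREAM_STRIDE,
    batch_size: int = 8,
) -> np.ndarray:
    """Class-1 probabilities for each record (softmax over the two logits)."""
    probs = []
    for lo in range(0, len(records), batch_size):
        chunk = records[lo : lo + batch_size]
        windows, nw = _window_stack(chunk, model, stride)
        B = windows.shape[0]
        flat = Tensor(windows.reshape(B * nw, *windows.shape[2:]))
        logits = model._forward_subjects_t(model._pt(), flat, nw).value
        probs.append(np_softmax(logits.astype(np.float64), axis=1)[:, 1])
    return np.concatenate(probs)


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def _pretrain_accuracy(model: MilcModel, records, batch_size: int) -> float:
    """Fraction of held-out (window, sequence) positives winning the batch argmax."""
    hits, total = 0, 0
    pt = model._pt()
    for lo in range(0, len(records) - 1, batch_size):
        chunk = records[lo : lo + batch_size]
        if len(chunk) < 2:
            continue
        windows, nw = _window_stack(chunk, model, PRETRAIN_STRIDE)
        S, owner, _ = _batch_scores(model, pt, windows, nw)
        hits += int((S.value.argmax(axis=1) == owner).sum())
        total += owner.size
    return hits / total if total else float("nan")


def pretrain(
    pool: Sequence[TimecourseRecord],
    model: MilcModel,
    config: TrainConfig,
    holdout_fraction: float = 0.15,
):
    """Self-supervised pretraining of `model` on an unlabeled pool (in place).

    Minimizes the InfoNCE loss over minibatches of subjects, using the other
    sequences in the batch as negatives.  A held-out split of the pool is
    scored each epoch with the window→sequence matching accuracy.  Returns
    ``(model, history)`` where history has one dict per epoch.
    """
    if len(pool) < max(config.batch_size, 2):
        raise ValueError("pool smaller than batch size")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pool))
    n_hold = max(2, int(round(holdout_fraction * len(pool)))) if len(pool) >= 4 else 0
    hold = [pool[i] for i in order[:n_hold]]
    train = [pool[i] for i in order[n_hold:]]

    opt = _Adam(model.params, config.learning_rate, weight_decay=config.weight_decay)
    history = []
    # one fixed batch partition: with frozen weights the per-epoch loss is
    # then exactly reproducible (in-batch negatives do not change)
    perm = rng.permutation(len(train))
    for epoch in range(config.epochs):
        total_loss, total_pairs = 0.0, 0
        for lo in range(0, len(train) - 1, config.batch_size):
            chunk = [train[i] for i in perm[lo : lo + config.batch_size]]
            if len(chunk) < 2:
                continue
            windows, nw = _window_stack(chunk, model, PRETRAIN_STRIDE)
            pt = model._pt(trainable=True)
            S, owner, _ = _batch_scores(model, pt, windows, nw)
            loss = _infonce_loss_t(S, owner) * (1.0 / owner.size)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"non-finite InfoNCE loss at epoch {epoch}, batch starting {lo}"
                )
            loss.backward()
            opt.step({k: t.grad for k, t in pt.items()})
            total_loss += float(loss.value) * owner.size
            total_pairs += owner.size
        acc = _pretrain_accuracy(model, hold, config.batch_size) if hold else float("nan")
        history.append(
            {
                "epoch": epoch,
                "loss": total_loss / max(total_pairs, 1),
                "heldout_accuracy": acc,
            }
        )
    return model, history


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def finetune(
    model: MilcModel,
    labeled: Sequence[TimecourseRecord],
    config: TrainConfig,
    pretrained: Optional[MilcModel] = None,
    batch_subjects: Optional[int] = None,
) -> MilcModel:
    """End-to-end supervised training with cross-entropy on the 2-logit head.

    ``finetune_from_pretrained`` copies encoder, top network and φ from the
    `pretrained` checkpoint (the head stays freshly initialized);
    ``finetune_from_scratch`` trains from the model's own random init.
    """
    labels = np.array([r.label for r in labeled])
    if any(l is None for l in labels):
        raise ValueError("all fine-tuning records need labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("fine-tuning requires both classes in the training set")
    if config.mode == "finetune_from_pretrained":
        if pretrained is None:
            raise ValueError("mode finetune_from_pretrained needs a pretrained model")
        model.load_state_from(pretrained, skip_head=True)

    if batch_subjects is None:
        batch_subjects = min(config.batch_size, len(labeled))
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate, weight_decay=config.weight_decay)
    y = labels.astype(int)

    z_cache = None
    if config.freeze_encoder:
        # encoder stays fixed: window embeddings are computed once up front
        zs = []
        for lo in range(0, len(labeled), batch_subjects):
            windows, nw = _window_stack(labeled[lo : lo + batch_subjects], model,
                                        DOWNSTREAM_STRIDE)
            B = windows.shape[0]
            flat = Tensor(windows.reshape(B * nw, *windows.shape[2:]))
            z = model._encode_windows_t(model._pt(), flat).value
            zs.append(z.reshape(B, nw, -1))
        z_cache = np.concatenate(zs)

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(labeled))
        for lo in range(0, len(labeled), batch_subjects):
            idx = perm[lo : lo + batch_subjects]
            pt = model._pt(trainable=True)
            if config.freeze_encoder:
                c = model._encode_sequence_t(pt, Tensor(z_cache[idx]))
                logits = model._classify_t(pt, c)
            else:
                chunk = [labeled[i] for i in idx]
                windows, nw = _window_stack(chunk, model, DOWNSTREAM_STRIDE)
                B = windows.shape[0]
                flat = Tensor(windows.reshape(B * nw, *windows.shape[2:]))
                logits = model._forward_subjects_t(pt, flat, nw)
            B = logits.shape[0]
            lse = logsumexp(logits, axis=1)
            picked = logits[np.arange(B), y[idx]]
            loss = (lse - picked).sum() * (1.0 / B)
            if not np.isfinite(loss.value):
                raise RuntimeError("non-finite cross-entropy loss during fine-tuning")
            loss.backward()
            grads = {k: t.grad for k, t in pt.items()}
            if config.freeze_encoder:
                grads = {k: g for k, g in grads.items()
                         if not (k.startswith("enc_lstm.") or k.startswith("enc_attn."))}
            opt.step(grads)
    return model


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Grid of test AUC/accuracy over (mode, train_size, fold, repeat).

    `manifest` records, for every cell, the subject ids used for training and
    the test-fold subject ids, so leakage can be audited after the fact.
    """

    table: pd.DataFrame
    manifest: list = field(default_factory=list)
    fold_test_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["mode", "train_size"])["auc"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def compare_modes(self, mode_a: str, mode_b: str):
        """Paired signed-rank test between two modes over matched cells."""
        from .temporal import wilcoxon_rank

        keys = ["train_size", "fold", "repeat"]
        a = self.table[self.table["mode"] == mode_a].set_index(keys)["auc"]
        b = self.table[self.table["mode"] == mode_b].set_index(keys)["auc"]
        joined = pd.concat([a, b], axis=1, join="inner")
        stat, p = wilcoxon_rank(joined.iloc[:, 0].values, joined.iloc[:, 1].values, paired=True)
        return {
            "mean_diff": float(joined.iloc[:, 0].mean() - joined.iloc[:, 1].mean()),
            "statistic": stat,
            "p_value": p,
        }


def _cell_seed(base_seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), *map(int, parts)]).generate_state(1)[0] % (2**31))


def cross_validate(
    cohort: Sequence[TimecourseRecord],
    k: int,
    train_sizes: Sequence[int],
    repeats: int = 10,
    base_seed: int = 0,
    modes: Sequence[str] = ("finetune_from_scratch",),
    pretrained: Optional[MilcModel] = None,
    epochs: int = 4,
    learning_rate: float = 1e-3,
    model_kwargs: Optional[dict] = None,
) -> CVResult:
    """Stratified K-fold CV with progressively larger balanced training sets.

    For each (fold, repeat, train_size, mode): subsample `train_size`
    subjects per class from the train folds with a cell-specific seed,
    fine-tune a fresh model and score AUC/accuracy on the untouched test
    fold.  Folds partition the cohort; test subjects never appear in any
    cell's training pool.
    """
    labels = np.array([r.label for r in cohort])
    if any(l is None for l in labels):
        raise ValueError("cross_validate requires a fully labeled cohort")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError("too few subjects per class for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=base_seed)
    model_kwargs = dict(model_kwargs or {})
    model_kwargs.setdefault("n_components", cohort[0].n_components)

    rows, manifest, fold_tests = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(cohort)), labels)):
        fold_tests.append([cohort[i].subject_id for i in test_idx])
        per_class = {c: train_idx[labels[train_idx] == c] for c in (0, 1)}
        for size in train_sizes:
            if any(len(v) < size for v in per_class.values()):
                raise ValueError(f"train_size {size} exceeds per-class pool in fold {fold}")
            for rep in range(repeats):
                seed = _cell_seed(base_seed, fold, rep, size)
                rng = np.random.default_rng(seed)
                chosen = np.concatenate(
                    [rng.choice(per_class[c], size=size, replace=False) for c in (0, 1)]
                )
                train_records = [cohort[i] for i in chosen]
                test_records = [cohort[i] for i in test_idx]
                for mode in modes:
                    cfg = TrainConfig(
                        batch_size=min(8, 2 * size),
                        epochs=epochs,
                        learning_rate=learning_rate,
                        seed=seed,
                        mode=mode,
                    )
                    model = MilcModel(seed=seed, **model_kwargs)
                    finetune(model, train_records, cfg, pretrained=pretrained)
                    p1 = subject_probabilities(model, test_records)
                    y_test = labels[test_idx]
                    rows.append(
                        {
                            "mode": mode,
                            "train_size": size,
                            "fold": fold,
                            "repeat": rep,
                            "seed": seed,
                            "auc": roc_auc_score(y_test, p1),
                            "accuracy": accuracy_score(y_test, (p1 > 0.5).astype(int)),
                        }
                    )
                    manifest.append(
                        {
                            "mode": mode,
                            "train_size": size,
                            "fold": fold,
                            "repeat": rep,
                            "train_ids": [r.subject_id for r in train_records],
                            "test_ids": [r.subject_id for r in test_records],
                        }
                    )
    return CVResult(table=pd.DataFrame(rows), manifest=manifest, fold_test_ids=fold_tests)
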