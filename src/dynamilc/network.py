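"""The whole-MILC network.

Two unidirectional LSTMs arranged top-down.  The lower LSTM is a
parameter-shared encoder that maps each sliding window (C components ×
20 time steps) to a 256-dimensional local embedding z via additive
attention over its hidden states; the top LSTM consumes the sequence of
window embeddings and produces a 200-dimensional whole-sequence context
embedding c the same way.  A bias-free linear map φ: R^256 → R^200 scores
window/sequence pairs as f(z, c) = φ(z)·c for the contrastive
pretraining objective, and a small feed-forward head on c yields the two
classification logits for patient/control discrimination.

Attention follows the additive convention: every hidden state h_i is
concatenated with the last hidden state h_n, passed through a two-layer
feed-forward scorer (tanh between layers, scalar output), the n scores
are softmax-normalized into weights α, and the pooled representation is
Σ_k α_k h_k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .autodiff import Tensor, concat, softmax, stack

__all__ = [
    "MilcModel",
    "AttentionState",
    "attention_pool",
    "encode_window",
    "encode_sequence",
    "score_pair",
    "classify_logits",
]


@dataclass
class AttentionState:
    """Hidden states with their alignment scores and softmax weights."""

    hidden_states: np.ndarray  # (n, d_h)
    alignment_scores: np.ndarray  # (n,)
    weights: np.ndarray  # (n,), nonnegative, sums to 1


def attention_pool(hidden_states: np.ndarray, scorer):
    """Additive-attention pooling of a hidden-state sequence.

    ``scorer`` maps the (n, 2·d_h) matrix of concat(h_i, h_n) pairs to n
    scalar alignment scores.  Returns the weighted sum Σ α_k h_k together
    with the full :class:`AttentionState`.
    """
    h = np.asarray(hidden_states, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("hidden_states must be a non-empty (n, d_h) matrix")
    n = h.shape[0]
    pairs = np.concatenate([h, np.broadcast_to(h[-1], h.shape)], axis=1)
    scores = np.asarray(scorer(pairs), dtype=float).reshape(n)
    shifted = scores - scores.max()
    w = np.exp(shifted)
    w /= w.sum()
    pooled = w @ h
    return pooled, AttentionState(hidden_states=h, alignment_scores=scores, weights=w)


class MilcModel:
    """Weight container and forward passes for the whole-MILC network.

    Default sizes follow the reference architecture: encoder LSTM hidden 256
    with a 512→64→1 attention scorer, top LSTM hidden 200 with a 400→128→1
    scorer, and a 200-hidden-unit classification head with two outputs.
    Forward passes are deterministic given weights and input (no dropout).
    """

    def __init__(
        self,
        n_components: int = 53,
        window_length: int = 20,
        d_enc: int = 256,
        d_top: int = 200,
        enc_attn_hidden: int = 64,
        top_attn_hidden: int = 128,
        d_head: int = 200,
        n_classes: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.config = dict(
            n_components=n_components,
            window_length=window_length,
            d_enc=d_enc,
            d_top=d_top,
            enc_attn_hidden=enc_attn_hidden,
            top_attn_hidden=top_attn_hidden,
            d_head=d_head,
            n_classes=n_classes,
        )
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- construction ---------------------------------------------------
    def _uniform(self, rng, shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape).astype(self.dtype)

    def _init_lstm(self, rng, prefix, d_in, d_h):
        self.params[f"{prefix}.W"] = self._uniform(rng, (d_in + d_h, 4 * d_h), d_in + d_h)
        b = np.zeros(4 * d_h, dtype=self.dtype)
        b[d_h : 2 * d_h] = 1.0  # forget-gate bias
        self.params[f"{prefix}.b"] = b

    def _init_ff(self, rng, prefix, d_in, d_hidden, d_out):
        self.params[f"{prefix}.W1"] = self._uniform(rng, (d_in, d_hidden), d_in)
        self.params[f"{prefix}.b1"] = np.zeros(d_hidden, dtype=self.dtype)
        self.params[f"{prefix}.W2"] = self._uniform(rng, (d_hidden, d_out), d_hidden)
        self.params[f"{prefix}.b2"] = np.zeros(d_out, dtype=self.dtype)

    def _init_params(self, rng):
        cfg = self.config
        C, de, dt = cfg["n_components"], cfg["d_enc"], cfg["d_top"]
        self._init_lstm(rng, "enc_lstm", C, de)
        self._init_ff(rng, "enc_attn", 2 * de, cfg["enc_attn_hidden"], 1)
        self._init_lstm(rng, "top_lstm", de, dt)
        self._init_ff(rng, "top_attn", 2 * dt, cfg["top_attn_hidden"], 1)
        self.params["phi.W"] = self._uniform(rng, (de, dt), de)
        self._init_ff(rng, "head", dt, cfg["d_head"], cfg["n_classes"])

    def copy(self) -> "MilcModel":
        out = MilcModel(seed=self.seed, dtype=self.dtype, **self.config)
        out.params = {k: v.copy() for k, v in self.params.items()}
        return out

    def load_state_from(self, other: "MilcModel", skip_head: bool = False) -> None:
        if other.config != self.config:
            raise ValueError("architecture mismatch between models")
        for k, v in other.params.items():
            if skip_head and k.startswith("head."):
                continue
            self.params[k] = v.copy()

    # -- tensor-level forward pieces (shared by training & attribution) --
    def _pt(self, trainable: bool = False) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=trainable) for k, v in self.params.items()}

    def _lstm(self, pt, prefix, xs: Tensor) -> Tensor:
        """Run an LSTM over xs (B, n, d_in); returns hidden states (B, n, H)."""
        B, n, _ = xs.shape
        W, b = pt[f"{prefix}.W"], pt[f"{prefix}.b"]
        H = W.shape[1] // 4
        h = Tensor(np.zeros((B, H), dtype=W.dtype))
        c = Tensor(np.zeros((B, H), dtype=W.dtype))
        hs = []
        for t in range(n):
            inp = concat([xs[:, t, :], h], axis=1)
            gates = inp @ W + b
            s = gates[:, : 3 * H].sigmoid()  # input, forget, output gates fused
            i, f, o = s[:, :H], s[:, H : 2 * H], s[:, 2 * H :]
            g = gates[:, 3 * H :].tanh()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return stack(hs, axis=1)

    def _attention(self, pt, prefix, h: Tensor):
        """Additive attention over h (B, n, H) → pooled (B, H), weights (B, n)."""
        B, n, H = h.shape
        h_last = h[:, n - 1 : n, :] + Tensor(np.zeros((1, n, 1), dtype=h.dtype))
        pairs = concat([h, h_last], axis=2).reshape(B * n, 2 * H)
        hid = (pairs @ pt[f"{prefix}.W1"] + pt[f"{prefix}.b1"]).tanh()
        scores = (hid @ pt[f"{prefix}.W2"] + pt[f"{prefix}.b2"]).reshape(B, n)
        alpha = softmax(scores, axis=1)
        pooled = (alpha.reshape(B, n, 1) * h).sum(axis=1)
        return pooled, alpha

    def _encode_windows_t(self, pt, windows: Tensor) -> Tensor:
        """(B, C, L) windows → (B, d_enc) local embeddings."""
        xs = windows.transpose(0, 2, 1)  # time-major features
        hs = self._lstm(pt, "enc_lstm", xs)
        z, _ = self._attention(pt, "enc_attn", hs)
        return z

    def _encode_sequence_t(self, pt, zs: Tensor) -> Tensor:
        """(S, n_windows, d_enc) window embeddings → (S, d_top) contexts."""
        hs = self._lstm(pt, "top_lstm", zs)
        c, _ = self._attention(pt, "top_attn", hs)
        return c

    def _classify_t(self, pt, c: Tensor) -> Tensor:
        hid = (c @ pt["head.W1"] + pt["head.b1"]).relu()
        return hid @ pt["head.W2"] + pt["head.b2"]

    def _scores_t(self, pt, z: Tensor, c: Tensor) -> Tensor:
        """Pair scores f(z_m, c_k) = φ(z_m)·c_k for all m, k → (M, K)."""
        return (z @ pt["phi.W"]) @ c.T

    def _forward_subjects_t(self, pt, windows: Tensor, n_windows: int):
        """(S·n_windows, C, L) stacked windows → logits (S, n_classes)."""
        z = self._encode_windows_t(pt, windows)
        S = windows.shape[0] // n_windows
        c = self._encode_sequence_t(pt, z.reshape(S, n_windows, z.shape[1]))
        return self._classify_t(pt, c)

    # -- NumPy-facing API -------------------------------------------------
    def _check_window(self, window: np.ndarray):
        C, L = self.config["n_components"], self.config["window_length"]
        if window.shape[-2:] != (C, L):
            raise ValueError(f"expected window shaped (..., {C}, {L}), got {window.shape}")

    def encode_window(self, window: np.ndarray) -> np.ndarray:
        """Encode one (C, L) window, or a (B, C, L) batch, into 256-d z."""
        w = np.asarray(window, dtype=self.dtype)
        self._check_window(w)
        single = w.ndim == 2
        if single:
            w = w[None]
        z = self._encode_windows_t(self._pt(), Tensor(w)).value
        return z[0] if single else z

    def encode_sequence(self, zs: np.ndarray) -> np.ndarray:
        """Encode an (n_windows, 256) embedding sequence into the 200-d context c."""
        zs = np.asarray(zs, dtype=self.dtype)
        if zs.ndim != 2 or zs.shape[0] < 1 or zs.shape[1] != self.config["d_enc"]:
            raise ValueError(f"expected (n_windows, {self.config['d_enc']}) embeddings")
        return self._encode_sequence_t(self._pt(), Tensor(zs[None])).value[0]

    def score_pair(self, z: np.ndarray, c: np.ndarray) -> float:
        """f(z, c) = φ(z)·c."""
        z = np.asarray(z, dtype=self.dtype).reshape(-1)
        c = np.asarray(c, dtype=self.dtype).reshape(-1)
        if z.shape[0] != self.config["d_enc"] or c.shape[0] != self.config["d_top"]:
            raise ValueError("embedding dimension mismatch")
        return float((z @ self.params["phi.W"]) @ c)

    def classify_logits(self, c: np.ndarray) -> np.ndarray:
        """Two class logits from a context embedding."""
        c = np.asarray(c, dtype=self.dtype).reshape(-1)
        if c.shape[0] != self.config["d_top"]:
            raise ValueError("context dimension mismatch")
        return self._classify_t(self._pt(), Tensor(c[None])).value[0]

    def subject_logits(self, windows: np.ndarray) -> np.ndarray:
        """Full forward pass on one subject's (n_windows, C, L) window stack."""
        w = np.asarray(windows, dtype=self.dtype)
        self._check_window(w)
        pt = self._pt()
        return self._forward_subjects_t(pt, Tensor(w), w.shape[0]).value[0]

    def attention_scorer(self, which: str):
        """The trained 2-layer scorer ('enc' or 'top') as a NumPy callable."""
        p = self.params
        W1, b1 = p[f"{which}_attn.W1"], p[f"{which}_attn.b1"]
        W2, b2 = p[f"{which}_attn.W2"], p[f"{which}_attn.b2"]

        def scorer(pairs):
            return (np.tanh(pairs @ W1 + b1) @ W2 + b2).reshape(-1)

        return scorer

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint all weights plus the architecture config and seed."""
        with h5py.File(path, "w") as h5:
            h5.attrs["config"] = json.dumps(self.config)
            h5.attrs["seed"] = self.seed
            h5.attrs["dtype"] = self.dtype.name
            grp = h5.create_group("params")
            for k, v in self.params.items():
                grp.create_dataset(k, data=v)

    @classmethod
    def load(cls, path) -> "MilcModel":
        with h5py.File(path, "r") as h5:
            config = json.loads(h5.attrs["config"])
            dtype = h5.attrs.get("dtype", "float32")
            model = cls(seed=int(h5.attrs["seed"]), dtype=np.dtype(dtype), **config)
            for k in model.params:
                if k not in h5["params"]:
                    raise ValueError(f"checkpoint missing parameter {k!r}")
                arr = h5["params"][k][()]
                if arr.shape != model.params[k].shape:
                    raise ValueError(f"architecture mismatch for {k!r}: {arr.shape}")
                model.params[k] = arr.astype(model.dtype)
        return model


# -- functional wrappers over a model ------------------------------------

def encode_window(window: np.ndarray, model: MilcModel) -> np.ndarray:
    return model.encode_window(window)


def encode_sequence(zs: np.ndarray, model: MilcModel) -> np.ndarray:
    return model.encode_sequence(zs)


def score_pair(z: np.ndarray, c: np.ndarray, model: MilcModel) -> float:
    return model.score_pair(z, c)


def classify_logits(c: np.ndarray, model: MilcModel) -> np.ndarray:
    return model.classify_logits(c)
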