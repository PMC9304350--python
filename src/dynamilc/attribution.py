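"""Post hoc saliency: integrated gradients, smoothgrad-IG, overlap assembly,
the random-permutation importance baseline, and top-fraction selection.

Attribution is computed on the stride-1 windowed view the downstream
classifier actually consumes, with respect to the class-specific logit
F_c of the predicted class c, against an all-zeros baseline, and the
per-window attributions of overlapping windows are averaged to yield a
single C × T saliency map per subject.  Top-fraction selection ranks
cells by *signed* attribution value (largest first) with a deterministic
(component, time) tie-break, so strongly negative attributions are never
retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor
from .cohort import SlidingWindowSpec, TimecourseRecord, make_windows, normalize_timecourses
from .network import MilcModel

__all__ = [
    "SaliencyMap",
    "WindowAttribution",
    "ImportanceEstimator",
    "RetainMask",
    "integrated_gradients",
    "smoothgrad_ig",
    "assemble_subject_saliency",
    "saliency_map",
    "random_importance",
    "select_top_fraction",
    "completeness_gap",
]


@dataclass
class SaliencyMap:
    """Per-subject attribution matrix, same shape as the input time courses."""

    values: np.ndarray  # (C, T)
    subject_id: str = ""
    predicted_class: int = -1
    method: str = "IG"  # IG | SGIG | RANDOM
    coverage: Optional[np.ndarray] = None  # per-time-point covering-window count


@dataclass
class WindowAttribution:
    """Window-level attributions (n_windows, C, L) before overlap assembly."""

    values: np.ndarray
    start_indices: np.ndarray
    subject_id: str = ""
    predicted_class: int = -1
    method: str = "IG"


@dataclass
class ImportanceEstimator:
    """Either a model-derived saliency order or the random baseline g^R."""

    tag: str  # "g_i" or "g_R"
    permutation: Optional[np.ndarray] = None  # cell indices in importance order
    shape: Optional[tuple] = None
    seed: Optional[int] = None


@dataclass
class RetainMask:
    """Boolean retain mask with exactly round(p·C·T) true cells."""

    mask: np.ndarray
    retain_fraction: float


# ---------------------------------------------------------------------------
# integrated gradients
# ---------------------------------------------------------------------------

def _ig_core(grad_fn, x: np.ndarray, baseline: np.ndarray, steps: int, chunk: int = 16):
    """Right-Riemann path integral: (x−x₀) ⊙ mean_k ∇F(x₀ + (k/steps)(x−x₀)), k=1..steps."""
    delta = x - baseline
    total = np.zeros_like(x, dtype=np.float64)
    alphas = (np.arange(1, steps + 1)) / steps
    for lo in range(0, steps, chunk):
        batch_alphas = alphas[lo : lo + chunk]
        pts = baseline[None] + batch_alphas.reshape((-1,) + (1,) * x.ndim) * delta[None]
        grads = grad_fn(pts)
        if not np.all(np.isfinite(grads)):
            bad = np.argwhere(~np.isfinite(grads))[0]
            raise FloatingPointError(f"non-finite gradient at path point index {bad.tolist()}")
        total += np.asarray(grads, dtype=np.float64).sum(axis=0)
    return delta * (total / steps)


def _model_grad_fn(model: MilcModel, n_windows: int, target_class: int):
    """Gradient of the target-class logit w.r.t. a (m, nw, C, L) window batch."""

    def grad_fn(pts: np.ndarray) -> np.ndarray:
        m = pts.shape[0]
        flat = Tensor(pts.reshape(m * n_windows, *pts.shape[2:]).astype(model.dtype),
                      requires_grad=True)
        logits = model._forward_subjects_t(model._pt(), flat, n_windows)
        logits[:, target_class].sum().backward()
        return flat.grad.reshape(pts.shape)

    return grad_fn


def _windowed_input(model: MilcModel, record: TimecourseRecord, normalize: bool = True):
    rec = normalize_timecourses(record) if normalize else record
    spec = SlidingWindowSpec(window_length=model.config["window_length"], stride=1)
    wt = make_windows(rec, spec)
    return wt.windows.astype(model.dtype), wt.start_indices


def _predicted_class(model: MilcModel, windows: np.ndarray) -> int:
    return int(np.argmax(model.subject_logits(windows)))


def integrated_gradients(
    model: MilcModel,
    record: TimecourseRecord,
    target_class: Optional[int] = None,
    baseline: Optional[np.ndarray] = None,
    steps: int = 64,
    path_chunk: int = 16,
    _normalize: bool = True,
) -> WindowAttribution:
    """Window-level integrated gradients of F_c against an all-zeros baseline.

    Satisfies completeness up to the Riemann discretization error: the sum of
    the attributions approaches F_c(x) − F_c(x₀) as ``steps`` grows.
    """
    if steps < 16:
        raise ValueError("steps must be >= 16")
    windows, starts = _windowed_input(model, record, normalize=_normalize)
    if baseline is None:
        baseline = np.zeros_like(windows)
    baseline = np.asarray(baseline, dtype=windows.dtype)
    if baseline.shape != windows.shape:
        raise ValueError("baseline must match the windowed input shape")
    if target_class is None:
        target_class = _predicted_class(model, windows)
    attr = _ig_core(_model_grad_fn(model, windows.shape[0], target_class),
                    windows, baseline, steps, chunk=path_chunk)
    return WindowAttribution(
        values=attr, start_indices=starts, subject_id=record.subject_id,
        predicted_class=target_class, method="IG",
    )


def smoothgrad_ig(
    model: MilcModel,
    record: TimecourseRecord,
    target_class: Optional[int] = None,
    noise_sd: Optional[float] = None,
    n_samples: int = 25,
    steps: int = 64,
    seed: int = 0,
    path_chunk: int = 16,
) -> WindowAttribution:
    """Smoothgrad on IG: mean IG over noisy copies x + ε, ε ~ N(0, noise_sd²).

    ``noise_sd`` defaults to 0.1 × (max − min) of the normalized record.
    With ``noise_sd == 0`` this reduces exactly to plain IG.  Noise is
    injected at the record level so overlapping windows stay consistent.
    """
    if n_samples < 1 or (noise_sd is not None and noise_sd < 0):
        raise ValueError("n_samples >= 1 and noise_sd >= 0 required")
    rec = normalize_timecourses(record)
    if noise_sd is None:
        noise_sd = 0.1 * float(rec.data.max() - rec.data.min())
    windows, starts = _windowed_input(model, rec, normalize=False)
    if target_class is None:
        target_class = _predicted_class(model, windows)
    if noise_sd == 0.0:
        out = integrated_gradients(model, rec, target_class, steps=steps,
                                   path_chunk=path_chunk, _normalize=False)
        out.method = "SGIG"
        return out
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(windows, dtype=np.float64)
    for _ in range(n_samples):
        noisy = TimecourseRecord(
            rec.subject_id, rec.data + noise_sd * rng.standard_normal(rec.data.shape),
            label=rec.label, cohort_tag=rec.cohort_tag,
        )
        attr = integrated_gradients(model, noisy, target_class, steps=steps,
                                    path_chunk=path_chunk, _normalize=False)
        acc += attr.values
    return WindowAttribution(
        values=acc / n_samples, start_indices=starts, subject_id=record.subject_id,
        predicted_class=target_class, method="SGIG",
    )


def assemble_subject_saliency(
    window_attributions: np.ndarray,
    start_indices: np.ndarray,
    n_timepoints: int,
    subject_id: str = "",
    predicted_class: int = -1,
    method: str = "IG",
) -> SaliencyMap:
    """Average the attributions of all windows covering each time point.

    Cells not covered by any full window (trailing tail) are set to 0 and
    flagged by a zero coverage count.
    """
    wa = np.asarray(window_attributions, dtype=np.float64)
    if wa.ndim != 3:
        raise ValueError("window_attributions must be (n_windows, C, L)")
    nw, C, L = wa.shape
    starts = np.asarray(start_indices)
    if starts.shape != (nw,):
        raise ValueError("one start index per window required")
    total = np.zeros((C, n_timepoints))
    count = np.zeros(n_timepoints, dtype=int)
    for w, s in enumerate(starts):
        total[:, s : s + L] += wa[w]
        count[s : s + L] += 1
    covered = count > 0
    values = np.zeros_like(total)
    values[:, covered] = total[:, covered] / count[covered]
    return SaliencyMap(values=values, subject_id=subject_id,
                       predicted_class=predicted_class, method=method, coverage=count)


def saliency_map(model: MilcModel, record: TimecourseRecord, method: str = "ig",
                 **kwargs) -> SaliencyMap:
    """Convenience: windowed attribution + overlap assembly in one call."""
    if method.lower() == "ig":
        wa = integrated_gradients(model, record, **kwargs)
    elif method.lower() == "sgig":
        wa = smoothgrad_ig(model, record, **kwargs)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return assemble_subject_saliency(
        wa.values, wa.start_indices, record.n_timepoints,
        subject_id=record.subject_id, predicted_class=wa.predicted_class, method=wa.method,
    )


def completeness_gap(model: MilcModel, record: TimecourseRecord,
                     attribution: WindowAttribution,
                     baseline: Optional[np.ndarray] = None) -> dict:
    """|Σ attributions − (F_c(x) − F_c(x₀))| and the reference difference."""
    windows, _ = _windowed_input(model, record)
    if baseline is None:
        baseline = np.zeros_like(windows)
    c = attribution.predicted_class
    fx = float(model.subject_logits(windows)[c])
    f0 = float(model.subject_logits(baseline)[c])
    gap = abs(float(attribution.values.sum()) - (fx - f0))
    return {"gap": gap, "delta": fx - f0, "relative_gap": gap / max(abs(fx - f0), 1e-12)}


# ---------------------------------------------------------------------------
# random baseline and top-fraction selection
# ---------------------------------------------------------------------------

def random_importance(shape: tuple, seed: int = 0) -> ImportanceEstimator:
    """Uniformly random permutation of the C·T cells as an importance order (g^R)."""
    C, T = shape
    perm = np.random.default_rng(seed).permutation(C * T)
    return ImportanceEstimator(tag="g_R", permutation=perm, shape=(C, T), seed=seed)


def select_top_fraction(source, p: float = 0.05) -> RetainMask:
    """Retain the round(p·C·T) most important cells.

    ``source`` is a :class:`SaliencyMap`, a raw (C, T) array (ranked by
    signed value, descending), or an :class:`ImportanceEstimator` (ranked by
    permutation order).  Ties break deterministically by (component, time).
    """
    if not (0 < p <= 1):
        raise ValueError("retain fraction must be in (0, 1]")
    if isinstance(source, ImportanceEstimator):
        C, T = source.shape
        k = int(round(p * C * T))
        flat = np.zeros(C * T, dtype=bool)
        flat[source.permutation[:k]] = True
        return RetainMask(mask=flat.reshape(C, T), retain_fraction=p)
    values = source.values if isinstance(source, SaliencyMap) else np.asarray(source)
    if values.ndim != 2:
        raise ValueError("saliency values must be a (C, T) matrix")
    C, T = values.shape
    k = int(round(p * C * T))
    flat = values.reshape(-1)
    comp = np.repeat(np.arange(C), T)
    time = np.tile(np.arange(T), C)
    order = np.lexsort((time, comp, -flat))  # primary: value desc; then (c, t)
    mask = np.zeros(C * T, dtype=bool)
    mask[order[:k]] = True
    return RetainMask(mask=mask.reshape(C, T), retain_fraction=p)
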