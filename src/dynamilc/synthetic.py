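"""Synthetic cohorts with planted, ground-truth salient structure.

The generator emulates the statistical regime the framework assumes for
ICA time courses: per subject, C latent first-order autoregressive
processes (stationary, unit variance) mixed through a subject-specific
random orthonormal loading plus white observation noise.  Patients
(class 1) receive one or both planted effects:

* ``connectivity_shift`` — a shared latent driver added to a subset of
  components, raising their pairwise correlations by a closed-form
  amount e²/(1 + σ² + e²);
* ``focal_event`` — a transient shared burst on the affected components,
  either concentrated inside a short event window (``spiky`` temporal
  profile) or spread over the whole series at matched total energy
  (``flat``).

Ground truth records the planted cells per subject and the affected
component pairs, serving as the oracle for saliency-localization and
retain-and-retrain validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import TimecourseRecord

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "generate_pretraining_pool"]

AR_COEF = 0.7  # stable autoregressive coefficient of the latent processes


def _default_affected(C: int, k: int = 6) -> tuple:
    return tuple(np.linspace(0, C - 1, k).round().astype(int))


@dataclass
class CohortSpec:
    """Study conditions for one two-class synthetic cohort."""

    n_per_class: int = 50
    n_components: int = 53
    n_timepoints: int = 140
    effect_type: str = "focal_event"  # connectivity_shift | focal_event | both
    affected_components: Optional[Sequence[int]] = None
    event_window: Optional[tuple] = None  # [t_start, t_end), default centered length 20
    effect_size: float = 2.5
    noise_sd: float = 0.5
    temporal_profile: str = "spiky"  # spiky | flat
    seed: int = 0

    def __post_init__(self):
        C, T = self.n_components, self.n_timepoints
        if self.effect_type not in ("connectivity_shift", "focal_event", "both"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.temporal_profile not in ("spiky", "flat"):
            raise ValueError(f"unknown temporal_profile {self.temporal_profile!r}")
        if self.affected_components is None:
            self.affected_components = _default_affected(C)
        self.affected_components = tuple(int(i) for i in self.affected_components)
        if not set(self.affected_components) <= set(range(C)):
            raise ValueError("affected_components outside the component range")
        if self.event_window is None:
            mid = T // 2
            self.event_window = (mid - 10, mid + 10)
        t0, t1 = self.event_window
        if not (0 <= t0 < t1 <= T):
            raise ValueError(f"event_window {self.event_window} outside [0, {T})")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")


@dataclass
class GroundTruth:
    """Planted salient cells per subject and the truly affected pairs."""

    masks: np.ndarray  # (n_subjects, C, T) boolean
    subject_ids: list
    affected_pairs: list  # [(i, j), ...] with i < j
    planted_fraction: float


def _ar1(rng: np.random.Generator, n_series: int, T: int, coef) -> np.ndarray:
    """Stationary AR(1) series, unit marginal variance, shape (n_series, T)."""
    coef = np.broadcast_to(np.asarray(coef, dtype=float), (n_series,))
    innov_sd = np.sqrt(1.0 - coef**2)
    x = np.empty((n_series, T))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, T))
    for t in range(1, T):
        x[:, t] = coef * x[:, t - 1] + innov_sd * eps[:, t]
    return x


def _orthonormal(rng: np.random.Generator, C: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((C, C)))
    return q * np.sign(np.diag(r))  # sign-fixed for a well-defined distribution


def _base_subject(rng, C, T, noise_sd, ar_coef=AR_COEF):
    latents = _ar1(rng, C, T, ar_coef)
    loading = _orthonormal(rng, C)
    return loading @ latents + noise_sd * rng.standard_normal((C, T))


def generate_cohort(spec: CohortSpec):
    """Generate a labeled two-class cohort plus its :class:`GroundTruth`.

    Controls (label 0) are pure base processes; patients (label 1) carry the
    planted effect(s).  With ``effect_size == 0`` the classes are
    exchangeable.  All randomness flows from ``spec.seed`` through
    independent per-subject substreams, so cohorts are bit-reproducible.
    """
    C, T = spec.n_components, spec.n_timepoints
    aff = np.array(spec.affected_components)
    t0, t1 = spec.event_window
    n = 2 * spec.n_per_class
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(n)]

    records, masks, ids = [], np.zeros((n, C, T), dtype=bool), []
    tag = f"synthetic-{spec.effect_type}"
    for j in range(n):
        label = int(j >= spec.n_per_class)
        rng = streams[j]
        data = _base_subject(rng, C, T, spec.noise_sd)
        mask = np.zeros((C, T), dtype=bool)
        if label == 1 and spec.effect_size > 0:
            if spec.effect_type in ("connectivity_shift", "both"):
                driver = _ar1(rng, 1, T, AR_COEF)[0]
                data[aff] += spec.effect_size * driver
                mask[aff, :] = True
            if spec.effect_type in ("focal_event", "both"):
                if spec.temporal_profile == "spiky":
                    burst = _ar1(rng, 1, t1 - t0, AR_COEF)[0]
                    data[aff[:, None], np.arange(t0, t1)] += spec.effect_size * burst
                    mask[aff[:, None], np.arange(t0, t1)] = True
                else:  # flat: same total energy spread over the whole series
                    burst = _ar1(rng, 1, T, AR_COEF)[0]
                    scale = spec.effect_size * np.sqrt((t1 - t0) / T)
                    data[aff] += scale * burst
                    mask[aff, :] = True
        sid = f"sub-{label}{j:04d}"
        ids.append(sid)
        masks[j] = mask
        records.append(TimecourseRecord(sid, data, label=label, cohort_tag=tag))

    pairs = [(int(a), int(b)) for i, a in enumerate(aff) for b in aff[i + 1 :]]
    patient_fraction = masks[spec.n_per_class :].mean()
    truth = GroundTruth(
        masks=masks, subject_ids=ids, affected_pairs=pairs, planted_fraction=float(patient_fraction)
    )
    return records, truth


def generate_pretraining_pool(
    n_subjects: int,
    C: int = 53,
    T: int = 140,
    seed: int = 0,
    noise_sd: float = 0.5,
    transients: bool = True,
) -> list:
    """Unlabeled "healthy pool" with subject-specific dynamics for pretraining.

    Each subject gets its own orthonormal loading and its own spectrum of
    AR(1) coefficients (uniform in [0.5, 0.9] per latent), so windows carry a
    subject-identifying signature and the window→sequence matching task is
    learnable but not trivial.  By default subjects also carry a few benign
    transient co-activation events (short shared bursts on random component
    subsets at random times) emulating spontaneous dynamics; these give the
    encoder exposure to localized amplitude structure without any class
    information.
    """
    if n_subjects < 2:
        raise ValueError("pool needs at least two subjects")
    records = []
    for j, ss in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        coefs = rng.uniform(0.5, 0.9, size=C)
        latents = _ar1(rng, C, T, coefs)
        loading = _orthonormal(rng, C)
        data = loading @ latents + noise_sd * rng.standard_normal((C, T))
        if transients:
            w = min(20, max(4, T // 4))
            for _ in range(int(rng.integers(1, 4))):
                comps = rng.choice(C, size=int(rng.integers(3, min(9, C + 1))), replace=False)
                t0 = int(rng.integers(0, T - w + 1))
                amp = rng.uniform(1.0, 3.0)
                data[comps[:, None], np.arange(t0, t0 + w)] += amp * _ar1(rng, 1, w, AR_COEF)[0]
        records.append(TimecourseRecord(f"pool-{j:04d}", data, label=None, cohort_tag="synthetic-pool"))
    return records
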