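"""Signal conditioning and beat extraction.

Clipping of extreme excursions, max-abs normalization into [-1, 1], R-peak
detection, fixed-window beat segmentation anchored at the R-peak, record
truncation to a fixed sample budget, per-beat augmentation (time shift,
amplitude scale, additive noise) and the stratified train/val/test split.

Conventions: 0-based sample indices; segment windows are half-open
``[r - pre, r + post)`` so every segment has exactly ``pre + post`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synth import BEAT_CLASSES, DatasetBundle, EcgRecord, DEFAULT_PRE, DEFAULT_POST


@dataclass
class BeatSegment:
    """Fixed-length window around one R-peak with its class label."""

    samples: np.ndarray
    label: str
    record_id: str = ""
    r_index: int = 0


@dataclass
class SplitSpec:
    """Train/validation/test proportions (must sum to 1) plus stratification flag."""

    train_frac: float = 0.855
    val_frac: float = 0.095
    test_frac: float = 0.05
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_frac, self.val_frac, self.test_frac)
        if any(f < 0 for f in fr):
            raise ValueError("split fractions must be >= 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fr)!r}")


def clip_extremes(x: np.ndarray, percentile: float = 99.9) -> np.ndarray:
    """Clamp samples whose magnitude exceeds the ``percentile``-th percentile of |x|.

    The percentile is the order statistic at ``floor((n-1)·p/100)`` (the
    "lower" convention) — with interpolation the bound would shrink on every
    application; with an order statistic clamping is a fixed point, so the
    operation is idempotent.  Order and length are preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot clip an empty signal")
    if not 50.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (50, 100], got {percentile}")
    bound = float(np.percentile(np.abs(x), percentile, method="lower"))
    return np.clip(x, -bound, bound)


def normalize(x: np.ndarray) -> np.ndarray:
    """Scale by 1/max|x| so the output lies in [-1, 1] with max|output| == 1."""
    x = np.asarray(x, dtype=float)
    m = float(np.max(np.abs(x))) if x.size else 0.0
    if m == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return x / m


def detect_r_peaks(record: EcgRecord, refractory: float = 0.2,
                   threshold_frac: float = 0.5) -> np.ndarray:
    """Locate R-peaks as local maxima above ``threshold_frac * max(x)``.

    Peaks closer than ``refractory`` seconds keep only the taller one.
    Returns strictly increasing sample indices (possibly empty).
    """
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    x = np.asarray(record.samples, dtype=float)
    if x.size == 0 or np.max(x) <= 0:
        return np.empty(0, dtype=int)
    height = threshold_frac * float(np.max(x))
    distance = max(1, int(round(refractory * record.fs)))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    return peaks.astype(int)


def segment_beats(record: EcgRecord, peaks: "np.ndarray | list[int]",
                  pre: int = DEFAULT_PRE, post: int = DEFAULT_POST,
                  label_tolerance: float = 0.05) -> list[BeatSegment]:
    """Cut one ``[r - pre, r + post)`` window per peak.

    Peaks without full context (closer than ``pre`` to the start or ``post``
    to the end) are dropped.  Labels come from the nearest annotation within
    ``label_tolerance`` seconds; unmatched peaks default to "N".
    """
    if pre <= 0 or post <= 0:
        raise ValueError("pre and post must be positive")
    x = np.asarray(record.samples, dtype=float)
    ann_idx = np.array([i for i, _ in record.annotations], dtype=int)
    ann_lab = [lab for _, lab in record.annotations]
    tol = int(round(label_tolerance * record.fs))

    out: list[BeatSegment] = []
    for r in np.asarray(peaks, dtype=int):
        if r - pre < 0 or r + post > len(x):
            continue
        label = "N"
        if ann_idx.size:
            j = int(np.argmin(np.abs(ann_idx - r)))
            if abs(int(ann_idx[j]) - int(r)) <= tol:
                label = ann_lab[j]
        out.append(BeatSegment(x[r - pre:r + post].copy(), label,
                               record.record_id, int(r)))
    return out


def segments_to_bundle(segments: list[BeatSegment], fs: float) -> DatasetBundle:
    if not segments:
        raise ValueError("no segments to bundle")
    length = len(segments[0].samples)
    return DatasetBundle(
        np.stack([s.samples for s in segments]),
        np.array([s.label for s in segments]),
        length, fs,
    )


def truncate_record(record: EcgRecord, n: int = 3000) -> EcgRecord:
    """Keep the first ``n`` samples; annotations beyond ``n`` are dropped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(record.samples) < n:
        raise ValueError(
            f"record has {len(record.samples)} samples, shorter than n={n}"
        )
    return EcgRecord(
        record.samples[:n].copy(), record.fs,
        [(i, lab) for i, lab in record.annotations if i < n],
        record.record_id,
    )


def augment(samples: np.ndarray, max_shift: int = 3,
            scale_range: tuple[float, float] = (0.9, 1.1),
            noise_sd: float = 0.01, seed: int = 0) -> np.ndarray:
    """Randomly perturb one beat: circular time shift, amplitude scale, noise.

    The shift is uniform on ``[-max_shift, max_shift]``, the scale uniform on
    ``scale_range``; the label (carried outside this function) is unchanged.
    """
    lo, hi = scale_range
    if lo > hi:
        raise ValueError("scale_range must satisfy lo <= hi")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(seed)
    shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    scale = rng.uniform(lo, hi)
    y = np.roll(x, shift) * scale
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return y


def _allocate(n: int, fracs: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items over three fractions."""
    raw = [n * f for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for r, b in zip(raw, base)])
    for j in range(rem):
        base[order[j]] += 1
    return base


def split_dataset(bundle: DatasetBundle, spec: SplitSpec) -> DatasetBundle:
    """Assign each beat to train/val/test; disjoint and exhaustive.

    Stratified mode shuffles and allocates within each class so per-class
    proportions match the fractions to within one item.  Any class with fewer
    items than the number of non-empty splits raises.
    """
    n = len(bundle.labels)
    fracs = (spec.train_frac, spec.val_frac, spec.test_frac)
    names = np.array(["train", "val", "test"])
    n_splits = sum(f > 0 for f in fracs)
    rng = np.random.default_rng(spec.seed)
    assign = np.empty(n, dtype=object)

    groups = ([np.flatnonzero(bundle.labels == c) for c in np.unique(bundle.labels)]
              if spec.stratified else [np.arange(n)])
    for idx in groups:
        if len(idx) < n_splits:
            raise ValueError(
                f"class with {len(idx)} items cannot fill {n_splits} splits"
            )
        idx = rng.permutation(idx)
        counts = _allocate(len(idx), fracs)
        start = 0
        for name, cnt in zip(names, counts):
            assign[idx[start:start + cnt]] = name
            start += cnt

    return DatasetBundle(bundle.segments.copy(), bundle.labels.copy(),
                         bundle.segment_length, bundle.fs,
                         assign.astype(str))
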