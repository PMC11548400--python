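"""Synthetic ECG generation.

Generates single-lead ECG records and labelled beat datasets that mimic the
statistical structure of ambulatory arrhythmia recordings (360 Hz sampling,
beats annotated at the R-peak, five beat classes: normal (N), left and right
bundle branch block (L, R), atrial premature (A) and premature ventricular
contraction (V)).  Each beat is a sum of five Gaussian bumps — one per
P, Q, R, S and T wave — with per-class morphology:

* ``N``: textbook P-QRS-T.
* ``L``/``R``: widened, notched/asymmetric QRS (bundle branch block).
* ``A``: P wave shifted toward the QRS and attenuated (ectopic atrial focus).
* ``V``: absent P, broad high-amplitude QRS with discordant T.

Everything is seeded and bit-reproducible; ground-truth annotations make the
R-peak detector and classifier downstream fully testable without external data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical beat-class order used everywhere in the package.
BEAT_CLASSES: tuple[str, ...] = ("N", "L", "R", "A", "V")

DEFAULT_FS = 360.0


@dataclass
class EcgRecord:
    """A sampled single-lead voltage trace with beat annotations.

    ``annotations`` is a list of ``(sample_index, label)`` pairs with strictly
    increasing indices inside ``[0, len(samples))`` and labels from
    :data:`BEAT_CLASSES`.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    annotations: list[tuple[int, str]] = field(default_factory=list)
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index outside the record")
        for _, lab in self.annotations:
            if lab not in BEAT_CLASSES:
                raise ValueError(f"unknown beat label {lab!r}")


@dataclass
class WaveParams:
    """One Gaussian bump: centre offset from the R-peak (s), width (s), amplitude (mV)."""

    center: float
    width: float
    amplitude: float


@dataclass
class BeatTemplateParams:
    """Morphology of one beat class as five Gaussian bumps (P, Q, R, S, T)."""

    label: str
    waves: dict[str, WaveParams]
    duration: float = 0.7       # s; template spans [-0.3, +0.4] around the R-peak
    r_offset: float = 0.3       # s from template start to the R-peak

    def __post_init__(self) -> None:
        for w in self.waves.values():
            if w.width <= 0:
                raise ValueError("wave widths must be positive")


def _default_templates() -> dict[str, BeatTemplateParams]:
    W = WaveParams
    return {
        "N": BeatTemplateParams("N", {
            "P": W(-0.180, 0.025, 0.15),
            "Q": W(-0.035, 0.012, -0.12),
            "R": W(0.000, 0.018, 1.00),
            "S": W(0.035, 0.014, -0.25),
            "T": W(0.220, 0.055, 0.30),
        }),
        # LBBB: broad notched QRS, discordant (inverted) T.
        "L": BeatTemplateParams("L", {
            "P": W(-0.180, 0.025, 0.12),
            "Q": W(-0.040, 0.015, -0.08),
            "R": W(0.000, 0.045, 0.90),
            "S": W(0.080, 0.028, 0.30),
            "T": W(0.250, 0.060, -0.25),
        }),
        # RBBB: rSR' pattern — slurred wide terminal wave.
        "R": BeatTemplateParams("R", {
            "P": W(-0.180, 0.025, 0.14),
            "Q": W(-0.040, 0.013, -0.10),
            "R": W(0.000, 0.020, 0.85),
            "S": W(0.040, 0.018, -0.45),
            "T": W(0.085, 0.035, 0.50),
        }),
        # Atrial premature: normal (narrow) QRS-T; the ectopic focus shows only
        # in the P wave — shifted toward the QRS and attenuated.
        "A": BeatTemplateParams("A", {
            "P": W(-0.125, 0.022, 0.10),
            "Q": W(-0.035, 0.012, -0.12),
            "R": W(0.000, 0.018, 1.00),
            "S": W(0.035, 0.014, -0.25),
            "T": W(0.220, 0.055, 0.30),
        }),
        # PVC: no P, broad tall QRS, deep wide S, discordant T.
        "V": BeatTemplateParams("V", {
            "P": W(-0.200, 0.020, 0.00),
            "Q": W(-0.060, 0.020, -0.15),
            "R": W(0.000, 0.060, 1.10),
            "S": W(0.110, 0.045, -0.55),
            "T": W(0.280, 0.070, -0.35),
        }),
    }


DEFAULT_TEMPLATES = _default_templates()


def make_beat_template(
    label: str,
    fs: float = DEFAULT_FS,
    params: BeatTemplateParams | None = None,
) -> np.ndarray:
    """Render one beat class as an amplitude vector of ``round(fs * duration)`` samples.

    Deterministic for fixed inputs.  The global maximum of the N/L/R/A
    templates sits at the declared R offset; the V template is recognisably
    broader (longer duration above half of its maximum).
    """
    if params is None:
        if label not in DEFAULT_TEMPLATES:
            raise ValueError(
                f"unknown beat label {label!r}; expected one of {BEAT_CLASSES}"
            )
        params = DEFAULT_TEMPLATES[label]
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    n = int(round(fs * params.duration))
    t = np.arange(n) / fs - params.r_offset
    x = np.zeros(n)
    for w in params.waves.values():
        x += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    return x


def template_r_index(label: str, fs: float = DEFAULT_FS,
                     params: BeatTemplateParams | None = None) -> int:
    """Sample index of the R-peak inside :func:`make_beat_template` output."""
    p = params or DEFAULT_TEMPLATES[label]
    return int(round(p.r_offset * fs))


def synth_record(
    n_beats: int,
    class_mix: "np.ndarray | list[float]" = (1.0, 0.0, 0.0, 0.0, 0.0),
    fs: float = DEFAULT_FS,
    rr_mean: float = 0.8,
    rr_sd: float = 0.05,
    baseline_wander: bool = False,
    wander_amplitude: float = 0.1,
    wander_freq: float = 0.3,
    seed: int = 0,
    record_id: str = "synthetic",
) -> EcgRecord:
    """Simulate a continuous annotated ECG record.

    Beat labels are drawn i.i.d. from ``class_mix`` (ordered as
    :data:`BEAT_CLASSES`); RR intervals are Normal(``rr_mean``, ``rr_sd``)
    truncated below at 0.3 s.  Baseline wander, when enabled, is a
    ``wander_freq`` Hz sinusoid of amplitude ``wander_amplitude`` mV.
    Annotations mark each beat's template R-peak sample exactly.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if rr_mean <= 0:
        raise ValueError("rr_mean must be positive")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (len(BEAT_CLASSES),):
        raise ValueError(f"class_mix must have {len(BEAT_CLASSES)} entries")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {mix.sum()!r}")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(BEAT_CLASSES), size=n_beats, p=mix)
    rr = rng.normal(rr_mean, rr_sd, size=n_beats - 1) if n_beats > 1 else np.empty(0)
    rr = np.maximum(rr, 0.3)

    # R-peak sample positions; leave room for the widest template on each side.
    lead_in = int(round(0.35 * fs))
    r_pos = lead_in + np.concatenate([[0], np.cumsum(np.round(rr * fs))]).astype(int)
    total = int(r_pos[-1] + round(0.45 * fs))

    x = np.zeros(total)
    annotations: list[tuple[int, str]] = []
    for pos, li in zip(r_pos, labels):
        lab = BEAT_CLASSES[li]
        tpl = make_beat_template(lab, fs)
        start = pos - template_r_index(lab, fs)
        lo, hi = max(start, 0), min(start + len(tpl), total)
        x[lo:hi] += tpl[lo - start:hi - start]
        annotations.append((int(pos), lab))

    if baseline_wander:
        t = np.arange(total) / fs
        phase = rng.uniform(0, 2 * np.pi)
        x += wander_amplitude * np.sin(2 * np.pi * wander_freq * t + phase)

    return EcgRecord(x, fs=fs, annotations=annotations, record_id=record_id)


@dataclass
class DatasetBundle:
    """Fixed-length labelled beat segments with optional train/val/test assignment."""

    segments: np.ndarray                 # (n, segment_length)
    labels: np.ndarray                   # (n,) strings from BEAT_CLASSES
    segment_length: int
    fs: float = DEFAULT_FS
    split: np.ndarray | None = None      # (n,) in {"train","val","test"} or None

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.segments.ndim != 2 or self.segments.shape[1] != self.segment_length:
            raise ValueError("all segments must share segment_length")
        if len(self.labels) != len(self.segments):
            raise ValueError("labels must parallel segments")

    def subset(self, which: str) -> "DatasetBundle":
        if self.split is None:
            raise ValueError("bundle has no split assignment")
        m = self.split == which
        return DatasetBundle(self.segments[m], self.labels[m],
                             self.segment_length, self.fs,
                             np.full(int(m.sum()), which))

    def with_segments(self, segments: np.ndarray) -> "DatasetBundle":
        """Same labels/split, new sample matrix (e.g. after noise or denoising)."""
        return DatasetBundle(np.asarray(segments, dtype=float), self.labels.copy(),
                             self.segment_length, self.fs,
                             None if self.split is None else self.split.copy())


# window conventions shared with the preprocess module
DEFAULT_PRE = 90     # samples kept before the R-peak (0.25 s at 360 Hz)
DEFAULT_POST = 144   # samples kept from the R-peak on (0.40 s at 360 Hz)

_QRS_SUPPORT_S = 0.12  # minimum window that still contains a QRS complex


def _jitter_params(p: BeatTemplateParams, rng: np.random.Generator,
                   amp_jitter: float, width_jitter: float,
                   center_jitter: float) -> BeatTemplateParams:
    """Per-beat morphological variability: scale each wave's amplitude and
    width by a uniform factor and nudge its centre (Gaussian, seconds)."""
    waves = {}
    for name, w in p.waves.items():
        waves[name] = WaveParams(
            w.center + rng.normal(0.0, center_jitter),
            w.width * rng.uniform(1 - width_jitter, 1 + width_jitter),
            w.amplitude * rng.uniform(1 - amp_jitter, 1 + amp_jitter),
        )
    return BeatTemplateParams(p.label, waves, p.duration, p.r_offset)


def make_dataset(
    n_per_class: "dict[str, int] | list[int] | tuple[int, ...]",
    segment_length: int = DEFAULT_PRE + DEFAULT_POST,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    noise_sd: float = 0.03,
    max_shift: int = 6,
    amp_jitter: float = 0.50,
    width_jitter: float = 0.30,
    center_jitter: float = 0.02,
) -> DatasetBundle:
    """Build a stratified labelled beat dataset.

    Each beat is rendered from its class template with per-beat morphological
    jitter (every wave's amplitude, width and centre perturbed — real beats of
    one class are never identical), cropped to ``segment_length`` samples
    around the R-peak, then perturbed by a small random circular shift,
    amplitude scale and additive Gaussian noise.  Counts per class are exact;
    order is shuffled; everything is seeded.
    """
    if isinstance(n_per_class, dict):
        counts = [int(n_per_class.get(c, 0)) for c in BEAT_CLASSES]
    else:
        counts = [int(c) for c in n_per_class]
    if len(counts) != len(BEAT_CLASSES) or any(c < 1 for c in counts):
        raise ValueError("need a count >= 1 for each of the five classes")
    if segment_length < int(round(_QRS_SUPPORT_S * fs)):
        raise ValueError(
            f"segment_length {segment_length} shorter than QRS support "
            f"({int(round(_QRS_SUPPORT_S * fs))} samples at {fs} Hz)"
        )

    rng = np.random.default_rng(seed)
    # crop window around the R-peak, biased like the pre/post convention
    pre = int(round(segment_length * DEFAULT_PRE / (DEFAULT_PRE + DEFAULT_POST)))
    post = segment_length - pre

    segs, labs = [], []
    for lab, cnt in zip(BEAT_CLASSES, counts):
        base_params = DEFAULT_TEMPLATES[lab]
        r = template_r_index(lab, fs)
        lo, hi = r - pre, r + post
        for _ in range(cnt):
            p = _jitter_params(base_params, rng, amp_jitter, width_jitter,
                               center_jitter)
            tpl = make_beat_template(lab, fs, p)
            base = np.zeros(segment_length)
            src_lo, src_hi = max(lo, 0), min(hi, len(tpl))
            base[src_lo - lo:src_hi - lo] = tpl[src_lo:src_hi]
            shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
            scale = rng.uniform(*scale_range)
            s = np.roll(base, shift) * scale
            if noise_sd > 0:
                s = s + rng.normal(0.0, noise_sd, size=segment_length)
            segs.append(s)
            labs.append(lab)

    order = rng.permutation(len(segs))
    return DatasetBundle(np.asarray(segs)[order], np.asarray(labs)[order],
                         segment_length, fs)


# ---------------------------------------------------------------------------
# plain-text writers (Kaggle-style per-beat CSV; record CSV + JSON sidecar)

def write_beats_csv(bundle: DatasetBundle, path: "str | Path") -> None:
    """Write one beat per row: ``label,s0,s1,...``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label"] + [f"s{i}" for i in range(bundle.segment_length)])
        for lab, seg in zip(bundle.labels, bundle.segments):
            w.writerow([lab] + [repr(float(v)) for v in seg])


def read_beats_csv(path: "str | Path", fs: float = DEFAULT_FS) -> DatasetBundle:
    """Read the per-beat CSV layout written by :func:`write_beats_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    labels = df.iloc[:, 0].astype(str).to_numpy()
    segments = df.iloc[:, 1:].to_numpy(dtype=float)
    return DatasetBundle(segments, labels, segments.shape[1], fs)


def write_record(record: EcgRecord, path: "str | Path") -> None:
    """Write ``index,amplitude_mV`` CSV plus a ``.annotations.json`` sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "amplitude_mV"])
        for i, v in enumerate(record.samples):
            w.writerow([i, repr(float(v))])
    side = path.with_suffix(path.suffix + ".annotations.json")
    side.write_text(json.dumps({
        "record_id": record.record_id,
        "fs": record.fs,
        "annotations": [[int(i), lab] for i, lab in record.annotations],
    }, indent=1))


def read_record(path: "str | Path") -> EcgRecord:
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    side = path.with_suffix(path.suffix + ".annotations.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return EcgRecord(
        df["amplitude_mV"].to_numpy(dtype=float),
        fs=float(meta.get("fs", DEFAULT_FS)),
        annotations=[(int(i), lab) for i, lab in meta.get("annotations", [])],
        record_id=str(meta.get("record_id", path.stem)),
    )
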