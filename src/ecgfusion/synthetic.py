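"""Synthetic annotated single-lead ECG with AAMI-class morphology.

Every beat is a sum of Gaussian bumps — one each for the P, Q, R, S and
T waves — with class-specific centers, widths and amplitudes:

* **NB** (normal): reference PQRST morphology, narrow QRS.
* **SVEB** (supraventricular ectopic): normal-shaped QRS with a flattened,
  early P wave, placed after a shortened preceding RR interval.
* **VEB** (ventricular ectopic): wide, high-amplitude QRS, no P wave,
  discordant (inverted) T.
* **FB** (fusion): convex combination of the NB and VEB templates.

Records are beat trains at jittered RR intervals plus sub-0.5 Hz
sinusoidal baseline drift and white noise, annotated with the true
R-peak positions and symbols (N/A/V/F).  Default class proportions
follow the heavily skewed mix of ambulatory arrhythmia data (~89.5%
normal, 2.7% supraventricular, 7% ventricular, 0.8% fusion).  The
generator is deliberately simple — deterministic given a seed, separable
by construction — so that pipeline and model tests measure the pipeline,
not the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cwt import compute_cwt_batch, make_scales, scalogram_array
from .preprocess import (
    EcgRecord,
    SegmentationConfig,
    remove_baseline,
    segment_heartbeats,
)
from .train_eval import AAMI_CLASSES, Dataset

__all__ = [
    "SyntheticConfig",
    "generate_beat",
    "generate_record",
    "generate_dataset",
    "CLASS_SYMBOLS",
]

#: annotation symbol written for each generated class
CLASS_SYMBOLS = {"NB": "N", "SVEB": "A", "VEB": "V", "FB": "F"}

# (center s from R, amplitude mV, width s) per wave, per class template
_NB_BUMPS = (
    (-0.16, 0.12, 0.020),   # P
    (-0.030, -0.15, 0.008),  # Q
    (0.0, 1.00, 0.010),      # R
    (0.030, -0.20, 0.008),   # S
    (0.25, 0.30, 0.040),     # T
)
_VEB_BUMPS = (
    (-0.035, -0.25, 0.020),  # deep leading deflection
    (0.0, 1.40, 0.030),      # wide, tall R
    (0.055, -0.45, 0.030),   # wide S
    (0.28, -0.35, 0.050),    # discordant T
)
_SVEB_BUMPS = (
    (-0.12, 0.04, 0.015),    # early, flattened P
    (-0.030, -0.15, 0.008),
    (0.0, 0.95, 0.010),
    (0.030, -0.20, 0.008),
    (0.24, 0.25, 0.035),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation conditions for a synthetic record."""

    fs: float = 360.0
    n_beats: int = 500
    class_proportions: tuple[float, float, float, float] = (
        0.895, 0.027, 0.070, 0.008
    )
    heart_rate: float = 75.0       # bpm
    rr_jitter: float = 0.05        # sd as a fraction of the RR interval
    baseline_amp: float = 0.15     # mV
    baseline_freq: float = 0.3     # Hz, respiratory-band drift
    noise_sd: float = 0.03         # mV
    amplitude_jitter: float = 0.05  # per-beat morphology variation
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class proportions must be non-negative")
        if self.baseline_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.baseline_freq >= 0.5:
            raise ValueError("baseline drift must stay below 0.5 Hz")
        if self.fs <= 0 or self.heart_rate <= 0:
            raise ValueError("fs and heart_rate must be positive")


def _bumps(t: np.ndarray, spec, gain: float = 1.0,
           jitter: np.ndarray | None = None) -> np.ndarray:
    out = np.zeros_like(t)
    for k, (center, amp, width) in enumerate(spec):
        a = amp * gain * (1.0 if jitter is None else jitter[k])
        out += a * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _template(aami_class: str, t: np.ndarray,
              jitter: np.ndarray | None = None) -> np.ndarray:
    if aami_class == "NB":
        return _bumps(t, _NB_BUMPS, jitter=jitter)
    if aami_class == "SVEB":
        return _bumps(t, _SVEB_BUMPS, jitter=jitter)
    if aami_class == "VEB":
        return _bumps(t, _VEB_BUMPS, jitter=jitter)
    if aami_class == "FB":
        j1 = jitter[: len(_NB_BUMPS)] if jitter is not None else None
        j2 = jitter[len(_NB_BUMPS) :] if jitter is not None else None
        return 0.5 * _bumps(t, _NB_BUMPS, jitter=j1) + 0.5 * _bumps(
            t, _VEB_BUMPS, jitter=j2
        )
    raise ValueError(f"unknown AAMI class {aami_class!r}")


def generate_beat(aami_class: str, fs: float = 360.0,
                  rng: np.random.Generator | None = None,
                  amplitude_jitter: float = 0.05):
    """One beat waveform and the sample offset of its R-peak.

    The waveform spans 0.3 s before to 0.45 s after the nominal R
    position; the returned offset is the argmax of the waveform, which
    by construction coincides with the R bump.  Deterministic given the
    generator state.
    """
    if aami_class not in AAMI_CLASSES:
        raise ValueError(
            f"unknown AAMI class {aami_class!r}; expected one of {AAMI_CLASSES}"
        )
    t = np.arange(int(round(-0.3 * fs)), int(round(0.45 * fs)) + 1) / fs
    jitter = None
    if rng is not None:
        n_bumps = len(_NB_BUMPS) + len(_VEB_BUMPS)  # enough for every class
        jitter = 1.0 + amplitude_jitter * rng.standard_normal(n_bumps)
    samples = _template(aami_class, t, jitter=jitter)
    return samples, int(np.argmax(samples))


def generate_record(cfg: SyntheticConfig | None = None) -> EcgRecord:
    """A full annotated record: beat train + drift + noise.

    Beat classes are drawn from the configured proportions; RR intervals
    jitter around the configured heart rate, with supraventricular
    ectopics arriving early (shortened preceding interval).  Overlapping
    templates are summed.  Annotations carry the true class symbols.
    """
    cfg = cfg or SyntheticConfig()
    if cfg.n_beats < 4:
        raise ValueError("need at least 4 beats")
    rng = np.random.default_rng(cfg.seed)
    classes = rng.choice(len(AAMI_CLASSES), size=cfg.n_beats,
                         p=cfg.class_proportions)
    rr = 60.0 / cfg.heart_rate
    intervals = rr * (1.0 + cfg.rr_jitter * rng.standard_normal(cfg.n_beats))
    intervals[classes == 1] *= 0.7  # SVEB: premature arrival
    intervals = np.clip(intervals, 0.35, None)
    r_times = 0.5 + np.cumsum(intervals)  # lead-in so the first beat fits

    n_total = int(np.ceil((r_times[-1] + 0.8) * cfg.fs))
    signal = np.zeros(n_total)
    annotations: list[tuple[int, str]] = []
    for cls_idx, r_time in zip(classes, r_times):
        name = AAMI_CLASSES[cls_idx]
        beat, peak_off = generate_beat(name, cfg.fs, rng,
                                       amplitude_jitter=cfg.amplitude_jitter)
        r_idx = int(round(r_time * cfg.fs))
        start = r_idx - peak_off
        stop = start + beat.size
        if start < 0 or stop > n_total:
            continue
        signal[start:stop] += beat
        annotations.append((r_idx, CLASS_SYMBOLS[name]))

    t = np.arange(n_total) / cfg.fs
    if cfg.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + cfg.baseline_amp * np.sin(
            2 * np.pi * cfg.baseline_freq * t + phase
        )
    if cfg.noise_sd > 0:
        signal = signal + cfg.noise_sd * rng.standard_normal(n_total)

    annotations.sort(key=lambda a: a[0])
    return EcgRecord(
        record_id=f"synthetic-{cfg.seed}", samples=signal, fs=cfg.fs,
        lead="MLII", annotations=annotations,
    )


def generate_dataset(
    cfg: SyntheticConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    wavelet: str = "gaus8",
    n_scales: int = 100,
    scale_lo: float = 2.16,
    scale_hi: float = 216.0,
    image_shape: tuple[int, int] = (100, 100),
) -> Dataset:
    """Run the full preprocess + CWT pipeline on a generated record."""
    cfg = cfg or SyntheticConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    record = generate_record(cfg)
    denoised = remove_baseline(record)
    result = segment_heartbeats(denoised, seg_cfg)
    symbol_to_idx = {sym: i for i, (cls, sym) in enumerate(
        (c, CLASS_SYMBOLS[c]) for c in AAMI_CLASSES)}
    beats = np.stack([seg.samples for seg in result.segments])
    labels = np.array([symbol_to_idx[seg.label] for seg in result.segments])
    grid = make_scales(n_scales, scale_lo, scale_hi)
    coeffs = compute_cwt_batch(beats, grid, wavelet, cfg.fs)
    scalograms = np.stack([
        scalogram_array(np.abs(c), image_shape) for c in coeffs
    ])
    return Dataset(beats=beats, scalograms=scalograms, labels=labels,
                   class_names=AAMI_CLASSES)
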