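"""Synthetic labeled IMU recordings and cohort fixtures.

Lower-back gait acceleration is quasi-periodic, so each activity is
emulated as a sum of up to three harmonics of a class-specific
fundamental (step-cycle) frequency plus white Gaussian noise and a
constant gravity-like baseline; quiet standing has no oscillatory
component.  Cohort generators reproduce the per-class window counts of
small clinical datasets (healthy, Parkinson's, stroke cohorts) so the
whole pipeline is exercisable without any external download.

The signal family is deliberately minimal: it captures the features the
pipeline actually consumes (class-dependent spectral structure, noise,
amplitude differences between accelerometer and gyroscope channels) and
nothing else.  A spectral nearest-peak classifier is included as an
independent check that noise-free cohorts are separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import periodogram

from .imu_io import IMU_CHANNELS, ImuRecording
from .preprocess import Window, normalize, segment

__all__ = [
    "ActivityProfile",
    "CohortSpec",
    "COHORT_COUNTS",
    "DEFAULT_NOISE_SD",
    "DEFAULT_ORIENTATION_SD",
    "classify_by_nearest_peak",
    "default_profiles",
    "dominant_frequency",
    "generate_cohort",
    "generate_recording",
]

#: per-class window counts of the three small clinical cohorts
#: (healthy subjects, Parkinson's disease, stroke survivors)
COHORT_COUNTS: dict[str, dict[str, int]] = {
    "HS": {"walking": 50, "ascent": 50, "descent": 49, "standing": 50},
    "PD": {"walking": 81, "ascent": 64, "descent": 60, "standing": 75},
    "SS": {"walking": 49, "ascent": 18, "descent": 31, "standing": 75},
}

#: default noise, in units of the walking fundamental's amplitude; the
#: residual non-periodic component of impaired gait is of the same order
#: as the periodic component, which is what limited clinical cohorts see
DEFAULT_NOISE_SD = 1.0
#: default sd (degrees) of the per-recording sensor-tilt rotation,
#: emulating device placement/orientation variability between recordings
DEFAULT_ORIENTATION_SD = 10.0


@dataclass(frozen=True)
class ActivityProfile:
    """Spectral recipe for one activity class.

    ``harmonic_amps`` has one row per channel and one column per
    harmonic (k = 1..3 multiples of ``fundamental_freq``);
    ``noise_sd`` and ``baseline`` are per-channel.  Standing is the
    degenerate case ``fundamental_freq = 0`` with zero amplitudes.
    """

    name: str
    fundamental_freq: float
    harmonic_amps: np.ndarray
    noise_sd: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        amps = np.atleast_2d(np.asarray(self.harmonic_amps, dtype=float))
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        base = np.atleast_1d(np.asarray(self.baseline, dtype=float))
        if noise.shape[0] == 1:
            noise = np.full(amps.shape[0], noise[0])
        if base.shape[0] == 1:
            base = np.full(amps.shape[0], base[0])
        if not (amps.shape[0] == noise.shape[0] == base.shape[0]):
            raise ValueError("per-channel fields disagree on channel count")
        if (noise < 0).any():
            raise ValueError("noise_sd must be >= 0")
        if self.fundamental_freq < 0:
            raise ValueError("fundamental_freq must be >= 0")
        if self.fundamental_freq == 0 and np.any(amps != 0):
            raise ValueError("a zero-frequency (static) profile must have zero amplitudes")
        object.__setattr__(self, "harmonic_amps", amps)
        object.__setattr__(self, "noise_sd", noise)
        object.__setattr__(self, "baseline", base)

    @property
    def n_channels(self) -> int:
        return self.harmonic_amps.shape[0]


def _amps(per_channel: Sequence[tuple[float, float, float]]) -> np.ndarray:
    return np.asarray(per_channel, dtype=float)


def default_profiles(
    n_channels: int = 6, noise_sd: float = DEFAULT_NOISE_SD
) -> dict[str, ActivityProfile]:
    """Profiles for walking / stair ascent / stair descent / standing.

    Fundamentals (step-cycle rates): walking 1.8 Hz, ascent 1.4 Hz,
    descent 1.6 Hz, standing 0 Hz — distinct so classes are spectrally
    separable.  Gyroscope channels get relatively larger amplitudes in
    the stair classes, reflecting that rotational activities express
    themselves mainly in angular velocity.  The vertical accelerometer
    axis carries a gravity-like baseline.
    """
    if n_channels not in (3, 6):
        raise ValueError("profiles support 3 or 6 channels")
    # rows: ax, ay, az, wx, wy, wz; columns: harmonics 1..3
    recipes: dict[str, tuple[float, list[tuple[float, float, float]]]] = {
        "walking": (
            1.8,
            [(1.0, 0.40, 0.15), (0.70, 0.25, 0.10), (0.90, 0.35, 0.12),
             (0.30, 0.10, 0.04), (0.25, 0.08, 0.03), (0.35, 0.12, 0.05)],
        ),
        "ascent": (
            1.4,
            [(0.70, 0.30, 0.12), (0.55, 0.20, 0.08), (0.75, 0.30, 0.10),
             (0.85, 0.35, 0.12), (0.80, 0.30, 0.10), (0.90, 0.40, 0.15)],
        ),
        "descent": (
            1.6,
            [(0.80, 0.30, 0.12), (0.60, 0.22, 0.09), (0.85, 0.32, 0.11),
             (0.75, 0.30, 0.10), (0.70, 0.28, 0.09), (0.80, 0.35, 0.12)],
        ),
        "standing": (0.0, [(0.0, 0.0, 0.0)] * 6),
    }
    baseline = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])  # gravity on az
    out = {}
    for name, (freq, rows) in recipes.items():
        out[name] = ActivityProfile(
            name=name,
            fundamental_freq=freq,
            harmonic_amps=_amps(rows[:n_channels]),
            noise_sd=np.full(n_channels, noise_sd),
            baseline=baseline[:n_channels],
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Per-class window-count targets plus sampling configuration."""

    counts: Mapping[str, int]
    sample_rate: float = 100.0
    window_len: int = 250
    seed: int = 0
    cohort: str = "other"
    orientation_sd: float = DEFAULT_ORIENTATION_SD

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("window counts must be >= 0")
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @classmethod
    def preset(cls, cohort: str, seed: int = 0, **kwargs) -> "CohortSpec":
        """Spec with the per-class counts of a named clinical cohort."""
        if cohort not in COHORT_COUNTS:
            raise KeyError(f"unknown cohort {cohort!r}; presets are {sorted(COHORT_COUNTS)}")
        return cls(counts=dict(COHORT_COUNTS[cohort]), seed=seed, cohort=cohort, **kwargs)


def _tilt_matrix(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Small random 3-D rotation: random axis, N(0, sd) angle (Rodrigues)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def generate_recording(
    profile: ActivityProfile,
    duration: float,
    sample_rate: float,
    seed: int | np.random.Generator = 0,
    orientation_sd: float = DEFAULT_ORIENTATION_SD,
    subject_id: str = "synthetic",
    cohort: str = "other",
) -> ImuRecording:
    """Generate ``round(duration * sample_rate)`` labeled samples.

    Each channel c is ``baseline_c + sum_k amp_{c,k} sin(2 pi k f t +
    k (phi + delta_c)) + noise``; the stride phase ``phi`` is drawn once
    per recording so repeated calls with different seeds give different
    gait phases, while an identical seed reproduces the signal exactly.

    When ``orientation_sd > 0`` a random per-recording sensor tilt — a
    small 3-D rotation applied to the accelerometer triad (and the
    gyroscope triad, when present) — emulates device placement and
    orientation variability between recordings/subjects.  This is the
    kind of between-recording position variation that image position
    augmentation is meant to compensate; it survives per-channel
    min-max normalization (which removes plain gain/offset changes).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if orientation_sd < 0:
        raise ValueError("orientation_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    n_ch = profile.n_channels
    phi = rng.uniform(0.0, 2.0 * np.pi)
    data = np.empty((n_ch, n), dtype=float)
    for c in range(n_ch):
        delta = 0.9 * c  # fixed per-channel phase offset
        signal = np.full(n, profile.baseline[c])
        for k in range(profile.harmonic_amps.shape[1]):
            amp = profile.harmonic_amps[c, k]
            if amp != 0.0 and profile.fundamental_freq > 0.0:
                signal = signal + amp * np.sin(
                    2.0 * np.pi * (k + 1) * profile.fundamental_freq * t
                    + (k + 1) * (phi + delta)
                )
        if profile.noise_sd[c] > 0:
            signal = signal + rng.normal(0.0, profile.noise_sd[c], size=n)
        data[c] = signal
    if orientation_sd > 0:
        rot = _tilt_matrix(rng, orientation_sd)
        data[:3] = rot @ data[:3]
        if n_ch == 6:
            data[3:] = rot @ data[3:]
    channels = IMU_CHANNELS[:n_ch] if n_ch in (3, 6) else IMU_CHANNELS
    return ImuRecording(
        sample_rate=sample_rate,
        channels=channels,
        data=data,
        labels=np.full(n, profile.name, dtype=object),
        subject_id=subject_id,
        cohort=cohort,
    )


def generate_cohort(
    spec: CohortSpec,
    profiles: Mapping[str, ActivityProfile],
    seed: int | None = None,
) -> list[Window]:
    """Exactly the requested number of normalized windows per class.

    Each window comes from a freshly generated single-activity
    recording of ``window_len`` samples, normalized per recording and
    segmented; the per-window random stream is derived from
    ``(seed, class index, window index)`` so output is independent of
    generation order and fully reproducible.
    """
    base_seed = spec.seed if seed is None else seed
    missing = [name for name in spec.counts if name not in profiles]
    if missing:
        raise ValueError(f"no profile for class(es) {missing}")
    windows: list[Window] = []
    duration = spec.window_len / spec.sample_rate
    for class_idx, (name, count) in enumerate(spec.counts.items()):
        profile = profiles[name]
        for j in range(count):
            rng = np.random.default_rng([base_seed, class_idx, j])
            rec = generate_recording(
                profile,
                duration=duration,
                sample_rate=spec.sample_rate,
                seed=rng,
                orientation_sd=spec.orientation_sd,
                subject_id=f"{spec.cohort}:{name}:{j}",
                cohort=spec.cohort,
            )
            rec_norm, _ = normalize(rec)
            segs = segment(rec_norm, spec.window_len, overlap_fraction=0.0)
            windows.extend(segs)
    return windows


# -- spectral oracle -----------------------------------------------------------


def dominant_frequency(
    values: np.ndarray, sample_rate: float, nfft: int = 8192
) -> float:
    """Frequency (Hz) of the strongest non-DC spectral peak of a 1-D
    signal, via a zero-padded periodogram; 0.0 for a (near-)constant
    signal."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) < 1e-9:
        return 0.0
    freqs, power = periodogram(values, fs=sample_rate, nfft=max(nfft, values.size), detrend="constant")
    return float(freqs[int(np.argmax(power))])


def classify_by_nearest_peak(
    windows: Sequence[Window],
    profiles: Mapping[str, ActivityProfile],
    sample_rate: float,
    channel: int = 0,
) -> list[str]:
    """Assign each window to the profile whose fundamental frequency is
    nearest to the window's dominant spectral peak.

    This is a deliberately simple frequency-domain classifier used as an
    independent separability check on noise-free cohorts; it is not part
    of the recognition pipeline.
    """
    fundamentals = {name: p.fundamental_freq for name, p in profiles.items()}
    out = []
    for w in windows:
        f_hat = dominant_frequency(w.values[channel], sample_rate)
        out.append(min(fundamentals, key=lambda name: abs(fundamentals[name] - f_hat)))
    return out
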