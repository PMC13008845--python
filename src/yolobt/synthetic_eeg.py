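"""Synthetic multichannel ERP screen generator with calibrated artifacts.

Generates 10-trial "screens" of ERP-like EEG: a 1/f (pink) noise background
plus a 10 Hz alpha component and a time-locked P300-like positive deflection
at 300 ms on every trial. Artifacts of four kinds (broadband noise bursts,
eye-movement deflections, EMG bursts, movement steps) are injected additively
with amplitudes calibrated so a trial's maximum peak-to-peak amplitude (Max
PTP) lands in a requested severity band:

* severe:   Max PTP > 3000 uV
* moderate: 500 uV < Max PTP <= 3000 uV
* clean:    Max PTP <= 500 uV

Ground-truth "bad" labels follow a context-adaptive rule: a trial is bad iff
its Max PTP exceeds ``max(absolute_floor, k * median clean-trial Max PTP of
the same screen)`` — so an identical artifact is labeled bad on a clean
screen and tolerated on a noisy one. The rule (floor 500 uV, k = 3) is a
convention of this package, standing in for expert annotations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "GenConfig", "ArtifactSpec", "SeverityBands", "EEGScreen",
    "ARTIFACT_KINDS", "ConfigurationError", "CalibrationError", "StatsError",
    "generate_background", "inject_artifact", "calibrate_severity",
    "compute_trial_stats", "make_screen_dataset", "adaptive_labels",
    "save_screens", "load_screens",
]

ARTIFACT_KINDS = ("signal_noise", "eye_movement", "emg", "movement")

#: Multiplier on noise_gain at quality_level = 0 (clean screens use 1.0).
_QUALITY_NOISE_SPAN = 6.0
#: Fraction of the noise scale given to the 10 Hz alpha component.
_ALPHA_FRACTION = 0.6

FORMAT_VERSION = 1


class ConfigurationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


class StatsError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenConfig:
    n_channels: int = 64
    sfreq: float = 250.0
    trial_len: float = 1.0
    trials_per_screen: int = 10
    quality_level: float = 1.0
    erp_amplitude: float = 10.0
    noise_gain: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.sfreq <= 0 or self.trial_len <= 0:
            raise ConfigurationError("sfreq and trial_len must be positive")
        if self.trials_per_screen != 10:
            raise ConfigurationError("trials_per_screen is fixed to 10")
        if not 0.0 <= self.quality_level <= 1.0:
            raise ConfigurationError("quality_level must lie in [0, 1]")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.sfreq * self.trial_len))


@dataclass(frozen=True)
class ArtifactSpec:
    kind: str
    channels: tuple[int, ...]
    onset: float
    duration: float
    amplitude: float  # artifact's own peak-to-peak amplitude, uV

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ConfigurationError(f"unknown artifact kind {self.kind!r}")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")


@dataclass(frozen=True)
class SeverityBands:
    moderate_low: float = 500.0
    severe_low: float = 3000.0

    def __post_init__(self):
        if not 0 < self.moderate_low < self.severe_low:
            raise ConfigurationError("need 0 < moderate_low < severe_low")


@dataclass
class EEGScreen:
    data: np.ndarray                    # (channels, trials, samples) uV
    bad_channel_mask: np.ndarray        # (channels,) bool
    trial_labels: np.ndarray            # (trials,) bool, True = bad
    injected: list = field(default_factory=list)   # (trial, ArtifactSpec)
    trial_stats: np.ndarray | None = None          # (trials, 2): max_ptp, max_std
    config: GenConfig | None = None
    quality_level: float | None = None

    def copy(self) -> "EEGScreen":
        return EEGScreen(
            data=self.data.copy(),
            bad_channel_mask=self.bad_channel_mask.copy(),
            trial_labels=self.trial_labels.copy(),
            injected=list(self.injected),
            trial_stats=None if self.trial_stats is None else self.trial_stats.copy(),
            config=self.config, quality_level=self.quality_level)


# ---------------------------------------------------------------------------
# Background generation
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int) -> np.ndarray:
    """1/f-shaped noise with unit standard deviation along the last axis."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0  # remove DC
    shaped = np.fft.irfft(spec * weights, n=n_samples, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std


def erp_template(config: GenConfig) -> np.ndarray:
    """P300-like positive deflection peaking at 300 ms (length n_samples)."""
    t = np.arange(config.n_samples) / config.sfreq
    return config.erp_amplitude * np.exp(-0.5 * ((t - 0.3) / 0.06) ** 2)


def noise_scale(config: GenConfig) -> float:
    """Effective noise standard deviation in uV for a quality level."""
    return config.noise_gain * (
        1.0 + _QUALITY_NOISE_SPAN * (1.0 - config.quality_level))


def generate_background(config: GenConfig) -> EEGScreen:
    """Artifact-free screen: pink noise + alpha + ERP template on each trial."""
    rng = np.random.default_rng(config.seed)
    nch, ntr, ns = config.n_channels, config.trials_per_screen, config.n_samples
    sigma = noise_scale(config)
    data = sigma * _pink_noise(rng, (nch, ntr), ns)
    # 10 Hz alpha with random per-(channel, trial) phase
    t = np.arange(ns) / config.sfreq
    phase = rng.uniform(0, 2 * np.pi, size=(nch, ntr, 1))
    data += (_ALPHA_FRACTION * sigma) * np.sin(2 * np.pi * 10.0 * t + phase)
    data += erp_template(config)
    screen = EEGScreen(
        data=data,
        bad_channel_mask=np.zeros(nch, dtype=bool),
        trial_labels=np.zeros(ntr, dtype=bool),
        config=config, quality_level=config.quality_level)
    screen.trial_stats = compute_trial_stats(screen)
    return screen


# ---------------------------------------------------------------------------
# Artifact waveforms
# ---------------------------------------------------------------------------


def _artifact_waveform(kind: str, n: int, sfreq: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-PTP artifact segment of length n samples."""
    t = np.arange(n) / sfreq
    if kind == "signal_noise":
        w = rng.standard_normal(n) * np.hanning(n)
    elif kind == "eye_movement":
        w = np.sin(np.pi * np.arange(n) / max(n - 1, 1))  # half-wave deflection
    elif kind == "emg":
        w = rng.standard_normal(n)
        if n > 18:  # band-limit to 20-100 Hz where the segment allows it
            nyq = sfreq / 2
            hi = min(100.0, 0.95 * nyq)
            sos = sps.butter(4, [20.0 / nyq, hi / nyq], btype="band", output="sos")
            w = sps.sosfiltfilt(sos, w)
        w = w * np.hanning(n)
    elif kind == "movement":
        w = np.where(t >= 0, 1.0, 0.0) + 0.5 * (t / t[-1] if n > 1 else 0.0)
    else:  # pragma: no cover - guarded by ArtifactSpec
        raise ConfigurationError(f"unknown artifact kind {kind!r}")
    # normalize so the trial-wide excursion is 1: the zero baseline outside the
    # artifact window counts toward the trial's peak-to-peak amplitude
    ptp = max(w.max(), 0.0) - min(w.min(), 0.0)
    if ptp == 0:
        raise CalibrationError(f"degenerate {kind} artifact of length {n}")
    return w / ptp


def inject_artifact(screen: EEGScreen, trial: int, spec: ArtifactSpec,
                    rng: np.random.Generator | None = None) -> EEGScreen:
    """Additive artifact on one trial; returns a new screen (input untouched)."""
    config = screen.config
    if config is None:
        raise ConfigurationError("screen has no generation config attached")
    if not 0 <= trial < config.trials_per_screen:
        raise IndexError(f"trial index {trial} out of range")
    for ch in spec.channels:
        if not 0 <= ch < config.n_channels:
            raise IndexError(f"channel index {ch} out of range")
    if spec.onset < 0 or spec.onset + spec.duration > config.trial_len + 1e-9:
        raise ConfigurationError("artifact window exceeds trial bounds")
    out = screen.copy()
    if spec.amplitude > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed + 7919 * (trial + 1))
        i0 = int(round(spec.onset * config.sfreq))
        n = max(int(round(spec.duration * config.sfreq)), 2)
        n = min(n, config.n_samples - i0)
        wave = spec.amplitude * _artifact_waveform(spec.kind, n, config.sfreq, rng)
        out.data[list(spec.channels), trial, i0:i0 + n] += wave
    out.injected.append((trial, spec))
    out.trial_stats = compute_trial_stats(out)
    return out


def compute_trial_stats(screen: EEGScreen) -> np.ndarray:
    """Per-trial (max_ptp, max_std) over channels not flagged bad."""
    good = ~np.asarray(screen.bad_channel_mask, dtype=bool)
    if not good.any():
        raise StatsError("all channels are flagged bad; trial stats undefined")
    data = screen.data[good]  # (good_ch, trials, samples)
    ptp = (data.max(axis=-1) - data.min(axis=-1)).max(axis=0)
    std = data.std(axis=-1).max(axis=0)
    return np.stack([ptp, std], axis=1)


# ---------------------------------------------------------------------------
# Severity calibration
# ---------------------------------------------------------------------------


def _spec_for_band(kind: str, band: str, background_ptp: float,
                   config: GenConfig, bands: SeverityBands,
                   rng: np.random.Generator | None = None,
                   channels_range: tuple[int, int] = (1, 3),
                   duration_range: tuple[float, float] = (0.25, 0.6)
                   ) -> ArtifactSpec:
    lo, hi = bands.moderate_low, bands.severe_low
    if rng is None:
        onset, duration, channels = 0.2, min(0.5, config.trial_len * 0.5), (0,)
    else:
        duration = float(rng.uniform(*duration_range)) * config.trial_len
        onset = float(rng.uniform(0, config.trial_len - duration))
        nch = int(rng.integers(channels_range[0], channels_range[1] + 1))
        nch = min(nch, config.n_channels)
        channels = tuple(int(c) for c in
                         rng.choice(config.n_channels, size=nch, replace=False))
    if band == "clean":
        if background_ptp > lo:
            raise CalibrationError(
                f"clean band unreachable: background Max PTP ~{background_ptp:.0f} uV "
                f"exceeds the {lo:.0f} uV band edge")
        return ArtifactSpec(kind=kind, channels=channels, onset=onset,
                            duration=duration, amplitude=0.0)
    if band == "moderate":
        amp = 0.5 * (lo + hi)
        if amp - background_ptp <= lo or amp + background_ptp > hi:
            raise CalibrationError(
                f"moderate band unreachable for background ~{background_ptp:.0f} uV")
        return ArtifactSpec(kind=kind, channels=channels, onset=onset,
                            duration=duration, amplitude=amp)
    if band == "severe":
        amp = 2.0 * hi
        if amp - background_ptp <= hi:
            raise CalibrationError(
                f"severe band unreachable for background ~{background_ptp:.0f} uV")
        return ArtifactSpec(kind=kind, channels=channels, onset=onset,
                            duration=duration, amplitude=amp)
    raise ConfigurationError(f"unknown band {band!r}")


def _estimate_background_ptp(config: GenConfig, n_screens: int = 3) -> float:
    worst = 0.0
    for k in range(n_screens):
        scr = generate_background(replace(config, seed=config.seed + 7001 * k))
        worst = max(worst, float(scr.trial_stats[:, 0].max()))
    return worst * 1.25  # safety margin over the empirical worst case


def calibrate_severity(kind: str, band: str, config: GenConfig,
                       bands: SeverityBands = SeverityBands()) -> ArtifactSpec:
    """Artifact spec whose injection drives a trial's Max PTP into ``band``.

    The background Max PTP for the given config is estimated by simulation;
    amplitudes are chosen with a margin so realized trials land strictly
    inside the requested band. Raises :class:`CalibrationError` when the band
    is unreachable (e.g. clean band on a very noisy background).
    """
    if band not in ("clean", "moderate", "severe"):
        raise ConfigurationError(f"unknown band {band!r}")
    bg = _estimate_background_ptp(config)
    return _spec_for_band(kind, band, bg, config, bands)


# ---------------------------------------------------------------------------
# Dataset assembly with adaptive ground-truth labels
# ---------------------------------------------------------------------------


def adaptive_labels(screen: EEGScreen, injected_trials: set[int],
                    absolute_floor: float = 500.0, k: float = 3.0) -> np.ndarray:
    """Context-adaptive bad-trial rule.

    bad  iff  max_ptp > max(absolute_floor, k * median clean-trial max_ptp)
    where "clean trials" are those without injected artifacts.
    """
    stats = screen.trial_stats
    if stats is None:
        raise StatsError("trial stats missing")
    ptp = stats[:, 0]
    clean = [t for t in range(len(ptp)) if t not in injected_trials]
    med = float(np.median(ptp[clean])) if clean else 0.0
    threshold = max(absolute_floor, k * med)
    return ptp > threshold


def make_screen_dataset(config: GenConfig, n_screens: int, mix: dict,
                        quality_range: tuple[float, float] = (0.8, 1.0),
                        bad_channel_prob: float = 0.3,
                        absolute_floor: float = 500.0, k: float = 3.0,
                        bands: SeverityBands = SeverityBands(),
                        channels_range: tuple[int, int] = (1, 3),
                        duration_range: tuple[float, float] = (0.25, 0.6)
                        ) -> list[EEGScreen]:
    """Randomized screens with per-trial artifact bands drawn from ``mix``.

    ``mix`` maps band names (clean/moderate/severe) to proportions summing
    to 1. Screen quality levels are drawn uniformly from ``quality_range``;
    a fraction of screens carries 1-3 bad channels (excluded from stats,
    rendered gray). Bad labels follow :func:`adaptive_labels`.
    """
    if n_screens <= 0:
        raise ConfigurationError("n_screens must be positive")
    names = list(mix.keys())
    props = np.array([mix[b] for b in names], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ConfigurationError("mix proportions must sum to 1")
    for b in names:
        if b not in ("clean", "moderate", "severe"):
            raise ConfigurationError(f"unknown band {b!r} in mix")
    rng = np.random.default_rng(config.seed)
    screens = []
    for si in range(n_screens):
        q = float(rng.uniform(*quality_range))
        cfg = replace(config, quality_level=q,
                      seed=int(rng.integers(0, 2 ** 31 - 1)))
        screen = generate_background(cfg)
        if rng.random() < bad_channel_prob:
            n_bad = int(rng.integers(1, 4))
            bad = rng.choice(cfg.n_channels, size=n_bad, replace=False)
            screen.bad_channel_mask[bad] = True
            # visible low-frequency garbage on the dead electrodes
            drift = 150.0 * _pink_noise(rng, (n_bad, cfg.trials_per_screen),
                                        cfg.n_samples)
            screen.data[bad] += drift
        screen.trial_stats = compute_trial_stats(screen)
        bg_ptp = float(screen.trial_stats[:, 0].max()) * 1.1
        injected_trials: set[int] = set()
        trial_bands = rng.choice(len(names), size=cfg.trials_per_screen, p=props)
        for t in range(cfg.trials_per_screen):
            band = names[trial_bands[t]]
            if band == "clean":
                continue
            kind = str(rng.choice(ARTIFACT_KINDS))
            try:
                spec = _spec_for_band(kind, band, bg_ptp, cfg, bands, rng=rng,
                                      channels_range=channels_range,
                                      duration_range=duration_range)
            except CalibrationError:
                continue  # band unreachable on this background; leave trial as-is
            screen = inject_artifact(screen, t, spec, rng=rng)
            injected_trials.add(t)
        screen.trial_labels = adaptive_labels(screen, injected_trials,
                                              absolute_floor=absolute_floor, k=k)
        screens.append(screen)
    return screens


# ---------------------------------------------------------------------------
# Serialization: per-screen .npy + JSON sidecar (format version 1)
# ---------------------------------------------------------------------------


def save_screens(screens: list[EEGScreen], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": FORMAT_VERSION, "n_screens": len(screens)}
    (out_dir / "dataset.json").write_text(json.dumps(manifest, indent=2))
    for i, s in enumerate(screens):
        stem = f"screen_{i:05d}"
        np.save(out_dir / f"{stem}.npy", s.data.astype(np.float32))
        sidecar = {
            "format_version": FORMAT_VERSION,
            "bad_channel_mask": s.bad_channel_mask.astype(int).tolist(),
            "trial_labels": s.trial_labels.astype(int).tolist(),
            "trial_stats": None if s.trial_stats is None else s.trial_stats.tolist(),
            "quality_level": s.quality_level,
            "config": None if s.config is None else dataclasses.asdict(s.config),
            "injected": [[t, dataclasses.asdict(sp)] for t, sp in s.injected],
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))


def load_screens(in_dir: str | Path) -> list[EEGScreen]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "dataset.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ConfigurationError("unsupported screen dataset format version")
    screens = []
    for npy in sorted(in_dir.glob("screen_*.npy")):
        side = json.loads(npy.with_suffix(".json").read_text())
        cfg = GenConfig(**side["config"]) if side.get("config") else None
        injected = [(t, ArtifactSpec(kind=sp["kind"],
                                     channels=tuple(sp["channels"]),
                                     onset=sp["onset"], duration=sp["duration"],
                                     amplitude=sp["amplitude"]))
                    for t, sp in side.get("injected", [])]
        screens.append(EEGScreen(
            data=np.load(npy).astype(np.float64),
            bad_channel_mask=np.array(side["bad_channel_mask"], dtype=bool),
            trial_labels=np.array(side["trial_labels"], dtype=bool),
            injected=injected,
            trial_stats=(None if side.get("trial_stats") is None
                         else np.array(side["trial_stats"])),
            config=cfg, quality_level=side.get("quality_level")))
    return screens
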