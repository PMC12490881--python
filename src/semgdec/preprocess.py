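"""Signal conditioning: sEMG filtering/normalization, kinematic smoothing
and resampling, and median-deviation outlier rejection.

The sEMG chain is notch filters at the power-line frequencies, a 4th-order
Butterworth high-pass at 20 Hz to suppress motion/baseline content below
the sEMG band, and per-channel z-score normalization.  Filters run
forward-backward (zero-phase) by default, which squares the magnitude
response — offline analysis trades latency for undistorted envelopes; a
causal mode is available.

Kinematic tracks are smoothed with an order-1 Savitzky-Golay filter
(a weighted moving average) over 502 samples — adjusted to the nearest odd
length, as the symmetric formulation requires — to remove motion-estimator
jitter, then linearly resampled onto the sEMG clock.

Outlier rejection: within each annotated gesture-hold interval, a sample
is kept iff no joint deviates from its interval median by 15 degrees or
more; this removes mistakes and corrections without touching clean holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session_io import GestureAnnotation, KinematicTrack, SemgRecording

__all__ = [
    "PreprocessConfig",
    "OutlierFilterConfig",
    "filter_semg",
    "design_semg_filter",
    "semg_filter_response",
    "zscore",
    "smooth_kinematics",
    "resample_kinematics",
    "reject_outlier_samples",
    "OutlierReport",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain, with the standard defaults.

    ``comb_base_freqs`` lists the line frequencies to notch (50 and 100 Hz
    for European mains and its first harmonic); ``comb_n_harmonics`` > 1
    extends each base to that many multiples (capped below Nyquist) for a
    full comb.  ``comb_quality`` is the notch Q (centre / -3 dB width).

    ``savgol_window`` counts samples on the ``savgol_ref_rate`` clock
    (default: the 4000 Hz sEMG clock, making the default window 125.5 ms —
    the scale of motion-estimator jitter).  When a track at another rate
    is smoothed, the window is converted to the same duration; set
    ``savgol_ref_rate=None`` to count samples on the track's own clock.
    A 125 ms average on a 120 Hz stream would otherwise silently become a
    4.2 s average that flattens entire gesture holds.
    """

    comb_base_freqs: tuple[float, ...] = (50.0, 100.0)
    comb_quality: float = 30.0
    comb_n_harmonics: int = 1
    hp_cutoff: float = 20.0
    hp_order: int = 4
    savgol_window: int = 502
    savgol_polyorder: int = 1
    savgol_ref_rate: float | None = 4000.0
    zscore: bool = True
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.comb_base_freqs):
            raise ValueError("comb base frequencies must be positive")
        if self.comb_quality <= 0:
            raise ValueError("comb_quality must be positive")
        if self.comb_n_harmonics < 1:
            raise ValueError("comb_n_harmonics must be >= 1")
        if self.hp_cutoff <= 0 or self.hp_order < 1:
            raise ValueError("invalid high-pass parameters")
        if self.savgol_polyorder >= self.savgol_window:
            raise ValueError("savgol_polyorder must be below savgol_window")

    @property
    def savgol_window_odd(self) -> int:
        """Window adjusted to the nearest odd length (502 -> 501)."""
        w = self.savgol_window
        return w if w % 2 == 1 else w - 1

    def savgol_window_for_rate(self, rate: float) -> int:
        """Duration-equivalent odd window for a track at ``rate`` Hz."""
        if self.savgol_ref_rate is None or self.savgol_ref_rate == rate:
            w = self.savgol_window
        else:
            w = int(round(self.savgol_window * rate / self.savgol_ref_rate))
        w = max(w, self.savgol_polyorder + 2, 3)
        return w if w % 2 == 1 else w - 1


@dataclass(frozen=True)
class OutlierFilterConfig:
    """Median-deviation rule: keep a sample iff every joint is within
    ``max_deviation`` degrees of its interval median."""

    max_deviation: float = 15.0

    def __post_init__(self) -> None:
        if not self.max_deviation > 0:
            raise ValueError("max_deviation must be positive")


def _notch_frequencies(config: PreprocessConfig, fs: float) -> list[float]:
    freqs: list[float] = []
    nyq = fs / 2
    for base in config.comb_base_freqs:
        for k in range(1, config.comb_n_harmonics + 1):
            f = base * k
            if f < nyq:
                freqs.append(f)
    return sorted(set(freqs))


def design_semg_filter(config: PreprocessConfig, fs: float) -> np.ndarray:
    """Design the cascaded notch + high-pass filter as one SOS array."""
    if config.hp_cutoff >= fs / 2:
        raise ValueError(f"hp_cutoff {config.hp_cutoff} must be below Nyquist {fs / 2}")
    sections = []
    for f in _notch_frequencies(config, fs):
        b, a = sps.iirnotch(f, config.comb_quality, fs=fs)
        sections.append(sps.tf2sos(b, a))
    sections.append(
        sps.butter(config.hp_order, config.hp_cutoff, btype="highpass", fs=fs, output="sos")
    )
    return np.vstack(sections)


def semg_filter_response(
    config: PreprocessConfig, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Magnitude response of the designed chain at ``freqs`` (Hz).

    Accounts for the zero-phase (forward-backward) squaring when
    ``config.zero_phase`` is set.
    """
    sos = design_semg_filter(config, fs)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    return mag**2 if config.zero_phase else mag


def zscore(samples: np.ndarray) -> np.ndarray:
    """Per-channel standardization to zero mean, unit variance.

    A constant channel has no scale; it maps to all zeros with a warning
    rather than raising on the zero division.
    """
    x = np.asarray(samples, dtype=float)
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    flat = sd[0] == 0
    if np.any(flat):
        warnings.warn(
            f"constant channel(s) {np.flatnonzero(flat).tolist()} z-scored to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd


def filter_semg(recording: SemgRecording, config: PreprocessConfig = PreprocessConfig()) -> SemgRecording:
    """Apply notch + high-pass (+ optional z-score) to all 16 channels."""
    x = np.asarray(recording.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sEMG contains non-finite samples")
    sos = design_semg_filter(config, recording.fs)
    if config.zero_phase:
        y = sps.sosfiltfilt(sos, x, axis=0)
    else:
        y = sps.sosfilt(sos, x, axis=0)
    if config.zscore:
        y = zscore(y)
    return SemgRecording(
        samples=y,
        fs=recording.fs,
        channel_ids=recording.channel_ids,
        grid_layout=recording.grid_layout,
    )


def smooth_kinematics(
    track: KinematicTrack, config: PreprocessConfig = PreprocessConfig()
) -> KinematicTrack:
    """Savitzky-Golay smoothing of every joint trajectory.

    The window length is converted to the track's rate so that the
    smoothing *duration* matches the configured window on its reference
    clock (see :class:`PreprocessConfig`).
    """
    window = config.savgol_window_for_rate(track.rate)
    if track.n_samples <= window:
        raise ValueError(
            f"track has {track.n_samples} samples but the smoothing window is "
            f"{window}; record longer or choose a smaller savgol_window"
        )
    smoothed = sps.savgol_filter(
        track.angles, window_length=window, polyorder=config.savgol_polyorder,
        axis=0, mode="interp",
    )
    return KinematicTrack(
        angles=smoothed, rate=track.rate, joint_names=track.joint_names,
        offset=track.offset,
    )


def resample_kinematics(
    track: KinematicTrack, target_fs: float, dtype=np.float64
) -> KinematicTrack:
    """Linear interpolation of the joint tracks onto a ``target_fs`` clock.

    Endpoints are held (constant extrapolation), so a constant track stays
    constant and a ramp keeps its endpoints exactly.
    """
    if track.n_samples == 0:
        raise ValueError("cannot resample an empty track")
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    src_t = track.times
    n_out = int(round(track.duration * target_fs))
    out_t = track.offset + np.arange(n_out) / target_fs
    out = np.empty((n_out, track.angles.shape[1]), dtype=dtype)
    for j in range(track.angles.shape[1]):
        out[:, j] = np.interp(out_t, src_t, track.angles[:, j])
    return KinematicTrack(
        angles=out, rate=target_fs, joint_names=track.joint_names, offset=track.offset
    )


@dataclass
class OutlierReport:
    """Keep-mask and bookkeeping from the median-deviation rule."""

    keep_mask: np.ndarray
    removed_fraction: dict[int, float]
    overall_removed_fraction: float


def reject_outlier_samples(
    track: KinematicTrack,
    annotation: GestureAnnotation,
    config: OutlierFilterConfig = OutlierFilterConfig(),
) -> OutlierReport:
    """Apply the per-interval median-deviation rule to gesture holds.

    For each annotated gesture-hold interval, compute the per-joint median
    over the interval and keep a sample iff the maximum over joints of
    |angle - median| is strictly below ``config.max_deviation``.  Samples
    outside every interval are untouched (kept).

    Returns a full-length boolean keep mask plus the removed fraction per
    interval (keyed by event index) and overall (over in-interval samples).
    """
    times = track.times
    keep = np.ones(track.n_samples, dtype=bool)
    removed: dict[int, float] = {}
    n_in, n_rm = 0, 0
    for i, e in enumerate(annotation):
        if e.onset < times[0] - 1e-9 or e.offset > times[-1] + 1.0 / track.rate + 1e-9:
            raise ValueError(
                f"event {i} ({e.label!r}) [{e.onset}, {e.offset}] lies outside the "
                f"track span [{times[0]}, {times[-1]}]"
            )
        lo = int(np.searchsorted(times, e.onset, side="left"))
        hi = int(np.searchsorted(times, e.offset, side="left"))
        if hi <= lo:
            raise ValueError(f"event {i} ({e.label!r}) covers no kinematic samples")
        seg = track.angles[lo:hi]
        med = np.median(seg, axis=0)
        dev = np.abs(seg - med).max(axis=1)
        ok = dev < config.max_deviation
        keep[lo:hi] &= ok
        removed[i] = float(np.mean(~ok))
        n_in += ok.size
        n_rm += int(np.sum(~ok))
    return OutlierReport(
        keep_mask=keep,
        removed_fraction=removed,
        overall_removed_fraction=(n_rm / n_in) if n_in else 0.0,
    )
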