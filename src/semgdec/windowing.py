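"""Rolling-window segmentation into grid "video" tensors, per-window
target/label assignment, and training-time augmentation.

The recording is cut into L overlapping windows (512 ms window, 2 ms
stride by default); with N input samples, S samples per window and stride
t, ``L = floor((N - S) / t) + 1`` and window k starts at sample ``k * t``.
Each window's 16 channels are then placed on the 4x4 electrode grid,
giving a video-shaped tensor ``[L x S x 4 x 4]``.

Windows over a full session are large (hours of overlap at a 2 ms
stride), so :class:`WindowTensor` keeps a single reference to the
channel-reordered signal plus start indices and materializes window data
on demand (``.data`` for the whole tensor, ``.batch(idx)`` for minibatches
during training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .session_io import (
    GRID_COLS,
    GRID_ROWS,
    N_CHANNELS,
    GestureAnnotation,
    KinematicTrack,
    SemgRecording,
)

__all__ = [
    "WindowingConfig",
    "AugmentConfig",
    "RawWindows",
    "WindowTensor",
    "REST_LABEL",
    "segment",
    "to_grid",
    "assign_targets",
    "augment",
    "augment_batch",
]

REST_LABEL = "rest"

TargetPolicy = Literal["window-end", "window-center", "window-mean"]


@dataclass(frozen=True)
class WindowingConfig:
    """Rolling-window geometry (defaults: 512 ms window, 2 ms stride)."""

    window_ms: float = 512.0
    stride_ms: float = 2.0
    grid_shape: tuple[int, int] = (GRID_ROWS, GRID_COLS)

    def __post_init__(self) -> None:
        if not self.window_ms > self.stride_ms > 0:
            raise ValueError("need window_ms > stride_ms > 0")
        if self.grid_shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"grid_shape must be {(GRID_ROWS, GRID_COLS)}")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def stride_samples(self, fs: float) -> int:
        return max(int(round(self.stride_ms * fs / 1000.0)), 1)


@dataclass(frozen=True)
class AugmentConfig:
    """Channel-silencing + additive-noise augmentation (training only).

    Independently per channel and window, with probability
    ``silence_prob`` one span of duration ~ Uniform[6, 400] ms is zeroed
    at a uniformly random feasible onset; afterwards i.i.d. Gaussian noise
    of standard deviation ``noise_sd`` (on the z-scored scale) is added to
    every sample.

    ``scale_jitter_sd`` (off by default) additionally multiplies each
    window — all channels alike — by a lognormal factor with unit mean and
    the given coefficient of variation, applied before silencing.  Muscle
    force, and with it overall sEMG amplitude, varies between repetitions
    of the same gesture; amplitude-scaling augmentation is the standard
    way to keep a decoder from keying on the absolute level.
    """

    silence_prob: float = 0.5
    silence_duration_ms: tuple[float, float] = (6.0, 400.0)
    noise_sd: float = 0.1
    scale_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.silence_prob <= 1:
            raise ValueError("silence_prob must be a probability")
        lo, hi = self.silence_duration_ms
        if not 0 < lo <= hi:
            raise ValueError("silence duration interval must be positive and ordered")
        if self.noise_sd < 0 or self.scale_jitter_sd < 0:
            raise ValueError("noise_sd and scale_jitter_sd must be nonnegative")


@dataclass
class RawWindows:
    """Lazy view of channel-major rolling windows over one recording."""

    signal: np.ndarray  # (N, 16) in recording channel order
    starts: np.ndarray  # (L,) start sample indices
    window_samples: int
    fs: float
    channel_ids: tuple[str, ...]
    grid_layout: dict[str, tuple[int, int]]

    def __len__(self) -> int:
        return len(self.starts)

    def materialize(self, idx: Sequence[int] | None = None) -> np.ndarray:
        """Windows as an explicit ``(L, S, 16)`` array (copies)."""
        view = np.lib.stride_tricks.sliding_window_view(
            self.signal, self.window_samples, axis=0
        )  # (N - S + 1, 16, S)
        sel = self.starts if idx is None else self.starts[np.asarray(idx)]
        return np.ascontiguousarray(view[sel].transpose(0, 2, 1))


def segment(recording: SemgRecording, config: WindowingConfig = WindowingConfig()) -> RawWindows:
    """Cut a recording into L = floor((N - S)/t) + 1 rolling windows."""
    n = recording.n_samples
    s = config.window_samples(recording.fs)
    t = config.stride_samples(recording.fs)
    if n < s:
        raise ValueError(
            f"recording has {n} samples, shorter than one {s}-sample window"
        )
    l = (n - s) // t + 1
    starts = np.arange(l) * t
    return RawWindows(
        signal=recording.samples,
        starts=starts,
        window_samples=s,
        fs=recording.fs,
        channel_ids=recording.channel_ids,
        grid_layout=recording.grid_layout,
    )


def _grid_permutation(
    layout: Mapping[str, tuple[int, int]], channel_ids: Sequence[str]
) -> np.ndarray:
    """Channel order such that reshaping to (4, 4) matches the layout."""
    perm = np.full(N_CHANNELS, -1, dtype=int)
    for i, c in enumerate(channel_ids):
        if c not in layout:
            raise ValueError(f"layout missing channel {c!r}")
        r, k = layout[c]
        cell = r * GRID_COLS + k
        if perm[cell] != -1:
            raise ValueError(f"layout maps two channels to cell ({r}, {k})")
        perm[cell] = i
    if np.any(perm < 0):
        raise ValueError("layout does not cover the full 4x4 grid")
    return perm


@dataclass
class WindowTensor:
    """The windowed grid-video tensor with per-window targets and labels.

    ``source`` holds the signal with channels permuted into row-major grid
    order, so window k's tensor is
    ``source[starts[k] : starts[k] + S].reshape(S, 4, 4)``.
    """

    source: np.ndarray  # (N, 16), grid-ordered channels
    starts: np.ndarray  # (L,)
    window_samples: int
    fs: float
    grid_shape: tuple[int, int] = (GRID_ROWS, GRID_COLS)
    targets: np.ndarray | None = None  # (L, 16) degrees
    labels: np.ndarray | None = None  # (L,) gesture names / "rest"
    window_times: np.ndarray | None = None  # (L,) target time, seconds
    event_index: np.ndarray | None = None  # (L,) annotation event id, -1 = rest

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def data(self) -> np.ndarray:
        """Materialized ``(L, S, 4, 4)`` array.  Copies; prefer
        :meth:`batch` for large tensors."""
        return self.batch(np.arange(len(self)))

    def batch(self, idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(idx)
        s = self.window_samples
        view = np.lib.stride_tricks.sliding_window_view(self.source, s, axis=0)
        block = view[self.starts[idx]]  # (B, 16, S)
        return np.ascontiguousarray(block.transpose(0, 2, 1)).reshape(
            len(idx), s, *self.grid_shape
        )

    def flat_channels(self, idx: Sequence[int] | None = None) -> np.ndarray:
        """Inverse of the grid mapping: ``(B, S, 16)`` in grid-cell order."""
        idx = np.arange(len(self)) if idx is None else np.asarray(idx)
        return self.batch(idx).reshape(len(idx), self.window_samples, N_CHANNELS)

    def select(self, idx: Sequence[int]) -> "WindowTensor":
        idx = np.asarray(idx)
        pick = lambda a: None if a is None else a[idx]
        return WindowTensor(
            source=self.source,
            starts=self.starts[idx],
            window_samples=self.window_samples,
            fs=self.fs,
            grid_shape=self.grid_shape,
            targets=pick(self.targets),
            labels=pick(self.labels),
            window_times=pick(self.window_times),
            event_index=pick(self.event_index),
        )


def to_grid(windows: RawWindows, layout: Mapping[str, tuple[int, int]] | None = None) -> WindowTensor:
    """Place each window's 16 channels onto the 4x4 grid.

    ``layout`` defaults to the recording's own grid map.  The mapping is a
    pure permutation: :meth:`WindowTensor.flat_channels` recovers the
    channel-major windows exactly (in grid-cell order).
    """
    layout = dict(layout) if layout is not None else windows.grid_layout
    perm = _grid_permutation(layout, windows.channel_ids)
    return WindowTensor(
        source=np.ascontiguousarray(windows.signal[:, perm]),
        starts=windows.starts,
        window_samples=windows.window_samples,
        fs=windows.fs,
    )


def _target_sample(starts: np.ndarray, s: int, policy: TargetPolicy) -> np.ndarray:
    if policy == "window-end":
        return starts + s - 1
    if policy == "window-center":
        return starts + (s - 1) // 2
    if policy == "window-mean":
        return starts  # unused marker; mean handled separately
    raise ValueError(f"unknown target policy {policy!r}")


def assign_targets(
    tensor: WindowTensor,
    kinematics: KinematicTrack,
    annotation: GestureAnnotation,
    policy: TargetPolicy = "window-end",
    keep_mask: np.ndarray | None = None,
    include_rest: bool = True,
) -> WindowTensor:
    """Attach per-window 16-joint targets and gesture labels.

    ``kinematics`` must already be on the sEMG clock (same rate as the
    windowed recording).  The target is the joint-angle vector at the
    window's end (default), centre, or mean over the window.  A window's
    label is the annotated gesture covering its target time, else
    ``"rest"``; ``include_rest=False`` drops rest/transition windows.
    ``keep_mask`` (per sEMG-clock sample, from outlier rejection) drops
    every window overlapping a removed sample.
    """
    if abs(kinematics.rate - tensor.fs) > 1e-6:
        raise ValueError(
            f"kinematics are at {kinematics.rate} Hz but windows at {tensor.fs} Hz; "
            "resample_kinematics() onto the sEMG clock first"
        )
    s = tensor.window_samples
    starts = tensor.starts
    n_kin = kinematics.n_samples
    ends = starts + s
    valid = ends <= n_kin
    if policy == "window-mean":
        # Mean over each window via cumulative sums (O(N)).
        csum = np.concatenate(
            [np.zeros((1, kinematics.angles.shape[1])), np.cumsum(kinematics.angles, axis=0)]
        )
        tgt_all = (csum[np.minimum(ends, n_kin)] - csum[starts]) / s
        tgt_time = (starts + (s - 1) / 2) / tensor.fs
    else:
        tgt_idx = np.minimum(_target_sample(starts, s, policy), n_kin - 1)
        tgt_all = kinematics.angles[tgt_idx]
        tgt_time = tgt_idx / tensor.fs

    labels = np.full(len(starts), REST_LABEL, dtype=object)
    event_index = np.full(len(starts), -1, dtype=int)
    for i, e in enumerate(annotation):
        inside = (tgt_time >= e.onset) & (tgt_time < e.offset)
        labels[inside] = e.label
        event_index[inside] = i

    keep = valid.copy()
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        bad = ~keep_mask
        cum_bad = np.concatenate([[0], np.cumsum(bad)])
        n_bad_in_window = cum_bad[np.minimum(ends, len(bad))] - cum_bad[np.minimum(starts, len(bad))]
        keep &= n_bad_in_window == 0
    if not include_rest:
        keep &= labels != REST_LABEL

    idx = np.flatnonzero(keep)
    out = tensor.select(idx)
    out.targets = np.asarray(tgt_all[idx], dtype=float)
    out.labels = labels[idx]
    out.window_times = tgt_time[idx]
    out.event_index = event_index[idx]
    return out


def augment_batch(
    batch: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
    fs: float,
) -> np.ndarray:
    """Augment a materialized ``(B, S, 4, 4)`` batch in place-free fashion.

    Per window and channel, with probability ``silence_prob``, one span of
    Uniform[6, 400] ms is zeroed at a uniform feasible onset (spans longer
    than the window are truncated with a warning); then Gaussian noise of
    sd ``noise_sd`` is added everywhere.  Shapes never change.
    """
    b, s, w, h = batch.shape
    out = batch.reshape(b, s, w * h).copy()
    if config.scale_jitter_sd > 0:
        s2 = np.log1p(config.scale_jitter_sd**2)
        factors = rng.lognormal(-s2 / 2, np.sqrt(s2), size=(b, 1, 1))
        out *= factors.astype(out.dtype)
    if config.silence_prob > 0:
        hit = rng.random((b, w * h)) < config.silence_prob
        lo, hi = config.silence_duration_ms
        dur_ms = rng.uniform(lo, hi, (b, w * h))
        dur = np.round(dur_ms * fs / 1000.0).astype(int).clip(1)
        if np.any(dur[hit] > s):
            warnings.warn(
                "silence span exceeds the window; truncating to the window length",
                RuntimeWarning,
                stacklevel=2,
            )
        dur = np.minimum(dur, s)
        onset_max = s - dur  # inclusive; uniform feasible onset
        onsets = np.floor(rng.random((b, w * h)) * (onset_max + 1)).astype(int)
        for bi, ci in zip(*np.nonzero(hit)):
            o = onsets[bi, ci]
            out[bi, o : o + dur[bi, ci], ci] = 0.0
    if config.noise_sd > 0:
        out += rng.normal(0.0, config.noise_sd, out.shape)
    return out.reshape(b, s, w, h)


def augment(tensor: WindowTensor, config: AugmentConfig) -> np.ndarray:
    """Materialize and augment the full tensor (seeded, reproducible).

    Returns the augmented ``(L, S, 4, 4)`` array; metadata (targets,
    labels, times) is unchanged by augmentation.  Intended for training
    data only — never augment at inference.
    """
    rng = np.random.default_rng(config.seed)
    return augment_batch(tensor.data, config, rng, tensor.fs)
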