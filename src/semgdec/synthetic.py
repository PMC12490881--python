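"""Synthetic recording sessions emulating the acquisition protocol.

The simulator reproduces the statistical structure the decoder relies on,
without pretending to be a physiological motor-unit model:

* **Protocol** — 14 gestures x 7 repetitions in randomized order, each held
  for 5 s with a 3 s inter-gesture pause, run under one of four
  hand-position settings (98 events per session by default).
* **Kinematics** — piecewise joint-angle trajectories: rest pose during
  pauses, linear transition ramps, plateau at the gesture's template
  angles during holds, plus Gaussian motion-estimator noise.
* **sEMG** — per channel, an activation envelope (the gesture's per-electrode
  gain, scaled per repetition by a lognormal force factor and lagging the
  kinematic onset) multiplies a band-limited Gaussian carrier; power-line
  sinusoids, baseline noise, nearest-neighbour grid crosstalk, and rare
  simultaneous all-channel spikes (mechanical artifacts) are then added.

All randomness flows from explicit seeds; identical seeds give bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .session_io import (
    DEFAULT_GESTURES,
    DEFAULT_JOINT_RANGES_DEG,
    GRID_COLS,
    GRID_ROWS,
    JOINT_NAMES,
    N_CHANNELS,
    N_JOINTS,
    GestureAnnotation,
    GestureEvent,
    KinematicTrack,
    SemgRecording,
    SessionBundle,
)

__all__ = [
    "ProtocolConfig",
    "GestureTemplateSet",
    "NoiseModel",
    "default_templates",
    "make_protocol",
    "synth_kinematics",
    "synth_semg",
    "make_session",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and composition of one session under one setting.

    Defaults give the standard 98-event session: 14 gestures x 7
    repetitions, 5 s hold, 3 s pause, randomized order, with a leading
    pause before the first cue.  ``cue_jitter_sd`` optionally perturbs
    each onset (subjects tend to anticipate the auditory cue); jitter is
    clipped to +/- 45% of the pause so events stay non-overlapping.
    """

    n_gestures: int = 14
    n_repetitions: int = 7
    hold_duration: float = 5.0
    pause_duration: float = 3.0
    setting: str = "static1"
    gestures: tuple[str, ...] = DEFAULT_GESTURES
    order_seed: int = 0
    cue_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_gestures < 1:
            raise ValueError("n_gestures must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be positive")
        if self.pause_duration < 0:
            raise ValueError("pause_duration must be nonnegative")
        if self.n_gestures > len(self.gestures):
            raise ValueError(
                f"n_gestures={self.n_gestures} exceeds vocabulary size {len(self.gestures)}"
            )
        if self.cue_jitter_sd < 0:
            raise ValueError("cue_jitter_sd must be nonnegative")
        if self.cue_jitter_sd > 0 and self.pause_duration == 0:
            raise ValueError("cue jitter requires a nonzero pause")

    @property
    def n_events(self) -> int:
        return self.n_gestures * self.n_repetitions

    @property
    def cycle(self) -> float:
        """Ideal gesture-to-gesture period (hold + pause), seconds."""
        return self.hold_duration + self.pause_duration


def _rest_pose() -> np.ndarray:
    """Neutral reference: every joint at the midpoint of its nominal range."""
    return np.array([DEFAULT_JOINT_RANGES_DEG[j] / 2 for j in JOINT_NAMES])


# Per-gesture flexion pattern over the five digits (T, I, M, R, P):
# 1 = digit flexed toward the high end of its range, 0 = extended.
# Every (pattern, abducted) combination is unique, so no two default
# gestures share a hand pose — angle templates stay pairwise distinct.
_FLEX_PATTERNS: dict[str, tuple[int, int, int, int, int]] = {
    "alef":          (1, 0, 0, 0, 0),
    "samech":        (0, 1, 1, 1, 1),
    "yod":           (1, 1, 0, 0, 0),
    "abduction":     (0, 0, 0, 0, 0),
    "two_fingers":   (0, 1, 1, 0, 0),
    "fist":          (1, 1, 1, 1, 1),
    "point":         (1, 0, 1, 1, 1),
    "pinch":         (1, 1, 0, 1, 1),
    "three_fingers": (0, 1, 1, 1, 0),
    "hook":          (0, 0, 1, 1, 1),
    "spread":        (1, 0, 0, 0, 0),
    "thumb_up":      (0, 1, 1, 1, 1),
    "flat_hand":     (0, 0, 0, 0, 0),
    "ok_sign":       (1, 1, 0, 0, 1),
}
# Digits spread wide apart (abduction joints at the high end).
_ABDUCTED = {"abduction", "spread", "thumb_up"}

_DIGIT_OF_JOINT = {j: {"T": 0, "I": 1, "M": 2, "R": 3, "P": 4}[j[0]] for j in JOINT_NAMES}
_IS_ABDUCTION = {j: j.endswith("A") for j in JOINT_NAMES}


@dataclass
class GestureTemplateSet:
    """Per-gesture kinematic targets and electrode activation patterns.

    ``angles[g]`` is the 16-joint plateau pose (degrees) held during
    gesture *g*; ``gains[g]`` the nonnegative sEMG envelope amplitude
    (microvolts) each of the 16 electrodes sees while *g* is active.

    The remaining fields describe execution phenomenology: transition ramp
    length, motion-estimator noise on the angle tracks, trial-to-trial
    force variability (coefficient of variation of a lognormal envelope
    scale), and the electromechanical-style lag of the sEMG envelope
    behind the kinematic onset.
    """

    angles: dict[str, np.ndarray]
    gains: dict[str, np.ndarray]
    rest_pose: np.ndarray = field(default_factory=_rest_pose)
    transition_time: float = 0.5
    angle_noise_sd: float = 2.0
    force_variability_cv: float = 0.2
    onset_lag: float = 0.1

    def __post_init__(self) -> None:
        self.angles = {g: np.asarray(a, dtype=float) for g, a in self.angles.items()}
        self.gains = {g: np.asarray(v, dtype=float) for g, v in self.gains.items()}
        if set(self.angles) != set(self.gains):
            raise ValueError("angles and gains must cover the same gesture labels")
        for g, a in self.angles.items():
            if a.shape != (N_JOINTS,):
                raise ValueError(f"template {g!r}: need {N_JOINTS} angles, got {a.shape}")
        for g, v in self.gains.items():
            if v.shape != (N_CHANNELS,):
                raise ValueError(f"template {g!r}: need {N_CHANNELS} gains, got {v.shape}")
            if np.any(v < 0):
                raise ValueError(f"template {g!r}: gains must be nonnegative")
        self.rest_pose = np.asarray(self.rest_pose, dtype=float)
        if self.rest_pose.shape != (N_JOINTS,):
            raise ValueError(f"rest_pose needs {N_JOINTS} angles")
        if self.transition_time <= 0:
            raise ValueError("transition_time must be positive")
        if self.angle_noise_sd < 0 or self.force_variability_cv < 0 or self.onset_lag < 0:
            raise ValueError("noise/variability/lag parameters must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.angles)

    def require(self, labels: Sequence[str]) -> None:
        missing = [l for l in labels if l not in self.angles]
        if missing:
            raise KeyError(f"no gesture template for label(s): {sorted(set(missing))}")


def default_templates(
    gestures: Sequence[str] = DEFAULT_GESTURES,
    separation: float = 1.0,
    **kwargs,
) -> GestureTemplateSet:
    """Build the documented default template set.

    Angles follow each gesture's digit flexion pattern (flexed digits at
    90% of the joint's nominal range, extended at 10%, abduction joints at
    70% for spread-type gestures and 20% otherwise).  Activation gains are
    binary recruitment patterns drawn from the rows of a 16x16 Hadamard
    matrix (+1 -> strongly recruited electrode, -1 -> weakly recruited):
    any two gestures then differ on exactly 8 of the 16 electrodes, a
    deliberately well-separated default that stands in for distinct muscle
    synergies while every electrode still sees some activity.

    ``separation`` in [0, 1] scales how far templates sit from the common
    rest/mean pattern; 1 is the well-separated default, smaller values make
    the discrimination problem harder.
    """
    gestures = list(gestures)
    rest = _rest_pose()
    ranges = np.array([DEFAULT_JOINT_RANGES_DEG[j] for j in JOINT_NAMES])
    angles: dict[str, np.ndarray] = {}
    gains: dict[str, np.ndarray] = {}
    from scipy.linalg import hadamard

    codes = hadamard(N_CHANNELS)[1:, :]  # skip the all-ones row
    for i, g in enumerate(gestures):
        pattern = _FLEX_PATTERNS.get(g)
        if pattern is None:
            # Unknown label: derive a distinct pattern from its position.
            bits = [(i >> b) & 1 for b in range(5)]
            pattern = tuple(bits)
        frac = np.empty(N_JOINTS)
        for k, j in enumerate(JOINT_NAMES):
            if _IS_ABDUCTION[j]:
                frac[k] = 0.7 if g in _ABDUCTED else 0.2
            else:
                frac[k] = 0.9 if pattern[_DIGIT_OF_JOINT[j]] else 0.1
        pose = frac * ranges
        angles[g] = rest + separation * (pose - rest)
        # Binary recruitment: strong electrodes at 50 uV, weak at 10 uV,
        # pulled toward the common mean as separation decreases.
        code = codes[i % len(codes)]
        base = 30.0 + 20.0 * code
        gains[g] = np.clip(base.mean() + separation * (base - base.mean()), 0.0, None)
    return GestureTemplateSet(angles=angles, gains=gains, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Additive/multiplicative noise structure of the synthetic sEMG.

    ``carrier_band`` bounds the band-limited Gaussian interference-pattern
    carrier; ``line_freqs`` maps power-line frequencies to sinusoid
    amplitudes (microvolts, common phase across channels); ``baseline_sd``
    is white instrumentation noise; ``crosstalk`` mixes each channel with
    the mean of its grid neighbours; ``artifact_rate`` controls rare brief
    spikes appearing simultaneously on all electrodes.
    """

    carrier_band: tuple[float, float] = (20.0, 450.0)
    line_freqs: Mapping[float, float] = field(
        default_factory=lambda: {50.0: 10.0, 100.0: 5.0}
    )
    baseline_sd: float = 3.0
    crosstalk: float = 0.1
    artifact_rate: float = 0.5
    artifact_amplitude: float = 200.0
    artifact_width: float = 0.005
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ValueError("carrier_band must satisfy 0 < low < high")
        if self.baseline_sd < 0 or self.artifact_rate < 0:
            raise ValueError("baseline_sd and artifact_rate must be nonnegative")
        if not (0 <= self.crosstalk < 1):
            raise ValueError("crosstalk must be in [0, 1)")
        object.__setattr__(self, "line_freqs", dict(self.line_freqs))


def make_protocol(config: ProtocolConfig = ProtocolConfig()) -> GestureAnnotation:
    """Randomize gesture order and lay out event times for one session.

    The session opens with one pause, then alternates 5 s holds and 3 s
    pauses; event *k* has onset ``pause + k * (hold + pause)`` (plus
    optional jitter).  Repetition indices count occurrences of each
    gesture, 1-based, in presentation order.
    """
    rng = np.random.default_rng(config.order_seed)
    labels = list(config.gestures[: config.n_gestures]) * config.n_repetitions
    order = rng.permutation(len(labels))
    sequence = [labels[i] for i in order]
    jitter = np.zeros(len(sequence))
    if config.cue_jitter_sd > 0:
        clip = 0.45 * config.pause_duration
        jitter = np.clip(
            rng.normal(0.0, config.cue_jitter_sd, len(sequence)), -clip, clip
        )
    seen: dict[str, int] = {}
    events = []
    for k, label in enumerate(sequence):
        seen[label] = seen.get(label, 0) + 1
        onset = config.pause_duration + k * config.cycle + jitter[k]
        events.append(
            GestureEvent(
                label=label,
                onset=float(onset),
                offset=float(onset + config.hold_duration),
                repetition=seen[label],
                setting=config.setting,
            )
        )
    return GestureAnnotation(events)


def session_duration(annotation: GestureAnnotation, trailing_pause: float = 3.0) -> float:
    """Nominal session length: last gesture offset plus one trailing pause."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    return annotation.events[-1].offset + trailing_pause


def _pose_keypoints(
    annotation: GestureAnnotation,
    templates: GestureTemplateSet,
    duration: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear pose timeline: rest -> ramp -> plateau -> ramp -> rest."""
    tt = templates.transition_time
    rest = templates.rest_pose
    times = [0.0]
    poses = [rest]
    events = annotation.events
    for i, e in enumerate(events):
        tmpl = templates.angles[e.label]
        up_end = min(e.onset + tt, e.offset)
        next_onset = events[i + 1].onset if i + 1 < len(events) else duration
        down = min(tt, max(next_onset - e.offset, 0.0))
        times += [e.onset, up_end, e.offset, e.offset + down]
        poses += [rest, tmpl, tmpl, rest]
    times.append(max(duration, times[-1]))
    poses.append(rest)
    t = np.asarray(times)
    # Guard monotonicity against zero-length segments.
    t = np.maximum.accumulate(t)
    return t, np.asarray(poses)


def synth_kinematics(
    annotation: GestureAnnotation,
    templates: GestureTemplateSet,
    rate: float = 120.0,
    duration: float | None = None,
    seed: int | None = None,
) -> KinematicTrack:
    """Synthesize the motion-sensor ground-truth joint-angle track.

    Rest pose during pauses, linear ramps of ``transition_time`` into and
    out of each hold, plateau at the gesture's template angles, and i.i.d.
    Gaussian estimator noise of ``angle_noise_sd`` degrees on every sample.
    """
    templates.require(annotation.labels)
    if duration is None:
        duration = session_duration(annotation)
    kt, kp = _pose_keypoints(annotation, templates, duration)
    t = np.arange(int(round(duration * rate))) / rate
    angles = np.empty((t.size, N_JOINTS))
    for j in range(N_JOINTS):
        angles[:, j] = np.interp(t, kt, kp[:, j])
    if templates.angle_noise_sd > 0:
        rng = np.random.default_rng(seed)
        angles += rng.normal(0.0, templates.angle_noise_sd, angles.shape)
    return KinematicTrack(angles=angles, rate=rate)


def _neighbor_mixing(crosstalk: float) -> np.ndarray:
    """16x16 mixing matrix: (1-x) self + x * mean of 4-neighbours on the grid."""
    m = np.eye(N_CHANNELS) * (1.0 - crosstalk)
    if crosstalk > 0:
        for c in range(N_CHANNELS):
            r, k = divmod(c, GRID_COLS)
            nbrs = [
                nr * GRID_COLS + nk
                for nr, nk in ((r - 1, k), (r + 1, k), (r, k - 1), (r, k + 1))
                if 0 <= nr < GRID_ROWS and 0 <= nk < GRID_COLS
            ]
            for n in nbrs:
                m[c, n] += crosstalk / len(nbrs)
    return m


def _envelope_keypoints(
    annotation: GestureAnnotation, templates: GestureTemplateSet, duration: float
) -> list[tuple[float, float, float, float]]:
    """Per event: (rise start, plateau start, fall start, fall end) times."""
    lag = templates.onset_lag
    tt = templates.transition_time
    spans = []
    events = annotation.events
    for i, e in enumerate(events):
        start = e.onset + lag
        rise_end = min(start + tt, e.offset + lag)
        fall_start = e.offset + lag
        nxt = events[i + 1].onset + lag if i + 1 < len(events) else duration
        fall_end = min(fall_start + tt, max(nxt, fall_start))
        spans.append((start, rise_end, fall_start, fall_end))
    return spans


def synth_semg(
    annotation: GestureAnnotation,
    templates: GestureTemplateSet,
    noise: NoiseModel = NoiseModel(),
    fs: float = 4000.0,
    duration: float | None = None,
    seed: int | None = None,
) -> SemgRecording:
    """Synthesize the 16-channel sEMG recording for an annotated session.

    Per channel: ``envelope(t) * carrier(t) + line + baseline + spikes``,
    where the envelope follows the active gesture's per-electrode gain
    (lognormal per-repetition force scale, onset lagging the kinematic
    onset by ``templates.onset_lag``) and the carrier is unit-RMS Gaussian
    noise band-limited to ``noise.carrier_band``.
    """
    templates.require(annotation.labels)
    lo, hi = noise.carrier_band
    if fs <= 2 * hi:
        raise ValueError(
            f"fs={fs} must exceed twice the carrier band top ({hi} Hz)"
        )
    if duration is None:
        duration = session_duration(annotation)
    if seed is None:
        seed = noise.rng_seed
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # Per-event lognormal force scale (mean 1, stated CV).
    cv = templates.force_variability_cv
    sigma2 = np.log1p(cv**2)
    scales = (
        rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=len(annotation))
        if cv > 0
        else np.ones(len(annotation))
    )
    spans = _envelope_keypoints(annotation, templates, duration)

    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    out = np.zeros((n, N_CHANNELS), dtype=np.float32)

    # Shared envelope shape (gain 1); per-channel envelope = shape * gain_c.
    env_t = [0.0]
    env_v = [0.0]
    for (start, rise_end, fall_start, fall_end), s in zip(spans, scales):
        env_t += [start, rise_end, fall_start, fall_end]
        env_v += [0.0, s, s, 0.0]
    env_t.append(max(duration, env_t[-1]))
    env_v.append(0.0)
    env_t = np.maximum.accumulate(np.asarray(env_t))
    env_v = np.asarray(env_v)

    # Which gesture is active at each keypoint segment matters because the
    # per-channel gain differs per gesture; build the envelope per channel
    # from per-event contributions instead of one global interp.
    gain_matrix = np.stack([templates.gains[e.label] for e in annotation])  # (E, C)

    base_shape = np.zeros(n)
    for c in range(N_CHANNELS):
        env = np.zeros(n)
        for (start, rise_end, fall_start, fall_end), s, g in zip(
            spans, scales, gain_matrix[:, c]
        ):
            if g == 0:
                continue
            i0, i1 = np.searchsorted(t, [start, fall_end])
            seg_t = t[i0:i1]
            seg = np.interp(
                seg_t,
                np.maximum.accumulate([start, rise_end, fall_start, fall_end]),
                [0.0, s * g, s * g, 0.0],
            )
            env[i0:i1] += seg
        if env.any():
            carrier = rng.standard_normal(n)
            carrier = sps.sosfiltfilt(sos, carrier)
            carrier /= np.sqrt(np.mean(carrier**2))
            out[:, c] = (env * carrier).astype(np.float32)
        else:
            # Keep the random stream aligned across channel activity patterns
            # is not required; skipping the draw keeps zero-gain channels zero.
            out[:, c] = base_shape.astype(np.float32)

    if noise.crosstalk > 0:
        out = (out @ _neighbor_mixing(noise.crosstalk).T.astype(np.float32))

    line_phase = {f: rng.uniform(0, 2 * np.pi) for f in noise.line_freqs}
    for f, a in noise.line_freqs.items():
        if a != 0:
            wave = (a * np.sin(2 * np.pi * f * t + line_phase[f])).astype(np.float32)
            out += wave[:, None]

    if noise.baseline_sd > 0:
        for c in range(N_CHANNELS):
            out[:, c] += rng.normal(0.0, noise.baseline_sd, n).astype(np.float32)

    if noise.artifact_rate > 0:
        n_spikes = rng.poisson(noise.artifact_rate * duration / 60.0)
        width = max(int(round(noise.artifact_width * fs)), 1)
        kernel = np.hanning(2 * width + 1).astype(np.float32)
        for _ in range(n_spikes):
            center = rng.integers(width, n - width)
            amp = noise.artifact_amplitude * rng.choice((-1.0, 1.0))
            out[center - width : center + width + 1, :] += (amp * kernel)[:, None]

    return SemgRecording(samples=out, fs=fs)


def make_session(
    protocol: ProtocolConfig = ProtocolConfig(),
    templates: GestureTemplateSet | None = None,
    noise: NoiseModel = NoiseModel(),
    fs: float = 4000.0,
    kin_rate: float = 120.0,
    subject_id: str = "synthetic",
    seed: int = 0,
) -> SessionBundle:
    """Generate a complete synchronized session bundle.

    A single ``seed`` deterministically derives the gesture-order, kinematic
    and sEMG sub-seeds (recorded in the bundle metadata), so regenerating
    with the same arguments is bit-identical.
    """
    ss = np.random.SeedSequence(seed)
    order_seed, kin_seed, semg_seed = (
        int(s) % (2**31) for s in ss.generate_state(3)
    )
    if protocol.order_seed == 0 and seed != 0:
        protocol = ProtocolConfig(
            **{**protocol.__dict__, "order_seed": order_seed}
        )
    if templates is None:
        templates = default_templates(protocol.gestures)
    annotation = make_protocol(protocol)
    duration = session_duration(annotation, trailing_pause=protocol.pause_duration)
    kinematics = synth_kinematics(
        annotation, templates, rate=kin_rate, duration=duration, seed=kin_seed
    )
    semg = synth_semg(
        annotation, templates, noise=noise, fs=fs, duration=duration, seed=semg_seed
    )
    return SessionBundle(
        semg=semg,
        kinematics=kinematics,
        annotation=annotation,
        subject_id=subject_id,
        metadata={
            "seed": seed,
            "order_seed": protocol.order_seed,
            "kin_seed": kin_seed,
            "semg_seed": semg_seed,
            "setting": protocol.setting,
            "n_events": len(annotation),
        },
    )
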