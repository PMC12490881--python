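"""Session data model, on-disk format, and repetition-based partitioning.

A *session* is one run of the acquisition protocol: a 16-channel surface-EMG
recording from a 4x4 electrode grid on the extensor digitorum, a synchronized
16-joint hand-kinematics track from an optical motion sensor, and a list of
timed gesture events.  All three share a single clock whose origin is the
first sEMG sample; annotation times are seconds on that clock.

On disk a session is a directory::

    <path>/
        semg.npy         float array [time x 16], microvolts
        kinematics.npy   float array [time x 16], degrees
        session.json     sidecar: rates, channel ids, grid layout,
                         joint names, events, subject id, metadata

The ``.npy`` container is lossless, so write -> read is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: The 16 tracked joint angles, in canonical order.  Naming: digit
#: (T humb / I ndex / M iddle / R ing / P inky), joint (C arpometacarpal,
#: M etacarpophalangeal, P roximal interphalangeal), motion (F lexion /
#: A bduction).
JOINT_NAMES: tuple[str, ...] = (
    "TCF", "TCA", "TMF", "TMA",
    "IMF", "IMA", "IPF",
    "MMF", "MMA", "MPF",
    "RMF", "RMA", "RPF",
    "PMF", "PMA", "PPF",
)

N_CHANNELS = 16
N_JOINTS = 16
GRID_ROWS = 4
GRID_COLS = 4

#: Nominal active range of motion per joint, degrees, in JOINT_NAMES order.
#: Round figures from standard goniometry references: ~90 deg of
#: metacarpophalangeal flexion, ~100 deg of proximal interphalangeal
#: flexion, 30-70 deg for abduction and thumb carpometacarpal motion.
#: These are configuration defaults (used for error normalization and as
#: the simulator's angle coordinate frame), not measured claims.
DEFAULT_JOINT_RANGES_DEG: dict[str, float] = {
    "TCF": 50.0, "TCA": 70.0, "TMF": 55.0, "TMA": 30.0,
    "IMF": 90.0, "IMA": 40.0, "IPF": 100.0,
    "MMF": 90.0, "MMA": 40.0, "MPF": 100.0,
    "RMF": 90.0, "RMA": 40.0, "RPF": 100.0,
    "PMF": 90.0, "PMA": 45.0, "PPF": 100.0,
}

#: The four hand-position conditions under which the protocol is run.
SETTINGS: tuple[str, ...] = ("static1", "static2", "static3", "dynamic")

#: Default 14-gesture vocabulary.  The gesture set mixes sign-language
#: letters with functional hand postures, several of which are visually
#: near-overlapping; the vocabulary is configuration, not a contract, and
#: any ordered list of unique names may be substituted.
DEFAULT_GESTURES: tuple[str, ...] = (
    "alef", "samech", "yod", "abduction", "two_fingers",
    "fist", "point", "pinch", "three_fingers", "hook",
    "spread", "thumb_up", "flat_hand", "ok_sign",
)


class SessionFormatError(ValueError):
    """Raised when an on-disk session violates the documented schema."""


def default_grid_layout(channel_ids: Sequence[str]) -> dict[str, tuple[int, int]]:
    """Row-major placement of 16 channels onto the 4x4 electrode grid."""
    if len(channel_ids) != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {len(channel_ids)}")
    return {c: (i // GRID_COLS, i % GRID_COLS) for i, c in enumerate(channel_ids)}


def _check_layout(layout: Mapping[str, tuple[int, int]], channel_ids: Sequence[str]) -> None:
    cells = {tuple(layout[c]) for c in channel_ids if c in layout}
    missing = [c for c in channel_ids if c not in layout]
    if missing:
        raise ValueError(f"grid_layout missing channels: {missing}")
    want = {(r, c) for r in range(GRID_ROWS) for c in range(GRID_COLS)}
    if cells != want:
        raise ValueError(
            "grid_layout must be a bijection onto the 4x4 grid; "
            f"covered cells: {sorted(cells)}"
        )


@dataclass
class SemgRecording:
    """Multichannel surface-EMG time series on the session clock.

    Parameters
    ----------
    samples
        ``[time x 16]`` array in microvolts (or dimensionless after
        z-scoring).
    fs
        Sampling rate in Hz.
    channel_ids
        16 channel labels, in column order of ``samples``.
    grid_layout
        Map channel id -> (row, col) on the 4x4 electrode grid.
    """

    samples: np.ndarray
    fs: float = 4000.0
    channel_ids: tuple[str, ...] = tuple(f"ch{i:02d}" for i in range(N_CHANNELS))
    grid_layout: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be [time x {N_CHANNELS}], got shape {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_ids = tuple(self.channel_ids)
        if len(self.channel_ids) != N_CHANNELS:
            raise ValueError(f"need {N_CHANNELS} channel ids")
        if not self.grid_layout:
            self.grid_layout = default_grid_layout(self.channel_ids)
        self.grid_layout = {c: tuple(rc) for c, rc in self.grid_layout.items()}
        _check_layout(self.grid_layout, self.channel_ids)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class KinematicTrack:
    """16 named joint-angle trajectories in degrees.

    ``offset`` is the time (s, session clock) of the first kinematic sample;
    it is 0 when the motion sensor and the sEMG stream started together.
    """

    angles: np.ndarray
    rate: float = 120.0
    joint_names: tuple[str, ...] = JOINT_NAMES
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_JOINTS:
            raise ValueError(
                f"angles must be [time x {N_JOINTS}], got shape {self.angles.shape}"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.joint_names = tuple(self.joint_names)
        if len(self.joint_names) != N_JOINTS:
            raise ValueError(f"need {N_JOINTS} joint names")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.offset + np.arange(self.n_samples) / self.rate


@dataclass(frozen=True)
class GestureEvent:
    """One timed execution of one gesture."""

    label: str
    onset: float
    offset: float
    repetition: int
    setting: str

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(
                f"event {self.label!r}: onset {self.onset} must precede offset {self.offset}"
            )
        if self.repetition < 1:
            raise ValueError("repetition indices are 1-based")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class GestureAnnotation:
    """Chronologically sorted, non-overlapping gesture events."""

    events: list[GestureEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"overlapping events: {a.label!r} [{a.onset}, {a.offset}] and "
                    f"{b.label!r} [{b.onset}, {b.offset}]"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def vocabulary(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.label)
        return list(seen)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    def filter(self, predicate) -> "GestureAnnotation":
        return GestureAnnotation([e for e in self.events if predicate(e)])


@dataclass
class SessionBundle:
    """A complete recorded (or simulated) session sharing one time origin."""

    semg: SemgRecording
    kinematics: KinematicTrack
    annotation: GestureAnnotation
    subject_id: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        horizon = max(self.semg.duration, self.kinematics.duration)
        for e in self.annotation:
            if e.offset > horizon + 1e-9:
                raise ValueError(
                    f"event {e.label!r} ends at {e.offset:.3f}s, beyond both "
                    f"signal durations ({horizon:.3f}s)"
                )


@dataclass(frozen=True)
class SplitSpec:
    """Repetition-based train/validation/test partition.

    By default the first repetition of every gesture is discarded (subjects
    adjusting to the task), the fifth is held out for testing, the fourth
    for validation, and the remaining repetitions {2, 3, 6, 7} train.
    """

    drop_repetitions: frozenset[int] = frozenset({1})
    test_repetitions: frozenset[int] = frozenset({5})
    val_repetitions: frozenset[int] = frozenset({4})

    def __post_init__(self) -> None:
        sets = (
            frozenset(self.drop_repetitions),
            frozenset(self.test_repetitions),
            frozenset(self.val_repetitions),
        )
        object.__setattr__(self, "drop_repetitions", sets[0])
        object.__setattr__(self, "test_repetitions", sets[1])
        object.__setattr__(self, "val_repetitions", sets[2])
        names = ("drop", "test", "val")
        for i in range(3):
            for j in range(i + 1, 3):
                common = sets[i] & sets[j]
                if common:
                    raise ValueError(
                        f"{names[i]} and {names[j]} repetition sets overlap: {sorted(common)}"
                    )


def split_by_repetition(
    annotation: GestureAnnotation, spec: SplitSpec = SplitSpec()
) -> tuple[GestureAnnotation, GestureAnnotation, GestureAnnotation]:
    """Partition events into (train, val, test) by repetition index.

    Dropped repetitions appear in no split; every other event lands in
    exactly one of the three outputs.
    """
    reps_present = {e.repetition for e in annotation}
    for name, reps in (
        ("test", spec.test_repetitions),
        ("val", spec.val_repetitions),
    ):
        missing = set(reps) - reps_present
        if missing:
            raise ValueError(
                f"{name} repetitions {sorted(missing)} not present in annotation "
                f"(found {sorted(reps_present)})"
            )
    train, val, test = [], [], []
    for e in annotation:
        if e.repetition in spec.drop_repetitions:
            continue
        if e.repetition in spec.test_repetitions:
            test.append(e)
        elif e.repetition in spec.val_repetitions:
            val.append(e)
        else:
            train.append(e)
    return GestureAnnotation(train), GestureAnnotation(val), GestureAnnotation(test)


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

_SIDECAR = "session.json"
_SEMG = "semg.npy"
_KIN = "kinematics.npy"
_SCHEMA_VERSION = 1


def write_session(bundle: SessionBundle, path: str | Path, overwrite: bool = False) -> Path:
    """Write a session directory (two ``.npy`` arrays + JSON sidecar).

    Refuses to clobber an existing session unless ``overwrite`` is set.
    The round trip through :func:`read_session` is lossless.
    """
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{path} already contains files; pass overwrite=True to replace"
        )
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / _SEMG, bundle.semg.samples)
    np.save(path / _KIN, bundle.kinematics.angles)
    sidecar = {
        "schema_version": _SCHEMA_VERSION,
        "subject_id": bundle.subject_id,
        "semg": {
            "fs": bundle.semg.fs,
            "channel_ids": list(bundle.semg.channel_ids),
            "grid_layout": {c: list(rc) for c, rc in bundle.semg.grid_layout.items()},
            "units": "uV",
        },
        "kinematics": {
            "rate": bundle.kinematics.rate,
            "joint_names": list(bundle.kinematics.joint_names),
            "offset": bundle.kinematics.offset,
            "units": "deg",
        },
        "events": [
            {
                "label": e.label,
                "onset": e.onset,
                "offset": e.offset,
                "repetition": e.repetition,
                "setting": e.setting,
            }
            for e in bundle.annotation
        ],
        "metadata": bundle.metadata,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise SessionFormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"unparseable sidecar {sidecar_path}: {exc}") from exc
    for key in ("semg", "kinematics", "events"):
        if key not in meta:
            raise SessionFormatError(f"sidecar {sidecar_path} lacks required key {key!r}")
    semg_arr = np.load(path / _SEMG)
    kin_arr = np.load(path / _KIN)
    try:
        semg = SemgRecording(
            samples=semg_arr,
            fs=meta["semg"]["fs"],
            channel_ids=tuple(meta["semg"]["channel_ids"]),
            grid_layout={c: tuple(rc) for c, rc in meta["semg"]["grid_layout"].items()},
        )
        kin = KinematicTrack(
            angles=kin_arr,
            rate=meta["kinematics"]["rate"],
            joint_names=tuple(meta["kinematics"]["joint_names"]),
            offset=meta["kinematics"].get("offset", 0.0),
        )
        annotation = GestureAnnotation(
            [GestureEvent(**ev) for ev in meta["events"]]
        )
        return SessionBundle(
            semg=semg,
            kinematics=kin,
            annotation=annotation,
            subject_id=meta.get("subject_id", "unknown"),
            metadata=meta.get("metadata", {}),
        )
    except ValueError as exc:
        raise SessionFormatError(f"invalid session at {path}: {exc}") from exc


def bundles_equal(a: SessionBundle, b: SessionBundle) -> bool:
    """Field-by-field equality of two bundles (exact array comparison)."""
    return (
        np.array_equal(a.semg.samples, b.semg.samples)
        and a.semg.fs == b.semg.fs
        and a.semg.channel_ids == b.semg.channel_ids
        and a.semg.grid_layout == b.semg.grid_layout
        and np.array_equal(a.kinematics.angles, b.kinematics.angles)
        and a.kinematics.rate == b.kinematics.rate
        and a.kinematics.joint_names == b.kinematics.joint_names
        and a.kinematics.offset == b.kinematics.offset
        and a.annotation.events == b.annotation.events
        and a.subject_id == b.subject_id
        and a.metadata == b.metadata
    )
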