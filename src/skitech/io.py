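"""Core data types and plain-text I/O for multi-tracker gyroscope recordings.

A recording is a uniformly sampled multichannel angular-velocity series from
body-worn motion trackers (up to 17 trackers x 3 axes = 51 channels, sampled
at 240 Hz by default).  Technique annotations are half-open frame intervals
with a 0-9 label convention (1-4 classical techniques, 5-8 skating
techniques, 0 start/end, 9 descending) plus a TURN label for end-of-lap
turning segments.  Frames covered by no interval are transitions; like 0, 9
and TURN frames they count as noise and are excised before segmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AXES",
    "TRACKERS",
    "PRESETS",
    "TECHNIQUES",
    "CLASSICAL_CODES",
    "SKATING_CODES",
    "TURN",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "TechniqueLabel",
    "Recording",
    "LabelTrack",
    "SensorConfig",
    "channel_name",
    "parse_channel",
    "style_of",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "select_channels",
]

AXES = ("x", "y", "z")

#: The 17 tracker locations of the full-body suit, in canonical column order.
TRACKERS = (
    "pelvis",
    "chest",
    "head",
    "right_shoulder",
    "left_shoulder",
    "right_upper_arm",
    "left_upper_arm",
    "right_forearm",
    "left_forearm",
    "right_hand",
    "left_hand",
    "right_upper_leg",
    "left_upper_leg",
    "right_lower_leg",
    "left_lower_leg",
    "right_foot",
    "left_foot",
)

_UPPER_BODY = (
    "pelvis", "chest", "head",
    "right_shoulder", "left_shoulder",
    "right_upper_arm", "left_upper_arm",
    "right_forearm", "left_forearm",
    "right_hand", "left_hand",
)
_LOWER_BODY = (
    "pelvis",
    "right_upper_leg", "left_upper_leg",
    "right_lower_leg", "left_lower_leg",
    "right_foot", "left_foot",
)
_SPORTS_BIOMECH = ("pelvis", "right_hand", "left_hand", "right_foot", "left_foot")


class FormatError(ValueError):
    """A tabular input file violates the expected layout."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


class ConfigurationError(ValueError):
    """A sensor configuration cannot be resolved against a recording."""


TURN = "TURN"

#: Technique code -> (abbreviation, style).  Codes 1-4 are classical,
#: 5-8 skating.
TECHNIQUES = {
    1: ("DS", "classical"),
    2: ("P-Off", "classical"),
    3: ("KDP", "classical"),
    4: ("DP", "classical"),
    5: ("V2", "skating"),
    6: ("V2A", "skating"),
    7: ("V1", "skating"),
    8: ("FS", "skating"),
}
CLASSICAL_CODES = (1, 2, 3, 4)
SKATING_CODES = (5, 6, 7, 8)

_VALID_LABELS = set(range(10)) | {TURN}


def style_of(code: int) -> str:
    """Return ``"classical"`` or ``"skating"`` for a technique code 1-8."""
    if code not in TECHNIQUES:
        raise ValueError(f"not a technique code: {code!r}")
    return TECHNIQUES[code][1]


@dataclass(frozen=True)
class TechniqueLabel:
    """One of the eight cyclic techniques (four per skiing style)."""

    code: int

    def __post_init__(self):
        if self.code not in TECHNIQUES:
            raise ValidationError(f"technique code must be 1-8, got {self.code}")

    @property
    def name(self) -> str:
        return TECHNIQUES[self.code][0]

    @property
    def style(self) -> str:
        return TECHNIQUES[self.code][1]


def channel_name(tracker: str, axis: str) -> str:
    return f"{tracker}_gyr_{axis}"


def parse_channel(name: str) -> tuple[str, str]:
    """Split a ``<tracker>_gyr_<axis>`` column name into (tracker, axis)."""
    tracker, sep, axis = name.rpartition("_gyr_")
    if not sep or axis not in AXES or not tracker:
        raise FormatError(f"malformed channel name {name!r} (want <tracker>_gyr_<x|y|z>)")
    return tracker, axis


def all_channels(trackers=TRACKERS) -> list[str]:
    """Channel names for the given trackers, tracker-major, axes x,y,z."""
    return [channel_name(t, a) for t in trackers for a in AXES]


@dataclass(frozen=True)
class SensorConfig:
    """A named subset of the 17 tracker locations."""

    name: str
    trackers: frozenset[str]

    def __post_init__(self):
        unknown = set(self.trackers) - set(TRACKERS)
        if unknown:
            raise ValidationError(f"unknown trackers in config {self.name!r}: {sorted(unknown)}")
        object.__setattr__(self, "trackers", frozenset(self.trackers))

    @property
    def n_trackers(self) -> int:
        return len(self.trackers)

    def channels(self) -> list[str]:
        """Channel names of this configuration, in canonical tracker order."""
        return [channel_name(t, a) for t in TRACKERS if t in self.trackers for a in AXES]


#: The five shipped sensor configurations (17, 11, 7, 5 and 1 trackers).
PRESETS: dict[str, SensorConfig] = {
    "whole_body": SensorConfig("whole_body", frozenset(TRACKERS)),
    "upper_body": SensorConfig("upper_body", frozenset(_UPPER_BODY)),
    "lower_body": SensorConfig("lower_body", frozenset(_LOWER_BODY)),
    "sports_biomechanics": SensorConfig("sports_biomechanics", frozenset(_SPORTS_BIOMECH)),
    "pelvis": SensorConfig("pelvis", frozenset(("pelvis",))),
}


@dataclass
class Recording:
    """A uniformly sampled multichannel angular-velocity series.

    Parameters
    ----------
    subject_id : str
        Identifier of the skier the recording belongs to.
    course : {"flat", "natural"}
        Track type the recording was made on.
    values : ndarray, shape (n_frames, n_channels)
        Angular velocity in rad/s, one column per channel.
    channels : list of str
        Column names, ``<tracker>_gyr_<axis>``, unique, in column order.
    sample_rate_hz : float, default 240
        Sampling frequency.
    """

    subject_id: str
    course: str
    values: np.ndarray
    channels: list[str]
    sample_rate_hz: float = 240.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[1] != len(self.channels):
            raise ValidationError(
                f"values has {self.values.shape[1]} columns but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            seen, dup = set(), None
            for c in self.channels:
                if c in seen:
                    dup = c
                    break
                seen.add(c)
            raise ValidationError(f"duplicate channel name {dup!r}")
        for c in self.channels:
            parse_channel(c)
        if self.course not in ("flat", "natural"):
            raise ValidationError(f"course must be 'flat' or 'natural', got {self.course!r}")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not present in recording") from None

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def slice_frames(self, start: int, end: int) -> "Recording":
        """Return the sub-recording of frames [start, end)."""
        if not (0 <= start <= end <= self.n_frames):
            raise ValidationError(f"frame slice [{start}, {end}) out of range for {self.n_frames} frames")
        return dataclasses.replace(self, values=self.values[start:end])


@dataclass
class LabelTrack:
    """Sorted, non-overlapping half-open frame intervals with labels.

    Labels are ints 0-9 or the string ``"TURN"``.  Intervals need not cover
    the recording; uncovered frames are transitions (noise).
    """

    intervals: list[tuple[int, int, object]] = field(default_factory=list)

    def __post_init__(self):
        ivs = [(int(s), int(e), (lab if lab == TURN else int(lab))) for s, e, lab in self.intervals]
        ivs.sort(key=lambda iv: iv[0])
        prev_end = None
        for s, e, lab in ivs:
            if lab not in _VALID_LABELS:
                raise ValidationError(f"unknown label {lab!r}")
            if s < 0 or e <= s:
                raise ValidationError(f"bad interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"overlapping intervals at frame {s}")
            prev_end = e
        self.intervals = ivs

    def validate_against(self, rec: Recording) -> None:
        if self.intervals and self.intervals[-1][1] > rec.n_frames:
            raise ValidationError(
                f"interval end {self.intervals[-1][1]} exceeds recording length {rec.n_frames}"
            )

    def technique_intervals(self) -> list[tuple[int, int, int]]:
        """The intervals carrying a technique code (1-8), in order."""
        return [(s, e, lab) for s, e, lab in self.intervals if lab in TECHNIQUES]

    @property
    def n_labeled_frames(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


def read_recording(path, sample_rate_hz: float = 240.0, subject_id: str = "",
                   course: str = "flat") -> Recording:
    """Read a recording from a comma-delimited text file.

    The file must have one header row of channel names (an optional leading
    ``frame`` index column is ignored) followed by numeric rows.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: missing header row") from None
    cols = list(df.columns)
    if cols and cols[0] == "frame":
        df = df.drop(columns=["frame"])
        cols = cols[1:]
    if not cols:
        raise FormatError(f"{path}: no channel columns")
    if any(c.startswith("Unnamed") for c in cols):
        raise FormatError(f"{path}: missing or blank header fields")
    dupes = [c for c in cols if c.endswith(".1") and c[:-2] in cols]
    if dupes:
        raise FormatError(f"{path}: duplicate channel name {dupes[0][:-2]!r}")
    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce")
        if bad.isna().any() and not df[c].isna().all():
            row = int(bad.isna().idxmax())
            raise FormatError(f"{path}: non-numeric cell at row {row}, column {c!r}")
    values = df.to_numpy(dtype=np.float64) if len(df) else np.empty((0, len(cols)))
    return Recording(subject_id=subject_id, course=course, values=values,
                     channels=cols, sample_rate_hz=sample_rate_hz)


def write_recording(rec: Recording, path, float_format: str = "%.6f") -> None:
    df = pd.DataFrame(rec.values, columns=rec.channels)
    df.insert(0, "frame", np.arange(rec.n_frames))
    df.to_csv(path, index=False, float_format=float_format)


def read_labels(path, rec: Recording | None = None) -> LabelTrack:
    """Read an interval label file (columns start_frame, end_frame, label)."""
    df = pd.read_csv(path)
    expected = ["start_frame", "end_frame", "label"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    intervals = []
    for _, row in df.iterrows():
        lab = row["label"]
        lab = TURN if str(lab).strip().upper() == TURN else int(lab)
        intervals.append((int(row["start_frame"]), int(row["end_frame"]), lab))
    track = LabelTrack(intervals)
    if rec is not None:
        track.validate_against(rec)
    return track


def write_labels(track: LabelTrack, path) -> None:
    df = pd.DataFrame(track.intervals, columns=["start_frame", "end_frame", "label"])
    df.to_csv(path, index=False)


def select_channels(rec: Recording, cfg: SensorConfig) -> Recording:
    """Restrict a recording to the channels of a sensor configuration.

    Column order of the original recording is preserved.  Every tracker in
    the configuration must be present with all three axes.
    """
    have = {}
    for c in rec.channels:
        t, a = parse_channel(c)
        have.setdefault(t, set()).add(a)
    for t in sorted(cfg.trackers):
        if set(AXES) - have.get(t, set()):
            raise ConfigurationError(
                f"configuration {cfg.name!r} needs tracker {t!r} with all 3 axes, "
                f"recording has axes {sorted(have.get(t, set()))}"
            )
    keep = [i for i, c in enumerate(rec.channels) if parse_channel(c)[0] in cfg.trackers]
    return dataclasses.replace(
        rec, values=rec.values[:, keep], channels=[rec.channels[i] for i in keep]
    )
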