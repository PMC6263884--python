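"""Cycle segmentation: from a labeled recording to a fixed-length cycle tensor.

The pipeline follows the classic stride-segmentation recipe for cyclic
whole-body motion: a zero-phase low-pass Butterworth filter smooths a
reference gyroscope channel (z-axis of the left lower-leg tracker by
default), peaks of the filtered channel delimit cycles, frames labeled as
noise (start/end, descending, turning, transitions) are excised first, and
every raw peak-to-peak slice is resampled to a fixed length of 333 frames
with an anti-aliasing FIR polyphase resampler running at (333/n) x 240 Hz
for an n-frame cycle.  Filtering is used only to localize peaks; the values
stored in the cycle tensor are raw.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import (
    TECHNIQUES,
    LabelTrack,
    Recording,
    SensorConfig,
    ValidationError,
    parse_channel,
    style_of,
)

__all__ = [
    "DEFAULT_REFERENCE_CHANNEL",
    "DEFAULT_TARGET_LEN",
    "FilterSpec",
    "CycleSet",
    "NoCyclesError",
    "lowpass_filter",
    "detect_cycle_peaks",
    "excise_noise",
    "resample_cycle",
    "build_cycle_set",
    "segment_recording",
]

DEFAULT_REFERENCE_CHANNEL = "left_lower_leg_gyr_z"
#: Fixed cycle length after resampling (the mean cycle length of the motion
#: regime this pipeline targets, in frames at 240 Hz).
DEFAULT_TARGET_LEN = 333


class NoCyclesError(RuntimeError):
    """Fewer than two peaks were found, so no cycle can be delimited."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``cutoff`` defaults to 0.007 interpreted as a fraction of the Nyquist
    frequency (0.84 Hz at a 240 Hz sample rate).  Read as an absolute
    0.007 Hz the filter would pass fewer than two events per five minutes
    and could never expose per-cycle peaks, so the normalized reading is
    the default; ``cutoff_mode="absolute_hz"`` selects the absolute one.
    """

    order: int = 4
    cutoff: float = 0.007
    cutoff_mode: str = "normalized_nyquist"

    def __post_init__(self):
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not self.cutoff > 0:
            raise ValidationError("cutoff must be positive")
        if self.cutoff_mode not in ("normalized_nyquist", "absolute_hz"):
            raise ValidationError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "normalized_nyquist" and not self.cutoff < 1:
            raise ValidationError("normalized cutoff must be < 1")

    def cutoff_hz(self, sample_rate_hz: float) -> float:
        """Effective cutoff in Hz at the given sample rate."""
        if self.cutoff_mode == "absolute_hz":
            return self.cutoff
        return self.cutoff * sample_rate_hz / 2.0

    def wn(self, sample_rate_hz: float) -> float:
        """Cutoff as a fraction of Nyquist (scipy's Wn convention)."""
        wn = 2.0 * self.cutoff_hz(sample_rate_hz) / sample_rate_hz
        if not 0 < wn < 1:
            raise ValidationError(
                f"effective cutoff {self.cutoff_hz(sample_rate_hz):g} Hz is outside "
                f"(0, Nyquist) at {sample_rate_hz:g} Hz"
            )
        return wn


def lowpass_filter(x: np.ndarray, spec: FilterSpec, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase filtering keeps peak locations unshifted, which matters
    because the filtered signal is used only to localize cycle boundaries.
    The two passes square the magnitude response: gain at the cutoff is 1/2
    rather than the single-pass 1/sqrt(2); DC gain is exactly 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n <= 3 * spec.order:
        raise ValidationError(f"series of length {n} too short for order-{spec.order} filtering")
    sos = signal.butter(spec.order, spec.wn(sample_rate_hz), btype="low", output="sos")
    padlen = min(n - 1, 6 * (2 * spec.order + 1))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def detect_cycle_peaks(
    rec: Recording,
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    spec: FilterSpec = FilterSpec(),
    min_period_frames: int | None = None,
    min_prominence_frac: float = 0.3,
) -> np.ndarray:
    """Find cycle-delimiting peaks on the filtered reference channel.

    Consecutive peaks ``p_i < p_{i+1}`` delimit cycles as half-open frame
    ranges ``[p_i, p_{i+1})``.  A candidate peak must be at least
    ``min_period_frames`` from its neighbours (default: half the fixed
    cycle length) and have prominence of at least ``min_prominence_frac``
    times the interquartile range of the filtered channel, which makes the
    criterion invariant to the amplitude scale of the data.

    Raises
    ------
    NoCyclesError
        If fewer than two qualifying peaks exist.
    """
    if min_period_frames is None:
        min_period_frames = DEFAULT_TARGET_LEN // 2
    if min_period_frames < 2:
        raise ValidationError("min_period_frames must be >= 2")
    x = rec.channel(reference_channel)
    filtered = lowpass_filter(x, spec, rec.sample_rate_hz)
    q75, q25 = np.percentile(filtered, [75, 25])
    iqr = q75 - q25
    # guard against float ripple on (near-)constant signals
    scale = max(1.0, float(np.abs(filtered).max()))
    if iqr <= 1e-8 * scale:
        raise NoCyclesError("reference channel is constant after filtering; no cycles")
    prominence = min_prominence_frac * iqr
    peaks, _ = signal.find_peaks(filtered, distance=min_period_frames, prominence=prominence)
    if len(peaks) < 2:
        raise NoCyclesError(f"found {len(peaks)} peak(s); need at least 2 to delimit a cycle")
    return peaks


def excise_noise(rec: Recording, track: LabelTrack) -> list[tuple[Recording, int]]:
    """Drop noise frames, returning one contiguous segment per technique interval.

    Frames labeled 0 (start/end), 9 (descending), TURN, or covered by no
    interval (transitions) are removed.  Each technique interval becomes its
    own segment, so segment boundaries never bridge an excised gap.
    """
    track.validate_against(rec)
    return [
        (rec.slice_frames(s, e), lab) for s, e, lab in track.technique_intervals()
    ]


def resample_cycle(cycle: np.ndarray, target_len: int = DEFAULT_TARGET_LEN,
                   sample_rate_hz: float = 240.0) -> np.ndarray:
    """Resample one raw cycle matrix (n x C) to ``target_len`` rows.

    Uses polyphase rational resampling by ``target_len/n`` with scipy's
    anti-aliasing FIR low-pass (equivalently: resampling an n-frame cycle at
    ``(target_len/n) x sample_rate_hz``).  The cycle is mirror-extended on
    both sides before filtering and cropped afterwards, which suppresses FIR
    edge transients; with a full mirror the crop index is exactly
    ``target_len`` because ``n * target_len/n`` is integral by construction.
    """
    cycle = np.asarray(cycle, dtype=np.float64)
    one_d = cycle.ndim == 1
    if one_d:
        cycle = cycle[:, None]
    n = cycle.shape[0]
    if n < 2:
        raise ValidationError(f"cycle must have at least 2 frames, got {n}")
    if n == target_len:
        return cycle[:, 0].copy() if one_d else cycle.copy()
    g = math.gcd(target_len, n)
    up, down = target_len // g, n // g
    ext = np.concatenate([cycle[::-1], cycle, cycle[::-1]], axis=0)
    out = signal.resample_poly(ext, up, down, axis=0)
    out = out[target_len:2 * target_len]
    return out[:, 0] if one_d else out


@dataclass
class CycleSet:
    """A stack of fixed-length cycle matrices with labels and provenance.

    Attributes
    ----------
    cycles : ndarray, shape (n_cycles, L, C), float32
        Resampled raw cycles.
    labels : ndarray of int, shape (n_cycles,)
        Technique codes 1-8.
    channels : list of str
        Channel names of the C columns.
    provenance : DataFrame
        One row per cycle: subject, course, style, source, start_frame,
        end_frame, orig_len.
    """

    cycles: np.ndarray
    labels: np.ndarray
    channels: list[str]
    provenance: pd.DataFrame
    sample_rate_hz: float = 240.0

    _PROV_COLS = ["subject", "course", "style", "source", "start_frame", "end_frame", "orig_len"]

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.cycles.ndim != 3:
            raise ValidationError(f"cycles must be 3-D, got shape {self.cycles.shape}")
        n, L, C = self.cycles.shape
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValidationError("cycles, labels and provenance must agree in length")
        if C != len(self.channels):
            raise ValidationError("channel names must match tensor width")
        if n and not np.isin(self.labels, list(TECHNIQUES)).all():
            raise ValidationError("labels must be technique codes 1-8")
        missing = [c for c in self._PROV_COLS if c not in self.provenance.columns]
        if missing:
            raise ValidationError(f"provenance missing columns {missing}")
        if (self.provenance["orig_len"].to_numpy() < 2).any() if n else False:
            raise ValidationError("original cycle lengths must be >= 2")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def target_len(self) -> int:
        return self.cycles.shape[1]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.provenance["subject"].unique()) if self.n_cycles else []

    def select_channels(self, cfg: SensorConfig) -> "CycleSet":
        """Column-subset the tensor to a sensor configuration (order kept)."""
        want = set(cfg.channels())
        have = {parse_channel(c)[0] for c in self.channels}
        missing = sorted(cfg.trackers - have)
        if missing:
            raise ValidationError(f"configuration {cfg.name!r} needs trackers {missing}")
        keep = [i for i, c in enumerate(self.channels) if c in want]
        return replace(self, cycles=self.cycles[:, :, keep],
                       channels=[self.channels[i] for i in keep],
                       provenance=self.provenance.copy())

    def subset(self, mask: np.ndarray) -> "CycleSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(self, cycles=self.cycles[idx], labels=self.labels[idx],
                       provenance=self.provenance.iloc[idx].reset_index(drop=True))

    @staticmethod
    def concat(sets: list["CycleSet"]) -> "CycleSet":
        sets = [s for s in sets if s.n_cycles]
        if not sets:
            raise ValidationError("nothing to concatenate")
        ref = sets[0]
        for s in sets[1:]:
            if s.channels != ref.channels or s.target_len != ref.target_len:
                raise ValidationError("cycle sets differ in channels or length")
        return replace(
            ref,
            cycles=np.concatenate([s.cycles for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            provenance=pd.concat([s.provenance for s in sets], ignore_index=True),
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "cycles.npy", self.cycles)
        manifest = self.provenance.copy()
        manifest.insert(0, "cycle_id", np.arange(self.n_cycles))
        manifest["label"] = self.labels
        manifest.to_csv(out / "manifest.csv", index=False)
        meta = {"channels": self.channels, "sample_rate_hz": self.sample_rate_hz}
        (out / "meta.json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(in_dir) -> "CycleSet":
        src = Path(in_dir)
        cycles = np.load(src / "cycles.npy")
        manifest = pd.read_csv(src / "manifest.csv")
        meta = json.loads((src / "meta.json").read_text())
        labels = manifest["label"].to_numpy()
        prov = manifest[CycleSet._PROV_COLS]
        return CycleSet(cycles, labels, list(meta["channels"]), prov,
                        sample_rate_hz=float(meta["sample_rate_hz"]))


def _empty_provenance() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("int64" if c.endswith(("frame", "len")) else "object"))
                         for c in CycleSet._PROV_COLS})


def build_cycle_set(
    segments: list[tuple[Recording, int]],
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL,
    filter_spec: FilterSpec = FilterSpec(),
    min_period_frames: int | None = None,
    min_prominence_frac: float = 0.3,
    target_len: int = DEFAULT_TARGET_LEN,
    source: str = "",
) -> CycleSet:
    """Detect cycles segment by segment and stack the resampled slices.

    Peaks are detected on the (filtered) reference channel *within each
    segment only*, so no cycle ever spans an excised gap.  Partial cycles
    before the first and after the last peak are discarded.  Raw inter-peak
    slices are resampled to ``target_len``; the filtered signal is never
    stored.  A segment with fewer than two peaks is skipped with a warning.
    """
    mats, labels, prov = [], [], []
    channels, fs = None, 240.0
    for seg, lab in segments:
        if channels is None:
            channels, fs = list(seg.channels), seg.sample_rate_hz
        try:
            peaks = detect_cycle_peaks(seg, reference_channel, filter_spec,
                                       min_period_frames, min_prominence_frac)
        except (NoCyclesError, ValidationError) as err:
            warnings.warn(f"skipping {TECHNIQUES[lab][0]} segment of {seg.n_frames} frames: {err}")
            continue
        for a, b in zip(peaks[:-1], peaks[1:]):
            mats.append(resample_cycle(seg.values[a:b], target_len, fs).astype(np.float32))
            labels.append(lab)
            prov.append((seg.subject_id, seg.course, style_of(lab), source, int(a), int(b), int(b - a)))
    if not mats:
        C = len(channels) if channels else 0
        return CycleSet(np.empty((0, target_len, C), np.float32), np.empty(0, np.int64),
                        channels or [], _empty_provenance(), sample_rate_hz=fs)
    return CycleSet(
        np.stack(mats), np.asarray(labels),
        channels, pd.DataFrame(prov, columns=CycleSet._PROV_COLS), sample_rate_hz=fs,
    )


def segment_recording(rec: Recording, track: LabelTrack, source: str = "", **kwargs) -> CycleSet:
    """Convenience wrapper: excise noise then build the cycle set."""
    return build_cycle_set(excise_noise(rec, track), source=source or rec.subject_id, **kwargs)
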