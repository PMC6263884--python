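"""Synthetic multi-subject gyroscope recordings with ground-truth labels.

Real multi-tracker recordings of skiing techniques are not publicly
deposited, so every end-to-end path in this package is exercised on a
simulator that emulates the *structure* of such data rather than its
biomechanics: each technique is a fixed template of low-order harmonic
waveforms per channel (class-discriminative, strongest on the hands and
feet, weakest at the pelvis), each subject perturbs the templates with
per-tracker amplitude scaling, a personal tempo with per-cycle jitter, and
additive white noise, and each file interleaves technique blocks with
non-technique noise segments (turning on flat courses, descending on
natural ones) plus unlabeled transition gaps.

Two deliberate design points mirror well-known properties of the real
task: a confusable technique pair (the push-off / double-poling analog)
shares every non-extremity waveform and differs only partially in the
hand/foot channels, and pelvis channels carry a mostly style-shared
waveform so a pelvis-only sensor configuration is genuinely
information-poor.

All randomness derives from one integer seed through per-file
``numpy.random.SeedSequence`` streams, so a dataset is reproducible file by
file on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import io as skio
from .io import TECHNIQUES, TRACKERS, TURN, LabelTrack, Recording, ValidationError
from .segmentation import DEFAULT_REFERENCE_CHANNEL, CycleSet, segment_recording

__all__ = [
    "N_HARMONICS", "REFERENCE_CHANNEL", "TechniqueTemplate", "SubjectProfile",
    "FileRecipe", "SimPlan", "default_templates", "default_profiles",
    "make_confusable_pair", "generate_recording", "generate_dataset",
    "build_cycles", "default_plan", "make_census_fixture", "FIXTURE_CYCLE_COUNTS",
]

N_HARMONICS = 3
REFERENCE_CHANNEL = DEFAULT_REFERENCE_CHANNEL
_CHANNELS = skio.all_channels()
_C = len(_CHANNELS)

#: Trackers whose waveforms are mostly shared within a style (the body core).
TORSO_TRACKERS = ("pelvis", "chest", "head")
#: Extremity trackers that carry the strongest class signature.
LIMB_TRACKERS = ("right_hand", "left_hand", "right_foot", "left_foot")

_TEMPLATE_ENTROPY = 903819  # fixed: templates are constants, not draws
#: Per-technique tempo multipliers (mean cycle length varies by technique).
_TEMPO_FACTOR = {1: 1.10, 2: 0.90, 3: 1.05, 4: 0.95, 5: 1.00, 6: 1.08, 7: 0.92, 8: 1.00}
_CONFUSABLE_SIMILARITY = 0.90  # push-off analog vs double-poling analog


@dataclass(frozen=True)
class TechniqueTemplate:
    """Canonical one-cycle waveform of a technique.

    ``amps``/``phases`` have shape (51, N_HARMONICS): channel c is
    ``sum_j amps[c, j] * cos(2*pi*(j+1)*t + phases[c, j])`` for cycle phase
    t in [0, 1).  The reference channel keeps a unit fundamental with zero
    phase in every template so its filtered peak marks the cycle start.
    """

    code: int
    amps: np.ndarray
    phases: np.ndarray
    tempo_factor: float = 1.0
    confusable_with: int | None = None
    similarity: float | None = None

    @property
    def name(self) -> str:
        return TECHNIQUES[self.code][0]

    @property
    def style(self) -> str:
        return TECHNIQUES[self.code][1]

    def waveform(self, n: int) -> np.ndarray:
        """Evaluate one cycle of n frames over all 51 channels."""
        t = np.arange(n)[:, None, None] / n
        j = np.arange(1, N_HARMONICS + 1)[None, None, :]
        return (self.amps[None] * np.cos(2 * np.pi * j * t + self.phases[None])).sum(axis=2)

    def channel_waveform(self, channel: str, n: int) -> np.ndarray:
        return self.waveform(n)[:, _CHANNELS.index(channel)]


def _tracker_of(idx: int) -> str:
    return skio.parse_channel(_CHANNELS[idx])[0]


_TRACKER_IDX = {t: [i for i in range(_C) if _tracker_of(i) == t] for t in TRACKERS}
_TORSO_COLS = [i for t in TORSO_TRACKERS for i in _TRACKER_IDX[t]]
_LIMB_COLS = [i for t in LIMB_TRACKERS for i in _TRACKER_IDX[t]]
_MID_COLS = [i for i in range(_C) if i not in _TORSO_COLS and i not in _LIMB_COLS]

#: Weight of the style-shared waveform per channel group.  Torso channels
#: are almost entirely style-shared (the body core moves alike across
#: techniques of a style), mid-body segments mostly follow the core, and
#: the extremities are fully class-specific -- so hands/feet carry the
#: class signature and the other trackers add little beyond it.
_STYLE_BLEND_TORSO = 0.9
_STYLE_BLEND_MID = 0.75
_REF_COL = _CHANNELS.index(REFERENCE_CHANNEL)

# amplitude ceilings per channel group; pelvis/torso <= limbs by design
_GROUP_SCALE = np.full(_C, 0.6)
_GROUP_SCALE[_LIMB_COLS] = 1.0
_GROUP_SCALE[_TORSO_COLS] = 0.35
_HARMONIC_DECAY = np.array([1.0, 0.5, 0.25])


def _random_coeffs(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    amps = rng.uniform(0.4, 1.0, size=(_C, N_HARMONICS)) * _GROUP_SCALE[:, None] * _HARMONIC_DECAY
    phases = rng.uniform(0, 2 * np.pi, size=(_C, N_HARMONICS))
    return amps, phases


def _style_base(style: str) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence(
        [_TEMPLATE_ENTROPY, 0 if style == "classical" else 1]))
    return _random_coeffs(rng)


def _anchor_reference(amps: np.ndarray, phases: np.ndarray) -> None:
    amps[_REF_COL] = np.array([1.0, 0.12, 0.0])
    phases[_REF_COL] = 0.0


def _blend(a_amps, a_phases, b_amps, b_phases, w: float):
    """Interpolate harmonic coefficients in the complex plane with weight w
    on the first template (w=1 -> first, w=0 -> second)."""
    za = a_amps * np.exp(1j * a_phases)
    zb = b_amps * np.exp(1j * b_phases)
    z = w * za + (1 - w) * zb
    return np.abs(z), np.angle(z)


def _make_template(code: int, rng: np.random.Generator) -> TechniqueTemplate:
    style = TECHNIQUES[code][1]
    base_amps, base_phases = _style_base(style)
    own_amps, own_phases = _random_coeffs(rng)
    amps, phases = own_amps.copy(), own_phases.copy()
    # torso channels: mostly the shared style waveform, small class flavor
    for cols, w in ((_TORSO_COLS, _STYLE_BLEND_TORSO), (_MID_COLS, _STYLE_BLEND_MID)):
        amps[cols], phases[cols] = _blend(
            base_amps[cols], base_phases[cols], own_amps[cols], own_phases[cols], w)
    _anchor_reference(amps, phases)
    return TechniqueTemplate(code, amps, phases, _TEMPO_FACTOR[code])


def make_confusable_pair(base: TechniqueTemplate, similarity: float,
                         code: int, rng: np.random.Generator | None = None
                         ) -> TechniqueTemplate:
    """Derive a technique template that is confusable with ``base``.

    For similarity s > 0 every non-extremity channel (torso, pelvis, arms,
    legs) is copied from the base -- the two motions differ only in their
    limb dynamics -- while the extremity (hand/foot) channels interpolate
    their harmonic coefficients toward the base with weight s.  s = 1 gives
    an identical template; s = 0 gives a fully independent one.
    """
    if not 0 <= similarity <= 1:
        raise ValidationError("similarity must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([_TEMPLATE_ENTROPY, 77, code])) \
        if rng is None else rng
    own_amps, own_phases = _random_coeffs(rng)
    if similarity > 0:
        amps, phases = base.amps.copy(), base.phases.copy()
        amps[_LIMB_COLS], phases[_LIMB_COLS] = _blend(
            base.amps[_LIMB_COLS], base.phases[_LIMB_COLS],
            own_amps[_LIMB_COLS], own_phases[_LIMB_COLS], similarity)
    else:
        amps, phases = own_amps, own_phases
    _anchor_reference(amps, phases)
    return TechniqueTemplate(code, amps, phases, _TEMPO_FACTOR[code],
                             confusable_with=base.code, similarity=similarity)


def default_templates() -> dict[int, TechniqueTemplate]:
    """The eight shipped technique templates (fixed constants).

    The push-off analog (code 2) is built from the double-poling analog
    (code 4) with a high fixed similarity, reproducing the pair of techniques that
    differ only in limb dynamics.
    """
    templates: dict[int, TechniqueTemplate] = {}
    for code in sorted(TECHNIQUES):
        if code == 2:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([_TEMPLATE_ENTROPY, 10, code]))
        templates[code] = _make_template(code, rng)
    templates[2] = make_confusable_pair(templates[4], _CONFUSABLE_SIMILARITY, code=2)
    return dict(sorted(templates.items()))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject rendering parameters.

    amplitude_scale : per-tracker gain in [0.7, 1.3] (subjects move with
    different vigor per body part); tempo_mean : mean cycle length in frames
    before the per-technique factor; tempo_jitter : per-cycle s.d. as a
    fraction of the mean; noise_sigma : additive white-noise s.d. in rad/s,
    the same for every channel (so weak channels have poorer SNR).
    """

    subject_id: str
    amplitude_scale: dict[str, float]
    tempo_mean: float = 333.0
    tempo_jitter: float = 0.05
    noise_sigma: float = 0.10

    def scale_vector(self) -> np.ndarray:
        return np.array([self.amplitude_scale[_tracker_of(i)] for i in range(_C)])


def default_profiles(subject_ids: list[str], seed: int) -> dict[str, SubjectProfile]:
    """Draw one profile per subject from the dataset seed."""
    profiles = {}
    for i, sid in enumerate(subject_ids):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 500, i]))
        scale = {t: float(rng.uniform(0.7, 1.3)) for t in TRACKERS}
        tempo = float(rng.uniform(300, 366))
        profiles[sid] = SubjectProfile(sid, scale, tempo_mean=tempo)
    return profiles


@dataclass(frozen=True)
class FileRecipe:
    """One simulated recording: a sequence of technique blocks on a course."""

    subject: str
    course: str
    style: str
    blocks: tuple[tuple[int, int], ...]  # (technique code, n_cycles)

    def __post_init__(self):
        for code, n in self.blocks:
            if TECHNIQUES[code][1] != self.style:
                raise ValidationError(
                    f"technique {TECHNIQUES[code][0]} is not {self.style} style")
            if n < 1:
                raise ValidationError("each block needs at least one cycle")


@dataclass(frozen=True)
class SimPlan:
    files: tuple[FileRecipe, ...]

    @property
    def subjects(self) -> list[str]:
        return sorted({f.subject for f in self.files})


def _wander(rng, n: int, sigma: float) -> np.ndarray:
    """Low-amplitude broadband wander (smoothed white noise), all channels."""
    return uniform_filter1d(rng.normal(0.0, sigma * 3, size=(n, _C)), 9, axis=0)


def _drift(rng, n: int, fs: float) -> np.ndarray:
    """Slow low-frequency drift for descending segments."""
    f = rng.uniform(0.05, 0.2)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi, size=_C)
    amp = rng.uniform(0.1, 0.3, size=_C)
    return amp[None, :] * np.sin(2 * np.pi * f * t[:, None] + phase[None, :]) \
        + rng.normal(0.0, 0.03, size=(n, _C))


def generate_recording(recipe: FileRecipe, templates: dict[int, TechniqueTemplate],
                       profile: SubjectProfile, seed: int, file_key: int = 0,
                       sample_rate_hz: float = 240.0
                       ) -> tuple[Recording, LabelTrack, np.ndarray]:
    """Render one recording.

    Returns the recording, its label track, and the ground-truth cycle start
    frames (one entry per generated cycle, absolute frame indices).
    Fully reproducible from ``(seed, file_key)``.
    """
    for code, _ in recipe.blocks:
        if code not in templates:
            raise ValidationError(f"no template for technique code {code}")
    if not recipe.blocks:
        raise ValidationError("recipe has no technique blocks")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9000, file_key]))
    fs = sample_rate_hz
    scale = profile.scale_vector()[None, :]
    chunks: list[np.ndarray] = []
    intervals: list[tuple[int, int, object]] = []
    boundaries: list[int] = []
    cursor = 0

    def emit(block: np.ndarray, label=None):
        nonlocal cursor
        if label is not None:
            intervals.append((cursor, cursor + len(block), label))
        chunks.append(block)
        cursor += len(block)

    emit(_wander(rng, int(rng.uniform(0.8, 1.5) * fs), 0.05), label=0)
    noise_label = TURN if recipe.course == "flat" else 9
    for b, (code, n_cycles) in enumerate(recipe.blocks):
        if b > 0:
            emit(rng.normal(0.0, 0.05, size=(int(0.2 * fs), _C)))  # unlabeled transition
            if noise_label == TURN:
                emit(_wander(rng, int(rng.uniform(1.0, 2.0) * fs), 0.08), label=TURN)
            else:
                emit(_drift(rng, int(rng.uniform(1.0, 2.0) * fs), fs), label=9)
            emit(rng.normal(0.0, 0.05, size=(int(0.2 * fs), _C)))
        template = templates[code]
        base_len = profile.tempo_mean * template.tempo_factor
        block_start = cursor
        rows = []
        for _ in range(n_cycles):
            n = max(int(round(base_len * (1.0 + profile.tempo_jitter * rng.standard_normal()))), 8)
            wave = template.waveform(n) * scale
            if profile.noise_sigma > 0:
                wave = wave + rng.normal(0.0, profile.noise_sigma, size=wave.shape)
            boundaries.append(cursor + sum(len(r) for r in rows))
            rows.append(wave)
        emit(np.concatenate(rows), label=code)
        del block_start
    emit(_wander(rng, int(rng.uniform(0.8, 1.5) * fs), 0.05), label=0)

    values = np.concatenate(chunks)
    rec = Recording(subject_id=recipe.subject, course=recipe.course,
                    values=values, channels=list(_CHANNELS), sample_rate_hz=fs)
    track = LabelTrack(intervals)
    track.validate_against(rec)
    return rec, track, np.asarray(boundaries)


def generate_dataset(plan: SimPlan, seed: int,
                     templates: dict[int, TechniqueTemplate] | None = None,
                     profiles: dict[str, SubjectProfile] | None = None
                     ) -> list[tuple[Recording, LabelTrack, np.ndarray]]:
    """Render every file of a plan; file_key is the file's index in the plan."""
    templates = default_templates() if templates is None else templates
    profiles = default_profiles(plan.subjects, seed) if profiles is None else profiles
    return [generate_recording(recipe, templates, profiles[recipe.subject], seed, file_key=i)
            for i, recipe in enumerate(plan.files)]


def build_cycles(plan: SimPlan, seed: int,
                 templates: dict[int, TechniqueTemplate] | None = None,
                 profiles: dict[str, SubjectProfile] | None = None,
                 **segment_kwargs) -> CycleSet:
    """Generate a plan and push every file through the segmentation pipeline.

    Files are rendered and segmented one at a time so only the cycle tensors
    stay in memory.
    """
    templates = default_templates() if templates is None else templates
    profiles = default_profiles(plan.subjects, seed) if profiles is None else profiles
    sets = []
    for i, recipe in enumerate(plan.files):
        rec, track, _ = generate_recording(recipe, templates, profiles[recipe.subject],
                                           seed, file_key=i)
        cs = segment_recording(rec, track, source=f"file{i:02d}", **segment_kwargs)
        if cs.n_cycles:
            sets.append(cs)
    return CycleSet.concat(sets)


def default_plan(n_subjects: int = 3, cycles_per_block: int = 12) -> SimPlan:
    """The shipped study design: per subject, one flat file per style (all
    four techniques, turning segments between blocks) and one natural file
    per style with the technique menu thinned the way real course preference
    thins it (no free-skate analog and no push-off analog on the natural
    course), giving the class-imbalance regime across courses."""
    c = cycles_per_block
    files = []
    for i in range(1, n_subjects + 1):
        sid = f"S{i}"
        files += [
            FileRecipe(sid, "flat", "classical", ((1, c), (2, c), (3, c), (4, c))),
            FileRecipe(sid, "flat", "skating", ((5, c), (6, c), (7, c), (8, c))),
            FileRecipe(sid, "natural", "classical", ((1, c), (3, c), (4, c))),
            FileRecipe(sid, "natural", "skating", ((5, c), (6, c), (7, c))),
        ]
    return SimPlan(tuple(files))


#: Per-subject, per-technique cycle counts of the bundled bookkeeping
#: fixture (three subjects x eight techniques; row sums 960/568/539,
#: grand total 2067).
FIXTURE_CYCLE_COUNTS = {
    "skier1": {1: 153, 2: 123, 3: 107, 4: 128, 5: 85, 6: 104, 7: 157, 8: 103},
    "skier2": {1: 103, 2: 83, 3: 94, 4: 68, 5: 38, 6: 56, 7: 65, 8: 61},
    "skier3": {1: 83, 2: 64, 3: 64, 4: 78, 5: 48, 6: 59, 7: 86, 8: 57},
}


def fixture_plan() -> SimPlan:
    """24 single-technique flat-course files (3 subjects x 8 techniques).

    Each file carries ``count + 2`` rendered cycles because peak-to-peak
    segmentation discards the leading and trailing partial cycles; the
    pipeline therefore recovers exactly ``count`` cycles per file.
    """
    files = []
    for sid, counts in FIXTURE_CYCLE_COUNTS.items():
        for code, count in counts.items():
            files.append(FileRecipe(sid, "flat", TECHNIQUES[code][1], ((code, count + 2),)))
    return SimPlan(tuple(files))


def make_census_fixture(seed: int) -> list[tuple[Recording, LabelTrack]]:
    """Generate the 24-file bookkeeping fixture for a given seed."""
    return [(rec, track) for rec, track, _ in generate_dataset(fixture_plan(), seed)]
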