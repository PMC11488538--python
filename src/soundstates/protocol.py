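"""Stimulus battery and session schedule construction.

The battery holds 307 short sounds (< 500 ms) split into eight categories
with fixed counts.  A session presents every short sound 12 times, in random
order, packed into blocks of 30 trials with 1-s onset spacing; 20 long
"natural" segments are interleaved between blocks, and every pair of
consecutive segments is separated by a silent gap of at least 3 s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UnsupportedStimulusError

__all__ = [
    "CATEGORIES",
    "CATEGORY_COUNTS",
    "SoundStimulus",
    "StimulusSet",
    "Segment",
    "Gap",
    "SessionSchedule",
    "pure_tone_frequencies",
    "build_stimulus_set",
    "build_session_schedule",
    "stimulus_envelope",
    "level_trajectory",
    "write_stimulus_csv",
    "read_stimulus_csv",
    "write_schedule_csv",
    "read_schedule_csv",
]

CATEGORIES = (
    "pure_tone",
    "ramp",
    "chord",
    "chirp",
    "white_noise",
    "am",
    "complex",
    "decomposition",
)

#: Number of sounds per category; sums to 307.
CATEGORY_COUNTS: dict[str, int] = {
    "pure_tone": 28,
    "ramp": 26,
    "chord": 48,
    "chirp": 20,
    "white_noise": 30,
    "am": 48,
    "complex": 60,
    "decomposition": 47,
}

FREQ_LO_KHZ = 2.0
FREQ_HI_KHZ = 80.0
LEVELS_DB = (50.0, 70.0)
EDGE_RAMP_S = 0.010  # cosine on/off ramp applied to every sound


@dataclass(frozen=True)
class SoundStimulus:
    """One short sound.

    ``level_db`` is a float for statically leveled sounds and a
    ``(start, end)`` pair for sounds whose level ramps linearly in dB over
    the duration.  ``frequency_params`` holds the category-specific spectral
    description (component frequencies, bands, modulation frequency, sweep
    endpoints) with frequencies in kHz.
    """

    sound_id: int
    category: str
    level_db: float | tuple[float, float]
    duration_s: float
    frequency_params: dict
    direction: str = "none"  # {"up", "down", "none"}

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"unknown category {self.category!r}")
        if not 0.0 < self.duration_s <= 0.5:
            raise InvalidParameterError(
                f"duration_s must be in (0, 0.5], got {self.duration_s}"
            )
        if self.direction not in ("up", "down", "none"):
            raise InvalidParameterError(f"bad direction {self.direction!r}")

    @property
    def is_level_ramped(self) -> bool:
        return isinstance(self.level_db, tuple)


@dataclass(frozen=True)
class StimulusSet:
    stimuli: tuple[SoundStimulus, ...]

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for s in self.stimuli:
            counts[s.category] += 1
        return counts

    @property
    def sound_ids(self) -> list[int]:
        return [s.sound_id for s in self.stimuli]

    def __len__(self) -> int:
        return len(self.stimuli)

    def __getitem__(self, sound_id: int) -> SoundStimulus:
        return self._by_id[sound_id]

    @property
    def _by_id(self) -> dict[int, SoundStimulus]:
        return {s.sound_id: s for s in self.stimuli}

    def by_category(self, category: str) -> list[SoundStimulus]:
        return [s for s in self.stimuli if s.category == category]

    def durations(self) -> dict[int, float]:
        return {s.sound_id: s.duration_s for s in self.stimuli}


@dataclass(frozen=True)
class Segment:
    kind: str  # {"block", "natural"}
    index: int
    start_s: float
    end_s: float
    trial_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class Gap:
    start_s: float
    duration_s: float


@dataclass
class SessionSchedule:
    segments: list[Segment]
    trials: pd.DataFrame  # trial_index, sound_id, onset_s, segment_index, state_label
    gaps: list[Gap]
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return sum(1 for s in self.segments if s.kind == "block")

    @property
    def n_natural(self) -> int:
        return sum(1 for s in self.segments if s.kind == "natural")

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    def trials_for_sound(self, sound_id: int) -> pd.DataFrame:
        return self.trials[self.trials["sound_id"] == sound_id]


def pure_tone_frequencies(n: int = 14, lo_khz: float = 2.0, hi_khz: float = 60.0) -> np.ndarray:
    """The pure-tone frequency grid: ``n`` log-spaced values on [lo, hi] kHz."""
    return np.geomspace(lo_khz, hi_khz, n)


def _chord_frequencies(rng: np.random.Generator, lo: float, hi: float, n_comp: int) -> list[float]:
    # components log-uniform in the group's band, kept >= 1/6 octave apart
    for _ in range(100):
        f = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), n_comp)))
        if n_comp == 1 or np.all(np.diff(np.log2(f)) >= 1 / 6):
            return [float(x) for x in f]
    return [float(x) for x in f]  # pragma: no cover - fallback


def build_stimulus_set(seed: int = 0) -> StimulusSet:
    """Build the full 307-sound battery.

    The seed only affects free parameters (exact chord/chirp/noise frequency
    draws, textures); category counts and the pure-tone grid are fixed.
    """
    rng = np.random.default_rng(seed)
    stimuli: list[SoundStimulus] = []
    sid = 0

    def add(category, level_db, duration_s, params, direction="none"):
        nonlocal sid
        stimuli.append(
            SoundStimulus(sid, category, level_db, duration_s, params, direction)
        )
        sid += 1

    # --- 28 pure tones: 14 log-spaced frequencies x 2 levels
    pt_freqs = pure_tone_frequencies()
    for f in pt_freqs:
        for level in LEVELS_DB:
            add("pure_tone", level, 0.25, {"frequencies_khz": [float(f)]})

    # --- 26 ramps: the 13 pure-tone frequencies <= 50 kHz, up and down in level
    ramp_freqs = [float(f) for f in pt_freqs if f <= 50.0]
    assert len(ramp_freqs) == 13
    for f in ramp_freqs:
        add("ramp", (50.0, 70.0), 0.5, {"frequencies_khz": [f]}, direction="up")
        add("ramp", (70.0, 50.0), 0.5, {"frequencies_khz": [f]}, direction="down")

    # --- 48 chords: 11 low + 11 medium + 11 high + 10 broad + 5 harmonic
    chord_groups = (
        ("low", 2.0, 8.0, 11),
        ("medium", 8.0, 20.0, 11),
        ("high", 20.0, 60.0, 11),
        ("broad", 2.0, 60.0, 10),
    )
    chord_freq_lists: list[list[float]] = []
    for name, lo, hi, count in chord_groups:
        for _ in range(count):
            n_comp = int(rng.integers(2, 5))
            freqs = _chord_frequencies(rng, lo, hi, n_comp)
            chord_freq_lists.append(freqs)
            add("chord", 70.0, 0.25, {"frequencies_khz": freqs, "group": name})
    for _ in range(5):
        f0 = float(rng.uniform(2.0, 10.0))
        n_harm = int(rng.integers(3, 5))
        freqs = [f0 * k for k in range(1, n_harm + 1) if f0 * k <= 60.0]
        chord_freq_lists.append(freqs)
        add("chord", 70.0, 0.25, {"frequencies_khz": freqs, "group": "harmonic"})

    # --- 20 chirps: 10 fixed-band sweeps of varying duration + 10 varying-band 500-ms sweeps
    for dur in (0.025, 0.05, 0.1, 0.2, 0.4):
        add("chirp", 50.0, dur, {"sweep_khz": [6.0, 12.0]}, direction="up")
        add("chirp", 50.0, dur, {"sweep_khz": [12.0, 6.0]}, direction="down")
    for i in range(10):
        lo = float(rng.uniform(4.0, 20.0))
        hi = float(min(50.0, lo * 2 ** rng.uniform(0.5, 3.0)))
        sweep = [lo, hi] if i % 2 == 0 else [hi, lo]
        add(
            "chirp",
            50.0,
            0.5,
            {"sweep_khz": sweep},
            direction="up" if i % 2 == 0 else "down",
        )

    # --- 30 noises: 6 broadband (2 static + 4 level-ramped) + 14 filtered + 10 ramped band pairs
    for level in LEVELS_DB:
        add("white_noise", level, 0.5, {"bands_khz": [[FREQ_LO_KHZ, FREQ_HI_KHZ]]})
    for dur in (0.1, 0.5):
        add("white_noise", (50.0, 70.0), dur, {"bands_khz": [[FREQ_LO_KHZ, FREQ_HI_KHZ]]}, "up")
        add("white_noise", (70.0, 50.0), dur, {"bands_khz": [[FREQ_LO_KHZ, FREQ_HI_KHZ]]}, "down")
    for i in range(14):
        lo = float(np.exp(rng.uniform(np.log(2.0), np.log(40.0))))
        hi = float(min(FREQ_HI_KHZ, lo * 2 ** rng.uniform(0.5, 3.0)))
        add("white_noise", LEVELS_DB[i % 2], 0.25, {"bands_khz": [[lo, hi]]})
    pair_sources = [chord_freq_lists[int(i)] for i in rng.choice(len(chord_freq_lists), 5, replace=False)]
    for freqs in pair_sources:
        two = sorted(freqs[:2])
        bands = [[max(FREQ_LO_KHZ, f - 0.5), min(FREQ_HI_KHZ, f + 0.5)] for f in two]
        add("white_noise", (50.0, 70.0), 0.5, {"bands_khz": bands}, "up")
        add("white_noise", (70.0, 50.0), 0.5, {"bands_khz": bands}, "down")

    # --- 48 AM sounds: 6 modulation frequencies x 8 carriers
    mod_freqs = np.geomspace(4.0, 160.0, 6)
    carrier_tones = [float(pt_freqs[int(i)]) for i in rng.choice(len(pt_freqs), 2, replace=False)]
    carrier_chords = [chord_freq_lists[int(i)] for i in rng.choice(len(chord_freq_lists), 5, replace=False)]
    carriers: list[dict] = (
        [{"frequencies_khz": [f]} for f in carrier_tones]
        + [{"frequencies_khz": list(freqs)} for freqs in carrier_chords]
        + [{"bands_khz": [[FREQ_LO_KHZ, FREQ_HI_KHZ]]}]
    )
    for fm in mod_freqs:
        for carrier in carriers:
            params = {"modulation_hz": float(fm), **carrier}
            add("am", 70.0, 0.5, params)

    # --- 60 complex sounds: 15 base textures x {forward, reversed} x {50, 70} dB
    complex_bands = []
    for _ in range(15):
        lo = float(np.exp(rng.uniform(np.log(2.0), np.log(20.0))))
        hi = float(min(FREQ_HI_KHZ, lo * 2 ** rng.uniform(1.0, 4.0)))
        complex_bands.append((lo, hi, int(rng.integers(0, 2**31))))
    for base_idx, (lo, hi, tex) in enumerate(complex_bands):
        for reversed_ in (False, True):
            for level in LEVELS_DB:
                add(
                    "complex",
                    level,
                    0.45,
                    {
                        "band_khz": [lo, hi],
                        "texture_seed": tex,
                        "base_index": base_idx,
                        "reversed": reversed_,
                    },
                )

    # --- 47 decomposition sounds: snippets of 4 parent complex sounds + 4 compositions
    parent_indices = [int(i) for i in rng.choice(15, 4, replace=False)]
    snippet_counts = (11, 11, 11, 10)
    for parent, n_snip in zip(parent_indices, snippet_counts):
        lo, hi, tex = complex_bands[parent]
        for j in range(n_snip):
            sub_lo = float(np.exp(rng.uniform(np.log(lo), np.log(max(lo, hi / 1.5)))))
            sub_hi = float(min(hi, sub_lo * 2 ** rng.uniform(0.3, 1.5)))
            add(
                "decomposition",
                70.0,
                float(rng.uniform(0.05, 0.3)),
                {
                    "band_khz": [sub_lo, sub_hi],
                    "texture_seed": tex + 1 + j,
                    "parent": parent,
                    "piece": "snippet",
                },
            )
        add(
            "decomposition",
            70.0,
            0.45,
            {"band_khz": [lo, hi], "texture_seed": tex, "parent": parent, "piece": "composition"},
        )

    out = StimulusSet(tuple(stimuli))
    assert len(out) == 307, len(out)
    assert out.category_counts == CATEGORY_COUNTS
    return out


def build_session_schedule(
    stimulus_set: StimulusSet,
    n_reps: int = 12,
    block_size: int = 30,
    onset_interval_s: float = 1.0,
    n_natural: int = 20,
    natural_duration_s: float = 30.0,
    gap_s: float = 3.0,
    lead_in_s: float = 1.0,
    seed: int = 0,
    state_label: str = "wake",
) -> SessionSchedule:
    """Order ``n_reps`` presentations of every sound into blocks with gaps.

    Trials are shuffled (seeded) and packed into blocks of at most
    ``block_size``; natural segments are inserted at ``n_natural`` distinct
    inter-block positions; a silent gap of ``gap_s`` seconds separates every
    pair of consecutive segments.
    """
    if block_size <= 0:
        raise InvalidParameterError(f"block_size must be positive, got {block_size}")
    if n_reps <= 0:
        raise InvalidParameterError(f"n_reps must be positive, got {n_reps}")
    if gap_s < 3.0:
        raise InvalidParameterError(f"gap_s must be >= 3 s, got {gap_s}")

    rng = np.random.default_rng(seed)
    sound_ids = np.repeat(np.array(stimulus_set.sound_ids), n_reps)
    order = rng.permutation(len(sound_ids))
    sound_ids = sound_ids[order]

    n_trials = len(sound_ids)
    n_blocks = math.ceil(n_trials / block_size)
    block_slices = [
        sound_ids[i * block_size : (i + 1) * block_size] for i in range(n_blocks)
    ]

    # natural segments sit between blocks, at distinct interior positions
    if n_natural > max(0, n_blocks - 1):
        raise InvalidParameterError(
            f"cannot place {n_natural} natural segments between {n_blocks} blocks"
        )
    natural_after = set(
        int(i) for i in rng.choice(n_blocks - 1, n_natural, replace=False)
    ) if n_natural else set()

    segments: list[Segment] = []
    gaps: list[Gap] = []
    rows = []
    t = float(lead_in_s)  # silent lead-in; not an inter-segment gap
    trial_index = 0
    seg_index = 0

    def close_gap():
        nonlocal t
        gaps.append(Gap(start_s=t, duration_s=gap_s))
        t += gap_s

    for b, block_sounds in enumerate(block_slices):
        if seg_index > 0:
            close_gap()
        start = t
        trial_idx_here = []
        for s in block_sounds:
            rows.append((trial_index, int(s), t, seg_index, state_label))
            trial_idx_here.append(trial_index)
            trial_index += 1
            t += onset_interval_s
        segments.append(Segment("block", seg_index, start, t, tuple(trial_idx_here)))
        seg_index += 1
        if b in natural_after:
            close_gap()
            segments.append(Segment("natural", seg_index, t, t + natural_duration_s))
            t += natural_duration_s
            seg_index += 1

    trials = pd.DataFrame(
        rows, columns=["trial_index", "sound_id", "onset_s", "segment_index", "state_label"]
    )
    return SessionSchedule(segments=segments, trials=trials, gaps=gaps, seed=seed)


# ---------------------------------------------------------------------------
# envelopes


def level_trajectory(stim: SoundStimulus, t: np.ndarray) -> np.ndarray:
    """Sound level (dB SPL) at times ``t`` within [0, duration]."""
    if stim.is_level_ramped:
        l0, l1 = stim.level_db
        return l0 + (l1 - l0) * np.clip(t / stim.duration_s, 0.0, 1.0)
    return np.full_like(np.asarray(t, dtype=float), float(stim.level_db))


def _edge_window(t: np.ndarray, duration_s: float, ramp_s: float = EDGE_RAMP_S) -> np.ndarray:
    """10-ms raised-cosine onset/offset ramps, amplitude scale in [0, 1]."""
    w = np.ones_like(t)
    rise = t < ramp_s
    fall = t > duration_s - ramp_s
    w[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / ramp_s))
    w[fall] = 0.5 * (1 - np.cos(np.pi * (duration_s - t[fall]).clip(0) / ramp_s))
    w[(t < 0) | (t > duration_s)] = 0.0
    return w


def texture_profile(texture_seed: int, t: np.ndarray, duration_s: float, reversed_: bool = False) -> np.ndarray:
    """Smooth deterministic amplitude texture for complex/decomposition sounds."""
    trng = np.random.default_rng(texture_seed)
    n_ctrl = max(3, int(round(duration_s / 0.05)) + 1)
    ctrl = trng.uniform(0.15, 1.0, n_ctrl)
    x = np.clip(t / duration_s, 0.0, 1.0)
    if reversed_:
        x = 1.0 - x
    return np.interp(x, np.linspace(0, 1, n_ctrl), ctrl)


def amplitude_profile(stim: SoundStimulus, t: np.ndarray) -> np.ndarray:
    """Category-specific temporal amplitude modulation (edge ramps included)."""
    prof = _edge_window(t, stim.duration_s)
    if stim.category == "am":
        fm = stim.frequency_params["modulation_hz"]
        prof = prof * 0.5 * (1.0 - np.cos(2 * np.pi * fm * t))
    elif stim.category in ("complex", "decomposition"):
        prof = prof * texture_profile(
            stim.frequency_params["texture_seed"],
            t,
            stim.duration_s,
            stim.frequency_params.get("reversed", False),
        )
    return prof


def chirp_frequency(stim: SoundStimulus, t: np.ndarray) -> np.ndarray:
    """Instantaneous sweep frequency (kHz), log-linear between the endpoints."""
    f0, f1 = stim.frequency_params["sweep_khz"]
    x = np.clip(t / stim.duration_s, 0.0, 1.0)
    return f0 * (f1 / f0) ** x


def stimulus_envelope(
    stim: SoundStimulus, time_step_s: float, freq_grid_khz: Sequence[float]
) -> np.ndarray:
    """Time x frequency energy envelope on a given grid.

    Energy is linear amplitude relative to a 70-dB reference tone; it is
    confined to the stimulus band(s), carries the 10-ms cosine edge ramps,
    and for AM sounds follows the sinusoidal modulation.
    """
    if time_step_s <= 0:
        raise InvalidParameterError("time_step_s must be positive")
    grid = np.asarray(freq_grid_khz, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("freq_grid must be sorted 1-D")
    n_t = max(1, int(round(stim.duration_s / time_step_s)))
    t = (np.arange(n_t) + 0.5) * time_step_s
    amp = 10.0 ** ((level_trajectory(stim, t) - 70.0) / 20.0) * amplitude_profile(stim, t)
    env = np.zeros((n_t, grid.size))

    def nearest_bin(f):
        return int(np.argmin(np.abs(np.log(grid) - np.log(f))))

    cat = stim.category
    if cat in ("pure_tone", "ramp", "chord"):
        for f in stim.frequency_params["frequencies_khz"]:
            env[:, nearest_bin(f)] += amp
    elif cat == "chirp":
        f_t = chirp_frequency(stim, t)
        bins = np.argmin(np.abs(np.log(grid)[None, :] - np.log(f_t)[:, None]), axis=1)
        env[np.arange(n_t), bins] += amp
    elif cat == "white_noise":
        for lo, hi in stim.frequency_params["bands_khz"]:
            sel = (grid >= lo) & (grid <= hi)
            if not sel.any():
                sel[nearest_bin(0.5 * (lo + hi))] = True
            env[:, sel] += amp[:, None] / max(1, sel.sum())
    elif cat == "am":
        if "frequencies_khz" in stim.frequency_params:
            for f in stim.frequency_params["frequencies_khz"]:
                env[:, nearest_bin(f)] += amp
        else:
            for lo, hi in stim.frequency_params["bands_khz"]:
                sel = (grid >= lo) & (grid <= hi)
                env[:, sel] += amp[:, None] / max(1, sel.sum())
    elif cat in ("complex", "decomposition"):
        lo, hi = stim.frequency_params["band_khz"]
        sel = (grid >= lo) & (grid <= hi)
        if not sel.any():
            sel[nearest_bin(0.5 * (lo + hi))] = True
        env[:, sel] += amp[:, None] / max(1, sel.sum())
    else:  # pragma: no cover - SoundStimulus validates categories
        raise UnsupportedStimulusError(f"no envelope model for category {cat!r}")
    return env


# ---------------------------------------------------------------------------
# plain-text persistence


def write_stimulus_csv(stimulus_set: StimulusSet, path) -> None:
    rows = []
    for s in stimulus_set.stimuli:
        rows.append(
            {
                "sound_id": s.sound_id,
                "category": s.category,
                "level_db": json.dumps(s.level_db),
                "duration_s": s.duration_s,
                "direction": s.direction,
                "frequency_params": json.dumps(s.frequency_params),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_stimulus_csv(path) -> StimulusSet:
    df = pd.read_csv(path, float_precision="round_trip")
    stimuli = []
    for _, r in df.iterrows():
        level = json.loads(r["level_db"])
        if isinstance(level, list):
            level = tuple(level)
        stimuli.append(
            SoundStimulus(
                int(r["sound_id"]),
                str(r["category"]),
                level,
                float(r["duration_s"]),
                json.loads(r["frequency_params"]),
                str(r["direction"]),
            )
        )
    return StimulusSet(tuple(stimuli))


def write_schedule_csv(schedule: SessionSchedule, trials_path, segments_path, gaps_path) -> None:
    schedule.trials.to_csv(trials_path, index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {"kind": s.kind, "index": s.index, "start_s": s.start_s, "end_s": s.end_s}
            for s in schedule.segments
        ]
    ).to_csv(segments_path, index=False, float_format="%.17g")
    pd.DataFrame(
        [{"start_s": g.start_s, "duration_s": g.duration_s} for g in schedule.gaps]
    ).to_csv(gaps_path, index=False, float_format="%.17g")


def read_schedule_csv(trials_path, segments_path, gaps_path, seed: int = 0) -> SessionSchedule:
    trials = pd.read_csv(trials_path, float_precision="round_trip").astype(
        {"trial_index": int, "sound_id": int, "onset_s": float, "segment_index": int}
    )
    seg_df = pd.read_csv(segments_path, float_precision="round_trip")
    segments = []
    for _, r in seg_df.iterrows():
        idx = int(r["index"])
        t_idx = tuple(
            int(i) for i in trials.loc[trials["segment_index"] == idx, "trial_index"]
        )
        segments.append(Segment(str(r["kind"]), idx, float(r["start_s"]), float(r["end_s"]), t_idx))
    gap_df = pd.read_csv(gaps_path, float_precision="round_trip")
    gaps = [Gap(float(r["start_s"]), float(r["duration_s"])) for _, r in gap_df.iterrows()]
    return SessionSchedule(segments=segments, trials=trials, gaps=gaps, seed=seed)
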