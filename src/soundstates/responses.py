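"""Per-unit response statistics.

All trial-resolved analysis runs on a ``ResponseTensor``: baseline-subtracted
firing rates binned at 10 ms over a [-0.3, 1.0) s window around sound onset,
with the mean of each trial's pre-onset bins subtracted from that trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .protocol import SessionSchedule, StimulusSet

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTensor",
    "TuningCurve",
    "HalfWidthResult",
    "ResponseChange",
    "baseline_subtract",
    "extract_response_tensor",
    "spontaneous_rate",
    "evoked_modulation",
    "reliability",
    "tuning_curve",
    "best_frequency",
    "half_width_octaves",
    "intensity_threshold",
    "trial_responses_at_sound",
    "classify_response_change",
]


@dataclass
class ResponseTensor:
    """Baseline-subtracted rates, shape (units, sounds, trials, time bins)."""

    values: np.ndarray
    unit_ids: list[int]
    sound_ids: list[int]
    bin_s: float = 0.01
    window: tuple[float, float] = (-0.3, 1.0)

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise InvalidInputError("tensor must be 4-D (units, sounds, trials, bins)")
        expected = int(round((self.window[1] - self.window[0]) / self.bin_s))
        if self.values.shape[3] != expected:
            raise InvalidInputError(
                f"bin count {self.values.shape[3]} inconsistent with window/bin_s ({expected})"
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_sounds(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def n_bins(self) -> int:
        return self.values.shape[3]

    @property
    def onset_bin(self) -> int:
        """Index of the first bin at or after sound onset (t = 0)."""
        return int(round(-self.window[0] / self.bin_s))

    def duration_bins(self, duration_s: float) -> slice:
        """Bin slice covering a sound presentation of the given duration."""
        n = max(1, int(np.ceil(duration_s / self.bin_s)))
        return slice(self.onset_bin, self.onset_bin + n)

    def sound_index(self, sound_id: int) -> int:
        return self.sound_ids.index(sound_id)

    def unit_index(self, unit_id: int) -> int:
        return self.unit_ids.index(unit_id)


@dataclass(frozen=True)
class TuningCurve:
    frequencies_khz: np.ndarray
    response: np.ndarray  # mean baseline-subtracted rate, spk/s
    level_db: float = 70.0

    def __post_init__(self) -> None:
        if len(self.frequencies_khz) != len(self.response):
            raise InvalidInputError("frequency and response lengths differ")
        if len(self.frequencies_khz) == 0:
            raise InvalidInputError("empty tuning curve")


@dataclass(frozen=True)
class HalfWidthResult:
    octaves: float
    censored_low: bool = False
    censored_high: bool = False

    @property
    def censored(self) -> bool:
        return self.censored_low or self.censored_high


class ResponseChange(str, Enum):
    DECREASE = "decrease"
    INCREASE = "increase"
    SIGN_CHANGE = "sign_change"
    NO_CHANGE = "no_change"
    NONRESPONSIVE = "nonresponsive"


def baseline_subtract(values: np.ndarray, onset_bin: int) -> np.ndarray:
    """Subtract each trial's mean pre-onset rate from all of its bins."""
    baseline = values[..., :onset_bin].mean(axis=-1, keepdims=True)
    return values - baseline


def extract_response_tensor(
    spike_trains: Mapping[int, np.ndarray],
    schedule: SessionSchedule,
    bin_s: float = 0.01,
    window: tuple[float, float] = (-0.3, 1.0),
) -> ResponseTensor:
    """Bin spikes around every trial onset and baseline-subtract per trial.

    ``spike_trains`` maps unit id to a sorted array of spike times (objects
    with ``unit_id``/``spike_times_s`` attributes are also accepted as a
    sequence).  Trials whose window extends past the session end are kept;
    a trial window starting before time 0 would be dropped with a warning.
    """
    if not isinstance(spike_trains, Mapping):
        spike_trains = {t.unit_id: t.spike_times_s for t in spike_trains}
    if bin_s <= 0:
        raise InvalidParameterError("bin_s must be positive")
    n_bins = int(round((window[1] - window[0]) / bin_s))
    onset_bin = int(round(-window[0] / bin_s))

    trials = schedule.trials
    bad = trials["onset_s"] + window[0] < 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} trial(s) whose window precedes the session")
        trials = trials[~bad]
    sound_ids = sorted(trials["sound_id"].unique())
    per_sound_onsets = {
        sid: np.sort(trials.loc[trials["sound_id"] == sid, "onset_s"].to_numpy())
        for sid in sound_ids
    }
    counts = {len(v) for v in per_sound_onsets.values()}
    n_trials = min(counts)
    if len(counts) > 1:
        warnings.warn(
            f"unequal trial counts per sound {sorted(counts)}; truncating to {n_trials}"
        )
    onsets = np.stack([per_sound_onsets[sid][:n_trials] for sid in sound_ids])

    edges = (
        onsets[:, :, None] + window[0] + np.arange(n_bins + 1) * bin_s
    )  # (sounds, trials, bins+1)
    unit_ids = sorted(spike_trains)
    values = np.empty((len(unit_ids), len(sound_ids), n_trials, n_bins), dtype=np.float32)
    flat_edges = edges.reshape(-1)
    order = np.argsort(flat_edges, kind="stable")
    for i, uid in enumerate(unit_ids):
        times = np.asarray(spike_trains[uid], dtype=float)
        pos = np.searchsorted(times, flat_edges[order])
        unsorted_pos = np.empty_like(pos)
        unsorted_pos[order] = pos
        cum = unsorted_pos.reshape(edges.shape)
        values[i] = np.diff(cum, axis=-1) / bin_s
    values = baseline_subtract(values, onset_bin)
    return ResponseTensor(
        values=values,
        unit_ids=list(unit_ids),
        sound_ids=list(sound_ids),
        bin_s=bin_s,
        window=window,
    )


def spontaneous_rate(
    spike_times_s: np.ndarray,
    schedule: SessionSchedule,
    window_start_offset_s: float = 0.3,
    window_len_s: float = 2.0,
) -> float:
    """Firing rate in silent inter-segment windows.

    A ``window_len_s`` window starting ``window_start_offset_s`` after each
    segment ends is pooled; the rate is total spikes over (number of gaps x
    window length).
    """
    gaps = schedule.gaps
    if not gaps:
        raise InvalidInputError("schedule has no inter-segment gaps")
    for g in gaps:
        if g.duration_s < window_start_offset_s + window_len_s:
            raise InvalidInputError(
                f"gap of {g.duration_s}s too short for a {window_len_s}s window "
                f"offset by {window_start_offset_s}s"
            )
    times = np.asarray(spike_times_s, dtype=float)
    total = 0
    for g in gaps:
        a = g.start_s + window_start_offset_s
        total += int(np.searchsorted(times, a + window_len_s) - np.searchsorted(times, a))
    return total / (len(gaps) * window_len_s)


def evoked_modulation(
    tensor: ResponseTensor, sound_durations: Mapping[int, float]
) -> np.ndarray:
    """Mean over sounds of (mean rate during the sound), per unit.

    The tensor is already baseline-subtracted, so this equals mean sound-
    driven rate minus mean baseline rate.
    """
    per_sound = np.empty((tensor.n_units, tensor.n_sounds))
    for j, sid in enumerate(tensor.sound_ids):
        sl = tensor.duration_bins(sound_durations[sid])
        per_sound[:, j] = tensor.values[:, j, :, sl].mean(axis=(1, 2))
    return per_sound.mean(axis=1)


def reliability(tensor: ResponseTensor, unit: int) -> float:
    """Mean Pearson correlation over all unordered pairs of trial response
    vectors (each trial's PSTHs concatenated across sounds)."""
    x = tensor.values[unit]  # (sounds, trials, bins)
    n_trials = x.shape[1]
    if n_trials < 2:
        raise InsufficientDataError("need >= 2 trials")
    vectors = np.transpose(x, (1, 0, 2)).reshape(n_trials, -1)
    sd = vectors.std(axis=1)
    valid = sd > 0
    if valid.sum() < 2:
        logger.warning("unit %d: fewer than 2 non-degenerate trial vectors", unit)
        return float("nan")
    if not valid.all():
        logger.warning(
            "unit %d: excluding %d zero-variance trial vector(s)", unit, (~valid).sum()
        )
    c = np.corrcoef(vectors[valid])
    iu = np.triu_indices_from(c, k=1)
    return float(c[iu].mean())


def tuning_curve(
    tensor: ResponseTensor,
    stimulus_set: StimulusSet,
    unit: int,
    level_db: float = 70.0,
) -> TuningCurve:
    """Mean response per pure-tone frequency at one level."""
    tones = [
        s
        for s in stimulus_set.by_category("pure_tone")
        if float(s.level_db) == float(level_db)
    ]
    if not tones:
        raise InvalidInputError(f"no pure tones at {level_db} dB in stimulus set")
    tones.sort(key=lambda s: s.frequency_params["frequencies_khz"][0])
    freqs = np.array([s.frequency_params["frequencies_khz"][0] for s in tones])
    resp = np.empty(len(tones))
    for i, s in enumerate(tones):
        j = tensor.sound_index(s.sound_id)
        sl = tensor.duration_bins(s.duration_s)
        resp[i] = tensor.values[unit, j, :, sl].mean()
    return TuningCurve(frequencies_khz=freqs, response=resp, level_db=level_db)


def best_frequency(tuning: TuningCurve) -> float:
    """Frequency of maximal response; ties resolve to the lower frequency."""
    return float(tuning.frequencies_khz[int(np.argmax(tuning.response))])


def half_width_octaves(tuning: TuningCurve) -> HalfWidthResult:
    """Tuning width at half the peak of |response|, in octaves.

    Walks outward from the peak while |r| stays at or above half-maximum and
    linearly interpolates the crossing on the log2-frequency axis.  If a side
    never drops below half-max before the grid edge, the half-frequency is
    censored at the edge and flagged.
    """
    r = np.abs(np.asarray(tuning.response, dtype=float))
    log2f = np.log2(np.asarray(tuning.frequencies_khz, dtype=float))
    i0 = int(np.argmax(r))
    peak = r[i0]
    if peak <= 0:
        raise InvalidInputError("peak |response| must be positive")
    half = peak / 2.0

    def crossing(direction: int) -> tuple[float, bool]:
        i = i0
        while True:
            j = i + direction
            if j < 0 or j >= r.size:
                return log2f[i], True  # censored at the grid edge
            if r[j] < half:
                frac = (r[i] - half) / (r[i] - r[j])
                return log2f[i] + frac * (log2f[j] - log2f[i]), False
            i = j

    x_hi, cen_hi = crossing(+1)
    x_lo, cen_lo = crossing(-1)
    return HalfWidthResult(octaves=float(x_hi - x_lo), censored_low=cen_lo, censored_high=cen_hi)


def intensity_threshold(
    psth: np.ndarray,
    onset_bin: int,
    bin_s: float = 0.01,
    ramp_levels_db: tuple[float, float] = (50.0, 70.0),
    ramp_duration_s: float = 0.5,
    sd_floor: float = 1e-9,
) -> float | None:
    """Level (dB SPL) at which a level-ramp response first exceeds twice the
    baseline SD, or None if the unit never crosses (unresponsive).

    ``psth`` is the trial-averaged baseline-subtracted PSTH at the unit's
    best frequency; its pre-onset bins supply the baseline SD (floored at
    ``sd_floor`` if degenerate).
    """
    psth = np.asarray(psth, dtype=float)
    if onset_bin < 1 or onset_bin >= psth.size:
        raise InvalidParameterError("onset_bin out of range")
    sd = float(psth[:onset_bin].std())
    if sd == 0.0:
        sd = sd_floor
    n_ramp = int(round(ramp_duration_s / bin_s))
    post = psth[onset_bin : onset_bin + n_ramp]
    above = np.nonzero(post > 2.0 * sd)[0]
    if above.size == 0:
        return None
    t = above[0] * bin_s
    l0, l1 = ramp_levels_db
    return float(l0 + (l1 - l0) * t / ramp_duration_s)


def trial_responses_at_sound(
    tensor: ResponseTensor, unit: int, sound_id: int, duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mean response during one sound, plus a duration-matched
    null sample: each trial's mean over an equally long window of its own
    baseline bins (so both samples average over the same number of bins)."""
    j = tensor.sound_index(sound_id)
    sl = tensor.duration_bins(duration_s)
    responses = tensor.values[unit, j, :, sl].mean(axis=1)
    n = min(tensor.onset_bin, sl.stop - sl.start)
    baseline = tensor.values[unit, j, :, :n].mean(axis=1)
    return responses, baseline


def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; degenerate all-tied inputs count as p = 1."""
    if x.size == 0 or y.size == 0:
        return 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def classify_response_change(
    wake_responses: np.ndarray,
    anes_responses: np.ndarray,
    wake_baseline: np.ndarray,
    anes_baseline: np.ndarray,
    alpha: float = 0.05,
) -> ResponseChange:
    """Classify the best-frequency response change between states.

    Responsiveness per state is a two-sided Mann-Whitney test of per-trial
    responses against pooled baseline-bin rates.  Units significant in both
    states with opposite-signed mean responses are ``sign_change``; otherwise
    a significant cross-state Mann-Whitney labels ``decrease``/``increase``
    (by the direction of the mean), else ``no_change``.  Units responsive in
    neither state are ``nonresponsive``.
    """
    wake_responses = np.asarray(wake_responses, dtype=float)
    anes_responses = np.asarray(anes_responses, dtype=float)
    if wake_responses.size < 3 or anes_responses.size < 3:
        raise InsufficientDataError("need >= 3 trials per state")
    sig_w = _mw_p(wake_responses, np.asarray(wake_baseline, float)) < alpha
    sig_a = _mw_p(anes_responses, np.asarray(anes_baseline, float)) < alpha
    if not sig_w and not sig_a:
        return ResponseChange.NONRESPONSIVE
    mean_w = wake_responses.mean()
    mean_a = anes_responses.mean()
    if sig_w and sig_a and mean_w * mean_a < 0:
        return ResponseChange.SIGN_CHANGE
    if _mw_p(wake_responses, anes_responses) < alpha:
        return ResponseChange.DECREASE if mean_a < mean_w else ResponseChange.INCREASE
    return ResponseChange.NO_CHANGE
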