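"""Synthetic two-state populations and spike generation.

Units carry per-state tuning parameters (spontaneous rate, best frequency,
half-width in octaves, signed gain, level threshold, latency) and a
remodeling class describing how their sound response changes between
wakefulness and anesthesia.  Firing rates follow a Gaussian-in-log2-frequency
tuning profile gated by sound level, and spikes are drawn from an
inhomogeneous Poisson process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .protocol import (
    SoundStimulus,
    StimulusSet,
    SessionSchedule,
    amplitude_profile,
    chirp_frequency,
    level_trajectory,
    pure_tone_frequencies,
)
from .responses import ResponseTensor, baseline_subtract

__all__ = [
    "STATES",
    "REMODEL_CLASSES",
    "DEFAULT_CLASS_PROBS",
    "DEFAULT_SILENCED_FRAC",
    "StateParams",
    "NeuronGroundTruth",
    "SpikeTrain",
    "Template",
    "sample_population",
    "rate_timecourse",
    "generate_spikes",
    "simulate_session",
    "simulate_response_tensor",
    "generate_templates",
    "synthesize_voltage",
]

STATES = ("wake", "anesthesia")
REMODEL_CLASSES = ("decrease", "increase", "sign_change", "no_change", "silenced")

#: Default remodeling-class probabilities for responsive units, matching the
#: observed per-class counts out of 129 classified units.
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "decrease": 24 / 129,
    "increase": 34 / 129,
    "sign_change": 35 / 129,
    "no_change": 36 / 129,
}

#: Default fraction of units fully silent under anesthesia (observed range
#: was roughly one third to one half, depending on sorting strategy).
DEFAULT_SILENCED_FRAC = 0.4

LEVEL_EDGE_DB = 5.0  # width of the soft level gate above threshold


@dataclass(frozen=True)
class StateParams:
    spont_rate: float  # spk/s
    best_freq_khz: float
    halfwidth_oct: float
    gain: float  # spk/s at tuning peak; negative = suppressed
    threshold_db: float
    latency_s: float = 0.005


@dataclass(frozen=True)
class NeuronGroundTruth:
    unit_id: int
    recording_id: int
    remodel_class: str
    wake: StateParams
    anesthesia: StateParams

    def params(self, state: str) -> StateParams:
        if state not in STATES:
            raise InvalidParameterError(f"unknown state {state!r}")
        return self.wake if state == "wake" else self.anesthesia


@dataclass(frozen=True)
class SpikeTrain:
    unit_id: int
    state_label: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", times)
        if times.size and np.any(np.diff(times) < 0):
            raise InvalidParameterError("spike times must be sorted")


@dataclass(frozen=True)
class Template:
    unit_id: int
    recording_id: int
    waveform: np.ndarray  # channels x samples, µV
    peak_channel: int

    @property
    def peak_amplitude(self) -> float:
        """Maximum absolute amplitude over channels and samples."""
        return float(np.max(np.abs(self.waveform)))


# ---------------------------------------------------------------------------
# population sampling


def sample_population(
    n_units: int,
    class_probs: Mapping[str, float] | None = None,
    silenced_frac: float = 0.0,
    n_recordings: int = 1,
    seed: int = 0,
) -> list[NeuronGroundTruth]:
    """Draw a ground-truth population.

    Remodeling classes are multinomial with ``class_probs`` (defaults to the
    observed per-class fractions); independently, a ``silenced_frac`` subset
    is overridden to be completely silent under anesthesia.  Wake spontaneous
    rates are drawn from a clipped lognormal spanning [0, 100] spk/s, and
    best frequencies sit on the pure-tone grid so tuning estimators have an
    exact target.
    """
    if n_units < 0:
        raise InvalidParameterError(f"n_units must be >= 0, got {n_units}")
    if n_recordings <= 0:
        raise InvalidParameterError("n_recordings must be positive")
    probs = dict(DEFAULT_CLASS_PROBS if class_probs is None else class_probs)
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(f"class_probs must sum to 1, got {p.sum()}")
    if not 0.0 <= silenced_frac <= 1.0:
        raise InvalidParameterError("silenced_frac must be in [0, 1]")

    rng = np.random.default_rng(seed)
    grid = pure_tone_frequencies()
    classes = rng.choice(names, size=n_units, p=p)
    silenced = rng.random(n_units) < silenced_frac

    units: list[NeuronGroundTruth] = []
    for u in range(n_units):
        cls = "silenced" if silenced[u] else str(classes[u])
        bf = float(rng.choice(grid))
        hw_w = float(rng.uniform(0.25, 0.55))
        hw_a = hw_w * float(rng.uniform(0.60, 0.95))
        thr_w = float(rng.uniform(45.0, 55.0))
        thr_a = float(min(64.0, thr_w + rng.uniform(2.0, 8.0)))
        spont_w = float(min(100.0, rng.lognormal(np.log(4.0), 1.0)))

        if cls == "no_change":
            gw = ga = float(rng.uniform(18.0, 40.0))
        elif cls == "decrease":
            gw = float(rng.uniform(22.0, 45.0))
            ga = gw * float(rng.uniform(0.1, 0.3))
        elif cls == "increase":
            gw = float(rng.uniform(15.0, 25.0))
            ga = gw * float(rng.uniform(2.0, 3.0))
        elif cls == "sign_change":
            # suppressed in wake: needs enough spontaneous firing to reveal it
            spont_w = float(rng.uniform(25.0, 60.0))
            gw = -float(rng.uniform(0.6, 0.9)) * spont_w
            ga = float(rng.uniform(15.0, 40.0))
        else:  # silenced
            gw = float(rng.uniform(15.0, 40.0))
            ga = 0.0

        spont_a = 0.0 if cls == "silenced" else spont_w * float(rng.uniform(0.1, 0.8))
        units.append(
            NeuronGroundTruth(
                unit_id=u,
                recording_id=u % n_recordings,
                remodel_class=cls,
                wake=StateParams(spont_w, bf, hw_w, gw, thr_w),
                anesthesia=StateParams(spont_a, bf, hw_a, ga, thr_a),
            )
        )
    return units


# ---------------------------------------------------------------------------
# rate model


def _tuning_weight(freq_khz, bf_khz, hw_oct):
    """Gaussian in log2 frequency: value 1 at BF, exactly 1/2 at hw octaves."""
    d = np.log2(np.asarray(freq_khz, dtype=float) / bf_khz)
    return 2.0 ** (-((d / hw_oct) ** 2))


def _band_weight(lo, hi, bf_khz, hw_oct):
    """Max tuning weight within a frequency band (unimodal tuning)."""
    if lo <= bf_khz <= hi:
        return 1.0
    edge = lo if bf_khz < lo else hi
    return float(_tuning_weight(edge, bf_khz, hw_oct))


def _level_gate(level_db, threshold_db):
    """Smoothstep from 0 at threshold to 1 at threshold + 5 dB."""
    with np.errstate(invalid="ignore"):
        u = np.clip((np.asarray(level_db, dtype=float) - threshold_db) / LEVEL_EDGE_DB, 0.0, 1.0)
    u = np.nan_to_num(u)
    return u * u * (3.0 - 2.0 * u)


def _effective_levels(stim: SoundStimulus, t: np.ndarray) -> np.ndarray:
    """Level trajectory (dB) including the temporal amplitude profile."""
    amp = amplitude_profile(stim, t)
    with np.errstate(divide="ignore"):
        return level_trajectory(stim, t) + 20.0 * np.log10(amp)


def _driven_fraction(
    stim: SoundStimulus,
    t: np.ndarray,
    bf: np.ndarray,
    hw: np.ndarray,
    thr: np.ndarray,
) -> np.ndarray:
    """Fraction of peak gain driven at each time, per unit: (U, T) array.

    The drive is the maximum over stimulus components of tuning weight times
    the soft level gate, so multi-component sounds recruit a unit through its
    best-matching component rather than summing energy.
    """
    bf = np.atleast_1d(np.asarray(bf, dtype=float))
    hw = np.atleast_1d(np.asarray(hw, dtype=float))
    thr = np.atleast_1d(np.asarray(thr, dtype=float))
    L = _effective_levels(stim, t)  # (T,)
    gate = _level_gate(L[None, :], thr[:, None])  # (U, T)
    out = np.zeros((bf.size, t.size))
    p = stim.frequency_params
    if stim.category == "chirp":
        f_t = chirp_frequency(stim, t)  # (T,)
        d = np.log2(f_t[None, :] / bf[:, None]) / hw[:, None]
        w = 2.0 ** (-(d**2))
        np.maximum(out, w * gate, out=out)
        return out
    weights: list[float | np.ndarray] = []
    if "frequencies_khz" in p:
        for f in p["frequencies_khz"]:
            weights.append(_tuning_weight(f, bf, hw))
    for key in ("bands_khz",):
        for lo, hi in p.get(key, []):
            weights.append(
                np.array([_band_weight(lo, hi, b, h) for b, h in zip(bf, hw)])
            )
    if "band_khz" in p:
        lo, hi = p["band_khz"]
        weights.append(np.array([_band_weight(lo, hi, b, h) for b, h in zip(bf, hw)]))
    for w in weights:
        np.maximum(out, np.asarray(w)[:, None] * gate, out=out)
    return out


def rate_timecourse(
    neuron: NeuronGroundTruth,
    stim: SoundStimulus,
    state: str,
    time_step_s: float = 0.01,
) -> np.ndarray:
    """Firing rate (spk/s) over the stimulus window, rectified at zero.

    The series covers [0, duration + latency); outside the (latency-shifted)
    stimulus the rate equals the spontaneous rate.
    """
    if time_step_s <= 0:
        raise InvalidParameterError("time_step_s must be positive")
    sp = neuron.params(state)
    shift = int(round(sp.latency_s / time_step_s))
    n_t = max(1, int(round(stim.duration_s / time_step_s)))
    t = (np.arange(n_t) + 0.5) * time_step_s
    driven = _driven_fraction(stim, t, sp.best_freq_khz, sp.halfwidth_oct, sp.threshold_db)[0]
    rate = np.full(n_t + shift, sp.spont_rate)
    rate[shift:] += sp.gain * driven
    return np.clip(rate, 0.0, None)


def generate_spikes(
    rate_series: np.ndarray,
    time_step_s: float,
    seed: int = 0,
    t_start_s: float = 0.0,
    unit_id: int = 0,
    state_label: str = "wake",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes from a piecewise-constant rate series."""
    rate = np.asarray(rate_series, dtype=float)
    if np.any(rate < 0):
        raise InvalidParameterError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * time_step_s)
    idx = np.repeat(np.arange(rate.size), counts)
    times = t_start_s + (idx + rng.random(idx.size)) * time_step_s
    times.sort()
    return SpikeTrain(unit_id=unit_id, state_label=state_label, spike_times_s=times)


# ---------------------------------------------------------------------------
# whole-session and whole-tensor simulation


def _state_param_arrays(population: Sequence[NeuronGroundTruth], state: str):
    get = lambda name: np.array([getattr(n.params(state), name) for n in population])
    return (
        get("spont_rate"),
        get("best_freq_khz"),
        get("halfwidth_oct"),
        get("gain"),
        get("threshold_db"),
        get("latency_s"),
    )


def _gain_profiles(
    population: Sequence[NeuronGroundTruth],
    stimulus_set: StimulusSet,
    state: str,
    time_step_s: float,
    pad_bins: int,
) -> tuple[np.ndarray, dict[int, int]]:
    """Per (unit, sound) additive rate profile, latency-shifted, zero padded."""
    spont, bf, hw, gain, thr, lat = _state_param_arrays(population, state)
    n_units = len(population)
    profiles = np.zeros((n_units, len(stimulus_set), pad_bins), dtype=np.float32)
    sound_index = {}
    for j, stim in enumerate(stimulus_set.stimuli):
        sound_index[stim.sound_id] = j
        n_t = max(1, int(round(stim.duration_s / time_step_s)))
        t = (np.arange(n_t) + 0.5) * time_step_s
        driven = _driven_fraction(stim, t, bf, hw, thr)  # (U, T)
        contrib = gain[:, None] * driven
        for u in range(n_units):
            shift = int(round(lat[u] / time_step_s))
            stop = min(pad_bins, shift + n_t)
            profiles[u, j, shift:stop] = contrib[u, : stop - shift]
    return profiles, sound_index


def simulate_session(
    population: Sequence[NeuronGroundTruth],
    stimulus_set: StimulusSet,
    schedule: SessionSchedule,
    state: str,
    seed: int = 0,
    time_step_s: float = 0.01,
    chunk: int = 32,
) -> list[SpikeTrain]:
    """Poisson spike trains for a full session timeline in one state."""
    if state not in STATES:
        raise InvalidParameterError(f"unknown state {state!r}")
    rng = np.random.default_rng(seed)
    spont = _state_param_arrays(population, state)[0]
    pad_bins = int(round(1.0 / time_step_s))
    profiles, sound_index = _gain_profiles(population, stimulus_set, state, time_step_s, pad_bins)

    n_units = len(population)
    n_bins = int(np.ceil(schedule.end_s / time_step_s)) + pad_bins
    drive = np.zeros((n_units, n_bins), dtype=np.float32)
    onsets = schedule.trials["onset_s"].to_numpy()
    sounds = schedule.trials["sound_id"].to_numpy()
    for onset, sid in zip(onsets, sounds):
        b = int(round(onset / time_step_s))
        drive[:, b : b + pad_bins] += profiles[:, sound_index[int(sid)], :]

    trains: list[SpikeTrain] = []
    for lo in range(0, n_units, chunk):
        hi = min(lo + chunk, n_units)
        rate = np.clip(spont[lo:hi, None] + drive[lo:hi], 0.0, None)
        counts = rng.poisson(rate * time_step_s)
        for k, u in enumerate(range(lo, hi)):
            idx = np.repeat(np.nonzero(counts[k])[0], counts[k][counts[k] > 0])
            times = (idx + rng.random(idx.size)) * time_step_s
            times.sort()
            trains.append(
                SpikeTrain(
                    unit_id=population[u].unit_id,
                    state_label=state,
                    spike_times_s=times,
                )
            )
    return trains


def simulate_response_tensor(
    population: Sequence[NeuronGroundTruth],
    stimulus_set: StimulusSet,
    state: str,
    n_trials: int = 12,
    seed: int = 0,
    bin_s: float = 0.01,
    window: tuple[float, float] = (-0.3, 1.0),
    chunk: int = 24,
) -> ResponseTensor:
    """Trial-resolved baseline-subtracted response tensor, bypassing the
    session timeline (each trial is an independent stimulus presentation)."""
    if state not in STATES:
        raise InvalidParameterError(f"unknown state {state!r}")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n_units, n_sounds = len(population), len(stimulus_set)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    onset_bin = int(round(-window[0] / bin_s))
    spont = _state_param_arrays(population, state)[0]
    profiles, _ = _gain_profiles(
        population, stimulus_set, state, bin_s, n_bins - onset_bin
    )

    rate = spont[:, None, None] + np.concatenate(
        [np.zeros((n_units, n_sounds, onset_bin), dtype=np.float32), profiles], axis=2
    )
    np.clip(rate, 0.0, None, out=rate)

    values = np.empty((n_units, n_sounds, n_trials, n_bins), dtype=np.float32)
    for lo in range(0, n_units, chunk):
        hi = min(lo + chunk, n_units)
        lam = np.broadcast_to(
            rate[lo:hi, :, None, :] * bin_s, (hi - lo, n_sounds, n_trials, n_bins)
        )
        values[lo:hi] = rng.poisson(lam).astype(np.float32) / bin_s
    values = baseline_subtract(values, onset_bin)
    return ResponseTensor(
        values=values,
        unit_ids=[n.unit_id for n in population],
        sound_ids=list(stimulus_set.sound_ids),
        bin_s=bin_s,
        window=window,
    )


# ---------------------------------------------------------------------------
# templates and voltage snippets


def _base_waveform(rng: np.random.Generator, n_channels: int, n_samples: int):
    """A unit's mean spike waveform: biphasic shape with channel-dependent
    spatial decay and propagation lag, normalized so max |amplitude| = amp."""
    pc = int(rng.integers(0, n_channels))
    amp = float(rng.uniform(60.0, 180.0))
    t = np.arange(n_samples, dtype=float)
    t0 = n_samples // 2 + rng.uniform(-6.0, 6.0)
    w1 = rng.uniform(1.0, 6.0)
    w2 = w1 * rng.uniform(1.2, 3.0)
    rebound = rng.uniform(0.1, 0.7)
    pre = rng.uniform(0.0, 0.4)  # pre-trough positivity, sometimes absent
    lag = rng.uniform(-1.2, 1.2)
    sigma_up = rng.uniform(0.6, 3.0)
    sigma_dn = rng.uniform(0.6, 3.0)

    ch = np.arange(n_channels, dtype=float)
    d = ch - pc
    spatial = np.where(
        d >= 0, np.exp(-(d**2) / (2 * sigma_up**2)), np.exp(-(d**2) / (2 * sigma_dn**2))
    )
    tt = t[None, :] - lag * d[:, None]
    shape = (
        -np.exp(-(((tt - t0) / w1) ** 2))
        + rebound * np.exp(-(((tt - t0 - 2 * w1) / w2) ** 2))
        + pre * np.exp(-(((tt - t0 + 1.5 * w1) / w1) ** 2))
    )
    wave = spatial[:, None] * shape
    wave *= amp / np.max(np.abs(wave))
    # sampling misalignment under the per-channel lag can move the realized
    # peak off the nominal center channel; report the realized peak channel
    pc = int(np.argmax(np.max(np.abs(wave), axis=1)))
    return wave, pc, amp


def generate_templates(
    population: Sequence[NeuronGroundTruth],
    jitter_sd: float = 0.05,
    seed: int = 0,
    n_channels: int = 20,
    n_samples: int = 61,
) -> tuple[list[Template], list[Template]]:
    """Per-state template pairs.

    The anesthesia copy of each waveform carries multiplicative amplitude
    jitter and small additive shape noise.  Units silenced under anesthesia
    emit no spikes there, so they get no anesthesia template.
    """
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wake: list[Template] = []
    anes: list[Template] = []
    for n in population:
        wave, pc, amp = _base_waveform(rng, n_channels, n_samples)
        wake.append(Template(n.unit_id, n.recording_id, wave, pc))
        if n.remodel_class == "silenced":
            continue
        noisy = wave * (1.0 + rng.normal(0.0, jitter_sd)) + rng.normal(
            0.0, jitter_sd * amp * 0.3, size=wave.shape
        )
        anes.append(Template(n.unit_id, n.recording_id, noisy, pc))
    return wake, anes


def synthesize_voltage(
    trains: Iterable[SpikeTrain],
    templates: Mapping[int, Template] | Sequence[Template],
    noise_sd: float,
    duration_s: float,
    sample_rate_hz: float = 30000.0,
    seed: int = 0,
) -> np.ndarray:
    """Additive Gaussian noise plus template waveforms at spike times.

    Returns a (channels, samples) trace.  Spikes whose waveform would extend
    beyond the trace are clipped with a warning.
    """
    if sample_rate_hz <= 0:
        raise InvalidParameterError("sample_rate_hz must be positive")
    if not isinstance(templates, Mapping):
        templates = {t.unit_id: t for t in templates}
    if not templates:
        raise InvalidParameterError("need at least one template")
    any_t = next(iter(templates.values()))
    n_channels, n_wave = any_t.waveform.shape
    n = int(round(duration_s * sample_rate_hz))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, size=(n_channels, n))
    clipped = 0
    for train in trains:
        tpl = templates.get(train.unit_id)
        if tpl is None:
            continue
        starts = np.round(train.spike_times_s * sample_rate_hz).astype(int) - n_wave // 2
        for s in starts:
            a = max(0, s)
            b = min(n, s + n_wave)
            if b <= a:
                continue
            if a != s or b != s + n_wave:
                clipped += 1
            trace[:, a:b] += tpl.waveform[:, a - s : b - s]
    if clipped:
        warnings.warn(f"{clipped} spike waveform(s) clipped at trace boundaries")
    return trace
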