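"""Cross-state unit matching by template correlation.

Each wake unit is paired with its most-correlated anesthesia template from
the same recording.  A pair is accepted when (i) the correlation exceeds an
empirical chance threshold built from maximal cross-recording correlations,
and (ii) no other simultaneously recorded anesthesia unit correlates within
a margin of the best match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .simulate import Template

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "template_correlation_matrix",
    "chance_threshold",
    "match_units",
]


@dataclass(frozen=True)
class MatchedPair:
    wake_unit: int
    anes_unit: int
    rho_max: float


@dataclass(frozen=True)
class RejectedUnit:
    wake_unit: int
    reason: str  # {"below_threshold", "ambiguous", "no_candidate"}
    rho_max: float = float("nan")


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    rejected: list[RejectedUnit]
    threshold: float
    margin: float
    null_distribution: np.ndarray | None = None

    @property
    def matched_wake_units(self) -> list[int]:
        return [p.wake_unit for p in self.pairs]


def _crop(waveform: np.ndarray, center: int, half_width: int) -> np.ndarray:
    lo = max(0, center - half_width)
    hi = min(waveform.shape[0], center + half_width + 1)
    return waveform[lo:hi]


def template_correlation_matrix(
    wake: Sequence[Template],
    anes: Sequence[Template],
    channel_window: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of flattened waveforms for every wake x anes pair.

    Waveforms are cropped to ``channel_window`` channels centered on the wake
    unit's peak channel before flattening.  Returns the correlation matrix
    and a boolean mask marking same-recording pairs (cross-recording values
    are kept, not zeroed; downstream consumers use the mask).
    """
    if not wake or not anes:
        raise InvalidInputError("need at least one template on each side")
    n_samples = wake[0].waveform.shape[1]
    for t in list(wake) + list(anes):
        if t.waveform.ndim != 2 or t.waveform.shape[1] != n_samples:
            raise InvalidInputError("template geometries differ (samples axis)")
    half = max(0, channel_window // 2)
    corr = np.empty((len(wake), len(anes)))
    mask = np.empty((len(wake), len(anes)), dtype=bool)
    for i, tw in enumerate(wake):
        ref = _crop(tw.waveform, tw.peak_channel, half)
        lo = max(0, tw.peak_channel - half)
        hi = lo + ref.shape[0]
        x = ref.ravel()
        x = x - x.mean()
        xn = np.linalg.norm(x)
        for j, ta in enumerate(anes):
            if ta.waveform.shape[0] != tw.waveform.shape[0]:
                raise InvalidInputError("template geometries differ (channel axis)")
            y = ta.waveform[lo:hi].ravel()
            y = y - y.mean()
            yn = np.linalg.norm(y)
            corr[i, j] = 0.0 if xn == 0 or yn == 0 else float(x @ y / (xn * yn))
            mask[i, j] = tw.recording_id == ta.recording_id
    return corr, mask


def chance_threshold(
    corr: np.ndarray, same_recording_mask: np.ndarray, percentile: float = 95.0
) -> tuple[float, np.ndarray]:
    """Empirical chance-correlation threshold.

    For every wake template, take its maximal correlation over anesthesia
    templates from *other* recordings; the threshold is the given percentile
    of that null distribution of chance maxima.
    """
    if not 0 < percentile < 100:
        raise InvalidParameterError("percentile must be in (0, 100)")
    cross = ~np.asarray(same_recording_mask, dtype=bool)
    if not cross.any():
        raise InvalidInputError(
            "cannot build a chance null: all template pairs share a recording"
        )
    maxima = []
    for i in range(corr.shape[0]):
        if cross[i].any():
            maxima.append(corr[i, cross[i]].max())
    null = np.array(maxima)
    return float(np.percentile(null, percentile)), null


def match_units(
    corr: np.ndarray,
    same_recording_mask: np.ndarray,
    threshold: float,
    margin: float = 0.2,
    wake_unit_ids: Sequence[int] | None = None,
    anes_unit_ids: Sequence[int] | None = None,
) -> MatchResult:
    """Accept wake->anesthesia pairs passing the threshold and margin rules.

    A wake unit's best same-recording partner rho_max must exceed the
    threshold, and every other simultaneously recorded anesthesia unit must
    correlate below rho_max - margin.  One-to-one assignment is enforced by
    keeping only the strongest wake claimant of each anesthesia unit.
    """
    if margin < 0:
        raise InvalidParameterError("margin must be >= 0")
    nw, na = corr.shape
    wake_ids = list(range(nw)) if wake_unit_ids is None else list(wake_unit_ids)
    anes_ids = list(range(na)) if anes_unit_ids is None else list(anes_unit_ids)

    candidates: list[MatchedPair] = []
    rejected: list[RejectedUnit] = []
    for i in range(nw):
        same = np.asarray(same_recording_mask[i], dtype=bool)
        if not same.any():
            rejected.append(RejectedUnit(wake_ids[i], "no_candidate"))
            continue
        row = corr[i]
        j_best = int(np.flatnonzero(same)[np.argmax(row[same])])
        rho_max = float(row[j_best])
        if rho_max <= threshold:
            rejected.append(RejectedUnit(wake_ids[i], "below_threshold", rho_max))
            continue
        others = same.copy()
        others[j_best] = False
        if others.any() and row[others].max() >= rho_max - margin:
            rejected.append(RejectedUnit(wake_ids[i], "ambiguous", rho_max))
            continue
        candidates.append(MatchedPair(wake_ids[i], anes_ids[j_best], rho_max))

    # mutual-best enforcement: one wake unit per anesthesia unit
    by_anes: dict[int, MatchedPair] = {}
    for pair in candidates:
        cur = by_anes.get(pair.anes_unit)
        if cur is None or pair.rho_max > cur.rho_max:
            if cur is not None:
                rejected.append(RejectedUnit(cur.wake_unit, "ambiguous", cur.rho_max))
                logger.info(
                    "anesthesia unit %d claimed twice; keeping strongest wake partner",
                    pair.anes_unit,
                )
            by_anes[pair.anes_unit] = pair
        else:
            rejected.append(RejectedUnit(pair.wake_unit, "ambiguous", pair.rho_max))
    pairs = sorted(by_anes.values(), key=lambda p: p.wake_unit)
    return MatchResult(pairs=pairs, rejected=rejected, threshold=threshold, margin=margin)
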