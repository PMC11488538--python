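"""Signal-level statistics: MAD noise estimate, spike SNR, fluctuation ratio.

The MAD here is the raw median absolute deviation, median(|V_t - median(V)|),
with no Gaussian-consistency scaling (for Gaussian noise of SD sigma it
converges to ~0.6745 sigma).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError
from .simulate import Template

__all__ = ["compute_mad", "compute_snr", "fluctuation_ratio"]


def compute_mad(trace: np.ndarray) -> float:
    """Median absolute deviation of a voltage trace (unscaled)."""
    v = np.asarray(trace, dtype=float).ravel()
    if v.size == 0:
        raise InvalidInputError("empty trace")
    return float(np.median(np.abs(v - np.median(v))))


def compute_snr(template: Template | np.ndarray, sigma_b: float) -> float:
    """Peak template amplitude over background noise, A_us / sigma_b."""
    if sigma_b <= 0:
        raise UndefinedMetricError(f"sigma_b must be positive, got {sigma_b}")
    waveform = template.waveform if isinstance(template, Template) else np.asarray(template)
    return float(np.max(np.abs(waveform)) / sigma_b)


def fluctuation_ratio(wake_trace: np.ndarray, anes_trace: np.ndarray) -> float:
    """MAD(wake) / MAD(anesthesia); the high-frequency fluctuation ratio."""
    mad_anes = compute_mad(anes_trace)
    if mad_anes == 0:
        raise UndefinedMetricError("anesthesia trace has zero MAD")
    return compute_mad(wake_trace) / mad_anes
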