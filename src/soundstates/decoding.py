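"""Pseudo-population nearest-neighbor sound decoding.

For each of ``n_splits`` random half-splits of trials, per-sound train and
test population vectors are built by averaging each half; the classifier
assigns every test vector to the train sound with the most correlated
vector.  Works within one state (same tensor on both sides) or across states
(train on one state's trials, test on the other's).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .responses import ResponseTensor

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingResult",
    "CrossStateResult",
    "BootstrapCategoryResult",
    "assemble_pseudopopulation",
    "split_indices",
    "nn_classify",
    "cross_state_design",
    "category_accuracy",
    "bootstrap_category_difference",
]


@dataclass
class DecodingResult:
    per_split_accuracy: np.ndarray  # (n_splits,)
    per_sound_accuracy: np.ndarray  # (n_sounds,)
    confusion_matrix: np.ndarray  # (n_sounds, n_sounds) counts; rows = true
    mode: str  # {"time_course", "time_averaged"}
    design: str  # {"same_state", "cross_state"}
    sound_ids: list[int]
    n_ties: int = 0

    @property
    def mean_accuracy(self) -> float:
        """Mean over sounds of the per-sound accuracy."""
        return float(self.per_sound_accuracy.mean())

    @property
    def sem_accuracy(self) -> float:
        """SEM of the per-sound accuracies, over sounds."""
        s = self.per_sound_accuracy
        return float(s.std(ddof=1) / math.sqrt(s.size))

    @property
    def n_splits(self) -> int:
        return self.per_split_accuracy.size


@dataclass
class CrossStateResult:
    wake_to_anes: DecodingResult
    anes_to_wake: DecodingResult

    @property
    def mean_accuracy(self) -> float:
        return 0.5 * (self.wake_to_anes.mean_accuracy + self.anes_to_wake.mean_accuracy)


def assemble_pseudopopulation(
    tensors: Sequence[ResponseTensor], seed: int = 0
) -> ResponseTensor:
    """Pool neurons from several recordings into one pseudo-population.

    Trial indices are permuted independently per recording and per sound
    before concatenation, so trial pairing across recordings is random.
    """
    if not tensors:
        raise InvalidInputError("need at least one tensor")
    first = tensors[0]
    for t in tensors[1:]:
        if t.sound_ids != first.sound_ids:
            raise InvalidInputError("sound sets differ across recordings")
        if t.n_bins != first.n_bins or t.bin_s != first.bin_s:
            raise InvalidInputError("bin structure differs across recordings")
        if t.n_trials != first.n_trials:
            raise InvalidInputError("trial counts differ across recordings")
    rng = np.random.default_rng(seed)
    blocks = []
    unit_ids: list[int] = []
    for t in tensors:
        v = t.values.copy()
        for j in range(t.n_sounds):
            v[:, j] = v[:, j, rng.permutation(t.n_trials)]
        blocks.append(v)
        unit_ids.extend(t.unit_ids)
    return ResponseTensor(
        values=np.concatenate(blocks, axis=0),
        unit_ids=unit_ids,
        sound_ids=list(first.sound_ids),
        bin_s=first.bin_s,
        window=first.window,
    )


def split_indices(
    n_trials: int, n_splits: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random half-splits of trial indices; odd counts favor the train half."""
    if n_trials < 2:
        raise InvalidInputError("need >= 2 trials to split")
    rng = np.random.default_rng(seed)
    n_train = (n_trials + 1) // 2
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n_trials)
        out.append((perm[:n_train], perm[n_train:]))
    return out


def _features(
    tensor: ResponseTensor,
    trial_idx: np.ndarray,
    mode: str,
    durations: Mapping[int, float] | None,
) -> np.ndarray:
    """Per-sound population vectors (sounds x features) from a trial subset."""
    mean = tensor.values[:, :, trial_idx, :].mean(axis=2)  # (units, sounds, bins)
    onset = tensor.onset_bin
    if mode == "time_course":
        post = mean[:, :, onset:]
        return np.transpose(post, (1, 0, 2)).reshape(tensor.n_sounds, -1)
    if mode == "time_averaged":
        out = np.empty((tensor.n_sounds, tensor.n_units))
        for j, sid in enumerate(tensor.sound_ids):
            sl = (
                tensor.duration_bins(durations[sid])
                if durations is not None
                else slice(onset, None)
            )
            out[j] = mean[:, j, sl].mean(axis=1)
        return out
    raise InvalidParameterError(f"unknown mode {mode!r}")


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    z = np.zeros_like(x)
    np.divide(x - mu, sd, out=z, where=sd > 0)
    return z, valid


def nn_classify(
    train_tensor: ResponseTensor,
    test_tensor: ResponseTensor,
    mode: str = "time_course",
    n_splits: int = 50,
    seed: int = 0,
    durations: Mapping[int, float] | None = None,
    design: str = "same_state",
) -> DecodingResult:
    """Nearest-correlation sound classification over random trial half-splits.

    Train vectors average one half of the trials of ``train_tensor``; test
    vectors average the complementary half of ``test_tensor``.  Prediction is
    the train sound with maximal Pearson correlation; ties (and degenerate
    zero-variance candidates, scored as -inf) resolve to the lowest sound
    index.
    """
    if train_tensor.sound_ids != test_tensor.sound_ids:
        raise InvalidInputError("train/test sound sets differ")
    if train_tensor.n_units != test_tensor.n_units:
        raise InvalidInputError("train/test unit counts differ")
    if min(train_tensor.n_trials, test_tensor.n_trials) < 2:
        raise InvalidInputError("need >= 2 trials per sound")
    n_sounds = train_tensor.n_sounds
    n_trials = min(train_tensor.n_trials, test_tensor.n_trials)
    splits = split_indices(n_trials, n_splits, seed)

    per_split = np.empty(n_splits)
    correct = np.zeros(n_sounds)
    confusion = np.zeros((n_sounds, n_sounds), dtype=int)
    n_ties = 0
    truth = np.arange(n_sounds)
    for k, (tr, te) in enumerate(splits):
        f_train = _features(train_tensor, tr, mode, durations)
        f_test = _features(test_tensor, te, mode, durations)
        z_tr, ok_tr = _standardize_rows(f_train)
        z_te, ok_te = _standardize_rows(f_test)
        if not ok_tr.all():
            logger.warning("split %d: %d zero-variance train vector(s)", k, (~ok_tr).sum())
        sim = z_te @ z_tr.T / f_train.shape[1]
        sim[:, ~ok_tr] = -np.inf
        sim[~ok_te, :] = -np.inf
        best = sim.max(axis=1)
        n_ties += int(((sim == best[:, None]).sum(axis=1) > 1).sum())
        pred = np.argmax(sim, axis=1)
        hits = pred == truth
        per_split[k] = hits.mean()
        correct += hits
        confusion[truth, pred] += 1
    if n_ties:
        logger.info("%d tied prediction(s) resolved to lowest sound index", n_ties)
    return DecodingResult(
        per_split_accuracy=per_split,
        per_sound_accuracy=correct / n_splits,
        confusion_matrix=confusion,
        mode=mode,
        design=design,
        sound_ids=list(train_tensor.sound_ids),
        n_ties=n_ties,
    )


def cross_state_design(
    wake_tensor: ResponseTensor,
    anes_tensor: ResponseTensor,
    mode: str = "time_course",
    n_splits: int = 50,
    seed: int = 0,
    durations: Mapping[int, float] | None = None,
) -> CrossStateResult:
    """Train on one state and test on the other, in both directions."""
    if wake_tensor.unit_ids != anes_tensor.unit_ids:
        raise InvalidInputError("cross-state decoding requires matched units")
    w2a = nn_classify(
        wake_tensor, anes_tensor, mode, n_splits, seed, durations, design="cross_state"
    )
    a2w = nn_classify(
        anes_tensor, wake_tensor, mode, n_splits, seed + 1, durations, design="cross_state"
    )
    return CrossStateResult(wake_to_anes=w2a, anes_to_wake=a2w)


def category_accuracy(
    result: DecodingResult, category_map: Mapping[int, str]
) -> dict[str, float]:
    """Mean accuracy over the test sounds of each category (the classifier
    still predicts among all sounds)."""
    missing = [sid for sid in result.sound_ids if sid not in category_map]
    if missing:
        raise InvalidInputError(f"sounds without category: {missing[:5]}...")
    cats = np.array([category_map[sid] for sid in result.sound_ids])
    return {
        c: float(result.per_sound_accuracy[cats == c].mean()) for c in np.unique(cats)
    }


@dataclass
class BootstrapCategoryResult:
    differences: np.ndarray  # (n_boot,) wake minus anesthesia accuracy
    mean: float
    p_value: float


def bootstrap_category_difference(
    wake_tensor: ResponseTensor,
    anes_tensor: ResponseTensor,
    category_map: Mapping[int, str],
    n_boot: int = 100,
    n_splits: int = 50,
    seed: int = 0,
    mode: str = "time_course",
    durations: Mapping[int, float] | None = None,
) -> dict[str, BootstrapCategoryResult]:
    """Neuron-resampling bootstrap of the wake-minus-anesthesia per-category
    same-state accuracy difference.

    Neurons are resampled with replacement independently in each state for
    each of ``n_boot`` populations; the one-sided p per category is the
    fraction of bootstrap differences on the opposite side of zero from the
    mean.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if n_boot < 10:
        warnings.warn("n_boot < 10 gives an unstable bootstrap p-value")
    rng = np.random.default_rng(seed)
    cats = sorted({category_map[sid] for sid in wake_tensor.sound_ids})
    diffs = {c: np.empty(n_boot) for c in cats}
    for b in range(n_boot):
        idx_w = rng.integers(0, wake_tensor.n_units, wake_tensor.n_units)
        idx_a = rng.integers(0, anes_tensor.n_units, anes_tensor.n_units)
        tw = ResponseTensor(
            wake_tensor.values[idx_w],
            [wake_tensor.unit_ids[i] for i in idx_w],
            wake_tensor.sound_ids,
            wake_tensor.bin_s,
            wake_tensor.window,
        )
        ta = ResponseTensor(
            anes_tensor.values[idx_a],
            [anes_tensor.unit_ids[i] for i in idx_a],
            anes_tensor.sound_ids,
            anes_tensor.bin_s,
            anes_tensor.window,
        )
        res_w = nn_classify(tw, tw, mode, n_splits, seed + 1000 + b, durations)
        res_a = nn_classify(ta, ta, mode, n_splits, seed + 2000 + b, durations)
        acc_w = category_accuracy(res_w, category_map)
        acc_a = category_accuracy(res_a, category_map)
        for c in cats:
            diffs[c][b] = acc_w[c] - acc_a[c]
    out = {}
    for c in cats:
        d = diffs[c]
        m = float(d.mean())
        p = float(np.mean(d <= 0) if m > 0 else np.mean(d >= 0))
        out[c] = BootstrapCategoryResult(differences=d, mean=m, p_value=p)
    return out
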