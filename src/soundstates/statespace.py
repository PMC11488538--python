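"""State-subspace analysis of sound-evoked population vectors.

Per-(sound, state) vectors are projected into principal components fit
jointly on both states; state identity is then classified with a 10-fold
linear SVM (folds stratified 1:1 by state), and projections can be rotated
so one axis is normal to the decision boundary for per-axis wake-vs-
anesthesia regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .errors import InvalidInputError
from .responses import ResponseTensor

__all__ = [
    "PcaResult",
    "SvmResult",
    "RotationResult",
    "sound_state_vectors",
    "pca_project",
    "svm_state_classification",
    "rotate_to_boundary",
]


@dataclass
class PcaResult:
    projections: np.ndarray  # (2 * n_sounds, k)
    explained_variance_ratio: np.ndarray  # (k,)
    components: np.ndarray  # (k, n_neurons)
    mean: np.ndarray  # (n_neurons,)


@dataclass
class SvmResult:
    cv_accuracy: float
    fold_accuracies: np.ndarray
    weights: np.ndarray  # decision-plane normal in PC space
    intercept: float


@dataclass
class RotationResult:
    rotated: np.ndarray  # (2 * n_sounds, 2): columns (normal, collinear)
    rotation: np.ndarray  # 2x2 rotation applied to row vectors
    pearson_r_normal: float
    pearson_r_collinear: float


def sound_state_vectors(
    wake_tensor: ResponseTensor,
    anes_tensor: ResponseTensor,
    durations: Mapping[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """One vector per (sound, state): response averaged over trials and time.

    Returns (X, state_labels, sound_ids) with wake rows first; labels are 0
    for wake and 1 for anesthesia.
    """
    if wake_tensor.unit_ids != anes_tensor.unit_ids:
        raise InvalidInputError("state tensors must share the same units")
    if wake_tensor.sound_ids != anes_tensor.sound_ids:
        raise InvalidInputError("state tensors must share the same sounds")

    def _avg(t: ResponseTensor) -> np.ndarray:
        mean = t.values.mean(axis=2)  # (units, sounds, bins)
        out = np.empty((t.n_sounds, t.n_units))
        for j, sid in enumerate(t.sound_ids):
            sl = t.duration_bins(durations[sid]) if durations is not None else slice(t.onset_bin, None)
            out[j] = mean[:, j, sl].mean(axis=1)
        return out

    x = np.vstack([_avg(wake_tensor), _avg(anes_tensor)])
    labels = np.repeat([0, 1], wake_tensor.n_sounds)
    return x, labels, list(wake_tensor.sound_ids)


def pca_project(vectors: np.ndarray, k: int = 3) -> PcaResult:
    """Project onto the top-k principal components of all samples jointly.

    Centering subtracts the grand mean; no per-neuron variance scaling is
    applied.  If k exceeds the data rank, k is reduced with a warning.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("need a 2-D sample matrix with >= 2 rows")
    max_k = min(x.shape[0] - 1, x.shape[1])
    if k > max_k:
        warnings.warn(f"k={k} exceeds data rank; using k={max_k}")
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(x)
    return PcaResult(
        projections=proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        mean=pca.mean_,
    )


def svm_state_classification(
    projections: np.ndarray,
    state_labels: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> SvmResult:
    """Cross-validated linear maximum-margin state classification.

    Folds partition *sounds* into ``n_folds`` groups; each fold's test set
    holds both states of its sounds, preserving a 1-to-1 state ratio.  The
    reported boundary is refit on all samples.
    """
    x = np.asarray(projections, dtype=float)
    y = np.asarray(state_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidInputError("need exactly two states present")
    n0 = int((y == classes[0]).sum())
    if n0 != (y == classes[1]).sum():
        raise InvalidInputError("states must contribute equally many samples")
    # row i (state 0) pairs with row n0 + i (state 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n0)
    fold_of_sound = np.empty(n0, dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of_sound[chunk] = f
    fold_of_row = np.concatenate([fold_of_sound, fold_of_sound])

    accs = []
    for f in range(n_folds):
        test = fold_of_row == f
        if not test.any() or test.all():
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[~test], y[~test])
        accs.append(float(clf.score(x[test], y[test])))
    clf_all = SVC(kernel="linear", C=C).fit(x, y)
    return SvmResult(
        cv_accuracy=float(np.mean(accs)),
        fold_accuracies=np.array(accs),
        weights=clf_all.coef_[0].copy(),
        intercept=float(clf_all.intercept_[0]),
    )


def rotate_to_boundary(
    projections_2pc: np.ndarray, boundary_weights: np.ndarray
) -> RotationResult:
    """Rotate 2-PC projections so axis 0 is normal to the decision line and
    axis 1 runs along it; report the Pearson correlation between wake and
    anesthesia coordinates on each axis.

    Rows must be ordered wake sounds then anesthesia sounds (equal counts).
    """
    x = np.asarray(projections_2pc, dtype=float)
    w = np.asarray(boundary_weights, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise InvalidInputError("projections must be (n, 2)")
    if w.shape != (2,) or np.linalg.norm(w) == 0:
        raise InvalidInputError("boundary direction is degenerate")
    if x.shape[0] % 2 != 0:
        raise InvalidInputError("expected equal wake/anesthesia sample counts")
    normal = w / np.linalg.norm(w)
    collinear = np.array([-normal[1], normal[0]])
    rot = np.stack([normal, collinear], axis=1)  # right-multiply row vectors
    rotated = x @ rot
    n = x.shape[0] // 2
    r_norm = float(stats.pearsonr(rotated[:n, 0], rotated[n:, 0]).statistic)
    r_coll = float(stats.pearsonr(rotated[:n, 1], rotated[n:, 1]).statistic)
    return RotationResult(
        rotated=rotated,
        rotation=rot,
        pearson_r_normal=r_norm,
        pearson_r_collinear=r_coll,
    )
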