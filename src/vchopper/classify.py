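"""UV-on vs gated-frame classification and its evaluation metrics.

Class 0 = gated (source-off) frames, class 1 = source-on frames with
autofluorescent background.  The metric convention treats class 0 as the
positive class: TP counts gated frames classified correctly.

Two classifiers are provided: a deterministic frame-mean intensity threshold
(the pipeline default; gated frames are far darker than source-on frames) and
a convolutional network (:mod:`vchopper.cnn`) mirroring the automated
workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .errors import InvalidConfigError
from .simulate import FrameStack

__all__ = [
    "ClassifierMetrics",
    "preprocess_frame",
    "threshold_classifier",
    "compute_metrics",
]

INPUT_SIZE = (128, 128)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and derived fractions (class 0 is positive).

    ``accuracy = (TP+TN)/(TP+TN+FP+FN)``, ``sensitivity = TP/(TP+FN)``,
    ``specificity = TN/(TN+FP)``; a fraction with an empty denominator is NaN
    and flagged in ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


def preprocess_frame(
    image: np.ndarray,
    out_size: tuple[int, int] = INPUT_SIZE,
    max_value: float | None = None,
) -> np.ndarray:
    """Convert a frame to grayscale ``out_size`` float32 scaled to [0, 1].

    RGB frames are converted to luminance; integer frames are scaled by their
    dtype full scale (override with ``max_value``); float frames are assumed
    already in intensity units with full scale ``max_value`` (default 1).
    """
    image = np.asarray(image)
    if image.size == 0 or image.ndim < 2:
        raise InvalidConfigError("empty or degenerate image")
    if image.ndim == 3:
        image = rgb2gray(image)
    if max_value is None:
        if np.issubdtype(image.dtype, np.integer):
            max_value = float(np.iinfo(image.dtype).max)
        else:
            max_value = 1.0
    out = image.astype(np.float32) / max_value
    if out.shape != tuple(out_size):
        out = resize(out, out_size, anti_aliasing=True, preserve_range=True).astype(
            np.float32
        )
    return np.clip(out, 0.0, 1.0)


def _frame_means(frames: FrameStack | np.ndarray) -> np.ndarray:
    if isinstance(frames, FrameStack):
        return frames.frame_means()
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 1:
        return arr
    return arr.reshape(len(arr), -1).mean(axis=1)


def threshold_classifier(
    frames: FrameStack | np.ndarray,
    method: Literal["fixed", "otsu"] = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Label frames by mean intensity: above threshold -> 1 (source on).

    ``otsu`` derives the threshold from the bimodal frame-mean histogram; a
    constant or unimodal series yields an ambiguous-threshold warning and
    all-zero labels.
    """
    means = _frame_means(frames)
    if len(means) < 2:
        raise InvalidConfigError("need at least two frames to threshold")
    if method == "fixed":
        if fixed_threshold is None:
            raise InvalidConfigError("fixed method requires fixed_threshold")
        thresh = fixed_threshold
    else:
        spread = np.ptp(means)
        if spread <= 1e-12 * max(1.0, abs(means).max()):
            warnings.warn("frame-mean series is constant; threshold ambiguous", stacklevel=2)
            return np.zeros(len(means), dtype=np.int8)
        thresh = threshold_otsu(means)
    labels = (means > thresh).astype(np.int8)
    if method == "otsu" and (labels.all() or not labels.any()):
        warnings.warn("frame-mean histogram is unimodal; threshold ambiguous", stacklevel=2)
        return np.zeros(len(means), dtype=np.int8)
    return labels


def compute_metrics(predicted: np.ndarray, truth: np.ndarray) -> ClassifierMetrics:
    """Confusion counts and accuracy/sensitivity/specificity (class 0 positive)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise InvalidConfigError("predicted and truth label lengths differ")
    tp = int(np.sum((predicted == 0) & (truth == 0)))
    tn = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 0) & (truth == 1)))
    fn = int(np.sum((predicted == 1) & (truth == 0)))
    undefined: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    return ClassifierMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        undefined=tuple(undefined),
    )
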