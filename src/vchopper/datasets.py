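"""Synthetic training data for the gated-frame classifier.

Builds a balanced, labeled set of source-on (class 1) and gated (class 0)
frames by rendering phantom videos at the standard microsecond-imaging
acquisition settings (50 Hz pulses at 40% duty, 30 fps video with a small
frame-rate drift, 1/350 s exposure) with the default camera noise.  Phantom
geometry, lifetimes and amplitudes are varied across videos so the
classifier cannot key on a single scene.
"""

from __future__ import annotations

import numpy as np

from .classify import preprocess_frame
from .simulate import NoiseModel, render_phantom_video, two_shape_phantom
from .timing import AcquisitionConfig

__all__ = ["gated_frame_dataset", "STANDARD_CONFIG"]

#: Microsecond-imaging acquisition used for classifier training data.
STANDARD_CONFIG = AcquisitionConfig(
    pulse_frequency_hz=50.0,
    duty_cycle=0.4,
    nominal_frame_rate_fps=30.0,
    frame_rate_drift_fps=0.02,
    drift_sign=-1,
    shutter_s=1.0 / 350.0,
)


def gated_frame_dataset(
    n_per_class: int = 800,
    seed: int = 0,
    image_size: int = 128,
    config: AcquisitionConfig = STANDARD_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced (images, labels) set of preprocessed grayscale frames.

    Renders as many phantom videos as needed (varying lifetimes, amplitudes
    and scene seed per video) and truncates each class to ``n_per_class``.
    Images are ``image_size`` x ``image_size`` float32 in [0, 1]; labels are
    0 (gated) / 1 (source-on).
    """
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    counts = {0: 0, 1: 0}
    video = 0
    while min(counts.values()) < n_per_class and video < 50:
        lifetimes = tuple(rng.uniform(120e-6, 600e-6, size=2))
        amplitudes = tuple(rng.uniform(0.5, 1.5, size=2))
        spec = two_shape_phantom(
            shape=(image_size, image_size),
            lifetimes_s=lifetimes,
            amplitudes=amplitudes,
            noise=NoiseModel(),
            rng_seed=int(rng.integers(2**31)),
        )
        stack = render_phantom_video(spec, config, duration_s=20.0)
        for frame, label in zip(stack.frames, stack.truth_labels):
            label = int(label)
            if counts[label] >= n_per_class:
                continue
            images.append(preprocess_frame(frame, out_size=(image_size, image_size)))
            labels.append(label)
            counts[label] += 1
        video += 1
    x = np.stack(images)
    y = np.array(labels, dtype=np.int64)
    order = rng.permutation(len(y))
    return x[order], y[order]
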