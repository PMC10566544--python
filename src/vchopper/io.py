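"""Frame-stack and result I/O: image directories, multi-page TIFF, manifests.

A frame stack on disk is either a directory of zero-padded numbered
PNG/TIFF frames or a single multi-page TIFF, with an optional JSON sidecar
manifest (``manifest.json``) carrying timestamps, frame rates, truth labels
and the acquisition configuration.  Lifetime results are written as 32-bit
float TIFF maps plus CSV tables and a manifest sufficient to re-execute the
run.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import re
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError
from .lifetime import LifetimeImage, RoiStats
from .simulate import FrameStack
from .timing import AcquisitionConfig

__all__ = [
    "read_frame_stack",
    "write_frame_stack",
    "write_outputs",
    "config_to_dict",
    "config_from_dict",
]

_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def config_to_dict(config: AcquisitionConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> AcquisitionConfig:
    return AcquisitionConfig(**data)


def _load_manifest(path: Path) -> dict:
    manifest_path = path / "manifest.json" if path.is_dir() else path.with_suffix(".json")
    if manifest_path.exists():
        return json.loads(manifest_path.read_text())
    return {}


def read_frame_stack(
    path: str | Path,
    fps: float | None = None,
    as_gray: bool = False,
) -> FrameStack:
    """Read a frame stack from a directory of numbered frames or a TIFF.

    Frames are ordered by the numeric part of their filenames; a gap in the
    numbering raises :class:`FormatError` naming the missing index.
    Timestamps come from the manifest when present, else ``k / f_real`` using
    the manifest's or the ``fps`` argument's frame rate.
    """
    path = Path(path)
    manifest = _load_manifest(path)

    if path.is_dir():
        entries = []
        for p in sorted(path.iterdir()):
            match = _FRAME_RE.search(p.name)
            if match:
                entries.append((int(match.group(1)), p))
        if not entries:
            raise FormatError(f"no numbered PNG/TIFF frames found in {path}")
        entries.sort()
        numbers = [n for n, _ in entries]
        expected = list(range(numbers[0], numbers[0] + len(numbers)))
        if numbers != expected:
            missing = sorted(set(expected) - set(numbers))[0]
            raise FormatError(f"frame numbering gap: frame {missing} is missing")
        frames = [iio.imread(p) for _, p in entries]
        shapes = {f.shape for f in frames}
        dtypes = {f.dtype for f in frames}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise FormatError("mixed frame shapes or dtypes in directory")
        arr = np.stack(frames)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        raise FormatError(f"unsupported frame-stack path: {path}")

    if as_gray and arr.ndim == 4:
        arr = (arr.astype(np.float64) @ np.array([0.2125, 0.7154, 0.0721])).astype(
            arr.dtype
        )

    nominal = manifest.get("nominal_fps", fps)
    actual = manifest.get("actual_fps", nominal)
    if "timestamps_s" in manifest:
        timestamps = np.asarray(manifest["timestamps_s"], dtype=float)
        if actual and len(timestamps) > 1:
            interval = float(np.median(np.diff(timestamps)))
            expected = 1.0 / float(actual)
            if abs(interval - expected) > 0.01 * expected:
                warnings.warn(
                    f"manifest timestamps (median interval {interval:.6g} s) "
                    f"disagree with the frame rate {actual} fps "
                    f"({expected:.6g} s) by more than 1%; deriving timestamps "
                    "from the frame rate",
                    stacklevel=2,
                )
                timestamps = np.arange(len(arr)) / float(actual)
    else:
        if actual is None:
            raise FormatError("no timestamps and no frame rate available")
        timestamps = np.arange(len(arr)) / actual
    labels = manifest.get("truth_labels")
    delays = manifest.get("truth_delay_s")
    meta = {k: v for k, v in manifest.items() if k not in (
        "timestamps_s", "truth_labels", "truth_delay_s", "nominal_fps", "actual_fps")}
    if "config" in meta:
        meta["config"] = config_from_dict(meta["config"])
    return FrameStack(
        frames=arr,
        timestamps_s=timestamps,
        nominal_fps=float(nominal) if nominal else float(actual or 0) or 0.0,
        actual_fps=float(actual) if actual else 0.0,
        truth_labels=None if labels is None else np.asarray(labels, dtype=np.int8),
        truth_delay_s=None if delays is None else np.asarray(delays, dtype=float),
        meta=meta,
    )


def write_frame_stack(
    stack: FrameStack,
    path: str | Path,
    layout: str = "tiff",
) -> Path:
    """Write a stack as a multi-page TIFF (``layout='tiff'``) or a directory
    of numbered PNGs (``layout='png'``), plus a JSON manifest."""
    path = Path(path)
    if layout == "tiff":
        if path.suffix.lower() not in (".tif", ".tiff"):
            path = path.with_suffix(".tif")
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames)
        manifest_path = path.with_suffix(".json")
    elif layout == "png":
        path.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(stack.n_frames)))
        for i, frame in enumerate(stack.frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
        manifest_path = path / "manifest.json"
    else:
        raise FormatError(f"unknown layout {layout!r}")

    manifest: dict = {
        "nominal_fps": stack.nominal_fps,
        "actual_fps": stack.actual_fps,
        "timestamps_s": stack.timestamps_s.tolist(),
    }
    if stack.truth_labels is not None:
        manifest["truth_labels"] = stack.truth_labels.tolist()
    if stack.truth_delay_s is not None:
        manifest["truth_delay_s"] = [
            None if not np.isfinite(d) else d for d in stack.truth_delay_s
        ]
    for key, value in stack.meta.items():
        if isinstance(value, AcquisitionConfig):
            manifest[key] = config_to_dict(value)
        elif isinstance(value, (int, float, str, bool, list, dict)) or value is None:
            manifest[key] = value
    manifest_path.write_text(json.dumps(manifest))
    return path


def write_outputs(
    image: LifetimeImage,
    stats: dict[str, RoiStats],
    out_dir: str | Path,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
    extra_manifest: dict | None = None,
) -> Path:
    """Write lifetime maps (float32 TIFF), ROI stats CSV, and a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "tau_map_s.tif", image.tau_map.astype(np.float32))
    tifffile.imwrite(out_dir / "fit_quality.tif", image.fit_quality_map.astype(np.float32))
    tifffile.imwrite(out_dir / "mask.tif", image.mask.astype(np.uint8))

    with open(out_dir / "roi_stats.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["roi", "mean_tau_s", "sd_tau_s", "cv", "pixel_count"]
        )
        for name, s in stats.items():
            writer.writerow([name, s.mean_tau_s, s.sd_tau_s, s.cv, s.pixel_count])

    import vchopper

    manifest = {
        "package_version": vchopper.__version__,
        "seed": seed,
        "config": config_to_dict(config) if config else None,
        "f_real_fps": config.actual_frame_rate_fps if config else None,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
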