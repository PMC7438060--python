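"""Image/result readers and writers and the run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .affine import AffineTransform2D
from .alignment import AlignmentResult

__all__ = ["RunConfig", "read_image", "write_result", "read_result",
           "write_config", "read_config", "ResultSchemaError"]


@dataclass
class RunConfig:
    """All tunables of an alignment run; every default is the pipeline default."""

    backend_name: str = "sift"
    max_tilt_index: int = 5
    nndr_ratio: float = 0.75
    ransac_iterations: int = 150_000
    ransac_confidence: float = 0.999
    reproj_threshold_px: float = 3.0
    n_repeats: int = 100
    clahe: bool = False
    clahe_tile_grid: tuple = (8, 8)
    clahe_clip_limit: float = 1.0
    min_roi_pixels: int = 60
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clahe_tile_grid"] = list(d["clahe_tile_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "clahe_tile_grid" in d:
            d["clahe_tile_grid"] = tuple(d["clahe_tile_grid"])
        return cls(**d)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    text = (json.dumps(config.to_dict(), indent=2) if path.suffix == ".json"
            else yaml.safe_dump(config.to_dict()))
    path.write_text(text)


def read_config(path) -> RunConfig:
    path = Path(path)
    data = (json.loads(path.read_text()) if path.suffix == ".json"
            else yaml.safe_load(path.read_text()))
    return RunConfig.from_dict(data)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def read_image(path, allow_rgb: bool = False) -> tuple[np.ndarray, dict]:
    """Read a TIFF/PNG plane or stack as an 8-bit grayscale FOV image.

    A stack is mean-projected over its first axis; anything not already 8-bit
    is min-max normalized to [0, 255].  Returns ``(array, metadata)`` where
    the metadata records the source dtype and whether a projection was
    applied.  RGB input is rejected unless ``allow_rgb`` requests a luminance
    conversion.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"could not read image {path}: {exc}") from exc
    meta = {"source_dtype": str(arr.dtype), "source_shape": list(arr.shape),
            "projected": False}
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if not allow_rgb:
            raise ValueError(
                f"{path} is RGB; pass allow_rgb=True for a grayscale conversion")
        arr = arr[..., :3].astype(float).mean(axis=-1)
    if arr.ndim == 3:
        arr = arr.astype(float).mean(axis=0)
        meta["projected"] = True
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image or a stack, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = _to_uint8(arr)
    return arr, meta


class ResultSchemaError(ValueError):
    pass


_REQUIRED_KEYS = ("transform", "n_inliers", "n_matched", "n_features_moving",
                  "n_features_template", "inlier_ratio", "l1_scores",
                  "selected_repeat", "backend_name", "seed")


def write_result(result: AlignmentResult, path) -> None:
    """Serialize an alignment result to JSON.

    The transform is stored as the 6 numbers ``[a, b, e, c, d, f]`` (2x3
    row-major); per-repeat L1 scores and inlier counts are kept for replay.
    """
    payload = {
        "transform": list(result.transform.matrix.ravel()),
        "n_inliers": result.n_inliers,
        "n_matched": result.n_matched,
        "n_features_moving": result.n_features_moving,
        "n_features_template": result.n_features_template,
        "inlier_ratio": result.inlier_ratio,
        "l1_scores": [s if np.isfinite(s) else None for s in result.l1_scores],
        "selected_repeat": result.selected_repeat,
        "backend_name": result.backend_name,
        "seed": result.seed,
        "repeat_inliers": list(map(int, result.repeat_inliers)),
        "repeat_transforms": [None if t is None else list(t.matrix.ravel())
                              for t in result.repeat_transforms],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_result(path) -> AlignmentResult:
    data = json.loads(Path(path).read_text())
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise ResultSchemaError(f"result file missing required key {key!r}")
    tf = np.asarray(data["transform"], dtype=float)
    if tf.size != 6:
        raise ResultSchemaError("transform must hold 6 numbers [a, b, e, c, d, f]")
    return AlignmentResult(
        transform=AffineTransform2D.from_matrix(tf.reshape(2, 3)),
        n_inliers=int(data["n_inliers"]),
        n_matched=int(data["n_matched"]),
        n_features_moving=int(data["n_features_moving"]),
        n_features_template=int(data["n_features_template"]),
        inlier_ratio=float(data["inlier_ratio"]),
        l1_scores=[float("inf") if s is None else float(s) for s in data["l1_scores"]],
        selected_repeat=int(data["selected_repeat"]),
        backend_name=data["backend_name"],
        seed=int(data["seed"]),
        repeat_inliers=[int(i) for i in data.get("repeat_inliers", [])],
        repeat_transforms=[
            None if t is None else AffineTransform2D.from_matrix(
                np.asarray(t, dtype=float).reshape(2, 3))
            for t in data.get("repeat_transforms", [])],
    )
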