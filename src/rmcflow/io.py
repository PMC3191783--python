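"""Image, contour, configuration and log I/O."""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .edge import ModelParams
from .grid import GridSpec, grid_for_image
from .stepping import ConvergenceRecord, SchedulePlan


def load_image(path) -> tuple[np.ndarray, GridSpec]:
    """Load a grayscale image as a field in ``[0, 1]`` with its grid.

    Multi-channel images are averaged to gray; intensities are min-max
    normalized.  Square images map to the unit square; non-square ones keep
    square cells on ``[0,1] x [0, ny/nx]``.  A constant image has no dynamic
    range to normalize and is rejected.
    """
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a 2D grayscale image")
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        raise ValueError(f"{path}: zero dynamic range")
    field = (arr - lo) / (hi - lo)
    return field, grid_for_image(field)


def save_image(path, field: np.ndarray) -> None:
    """Save a ``[0, 1]`` field as 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    data = np.clip(np.asarray(field, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(data * 65535).astype(np.uint16))


def save_contour_csv(path, points: np.ndarray) -> None:
    """Write contour points as ``x,y`` rows in domain coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        w.writerows(pts.tolist())


def load_contour_csv(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0][:2] == ["x", "y"]:
        rows = rows[1:]
    pts = np.array([[float(r[0]), float(r[1])] for r in rows])
    if pts.size == 0:
        raise ValueError(f"{path}: empty contour file")
    return pts


def save_convergence_record(path, record: ConvergenceRecord) -> None:
    """Serialize a convergence record to JSON (per-step solver statistics)."""
    payload = {
        "scheme": record.scheme,
        "stopped_early": record.stopped_early,
        "failed": record.failed,
        "message": record.message,
        "steps": record.to_dicts(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclasses.dataclass
class RunConfig:
    """Flat, file-round-trippable description of one segmentation run."""

    model: ModelParams = dataclasses.field(default_factory=ModelParams)
    scheme: str = "semi_implicit"
    seed_center: tuple[float, float] = (0.5, 0.5)
    seed_radius: float = 0.15
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_center"] = list(self.seed_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelParams(**d["model"])
        if "seed_center" in d:
            d["seed_center"] = tuple(d["seed_center"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_provenance(path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable record sufficient to reproduce a run."""
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
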