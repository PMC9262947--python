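"""Calibrated file I/O: multi-page TIFF stacks with YAML sidecars, CSV
tables, JSON metrics and run manifests.

Convention: one grayscale 16-bit TIFF per channel, with a ``<stem>.yaml``
sidecar holding the physical calibration (and, for synthetic data, the
ground-truth parameters).  Reading a stack without calibration — no sidecar
and no explicit overrides — is an error; pixel units are never silently
assumed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from minwaves.geometry import GeometryError, ImageStack, StackGeometry

__all__ = [
    "CalibrationError",
    "write_stack",
    "read_stack",
    "sidecar_path",
    "RunManifest",
    "write_manifest",
    "file_digest",
]


class CalibrationError(ValueError):
    """Physical calibration is missing and no override was given."""


def sidecar_path(stack_path: Path | str) -> Path:
    return Path(stack_path).with_suffix(".yaml")


def write_stack(
    stack: ImageStack, path: Path | str, ground_truth: dict | None = None
) -> Path:
    """Write a stack as grayscale 16-bit multi-page TIFF plus YAML sidecar.

    Intensities are rounded and clipped to the uint16 range (fixed scaling:
    1 intensity unit = 1 grey level); integer-valued data in range round-trip
    losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.geometry.pixel_size_um,
        "frame_interval_s": stack.geometry.frame_interval_s,
        "channel_label": stack.channel_label,
    }
    if ground_truth:
        meta["ground_truth"] = ground_truth
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(
    path: Path | str,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a calibrated stack from multi-page TIFF.

    Calibration comes from the YAML sidecar unless explicitly overridden.
    Raises :class:`CalibrationError` when neither source provides it, and
    rejects RGB input (one grayscale channel per file).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise GeometryError(
            f"{path.name}: expected a single-channel T x H x W stack, got shape "
            f"{data.shape} (RGB/multi-sample input is not supported)"
        )

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise CalibrationError(
            f"{path.name}: no calibration found — provide a YAML sidecar or "
            "explicit pixel_size_um / frame_interval_s (pixel units are never assumed)"
        )
    geom = StackGeometry(
        n_frames=data.shape[0],
        height=data.shape[1],
        width=data.shape[2],
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
    )
    return ImageStack(
        data.astype(float), geom, channel_label=str(meta.get("channel_label", ""))
    )


def file_digest(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per output directory."""

    tool_version: str
    config: dict
    seed: int | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    started_utc: str = ""
    finished_utc: str = ""
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/error msg

    def mark(self, stage: str, status: str) -> None:
        self.stages[stage] = status


def write_manifest(manifest: RunManifest, out_dir: Path | str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest.__dict__, sort_keys=False))
    return path


def write_json(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
    return path
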