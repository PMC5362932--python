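"""Stack and table I/O.

Stacks are written as multi-page TIFF (axes CZYX) with a JSON sidecar
carrying voxel size and channel names; on load, voxel size is resolved
with the precedence explicit config > sidecar > OME metadata, and a
conflict between config and file metadata is logged (config wins).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image_ops import ImageStack
from .scene_sim import GroundTruthScene, SceneConfig

logger = logging.getLogger(__name__)

__all__ = [
    "save_stack",
    "load_stack",
    "save_truth",
    "load_config",
    "save_config",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(stack.voxel_size),
        "channel_names": list(stack.channel_names),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _ome_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    ome = getattr(tif, "ome_metadata", None)
    if not ome:
        return None
    sizes = {}
    for axis in "ZYX":
        m = re.search(rf'PhysicalSize{axis}="([\d.eE+-]+)"', ome)
        if m:
            sizes[axis] = float(m.group(1))
    if set(sizes) == {"Z", "Y", "X"}:
        return (sizes["Z"], sizes["Y"], sizes["X"])
    return None


def load_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into an ImageStack.

    Metadata resolution: an explicit ``voxel_size``/``channel_names``
    argument wins over the JSON sidecar, which wins over OME metadata;
    a disagreement between argument and file metadata is logged.  A
    missing voxel size with no fallback is an error, as is a channel
    count that contradicts the supplied names.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_vs = _ome_voxel_size(tif)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: cannot interpret shape {data.shape} as (C, Z, Y, X)")

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    file_vs = meta.get("voxel_size_um") or ome_vs
    if voxel_size is not None and file_vs is not None:
        if not np.allclose(voxel_size, file_vs):
            logger.warning(
                "%s: config voxel size %s overrides file metadata %s",
                path, voxel_size, tuple(file_vs),
            )
    vs = voxel_size or file_vs
    if vs is None:
        raise ValueError(f"{path}: no voxel size in metadata and none supplied")

    names = channel_names or meta.get("channel_names")
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {len(names)} channel names supplied for "
            f"{data.shape[0]} channels in the file"
        )
    return ImageStack(data=data, voxel_size=tuple(vs), channel_names=tuple(names))


def save_truth(truth: GroundTruthScene, directory: str | Path) -> None:
    """Write ground truth as CSV and the generating config as YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.objects_frame().to_csv(directory / "truth.csv", index=False)
    save_config(truth.config, directory / "scene_config.yaml")


def save_config(cfg: SceneConfig, path: str | Path) -> None:
    d = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items()
    }
    d["nucleus_radii_um"] = [list(r) for r in cfg.nucleus_radii_um]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def load_config(path: str | Path) -> SceneConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return SceneConfig(**{k: _tuplify(v) for k, v in raw.items()})
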