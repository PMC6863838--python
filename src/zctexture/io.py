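"""Image and table I/O plus analysis configuration.

Images travel as single- or multi-page TIFF with a JSON sidecar carrying
the pixel size and channel names (TIFF itself does not reliably store
physical calibration, so the sidecar — or an explicit argument — is the
source of truth; a missing pixel size is an error, never a silent default).
Scenes round-trip as multi-page TIFF + a JSON truth summary.  Tables are
plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image import ImagePlane
from .synthetic import Scene, SceneConfig, SceneTruth

__all__ = [
    "read_image",
    "write_image",
    "write_scene",
    "read_scene",
    "AnalysisConfig",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(
    path: str | Path,
    planes: dict[str, ImagePlane] | ImagePlane,
    dtype=None,
) -> None:
    """Write channel planes as a multi-page TIFF with a JSON sidecar.

    16-bit integer data round-trips bit-exactly when ``dtype=np.uint16``;
    float data is written as float32 by default.
    """
    path = Path(path)
    if isinstance(planes, ImagePlane):
        planes = {planes.channel or "ch0": planes}
    names = list(planes)
    px = {p.pixel_size_um for p in planes.values()}
    if len(px) != 1:
        raise ValueError("all channels must share one pixel size")
    stack = np.stack([planes[n].data for n in names])
    out_dtype = dtype or np.float32
    tifffile.imwrite(path, stack.astype(out_dtype))
    meta = {"pixel_size_um": px.pop(), "channels": names}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_names: list[str] | None = None,
) -> dict[str, ImagePlane]:
    """Read a single- or multi-page TIFF into named float ImagePlanes.

    The pixel size comes from the JSON sidecar when present, else from the
    ``pixel_size_um`` argument; if neither is available the read fails.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            f"pixel size for {path} is unknown: no sidecar metadata and no pixel_size_um given"
        )
    names = channel_names or meta.get("channels") or [f"ch{i}" for i in range(len(data))]
    if len(names) != len(data):
        raise ValueError(f"{len(data)} pages but {len(names)} channel names")
    return {
        n: ImagePlane(page.astype(np.float64), float(px), channel=n)
        for n, page in zip(names, data)
    }


def write_scene(scene: Scene, out_dir: str | Path, stem: str = "scene") -> Path:
    """Write a scene as multi-page TIFF + JSON sidecar with config and truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    write_image(tif, scene.channels)
    truth = {
        "config": asdict(scene.config),
        "char_length_um": scene.truth.char_length_um,
        "cell_area_px": int(scene.truth.cell_mask.sum()),
        "centrelines": [c.tolist() for c in scene.truth.structure_centrelines],
    }
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(truth))
    np.savetxt(out_dir / f"{stem}.cellmask.csv", scene.truth.cell_mask.astype(np.uint8), fmt="%d", delimiter=",")
    return tif


def read_scene(out_dir: str | Path, stem: str = "scene") -> tuple[dict[str, ImagePlane], dict]:
    """Read back a written scene's channels and truth summary."""
    out_dir = Path(out_dir)
    channels = read_image(out_dir / f"{stem}.tif")
    truth = json.loads((out_dir / f"{stem}.truth.json").read_text())
    return channels, truth


@dataclass
class AnalysisConfig:
    """Configuration of an end-to-end timecourse analysis run."""

    times_min: list[float] = field(default_factory=lambda: [0.0, 10.0, 60.0])
    n_experiments: int = 3
    cells_per_time: int = 10
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (128, 128)
    n_lines: int = 400
    window_um: float = 10.0
    seed: int = 0
    posthoc: str = "bonferroni"
    anchor_low: float = 0.0
    anchor_high: float = 60.0
    out_dir: str = "results"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.image_shape = tuple(cfg.image_shape)  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_shape"] = list(d["image_shape"])
        Path(path).write_text(yaml.safe_dump(d))
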