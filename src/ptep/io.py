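"""Image-stack container and file I/O.

The :class:`ImageStack` is the common currency between the simulator and
every analysis stage: an ordered set of equally shaped intensity frames in
[0, 255] plus the two pieces of metadata nothing downstream can be trusted
without — the frame rate (fps) and the pixel size (µm/px).  Recordings in
this domain are reported at both 30 fps and 28 fps, so the frame rate is
mandatory and never assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    frames: np.ndarray            # (T, H, W) or (T, H, W, 3), values in [0, 255]
    frame_rate: float             # fps
    pixel_size_um: float          # µm per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, 3)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:3]

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i):
        return self.frames[i]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page 8-bit TIFF (``.tif``) or a numbered PNG
    sequence (``path`` treated as a directory).  A JSON sidecar carries the
    frame rate and pixel size."""
    path = Path(path)
    frames = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames)
        sidecar = path.with_suffix(path.suffix + ".json")
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
        sidecar = path / "stack.json"
    sidecar.write_text(json.dumps(
        {"frame_rate": stack.frame_rate, "pixel_size_um": stack.pixel_size_um}))
    return path


def read_stack(path: str | Path, frame_rate: float | None = None,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF or a directory of numbered PNG/TIFF frames.

    Metadata is taken from the JSON sidecar written by :func:`write_stack`
    when present; otherwise ``frame_rate`` and ``pixel_size_um`` must be
    given explicitly.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
        sidecar = path / "stack.json"
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_rate = frame_rate or meta.get("frame_rate")
        pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
    if frame_rate is None or pixel_size_um is None:
        raise ValueError("frame_rate and pixel_size_um are mandatory stack "
                         "metadata; provide them or a JSON sidecar")
    return ImageStack(frames=frames, frame_rate=float(frame_rate),
                      pixel_size_um=float(pixel_size_um))
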