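"""3-D OCT intensity volumes and their on-disk format.

The z axis is *optical-path* space: a pixel step of ``z_pitch`` micrometres
corresponds to ``z_pitch`` micrometres of optical path length (geometric
distance times the local refractive index), which is what a spectral-domain
OCT instrument actually samples.  Conversion to geometric distance happens
downstream in :mod:`danioeye.oct_biometry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class OctVolume:
    """An OCT intensity volume with axes (z, y, x).

    Parameters
    ----------
    data
        Intensity array, shape (nz, ny, nx), arbitrary units.  The z axis is
        depth in optical-path space, index 0 at the shallowest pixel.
    z_pitch
        Depth sampling pitch in µm of optical path per pixel.
    lateral_pitch
        Lateral sampling pitch in µm (geometric) per pixel, both y and x.
    meta
        Free-form metadata (written to the JSON sidecar on save).
    """

    data: np.ndarray
    z_pitch: float = 2.0
    lateral_pitch: float = 12.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D (z, y, x), got shape {self.data.shape}")
        if self.z_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def depth_um(self) -> float:
        """Total depth of the volume in optical-path µm."""
        return self.data.shape[0] * self.z_pitch

    def save(self, path: str | Path) -> Path:
        """Write a multi-page 16-bit grayscale TIFF (z as page axis) plus a
        JSON sidecar ``<path>.json`` holding the pixel pitches."""
        path = Path(path)
        data = np.clip(self.data, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = {
            "z_pitch_um": self.z_pitch,
            "lateral_pitch_um": self.lateral_pitch,
            "axes": "ZYX",
            **self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "OctVolume":
        """Read a TIFF volume written by :meth:`save` (sidecar required)."""
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        return cls(
            data=np.asarray(data),
            z_pitch=float(meta.pop("z_pitch_um")),
            lateral_pitch=float(meta.pop("lateral_pitch_um")),
            meta=meta,
        )
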