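"""In-memory container for multi-bit fluorescence image stacks.

Axis order is ``(bit, z, y, x)`` with 0-based pixel coordinates.  Each
bit corresponds to one round/color combination: ``bit = round * n_colors
+ color``.  Per-bit drift is stored as integer ``(dz, dy, dx)`` pixel
offsets of that bit's images relative to the reference round; drift is
applied to *coordinates* downstream, never by resampling images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    data: np.ndarray  # (n_bits, z, y, x)
    n_colors: int = 2
    pixel_size_um: float = 0.108
    z_step_um: float = 1.0
    drift: np.ndarray = field(default=None)  # (n_bits, 3) int, (dz, dy, dx)
    anchors: np.ndarray | None = None  # (n_rounds, z, y, x) DAPI-like channel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_bits, z, y, x)")
        if self.drift is None:
            self.drift = np.zeros((self.n_bits, 3), dtype=int)
        self.drift = np.asarray(self.drift, dtype=int)
        if self.drift.shape != (self.n_bits, 3):
            raise ValueError("drift must be (n_bits, 3)")

    @property
    def n_bits(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def round_of(self, bit: int) -> int:
        return bit // self.n_colors

    def color_of(self, bit: int) -> int:
        return bit % self.n_colors

    def copy(self) -> "ImageStack":
        return ImageStack(
            data=self.data.copy(),
            n_colors=self.n_colors,
            pixel_size_um=self.pixel_size_um,
            z_step_um=self.z_step_um,
            drift=self.drift.copy(),
            anchors=None if self.anchors is None else self.anchors.copy(),
        )

    def save(self, directory) -> None:
        """One multi-page TIFF per bit plus a JSON sidecar with metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for b in range(self.n_bits):
            tifffile.imwrite(directory / f"bit{b:03d}.tif", self.data[b].astype(np.float32))
        if self.anchors is not None:
            for r in range(self.anchors.shape[0]):
                tifffile.imwrite(
                    directory / f"anchor_round{r:03d}.tif",
                    self.anchors[r].astype(np.float32),
                )
        meta = {
            "n_bits": self.n_bits,
            "n_colors": self.n_colors,
            "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.z_step_um,
            "drift": self.drift.tolist(),
            "n_anchor_rounds": 0 if self.anchors is None else int(self.anchors.shape[0]),
            "bit_map": [
                {"bit": b, "round": self.round_of(b), "color": self.color_of(b)}
                for b in range(self.n_bits)
            ],
        }
        (directory / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "ImageStack":
        directory = Path(directory)
        meta = json.loads((directory / "stack.json").read_text())
        data = np.stack(
            [
                tifffile.imread(directory / f"bit{b:03d}.tif")
                for b in range(meta["n_bits"])
            ]
        )
        anchors = None
        if meta.get("n_anchor_rounds"):
            anchors = np.stack(
                [
                    tifffile.imread(directory / f"anchor_round{r:03d}.tif")
                    for r in range(meta["n_anchor_rounds"])
                ]
            )
        return cls(
            data=data.astype(float),
            n_colors=meta["n_colors"],
            pixel_size_um=meta["pixel_size_um"],
            z_step_um=meta["z_step_um"],
            drift=np.asarray(meta["drift"], dtype=int),
            anchors=anchors,
        )
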