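"""Readers and writers for gated hyperstacks, masks and configs.

On disk a gated hyperstack is a multi-page TIFF with pages ordered
gate-fastest (gate index cycles within each z-plane, z within each
timepoint); the gate timing travels in a YAML sidecar or an
:class:`AcquisitionConfig`.  Parameter images are written as 32-bit float
multi-page TIFFs, masks as 8/16-bit label TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import GatedStack, GateTimeline
from .corrections import PileupFactor

__all__ = ["AcquisitionConfig", "read_gated_tiff", "write_gated_tiff",
           "write_parameter_tiff", "read_mask_tiff", "write_mask_tiff",
           "write_provenance"]

_MODE_F = {"static": 1.0, "scanning": 3.5}


@dataclass
class AcquisitionConfig:
    """Acquisition description loaded from a YAML config file."""

    timeline: GateTimeline
    mode: str = "static"
    pileup_F: float | None = None
    data_path: str | None = None
    background_path: str | None = None
    irf_path: str | None = None
    pixel_size_um: float = 0.41

    def __post_init__(self) -> None:
        if self.mode not in _MODE_F:
            raise ValueError("mode must be 'static' or 'scanning'")

    @property
    def pileup(self) -> PileupFactor:
        F = self.pileup_F if self.pileup_F is not None else _MODE_F[self.mode]
        return PileupFactor(F=F, mode=self.mode)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionConfig":
        d = yaml.safe_load(Path(path).read_text())
        timeline = GateTimeline.from_dict(d["timeline"])
        cfg = cls(timeline=timeline, mode=d.get("mode", "static"),
                  pileup_F=d.get("pileup_F"),
                  data_path=d.get("data_path"),
                  background_path=d.get("background_path"),
                  irf_path=d.get("irf_path"),
                  pixel_size_um=d.get("pixel_size_um", 0.41))
        base = Path(path).parent
        for attr in ("data_path", "background_path", "irf_path"):
            p = getattr(cfg, attr)
            if p is not None:
                full = (base / p) if not Path(p).is_absolute() else Path(p)
                if not full.exists():
                    raise FileNotFoundError(f"{attr} does not exist: {full}")
                setattr(cfg, attr, str(full))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = {"timeline": self.timeline.to_dict(), "mode": self.mode,
             "pixel_size_um": self.pixel_size_um}
        if self.pileup_F is not None:
            d["pileup_F"] = self.pileup_F
        for attr in ("data_path", "background_path", "irf_path"):
            if getattr(self, attr) is not None:
                d[attr] = getattr(self, attr)
        Path(path).write_text(yaml.safe_dump(d))


def read_gated_tiff(path: str | Path, timeline: GateTimeline) -> GatedStack:
    """Read a gate-fastest multi-page TIFF into a gated hyperstack.

    The page count must be divisible by the timeline's gate count; the
    remaining pages become the z axis.  Dtype is preserved.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    k = timeline.n_gates
    n_pages = pages.shape[0]
    if n_pages % k != 0:
        raise ValueError(
            f"page count {n_pages} not divisible by n_gates={k}")
    n_z = n_pages // k
    data = pages.reshape(n_z, k, *pages.shape[1:]).swapaxes(0, 1)
    if n_z == 1:
        data = data[:, 0]
    return GatedStack(np.ascontiguousarray(data), timeline)


def write_gated_tiff(path: str | Path, stack: GatedStack) -> None:
    """Write a gated hyperstack as a gate-fastest multi-page TIFF."""
    data = stack.data
    if data.ndim == 3:
        pages = data
    elif data.ndim == 4:
        pages = data.swapaxes(0, 1).reshape(-1, *data.shape[2:])
    else:
        raise ValueError("only (gate, y, x) or (gate, z, y, x) stacks "
                         "can be written")
    tifffile.imwrite(str(path), np.ascontiguousarray(pages))


def write_parameter_tiff(path: str | Path, images: dict[str, np.ndarray]) -> None:
    """Write named parameter images as a float32 multi-page TIFF; page
    names go into the page descriptions."""
    pages = np.stack([np.asarray(img, dtype=np.float32)
                      for img in images.values()])
    tifffile.imwrite(str(path), pages,
                     description=json.dumps(list(images.keys())))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint8)
    tifffile.imwrite(str(path), mask)


def write_provenance(path: str | Path, command: str, inputs: dict,
                     parameters: dict) -> None:
    """JSON provenance record sufficient to re-run a CLI subcommand."""
    from . import __version__
    record = {"command": command, "inputs": inputs, "parameters": parameters,
              "software": {"name": "gatedflim", "version": __version__}}
    Path(path).write_text(json.dumps(record, indent=2, default=str))
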