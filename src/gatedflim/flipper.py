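"""Two-round lifetime analysis for the Flipper-TR membrane tension probe.

Flipper-TR decays are well described by two exponential components whose
long lifetime tracks membrane tension.  Round 1 fits a free two-component
model to the summed decay of each z-plane (pixels between the 50th and
95th intensity percentile, selecting in-focus membrane and excluding the
brightest, pile-up-prone areas) and averages the short lifetime and the
short-amplitude fraction over planes and organoids.  Round 2 re-fits every
plane/timepoint (or every segmented cell) with those two values fixed,
leaving only the long lifetime and the overall amplitude free — a far
lower-variance estimator of the tension-reporting lifetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .core import GatedStack, IRFParams
from .fitting import FitConfig, FitResult, fit_decay, sum_fit

__all__ = ["FlipperGlobals", "percentile_mask", "round1_free_fit",
           "round2_fixed_fit", "cell_fit"]


@dataclass(frozen=True)
class FlipperGlobals:
    """Globally fixed short lifetime and short-amplitude fraction.

    ``amplitude_ratio`` is the short-component amplitude fraction
    a1 / (a1 + a2); 0.45 means 45% of the pre-exponential amplitude is in
    the short component.
    """

    tau1: float
    amplitude_ratio: float
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError("tau1 must be > 0")
        if not (0.0 < self.amplitude_ratio < 1.0):
            raise ValueError("amplitude ratio must be in (0, 1)")


def percentile_mask(image: np.ndarray, lo: float = 50.0,
                    hi: float = 95.0) -> np.ndarray:
    """Pixels with intensity between the lo-th and hi-th percentile
    (inclusive): in-focus areas without the very bright, pile-up-prone
    pixels.  A constant image yields an empty mask (with a warning)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    p_lo, p_hi = np.percentile(image, [lo, hi])
    if p_lo == p_hi:
        warnings.warn("constant image: percentile mask is empty", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    return (image >= p_lo) & (image <= p_hi)


def round1_free_fit(planes: Sequence[GatedStack], irf: IRFParams,
                    config: FitConfig | None = None,
                    ) -> tuple[FlipperGlobals, pd.DataFrame]:
    """Free two-component sum fits per plane; unweighted average globals.

    Each plane is percentile-masked, its masked decay summed and fitted
    with both lifetimes and the amplitude ratio free.  Returns the
    :class:`FlipperGlobals` (mean tau1 and ratio over converged planes)
    and the per-plane fit table (tau1, tau2, ratio, photons, converged).
    """
    if not planes:
        raise ValueError("need at least one plane")
    rows = []
    for i, plane in enumerate(planes):
        mask = percentile_mask(plane.total_counts())
        if not mask.any():
            rows.append((i, np.nan, np.nan, np.nan, 0.0, False))
            continue
        res = sum_fit(plane, mask, irf, n_components=2, config=config)
        p = res.params
        rows.append((i, p["tau1"], p["tau2"], p["f1"], res.n_photons,
                     res.converged))
    table = pd.DataFrame(rows, columns=["plane", "tau1", "tau2", "ratio",
                                        "n_photons", "converged"])
    ok = table[table.converged]
    if len(ok) == 0:
        raise RuntimeError("no plane fit converged; cannot form globals")
    if len(ok) < 3:
        warnings.warn(f"only {len(ok)} converged plane(s); globals may be "
                      "unreliable", stacklevel=2)
    globals_ = FlipperGlobals(tau1=float(ok.tau1.mean()),
                              amplitude_ratio=float(ok.ratio.mean()),
                              provenance=tuple(ok.plane.astype(int)))
    return globals_, table


def _fixed_fit(counts: np.ndarray, timeline, irf: IRFParams,
               globals_: FlipperGlobals,
               config: FitConfig | None) -> FitResult:
    return fit_decay(counts, timeline, irf, n_components=2,
                     fixed={"tau1": globals_.tau1,
                            "f1": globals_.amplitude_ratio},
                     config=config)


def round2_fixed_fit(planes: Mapping[tuple[float, float], GatedStack],
                     irf: IRFParams, globals_: FlipperGlobals,
                     config: FitConfig | None = None) -> pd.DataFrame:
    """Fixed-globals fits per (time, z) plane.

    ``planes`` maps (time_s, z_um) to corrected gated planes.  Each plane
    is percentile-masked, the masked decay summed and fitted with only the
    long lifetime and amplitude free.  Reports the mean masked intensity
    alongside tau2.  Zero-photon planes are kept as non-converged rows.
    """
    rows = []
    for (time_s, z_um), plane in sorted(planes.items()):
        intensity = plane.total_counts()
        mask = percentile_mask(intensity)
        if not mask.any() or plane.data[:, mask].sum() <= 0:
            rows.append((time_s, z_um, np.nan, np.nan, 0.0, False))
            continue
        counts = plane.data[:, mask].sum(axis=1)
        res = _fixed_fit(counts, plane.timeline, irf, globals_, config)
        rows.append((time_s, z_um, res.params["tau2"],
                     float(intensity[mask].mean()), res.n_photons,
                     res.converged))
    return pd.DataFrame(rows, columns=["time_s", "z_um", "tau2_ns",
                                       "mean_intensity", "n_photons",
                                       "converged"])


def cell_fit(stacks: Mapping[float, GatedStack],
             cell_masks: Mapping[float, np.ndarray],
             irf: IRFParams, globals_: FlipperGlobals,
             dilation_radius: int = 1,
             config: FitConfig | None = None) -> pd.DataFrame:
    """Per-cell fixed-globals fits over a time-lapse.

    ``stacks`` maps time to the (single z-plane) gated stack containing
    the cells; ``cell_masks`` maps time to an integer label image (0 =
    background).  Each cell mask is dilated with a disk of radius 1 to
    cover the full width of the cell outline before summing its decay.
    Cells missing at a timepoint are skipped.
    """
    rows = []
    footprint = disk(dilation_radius)
    for time_s in sorted(stacks):
        if time_s not in cell_masks:
            continue
        stack = stacks[time_s]
        labels = np.asarray(cell_masks[time_s])
        intensity = stack.total_counts()
        for cell_id in np.unique(labels):
            if cell_id == 0:
                continue
            mask = binary_dilation(labels == cell_id, footprint)
            counts = stack.data[:, mask].sum(axis=1)
            if counts.sum() <= 0:
                continue
            res = _fixed_fit(counts, stack.timeline, irf, globals_, config)
            rows.append((time_s, int(cell_id), res.params["tau2"],
                         float(intensity[mask].mean()), res.n_photons,
                         res.converged))
    return pd.DataFrame(rows, columns=["time_s", "cell", "tau2_ns",
                                       "mean_intensity", "n_photons",
                                       "converged"])
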