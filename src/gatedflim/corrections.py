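"""Dark-count background subtraction and pile-up correction.

A photon-counting gate assembled from 255 binary frames saturates: when
the per-frame detection probability is no longer small, the measured 8-bit
count under-reports the true photon number.  The logarithmic inversion

    N_corr = -ln(1 - N * F / 255) * 255 / F

undoes this, with ``F = 1`` for static light-sheet illumination and
``F = 3.5`` for scanning illumination (where the beam passage concentrates
the exposure of each pixel row into a fraction of the frame time).
Background subtraction is applied first, pile-up correction second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GatedStack

__all__ = ["PileupFactor", "subtract_background", "pileup_correct",
           "correct_stack"]

_EPS = 1e-3  # clamp margin for saturated pixels, in units of 255/F


@dataclass(frozen=True)
class PileupFactor:
    """Pile-up factor F with its illumination-mode tag."""

    F: float
    mode: str = "static"

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if self.mode not in ("static", "scanning"):
            raise ValueError("mode must be 'static' or 'scanning'")

    @classmethod
    def static(cls) -> "PileupFactor":
        return cls(F=1.0, mode="static")

    @classmethod
    def scanning(cls, F: float = 3.5) -> "PileupFactor":
        return cls(F=F, mode="scanning")


def subtract_background(stack: GatedStack, background: GatedStack,
                        clip: bool = True) -> GatedStack:
    """Subtract a dark-count background stack per gate and pixel.

    With ``clip=True`` (default) negative differences are set to 0, which
    keeps the stack valid for the phasor transform but adds a small
    positive floor to very-low-count gates (the clip only ever removes
    negative values).  Summed-decay fitting over many pixels is better
    served by ``clip=False``, which keeps the per-gate sums unbiased.
    """
    if stack.data.shape != background.data.shape:
        raise ValueError(
            f"shape mismatch: data {stack.data.shape} vs "
            f"background {background.data.shape}")
    out = stack.data.astype(float) - background.data.astype(float)
    if clip:
        np.clip(out, 0.0, None, out=out)
    return GatedStack(out, stack.timeline)


def pileup_correct(N, factor: PileupFactor | float):
    """Invert gate saturation on measured 8-bit counts.

    Returns ``(N_corr, saturated)``.  Slightly negative inputs (from
    unclipped background subtraction) pass through the same smooth
    formula, which approaches the identity near 0.  Counts at or beyond
    the invertible range ``N >= 255/F`` are clamped to the correction at
    ``(255/F)(1 - 1e-3)`` and flagged in the boolean ``saturated`` array.
    """
    F = factor.F if isinstance(factor, PileupFactor) else float(factor)
    if F <= 0:
        raise ValueError("F must be > 0")
    N = np.asarray(N, dtype=float)
    if np.any(N * F / 255.0 <= -1.0):
        raise ValueError("counts below the correction domain")
    nmax = 255.0 / F
    saturated = N >= nmax * (1.0 - _EPS)
    N_eff = np.where(saturated, nmax * (1.0 - _EPS), N)
    N_corr = -np.log1p(-N_eff * F / 255.0) * 255.0 / F
    return N_corr, saturated


def correct_stack(stack: GatedStack, background: GatedStack | None,
                  factor: PileupFactor | float,
                  clip: bool = True) -> tuple[GatedStack, np.ndarray]:
    """Background subtraction followed by pile-up correction.

    The order matters and is fixed: dark counts are removed first, then the
    saturation inversion is applied per gate image.  Returns the corrected
    float stack and a per-pixel saturation mask aggregated over all gates.
    """
    work = stack
    if background is not None:
        work = subtract_background(stack, background, clip=clip)
    corrected, sat = pileup_correct(work.data, factor)
    sat_mask = sat.any(axis=0)
    return GatedStack(corrected, stack.timeline), sat_mask
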