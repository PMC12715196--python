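"""Two-species lifetime unmixing by pattern matching.

Each fluorophore species is summarized by a fixed two-component decay
signature (:class:`~gatedflim.core.LifetimePattern`).  Patterns are derived
from phasor-selected pixel masks by summed-decay fitting; a superposition
of the patterns, with only the per-species amplitudes free, is then fitted
to every pixel, and the amplitudes weight the total pixel intensity into
unmixed per-species intensity images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import GatedStack, GateTimeline, IRFParams, LifetimePattern
from .decay import gated_decay
from .fitting import FitConfig, FitResult, sum_fit

__all__ = ["UnmixResult", "derive_patterns", "average_patterns",
           "pattern_curve", "pattern_fit", "composite_image"]


@dataclass
class UnmixResult:
    """Pixel-wise pattern decomposition.

    ``amplitudes`` are the raw per-species amplitude images;
    ``amplitudes_smoothed`` the Gaussian-smoothed (sigma = 1 px) maps used
    for intensity weighting.  ``unmixed`` are the species intensity images
    from the smoothed amplitudes; ``unmixed_raw`` uses the raw amplitudes
    and sums exactly to the total intensity.
    """

    labels: list[str]
    amplitudes: np.ndarray        # (species, y, x)
    amplitudes_smoothed: np.ndarray
    unmixed: np.ndarray           # (species, y, x)
    unmixed_raw: np.ndarray
    residual: np.ndarray          # (y, x) rms of fit residuals
    total: np.ndarray


def derive_patterns(stack: GatedStack, masks: Sequence[np.ndarray],
                    irf: IRFParams, labels: Sequence[str] | None = None,
                    config: FitConfig | None = None,
                    ) -> tuple[list[LifetimePattern], list[FitResult]]:
    """Fit a free two-component model to each mask's summed decay.

    Masks must be disjoint and non-empty.  Returns one
    :class:`LifetimePattern` (tau1, tau2, short-amplitude fraction) per
    mask together with the underlying :class:`FitResult`.
    """
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    overlap = np.zeros(stack.frame_shape, dtype=int)
    for m in masks:
        overlap += np.asarray(m, dtype=bool).astype(int)
    if np.any(overlap > 1):
        raise ValueError("masks must be disjoint")
    labels = list(labels) if labels is not None \
        else [f"species_{i}" for i in range(len(masks))]
    patterns, results = [], []
    for label, mask in zip(labels, masks):
        res = sum_fit(stack, mask, irf, n_components=2, config=config)
        if not res.converged:
            raise RuntimeError(
                f"pattern fit for {label!r} did not converge: {res.message} "
                f"(photons={res.n_photons:.3g})")
        p = res.params
        patterns.append(LifetimePattern(label=label, tau1=p["tau1"],
                                        tau2=p["tau2"], a1=p["f1"]))
        results.append(res)
    return patterns, results


def average_patterns(patterns: Sequence[LifetimePattern],
                     weights: Sequence[float] | None = None) -> LifetimePattern:
    """Photon-weighted average of per-plane/per-organoid patterns."""
    if not patterns:
        raise ValueError("no patterns to average")
    w = np.ones(len(patterns)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    return LifetimePattern(
        label=patterns[0].label,
        tau1=float(np.sum(w * [p.tau1 for p in patterns])),
        tau2=float(np.sum(w * [p.tau2 for p in patterns])),
        a1=float(np.sum(w * [p.a1 for p in patterns])))


def pattern_curve(pattern: LifetimePattern, timeline: GateTimeline,
                  irf: IRFParams) -> np.ndarray:
    """Unit-amplitude gated model curve of a two-component pattern."""
    t = timeline.delays
    g1 = gated_decay(t, 1.0, pattern.tau1, irf.t0, irf.sigma, irf.gate_width)
    g2 = gated_decay(t, 1.0, pattern.tau2, irf.t0, irf.sigma, irf.gate_width)
    return pattern.a1 * g1 + pattern.a2 * g2


def _poisson_amplitudes(counts: np.ndarray, curves: np.ndarray,
                        n_iter: int = 2000, rtol: float = 1e-12) -> np.ndarray:
    """Non-negative Poisson MLE of superposition amplitudes, all pixels at
    once, by multiplicative (EM / Richardson-Lucy type) updates.

    counts: (k, n_pix); curves: (species, k).  Returns (species, n_pix).
    """
    n_species, k = curves.shape
    totals = counts.sum(axis=0)
    curve_sums = curves.sum(axis=1)  # (species,)
    # start from equal photon split among species
    a = np.tile((totals / max(n_species, 1))[None, :], (n_species, 1))
    a /= curve_sums[:, None]
    a = np.maximum(a, 1e-30)
    for _ in range(n_iter):
        mu = curves.T @ a                      # (k, n_pix)
        ratio = np.where(mu > 0, counts / np.maximum(mu, 1e-300), 0.0)
        update = (curves @ ratio) / curve_sums[:, None]
        a_new = a * update
        if np.max(np.abs(a_new - a)) <= rtol * max(np.max(a), 1e-30):
            a = a_new
            break
        a = a_new
    a[:, totals <= 0] = 0.0
    return a


def pattern_fit(stack: GatedStack, patterns: Sequence[LifetimePattern],
                irf: IRFParams, smooth_sigma: float = 1.0) -> UnmixResult:
    """Pixel-wise superposition fit with fixed patterns, amplitudes free.

    The per-pixel expected curve is ``sum_s a_s * pattern_curve_s`` with
    the pattern curves normalized to unit gate-sum, so each fitted
    amplitude is the photon count attributed to that species; the
    non-negative amplitudes are the Poisson MLE.  Amplitude maps are then
    smoothed with a Gaussian kernel (``smooth_sigma`` pixels) before
    weighting the total intensity into unmixed species images.
    """
    if stack.data.ndim != 3:
        raise ValueError("pattern_fit expects a (gate, y, x) stack")
    curves = np.stack([pattern_curve(p, stack.timeline, irf) for p in patterns])
    curves /= curves.sum(axis=1, keepdims=True)
    k, h, w = stack.data.shape
    counts = stack.data.reshape(k, -1).astype(float)
    amps = _poisson_amplitudes(counts, curves).reshape(len(patterns), h, w)

    mu = np.einsum("sk,syx->kyx", curves, amps)
    residual = np.sqrt(np.mean((stack.data - mu) ** 2, axis=0))
    total = stack.total_counts().astype(float)

    def weighted(a):
        s = a.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(s > 0, a / s, 0.0)
        return frac * total[None]

    smoothed = np.stack([gaussian_filter(a, smooth_sigma) for a in amps]) \
        if smooth_sigma > 0 else amps.copy()
    return UnmixResult(labels=[p.label for p in patterns],
                       amplitudes=amps, amplitudes_smoothed=smoothed,
                       unmixed=weighted(smoothed), unmixed_raw=weighted(amps),
                       residual=residual, total=total)


def composite_image(result: UnmixResult, smoothed: bool = True) -> np.ndarray:
    """Stack the unmixed species images into a multi-channel composite.

    Returns a float32 array of shape (species, y, x); channel order follows
    the pattern order of the fit.
    """
    channels = result.unmixed if smoothed else result.unmixed_raw
    return np.asarray(channels, dtype=np.float32)
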