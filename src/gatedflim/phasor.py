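"""Phasor analysis of gated decay stacks.

The discretized phasor transform maps each pixel's gated decay to a point
(G, S) in the complex plane:

    G = sum_m N_m cos(w (m + 1/2) dT) / sum_m N_m
    S = sum_m N_m sin(w (m + 1/2) dT) / sum_m N_m

with angular frequency w = 2 pi / T and T = k * dT the total detection
time spanned by the gates.  After dividing out the IRF phasor (complex
division per pixel), mono-exponential decays fall on the universal
semicircle G^2 + S^2 = G.  Species with distinct lifetimes form separate
clusters; elliptic cursors around the clusters are mapped back to pixel
masks for downstream pattern extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter
from sklearn.cluster import KMeans

from .core import GatedStack, GateTimeline, IRFParams
from .decay import irf_model

__all__ = ["PhasorImage", "EllipseCursor", "phasor_transform", "irf_phasor",
           "irf_correct", "select_and_backmap", "auto_cursors"]


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates with the gate-summed counts image."""

    G: np.ndarray
    S: np.ndarray
    omega: float
    counts: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.G) & np.isfinite(self.S)

    def median_filtered(self, size: int = 3) -> "PhasorImage":
        """3x3 median filtering of G and S (counts untouched)."""
        return PhasorImage(median_filter(self.G, size=size),
                           median_filter(self.S, size=size),
                           self.omega, self.counts)


@dataclass(frozen=True)
class EllipseCursor:
    """A rotated elliptic selection region in (G, S) space."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("semi-axes must be positive")

    def normalized_distance(self, g, s):
        """Ellipse-normalized distance: <= 1 inside or on the boundary."""
        g = np.asarray(g, dtype=float) - self.center[0]
        s = np.asarray(s, dtype=float) - self.center[1]
        c, sn = np.cos(self.angle), np.sin(self.angle)
        u = c * g + sn * s
        v = -sn * g + c * s
        return np.sqrt((u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2)

    def contains(self, g, s):
        return self.normalized_distance(g, s) <= 1.0

    def to_dict(self) -> dict:
        return {"center": list(self.center), "semi_axes": list(self.semi_axes),
                "angle": self.angle, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseCursor":
        return cls(center=tuple(d["center"]), semi_axes=tuple(d["semi_axes"]),
                   angle=d.get("angle", 0.0), label=d.get("label", ""))


def save_cursors(cursors, path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in cursors], indent=2))


def load_cursors(path: str | Path) -> list[EllipseCursor]:
    return [EllipseCursor.from_dict(d) for d in json.loads(Path(path).read_text())]


def phasor_transform(stack: GatedStack) -> PhasorImage:
    """Discretized phasor transform of a corrected gated stack.

    Zero-count pixels get NaN coordinates.  The phasor frequency is
    ``2 pi / (k * gate_step)`` — the total detection time spanned by the
    gates, independent of the laser period.
    """
    data = np.asarray(stack.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("counts must be non-negative")
    tl = stack.timeline
    T = tl.total_detection_time_ns
    omega = 2.0 * np.pi / T
    phase = omega * tl.gate_step_ns * (np.arange(tl.n_gates) + 0.5)
    shape = (-1,) + (1,) * (data.ndim - 1)
    cosw = np.cos(phase).reshape(shape)
    sinw = np.sin(phase).reshape(shape)
    total = data.sum(axis=0)
    if not np.any(total > 0):
        raise ValueError("stack has no counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (data * cosw).sum(axis=0) / total
        S = (data * sinw).sum(axis=0) / total
    G = np.where(total > 0, G, np.nan)
    S = np.where(total > 0, S, np.nan)
    return PhasorImage(G=G, S=S, omega=omega, counts=total)


def irf_phasor(irf: IRFParams, timeline: GateTimeline) -> tuple[float, float]:
    """Phasor coordinates of the parametrized IRF sampled on the timeline."""
    counts = irf_model(timeline.delays, irf)
    stack = GatedStack(counts.reshape(-1, 1, 1), timeline)
    ph = phasor_transform(stack)
    return float(ph.G[0, 0]), float(ph.S[0, 0])


def irf_correct(total: PhasorImage, irf_ph: tuple[float, float]) -> PhasorImage:
    """Divide the IRF phasor out of every pixel (complex division)."""
    g0, s0 = irf_ph
    denom = g0 * g0 + s0 * s0
    if denom <= 0:
        raise ValueError("IRF phasor has zero modulus")
    z = (total.G + 1j * total.S) / (g0 + 1j * s0)
    return PhasorImage(G=z.real, S=z.imag, omega=total.omega,
                       counts=total.counts)


def select_and_backmap(ph: PhasorImage,
                       cursors: list[EllipseCursor]) -> list[np.ndarray]:
    """Map elliptic cursor selections back to pixel masks.

    A pixel belongs to cursor i when its (G, S) lies inside the ellipse
    (boundary inclusive); pixels inside several cursors go to the one with
    the smaller ellipse-normalized distance.
    """
    if not cursors:
        raise ValueError("need at least one cursor")
    dists = np.stack([c.normalized_distance(ph.G, ph.S) for c in cursors])
    dists = np.where(np.isfinite(dists), dists, np.inf)
    winner = np.argmin(dists, axis=0)
    inside = np.min(dists, axis=0) <= 1.0
    return [(winner == i) & inside for i in range(len(cursors))]


def auto_cursors(ph: PhasorImage, n: int = 2, min_counts: float = 100.0,
                 n_sigma: float = 2.0, seed: int = 0) -> list[EllipseCursor]:
    """Automatic cursor placement by count-weighted k-means in (G, S).

    Pixels with at least ``min_counts`` photons enter a k-means clustering
    weighted by their counts; each cluster becomes an ellipse at
    ``n_sigma`` Mahalanobis sigma of its weighted covariance.  Degenerate
    single-cluster data (cluster centers closer than the within-cluster
    spread) raise a warning via the returned cursors' labels.
    """
    if n < 1:
        raise ValueError("need n >= 1 cursors")
    sel = ph.valid & (ph.counts >= min_counts)
    if not np.any(sel):
        raise ValueError("no phasor points above the count threshold")
    pts = np.column_stack([ph.G[sel], ph.S[sel]])
    wts = ph.counts[sel].astype(float)
    if len(pts) < n:
        raise ValueError("fewer phasor points than requested cursors")
    km = KMeans(n_clusters=n, n_init=10, random_state=seed)
    labels = km.fit_predict(pts, sample_weight=wts)
    cursors = []
    for i in range(n):
        in_i = labels == i
        p, w = pts[in_i], wts[in_i]
        mean = np.average(p, axis=0, weights=w)
        d = p - mean
        cov = (d * w[:, None]).T @ d / w.sum()
        cov += np.eye(2) * 1e-12
        evals, evecs = np.linalg.eigh(cov)
        angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
        axes = n_sigma * np.sqrt(np.maximum(evals[::-1], 1e-12))
        cursors.append(EllipseCursor(center=(float(mean[0]), float(mean[1])),
                                     semi_axes=(float(axes[0]), float(axes[1])),
                                     angle=angle, label=f"cluster_{i}"))
    if n >= 2:
        # k-means splits even a single Gaussian into halves separated by
        # ~2.7x the within-half spread along the split axis; genuinely
        # bimodal clouds separate much further
        centers = np.array([c.center for c in cursors])
        axis = centers[1] - centers[0]
        sep = np.linalg.norm(axis)
        axis = axis / max(sep, 1e-12)
        spreads = []
        for i in (0, 1):
            in_i = labels == i
            proj = (pts[in_i] - centers[i]) @ axis
            w_i = wts[in_i]
            spreads.append(np.sqrt(np.average(proj**2, weights=w_i)))
        if sep < 3.0 * np.mean(spreads):
            import warnings
            warnings.warn("phasor clusters overlap: data may be single-species",
                          stacklevel=2)
            cursors = [EllipseCursor(center=c.center, semi_axes=c.semi_axes,
                                     angle=c.angle, label=c.label + "_degenerate")
                       for c in cursors]
    return cursors
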