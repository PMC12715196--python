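"""Maximum-likelihood fitting of gated decay and IRF models.

The estimation API follows the model/results pattern: a model object is
built from a gated count vector plus the acquisition clock, ``fit()`` runs
bounded quasi-Newton (L-BFGS-B) optimization of the Poisson negative
log-likelihood (or a weighted least-squares objective), and returns a
:class:`FitResult` carrying the estimates, their standard errors from the
observed information, convergence diagnostics and a ``summary()`` table.

Decay fits support one or two exponential components with any subset of
{total amplitude, short-amplitude fraction, lifetimes, time offset,
baseline} held fixed; the IRF parameters sigma and gate width are always
taken from an IRF measurement and held fixed, as gated data alone cannot
constrain them together with the lifetimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import GatedStack, GateTimeline, IRFParams
from .decay import gated_decay, irf_model

__all__ = [
    "FitConfig",
    "FitResult",
    "GatedDecayModel",
    "IRFModel",
    "fit_irf",
    "fit_decay",
    "sum_fit",
    "pixelwise_fit",
]

_TINY = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings and bounds shared by all fits.

    ``likelihood`` is ``"poisson"`` (negative log-likelihood of Poisson
    counts, the default) or ``"lsq"`` (least squares weighted by
    ``max(counts, 1)``, useful when pile-up-corrected counts are no longer
    Poisson).  ``min_photons`` flags fits on fewer total counts as
    non-converged without running the optimizer.
    """

    likelihood: str = "poisson"
    tau_bounds: tuple[float, float] = (0.05, 20.0)
    sigma_bounds: tuple[float, float] = (0.01, 5.0)
    max_iter: int = 500
    tol: float = 1e-8
    min_photons: float = 100.0

    def __post_init__(self) -> None:
        if self.likelihood not in ("poisson", "lsq"):
            raise ValueError("likelihood must be 'poisson' or 'lsq'")
        if self.tau_bounds[0] >= self.tau_bounds[1]:
            raise ValueError("tau bounds must satisfy lower < upper")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class FitResult:
    """Estimates and diagnostics of one maximum-likelihood fit."""

    estimates: dict[str, float]
    fixed: dict[str, float]
    neg_log_likelihood: float
    n_photons: float
    converged: bool
    n_gates_used: int
    bse: dict[str, float] | None = None
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        """All parameters, free estimates and fixed values merged."""
        return {**self.fixed, **self.estimates}

    def summary(self) -> pd.DataFrame:
        """Parameter table: estimate, std. error, fixed flag."""
        rows = []
        for name, value in self.estimates.items():
            se = self.bse.get(name, np.nan) if self.bse else np.nan
            rows.append((name, value, se, False))
        for name, value in self.fixed.items():
            rows.append((name, value, np.nan, True))
        df = pd.DataFrame(rows, columns=["param", "estimate", "std_err", "fixed"])
        df.attrs["neg_log_likelihood"] = self.neg_log_likelihood
        df.attrs["n_photons"] = self.n_photons
        df.attrs["converged"] = self.converged
        return df.set_index("param")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        est = ", ".join(f"{k}={v:.4g}" for k, v in self.estimates.items())
        return (f"FitResult({est}; nll={self.neg_log_likelihood:.4g}, "
                f"photons={self.n_photons:.3g}, converged={self.converged})")


def _lsq_weights(counts: np.ndarray) -> np.ndarray:
    """Poisson-motivated least-squares weights, floored at 5% of the mean
    count so they stay homogeneous in the count scale (estimates are then
    invariant under uniform rescaling of the data)."""
    floor = 0.05 * counts.mean()
    if floor <= 0:
        floor = 1.0
    return np.maximum(counts, floor)


def _nll(counts: np.ndarray, mu: np.ndarray, kind: str) -> float:
    mu = np.maximum(mu, _TINY)
    if kind == "poisson":
        return float(np.sum(mu - counts * np.log(mu)))
    return float(0.5 * np.sum((counts - mu) ** 2 / _lsq_weights(counts)))


def _tail_lifetime(counts: np.ndarray, delays: np.ndarray) -> float:
    """Deterministic lifetime initializer: log-slope of the decay tail.

    Uses the last 60% of gates after the peak that sit above the baseline
    level (minimum gate count).
    """
    peak = int(np.argmax(counts))
    tail_c = counts[peak:]
    tail_t = delays[peak:]
    base = tail_c.min()
    keep = tail_c > base + _TINY
    if keep.sum() >= 3:
        tail_c, tail_t = tail_c[keep], tail_t[keep]
    n = len(tail_c)
    if n < 3:
        return 2.0
    start = max(0, n - max(3, int(np.ceil(0.6 * n))))
    y = np.log(np.maximum(tail_c[start:] - base * 0.0, _TINY))
    t = tail_t[start:]
    slope = np.polyfit(t, y, 1)[0]
    if slope >= -1e-9:
        return 2.0
    return float(-1.0 / slope)


class _LikelihoodModel:
    """Shared machinery: L-BFGS-B optimization + observed-information SEs."""

    counts: np.ndarray
    config: FitConfig
    free_names: list[str]
    bounds: list[tuple[float, float]]
    fixed: dict[str, float]

    def expected(self, values: Mapping[str, float]) -> np.ndarray:
        raise NotImplementedError

    def _vector_to_params(self, x: np.ndarray) -> dict[str, float]:
        p = dict(self.fixed)
        p.update({n: float(v) for n, v in zip(self.free_names, x)})
        return p

    def nloglike(self, x: np.ndarray) -> float:
        mu = self.expected(self._vector_to_params(x))
        return _nll(self.counts, mu, self.config.likelihood)

    def _optimize(self, starts: Sequence[np.ndarray]) -> tuple[np.ndarray, float, bool, str]:
        best = None
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in self.bounds])
        hi = np.array([b[1] if b[1] is not None else np.inf for b in self.bounds])
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            res = minimize(self.nloglike, x0, method="L-BFGS-B",
                           bounds=self.bounds,
                           options={"maxiter": self.config.max_iter,
                                    "ftol": self.config.tol,
                                    "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        msg = best.message if isinstance(best.message, str) else str(best.message)
        return best.x, float(best.fun), bool(best.success), msg

    def _standard_errors(self, x: np.ndarray) -> dict[str, float] | None:
        """Standard errors from the inverse observed information (numerical
        Hessian of the NLL, central differences)."""
        n = len(x)
        h = np.maximum(1e-4, 1e-4 * np.abs(x))
        H = np.zeros((n, n))
        f0 = self.nloglike(x)
        try:
            for i in range(n):
                for j in range(i, n):
                    ei = np.zeros(n); ei[i] = h[i]
                    ej = np.zeros(n); ej[j] = h[j]
                    if i == j:
                        H[i, i] = (self.nloglike(x + ei) - 2 * f0
                                   + self.nloglike(x - ei)) / h[i] ** 2
                    else:
                        H[i, j] = H[j, i] = (
                            self.nloglike(x + ei + ej) - self.nloglike(x + ei - ej)
                            - self.nloglike(x - ei + ej) + self.nloglike(x - ei - ej)
                        ) / (4 * h[i] * h[j])
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0):
                return None
            return {n_: float(np.sqrt(v)) for n_, v in zip(self.free_names, d)}
        except np.linalg.LinAlgError:
            return None


class IRFModel(_LikelihoodModel):
    """MLE of the parametrized instrument response from a gated count vector.

    Free parameters: ``sigma`` (pulse width, ns), ``w`` (gate width, ns),
    ``t0`` (delay offset, ns) and ``amplitude`` (peak counts of the
    underlying Gaussian).
    """

    param_names = ("sigma", "w", "t0", "amplitude")

    def __init__(self, counts, timeline: GateTimeline,
                 config: FitConfig | None = None):
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != timeline.n_gates:
            raise ValueError("counts must be a length-k vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("empty decay: all-zero counts")
        self.timeline = timeline
        self.config = config or FitConfig()
        self.fixed = {}
        self.free_names = list(self.param_names)
        span = timeline.delays[-1] + timeline.gate_width_ns
        self.bounds = [
            self.config.sigma_bounds,
            (0.1 * timeline.gate_step_ns, span),
            (0.0, span),
            (_TINY, None),
        ]

    def expected(self, values: Mapping[str, float]) -> np.ndarray:
        p = IRFParams(sigma=values["sigma"], gate_width=values["w"],
                      t0=values["t0"], amplitude=values["amplitude"])
        return irf_model(self.timeline.delays, p)

    def _starts(self) -> list[np.ndarray]:
        c, t = self.counts, self.timeline.delays
        half = c.max() / 2.0
        above = np.where(c >= half)[0]
        # gated IRF is a plateau from ~t0-w to ~t0: falling edge locates t0
        w0 = max(t[above[-1]] - t[above[0]], self.timeline.gate_step_ns)
        t0_0 = t[above[-1]]
        sigma0 = max(self.timeline.gate_step_ns / 4.0, self.config.sigma_bounds[0])
        starts = []
        # the discrete gate sampling creates local optima within +-1 step
        # of the edge estimates: seed a small grid around them
        step = self.timeline.gate_step_ns
        for dt0 in (-step, -step / 2, 0.0, step / 2, step):
            for dw in (-step / 2, 0.0, step / 2):
                shape = irf_model(t, IRFParams(sigma=sigma0,
                                               gate_width=w0 + dw,
                                               t0=t0_0 + dt0))
                amp0 = c.sum() / max(shape.sum(), _TINY)
                starts.append(np.array([sigma0, w0 + dw, t0_0 + dt0, amp0]))
        return starts

    def fit(self, start_params: Sequence[float] | None = None,
            compute_bse: bool = True) -> FitResult:
        starts = [np.asarray(start_params, float)] if start_params is not None \
            else self._starts()
        # profile the count-scale amplitude out (it enters linearly), so
        # the optimizer only sees the ns-scale shape parameters
        shape_names = ["sigma", "w", "t0"]
        shape_bounds = self.bounds[:3]

        def shape_curve(x_red):
            return irf_model(self.timeline.delays,
                             IRFParams(sigma=x_red[0], gate_width=x_red[1],
                                       t0=x_red[2], amplitude=1.0))

        def amp_for(shape):
            if self.config.likelihood == "poisson":
                return float(self.counts.sum() / max(shape.sum(), _TINY))
            w = _lsq_weights(self.counts)
            denom = float(np.sum(shape**2 / w))
            return max(float(np.sum(self.counts * shape / w))
                       / max(denom, _TINY), _TINY)

        def red_nll(x_red):
            shape = shape_curve(x_red)
            return _nll(self.counts, amp_for(shape) * shape,
                        self.config.likelihood)

        lo = np.array([b[0] for b in shape_bounds])
        hi = np.array([b[1] for b in shape_bounds])
        best = None
        for x0 in starts:
            res = minimize(red_nll, np.clip(x0[:3], lo, hi),
                           method="L-BFGS-B", bounds=shape_bounds,
                           options={"maxiter": self.config.max_iter,
                                    "ftol": self.config.tol, "gtol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        amp = amp_for(shape_curve(best.x))
        x = np.append(best.x, amp)
        est = self._vector_to_params(x)
        msg = best.message if isinstance(best.message, str) else str(best.message)
        bse = self._standard_errors(x) if compute_bse else None
        return FitResult(estimates=est, fixed={},
                         neg_log_likelihood=float(best.fun),
                         n_photons=float(self.counts.sum()),
                         converged=bool(best.success),
                         n_gates_used=len(self.counts), bse=bse, message=msg)

    def params_as_irf(self, result: FitResult) -> IRFParams:
        p = result.params
        return IRFParams(sigma=p["sigma"], gate_width=p["w"],
                         t0=p["t0"], amplitude=p["amplitude"])


class GatedDecayModel(_LikelihoodModel):
    """MLE of a 1- or 2-component gated exponential decay.

    Parametrization (2 components): total pre-exponential ``amplitude``,
    short-amplitude fraction ``f1`` in [0, 1], lifetimes ``tau1 <= tau2``,
    time offset ``t0`` and per-gate ``baseline``.  With one component only
    ``amplitude``, ``tau1``, ``t0``, ``baseline`` exist.  Expected counts:

    ``amplitude * [f1 * g(t; tau1) + (1 - f1) * g(t; tau2)] + baseline``

    where ``g`` is the unit-amplitude gated Gaussian-convolved exponential
    with the IRF's sigma and gate width.  Any parameter can be fixed via
    ``fixed``; ``t0`` and ``baseline`` are fixed by default (``t0`` to the
    IRF's offset, baseline to 0).
    """

    def __init__(self, counts, timeline: GateTimeline, irf: IRFParams,
                 n_components: int = 1,
                 fixed: Mapping[str, float] | None = None,
                 free_t0: bool = False, free_baseline: bool = False,
                 config: FitConfig | None = None):
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != timeline.n_gates:
            raise ValueError("counts must be a length-k vector")
        if n_components not in (1, 2):
            raise ValueError("1 or 2 components supported")
        self.timeline = timeline
        self.irf = irf
        self.n_components = n_components
        self.config = config or FitConfig()

        names = ["amplitude", "tau1"]
        if n_components == 2:
            names += ["f1", "tau2"]
        if free_t0:
            names.append("t0")
        if free_baseline:
            names.append("baseline")
        defaults = {"t0": irf.t0, "baseline": 0.0}
        self.fixed = dict(defaults)
        for k, v in (fixed or {}).items():
            if k not in ("amplitude", "tau1", "tau2", "f1", "t0", "baseline"):
                raise ValueError(f"unknown parameter {k!r}")
            self.fixed[k] = float(v)
            if k in names:
                names.remove(k)
        # drop defaults that are actually free
        for k in list(self.fixed):
            if k in names:
                del self.fixed[k]
        self.free_names = names
        span = timeline.delays[-1] + timeline.gate_width_ns
        all_bounds = {
            "amplitude": (0.0, None),
            "tau1": self.config.tau_bounds,
            "tau2": self.config.tau_bounds,
            "f1": (0.0, 1.0),
            "t0": (0.0, span),
            "baseline": (0.0, None),
        }
        self.bounds = [all_bounds[n] for n in names]

    def expected(self, values: Mapping[str, float]) -> np.ndarray:
        t = self.timeline.delays
        g1 = gated_decay(t, 1.0, values["tau1"], values["t0"],
                         self.irf.sigma, self.irf.gate_width)
        if self.n_components == 1:
            shape = g1
        else:
            g2 = gated_decay(t, 1.0, values["tau2"], values["t0"],
                             self.irf.sigma, self.irf.gate_width)
            f1 = values["f1"]
            shape = f1 * g1 + (1.0 - f1) * g2
        return values["amplitude"] * shape + values["baseline"]

    # -- initialization ---------------------------------------------------
    def _amplitude_for(self, values: dict[str, float]) -> float:
        """Scale matching total model counts to total observed counts."""
        trial = dict(values, amplitude=1.0)
        s = self.expected(trial).sum() - trial["baseline"] * self.timeline.n_gates
        excess = self.counts.sum() - values["baseline"] * self.timeline.n_gates
        return max(excess / max(s, _TINY), _TINY)

    def _starts(self) -> list[np.ndarray]:
        tau_est = float(np.clip(_tail_lifetime(self.counts, self.timeline.delays),
                                *self.config.tau_bounds))
        base = {n: self.fixed.get(n) for n in ("t0", "baseline", "tau1", "tau2", "f1")}
        if base["t0"] is None:
            base["t0"] = self.irf.t0
        if base["baseline"] is None:
            base["baseline"] = 0.0
        starts = []
        if self.n_components == 1:
            tau_grid = [tau_est, 0.5 * tau_est, 2.0 * tau_est]
            for tau in tau_grid:
                vals = dict(base)
                vals["tau1"] = vals["tau1"] if vals["tau1"] is not None else tau
                vals["amplitude"] = self._amplitude_for(vals)
                starts.append(np.array([vals[n] for n in self.free_names]))
        else:
            pair_grid = [(0.45, 1.3), (0.25, 1.1), (0.6, 2.0), (0.9, 0.95)]
            f_grid = [0.5, 0.3, 0.7]
            for (r1, r2), f in zip(pair_grid * len(f_grid),
                                   np.repeat(f_grid, len(pair_grid))):
                vals = dict(base)
                if vals["tau1"] is None:
                    vals["tau1"] = r1 * tau_est
                if vals["tau2"] is None:
                    vals["tau2"] = r2 * tau_est
                if vals["f1"] is None:
                    vals["f1"] = f
                vals["tau1"], vals["tau2"] = (min(vals["tau1"], vals["tau2"]),
                                              max(vals["tau1"], vals["tau2"]))
                vals["amplitude"] = self._amplitude_for(vals)
                starts.append(np.array([vals[n] for n in self.free_names]))
        return starts

    # -- amplitude profiling ---------------------------------------------
    # With the per-gate baseline fixed at 0 the optimal overall amplitude
    # has a closed form for both likelihood kinds, so the optimizer only
    # sees the shape parameters (lifetimes, fraction, t0).  This avoids the
    # scale mismatch between a counts-scale amplitude and ns-scale
    # lifetimes that otherwise stalls quasi-Newton steps.
    def _can_profile(self) -> bool:
        return ("amplitude" in self.free_names
                and "baseline" not in self.free_names
                and self.fixed.get("baseline", 0.0) == 0.0)

    def _shape(self, values: Mapping[str, float]) -> np.ndarray:
        return self.expected({**values, "amplitude": 1.0, "baseline": 0.0})

    def _profiled_amplitude(self, shape: np.ndarray) -> float:
        if self.config.likelihood == "poisson":
            return float(self.counts.sum() / max(shape.sum(), _TINY))
        w = _lsq_weights(self.counts)
        denom = float(np.sum(shape**2 / w))
        return max(float(np.sum(self.counts * shape / w)) / max(denom, _TINY),
                   0.0)

    def _fit_profiled(self, starts: Sequence[np.ndarray]
                      ) -> tuple[np.ndarray, float, bool, str]:
        i_amp = self.free_names.index("amplitude")
        red_names = [n for n in self.free_names if n != "amplitude"]
        red_bounds = [b for n, b in zip(self.free_names, self.bounds)
                      if n != "amplitude"]

        def red_nll(x_red: np.ndarray) -> float:
            values = dict(self.fixed)
            values.update(zip(red_names, x_red))
            shape = self._shape(values)
            amp = self._profiled_amplitude(shape)
            return _nll(self.counts, amp * shape, self.config.likelihood)

        best = None
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in red_bounds])
        hi = np.array([b[1] if b[1] is not None else np.inf for b in red_bounds])
        seen = set()
        for x0 in starts:
            x0_red = np.clip(np.delete(x0, i_amp), lo, hi)
            key = tuple(np.round(x0_red, 6))
            if key in seen:
                continue
            seen.add(key)
            res = minimize(red_nll, x0_red, method="L-BFGS-B",
                           bounds=red_bounds,
                           options={"maxiter": self.config.max_iter,
                                    "ftol": self.config.tol,
                                    "gtol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        values = dict(self.fixed)
        values.update(zip(red_names, best.x))
        amp = self._profiled_amplitude(self._shape(values))
        x_full = np.insert(best.x, i_amp, amp)
        msg = best.message if isinstance(best.message, str) else str(best.message)
        return x_full, float(best.fun), bool(best.success), msg

    def fit(self, start_params: Sequence[float] | None = None,
            compute_bse: bool = False) -> FitResult:
        n_photons = float(self.counts.sum())
        if n_photons < self.config.min_photons:
            starts = self._starts() if start_params is None \
                else [np.asarray(start_params, float)]
            est = self._vector_to_params(starts[0])
            return FitResult(
                estimates={n: est[n] for n in self.free_names},
                fixed=dict(self.fixed),
                neg_log_likelihood=np.nan, n_photons=n_photons,
                converged=False, n_gates_used=len(self.counts),
                message="below min_photons; estimates are initial values")
        starts = [np.asarray(start_params, float)] if start_params is not None \
            else self._starts()
        if self._can_profile():
            x, nll, success, msg = self._fit_profiled(starts)
        else:
            x, nll, success, msg = self._optimize(starts)
        est = self._vector_to_params(x)
        est = self._canonical_order(est)
        x = np.array([est[n] for n in self.free_names])
        converged = success and not self._lifetime_at_bound(est)
        bse = self._standard_errors(x) if compute_bse else None
        return FitResult(estimates={n: est[n] for n in self.free_names},
                         fixed=dict(self.fixed), neg_log_likelihood=nll,
                         n_photons=n_photons, converged=converged,
                         n_gates_used=len(self.counts), bse=bse, message=msg)

    def _canonical_order(self, est: dict[str, float]) -> dict[str, float]:
        """Enforce tau1 <= tau2 by swapping lifetimes and flipping f1
        (only when both lifetimes are free)."""
        if (self.n_components == 2 and "tau1" in self.free_names
                and "tau2" in self.free_names and est["tau1"] > est["tau2"]):
            est = dict(est)
            est["tau1"], est["tau2"] = est["tau2"], est["tau1"]
            if "f1" in est:
                est["f1"] = 1.0 - est["f1"]
        return est

    def _lifetime_at_bound(self, est: dict[str, float]) -> bool:
        lo, hi = self.config.tau_bounds
        for name in ("tau1", "tau2"):
            if name in self.free_names:
                v = est[name]
                if v <= lo * (1 + 1e-6) or v >= hi * (1 - 1e-6):
                    return True
        return False


# -- convenience wrappers -------------------------------------------------

def fit_irf(counts, timeline: GateTimeline,
            config: FitConfig | None = None) -> FitResult:
    """MLE of the IRF parameters (sigma, w, t0, amplitude) from gated counts."""
    return IRFModel(counts, timeline, config=config).fit()


def fit_decay(counts, timeline: GateTimeline, irf: IRFParams,
              n_components: int = 1,
              fixed: Mapping[str, float] | None = None,
              free_t0: bool = False, free_baseline: bool = False,
              config: FitConfig | None = None,
              compute_bse: bool = False) -> FitResult:
    """MLE of a gated exponential decay with the IRF shape held fixed."""
    model = GatedDecayModel(counts, timeline, irf, n_components=n_components,
                            fixed=fixed, free_t0=free_t0,
                            free_baseline=free_baseline, config=config)
    return model.fit(compute_bse=compute_bse)


def sum_fit(stack: GatedStack, mask, irf: IRFParams, n_components: int = 1,
            fixed: Mapping[str, float] | None = None,
            config: FitConfig | None = None,
            compute_bse: bool = False) -> FitResult:
    """Sum the decays of all masked pixels, then fit the summed decay.

    ``mask`` is a boolean image matching the stack's frame shape; the stack
    must already be background/pile-up corrected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frame_shape:
        raise ValueError("mask shape does not match stack frames")
    if not mask.any():
        raise ValueError("empty mask")
    counts = stack.data[:, mask].sum(axis=1)
    return fit_decay(counts, stack.timeline, irf, n_components=n_components,
                     fixed=fixed, config=config, compute_bse=compute_bse)


def pixelwise_fit(stack: GatedStack, irf: IRFParams, n_components: int = 1,
                  fixed: Mapping[str, float] | None = None,
                  min_photons: float = 100.0,
                  config: FitConfig | None = None) -> dict[str, np.ndarray]:
    """Independent per-pixel decay fits over a 2D gated image.

    Returns a dict of parameter images (NaN where the pixel has fewer than
    ``min_photons`` counts or the fit did not converge) plus ``n_photons``
    (gate-summed counts) and ``converged`` (boolean image).
    """
    if stack.data.ndim != 3:
        raise ValueError("pixelwise_fit expects a (gate, y, x) stack")
    config = config or FitConfig(min_photons=min_photons)
    if config.min_photons != min_photons:
        config = FitConfig(likelihood=config.likelihood,
                           tau_bounds=config.tau_bounds,
                           sigma_bounds=config.sigma_bounds,
                           max_iter=config.max_iter, tol=config.tol,
                           min_photons=min_photons)
    h, w_ = stack.frame_shape
    counts_img = stack.total_counts().astype(float)
    param_names = ["amplitude", "tau1"] + (["f1", "tau2"] if n_components == 2 else [])
    if fixed:
        param_names = [n for n in param_names if n not in fixed]
    out = {n: np.full((h, w_), np.nan) for n in param_names}
    out["n_photons"] = counts_img
    out["converged"] = np.zeros((h, w_), dtype=bool)
    for i in range(h):
        for j in range(w_):
            if counts_img[i, j] < min_photons:
                continue
            res = fit_decay(stack.data[:, i, j], stack.timeline, irf,
                            n_components=n_components, fixed=fixed,
                            config=config)
            out["converged"][i, j] = res.converged
            if res.converged:
                for n in param_names:
                    out[n][i, j] = res.estimates[n]
    return out
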