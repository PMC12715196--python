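"""Maximum-likelihood IRF and decay fitting: round trips on generated
data, degenerate-input contracts, and likelihood properties."""

import numpy as np
import pytest

from gatedflim import (FitConfig, GatedDecayModel, GatedStack, GateTimeline,
                       IRFParams, fit_decay, fit_irf, gated_decay, irf_model,
                       pixelwise_fit, sum_fit)


def one_exp_counts(timeline, irf, amplitude, tau):
    return gated_decay(timeline.delays, amplitude, tau, irf.t0,
                       irf.sigma, irf.gate_width)


def two_exp_counts(timeline, irf, total, f1, tau1, tau2):
    t = timeline.delays
    shape = (f1 * gated_decay(t, 1.0, tau1, irf.t0, irf.sigma, irf.gate_width)
             + (1 - f1) * gated_decay(t, 1.0, tau2, irf.t0, irf.sigma,
                                      irf.gate_width))
    return shape / shape.sum() * total


class TestIRFFit:
    def test_noiseless_round_trip(self):
        tl = GateTimeline(n_gates=50, gate_step_ns=0.5, gate_width_ns=5.0)
        truth = IRFParams(sigma=0.25, gate_width=5.0, t0=10.0, amplitude=40.0)
        res = fit_irf(irf_model(tl.delays, truth), tl)
        assert res.converged
        assert res.estimates["sigma"] == pytest.approx(0.25, rel=0.01)
        assert res.estimates["w"] == pytest.approx(5.0, rel=0.01)
        assert res.estimates["t0"] == pytest.approx(10.0, rel=0.01)

    def test_t0_recovery_under_poisson_noise(self):
        tl = GateTimeline(n_gates=50, gate_step_ns=0.5, gate_width_ns=5.0)
        # amplitude chosen for ~1e4 counts in the plateau gates
        amp = 1e4 / (np.sqrt(2 * np.pi) * 0.25)
        truth = IRFParams(sigma=0.25, gate_width=5.0, t0=10.0, amplitude=amp)
        mu = irf_model(tl.delays, truth)
        errs = []
        for seed in range(25):
            counts = np.random.default_rng(seed).poisson(mu)
            res = fit_irf(counts, tl)
            errs.append(abs(res.estimates["t0"] - 10.0))
        assert np.median(errs) < 0.05

    def test_all_zero_counts_raise(self, timeline):
        with pytest.raises(ValueError, match="empty decay"):
            fit_irf(np.zeros(timeline.n_gates), timeline)

    def test_summary_table(self):
        tl = GateTimeline(n_gates=50, gate_step_ns=0.5, gate_width_ns=5.0)
        truth = IRFParams(sigma=0.25, gate_width=5.0, t0=10.0, amplitude=40.0)
        res = fit_irf(irf_model(tl.delays, truth), tl)
        table = res.summary()
        assert set(table.index) >= {"sigma", "w", "t0", "amplitude"}
        assert not table.loc["sigma", "fixed"]


class TestDecayFit:
    def test_noiseless_single_exponential(self, timeline, irf):
        counts = one_exp_counts(timeline, irf, 50.0, 2.5)
        res = fit_decay(counts, timeline, irf, n_components=1)
        assert res.converged
        assert res.estimates["tau1"] == pytest.approx(2.5, rel=1e-3)

    def test_two_component_poisson_recovery(self, timeline, irf):
        # Flipper-like regime: tau = (1.0, 5.0) ns, amplitude ratio 0.45
        mu = two_exp_counts(timeline, irf, 1e5, 0.45, 1.0, 5.0)
        errs = []
        for seed in range(20):
            counts = np.random.default_rng(seed).poisson(mu)
            res = fit_decay(counts, timeline, irf, n_components=2)
            errs.append(abs(res.estimates["tau2"] - 5.0))
        assert np.median(errs) < 0.15

    def test_fixed_lifetime_fit(self, timeline, irf):
        mu = two_exp_counts(timeline, irf, 1e5, 0.45, 1.0, 5.0)
        res = fit_decay(mu, timeline, irf, n_components=2,
                        fixed={"tau1": 1.0, "f1": 0.45})
        assert res.converged
        assert res.fixed == {"tau1": 1.0, "f1": 0.45, "t0": irf.t0,
                             "baseline": 0.0}
        assert res.estimates["tau2"] == pytest.approx(5.0, rel=1e-3)

    def test_single_gate_counts_hit_bound_and_flag(self):
        # non-overlapping gates so a single-gate decay is representable
        tl = GateTimeline(n_gates=25, gate_step_ns=2.0, gate_width_ns=2.0)
        irf2 = IRFParams(sigma=0.25, gate_width=2.0, t0=3.0)
        counts = np.zeros(25)
        counts[1] = 1000.0  # gate 1 spans 2-4 ns and contains the pulse
        res = fit_decay(counts, tl, irf2, n_components=1)
        lo = FitConfig().tau_bounds[0]
        assert res.estimates["tau1"] == pytest.approx(lo, rel=1e-3)
        assert not res.converged

    def test_below_min_photons_returns_initials_flagged(self, timeline, irf):
        counts = one_exp_counts(timeline, irf, 0.1, 2.5)  # ~ a few counts
        res = fit_decay(counts, timeline, irf, n_components=1)
        assert not res.converged
        assert "min_photons" in res.message

    def test_bias_decreases_with_photons(self, timeline, irf):
        # Poisson-MLE consistency: |bias of tau2| shrinks as photons grow
        biases = []
        for total in (1e3, 1e4, 1e5):
            mu = two_exp_counts(timeline, irf, total, 0.45, 1.0, 5.0)
            est = [fit_decay(np.random.default_rng(s).poisson(mu), timeline,
                             irf, n_components=2,
                             fixed={"tau1": 1.0, "f1": 0.45}
                             ).estimates["tau2"] for s in range(25)]
            biases.append(abs(np.mean(est) - 5.0))
        assert biases[2] < biases[0]

    def test_lsq_estimates_invariant_under_count_rescaling(self, timeline, irf):
        cfg = FitConfig(likelihood="lsq", min_photons=0.0)
        counts = np.random.default_rng(3).poisson(
            one_exp_counts(timeline, irf, 200.0, 2.5))
        r1 = fit_decay(counts.astype(float), timeline, irf, config=cfg)
        r2 = fit_decay(counts * 10.0, timeline, irf, config=cfg)
        assert r2.estimates["tau1"] == pytest.approx(r1.estimates["tau1"],
                                                     rel=1e-6)
        assert r2.estimates["amplitude"] == pytest.approx(
            10 * r1.estimates["amplitude"], rel=1e-6)

    def test_fixing_parameters_never_improves_likelihood(self, timeline, irf):
        mu = two_exp_counts(timeline, irf, 1e4, 0.45, 1.0, 5.0)
        counts = np.random.default_rng(11).poisson(mu)
        free = fit_decay(counts, timeline, irf, n_components=2)
        fixed = fit_decay(counts, timeline, irf, n_components=2,
                          fixed={"tau1": 1.2, "f1": 0.5})
        assert fixed.neg_log_likelihood >= free.neg_log_likelihood - 1e-6

    def test_standard_errors_scale_with_photons(self, timeline, irf):
        ses = []
        for total in (1e3, 1e5):
            counts = np.random.default_rng(5).poisson(
                two_exp_counts(timeline, irf, total, 0.45, 1.0, 5.0))
            res = fit_decay(counts, timeline, irf, n_components=2,
                            fixed={"tau1": 1.0, "f1": 0.45},
                            compute_bse=True)
            assert res.bse is not None
            ses.append(res.bse["tau2"])
        # 100x photons -> ~10x smaller standard error
        assert ses[1] < ses[0] / 5


class TestSumFit:
    def make_stack(self, timeline, irf, rng):
        mu = one_exp_counts(timeline, irf, 40.0, 2.5)
        data = rng.poisson(mu[:, None, None] * np.ones((1, 6, 6)))
        return GatedStack(data.astype(float), timeline)

    def test_single_pixel_mask_equals_fit_decay(self, timeline, irf, rng):
        stack = self.make_stack(timeline, irf, rng)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True
        res_sum = sum_fit(stack, mask, irf)
        res_direct = fit_decay(stack.data[:, 2, 3], timeline, irf)
        assert res_sum.estimates == res_direct.estimates
        assert res_sum.n_photons == res_direct.n_photons

    def test_photon_conservation_over_disjoint_masks(self, timeline, irf, rng):
        stack = self.make_stack(timeline, irf, rng)
        m1 = np.zeros((6, 6), dtype=bool); m1[:3] = True
        m2 = ~m1
        r1 = sum_fit(stack, m1, irf)
        r2 = sum_fit(stack, m2, irf)
        r12 = sum_fit(stack, m1 | m2, irf)
        assert r12.n_photons == pytest.approx(r1.n_photons + r2.n_photons)

    def test_empty_mask_raises(self, timeline, irf, rng):
        stack = self.make_stack(timeline, irf, rng)
        with pytest.raises(ValueError, match="empty mask"):
            sum_fit(stack, np.zeros((6, 6), dtype=bool), irf)


class TestPixelwiseFit:
    def test_uniform_image_lifetime_histogram(self, timeline, irf, rng):
        # ~1000 counts/pixel: pixel-lifetime median within 2% of truth
        mu = one_exp_counts(timeline, irf, 1.0, 2.5)
        mu = mu / mu.sum() * 1000.0
        data = rng.poisson(mu[:, None, None] * np.ones((1, 12, 12)))
        stack = GatedStack(data.astype(float), timeline)
        out = pixelwise_fit(stack, irf, n_components=1, min_photons=100)
        taus = out["tau1"][np.isfinite(out["tau1"])]
        assert len(taus) > 100
        assert np.median(taus) == pytest.approx(2.5, rel=0.02)

    def test_precision_improves_with_exposure(self, timeline, irf, rng):
        mu = one_exp_counts(timeline, irf, 1.0, 2.5)
        iqrs = []
        for total in (500.0, 2000.0):  # 4x counts -> ~2x smaller IQR
            m = mu / mu.sum() * total
            data = rng.poisson(m[:, None, None] * np.ones((1, 10, 10)))
            out = pixelwise_fit(GatedStack(data.astype(float), timeline),
                                irf, min_photons=50)
            taus = out["tau1"][np.isfinite(out["tau1"])]
            q75, q25 = np.percentile(taus, [75, 25])
            iqrs.append(q75 - q25)
        ratio = iqrs[0] / iqrs[1]
        assert 2.0 * 0.6 < ratio < 2.0 * 1.6

    def test_zero_count_pixels_are_nan(self, timeline, irf):
        data = np.zeros((timeline.n_gates, 3, 3))
        data[:, 0, 0] = one_exp_counts(timeline, irf, 30.0, 2.5)
        out = pixelwise_fit(GatedStack(data, timeline), irf, min_photons=100)
        assert np.isfinite(out["tau1"][0, 0])
        assert np.isnan(out["tau1"][1, 1])
        assert out["n_photons"][1, 1] == 0


class TestModelObjects:
    def test_unknown_fixed_parameter_rejected(self, timeline, irf):
        with pytest.raises(ValueError, match="unknown parameter"):
            GatedDecayModel(np.ones(timeline.n_gates), timeline, irf,
                            fixed={"gamma": 1.0})

    def test_canonical_lifetime_ordering(self, timeline, irf):
        mu = two_exp_counts(timeline, irf, 1e5, 0.45, 1.0, 5.0)
        res = fit_decay(mu, timeline, irf, n_components=2)
        assert res.estimates["tau1"] <= res.estimates["tau2"]
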