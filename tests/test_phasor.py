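"""Phasor transform, IRF division, elliptic cursors and back-mapping."""

import numpy as np
import pytest

from gatedflim import (EllipseCursor, GatedStack, GateTimeline, IRFParams,
                       auto_cursors, gated_decay, irf_correct, irf_phasor,
                       phasor_transform, select_and_backmap)
from gatedflim.phasor import PhasorImage


def stack_from_curve(curve, timeline):
    return GatedStack(np.asarray(curve, float).reshape(-1, 1, 1), timeline)


class TestPhasorTransform:
    def test_delta_decay_closed_form(self, timeline):
        data = np.zeros((25, 1, 1))
        data[0] = 100.0
        ph = phasor_transform(GatedStack(data, timeline))
        assert ph.G[0, 0] == pytest.approx(np.cos(np.pi / 25), abs=1e-12)
        assert ph.S[0, 0] == pytest.approx(np.sin(np.pi / 25), abs=1e-12)
        assert ph.G[0, 0] == pytest.approx(0.9921, abs=1e-4)
        assert ph.S[0, 0] == pytest.approx(0.1253, abs=1e-4)

    def test_uniform_counts_map_to_origin(self, timeline):
        ph = phasor_transform(GatedStack(np.ones((25, 2, 2)), timeline))
        np.testing.assert_allclose(ph.G, 0.0, atol=1e-12)
        np.testing.assert_allclose(ph.S, 0.0, atol=1e-12)

    def test_fine_gate_monoexponential_on_semicircle(self):
        k, T, tau = 500, 50.0, 2.0
        tl = GateTimeline(n_gates=k, gate_step_ns=T / k, gate_width_ns=T / k,
                          laser_period_ns=T)
        counts = gated_decay(tl.delays, 1.0, tau, 0.0, 1e-3, tl.gate_width_ns)
        ph = phasor_transform(stack_from_curve(counts, tl))
        wt = ph.omega * tau
        assert ph.G[0, 0] == pytest.approx(1 / (1 + wt**2), abs=1e-2)
        assert ph.S[0, 0] == pytest.approx(wt / (1 + wt**2), abs=1e-2)
        # on the universal semicircle G^2 + S^2 = G
        g, s = ph.G[0, 0], ph.S[0, 0]
        assert g**2 + s**2 == pytest.approx(g, abs=5e-3)

    def test_zero_count_pixels_get_nan(self, timeline):
        data = np.zeros((25, 1, 2))
        data[0, 0, 0] = 10.0
        ph = phasor_transform(GatedStack(data, timeline))
        assert np.isfinite(ph.G[0, 0])
        assert np.isnan(ph.G[0, 1]) and np.isnan(ph.S[0, 1])

    def test_all_zero_stack_raises(self, timeline):
        with pytest.raises(ValueError, match="no counts"):
            phasor_transform(GatedStack(np.zeros((25, 2, 2)), timeline))

    def test_linearity_pixel_sum_is_count_weighted_mean(self, timeline, rng):
        data = rng.poisson(20.0, size=(25, 4, 4)).astype(float)
        ph = phasor_transform(GatedStack(data, timeline))
        summed = data.reshape(25, -1).sum(axis=1).reshape(25, 1, 1)
        ph_sum = phasor_transform(GatedStack(summed, timeline))
        w = ph.counts / ph.counts.sum()
        assert ph_sum.G[0, 0] == pytest.approx(float((w * ph.G).sum()),
                                               rel=1e-10)
        assert ph_sum.S[0, 0] == pytest.approx(float((w * ph.S).sum()),
                                               rel=1e-10)


class TestIRFCorrect:
    def test_unit_irf_phasor_is_identity(self, timeline, rng):
        data = rng.poisson(30.0, size=(25, 3, 3)).astype(float)
        ph = phasor_transform(GatedStack(data, timeline))
        out = irf_correct(ph, (1.0, 0.0))
        np.testing.assert_allclose(out.G, ph.G)
        np.testing.assert_allclose(out.S, ph.S)

    def test_self_division_gives_one(self, timeline, irf):
        gph = irf_phasor(irf, timeline)
        img = PhasorImage(G=np.full((1, 1), gph[0]),
                          S=np.full((1, 1), gph[1]),
                          omega=0.1, counts=np.ones((1, 1)))
        out = irf_correct(img, gph)
        assert out.G[0, 0] == pytest.approx(1.0)
        assert out.S[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_modulus_irf_phasor_raises(self, timeline, rng):
        data = rng.poisson(30.0, size=(25, 1, 1)).astype(float)
        ph = phasor_transform(GatedStack(data, timeline))
        with pytest.raises(ValueError, match="zero modulus"):
            irf_correct(ph, (0.0, 0.0))

    def test_division_inverts_multiplication_exactly(self, timeline, rng):
        data = rng.poisson(30.0, size=(25, 2, 2)).astype(float)
        ph = phasor_transform(GatedStack(data, timeline))
        g0, s0 = 0.8, 0.3
        z = (ph.G + 1j * ph.S) * (g0 + 1j * s0)
        mult = PhasorImage(G=z.real, S=z.imag, omega=ph.omega,
                           counts=ph.counts)
        back = irf_correct(mult, (g0, s0))
        np.testing.assert_allclose(back.G, ph.G, atol=1e-12)
        np.testing.assert_allclose(back.S, ph.S, atol=1e-12)

    def test_corrected_phasor_removes_irf_shift_and_width(self):
        # fine gates: dividing by the IRF phasor maps a decay measured with
        # a shifted/broadened IRF onto the sharp-IRF decay's phasor
        k = 800
        tl = GateTimeline(n_gates=k, gate_step_ns=50.0 / k,
                          gate_width_ns=5.0, laser_period_ns=50.0)
        broad = IRFParams(sigma=0.3, gate_width=5.0, t0=10.0)
        sharp = IRFParams(sigma=1e-3, gate_width=5.0, t0=0.0)
        for tau in (1.0, 2.5, 5.0):
            c1 = gated_decay(tl.delays, 1.0, tau, 10.0, 0.3, 5.0)
            c2 = gated_decay(tl.delays, 1.0, tau, 0.0, 1e-3, 5.0)
            p1 = irf_correct(phasor_transform(stack_from_curve(c1, tl)),
                             irf_phasor(broad, tl))
            p2 = irf_correct(phasor_transform(stack_from_curve(c2, tl)),
                             irf_phasor(sharp, tl))
            assert p1.G[0, 0] == pytest.approx(p2.G[0, 0], abs=5e-3)
            assert p1.S[0, 0] == pytest.approx(p2.S[0, 0], abs=5e-3)


class TestCursors:
    def make_phasor(self, G, S, counts=None):
        G = np.asarray(G, float)
        counts = np.ones_like(G) if counts is None else counts
        return PhasorImage(G=G, S=np.asarray(S, float), omega=0.1,
                           counts=counts)

    def test_whole_plane_cursor_selects_all_valid(self):
        ph = self.make_phasor([[0.1, 0.9], [0.5, np.nan]],
                              [[0.2, 0.1], [0.4, np.nan]])
        cursor = EllipseCursor(center=(0.5, 0.25), semi_axes=(10.0, 10.0))
        masks = select_and_backmap(ph, [cursor])
        assert masks[0].sum() == 3  # NaN pixel excluded

    def test_boundary_point_is_inside(self):
        cursor = EllipseCursor(center=(0.0, 0.0), semi_axes=(1.0, 0.5))
        assert cursor.contains(1.0, 0.0)
        assert cursor.contains(0.0, 0.5)
        assert not cursor.contains(1.0 + 1e-9, 0.0)

    def test_overlapping_cursors_assign_by_normalized_distance(self):
        ph = self.make_phasor([[0.4]], [[0.0]])
        c1 = EllipseCursor(center=(0.0, 0.0), semi_axes=(1.0, 1.0))
        c2 = EllipseCursor(center=(0.5, 0.0), semi_axes=(1.0, 1.0))
        masks = select_and_backmap(ph, [c1, c2])
        assert not masks[0][0, 0] and masks[1][0, 0]

    def test_rotated_ellipse_selection(self):
        c = EllipseCursor(center=(0.0, 0.0), semi_axes=(2.0, 0.1),
                          angle=np.pi / 2)
        assert c.contains(0.0, 1.5)       # long axis now along S
        assert not c.contains(1.5, 0.0)

    def test_no_cursors_raises(self, timeline, rng):
        data = rng.poisson(30.0, size=(25, 1, 1)).astype(float)
        ph = phasor_transform(GatedStack(data, timeline))
        with pytest.raises(ValueError):
            select_and_backmap(ph, [])


class TestAutoCursors:
    def two_cluster_phasor(self, rng, n=400, sep=10.0):
        sd = 0.01
        g = np.concatenate([rng.normal(0.3, sd, n), rng.normal(0.3 + sep * sd, sd, n)])
        s = np.concatenate([rng.normal(0.2, sd, n), rng.normal(0.2 + sep * sd, sd, n)])
        counts = np.full(2 * n, 500.0)
        side = int(np.sqrt(2 * n))
        m = side * side
        return PhasorImage(G=g[:m].reshape(side, side),
                           S=s[:m].reshape(side, side), omega=0.1,
                           counts=counts[:m].reshape(side, side))

    def test_well_separated_clusters_recovered(self, rng):
        ph = self.two_cluster_phasor(rng, sep=10.0)
        cursors = auto_cursors(ph, n=2, min_counts=100, seed=0)
        centers = sorted(c.center for c in cursors)
        assert centers[0][0] == pytest.approx(0.3, abs=0.01)
        assert centers[1][0] == pytest.approx(0.4, abs=0.01)
        assert not any("degenerate" in c.label for c in cursors)

    def test_single_cluster_flagged_degenerate(self, rng):
        ph = self.two_cluster_phasor(rng, sep=0.3)
        with pytest.warns(UserWarning, match="overlap"):
            cursors = auto_cursors(ph, n=2, min_counts=100, seed=0)
        assert all("degenerate" in c.label for c in cursors)

    def test_single_cursor_centers_on_species_phasor(self, rng):
        sd = 0.01
        side = 20
        ph = PhasorImage(G=rng.normal(0.6, sd, (side, side)),
                         S=rng.normal(0.35, sd, (side, side)), omega=0.1,
                         counts=np.full((side, side), 400.0))
        (cursor,) = auto_cursors(ph, n=1, min_counts=100, seed=0)
        assert cursor.center[0] == pytest.approx(0.6, abs=0.01)
        assert cursor.center[1] == pytest.approx(0.35, abs=0.01)

    def test_empty_phasor_raises(self):
        ph = PhasorImage(G=np.full((2, 2), np.nan), S=np.full((2, 2), np.nan),
                         omega=0.1, counts=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            auto_cursors(ph, n=2)

    def test_cursor_json_round_trip(self, tmp_path):
        from gatedflim.phasor import load_cursors, save_cursors
        cursors = [EllipseCursor(center=(0.5, 0.2), semi_axes=(0.1, 0.05),
                                 angle=0.3, label="a")]
        save_cursors(cursors, tmp_path / "c.json")
        assert load_cursors(tmp_path / "c.json") == cursors
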