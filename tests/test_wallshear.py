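"""WSS field analytics: TAWSS, OSI, area weighting, Q-criterion."""

import numpy as np
import pytest

from valvekit import synthetic as syn
from valvekit import wallshear as ws
from valvekit.errors import DataError, DomainError

TRI_NODES = [[0, 0, 0], [1, 0, 0], [0, 1, 0]]
TRI = [[0, 1, 2]]


def single_direction_field(signal, T=1.0, n_nodes=3):
    """Field whose x-component follows ``signal(t)`` at every node."""
    K = signal.size - 1
    times = np.linspace(0, T, K + 1)
    wss = np.zeros((K + 1, n_nodes, 3))
    wss[:, :, 0] = signal[:, None]
    nodes = np.array(TRI_NODES, dtype=float)
    return ws.WSSSurfaceField(nodes=nodes, triangles=TRI, times=times, wss_vectors=wss)


class TestWSSFromProfile:
    def test_linear_profile_unit_conversion(self):
        # du/dn = 100 1/s at mu = 1.07 cP -> 1.07 dynes/cm^2
        tau = ws.wss_from_near_wall_profile([0.0, 1e-4], [0.0, 1e-2], mu=1.07)
        assert tau == pytest.approx(1.07)

    def test_zero_velocity_everywhere(self):
        assert ws.wss_from_near_wall_profile([0.0, 1e-4], [0.0, 0.0]) == 0.0

    def test_linearity_in_viscosity(self):
        t1 = ws.wss_from_near_wall_profile([0.0, 1e-4], [0.0, 1e-2], mu=1.0)
        t2 = ws.wss_from_near_wall_profile([0.0, 1e-4], [0.0, 1e-2], mu=2.0)
        assert t2 == pytest.approx(2 * t1)

    def test_nonpositive_offsets_rejected(self):
        with pytest.raises(DomainError):
            ws.wss_from_near_wall_profile([0.0, -1e-4], [0.0, 1.0])


class TestTAWSS:
    def test_constant_magnitude(self):
        f = single_direction_field(np.full(65, 10.0))
        assert np.allclose(ws.compute_tawss(f), 10.0)

    def test_rectified_sine_mean(self):
        t = np.linspace(0, 1, 257)
        f = single_direction_field(5.0 * np.sin(2 * np.pi * t))
        assert np.allclose(ws.compute_tawss(f), 2 * 5.0 / np.pi, rtol=1e-3)

    def test_square_wave_magnitude(self):
        sig = np.where(np.arange(65) % 64 < 32, 4.0, -4.0)
        f = single_direction_field(sig)
        assert np.allclose(ws.compute_tawss(f), 4.0)

    def test_quadrature_error_is_second_order(self):
        def err(K):
            t = np.linspace(0, 1, K + 1)
            f = single_direction_field(np.cos(2 * np.pi * t))
            return abs(ws.compute_tawss(f)[0] - 2 / np.pi)

        ratio = err(64) / err(128)
        assert 3.0 < ratio < 5.0

    def test_nonfinite_field_rejected(self):
        wss = np.zeros((9, 3, 3))
        wss[0, 0, 0] = np.nan
        with pytest.raises(DataError):
            ws.WSSSurfaceField(
                nodes=TRI_NODES, triangles=TRI,
                times=np.linspace(0, 1, 9), wss_vectors=wss,
            )


class TestOSI:
    def test_unidirectional_constant_zero(self):
        f = single_direction_field(np.full(65, 3.0))
        assert np.allclose(ws.compute_osi(f), 0.0, atol=1e-12)

    def test_zero_mean_oscillation_half(self):
        sig = np.where(np.arange(65) % 64 < 32, 2.0, -2.0)
        f = single_direction_field(sig)
        assert np.allclose(ws.compute_osi(f), 0.5, atol=1e-12)

    def test_duty_three_quarters_square_wave(self):
        k = np.arange(201) % 200
        sig = np.where(k < 150, 1.0, -1.0)
        f = single_direction_field(sig)
        assert np.allclose(ws.compute_osi(f), 0.25, atol=0.005)

    def test_zero_field_osi_defined_zero(self):
        f = single_direction_field(np.zeros(65))
        assert np.allclose(ws.compute_osi(f), 0.0)


class TestFieldProperties:
    def test_osi_bounds_and_triangle_inequality_random_fields(self, rng):
        """OSI in [0, 0.5] and T*TAWSS >= ||int tau dt|| on random fields."""
        K, N = 24, 200
        times = np.sort(rng.uniform(0, 1, K - 2))
        times = np.concatenate([[0.0], times, [1.0]])
        wss = rng.normal(0, 5, (K, N, 3))
        f = ws.WSSSurfaceField(
            nodes=rng.normal(size=(N, 3)),
            triangles=[[i, (i + 1) % N, (i + 2) % N] for i in range(N - 2)],
            times=times,
            wss_vectors=wss,
        )
        osi = ws.compute_osi(f)
        tawss = ws.compute_tawss(f)
        mean_vec = np.trapezoid(f.wss_vectors, times, axis=0) / f.period
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)
        assert np.all(tawss >= np.linalg.norm(mean_vec, axis=1) - 1e-12)

    def test_rotation_invariance(self, rng):
        field, _ = syn.gen_wss_surface_field(
            syn.WSSFieldParams(n_nodes=60, noise_sd=1.0, seed=4)
        )
        # random 3-D rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = ws.WSSSurfaceField(
            nodes=field.nodes,
            triangles=field.triangles,
            times=field.times,
            wss_vectors=field.wss_vectors @ Q.T,
        )
        assert np.allclose(ws.compute_tawss(rotated), ws.compute_tawss(field))
        assert np.allclose(ws.compute_osi(rotated), ws.compute_osi(field), atol=1e-10)


class TestAreaWeightedMean:
    def test_constant_field(self):
        assert ws.area_weighted_mean([7.0, 7.0, 7.0], TRI_NODES, TRI) == pytest.approx(7.0)

    def test_two_equal_patches(self):
        nodes = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        tris = [[0, 1, 2], [0, 2, 3]]
        # values constant 0 on one triangle's exclusive vertex, 10 on the other's;
        # shared vertices at 5 keep each patch's nodal mean at its patch value
        assert ws.area_weighted_mean([5.0, 0.0, 5.0, 10.0], nodes, tris) == pytest.approx(5.0)

    def test_subdivision_invariance_for_linear_field(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        f = lambda p: 2.0 * p[:, 0] + 3.0 * p[:, 1] + 1.0
        coarse = ws.area_weighted_mean(f(nodes), nodes, [[0, 1, 2]])
        mids = np.array([(nodes[0] + nodes[1]) / 2, (nodes[1] + nodes[2]) / 2, (nodes[2] + nodes[0]) / 2])
        nodes_f = np.vstack([nodes, mids])
        tris_f = [[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]]
        fine = ws.area_weighted_mean(f(nodes_f), nodes_f, tris_f)
        assert fine == pytest.approx(coarse)

    def test_degenerate_surface_rejected(self):
        nodes = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]  # collinear
        with pytest.raises(DataError):
            ws.area_weighted_mean([1.0, 2.0, 3.0], nodes, TRI)


class TestQCriterion:
    @pytest.mark.parametrize(
        "kind, expected", [("rotation", 100.0), ("shear", 0.0), ("strain", -100.0)]
    )
    def test_canonical_fields(self, kind, expected):
        grid, _ = syn.gen_velocity_grid(kind, magnitude=10.0)
        q = ws.compute_q_criterion(grid)
        interior = q[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, expected, atol=1e-6)

    def test_lamb_oseen_matches_analytic(self):
        grid, truth = syn.gen_velocity_grid(
            "lamb_oseen", magnitude=1e-3, grid_shape=(48, 48, 4), spacing=2.5e-4
        )
        q = ws.compute_q_criterion(grid)
        sl = (slice(4, -4), slice(4, -4), slice(1, -1))
        scale = np.abs(truth["q_field"][sl]).max()
        assert np.allclose(q[sl], truth["q_field"][sl], atol=0.05 * scale)

    def test_small_grid_rejected(self):
        grid = ws.VelocityGrid(spacing=(1e-3,) * 3, velocity=np.zeros((3, 8, 8, 3)))
        with pytest.raises(DataError):
            ws.compute_q_criterion(grid)


class TestBioreactorPreset:
    def test_preset_field_matches_conditioning_targets(self):
        field, _ = syn.gen_wss_surface_field(syn.bioreactor_preset())
        s = ws.summarize_field(field)
        assert s.osi_mean == pytest.approx(0.5, abs=0.01)
        assert 3.0 <= s.tawss_mean <= 4.0
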