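"""Covariance formation, eigen-descriptors, and vegetation indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croplab.polarimetry import (
    C2Grid,
    DegenerateCovarianceError,
    PolarimetryError,
    build_c2,
    decompose,
    dprvi,
    index_stack,
    rvi_dual_pol,
    vv_vh_ratio,
)
from croplab.simulate import SimulationConfig, generate_scene, sample_speckle, target_c2_from_dprvi

from conftest import random_psd_c2


class TestBuildC2:
    def test_constant_vv_only(self):
        vv = np.full((6, 6), 1 + 0j)
        vh = np.zeros((6, 6), complex)
        c2 = build_c2(vv, vh, window=3)
        assert np.allclose(c2.c11, 1.0)
        assert np.allclose(c2.c22, 0.0)
        assert np.allclose(c2.c12, 0.0)

    def test_constant_vh_only(self):
        c2 = build_c2(np.zeros((4, 4), complex), np.full((4, 4), 2 + 0j), window=3)
        assert np.allclose(c2.c11, 0.0)
        assert np.allclose(c2.c22, 4.0)

    def test_center_matches_double_loop(self, rng):
        """Window means equal an explicit double-loop average at the center."""
        vv = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
        vh = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
        c2 = build_c2(vv, vh, window=5)
        c11 = c22 = 0.0
        c12 = 0.0 + 0.0j
        for i in range(5):
            for j in range(5):
                c11 += abs(vv[i, j]) ** 2
                c22 += abs(vh[i, j]) ** 2
                c12 += vv[i, j] * np.conj(vh[i, j])
        assert c2.c11[2, 2] == pytest.approx(c11 / 25, rel=1e-12)
        assert c2.c22[2, 2] == pytest.approx(c22 / 25, rel=1e-12)
        assert c2.c12[2, 2] == pytest.approx(c12 / 25, rel=1e-12)

    def test_edge_pixels_use_valid_intersection(self, rng):
        vv = rng.normal(size=(4, 4)) + 0j
        vh = np.zeros((4, 4), complex)
        c2 = build_c2(vv, vh, window=3)
        corner = np.mean(np.abs(vv[:2, :2]) ** 2)
        assert c2.c11[0, 0] == pytest.approx(corner, rel=1e-12)

    @pytest.mark.parametrize(
        "vv_shape,vh_shape,window",
        [((3, 3), (4, 4), 3), ((4, 4), (4, 4), 2), ((4, 4), (4, 4), 0)],
    )
    def test_invalid_inputs(self, vv_shape, vh_shape, window):
        with pytest.raises(PolarimetryError):
            build_c2(np.zeros(vv_shape, complex), np.zeros(vh_shape, complex), window)


class TestDecompose:
    @pytest.mark.parametrize(
        "c11,c22,m,beta,d",
        [
            (1.0, 0.0, 1.0, 1.0, 0.0),     # fully polarized limit
            (1.0, 1.0, 0.0, 0.5, 1.0),     # fully depolarized limit
            (3.0, 1.0, 0.5, 0.75, 0.625),  # hand eigencomputation
        ],
    )
    def test_closed_form_cases(self, c11, c22, m, beta, d):
        desc = decompose(C2Grid.single(c11, c22))
        assert float(desc.m) == pytest.approx(m, abs=1e-12)
        assert float(desc.beta) == pytest.approx(beta, abs=1e-12)
        assert float(desc.dprvi) == pytest.approx(d, abs=1e-12)

    def test_matches_general_eigensolver(self, rng):
        """Closed-form eigenvalues agree with numpy's Hermitian solver to 1e-9."""
        mats = random_psd_c2(rng, 1000)
        c2 = C2Grid(mats[:, 0, 0].real, mats[:, 1, 1].real, mats[:, 0, 1])
        desc = decompose(c2)
        ref = np.linalg.eigvalsh(mats)  # ascending
        scale = np.maximum(c2.trace, 1.0)
        assert np.all(np.abs(desc.lambda1 - ref[:, 1]) / scale < 1e-9)
        assert np.all(np.abs(desc.lambda2 - ref[:, 0]) / scale < 1e-9)

    def test_eigen_identities_and_ranges(self, rng):
        mats = random_psd_c2(rng, 500)
        c2 = C2Grid(mats[:, 0, 0].real, mats[:, 1, 1].real, mats[:, 0, 1])
        desc = decompose(c2)
        np.testing.assert_allclose(desc.lambda1 + desc.lambda2, c2.trace, rtol=1e-9)
        np.testing.assert_allclose(
            desc.lambda1 * desc.lambda2, c2.det, rtol=1e-9, atol=1e-9 * c2.trace.max() ** 2
        )
        assert np.all((desc.m >= 0) & (desc.m <= 1))
        assert np.all((desc.beta >= 0.5) & (desc.beta <= 1))
        assert np.all((desc.dprvi >= 0) & (desc.dprvi <= 1))

    def test_beta_is_normalized_leading_eigenvalue(self, rng):
        mats = random_psd_c2(rng, 100)
        c2 = C2Grid(mats[:, 0, 0].real, mats[:, 1, 1].real, mats[:, 0, 1])
        desc = decompose(c2)
        np.testing.assert_allclose(
            desc.beta, desc.lambda1 / (desc.lambda1 + desc.lambda2), rtol=1e-12
        )

    def test_zero_trace_convention(self):
        desc = decompose(C2Grid.single(0.0, 0.0))
        assert float(desc.m) == 0.0
        assert float(desc.beta) == 0.5
        assert np.isnan(float(desc.dprvi))

    def test_non_psd_rejected(self):
        with pytest.raises(DegenerateCovarianceError):
            decompose(C2Grid.single(1.0, 1.0, 2.0))  # |c12|^2 > c11 c22
        with pytest.raises(DegenerateCovarianceError):
            decompose(C2Grid.single(-1.0, 1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        c11=st.floats(0.0, 10.0),
        c22=st.floats(0.0, 10.0),
        frac=st.floats(0.0, 1.0),
        phase=st.floats(0.0, 2 * np.pi),
    )
    def test_dprvi_bounds_property(self, c11, c22, frac, phase):
        """Any Hermitian PSD matrix yields m, beta, DpRVI in their ranges."""
        c12 = frac * np.sqrt(c11 * c22) * np.exp(1j * phase)
        desc = decompose(C2Grid.single(c11, c22, c12))
        assert 0.0 <= float(desc.m) <= 1.0
        assert 0.5 <= float(desc.beta) <= 1.0
        d = dprvi(desc)
        assert np.isnan(d) or 0.0 <= float(d) <= 1.0


class TestIntensityIndices:
    @pytest.mark.parametrize("svv,svh,expected", [(1.0, 1.0, 2.0), (3.0, 1.0, 1.0)])
    def test_rvi_values(self, svv, svh, expected):
        assert rvi_dual_pol(svv, svh) == pytest.approx(expected)

    def test_rvi_vanishing_cross_pol_limit(self):
        assert rvi_dual_pol(1.0, 1e-12) == pytest.approx(0.0, abs=1e-11)

    def test_rvi_rejects_nonpositive(self):
        with pytest.raises(PolarimetryError):
            rvi_dual_pol(-1.0, 1.0)

    @pytest.mark.parametrize("svv,svh,expected", [(1.0, 1.0, 1.0), (4.0, 2.0, 2.0)])
    def test_vvvh_values(self, svv, svh, expected):
        assert vv_vh_ratio(svv, svh) == pytest.approx(expected)

    def test_vvvh_reciprocal_identity(self, rng):
        svv, svh = rng.uniform(0.1, 5.0, size=2)
        assert vv_vh_ratio(svv, svh) == pytest.approx(1.0 / vv_vh_ratio(svh, svv))

    def test_vvvh_rejects_zero_cross_pol(self):
        with pytest.raises(PolarimetryError):
            vv_vh_ratio(1.0, 0.0)


class TestMonteCarloConsistency:
    def test_dprvi_bias_shrinks_with_looks(self):
        """Multi-look DpRVI estimates converge to the closed form as looks grow."""
        target = 0.625
        c2_true = target_c2_from_dprvi(target)
        rng = np.random.default_rng(42)
        biases = []
        for n_looks in (9, 49, 225):
            estimates = []
            for _ in range(300):
                s = sample_speckle(c2_true, n_looks, rng)
                c2 = C2Grid.single(
                    np.mean(np.abs(s[:, 0]) ** 2),
                    np.mean(np.abs(s[:, 1]) ** 2),
                    np.mean(s[:, 0] * np.conj(s[:, 1])),
                )
                estimates.append(float(decompose(c2).dprvi))
            biases.append(abs(np.mean(estimates) - target))
        assert biases[0] > biases[1] > biases[2]
        assert biases[2] < 0.01


class TestIndexStack:
    def test_constant_stack_closed_form(self):
        vv = np.full((8, 8), np.sqrt(3) + 0j)
        vh = np.full((8, 8), 1 + 0j)
        rasters = index_stack([(vv, vh)] * 2, [121, 133], "dprvi", window=3)
        assert len(rasters) == 2
        # constant fields make c12 = sqrt(3), a coherent (fully polarized) signal
        expected = float(decompose(C2Grid.single(3.0, 1.0, np.sqrt(3))).dprvi)
        for r in rasters:
            assert np.allclose(r.values, expected)

    def test_empty_input(self):
        assert index_stack([], [], "dprvi") == []

    def test_inconsistent_grids_rejected(self):
        pair1 = (np.zeros((3, 3), complex), np.zeros((3, 3), complex))
        pair2 = (np.zeros((4, 4), complex), np.zeros((4, 4), complex))
        with pytest.raises(PolarimetryError):
            index_stack([pair1, pair2], [121, 133])

    def test_nodata_propagates(self):
        vv = np.zeros((6, 6), complex)
        vh = np.zeros((6, 6), complex)
        r = index_stack([(vv, vh)], [121], "dprvi", window=1)[0]
        assert np.isnan(r.values).all()

    @pytest.mark.parametrize("n_looks,tol", [(25, 0.04), (225, 0.02)])
    def test_mean_tracks_generator_trajectory(self, n_looks, tol):
        """Scene-mean DpRVI per date stays close to the simulated trajectory."""
        config = SimulationConfig(
            field_counts={"train": {"soybean": 3}},
            field_shape=(12, 12),
            n_looks=n_looks,
            pixel_jitter=0.0,
        )
        scene = generate_scene(config, seed=1)
        rasters = scene.index_rasters("dprvi", window=1)
        from croplab.simulate import KHABAROVSKIY_PROFILES

        profile = next(p for p in KHABAROVSKIY_PROFILES if p.class_label == "soybean")
        for r in rasters:
            per_field = []
            for _, f in scene.truth.iterrows():
                block = r.values[
                    f.row0 : f.row0 + f.height, f.col0 : f.col0 + f.width
                ]
                target = profile.trajectory(
                    [r.doy], peak_value=f.peak_value, peak_doy=f.peak_doy
                )[0]
                per_field.append(np.nanmean(block) - target)
            assert abs(np.mean(per_field)) < tol
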