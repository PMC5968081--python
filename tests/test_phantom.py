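"""Phantom construction and acquisition simulation."""

import numpy as np
import pytest

from hippodmri.core import HIPPOCAMPAL_LEGEND, WHITE_MATTER_STRUCTURES
from hippodmri.microstructure import NoddiParams, noddi_forward
from hippodmri.phantom import (DEFAULT_SHELL_SNRS, HYDI_SHELLS, PhantomSpec,
                               add_rician_noise, build_phantom, hydi_scheme,
                               simulate_dwi, simulate_msme)
from hippodmri.relaxometry import DEFAULT_ECHO_TIMES, fit_t2_map

SMALL = PhantomSpec(shape=(12, 24, 24), rng_seed=3)


@pytest.fixture(scope="module")
def truth():
    return build_phantom(SMALL)


class TestBuildPhantom:
    def test_labels_and_rim_partition_the_mask(self, truth):
        tissue = truth.labels.labels > 0
        rim = truth.mask & ~tissue
        assert np.all(truth.f_iso[rim] == 1.0)
        assert not np.any(tissue & rim)
        assert np.array_equal(tissue | rim, truth.mask)

    def test_all_22_regions_present_with_default_geometry(self):
        t = build_phantom(PhantomSpec())
        present = set(np.unique(t.labels.labels).tolist()) - {0}
        assert present == set(HIPPOCAMPAL_LEGEND)

    def test_layer_contrasts(self, truth):
        labels, legend = truth.labels.labels, truth.labels.legend
        of = {}
        for lab, (part, structure) in legend.items():
            sel = labels == lab
            if sel.any():
                of.setdefault(structure, []).append(truth.f_ic_star[sel].mean())
        white = np.mean(of["Alveus"])
        pyramidal = np.mean(of["CA1"])
        molecular = np.mean(of["Lacunosum-molecular layer"])
        assert white > molecular > pyramidal

    def test_positive_slope_gives_anterior_dominance(self, truth):
        labels = truth.labels.labels
        grey = np.zeros_like(truth.mask)
        for lab, (_, s) in HIPPOCAMPAL_LEGEND.items():
            if s not in WHITE_MATTER_STRUCTURES:
                grey |= labels == lab
        nz = truth.grid.shape[2]
        ant = truth.f_ic_star[..., :nz // 3][grey[..., :nz // 3]]
        post = truth.f_ic_star[..., -(nz // 3):][grey[..., -(nz // 3):]]
        assert ant.mean() > post.mean()

    def test_crossing_block_has_two_populations(self, truth):
        two = (truth.weights > 0).sum(axis=-1) == 2
        assert two.any()
        w = truth.weights[two]
        np.testing.assert_allclose(w.sum(axis=1), 1.0)
        d = np.abs(np.einsum("ij,ij->i", truth.orientations[two][:, 0],
                             truth.orientations[two][:, 1]))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)  # 90 degree crossing

    def test_same_seed_reproduces_ground_truth(self):
        a = build_phantom(SMALL)
        b = build_phantom(SMALL)
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)
        np.testing.assert_array_equal(a.t2, b.t2)
        np.testing.assert_array_equal(a.f_ic_star, b.f_ic_star)


class TestSimulateDwi:
    def test_noiseless_b0_equals_s0(self, truth, hydi60):
        dwi = simulate_dwi(truth, hydi60, None)
        b0 = dwi.signal[..., hydi60.b == 0][truth.mask]
        expected = np.broadcast_to(truth.s0[truth.mask][:, None], b0.shape)
        np.testing.assert_allclose(b0, expected)

    def test_noiseless_attenuation_bounded(self, truth, hydi60):
        dwi = simulate_dwi(truth, hydi60, None)
        atten = dwi.signal[truth.mask] / truth.s0[truth.mask][:, None]
        assert atten.min() >= 0.0
        assert atten.max() <= 1.0 + 1e-9

    def test_free_water_voxel_attenuation(self, truth, hydi60):
        dwi = simulate_dwi(truth, hydi60, None)
        rim = truth.mask & (truth.labels.labels == 0)
        vox = tuple(np.argwhere(rim)[0])
        sel = hydi60.b == 4500.0
        np.testing.assert_allclose(dwi.signal[vox][sel] / truth.s0[vox],
                                   np.exp(-9.0), rtol=1e-9)

    def test_two_population_voxels_mix_linearly(self, truth, hydi60):
        dwi = simulate_dwi(truth, hydi60, None)
        two = (truth.weights > 0).sum(axis=-1) == 2
        vox = tuple(np.argwhere(two)[0])
        from hippodmri.microstructure import odi_to_kappa
        expected = np.zeros(len(hydi60))
        for mu, w in zip(truth.orientations[vox], truth.weights[vox]):
            p = NoddiParams(truth.f_iso[vox], truth.f_stat_prime[vox],
                            truth.f_ic_star[vox],
                            float(odi_to_kappa(truth.odi[vox])), mu)
            expected += w * noddi_forward(p, hydi60)
        np.testing.assert_allclose(dwi.signal[vox],
                                   truth.s0[vox] * expected, rtol=1e-9)

    def test_shell_snr_calibration(self, truth, hydi60):
        # measured b0 fluctuation per shell should track the requested SNR
        dwi = simulate_dwi(truth, hydi60, DEFAULT_SHELL_SNRS,
                           t2_weighting=True, rng_seed=5)
        clean = simulate_dwi(truth, hydi60, None, t2_weighting=True)
        for snr, (_, idx) in zip(DEFAULT_SHELL_SNRS, hydi60.shells()):
            b0 = idx[hydi60.b[idx] == 0]
            ref = clean.signal[truth.mask][:, b0].mean()
            resid = dwi.signal[truth.mask][:, b0] - clean.signal[truth.mask][:, b0]
            assert resid.std() == pytest.approx(ref / snr, rel=0.15)

    def test_same_seed_is_bit_identical(self, truth, hydi60):
        a = simulate_dwi(truth, hydi60, DEFAULT_SHELL_SNRS, rng_seed=11)
        b = simulate_dwi(truth, hydi60, DEFAULT_SHELL_SNRS, rng_seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_snr_count_mismatch_rejected(self, truth, hydi60):
        from hippodmri.core import ValidationError
        with pytest.raises(ValidationError):
            simulate_dwi(truth, hydi60, (9.9, 7.6))


class TestSimulateMsme:
    def test_closed_form_echo_value(self, truth):
        series = simulate_msme(truth.t2_map(), truth.s0,
                               echo_times=np.array([46.4, 92.8]))
        vox = tuple(np.argwhere(truth.mask)[0])
        expected = truth.s0[vox] * np.exp(-46.4 / truth.t2[vox])
        assert series.signal[vox][0] == pytest.approx(expected, rel=1e-12)

    def test_noiseless_series_strictly_decreasing(self, truth):
        series = simulate_msme(truth.t2_map(), truth.s0)
        masked = series.signal[truth.mask]
        assert np.all(np.diff(masked, axis=1) < 0)

    def test_round_trip_with_fit(self, truth):
        series = simulate_msme(truth.t2_map(), truth.s0)
        sub = truth.mask.copy()
        sub[:, :, 6:] = False  # small subset for speed
        fit = fit_t2_map(series, sub)
        rel = np.abs(fit.t2[sub] - truth.t2[sub]) / truth.t2[sub]
        assert rel.max() < 1e-3

    def test_closed_form_1000_over_e(self):
        # S0 = 1000, T2 = TE = 46.4 -> signal 1000/e
        from hippodmri.core import VolumeGrid
        from hippodmri.relaxometry import T2Map
        grid = VolumeGrid.isotropic((1, 1, 1))
        t2m = T2Map(grid, np.full((1, 1, 1), 46.4), np.full((1, 1, 1), 1000.0),
                    np.ones((1, 1, 1), bool))
        series = simulate_msme(t2m, np.full((1, 1, 1), 1000.0),
                               echo_times=np.array([46.4, 92.8]))
        assert series.signal[0, 0, 0, 0] == pytest.approx(1000 / np.e,
                                                          rel=1e-12)


class TestAddRicianNoise:
    def test_zero_sigma_is_identity(self):
        v = np.linspace(0, 10, 5)
        np.testing.assert_array_equal(add_rician_noise(v, 0.0, 1), v)

    def test_negative_sigma_rejected(self):
        from hippodmri.core import ValidationError
        with pytest.raises(ValidationError):
            add_rician_noise(np.ones(3), -1.0, 0)

    def test_second_moment_matches_rice_distribution(self):
        # E[m^2] = v^2 + 2 sigma^2 for Rice(v, sigma)
        v, sigma, n = 5.0, 1.5, 10**6
        noisy = add_rician_noise(np.full(n, v), sigma, 123)
        assert (noisy**2).mean() == pytest.approx(v**2 + 2 * sigma**2,
                                                  rel=0.01)

    def test_high_snr_gaussian_limit(self):
        # at v/sigma = 10 the mean is within 1% of v
        v, sigma, n = 10.0, 1.0, 10**5
        noisy = add_rician_noise(np.full(n, v), sigma, 7)
        assert noisy.mean() == pytest.approx(v, rel=0.01)


class TestProtocolConstants:
    def test_table_timings(self):
        assert [s[0] for s in HYDI_SHELLS] == [4500.0, 7500.0, 10000.0]
        assert [s[1] for s in HYDI_SHELLS] == [24.2, 39.8, 54.8]
        assert [s[2] for s in HYDI_SHELLS] == [14.4, 30.0, 45.0]

    def test_default_echoes_match_msme_protocol(self):
        assert DEFAULT_ECHO_TIMES[0] == 6.4
        assert DEFAULT_ECHO_TIMES[-1] == 76.8
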