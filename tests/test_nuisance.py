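import numpy as np
import pytest

from walinet.axis import AXIS_3D
from walinet.lipid_l2 import lipid_project
from walinet.nuisance import (
    LipidComponent,
    NuisanceParams,
    assemble_training_set,
    build_phantom,
    draw_subject_params,
    reference_scale,
    sample_lipid_spectrum,
    sample_water_spectrum,
    truncate_kspace,
)
from walinet.spectrum import Spectrum


class TestLipidGenerator:
    def test_zero_amplitude_interval_gives_zero(self, axis):
        comps = tuple(
            LipidComponent(c.center_ppm, c.linewidth_hz, (0.0, 0.0))
            for c in NuisanceParams().lipid_components
        )
        p = NuisanceParams(lipid_components=comps)
        assert np.all(sample_lipid_spectrum(p, axis, 0).data == 0)

    def test_lipid_range_energy_dominates(self, axis, nuisance_params):
        """Lipid-range energy beats mid-metabolite-range energy >= 95%."""
        lip = axis.ppm_mask(0.7, 1.9)
        met = axis.ppm_mask(2.5, 4.2)
        wins = 0
        n = 1000
        for seed in range(n):
            s = sample_lipid_spectrum(nuisance_params, axis, seed).data
            wins += np.linalg.norm(s[lip]) > np.linalg.norm(s[met])
        assert wins / n >= 0.95

    def test_scale_one_to_two_orders_above_reference(self, axis, nuisance_params):
        peaks = [
            np.abs(sample_lipid_spectrum(nuisance_params, axis, s, ref_scale=1.0).data).max()
            for s in range(100)
        ]
        assert min(peaks) >= 10.0 * 0.99
        assert max(peaks) <= 100.0 * 1.01

    def test_deterministic_per_seed(self, axis, nuisance_params):
        a = sample_lipid_spectrum(nuisance_params, axis, 42).data
        b = sample_lipid_spectrum(nuisance_params, axis, 42).data
        assert np.array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NuisanceParams(
                lipid_components=(LipidComponent(7.0, (30, 60), (0, 1)),)
            )
        with pytest.raises(ValueError):
            NuisanceParams(
                lipid_components=(LipidComponent(1.0, (1.0, 2.0), (0, 1)),)
            )


class TestWaterGenerator:
    def test_zero_reference_gives_zero(self, axis, nuisance_params):
        assert np.all(
            sample_water_spectrum(nuisance_params, axis, 0, ref_scale=0.0).data == 0
        )

    def test_peak_near_468_ppm(self, axis, nuisance_params):
        for seed in range(50):
            s = sample_water_spectrum(nuisance_params, axis, seed).data
            peak = axis.ppm[np.argmax(np.abs(s))]
            assert abs(peak - 4.68) <= 0.1

    def test_scale_three_to_four_orders_above_reference(self, axis, nuisance_params):
        peaks = [
            np.abs(sample_water_spectrum(nuisance_params, axis, s, ref_scale=1.0).data).max()
            for s in range(100)
        ]
        assert min(peaks) >= 1e3 * 0.99
        assert max(peaks) <= 1e4 * 1.01

    def test_asymmetric_tails(self, axis, nuisance_params):
        """Tails exceed a symmetric Lorentzian fitted at the peak width."""
        heavier = 0
        for seed in range(20):
            s = np.abs(sample_water_spectrum(nuisance_params, axis, seed).data)
            k = int(np.argmax(s))
            # half width in bins where signal first drops below half max
            r = 1
            while s[k + r] > s[k] / 2 or s[k - r] > s[k] / 2:
                r += 1
            gamma = r * axis.hz_per_point
            off = 40  # bins from the peak
            lorentz = s[k] * (gamma**2 / (gamma**2 + (off * axis.hz_per_point) ** 2))
            tail = max(s[k + off], s[k - off])
            heavier += tail > lorentz
        assert heavier >= 15


@pytest.fixture(scope="module")
def phantom(basis, rel_conc, nuisance_params):
    return build_phantom(
        (16, 16), nuisance_params, basis, rel_conc, seed=0, hires_factor=4
    )


class TestPhantom:

    def test_masks_disjoint_and_nonempty(self, phantom):
        ph, vol = phantom
        assert ph.scalp_mask.sum() > 0
        assert not np.any(ph.brain_mask & ph.scalp_mask)
        assert vol.scalp_mask.sum() > 0
        assert not np.any(vol.brain_mask & vol.scalp_mask)

    def test_lipid_zero_outside_scalp(self, phantom):
        ph, _ = phantom
        assert np.all(ph.lipid_amplitude[~ph.scalp_mask] == 0.0)

    def test_ringing_leaks_lipid_into_brain(
        self, basis, rel_conc, nuisance_params
    ):
        lip_mask = AXIS_3D.ppm_mask(0.7, 1.9)

        def brain_lipid_energy(lipid_on):
            _, vol = build_phantom(
                (16, 16), nuisance_params, basis, rel_conc, seed=1,
                hires_factor=4, lipid_on=lipid_on, water_on=False,
                noise_sigma_rel=0.0,
            )
            spec = vol.to_freq()
            return np.linalg.norm(
                spec.casorati()[vol.brain_mask.ravel()][:, lip_mask], axis=1
            ).mean()

    # with lipids on, truncation ringing adds energy well above the
    # metabolite-only reference
        assert brain_lipid_energy(True) > 2.0 * brain_lipid_energy(False)

    def test_point_source_matches_dft_truncation_oracle(self):
        """k-space crop of a delta equals the direct DFT point spread."""
        rng = np.random.default_rng(0)
        hi = np.zeros((32, 32), dtype=complex)
        hi[3, 17] = 1.0  # single high-res source near the rim
        got = truncate_kspace(hi[..., None], (8, 8))[..., 0]
        # oracle: explicit truncated Fourier series evaluated voxel-wise
        ky = np.fft.fftshift(np.fft.fftfreq(32))[32 // 2 - 4 : 32 // 2 + 4]
        kx = ky.copy()
        y = np.arange(8) * 4
        x = np.arange(8) * 4
        oracle = np.zeros((8, 8), dtype=complex)
        for i, yy in enumerate(y):
            for j, xx in enumerate(x):
                phase = np.exp(
                    2j * np.pi * (np.add.outer(ky * (yy - 3), kx * (xx - 17)))
                )
                oracle[i, j] = phase.sum() / (32 * 32)
        assert np.abs(got - oracle).max() < 1e-10

    def test_invalid_hires_factor(self, basis, rel_conc, nuisance_params):
        with pytest.raises(ValueError):
            build_phantom((8, 8), nuisance_params, basis, rel_conc, hires_factor=1)


class TestAssembly:
    def test_nonpositive_n_rejected(self, basis, rel_conc):
        with pytest.raises(ValueError):
            assemble_training_set(0, "walinet", basis, rel_conc)

    def test_deterministic_per_seed(self, basis, rel_conc):
        a = assemble_training_set(20, "walinet", basis, rel_conc, n_subjects=2, seed=9)
        b = assemble_training_set(20, "walinet", basis, rel_conc, n_subjects=2, seed=9)
        assert np.array_equal(a.x1, b.x1)
        assert np.array_equal(a.x2, b.x2)

    def test_x2_recomputable_from_subject_operator(self, small_dataset):
        """x2 equals an independent lipid projection of x1 exactly."""
        axis = small_dataset.axis
        for i in (0, 57, 119):
            sid = int(small_dataset.subject_ids[i])
            x2 = lipid_project(
                Spectrum(small_dataset.x1[i], axis, "freq"),
                small_dataset.subspaces[sid],
            ).data
            assert np.abs(x2 - small_dataset.x2[i]).max() < 1e-10

    def test_composition_identity(self, small_dataset):
        assert np.allclose(
            small_dataset.x1,
            small_dataset.m + small_dataset.lipid + small_dataset.water,
        )

    def test_walinet_target_includes_water(self, small_dataset):
        _, _, y = small_dataset.arrays("walinet")
        assert np.array_equal(y, small_dataset.lipid + small_dataset.water)
        _, _, y_lip = small_dataset.arrays("lipnet")
        assert np.array_equal(y_lip, small_dataset.lipid)

    def test_lipnet_mode_has_no_water(self, basis, rel_conc):
        ds = assemble_training_set(10, "lipnet", basis, rel_conc, n_subjects=2, seed=0)
        assert np.all(ds.water == 0)

    def test_subjects_grouped_and_calibrated(self, small_dataset):
        assert set(np.unique(small_dataset.subject_ids)) == set(
            small_dataset.subspaces
        )
        for sub in small_dataset.subspaces.values():
            assert abs(sub.mean_abs_diag() - 0.938) <= 1e-3


def test_subject_draw_narrows_within_population(nuisance_params, rng):
    subj = draw_subject_params(nuisance_params, rng)
    for pop, sub in zip(nuisance_params.lipid_components, subj.lipid_components):
        assert pop.rel_amp[0] <= sub.rel_amp[0] <= sub.rel_amp[1] <= pop.rel_amp[1]
        assert pop.linewidth_hz[0] <= sub.linewidth_hz[0]
        assert sub.linewidth_hz[1] <= pop.linewidth_hz[1]


def test_reference_scale_positive(basis, rel_conc):
    assert reference_scale(basis, rel_conc) > 0
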