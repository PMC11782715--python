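import numpy as np
import pytest

from walinet.axis import AXIS_3D, SpectralAxis
from walinet.spin_sim import (
    MetaboliteSampleParams,
    SpinCountError,
    SpinSystem,
    build_basis,
    load_catalog,
    sample_metabolite_spectrum,
    sample_params,
    simulate_metabolite_fid,
)


def _singlet(shift=3.0, mult=1, t2=0.12, name="X"):
    n = 1
    return SpinSystem(name, (shift,), np.zeros((n, n)), (mult,), t2=t2)


def _power_fwhm_hz(spec):
    """FWHM of the power spectrum of an isolated line, in Hz."""
    axis = spec.axis
    p = np.abs(spec.to_freq().data) ** 2
    k = int(np.argmax(p))
    half = p[k] / 2.0

    def cross(direction):
        i = k
        while 0 < i < p.size - 1 and p[i + direction] > half:
            i += direction
        j = i + direction
        frac = (p[i] - half) / (p[i] - p[j])
        return axis.freq_hz[i] + frac * (axis.freq_hz[j] - axis.freq_hz[i])

    return abs(cross(-1) - cross(+1))


class TestSimulate:
    def test_single_spin_closed_form(self):
        """An uncoupled spin is exactly exp(2i pi f t - t/t2)."""
        axis = AXIS_3D
        sys = _singlet(shift=3.0, t2=0.12)
        fid = simulate_metabolite_fid(sys, axis)
        f = (3.0 - axis.carrier_ppm) * axis.field_mhz
        ref = np.exp(2j * np.pi * f * axis.time - axis.time / 0.12)
        assert np.abs(fid.data - ref).max() < 1e-12

    def test_ax_doublet_splitting(self, fine_axis):
        """Weakly coupled AX pair: each line split by J within 0.1 Hz."""
        j = 6.9
        jm = np.array([[0.0, j], [j, 0.0]])
        sys = SpinSystem("AX", (1.0, 4.0), jm, (1, 1), t2=5.0)
        spec = simulate_metabolite_fid(sys, fine_axis).to_freq()
        mag = np.abs(spec.data)
        for center in (1.0, 4.0):
            mask = fine_axis.ppm_mask(center - 0.1, center + 0.1)
            idx = np.flatnonzero(mask)
            sub = mag[mask]
            # two strongest local maxima = the doublet lines
            peaks = idx[
                np.flatnonzero((sub[1:-1] > sub[:-2]) & (sub[1:-1] > sub[2:])) + 1
            ]
            peaks = peaks[np.argsort(mag[peaks])[-2:]]
            split = abs(np.diff(fine_axis.freq_hz[peaks]))[0]
            assert abs(split - j) < 0.1

    def test_lactate_doublet_and_quartet_positions(self, fine_axis, catalog):
        """Lactate: methyl doublet at 1.3 ppm, methine resonance near 4.1."""
        systems, _ = catalog
        lac = next(s for s in systems if s.name == "Lac")
        mag = np.abs(simulate_metabolite_fid(lac, fine_axis).to_freq().data)
        assert abs(fine_axis.ppm[np.argmax(mag)] - 1.31) < 0.05
        m = fine_axis.ppm_mask(3.9, 4.3)
        sub_peak = fine_axis.ppm[np.flatnonzero(m)[np.argmax(mag[m])]]
        assert abs(sub_peak - 4.10) < 0.05

    def test_resonance_within_half_bin_across_axes(self):
        for axis in (
            AXIS_3D,
            SpectralAxis(n_points=512, bandwidth_hz=4000.0),
            SpectralAxis(n_points=300, bandwidth_hz=1500.0, carrier_ppm=4.2),
        ):
            sys = _singlet(shift=2.5, t2=2.0)
            spec = simulate_metabolite_fid(sys, axis).to_freq()
            peak = axis.ppm[np.argmax(np.abs(spec.data))]
            assert abs(peak - 2.5) <= axis.ppm_per_point / 2 + 1e-9

    def test_spectrum_matches_analytic_discrete_lorentzian(self):
        """DFT of the damped exponential equals the finite geometric sum."""
        axis = AXIS_3D
        sys = _singlet(shift=2.0, t2=0.08)
        spec = simulate_metabolite_fid(sys, axis).to_freq().data
        f0 = axis.ppm_to_hz(2.0)
        dt = axis.dwell_time
        n = axis.n_points
        r = np.exp((2j * np.pi * f0 - 1.0 / 0.08) * dt)
        z = r * np.exp(-2j * np.pi * axis.freq_hz * dt)
        ref = (1.0 - z**n) / (1.0 - z)
        assert np.linalg.norm(spec - ref) / np.linalg.norm(ref) < 1e-6

    def test_spin_cap_raises_resource_error(self):
        n = 9
        j = np.full((n, n), 1.0) - np.eye(n)
        sys = SpinSystem("big", tuple([1.0] * n), j, tuple([1] * n))
        with pytest.raises(SpinCountError, match="subgroup"):
            simulate_metabolite_fid(sys, AXIS_3D)

    def test_uncoupled_groups_split_into_components(self):
        """10 mutually uncoupled protons simulate fine despite the cap."""
        n = 10
        sys = SpinSystem("free", tuple([2.0] * n), np.zeros((n, n)), tuple([1] * n))
        fid = simulate_metabolite_fid(sys, AXIS_3D)
        assert abs(fid.data[0] - n) < 1e-9


class TestBasis:
    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_basis([], AXIS_3D)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_basis([_singlet(), _singlet()], AXIS_3D)

    def test_catalog_covers_major_metabolites(self, basis):
        majors = {"NAA", "Cr", "Cho", "Glu", "Ins", "Lac"}
        assert len(basis.entries) >= 10
        assert majors <= set(basis.names)

    def test_peak_integral_scales_with_multiplicity(self, axis):
        one = simulate_metabolite_fid(_singlet(mult=1), axis)
        three = simulate_metabolite_fid(_singlet(mult=3), axis)
        ratio = np.abs(three.to_freq().data).sum() / np.abs(one.to_freq().data).sum()
        assert abs(ratio - 3.0) < 1e-9

    def test_reproducible(self, axis, catalog):
        systems, _ = catalog
        b1 = build_basis(systems[:3], axis)
        b2 = build_basis(systems[:3], axis)
        for n in b1.names:
            assert np.array_equal(b1.entries[n].data, b2.entries[n].data)


class TestSampler:
    def test_all_zero_gives_zero_spectrum(self, basis):
        p = MetaboliteSampleParams(concentrations={n: 0.0 for n in basis.names})
        assert np.all(sample_metabolite_spectrum(basis, p).data == 0)

    def test_concentration_linearity(self, basis):
        p1 = MetaboliteSampleParams(concentrations={"NAA": 1.0})
        p2 = MetaboliteSampleParams(concentrations={"NAA": 2.0})
        s1 = sample_metabolite_spectrum(basis, p1).data
        s2 = sample_metabolite_spectrum(basis, p2).data
        assert np.abs(s2 - 2 * s1).max() < 1e-10 * np.abs(s1).max()

    def test_mixture_linearity(self, basis):
        names = basis.names[:4]
        conc = {n: 0.3 + 0.2 * i for i, n in enumerate(names)}
        mix = sample_metabolite_spectrum(
            basis, MetaboliteSampleParams(concentrations=conc)
        ).data
        parts = sum(
            sample_metabolite_spectrum(
                basis, MetaboliteSampleParams(concentrations={n: c})
            ).data
            for n, c in conc.items()
        )
        assert np.linalg.norm(mix - parts) / np.linalg.norm(mix) < 1e-10

    @pytest.mark.parametrize("g", [5.0, 12.0, 20.0])
    def test_lorentzian_broadening_adds_to_fwhm(self, g):
        axis = SpectralAxis(n_points=8192, bandwidth_hz=2326.0)
        sys = _singlet(shift=3.0, t2=0.12)
        from walinet.spin_sim import MetaboliteBasis

        b = MetaboliteBasis(axis=axis, entries={"X": simulate_metabolite_fid(sys, axis)})
        w0 = _power_fwhm_hz(
            sample_metabolite_spectrum(
                b, MetaboliteSampleParams(concentrations={"X": 1.0})
            )
        )
        wg = _power_fwhm_hz(
            sample_metabolite_spectrum(
                b,
                MetaboliteSampleParams(concentrations={"X": 1.0}, linewidth_hz=g),
            )
        )
        assert abs((wg - w0) - g) < 0.1 * g

    def test_unknown_metabolite_rejected(self, basis):
        with pytest.raises(ValueError, match="unknown"):
            sample_metabolite_spectrum(
                basis, MetaboliteSampleParams(concentrations={"nope": 1.0})
            )

    def test_seeded_draw_bit_identical(self, basis, rel_conc):
        p = sample_params(basis, rel_conc, np.random.default_rng(5))
        a = sample_metabolite_spectrum(basis, p).data
        b = sample_metabolite_spectrum(basis, p).data
        assert np.array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteSampleParams(concentrations={}, linewidth_hz=-1.0)
        with pytest.raises(ValueError):
            MetaboliteSampleParams(concentrations={}, noise_sigma=-1.0)
        with pytest.raises(ValueError):
            MetaboliteSampleParams(concentrations={"a": -0.1})
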