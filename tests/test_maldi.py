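"""MALDI spectrum preprocessing, regions, peaks and annotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senometrix import maldi
from senometrix.containers import Spectrum, SpectrumSet
from senometrix.synthetic import SpectraSimConfig, simulate_spectra, write_spectra


def simple_spectrum(intensities, mz=None, **ids):
    intensities = np.asarray(intensities, dtype=float)
    if mz is None:
        mz = np.arange(1.0, intensities.size + 1)
    return Spectrum(mz=mz, intensity=intensities, **ids)


class TestTicNormalize:
    def test_direct_normalization(self):
        out = maldi.tic_normalize(simple_spectrum([5.0, 5.0, 10.0]))
        assert out.intensity.tolist() == [0.25, 0.25, 0.50]

    def test_idempotent(self):
        s = maldi.tic_normalize(simple_spectrum([1.0, 2.0, 3.0]))
        again = maldi.tic_normalize(s)
        assert np.allclose(again.intensity, s.intensity)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = np.array([1.0, 4.0, 2.0, 3.0])
        a = maldi.tic_normalize(simple_spectrum(base))
        b = maldi.tic_normalize(simple_spectrum(c * base))
        assert np.allclose(a.intensity, b.intensity)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            maldi.tic_normalize(simple_spectrum([0.0, 0.0]))


class TestAverageSpectra:
    def test_identical_spectra_average_to_themselves(self):
        s = simple_spectrum([1.0, 2.0, 3.0, 4.0])
        avg = maldi.average_spectra([s, s])
        assert np.allclose(avg.intensity, np.interp(avg.mz, s.mz, s.intensity))

    def test_constants_average_to_midpoint(self):
        a = simple_spectrum(np.full(10, 2.0))
        b = simple_spectrum(np.full(10, 6.0))
        avg = maldi.average_spectra([a, b])
        assert np.allclose(avg.intensity, 4.0)

    def test_offset_grids_match_hand_interpolation(self, rng):
        mz_a = np.linspace(100, 200, 101)
        mz_b = np.linspace(100.3, 200.3, 97)
        a = Spectrum(mz=mz_a, intensity=rng.random(101))
        b = Spectrum(mz=mz_b, intensity=rng.random(97))
        grid = np.linspace(101, 199, 40)
        avg = maldi.average_spectra([a, b], grid=grid)
        for point in rng.choice(grid, 20, replace=False):
            expected = 0.5 * (
                np.interp(point, mz_a, a.intensity)
                + np.interp(point, mz_b, b.intensity)
            )
            measured = avg.intensity[np.argmin(np.abs(avg.mz - point))]
            assert measured == pytest.approx(expected)

    def test_disjoint_ranges_rejected(self):
        a = Spectrum(mz=np.array([1.0, 2.0]), intensity=np.ones(2))
        b = Spectrum(mz=np.array([10.0, 11.0]), intensity=np.ones(2))
        with pytest.raises(ValueError):
            maldi.average_spectra([a, b])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            maldi.average_spectra([])


class TestRegions:
    @pytest.mark.parametrize(
        "center, region",
        [(700.0, "region1"), (900.0, "region2"), (1400.0, "region3")],
    )
    def test_narrow_peak_lands_in_expected_region(self, gaussian_spectrum,
                                                  center, region):
        s = gaussian_spectrum([center], [100.0], fwhm=0.3)
        integrals = maldi.region_intensity(s)
        others = {k: v for k, v in integrals.items() if k != region}
        assert integrals[region] > 0.99 * sum(integrals.values())
        assert all(v < 1e-6 * integrals[region] for v in others.values())

    def test_boundary_point_belongs_to_upper_region(self):
        # half-open convention: a point mass exactly at 825 is Region 2
        mz = np.arange(820.0, 830.0, 0.5)
        intensity = np.where(mz == 825.0, 50.0, 0.0)
        integrals = maldi.region_intensity(Spectrum(mz=mz, intensity=intensity))
        assert integrals["region2"] > 0
        assert integrals["region1"] == 0.0

    def test_gaussian_masses_match_closed_form(self, gaussian_spectrum):
        fwhm = 0.5
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        s = gaussian_spectrum([700.0, 900.0, 1400.0], [10.0, 20.0, 5.0],
                              fwhm=fwhm)
        integrals = maldi.region_intensity(s)
        for region, amp in [("region1", 10.0), ("region2", 20.0),
                            ("region3", 5.0)]:
            assert integrals[region] == pytest.approx(
                amp * sigma * np.sqrt(2 * np.pi), rel=0.01
            )

    def test_region_outside_range_warns_and_zeroes(self):
        s = simple_spectrum([1.0, 1.0], mz=np.array([700.0, 701.0]))
        with pytest.warns(UserWarning):
            integrals = maldi.region_intensity(s)
        assert integrals["region3"] == 0.0

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(ValueError):
            maldi.RegionScheme((("a", 0.0, 10.0), ("b", 5.0, 20.0)))


class TestExtractPeak:
    def test_gaussian_amplitude_recovered(self, gaussian_spectrum):
        # the apex falls between grid samples, so recovery is up to the
        # 0.05 Da discretization of the grid
        s = gaussian_spectrum([616.47], [42.0], fwhm=0.18)
        assert maldi.extract_peak(s, 616.47, tol=0.2) == pytest.approx(42.0,
                                                                       rel=0.05)

    def test_flat_zero_spectrum(self):
        s = simple_spectrum(np.zeros(201), mz=np.arange(600.0, 700.5, 0.5))
        assert maldi.extract_peak(s, 650.0, tol=0.5) == 0.0

    def test_close_neighbor_excluded(self, gaussian_spectrum):
        s = gaussian_spectrum([800.0, 800.5], [10.0, 50.0], fwhm=0.05)
        sel = (s.mz >= 799.8) & (s.mz <= 800.2)
        assert maldi.extract_peak(s, 800.0, tol=0.2) == pytest.approx(
            s.intensity[sel].max()
        )
        assert maldi.extract_peak(s, 800.0, tol=0.2) < 20.0

    def test_empty_window_rejected(self):
        s = simple_spectrum([1.0, 1.0], mz=np.array([600.0, 700.0]))
        with pytest.raises(ValueError):
            maldi.extract_peak(s, 650.0, tol=0.1)


class TestAnnotate:
    @pytest.mark.parametrize(
        "mz, species",
        [
            (616.47, "CerP (d16:1/18:0)"),
            (773.0, "PG (18:1/18:1)"),
            (797.67, "SM (d18:1/24:1)"),
            (819.0, "PG (18:1/22:6)"),
        ],
    )
    def test_diagnostic_assignments(self, mz, species):
        ann = maldi.annotate(mz)
        assert ann is not None and ann.species == species

    def test_unknown_mass_returns_none(self):
        assert maldi.annotate(500.0) is None

    def test_region3_masses_called_cardiolipin(self):
        ann = maldi.annotate(1420.0)
        assert ann is not None and ann.lipid_class == "CL"


class TestPeakGroupSummary:
    def test_injected_effect_detected_up(self):
        cfg = SpectraSimConfig(
            group_effects={"control": {}, "senescent": {773.0: 2.0}},
            n_spectra_per_group=30, seed=17,
        )
        spectra, _ = simulate_spectra(cfg)
        _, comps = maldi.peak_group_summary(spectra, [773.0],
                                            control_group="control")
        row = comps.iloc[0]
        assert row["p_two_sided"] < 0.01
        assert row["direction"] == "up"

    def test_identical_groups_p_one(self, quiet_spectra_cfg):
        spectra, _ = simulate_spectra(quiet_spectra_cfg)
        duplicated = SpectrumSet(
            [Spectrum(mz=s.mz, intensity=s.intensity, sample=s.sample + g,
                      group=g) for s in spectra.by_group("control")
             for g in ("x", "y")]
        )
        _, comps = maldi.peak_group_summary(duplicated, [773.0, 819.0])
        assert (comps["p_two_sided"] == 1.0).all()

    def test_long_table_shape(self, quiet_spectra_cfg):
        spectra, _ = simulate_spectra(quiet_spectra_cfg)
        long, _ = maldi.peak_group_summary(spectra, [773.0, 819.0])
        assert len(long) == 2 * len(spectra)


def test_csv_roundtrip(tmp_path, quiet_spectra_cfg):
    spectra, _ = simulate_spectra(quiet_spectra_cfg)
    manifest = write_spectra(tmp_path, spectra)
    loaded = maldi.read_spectra(manifest)
    assert len(loaded) == len(spectra)
    assert loaded.groups == spectra.groups
    first, first_loaded = next(iter(spectra)), next(iter(loaded))
    assert np.allclose(first.intensity, first_loaded.intensity)
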