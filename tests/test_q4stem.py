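"""q4STEM: angular calibration, radial integration, DF/BF inversion."""
import math

import numpy as np
import pytest

from lamellometer import (
    DetectorGeometry,
    McTable,
    RadialProfile,
    ScatterPattern,
    build_table,
    df_bf_ratio,
    most_common_angle,
    pixel_to_angle,
    radial_profile,
    thickness_from_pattern,
    thickness_line_scan,
)
from lamellometer.errors import OutOfRangeError, TableQualityError
from lamellometer.q4stem import bf_cutoff_from_vacuum, simulated_ratio
from lamellometer import mc


def _geometry(n_px=101, max_angle=218.0):
    half = (n_px - 1) / 2
    px = 300.0 * math.tan(max_angle / 1000.0) / half
    return DetectorGeometry(pixel_size_um=px, center_px=(half, half),
                            max_angle_mrad=max_angle)


class TestAngularCalibration:
    def test_scale_bar_example(self):
        geom = _geometry()
        assert 109.0 <= pixel_to_angle(33.0, geom) <= 110.0

    def test_limits(self):
        geom = _geometry()
        assert pixel_to_angle(0.0, geom) == 0.0
        assert pixel_to_angle(300.0, geom) == pytest.approx(1000 * math.pi / 4)


class TestRadialProfile:
    def test_delta_ring_lands_in_one_bin(self):
        geom = _geometry()
        img = np.zeros((101, 101))
        # ring of pixels at the radius corresponding to 100 mrad
        r_px = 300.0 * math.tan(0.100) / geom.pixel_size_um
        phi = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        rows = np.round(50 + r_px * np.sin(phi)).astype(int)
        cols = np.round(50 + r_px * np.cos(phi)).astype(int)
        img[rows, cols] = 1.0
        # bins wide enough that pixel rounding (+-1 px ~ +-1.3 mrad) cannot
        # spill the ring across a bin edge
        prof = radial_profile(ScatterPattern(img, geom), n_bins=16)
        peak_bin = int(np.argmax(prof.intensity))
        assert abs(prof.angle_mrad[peak_bin] - 100.0) <= prof.bin_width_mrad
        assert prof.intensity[peak_bin] == prof.intensity.sum()

    def test_uniform_image_matches_pixel_count_oracle(self):
        geom = _geometry(n_px=41)
        img = np.ones((41, 41))
        n_bins = 16
        prof = radial_profile(ScatterPattern(img, geom), n_bins=n_bins)
        # brute-force per-pixel binning oracle
        expected = np.zeros(n_bins)
        width = geom.max_angle_mrad / n_bins
        for i in range(41):
            for j in range(41):
                r = math.hypot(i - 20, j - 20) * geom.pixel_size_um
                ang = math.atan(r / 300.0) * 1000
                if ang <= geom.max_angle_mrad:
                    expected[min(int(ang / width), n_bins - 1)] += 1.0
        assert np.array_equal(prof.intensity, expected)

    def test_total_counts_conserved(self, rng):
        geom = _geometry(n_px=41)
        img = rng.random((41, 41))
        prof = radial_profile(ScatterPattern(img, geom), n_bins=16)
        rows = (np.arange(41) - 20)[:, None]
        cols = (np.arange(41) - 20)[None, :]
        ang = np.arctan(np.hypot(rows, cols) * geom.pixel_size_um / 300.0) * 1000
        assert prof.intensity.sum() == pytest.approx(
            img[ang <= geom.max_angle_mrad].sum(), rel=1e-12
        )

    def test_zero_image_gives_zero_profile(self):
        geom = _geometry(n_px=41)
        prof = radial_profile(ScatterPattern(np.zeros((41, 41)), geom), n_bins=8)
        assert not prof.intensity.any()


class TestDfBfRatio:
    def _profile(self, intensities, cutoff=30.0):
        n = len(intensities)
        centers = np.linspace(5, 215, n)
        return RadialProfile(centers, np.asarray(intensities, float),
                             bin_width_mrad=210 / n, bf_cutoff_mrad=cutoff)

    def test_all_inside_cutoff_is_zero(self):
        prof = self._profile([5.0] + [0.0] * 20)
        assert df_bf_ratio(prof) == 0.0

    def test_equal_split_is_unity(self):
        centers = np.array([10.0, 50.0])
        prof = RadialProfile(centers, np.array([7.0, 7.0]), 40.0, bf_cutoff_mrad=30.0)
        assert df_bf_ratio(prof) == 1.0

    def test_thirty_seventy_split(self):
        centers = np.array([10.0, 50.0])
        prof = RadialProfile(centers, np.array([70.0, 30.0]), 40.0, bf_cutoff_mrad=30.0)
        assert df_bf_ratio(prof) == pytest.approx(3.0 / 7.0)

    def test_scale_invariance(self, rng):
        vals = rng.random(21) + 0.1
        assert df_bf_ratio(self._profile(vals)) == pytest.approx(
            df_bf_ratio(self._profile(100.0 * vals)), rel=1e-12
        )

    def test_zero_bright_field_raises(self):
        prof = RadialProfile(np.array([100.0, 200.0]), np.array([1.0, 1.0]), 100.0,
                             bf_cutoff_mrad=30.0)
        with pytest.raises(ZeroDivisionError):
            df_bf_ratio(prof)


class TestMostCommonAngle:
    def test_delta_ring_peak(self):
        centers = np.linspace(5, 215, 22)
        vals = np.zeros(22)
        vals[np.argmin(np.abs(centers - 100))] = 50.0
        prof = RadialProfile(centers, vals, 10.0)
        assert most_common_angle(prof).angle_mrad == pytest.approx(100.0, abs=5.0)

    def test_unscattered_beam_peaks_below_cutoff(self):
        centers = np.linspace(5, 215, 22)
        vals = np.zeros(22)
        vals[0] = 1000.0
        prof = RadialProfile(centers, vals, 10.0)
        assert most_common_angle(prof).angle_mrad < 30.0

    def test_tie_returns_lower_angle_with_flag(self):
        centers = np.array([50.0, 150.0])
        theta = centers / 1000
        half = 0.05
        # equal *density*: intensities proportional to the annulus solid angle
        solid = np.cos(theta - half) - np.cos(theta + half)
        prof = RadialProfile(centers, solid / solid[0], 100.0)
        res = most_common_angle(prof)
        assert res.ambiguous and res.angle_mrad == pytest.approx(50.0)


@pytest.fixture(scope="module")
def table():
    grid = np.linspace(50, 1000, 12)
    return build_table(grid, n_electrons=12000, seed=1)


class TestTableAndInversion:
    def test_ratio_monotone_in_thickness(self, table):
        assert np.all(np.diff(table.df_bf_ratio) > 0)
        # a thick (~900 nm) lamella scatters far more than a thin (~200 nm) one
        assert table.df_bf_ratio[-2] > table.df_bf_ratio[2]

    def test_zero_thickness_entry_has_zero_ratio(self):
        res = mc.mc_simulate(0.0, 30.0, 500, 0)
        ratio, _se = simulated_ratio(res, 30.0)
        assert ratio == 0.0

    def test_two_seeds_agree_within_three_standard_errors(self):
        grid = np.array([200.0, 600.0])
        t1 = build_table(grid, n_electrons=8000, seed=21)
        t2 = build_table(grid, n_electrons=8000, seed=22)
        for a, b, sa, sb in zip(t1.df_bf_ratio, t2.df_bf_ratio,
                                t1.ratio_se, t2.ratio_se):
            assert abs(a - b) <= 3 * math.hypot(sa, sb)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(TableQualityError, match="n_electrons"):
            McTable(
                thickness_nm=np.array([100.0, 200.0, 300.0]),
                df_bf_ratio=np.array([1.0, 3.0, 2.0]),
                ratio_se=np.zeros(3),
                most_common_angle_mrad=np.zeros(3),
                beam_energy_keV=30.0, bf_cutoff_mrad=30.0,
                max_angle_mrad=218.0, n_electrons=10, seed=0,
            )

    def test_csv_round_trip(self, table, tmp_path):
        path = table.to_csv(tmp_path / "table.csv")
        loaded = McTable.from_csv(path)
        assert np.allclose(loaded.df_bf_ratio, table.df_bf_ratio)
        assert loaded.seed == table.seed and loaded.n_electrons == table.n_electrons

    def test_incidence_correction_is_cosine_on_path_length(self):
        # constructed table with a node at 325 nm: ratio 2 -> path 325,
        # thickness 325*cos(52) ~ 200.1 nm
        table = McTable(
            thickness_nm=np.array([100.0, 325.0, 600.0]),
            df_bf_ratio=np.array([1.0, 2.0, 3.0]),
            ratio_se=np.zeros(3),
            most_common_angle_mrad=np.array([40.0, 80.0, 120.0]),
            beam_energy_keV=30.0, bf_cutoff_mrad=30.0,
            max_angle_mrad=218.0, n_electrons=10, seed=0,
        )
        geom = _geometry(n_px=41)
        # two-pixel image engineered to a DF/BF ratio of exactly 2
        img = np.zeros((41, 41))
        img[20, 20] = 1.0  # on-axis -> bright field
        img[20, 35] = 2.0  # 15 px -> ~66 um -> ~215 mrad -> dark field
        pattern = ScatterPattern(img, geom)
        res52 = thickness_from_pattern(pattern, table, incidence_deg=52.0)
        res0 = thickness_from_pattern(pattern, table, incidence_deg=0.0)
        assert res0.d_nm == pytest.approx(325.0)
        assert res52.d_nm == pytest.approx(325.0 * math.cos(math.radians(52.0)))
        assert res52.d_nm == pytest.approx(200.1, abs=0.1)

    def test_out_of_range_ratio_raises(self, table):
        geom = _geometry(n_px=41)
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        img[20, 35] = 1000.0  # ratio far beyond the table
        with pytest.raises(OutOfRangeError):
            thickness_from_pattern(ScatterPattern(img, geom), table)

    def test_empty_line_scan_rejected(self, table):
        with pytest.raises(ValueError, match="empty"):
            thickness_line_scan([], table)


def test_bf_cutoff_from_vacuum_brackets_beam():
    geom = _geometry(n_px=101)
    img = np.zeros((101, 101))
    img[48:53, 48:53] = 100.0  # tight central beam, ~2.5 px radius
    cutoff = bf_cutoff_from_vacuum(ScatterPattern(img, geom))
    beam_edge = pixel_to_angle(3.6 * geom.pixel_size_um, geom)
    assert 0 < cutoff <= beam_edge
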