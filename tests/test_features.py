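"""Feature-extraction oracles: closed-form Gaussian geometry, independent
moment arithmetic, and structural invariants of the 14-descriptor vector."""

import math

import numpy as np
import pytest

from voltgrade import (
    FEATURE_NAMES,
    Voltammogram,
    extract_features,
    read_voltammogram,
    write_voltammogram,
)
from voltgrade.features import (
    VoltammogramError,
    charge,
    derivative_extrema,
    distribution_moments,
    peak_descriptors,
)

from conftest import make_gaussian_trace

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548…


def grid_step(vg):
    return abs(vg.potential[1] - vg.potential[0])


class TestVoltammogramValidation:
    def test_short_trace_rejected_with_row_count(self):
        with pytest.raises(VoltammogramError, match="fewer than 16"):
            Voltammogram(np.linspace(0, 1, 3), np.zeros(3), scan_rate=0.05)

    def test_non_monotone_potential_rejected(self):
        pot = np.linspace(-0.05, -0.45, 32)
        pot[10] = pot[8]  # direction reversal
        with pytest.raises(VoltammogramError, match="monotone"):
            Voltammogram(pot, np.zeros(32), scan_rate=0.05)

    def test_length_mismatch_and_bad_scan_rate(self):
        pot = np.linspace(0, 1, 20)
        with pytest.raises(VoltammogramError):
            Voltammogram(pot, np.zeros(19), scan_rate=0.05)
        with pytest.raises(VoltammogramError):
            Voltammogram(pot, np.zeros(20), scan_rate=0.0)


class TestIO:
    def test_round_trip_preserves_values(self, tmp_path, gaussian_trace):
        path = tmp_path / "trace.csv"
        write_voltammogram(gaussian_trace, path)
        back = read_voltammogram(path)
        np.testing.assert_array_equal(back.potential, gaussian_trace.potential)
        np.testing.assert_array_equal(back.current, gaussian_trace.current)
        assert back.scan_rate == gaussian_trace.scan_rate

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("potential_V,amps\n" + "\n".join(f"{i},0" for i in range(20)))
        with pytest.raises(VoltammogramError, match="current_uA"):
            read_voltammogram(path, scan_rate=0.05)

    def test_too_few_rows_is_a_parse_error(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("potential_V,current_uA\n0.0,0.0\n0.1,1.0\n0.2,0.0\n")
        with pytest.raises(VoltammogramError, match="fewer than 16"):
            read_voltammogram(path, scan_rate=0.05)


class TestCharge:
    def test_constant_current_rectangle(self):
        # 0.4 V sweep at 0.05 V/s = 8 s; 3 µA * 8 s = 24 µC
        vg = Voltammogram(np.linspace(-0.05, -0.45, 64), np.full(64, 3.0), 0.05)
        assert charge(vg) == pytest.approx(3.0 * 8.0, rel=1e-12)

    def test_zero_current_zero_charge(self):
        vg = Voltammogram(np.linspace(0, 1, 64), np.zeros(64), 0.05)
        assert charge(vg) == 0.0

    def test_gaussian_charge_matches_analytic_integral(self):
        # Q = A·σ·sqrt(2π)/v for a wide window, zero baseline
        vg = make_gaussian_trace(amplitude=2.0, sd=0.04, n_points=1024)
        expected = 2.0 * 0.04 * math.sqrt(2 * math.pi) / 0.05
        assert charge(vg) == pytest.approx(expected, rel=0.005)

    def test_gaussian_charge_matches_dense_grid_oracle(self):
        vg = make_gaussian_trace(n_points=512)
        dense = make_gaussian_trace(n_points=5120)
        assert charge(vg) == pytest.approx(charge(dense), rel=0.005)


class TestPeakDescriptors:
    def test_gaussian_fwhm_and_half_peak_potential(self):
        sd = 0.04
        vg = make_gaussian_trace(sd=sd, n_points=4096)
        d = peak_descriptors(vg)
        step = grid_step(vg)
        assert d["peak_width_half_height"] == pytest.approx(
            FWHM_FACTOR * sd, abs=2 * step
        )
        # flank toward sweep start (-0.05 side, i.e. higher potential)
        expected_hpp = -0.25 + math.sqrt(2 * math.log(2)) * sd
        assert d["half_peak_potential"] == pytest.approx(expected_hpp, abs=2 * step)
        assert not d["degenerate"]

    def test_peak_located_at_grid_point_nearest_center(self):
        vg = make_gaussian_trace(n_points=256)
        d = peak_descriptors(vg)
        nearest = vg.potential[np.argmin(np.abs(vg.potential - (-0.25)))]
        assert d["positive_peak_potential"] == pytest.approx(nearest, abs=1e-12)

    def test_negated_trace_swaps_peaks(self, gaussian_trace):
        d = peak_descriptors(gaussian_trace)
        flipped = Voltammogram(
            gaussian_trace.potential, -gaussian_trace.current,
            gaussian_trace.scan_rate,
        )
        df = peak_descriptors(flipped)
        assert df["positive_peak_current"] == -d["negative_peak_current"]
        assert df["negative_peak_current"] == -d["positive_peak_current"]
        assert df["positive_peak_potential"] == d["negative_peak_potential"]
        assert df["negative_peak_potential"] == d["positive_peak_potential"]

    def test_constant_trace_degenerate(self):
        vg = Voltammogram(np.linspace(0, 1, 32), np.full(32, 1.5), 0.05)
        d = peak_descriptors(vg)
        assert d["degenerate"]
        assert d["peak_width_half_height"] == 0.0
        assert d["half_peak_potential"] == 0.0


class TestMoments:
    def test_constant_trace(self):
        vg = Voltammogram(np.linspace(0, 1, 32), np.full(32, 2.5), 0.05)
        m = distribution_moments(vg)
        assert m["mean_current"] == m["median_current"] == 2.5
        assert m["std_current"] == 0.0
        assert m["degenerate"]

    def test_moments_match_textbook_formulas(self):
        rng = np.random.default_rng(42)
        cur = rng.normal(1.0, 2.0, size=100)
        vg = Voltammogram(np.linspace(0, 1, 100), cur, 0.05)
        m = distribution_moments(vg)
        # independent textbook recomputation
        n = cur.size
        mu = cur.sum() / n
        dev = cur - mu
        var_n = (dev**2).sum() / n
        skew = ((dev**3).sum() / n) / var_n**1.5
        kurt = ((dev**4).sum() / n) / var_n**2 - 3.0
        std = math.sqrt((dev**2).sum() / (n - 1))
        assert m["mean_current"] == pytest.approx(mu, rel=1e-10)
        assert m["median_current"] == pytest.approx(np.median(cur), rel=1e-10)
        assert m["std_current"] == pytest.approx(std, rel=1e-10)
        assert m["skewness"] == pytest.approx(skew, rel=1e-10)
        assert m["kurtosis"] == pytest.approx(kurt, rel=1e-10)

    def test_symmetric_trace_zero_skew(self):
        # mirror every value about the mean → exactly symmetric sample set
        rng = np.random.default_rng(7)
        v = rng.normal(0.5, 1.0, size=64)
        cur = np.concatenate([v, 2 * v.mean() - v])
        vg = Voltammogram(np.linspace(0, 1, cur.size), cur, 0.05)
        assert distribution_moments(vg)["skewness"] == pytest.approx(0.0, abs=1e-12)


class TestDerivatives:
    def test_linear_ramp_exact(self):
        pot = np.linspace(-0.05, -0.45, 64)
        vg = Voltammogram(pot, 3.5 * pot + 0.2, 0.05)
        d = derivative_extrema(vg)
        assert d["peak_derivative"] == pytest.approx(3.5, abs=1e-9)
        assert d["peak_second_derivative"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_trace_zero_derivatives(self):
        vg = Voltammogram(np.linspace(0, 1, 32), np.full(32, 1.0), 0.05)
        d = derivative_extrema(vg)
        assert d["peak_derivative"] == pytest.approx(0.0, abs=1e-12)
        assert d["peak_second_derivative"] == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_derivative_extremum_analytic(self):
        amplitude, sd = 2.0, 0.04
        vg = make_gaussian_trace(amplitude=amplitude, sd=sd, n_points=4096)
        d = derivative_extrema(vg)
        expected = amplitude * math.exp(-0.5) / sd
        assert abs(d["peak_derivative"]) == pytest.approx(expected, rel=0.01)


class TestExtractFeatures:
    def test_vector_has_14_finite_fields(self, gaussian_trace):
        vec = extract_features(gaussian_trace)
        values = vec.as_array()
        assert values.shape == (14,)
        assert np.isfinite(values).all()
        assert list(vec.as_dict()) == list(FEATURE_NAMES)
        assert vec.positive_peak_current >= vec.negative_peak_current

    def test_pure_function_bit_identical(self, gaussian_trace):
        a = extract_features(gaussian_trace).as_array()
        b = extract_features(gaussian_trace).as_array()
        np.testing.assert_array_equal(a, b)

    def test_sign_flip_symmetry(self, gaussian_trace):
        vec = extract_features(gaussian_trace)
        flipped = extract_features(
            Voltammogram(gaussian_trace.potential, -gaussian_trace.current,
                         gaussian_trace.scan_rate)
        )
        assert flipped.positive_peak_current == -vec.negative_peak_current
        assert flipped.mean_current == -vec.mean_current
        assert flipped.std_current == pytest.approx(vec.std_current, rel=1e-12)

    @pytest.mark.parametrize("delta", [0.1, -0.3])
    def test_potential_shift_equivariance(self, gaussian_trace, delta):
        shifted = Voltammogram(
            gaussian_trace.potential + delta, gaussian_trace.current,
            gaussian_trace.scan_rate,
        )
        a, b = extract_features(gaussian_trace), extract_features(shifted)
        for name in ("positive_peak_potential", "negative_peak_potential",
                     "half_peak_potential"):
            assert getattr(b, name) == pytest.approx(getattr(a, name) + delta,
                                                     abs=1e-9)
        for name in ("charge_Q", "mean_current", "std_current", "skewness",
                     "kurtosis", "peak_width_half_height",
                     "positive_peak_current", "negative_peak_current"):
            assert getattr(b, name) == pytest.approx(getattr(a, name),
                                                     rel=1e-9, abs=1e-12)

    def test_grid_refinement_halves_errors(self):
        # charge, FWHM and derivative errors vs analytic values must shrink
        # at least ~linearly when the grid is doubled (factor-3 slack).
        amplitude, sd = 2.0, 0.04
        q_exact = amplitude * sd * math.sqrt(2 * math.pi) / 0.05
        w_exact = FWHM_FACTOR * sd
        d_exact = amplitude * math.exp(-0.5) / sd
        errs = {}
        for n in (128, 256):
            vg = make_gaussian_trace(amplitude=amplitude, sd=sd, n_points=n)
            vec = extract_features(vg)
            errs[n] = (
                abs(vec.charge_Q - q_exact),
                abs(vec.peak_width_half_height - w_exact),
                abs(abs(vec.peak_derivative) - d_exact),
            )
        for coarse, fine in zip(errs[128], errs[256]):
            assert fine <= coarse / 2 * 3
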