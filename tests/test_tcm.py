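"""Tube-current modulation: longitudinal/angular equations, organ-based
sector reduction, weight normalization and scheme table round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcmdose.tcm import (
    ATCMParams,
    AttenuationProfile,
    TCMScheme,
    Topogram,
    angular_modulation,
    apply_obtcm,
    compose_atcm,
    longitudinal_atcm,
    normalize_weights,
    read_tcm_table,
    write_tcm_table,
)


def topo_from_dims(ap, lat):
    ap = np.asarray(ap, float)
    return Topogram(np.arange(len(ap), dtype=float), ap, np.asarray(lat, float))


class TestLongitudinal:
    def test_reference_attenuation_anchor(self):
        # at A_max = A_ref the exponent is irrelevant: mA = QRM*pitch/t
        p = ATCMParams()
        d_ref = np.log(p.a_ref) / p.mu_water
        ma = longitudinal_atcm(topo_from_dims([d_ref], [d_ref]), p)
        assert ma[0] == pytest.approx(140.0 * 0.6 / 0.5, rel=1e-12)  # 168 mA

    def test_lat_dominates_a_max(self):
        p = ATCMParams()
        _, a_max = longitudinal_atcm(topo_from_dims([20.0], [30.0]), p, return_a_max=True)
        assert a_max[0] == pytest.approx(np.exp(6.0), rel=1e-12)

    def test_overweight_strength_exponent(self):
        # A_max = 4*A_ref with b=0.33: mA = 168 * 4^0.33
        p = ATCMParams(ma_max=1e9)
        d = np.log(4.0 * p.a_ref) / p.mu_water
        ma = longitudinal_atcm(topo_from_dims([d], [d]), p)
        assert ma[0] == pytest.approx(168.0 * 4.0**0.33, rel=1e-9)
        assert ma[0] == pytest.approx(265.45, abs=0.05)

    def test_underweight_uses_half_exponent(self):
        p = ATCMParams(ma_min=0.0)
        d = np.log(0.25 * p.a_ref) / p.mu_water
        ma = longitudinal_atcm(topo_from_dims([d], [d]), p)
        assert ma[0] == pytest.approx(168.0 * 0.25**0.5, rel=1e-9)

    def test_monotone_in_patient_size(self):
        p = ATCMParams()
        sizes = np.linspace(15, 40, 30)
        ma = longitudinal_atcm(topo_from_dims(sizes, sizes), p)
        assert np.all(np.diff(ma) >= 0)


class TestAngular:
    def test_lag_at_max_gives_unity(self):
        prof = AttenuationProfile(np.array([400.0]), np.array([100.0]), np.array([400.0]))
        assert angular_modulation(prof, ATCMParams())[0] == pytest.approx(1.0)

    def test_lag_at_min_gives_full_depth(self):
        p = ATCMParams(mu_limit=0.9)
        prof = AttenuationProfile(np.array([400.0]), np.array([100.0]), np.array([100.0]))
        assert angular_modulation(prof, p)[0] == pytest.approx(1.0 - 0.9)

    def test_intermediate_value_direct_evaluation(self):
        p = ATCMParams(q=0.75, mu_limit=0.9)
        prof = AttenuationProfile(np.array([400.0]), np.array([100.0]), np.array([200.0]))
        expected = 1.0 - 0.9 * (400**0.75 - 200**0.75) / (400**0.75 - 100**0.75)
        m = angular_modulation(prof, p)[0]
        assert m == pytest.approx(expected, rel=1e-12)
        assert m == pytest.approx(0.43559, abs=1e-5)

    def test_degenerate_window_defaults_to_unity(self):
        prof = AttenuationProfile(np.array([100.0]), np.array([100.0]), np.array([100.0]))
        assert angular_modulation(prof, ATCMParams())[0] == 1.0

    @given(
        a_lag_frac=st.floats(0.0, 1.0),
        mu=st.floats(0.0, 1.0),
        q=st.floats(0.5, 1.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_floor_bounded(self, a_lag_frac, mu, q):
        a_min, a_max = 50.0, 400.0
        a_lag = a_min + a_lag_frac * (a_max - a_min)
        p = ATCMParams(mu_limit=mu, q=q)
        prof = AttenuationProfile(np.array([a_max]), np.array([a_min]), np.array([a_lag]))
        m = angular_modulation(prof, p)[0]
        assert 1.0 - mu - 1e-12 <= m <= 1.0 + 1e-12


class TestCompose:
    def test_circular_phantom_flat_angular_profile(self):
        # constant attenuation => m = 1 => no angular dip anywhere
        d = np.full(12, 24.0)
        p = ATCMParams()
        scheme = compose_atcm(Topogram(np.arange(12.0), d, d), p)
        ma = longitudinal_atcm(Topogram(np.arange(12.0), d, d), p)
        assert np.allclose(scheme.current, ma[:, None], rtol=1e-12)

    def test_lateral_angle_reaches_longitudinal_value(self):
        rng = np.random.default_rng(0)
        ap = 20.0 + 4.0 * rng.random(15)
        lat = ap + 5.0
        topo = Topogram(np.arange(15.0), ap, lat)
        p = ATCMParams()
        scheme = compose_atcm(topo, p)
        ma = longitudinal_atcm(topo, p)
        # per-position max over angle equals mA(i), attained laterally
        assert np.allclose(scheme.current.max(axis=1), ma, rtol=1e-12)
        i90 = np.argmin(np.abs(scheme.angle_bins - np.pi / 2))
        assert np.allclose(scheme.current[:, i90], ma, rtol=1e-12)

    def test_monotone_in_local_attenuation(self):
        base = np.full(10, 24.0)
        bigger = base.copy()
        bigger[5] += 2.0
        p = ATCMParams()
        s0 = compose_atcm(Topogram(np.arange(10.0), base, base), p)
        s1 = compose_atcm(Topogram(np.arange(10.0), bigger, bigger), p)
        assert s1.current[5].max() >= s0.current[5].max()


class TestObtcm:
    def test_no_reduction_is_identity(self, flat_scheme):
        out = apply_obtcm(flat_scheme, 1.0, 120, compensate=True)
        assert np.allclose(out.current, flat_scheme.current, atol=1e-12)

    def test_flat_scheme_arithmetic(self, flat_scheme):
        out = apply_obtcm(flat_scheme, 0.25, 120, compensate=True)
        i_ant = 0  # theta = 0
        i_post = len(out.angle_bins) // 2
        assert out.current[0, i_ant] == pytest.approx(25.0, rel=1e-12)
        assert out.current[0, i_post] == pytest.approx(137.5, rel=1e-12)
        assert out.rotation_mean[0] == pytest.approx(100.0, rel=1e-12)

    def test_uncompensated_mean(self, flat_scheme):
        out = apply_obtcm(flat_scheme, 0.25, 120, compensate=False)
        assert out.rotation_mean[0] == pytest.approx(
            25.0 / 3.0 + 2.0 * 100.0 / 3.0, rel=1e-12
        )

    @given(r=st.floats(0.05, 1.0), sector=st.floats(30.0, 300.0))
    @settings(deadline=None, max_examples=40)
    def test_compensation_preserves_rotation_mean(self, r, sector):
        theta = np.arange(36) * 2.0 * np.pi / 36.0
        cur = 100.0 * (0.4 + 0.6 * np.sin(theta) ** 2)  # angularly modulated base
        base = TCMScheme(np.arange(3.0), theta, np.tile(cur, (3, 1)), "file")
        out = apply_obtcm(base, r, sector, compensate=True)
        assert np.allclose(out.rotation_mean, base.rotation_mean, rtol=1e-12)

    def test_invalid_sector_rejected(self, flat_scheme):
        with pytest.raises(ValueError):
            apply_obtcm(flat_scheme, 0.25, 0.0)
        with pytest.raises(ValueError):
            apply_obtcm(flat_scheme, 0.25, 360.0)


class TestWeights:
    def test_constant_scheme_all_ones(self, flat_scheme):
        assert np.all(normalize_weights(flat_scheme) == 1.0)

    def test_peak_cell_is_exactly_one_and_round_trips(self, flat_scheme):
        cur = flat_scheme.current.copy()
        cur[3, 7] = 250.0
        s = TCMScheme(flat_scheme.table_positions, flat_scheme.angle_bins, cur, "file")
        w = normalize_weights(s)
        assert w[3, 7] == 1.0
        assert np.array_equal(w * 250.0, s.current)

    def test_all_zero_rejected(self, flat_scheme):
        s = TCMScheme(
            flat_scheme.table_positions,
            flat_scheme.angle_bins,
            np.zeros_like(flat_scheme.current),
            "file",
        )
        with pytest.raises(ValueError):
            normalize_weights(s)


class TestTableIO:
    def test_round_trip(self, flat_scheme, tmp_path):
        cur = flat_scheme.current * np.random.default_rng(1).random(flat_scheme.current.shape)
        s = TCMScheme(flat_scheme.table_positions, flat_scheme.angle_bins, cur, "file")
        path = tmp_path / "scheme.csv"
        write_tcm_table(s, path)
        back = read_tcm_table(path)
        assert np.allclose(back.current, s.current, rtol=1e-12)
        assert np.allclose(back.table_positions, s.table_positions)
        assert np.allclose(back.angle_bins, s.angle_bins, atol=1e-12)

    def test_degrees_converted_to_radian_bins(self, tmp_path):
        import pandas as pd

        rows = [
            {"table_position_cm": z, "angle_deg": a, "current_mA": 100.0}
            for z in range(3)
            for a in range(0, 360, 10)
        ]
        path = tmp_path / "deg.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        s = read_tcm_table(path)
        assert len(s.angle_bins) == 36
        assert s.angle_bins.max() < 2 * np.pi

    def test_negative_current_names_row(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"table_position_cm": [0, 0], "angle_deg": [0, 180], "current_mA": [100, -5]}
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_tcm_table(path)

    def test_missing_column_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "cols.csv"
        pd.DataFrame({"table_position_cm": [0], "current_mA": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="angle_deg"):
            read_tcm_table(path)
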