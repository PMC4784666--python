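"""CC_ano, the anomalous difference Fourier, S_ano and the closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sadsignal as ss
from sadsignal.errors import EmptyDataError, InvalidParameterError, UndefinedMetricError


class TestObservedDifferences:
    def test_equal_amplitudes_give_zero(self, default_dataset):
        df = default_dataset.reflections.copy()
        df["Fminus"] = df["Fplus"]
        obs = ss.observed_anomalous_differences(df)
        assert (obs["delta"] == 0).all()

    def test_incomplete_pairs_excluded(self, default_dataset):
        df = default_dataset.reflections.copy()
        df.loc[df.index[:10], "Fminus"] = np.nan
        obs = ss.observed_anomalous_differences(df)
        n_acentric = int((~df["centric"]).sum())
        assert len(obs) == n_acentric - int((~df["centric"][:10]).sum())

    def test_all_excluded_raises(self, default_dataset):
        df = default_dataset.reflections.copy()
        df["Fplus"] = np.nan
        with pytest.raises(EmptyDataError):
            ss.observed_anomalous_differences(df)


class TestCorrelation:
    def test_identity_and_scale_invariance(self, rng):
        ideal = rng.normal(size=1000)
        assert ss.useful_anomalous_correlation(ideal, ideal) == pytest.approx(1.0)
        assert ss.useful_anomalous_correlation(2.5 * ideal, ideal) == pytest.approx(1.0)

    def test_noise_at_variance_ratio_three(self, rng):
        """corr(x + eps, x) with var(eps) = 3 var(x) is 1/sqrt(1+3) = 0.5."""
        ideal = rng.normal(size=5000)
        noisy = ideal + rng.normal(scale=np.sqrt(3.0), size=5000)
        assert ss.useful_anomalous_correlation(noisy, ideal) == pytest.approx(0.5, abs=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ss.useful_anomalous_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedMetricError):
            ss.useful_anomalous_correlation([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "vo, ve, vu, e2, cc",
        [(0, 0, 2.0, 0.0, 1.0), (1.5, 1.5, 1.0, 3.0, 0.5), (0.4, 0.6, 1.0, 1.0, 2**-0.5)],
    )
    def test_error_model_closed_form(self, vo, ve, vu, e2, cc):
        got_e2, got_cc = ss.error_model_stats(vo, ve, vu)
        assert got_e2 == pytest.approx(e2)
        assert got_cc == pytest.approx(cc)

    def test_error_model_undefined_for_zero_useful_variance(self):
        with pytest.raises(UndefinedMetricError):
            ss.error_model_stats(1.0, 1.0, 0.0)


def random_coefficients(rng, n=400, hmax=10):
    """Random unique Friedel representatives with coefficients."""
    seen = set()
    while len(seen) < n:
        h = tuple(rng.integers(-hmax, hmax + 1, size=3))
        if h == (0, 0, 0) or h in seen or tuple(-np.array(h)) in seen:
            continue
        seen.add(h)
    hkl = np.array(sorted(seen))
    delta = rng.normal(size=n)
    phi = rng.uniform(-np.pi, np.pi, size=n)
    return hkl, delta, phi


class TestFourier:
    def test_zero_coefficients_zero_map(self, rng):
        cell = ss.UnitCell(20, 20, 20)
        hkl, delta, phi = random_coefficients(rng)
        rho = ss.adf_at_points(np.zeros_like(delta), phi, hkl, cell, [(0.1, 0.2, 0.3)])
        assert np.all(rho == 0)
        assert ss.map_rms(np.zeros_like(delta), cell) == 0

    def test_full_sphere_sum_is_real(self, rng):
        """Explicit conjugate-symmetric summation: imaginary part vanishes."""
        cell = ss.UnitCell(20, 20, 20)
        hkl, delta, phi = random_coefficients(rng)
        x = np.array([0.12, 0.34, 0.56])
        coef = delta * np.exp(1j * (phi - np.pi / 2))
        full = np.concatenate([coef, np.conj(coef)])
        hkl_full = np.vstack([hkl, -hkl])
        rho_c = np.sum(full * np.exp(-2j * np.pi * (hkl_full @ x))) / cell.volume
        assert abs(rho_c.imag) < 1e-8 * max(abs(rho_c), 1e-30)
        mine = ss.adf_at_points(delta, phi, hkl, cell, x[None, :])[0]
        assert mine == pytest.approx(rho_c.real, rel=1e-10)

    def test_parseval_matches_grid_synthesis(self, rng):
        cell = ss.UnitCell(25, 25, 25)
        for _ in range(3):
            hkl, delta, phi = random_coefficients(rng, n=300, hmax=12)
            grid = ss.adf_grid(delta, phi, hkl, cell, n=64)
            assert ss.map_rms(delta, cell) == pytest.approx(
                np.sqrt(np.mean(grid**2)), rel=0.02
            )

    def test_grid_agrees_with_direct_summation(self, rng):
        cell = ss.UnitCell(25, 25, 25)
        hkl, delta, phi = random_coefficients(rng, n=100, hmax=6)
        n = 32
        grid = ss.adf_grid(delta, phi, hkl, cell, n=n)
        pts = np.array([[0, 0, 0], [1, 2, 3], [16, 8, 24]]) / n
        direct = ss.adf_at_points(delta, phi, hkl, cell, pts)
        for p, v in zip(pts, direct):
            idx = tuple((p * n).astype(int))
            assert grid[idx] == pytest.approx(v, rel=1e-9, abs=1e-12)

    def test_doubling_coefficients_doubles_rms(self, rng):
        cell = ss.UnitCell(20, 20, 20)
        _, delta, _ = random_coefficients(rng)
        assert ss.map_rms(2 * delta, cell) == pytest.approx(2 * ss.map_rms(delta, cell))


class TestMeasuredSignal:
    def test_single_site_peak_matches_expected_height(self):
        """Noise-free peak at the site equals N <f_hB> / V (full sphere)."""
        cfg = ss.SimulationConfig(
            cell=(40, 40, 40, 90, 90, 90), d_min=2.5, n_ordinary_atoms=2000,
            n_substructure_sites=1, n_minor_sites=0, noise_sigma=0.0,
            b_range_substructure=(20, 20), seed=13,
        )
        ds = ss.simulate(cfg)
        ideal = ds.ideal
        site = np.array([ds.model.substructure_atoms[0].frac])
        rho = ss.adf_at_points(
            ideal.delta_ano, ideal.phi_c, ideal.reflections.hkl, ds.model.cell, site
        )[0]
        n_sphere = 2 * len(ideal.delta_ano)
        expected = n_sphere * np.mean(ss.f_hB(3.8, 20.0, ideal.reflections.s)) / ds.model.cell.volume
        assert rho == pytest.approx(expected, rel=0.02)

    def test_pure_noise_map_has_no_signal(self, rng):
        cell = ss.UnitCell(20, 20, 20)
        hkl, delta, phi = random_coefficients(rng, n=2000, hmax=9)
        sites = rng.random((5, 3))
        sample = ss.measured_anomalous_signal(delta, phi, hkl, cell, sites)
        # site values of a random map are ~N(0, rms^2); their mean over 5
        # sites divided by rms stays within 3/sqrt(5)
        assert abs(sample.s_ano) < 3.0 / np.sqrt(5)

    def test_zero_map_signal_undefined(self):
        sample = ss.MapSample(site_values=np.zeros(2), rms=0.0)
        with pytest.raises(UndefinedMetricError):
            sample.s_ano


class TestClosedForms:
    @pytest.mark.parametrize(
        "cc, n_refl, n_sites, f_b, expected",
        [
            (1.0, 10000, 1, 1.0, 100.0),
            (0.5, 10000, 4, 1.0, 25.0),
            (0.3, 40000, 10, 1.25, 0.3 * np.sqrt(4000.0) / 1.25),
        ],
    )
    def test_predicted_signal_arithmetic(self, cc, n_refl, n_sites, f_b, expected):
        assert ss.predicted_anomalous_signal(cc, n_refl, n_sites, f_b) == pytest.approx(expected)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidParameterError):
            ss.predicted_anomalous_signal(1.0, 100, 0, 1.0)
        with pytest.raises(InvalidParameterError):
            ss.predicted_anomalous_signal(1.5, 100, 1, 1.0)
        with pytest.raises(InvalidParameterError):
            ss.predicted_anomalous_signal(1.0, 100, 1, 0.5)

    @pytest.mark.parametrize(
        "n_refl, n_sites, e2, f_b, expected",
        [(16000, 4, 12.0, 1.0, np.sqrt(1000.0)), (5000, 2, 0.0, 1.1, np.sqrt(2500.0) / 1.1)],
    )
    def test_sites_scaling_arithmetic(self, n_refl, n_sites, e2, f_b, expected):
        assert ss.sites_scaling_signal(n_refl, n_sites, e2, f_b) == pytest.approx(expected)

    def test_sites_scaling_consistent_with_cc_route(self):
        """E^2 = e^2/n_sites makes the two expressions identical."""
        n_refl, n_sites, e2, f_b = 20000, 5, 7.5, 1.2
        cc = 1.0 / np.sqrt(1.0 + e2 / n_sites)
        assert ss.sites_scaling_signal(n_refl, n_sites, e2, f_b) == pytest.approx(
            ss.predicted_anomalous_signal(cc, n_refl, n_sites, f_b), rel=1e-12
        )

    def test_signal_strictly_decreasing_in_sites(self):
        vals = [ss.sites_scaling_signal(16000, n, 12.0, 1.0) for n in (1, 2, 4, 8, 16)]
        assert np.all(np.diff(vals) < 0)

    @given(
        cc=st.floats(0.0, 1.0),
        n_refl=st.integers(1, 10**6),
        n_sites=st.floats(0.5, 100),
        f_b=st.floats(1.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_signal_ordering(self, cc, n_refl, n_sites, f_b):
        """predicted <= ideal <= maximum for all valid parameters."""
        pred = ss.predicted_anomalous_signal(cc, n_refl, n_sites, f_b)
        ideal = ss.ideal_anomalous_signal(n_refl, n_sites, f_b)
        if n_sites >= 1:
            assert pred <= ideal + 1e-12
            assert ideal <= ss.max_anomalous_signal(n_refl) + 1e-12


class TestEstimateAndScan:
    def test_estimate_on_noiseless_data(self, noiseless_dataset):
        ds = noiseless_dataset
        rep = ss.estimate_signal(ds.reflections, ds.model, ss.SolvabilityCalibration())
        assert rep.cc_ano == pytest.approx(1.0, abs=1e-6)
        assert rep.s_ano_pred == pytest.approx(rep.s_ano_ideal, rel=1e-6)
        assert rep.s_ano_measured == pytest.approx(rep.s_ano_pred, rel=0.08)
        assert rep.s_ano_pred <= rep.s_ano_ideal <= rep.s_ano_max
        assert 0 <= rep.solve_probability <= 1

    def test_zero_difference_shell_leaves_signal_unchanged(self, noiseless_dataset):
        ds = noiseless_dataset
        base = ss.estimate_signal(ds.reflections, ds.model)
        extended = _with_extra_shell(ds, zero_delta=True)
        ext = ss.estimate_signal(extended, ds.model)
        assert ext.s_ano_measured == pytest.approx(base.s_ano_measured, rel=1e-12)

    def test_random_difference_shell_decreases_signal(self, noiseless_dataset):
        ds = noiseless_dataset
        base = ss.estimate_signal(ds.reflections, ds.model)
        extended = _with_extra_shell(ds, zero_delta=False)
        ext = ss.estimate_signal(extended, ds.model)
        assert ext.s_ano_measured < base.s_ano_measured

    def test_truncation_scan_table(self, noiseless_dataset):
        ds = noiseless_dataset
        table = ss.truncation_scan(ds.reflections, ds.model, [3.0, 3.5, 4.5])
        assert list(table["d_min"]) == [4.5, 3.5, 3.0]
        assert list(table["n_refl"]) == sorted(table["n_refl"])
        assert (table["f_b"] >= 1).all()

    def test_truncation_beyond_data_raises(self, noiseless_dataset):
        ds = noiseless_dataset
        with pytest.raises(EmptyDataError):
            ss.truncation_scan(ds.reflections, ds.model, [50.0])


def _with_extra_shell(ds, zero_delta):
    """Append a 2.8-3.0 A shell of synthetic observations to 3.0 A data."""
    model = ds.model
    refl = ss.enumerate_unique_reflections(model.cell, model.sym, 2.8)
    shell = refl.select(refl.d < ds.reflections["d"].min())
    rng = np.random.default_rng(99)
    mean_f = float(np.mean(0.5 * (ds.reflections["Fplus"] + ds.reflections["Fminus"])))
    base = np.full(len(shell), mean_f)
    if zero_delta:
        fp = fm = base
    else:
        typical = float(np.sqrt(np.mean(ds.ideal.delta_ano**2)))
        delta = rng.normal(scale=typical, size=len(shell))
        fp, fm = base + delta / 2, base - delta / 2
    extra = ds.reflections.iloc[:0].copy()
    extra = extra.reindex(range(len(shell)))
    extra["h"], extra["k"], extra["l"] = shell.hkl.T
    extra["d"] = shell.d
    extra["centric"] = shell.centric
    extra["Fplus"], extra["Fminus"] = fp, fm
    extra["sigFplus"] = extra["sigFminus"] = 0.0
    out = pd.concat([ds.reflections, extra], ignore_index=True)
    return out.astype(ds.reflections.dtypes.to_dict())
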