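"""Survival yield, center-of-mass energy, E50 fitting, spectrum comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalloform import (
    SYFitError,
    Spectrum,
    e_com,
    fit_sy,
    shared_ion_analysis,
    simulate_sy_series,
    spectral_correlation,
    survival_yield,
    union_peak_table,
)


def _spec(mz, inten, voltage=None, label="s"):
    meta = {"label": label}
    if voltage is not None:
        meta["collision_voltage"] = voltage
    return Spectrum(np.asarray(mz, float), np.asarray(inten, float), "centroid", meta)


class TestEcom:
    def test_plug_in_arithmetic(self):
        # 5+, 40 V, 7200 Da ion, argon
        assert e_com(40, 5, 7200.0) == pytest.approx(1.103, abs=2e-3)

    def test_zero_voltage(self):
        assert e_com(0, 5, 7200.0) == 0.0

    def test_heavy_gas_limit(self):
        assert e_com(40, 5, 7200.0, gas_mass=1e12) == pytest.approx(200.0, rel=1e-6)

    @given(v=st.floats(0.1, 100), z=st.integers(1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_in_voltage_and_charge(self, v, z):
        base = e_com(v, z, 7200.0)
        assert e_com(2 * v, z, 7200.0) == pytest.approx(2 * base, rel=1e-9)
        assert e_com(v, 1, 7200.0) * z == pytest.approx(base, rel=1e-9)


class TestSurvivalYield:
    def test_all_intensity_in_precursor_window(self):
        curve = survival_yield(
            [_spec([1486.0], [100.0], voltage=10.0)], (1480, 1490), 5, 7200.0
        )
        assert curve.sy[0] == 1.0

    def test_no_intensity_in_window(self):
        curve = survival_yield(
            [_spec([700.0], [100.0], voltage=10.0)], (1480, 1490), 5, 7200.0
        )
        assert curve.sy[0] == 0.0

    def test_three_to_one_split(self):
        curve = survival_yield(
            [_spec([700.0, 1486.0], [25.0, 75.0], voltage=10.0)],
            (1480, 1490),
            5,
            7200.0,
        )
        assert curve.sy[0] == pytest.approx(0.75)

    def test_scale_invariance(self):
        a = survival_yield(
            [_spec([700.0, 1486.0], [30.0, 70.0], voltage=v) for v in (10, 20)],
            (1480, 1490), 5, 7200.0,
        )
        b = survival_yield(
            [_spec([700.0, 1486.0], [3000.0, 7000.0], voltage=v) for v in (10, 20)],
            (1480, 1490), 5, 7200.0,
        )
        assert np.allclose(a.sy, b.sy)

    def test_zero_total_point_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            curve = survival_yield(
                [
                    _spec([700.0], [0.0], voltage=10.0),
                    _spec([1486.0], [5.0], voltage=20.0),
                ],
                (1480, 1490), 5, 7200.0,
            )
        assert len(curve.sy) == 1

    def test_ecom_increases_with_voltage(self):
        spectra, _ = simulate_sy_series(0.8, 0.05, [10, 20, 30, 40], 5, 7200.0, sigma=0.0)
        curve = survival_yield(spectra, (1440.5, 1442.5), 5, 7200.0)
        assert np.all(np.diff(curve.e_com) > 0)


class TestFitSY:
    def test_noiseless_sigmoid_recovered_exactly(self):
        voltages = np.linspace(10, 70, 10)
        spectra, _ = simulate_sy_series(0.80, 0.05, voltages, 5, 7200.0, sigma=0.0)
        curve = survival_yield(spectra, (1440.5, 1442.5), 5, 7200.0)
        fit = fit_sy(curve)
        assert fit.e50 == pytest.approx(0.80, abs=1e-6)
        assert fit.slope == pytest.approx(0.05, abs=1e-6)
        assert not fit.extrapolated

    def test_noisy_recovery_close(self):
        spectra, _ = simulate_sy_series(
            0.80, 0.05, np.linspace(10, 70, 12), 5, 7200.0, sigma=0.02, seed=21
        )
        curve = survival_yield(spectra, (1440.5, 1442.5), 5, 7200.0)
        assert fit_sy(curve).e50 == pytest.approx(0.80, abs=0.02)

    def test_flat_curve_refused(self):
        spectra = [_spec([700.0, 1486.0], [50.0, 50.0], voltage=v) for v in (10, 20, 30, 40, 50)]
        curve = survival_yield(spectra, (1480, 1490), 5, 7200.0)
        with pytest.raises(SYFitError, match="no SY decline"):
            fit_sy(curve)

    def test_too_few_points_refused(self):
        spectra, _ = simulate_sy_series(0.8, 0.05, [40.0], 5, 7200.0)
        curve = survival_yield(spectra, (1440.5, 1442.5), 5, 7200.0)
        with pytest.raises(SYFitError, match=">= 4"):
            fit_sy(curve)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        s = _spec([100.0, 200.0, 300.0], [1.0, 5.0, 2.0], label="a")
        t = _spec([100.0, 200.0, 300.0], [1.0, 5.0, 2.0], label="b")
        corr = spectral_correlation([s, t])
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_disjoint_spectra_nonpositive(self):
        s = _spec([100.0, 200.0, 300.0], [1.0, 5.0, 2.0], label="a")
        t = _spec([150.0, 250.0, 350.0], [2.0, 1.0, 4.0], label="b")
        assert spectral_correlation([s, t]).iloc[0, 1] <= 0.0

    def test_mostly_shared_beats_disjoint(self):
        rng = np.random.default_rng(0)
        base_mz = np.sort(rng.uniform(300, 2000, 50))
        base_i = rng.uniform(1, 100, 50)
        a = _spec(base_mz, base_i, label="a")
        # b shares 80% of peaks with proportional intensities
        keep = np.sort(rng.choice(50, 40, replace=False))
        extra = np.sort(rng.uniform(2100, 2500, 10))
        b_mz = np.sort(np.concatenate([base_mz[keep], extra]))
        b_i = np.concatenate([2.0 * base_i[keep], rng.uniform(1, 100, 10)])
        order = np.argsort(np.concatenate([base_mz[keep], extra]))
        b = _spec(b_mz, b_i[order], label="b")
        c = _spec(base_mz + 47.5, base_i, label="c")  # disjoint
        corr = spectral_correlation([a, b, c])
        assert corr.loc["a", "b"] > corr.loc["a", "c"]
        assert corr.loc["a", "b"] > 0.7

    def test_matrix_symmetric_psd_on_union_table(self):
        rng = np.random.default_rng(1)
        spectra = []
        base = np.sort(rng.uniform(300, 2000, 40))
        for k in range(4):
            sel = np.sort(rng.choice(40, 30, replace=False))
            spectra.append(_spec(base[sel], rng.uniform(1, 10, 30), label=f"s{k}"))
        corr = spectral_correlation(spectra).to_numpy()
        assert np.allclose(corr, corr.T)
        eigenvalues = np.linalg.eigvalsh(corr)
        assert eigenvalues.min() > -1e-9

    def test_degenerate_spectrum_flagged(self):
        s = _spec([100.0, 200.0], [1.0, 2.0], label="a")
        t = _spec([100.0], [1.0], label="b")
        with pytest.warns(UserWarning, match="<2 peaks"):
            corr = spectral_correlation([s, t])
        assert np.isnan(corr.iloc[0, 1])

    def test_needs_two_spectra(self):
        with pytest.raises(ValueError):
            spectral_correlation([_spec([1.0], [1.0])])


class TestSharedIons:
    def test_identical_spectra_fully_shared(self):
        s = _spec([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], label="a")
        t = _spec([100.0, 200.0, 300.0], [3.0, 2.0, 1.0], label="b")
        result = shared_ion_analysis([s, t])
        assert result.pairwise["shared_pct"].iloc[0] == pytest.approx(100.0)
        assert result.common_pct == pytest.approx(100.0)

    def test_disjoint_spectra_share_nothing(self):
        s = _spec([100.0, 200.0], [1.0, 2.0], label="a")
        t = _spec([150.0, 250.0], [1.0, 2.0], label="b")
        result = shared_ion_analysis([s, t])
        assert result.pairwise["shared_pct"].iloc[0] == 0.0
        assert result.common_pct == 0.0

    def test_planted_seventy_percent_overlap_exact(self):
        shared = np.arange(100.0, 170.0)  # 70 shared ions
        only_a = np.arange(300.0, 315.0)  # 15 unique each
        only_b = np.arange(400.0, 415.0)
        a_mz = np.sort(np.concatenate([shared, only_a]))
        b_mz = np.sort(np.concatenate([shared, only_b]))
        a = _spec(a_mz, np.ones_like(a_mz), label="a")
        b = _spec(b_mz, np.ones_like(b_mz), label="b")
        result = shared_ion_analysis([a, b])
        assert result.pairwise["shared"].iloc[0] == 70
        assert result.pairwise["union"].iloc[0] == 100
        assert result.pairwise["shared_pct"].iloc[0] == pytest.approx(70.0)

    def test_exclusive_combination_counts(self):
        a = _spec([100.0, 200.0, 300.0], [1.0, 1.0, 1.0], label="a")
        b = _spec([100.0, 200.0, 400.0], [1.0, 1.0, 1.0], label="b")
        result = shared_ion_analysis([a, b])
        excl = {row["members"]: row["count"] for _, row in result.exclusive.iterrows()}
        assert excl == {"a;b": 2, "a": 1, "b": 1}

    def test_union_table_alignment_tolerance(self):
        a = _spec([100.000, 200.000], [1.0, 1.0], label="a")
        b = _spec([100.004, 250.000], [1.0, 1.0], label="b")
        table = union_peak_table([a, b], match_tol=0.05)
        assert table.shape[1] == 3  # 100-ish shared, 200, 250
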