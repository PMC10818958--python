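"""Connectivity estimators: defining identities, closed forms, oracles."""

import numpy as np
import pytest
from scipy.signal import periodogram

from rehabconn.connectivity import (
    BANDS,
    ConnectivityTensor,
    analytic_band,
    amplitude_entropy,
    connectivity_matrices,
    cpcc,
    get_band,
    granger,
    mutual_information,
    plv,
    vectorize_features,
    wpli,
)

from conftest import make_analytic, make_epoched
import _oracles

FS = 500.0


# ---------------------------------------------------------------------------
# analytic signal extraction
# ---------------------------------------------------------------------------

class TestAnalyticBand:
    def test_tone_amplitude_constant_and_phase_advances(self, rng):
        t = np.arange(550) / FS
        data = np.cos(2 * np.pi * 5.0 * t)[None, None, :] * np.ones((2, 1, 1))
        epochs = analytic_band(make_epoched(data), "theta")
        a = epochs[0]
        core = slice(60, 490)
        amp = a.amplitude[0, core]
        assert amp.std() / amp.mean() < 0.05  # constant envelope for a tone
        dphi = np.diff(np.unwrap(a.phase[0, core]))
        assert np.allclose(dphi, 2 * np.pi * 5.0 / FS, atol=0.01)

    def test_real_part_is_bandpassed_input(self, rng):
        data = rng.standard_normal((1, 2, 550))
        a = analytic_band(make_epoched(data), "theta")[0]
        # Hilbert identity: Re(analytic) equals the filtered real signal;
        # verify the real part carries only in-band power.
        f, p = periodogram(np.real(a.x[0]), fs=FS)
        inband = p[(f >= 2.0) & (f <= 10.0)].sum()
        assert inband / p.sum() > 0.95

    def test_band_power_confined(self, rng):
        data = rng.standard_normal((1, 1, 2000))
        a = analytic_band(make_epoched(data), "low_gamma")[0]
        f, p = periodogram(np.real(a.x[0]), fs=FS)
        out_of_band = p[(f < 25.0) | (f > 50.0)].sum()
        assert out_of_band / p.sum() < 0.05

    def test_band_below_epoch_resolution_rejected(self, rng):
        from rehabconn.connectivity import BandSpec
        ep = make_epoched(rng.standard_normal((1, 2, 550)))
        with pytest.raises(ValueError, match="too short"):
            analytic_band(ep, BandSpec("sub_delta", 0.05, 0.2))

    def test_unknown_band_name(self):
        with pytest.raises(ValueError, match="unknown band"):
            get_band("alpha_prime")


# ---------------------------------------------------------------------------
# scalar estimators, defining cases
# ---------------------------------------------------------------------------

class TestPhaseMeasures:
    def test_self_plv_is_one(self, tone_pair):
        assert plv(tone_pair, 0, 0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_lag_gives_unit_plv_and_wpli(self, tone_pair):
        assert plv(tone_pair, 0, 1) == pytest.approx(1.0, abs=1e-9)
        assert wpli(tone_pair, 0, 1) == pytest.approx(1.0, abs=1e-9)

    def test_null_plv_near_rayleigh_level(self, rng):
        """Independent phases: E[PLV] ~ sqrt(pi/4)/sqrt(N)."""
        n = 1000
        vals = []
        for _ in range(100):
            x = np.exp(1j * rng.uniform(-np.pi, np.pi, (2, n)))
            vals.append(plv(make_analytic(x), 0, 1))
        assert np.mean(vals) < 0.1

    def test_wpli_zero_for_zero_lag_copy(self, rng):
        x = np.exp(1j * rng.uniform(-np.pi, np.pi, 500))
        a = make_analytic(np.stack([x, 3.0 * x]))
        assert wpli(a, 0, 1) == 0.0

    def test_volume_conduction_contract(self, rng):
        """Zero-lag mixing: PLV/absCPCC inflated, wPLI/iCPCC stay near zero."""
        from scipy.signal import hilbert
        from rehabconn.preprocessing import FilterSpec, design_windowed_sinc, filter_zero_phase
        taps = design_windowed_sinc(FilterSpec("band_pass", 100, (30.0, 45.0), FS))
        s1 = filter_zero_phase(rng.standard_normal(20000), taps)
        s2 = filter_zero_phase(rng.standard_normal(20000), taps)
        s1, s2 = s1 / s1.std(), s2 / s2.std()
        ch1 = 0.65 * s1 + 0.35 * s2
        ch2 = 0.35 * s1 + 0.65 * s2
        a = make_analytic(np.stack([hilbert(ch1), hilbert(ch2)]), band="low_gamma")
        assert plv(a, 0, 1) > 0.5
        assert abs(cpcc(a, 0, 1)) > 0.5
        assert wpli(a, 0, 1) < 0.15
        assert abs(cpcc(a, 0, 1).imag) < 0.1


class TestCPCC:
    def test_self_is_exactly_one(self, tone_pair):
        assert cpcc(tone_pair, 0, 0) == pytest.approx(1.0 + 0j, abs=1e-12)

    def test_positive_scaling_invariance(self, rng):
        x = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        a = make_analytic(np.stack([x, 2.7 * x]))
        c = cpcc(a, 0, 1)
        assert abs(c) == pytest.approx(1.0, abs=1e-12)
        assert c.imag == pytest.approx(0.0, abs=1e-12)

    def test_quarter_cycle_delay_is_purely_imaginary(self):
        t = np.arange(2000) / FS
        x = np.exp(1j * 2 * np.pi * 10 * t)
        y = np.exp(1j * (2 * np.pi * 10 * t - np.pi / 2))
        a = make_analytic(np.stack([x, y]))
        c = cpcc(a, 0, 1)
        assert abs(c.imag) == pytest.approx(1.0, abs=1e-6)
        assert abs(c.real) < 1e-6

    def test_zero_energy_channel_rejected(self):
        a = make_analytic(np.stack([np.zeros(100, complex), np.ones(100, complex)]))
        with pytest.raises(ValueError, match="zero-energy"):
            cpcc(a, 0, 1)


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, rng):
        x = rng.standard_normal(550) + 1j * rng.standard_normal(550)
        a = make_analytic(np.stack([x, x]))
        assert mutual_information(a, 0, 0) == pytest.approx(
            amplitude_entropy(a, 0), abs=1e-9
        )

    def test_independent_channels_below_bias_bound(self, rng):
        """Plug-in MI bias for independent data ~ (nb-1)^2 / (2 N ln 2)."""
        n = 550
        nb = int(np.ceil(np.sqrt(n / 5)))
        bound = (nb - 1) ** 2 / (2 * n * np.log(2))
        vals = []
        for _ in range(100):
            x = rng.standard_normal((2, n)) + 1j * rng.standard_normal((2, n))
            vals.append(mutual_information(make_analytic(x), 0, 1))
        assert np.mean(vals) < 2 * bound

    def test_gaussian_closed_form(self, rng):
        """Correlated Gaussian amplitudes: MI ~ -0.5 log2(1 - rho^2)."""
        n, rho = 5000, 0.9
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        # envelopes = shifted Gaussians (positive), carried on unit phasors
        a1, a2 = 10 + z1, 10 + z2
        x = np.stack([a1 * np.exp(1j * rng.uniform(-np.pi, np.pi, n)),
                      a2 * np.exp(1j * rng.uniform(-np.pi, np.pi, n))])
        est = mutual_information(make_analytic(x), 0, 1)
        expected = -0.5 * np.log2(1 - rho**2)
        assert abs(est - expected) / expected < 0.25

    def test_constant_amplitude_gives_zero(self):
        x = np.stack([np.exp(1j * np.linspace(0, 20, 550)),
                      2 * np.exp(1j * np.linspace(0, 10, 550))])
        assert mutual_information(make_analytic(x), 0, 1) == 0.0


class TestGranger:
    def test_independent_white_noise_small_bias(self, rng):
        """In-sample GC of independent channels is O(p/N)."""
        vals = []
        for _ in range(100):
            x, y = rng.standard_normal((2, 550))
            gxy, gyx = granger(x, y, order=5)
            vals.extend([gxy, gyx])
        assert np.mean(vals) < 0.06

    def test_unidirectional_system_matches_closed_form(self, rng):
        """y[n] = 0.8 x[n-1] + e: GC_xy -> log((0.64 Var x + s^2)/s^2)."""
        n = 20000
        x = rng.standard_normal(n)
        noise = 0.5 * rng.standard_normal(n)
        y = np.zeros(n)
        y[1:] = 0.8 * x[:-1] + noise[1:]
        gxy, gyx = granger(x, y, order=5)
        expected = np.log((0.64 * 1.0 + 0.25) / 0.25)
        assert abs(gxy - expected) / expected < 0.10
        assert gyx < 0.05

    def test_short_epoch_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            granger(rng.standard_normal(30), rng.standard_normal(30), order=5)


# ---------------------------------------------------------------------------
# oracle equivalence: vectorized vs brute force
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_scalar_estimators_match_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal((2, 200)) + 1j * rng.standard_normal((2, 200))
            a = make_analytic(x)
            assert plv(a, 0, 1) == pytest.approx(_oracles.plv_brute(x[0], x[1]), abs=1e-9)
            assert wpli(a, 0, 1) == pytest.approx(_oracles.wpli_brute(x[0], x[1]), abs=1e-9)
            c = cpcc(a, 0, 1)
            cb = _oracles.cpcc_brute(x[0], x[1])
            assert abs(c - cb) < 1e-9
            assert mutual_information(a, 0, 1) == pytest.approx(
                _oracles.mi_brute(np.abs(x[0]), np.abs(x[1])), abs=1e-9
            )

    def test_granger_matches_normal_equation_oracle(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 200))
            ours = granger(x, y, order=4)
            brute = _oracles.gc_brute(x, y, order=4)
            assert ours == pytest.approx(brute, abs=1e-9)

    def test_matrix_functions_match_scalar_estimators(self, rng):
        """The vectorized tensors agree with per-pair scalar calls."""
        ep = make_epoched(rng.standard_normal((2, 5, 550)))
        from rehabconn.connectivity import analytic_band
        epochs = analytic_band(ep, "theta")
        for measure, fn in (("plv", plv), ("wpli", wpli),
                            ("mi", mutual_information)):
            tensor = connectivity_matrices(ep, measure, "theta")
            for e, a in enumerate(epochs):
                for i in range(5):
                    for j in range(i + 1, 5):
                        assert tensor.values[e, i, j] == pytest.approx(
                            fn(a, i, j), abs=1e-9), (measure, e, i, j)
        tensor = connectivity_matrices(ep, "cpcc", "theta")
        for e, a in enumerate(epochs):
            assert tensor.values[e, 1, 3] == pytest.approx(cpcc(a, 1, 3), abs=1e-9)
        gc_t = connectivity_matrices(ep, "gc", "broadband", gc_order=3)
        for e in range(2):
            x, y = ep.data[e, 1], ep.data[e, 3]
            gxy, gyx = granger(x, y, order=3)
            assert gc_t.values[e, 1, 3] == pytest.approx(gxy, abs=1e-9)
            assert gc_t.values[e, 3, 1] == pytest.approx(gyx, abs=1e-9)


# ---------------------------------------------------------------------------
# tensor conventions and invariants
# ---------------------------------------------------------------------------

class TestTensors:
    @pytest.mark.parametrize("measure,diag", [
        ("plv", 1.0), ("wpli", 0.0), ("abs_cpcc", 1.0),
    ])
    def test_undirected_symmetry_and_diagonal(self, rng, measure, diag):
        ep = make_epoched(rng.standard_normal((3, 8, 550)))
        t = connectivity_matrices(ep, measure, "low_gamma")
        v = t.values
        assert np.allclose(v, v.transpose(0, 2, 1), atol=1e-12)
        for e in range(3):
            assert np.allclose(np.diag(v[e]), diag)
        assert not t.directed

    def test_icpcc_antisymmetric_with_zero_diagonal(self, rng):
        """Im CPCC flips sign with pair order (the cross-spectrum is Hermitian)."""
        ep = make_epoched(rng.standard_normal((3, 8, 550)))
        v = connectivity_matrices(ep, "i_cpcc", "low_gamma").values
        assert np.allclose(v, -v.transpose(0, 2, 1), atol=1e-12)
        assert np.allclose(np.einsum("eii->ei", v), 0.0)

    def test_bounds_on_random_inputs(self, rng):
        ep = make_epoched(rng.standard_normal((3, 6, 550)))
        for measure in ("plv", "wpli", "abs_cpcc"):
            v = connectivity_matrices(ep, measure, "theta").values
            assert v.min() >= -1e-12 and v.max() <= 1 + 1e-9
        assert connectivity_matrices(ep, "mi", "theta").values.min() >= 0
        assert connectivity_matrices(ep, "gc", gc_order=3).values.min() >= 0

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((2, 4, 550))
        scaled = data.copy()
        scaled[:, 2] *= 13.5
        for measure in ("plv", "wpli", "abs_cpcc", "gc"):
            kw = {"band": "theta"} if measure != "gc" else {"gc_order": 3}
            a = connectivity_matrices(make_epoched(data), measure, **kw).values
            b = connectivity_matrices(make_epoched(scaled), measure, **kw).values
            assert np.allclose(a, b, atol=1e-9), measure

    def test_gc_is_directed_with_zero_diagonal(self, rng):
        ep = make_epoched(rng.standard_normal((2, 6, 550)))
        t = connectivity_matrices(ep, "gc", gc_order=3)
        assert t.directed
        assert np.allclose(np.einsum("eii->ei", t.values), 0.0)
        assert not np.allclose(t.values, t.values.transpose(0, 2, 1))

    def test_gc_refuses_narrow_band(self, rng):
        ep = make_epoched(rng.standard_normal((2, 4, 550)))
        with pytest.raises(ValueError, match="broadband"):
            connectivity_matrices(ep, "gc", "theta")

    def test_permutation_equivariance(self, rng):
        data = rng.standard_normal((2, 6, 550))
        perm = np.array([3, 1, 5, 0, 4, 2])
        a = connectivity_matrices(make_epoched(data), "plv", "theta").values
        b = connectivity_matrices(make_epoched(data[:, perm]), "plv", "theta").values
        assert np.allclose(b, a[:, perm][:, :, perm], atol=1e-12)


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def _tensor(rng, c, measure="plv", directed=False, complex_valued=False):
    shape = (2, c, c)
    values = rng.standard_normal(shape) + (
        1j * rng.standard_normal(shape) if complex_valued else 0
    )
    return ConnectivityTensor(values=values, measure=measure, band=BANDS["theta"],
                              directed=directed, complex_valued=complex_valued,
                              subject_id="S00", session="before", task="verbal")


class TestVectorization:
    def test_upper_triangle_counts(self, rng):
        assert vectorize_features(_tensor(rng, 16)).n_features == 120

    def test_half_matrix_convention_at_122_channels(self, rng):
        assert vectorize_features(_tensor(rng, 122), "paper_half").n_features == 7442
        gc = _tensor(rng, 122, measure="gc", directed=True)
        assert vectorize_features(gc, "paper_half").n_features == 14884

    def test_directed_offdiagonal_count(self, rng):
        gc = _tensor(rng, 16, measure="gc", directed=True)
        assert vectorize_features(gc, "full_offdiag").n_features == 240

    def test_cpcc_contributes_two_features_per_pair(self, rng):
        t = _tensor(rng, 8, measure="cpcc", complex_valued=True)
        ft = vectorize_features(t)
        assert ft.n_features == 2 * 28
        assert {c for (_, _, c) in ft.pair_index} == {"re", "im"}

    def test_odd_channel_count_rejected_for_half_convention(self, rng):
        with pytest.raises(ValueError, match="even"):
            vectorize_features(_tensor(rng, 15), "paper_half")

    def test_pair_index_is_bijective(self, rng):
        ft = vectorize_features(_tensor(rng, 10))
        assert len(set(ft.pair_index)) == ft.n_features
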