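"""Melting-temperature windows, LLR tracks, rescaling, metagenes and the
smoothing spline."""

import math

import numpy as np
import pytest

from domainscape.genes import IsoformModel
from domainscape.io import SignalTrack
from domainscape.profiles import (TmParams, build_metagene, loglik_enrichment,
                                  rescale_profile, signal_profile,
                                  smooth_spline_fit, window_tm, _spline_fit,
                                  _hat_diagonal)

R = 1.987


class TestWindowTm:
    def test_single_window_hand_summed_from_breslauer_table(self):
        # GCATTGCAA: stacks GC,CA,AT,TT,TG,GC,CA,AA summed by hand from the
        # Breslauer 1986 dH/dS table (kcal/mol, cal/(mol K)); TT and AA both
        # read AA/TT, TG reads its reverse orientation CA/GT:
        dh = -11.1 - 5.8 - 8.6 - 9.1 - 5.8 - 11.1 - 5.8 - 9.1
        ds = -26.7 - 12.9 - 23.9 - 24.0 - 12.9 - 26.7 - 12.9 - 24.0
        ds += -16.8  # duplex initiation, at least one G/C pair
        k = 50e-9 / 4
        expected = 1000 * dh / (ds + R * math.log(k)) - 273.15 \
            + 16.6 * math.log10(0.05)
        got = window_tm("GCATTGCAA", TmParams())
        assert len(got) == 1
        assert got[0] == pytest.approx(expected, abs=0.01)

    def test_matches_biopython_on_random_sequence(self, rng):
        from Bio.SeqUtils import MeltingTemp as mt
        seq = "".join(rng.choice(list("ACGT"), 120))
        ours = window_tm(seq, TmParams())
        ref = [mt.Tm_NN(seq[i:i + 9], nn_table=mt.DNA_NN1, dnac1=25, dnac2=25,
                        Na=50, saltcorr=1) for i in range(len(seq) - 8)]
        assert np.allclose(ours, ref, atol=1e-9)

    def test_gc_stability_ordering(self):
        lo = window_tm("AAAAAAAAA", TmParams())[0]
        hi = window_tm("GGGGGGGGG", TmParams())[0]
        assert hi > lo

    def test_strictly_increasing_in_gc_count_for_block_windows(self):
        tms = [window_tm("A" * (9 - k) + "G" * k, TmParams())[0] for k in range(10)]
        assert all(b > a for a, b in zip(tms, tms[1:]))

    def test_n_window_missing_and_short_sequence_empty(self):
        vals = window_tm("ACGTNACGTACGTA", TmParams())
        assert np.isnan(vals[:5]).all() and not np.isnan(vals[5:]).any()
        assert len(window_tm("ACGT", TmParams())) == 0

    def test_window_equal_length_yields_one_value(self):
        assert len(window_tm("ACGTACGTA", TmParams(window=9))) == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TmParams(window=1)
        with pytest.raises(ValueError):
            TmParams(dnac_nM=0)


class TestLoglikEnrichment:
    def test_equal_tracks_all_zero(self):
        t = SignalTrack("c", [0], [50], [3.0])
        assert not loglik_enrichment(t, t).to_dense(50).any()

    def test_sign_contract(self):
        t = SignalTrack("c", [0], [10], [5.0])
        c = SignalTrack("c", [0], [10], [2.0])
        assert loglik_enrichment(t, c).to_dense(10).min() > 0
        assert loglik_enrichment(c, t).to_dense(10).max() < 0

    def test_matches_poisson_log_pmf_oracle(self, rng):
        from scipy.stats import poisson
        n = 40
        x = np.round(rng.uniform(0, 20, n), 3)
        y = np.round(rng.uniform(0, 20, n), 3)
        t = SignalTrack("c", np.arange(n), np.arange(n) + 1, x)
        c = SignalTrack("c", np.arange(n), np.arange(n) + 1, y)
        got = loglik_enrichment(t, c, pseudocount=1e-5).to_dense(n)
        p = 1e-5
        for i in range(n):
            xi, yi = x[i] + p, y[i] + p
            big, small = max(xi, yi), min(xi, yi)
            # continuous Poisson log-likelihood ratio at observation = big
            oracle = (big * math.log(big / small) - big + small) / math.log(10)
            oracle *= math.copysign(1.0, xi - yi) if xi != yi else 0.0
            assert got[i] == pytest.approx(oracle, abs=1e-9)

    def test_antisymmetric(self, rng):
        n = 30
        x = rng.uniform(0, 10, n)
        y = rng.uniform(0, 10, n)
        t = SignalTrack("c", np.arange(n), np.arange(n) + 1, x)
        c = SignalTrack("c", np.arange(n), np.arange(n) + 1, y)
        assert np.allclose(loglik_enrichment(t, c).to_dense(n),
                           -loglik_enrichment(c, t).to_dense(n), atol=1e-12)

    def test_negative_values_rejected(self):
        t = SignalTrack("c", [0], [10], [-1.0])
        c = SignalTrack("c", [0], [10], [2.0])
        with pytest.raises(ValueError):
            loglik_enrichment(t, c)


class TestRescaleProfile:
    def test_constant_profile(self):
        out = rescale_profile(np.full(7, 2.5), 31)
        assert np.allclose(out, 2.5)

    def test_identity_at_target_length(self):
        v = np.arange(10.0)
        assert np.array_equal(rescale_profile(v, 10), v)

    def test_linear_ramp_closed_form(self):
        out = rescale_profile(np.linspace(0, 1, 11), 41)
        assert np.allclose(out, np.linspace(0, 1, 41), atol=1e-12)

    def test_monotone_minmax_preserved_and_idempotent(self, rng):
        v = np.cumsum(rng.uniform(0, 1, 20))
        out = rescale_profile(v, 50)
        assert out.min() == v.min() and out.max() == v.max()
        assert np.allclose(rescale_profile(out, 50), out)

    def test_missing_propagates_not_interpolated(self):
        v = np.array([0.0, np.nan, 2.0, 3.0])
        out = rescale_profile(v, 7)
        # points needing the NaN source neighbour are NaN
        assert np.isnan(out[1]) and np.isnan(out[2])
        assert out[0] == 0.0 and out[-1] == 3.0

    def test_all_missing_stays_missing(self):
        assert np.isnan(rescale_profile([np.nan, np.nan], 5)).all()


class TestBuildMetagene:
    def test_single_gene_identity(self):
        up = np.arange(5.0)
        span = np.linspace(0, 1, 21)
        down = np.arange(5.0) + 10
        mg = build_metagene([(up, span, down)], span_length=20, flank=5)
        assert len(mg.positions) == 20 + 2 * 5 + 1
        assert np.allclose(mg.median[:5], up)
        assert np.allclose(mg.median[5:26], span)
        assert np.allclose(mg.median[26:], down)

    def test_median_of_opposite_genes_is_zero(self):
        v = np.ones(11)
        mg = build_metagene([(v[:3], v, v[:3]), (-v[:3], -v, -v[:3])],
                            span_length=10, flank=3)
        assert np.allclose(mg.median, 0)
        assert (mg.n_genes == 2).all()

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            build_metagene([], 10, 3)

    def test_short_flank_padded_with_missing(self):
        mg = build_metagene([(np.ones(2), np.ones(5), np.ones(3))],
                            span_length=4, flank=3)
        assert np.isnan(mg.median[0]) and mg.n_genes[0] == 0


class TestSignalProfile:
    def make_iso(self, strand):
        return IsoformModel("g", "t", "c", strand, [(10, 20), (30, 40)])

    def test_plus_minus_symmetry_on_mirrored_track(self):
        n = 60
        vals = np.arange(n, dtype=float)
        fwd = SignalTrack("c", np.arange(n), np.arange(n) + 1, vals)
        rev = SignalTrack("c", np.arange(n), np.arange(n) + 1, vals[::-1])
        up_p, sp_p, dn_p = signal_profile(fwd, self.make_iso("+"), flank=5, seq_length=n)
        iso_m = IsoformModel("g", "t", "c", "-", [(n - 40, n - 30), (n - 20, n - 10)])
        up_m, sp_m, dn_m = signal_profile(rev, iso_m, flank=5, seq_length=n)
        assert np.allclose(up_p, up_m) and np.allclose(sp_p, sp_m) \
            and np.allclose(dn_p, dn_m)

    def test_zero_track_zero_profiles(self):
        tr = SignalTrack("c", [0], [60], [0.0])
        up, sp, dn = signal_profile(tr, self.make_iso("+"), flank=5, seq_length=60)
        assert not np.concatenate([up, sp, dn]).any()

    def test_per_base_dictionary_oracle(self, rng):
        n = 80
        vals = rng.uniform(-3, 3, n)
        tr = SignalTrack("c", np.arange(n), np.arange(n) + 1, vals)
        iso = IsoformModel("g", "t", "c", "+", [(20, 35), (45, 60)])
        up, sp, dn = signal_profile(tr, iso, flank=10, seq_length=n)
        lookup = dict(enumerate(vals))
        assert np.allclose(up, [lookup[b] for b in range(10, 20)])
        assert np.allclose(sp, [lookup[b] for b in range(20, 60)])
        assert np.allclose(dn, [lookup[b] for b in range(60, 70)])

    def test_flank_beyond_contig_truncated_with_missing(self):
        tr = SignalTrack("c", [0], [30], [1.0])
        iso = IsoformModel("g", "t", "c", "+", [(2, 12)])
        up, sp, dn = signal_profile(tr, iso, flank=5, seq_length=30)
        assert np.isnan(up[:3]).all() and np.isfinite(up[3:]).all()


class TestSmoothSpline:
    def test_noiseless_line_exact(self):
        x = np.arange(60, dtype=float)
        y = 0.7 * x - 3
        assert np.allclose(smooth_spline_fit(y), y, atol=1e-6)

    def test_constant_profile(self):
        assert np.allclose(smooth_spline_fit(np.full(40, 2.0)), 2.0, atol=1e-9)

    def test_noisy_sine_denoised(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4 * np.pi, 500)
        truth = np.sin(t)
        noisy = truth + rng.normal(0, 0.3, len(t))
        fit = smooth_spline_fit(noisy, x=t)
        assert np.sqrt(np.mean((fit - truth) ** 2)) \
            < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_hat_diagonal_matches_unit_vector_smoothing(self):
        rng = np.random.default_rng(4)
        n = 35
        x = np.sort(rng.uniform(0, 5, n))
        lam = 0.2
        _, system = _spline_fit(x, rng.normal(0, 1, n), lam)
        diag = _hat_diagonal(n, system, lam)
        for i in range(0, n, 5):
            e = np.zeros(n)
            e[i] = 1.0
            fit, _ = _spline_fit(x, e, lam)
            assert diag[i] == pytest.approx(fit[i], abs=1e-9)

    def test_matches_scipy_at_fixed_lambda(self, rng):
        from scipy.interpolate import make_smoothing_spline
        x = np.arange(50, dtype=float)
        y = rng.normal(0, 1, 50)
        ours, _ = _spline_fit(x, y, 3.0)
        assert np.allclose(ours, make_smoothing_spline(x, y, lam=3.0)(x), atol=1e-10)

    def test_nan_positions_left_undefined(self):
        y = np.sin(np.linspace(0, 3, 40))
        y[5] = np.nan
        out = smooth_spline_fit(y)
        assert np.isnan(out[5]) and np.isfinite(np.delete(out, 5)).all()

    def test_under_ten_points_passes_through_with_warning(self):
        y = np.arange(5.0)
        with pytest.warns(UserWarning, match="fewer than 10"):
            out = smooth_spline_fit(y)
        assert np.array_equal(out, y)
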