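"""Biomarker operations against closed-form, Monte-Carlo and surrogate
oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps

import fatiguemark as fm
from fatiguemark.bands import get_band
from fatiguemark.biomarkers import (
    FeatureConfig,
    _interior,
    bandpass,
    entropy_from_distribution,
    fit_mvar,
    hjorth,
    modulation_index_from_distribution,
    mvar_order_scan,
    mvar_spectral_radius,
    pac_mi,
    pdc_from_coefficients,
    wavelet_relative_energies,
)
from fatiguemark.synthetic import coupling_ar_coefficients, simulate_var

FS = 508.6
N = 509


def tone(freq, n=N, fs=FS, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


# ---------------------------------------------------------------------------
# band power


class TestBandPower:
    def test_zero_signal_has_zero_power_in_every_band(self):
        for band in fm.BAND_REGISTRY:
            assert fm.band_power(np.zeros(N), band, FS) == 0.0

    def test_tone_lands_in_its_band(self):
        x = tone(6.0)
        assert fm.band_power(x, "theta", FS) >= 100 * fm.band_power(x, "delta", FS)

    def test_white_noise_power_scales_with_bandwidth(self):
        # high_gamma (100 Hz wide) vs delta (3 Hz wide): ratio 100/3
        rng = np.random.default_rng(0)
        hg, dl = [], []
        for _ in range(1000):
            x = rng.standard_normal(N)
            hg.append(fm.band_power(x, "high_gamma", FS))
            dl.append(fm.band_power(x, "delta", FS))
        ratio = np.mean(hg) / np.mean(dl)
        assert ratio == pytest.approx(100 / 3, rel=0.10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fm.band_power(np.zeros(N), "high_gamma", fs=350.0)


# ---------------------------------------------------------------------------
# wavelet entropy


class TestWaveletEntropy:
    def test_point_mass_entropy_zero(self):
        assert entropy_from_distribution(np.array([1, 0, 0, 0, 0])) == 0.0

    def test_uniform_distribution_attains_ln_k(self):
        assert entropy_from_distribution(np.full(5, 0.2)) == pytest.approx(np.log(5))

    def test_relative_energies_sum_to_one(self):
        rng = np.random.default_rng(1)
        p = wavelet_relative_energies(rng.standard_normal(N))
        assert p.size == 5
        assert p.sum() == pytest.approx(1.0)

    def test_detail_only_mode_has_four_subbands(self):
        rng = np.random.default_rng(1)
        p = wavelet_relative_energies(rng.standard_normal(N), include_approx=False)
        assert p.size == 4
        assert p.sum() == pytest.approx(1.0)

    def test_bounds_on_noise(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            e = fm.wavelet_entropy(rng.standard_normal(N))
            assert 0.0 <= e <= np.log(5) + 1e-12

    def test_tone_less_entropic_than_noise(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(200):
            e_tone = fm.wavelet_entropy(tone(10.0, phase=rng.uniform(0, 2 * np.pi)))
            e_noise = fm.wavelet_entropy(rng.standard_normal(N))
            wins += e_tone < e_noise
        assert wins >= 190  # >= 95% of draws

    def test_all_zero_epoch_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fm.wavelet_entropy(np.zeros(N))


# ---------------------------------------------------------------------------
# Hjorth


class TestHjorth:
    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(0, 10))
    def test_scale_invariance(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        a0, m0, k0 = hjorth(x)
        a1, m1, k1 = hjorth(c * x)
        assert a1 == pytest.approx(c**2 * a0, rel=1e-9)
        assert m1 == pytest.approx(m0, rel=1e-9)
        assert k1 == pytest.approx(k0, rel=1e-9)

    @pytest.mark.parametrize("freq", [5.0, 20.0, 60.0])
    def test_tone_mobility_closed_form(self, freq):
        # first difference of a sampled tone: mobility = 2 sin(pi f / fs)
        _, mob, _ = hjorth(tone(freq, n=20000))
        assert mob == pytest.approx(2 * np.sin(np.pi * freq / FS), rel=1e-3)

    def test_white_noise_complexity_above_one(self):
        rng = np.random.default_rng(4)
        comps = [hjorth(rng.standard_normal(N))[2] for _ in range(200)]
        assert np.mean(comps) > 1.0

    def test_constant_signal_degenerate(self):
        act, mob, comp = hjorth(np.full(N, 3.7))
        assert act == 0.0
        assert np.isnan(mob) and np.isnan(comp)


# ---------------------------------------------------------------------------
# PAC modulation index


class TestPacMi:
    def test_uniform_distribution_gives_zero(self):
        assert modulation_index_from_distribution(np.full(18, 1 / 18)) == 0.0

    def test_point_mass_gives_one(self):
        p = np.zeros(18)
        p[4] = 1.0
        assert modulation_index_from_distribution(p) == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            pac_mi(np.zeros(N), FS, n_bins=1)
        with pytest.raises(ValueError):
            modulation_index_from_distribution(np.array([1.0]))

    def test_coupled_signal_beats_phase_shuffled_surrogates(self):
        # 100 Hz carrier amplitude-modulated by a stochastic 4-6 Hz rhythm
        # (a periodic modulator would survive the circular-shift null)
        rng = np.random.default_rng(5)
        n = 4 * N
        t = np.arange(n) / FS
        slow = sps.sosfiltfilt(
            sps.butter(4, [4, 6], btype="bandpass", fs=FS, output="sos"),
            rng.standard_normal(n),
        )
        slow /= slow.std()
        x = slow + (1 + 0.8 * np.clip(slow, -1, 1)) * np.sin(2 * np.pi * 100.0 * t) \
            + 0.3 * rng.standard_normal(n)
        mi = pac_mi(x, FS)
        from fatiguemark.bands import PAC_AMP_BAND, PAC_PHASE_BAND
        from fatiguemark.biomarkers import _mi_from_phase_amp

        phase = np.angle(sps.hilbert(bandpass(x, PAC_PHASE_BAND, FS)))
        amp = np.abs(sps.hilbert(bandpass(x, PAC_AMP_BAND, FS)))
        sl = _interior(n, 0.1)
        phase, amp = phase[sl], amp[sl]
        null = [
            _mi_from_phase_amp(phase, np.roll(amp, int(rng.integers(50, amp.size - 50))), 18)
            for _ in range(200)
        ]
        assert mi > np.quantile(null, 0.95)

    def test_mi_bounded(self, small_table):
        cols = [c for c in small_table.feature_names if c.startswith("pac.")]
        vals = small_table.values[cols].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()


# ---------------------------------------------------------------------------
# IA / IF


class TestIaIf:
    def test_tone_amplitude_recovered(self):
        ia, _, _ = fm.ia_if(tone(2.0, n=8 * N, amp=7.5), FS)
        assert ia == pytest.approx(7.5, rel=0.02)

    def test_tone_frequency_recovered(self):
        _, inst_f, _ = fm.ia_if(tone(10.0), FS)
        assert inst_f == pytest.approx(10.0, rel=0.02)

    def test_linear_chirp_mean_frequency(self):
        # 4 -> 14 Hz linear chirp: mean instantaneous frequency 9 Hz
        t = np.arange(N) / FS
        x = sps.chirp(t, f0=4.0, f1=14.0, t1=t[-1], method="linear")
        _, inst_f, _ = fm.ia_if(x, FS)
        assert inst_f == pytest.approx(9.0, rel=0.05)

    def test_ratio_consistency(self):
        x = tone(2.0, amp=5.0) + tone(10.0, amp=1.0)
        ia, inst_f, ratio = fm.ia_if(x, FS)
        assert ratio == pytest.approx(ia / inst_f, rel=1e-9)


# ---------------------------------------------------------------------------
# PDC


class TestPdc:
    def test_column_normalization_exact(self):
        rng = np.random.default_rng(6)
        A = fit_mvar(rng.standard_normal((10, 2000)), 5)
        M = pdc_from_coefficients(A, FS, np.arange(1.0, 20.0))
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)

    def test_embedded_ar_system_matches_analytic_pdc(self):
        # one-way coupled AR(2) pair in channels 0,1; 8 white channels
        rng = np.random.default_rng(7)
        A2 = coupling_ar_coefficients(coupling=1.0, fs=FS)
        pair = simulate_var(A2, 5000, rng)
        X = np.vstack([pair, rng.standard_normal((8, 5000))])
        A10 = np.zeros((2, 10, 10))
        A10[:, :2, :2] = A2
        for band in ("delta", "theta"):
            freqs = get_band(band).frequencies()
            true = pdc_from_coefficients(A10, FS, freqs).mean(axis=0)
            est = fm.pdc(X, FS, band, order=5)
            assert abs(est[1, 0] - true[1, 0]) < 0.1  # driven direction
            assert est[0, 1] < 0.15  # no reverse coupling

    def test_white_noise_off_diagonal_near_null_level(self):
        rng = np.random.default_rng(8)
        off = ~np.eye(10, dtype=bool)
        null = [fm.pdc(rng.standard_normal((10, 2000)), FS, "alpha")[off].mean()
                for _ in range(5)]
        for v in null:
            assert v < 2 * np.mean(null)

    def test_short_epoch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too short"):
            fit_mvar(rng.standard_normal((10, 60)), 5)

    def test_singular_regression_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((10, 2000))
        x[1] = x[0]  # duplicate channel
        with pytest.raises(ValueError, match="singular"):
            fit_mvar(x, 5)

    def test_unstable_coefficients_rejected_by_simulator(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[1.05, 0.0], [0.3, 0.5]]
        assert mvar_spectral_radius(A) >= 1.0
        with pytest.raises(ValueError, match="unstable"):
            simulate_var(A, 100, np.random.default_rng(0))

    def test_order_scan_prefers_true_order_region(self):
        rng = np.random.default_rng(10)
        x = simulate_var(coupling_ar_coefficients(fs=FS), 4000, rng)
        scan = mvar_order_scan(x, FS, orders=range(1, 7))
        best = int(scan.loc[scan.aic.idxmin(), "order"])
        assert best >= 2


# ---------------------------------------------------------------------------
# PLI


class TestPli:
    def test_identical_signals_fully_locked(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(N)
        assert fm.pli(x, x, FS, "alpha") == pytest.approx(1.0, abs=1e-9)

    def test_fixed_lag_tones_fully_locked(self):
        n = 8 * N
        assert fm.pli(tone(10.0, n=n), tone(10.0, n=n, phase=1.1), FS, "alpha") == (
            pytest.approx(1.0, abs=1e-3)
        )

    def test_independent_noise_matches_random_phase_asymptotics(self):
        # E|PLI| = sqrt(pi)/2 * sqrt(sum |rho|^2 / T) with rho the band
        # phasor autocorrelation, estimated from one long realization
        rng = np.random.default_rng(12)
        band = get_band("alpha")
        long = rng.standard_normal(400_000)
        z = np.exp(1j * np.angle(sps.hilbert(bandpass(long, band, FS))))
        z = z - z.mean()
        ac = np.array(
            [np.mean(z[: z.size - k] * np.conj(z[k:])) for k in range(3000)]
        )
        ac /= ac[0]
        T = len(range(*_interior(N, 0.1).indices(N)))
        pred = np.sqrt(np.pi) / 2 * np.sqrt((1 + 2 * np.sum(np.abs(ac[1:]) ** 2)) / T)
        vals = np.array(
            [fm.pli(rng.standard_normal(N), rng.standard_normal(N), FS, "alpha")
             for _ in range(300)]
        )
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - pred) < 3 * se

    def test_bounded(self, small_table):
        cols = [c for c in small_table.feature_names if c.startswith("pli.")]
        vals = small_table.values[cols].to_numpy()
        assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# global coherence


class TestGlobalCoherence:
    def test_identical_channels_near_one(self):
        rng = np.random.default_rng(13)
        x = np.tile(rng.standard_normal(4 * N), (10, 1))
        assert fm.global_coherence(x, FS, "alpha") > 0.999

    def test_lower_bound_one_over_c(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            v = fm.global_coherence(rng.standard_normal((10, N)), FS, "alpha")
            assert 1 / 10 - 1e-12 <= v <= 1 + 1e-12

    def test_independent_noise_null_level(self):
        rng = np.random.default_rng(15)
        vals = np.array(
            [fm.global_coherence(rng.standard_normal((10, 10 * N)), FS, "alpha")
             for _ in range(8)]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert vals.mean() < 0.5
        assert abs(vals[0] - vals.mean()) < max(3 * se, 0.02)

    def test_needs_two_channels(self):
        with pytest.raises(ValueError, match="2 channels"):
            fm.global_coherence(np.zeros((1, N)), FS, "alpha")


# ---------------------------------------------------------------------------
# feature table assembly


class TestExtractFeatures:
    def test_column_contract(self, small_table):
        counts = {}
        for col in small_table.feature_names:
            fam = small_table.family_of(col)
            counts[fam] = counts.get(fam, 0) + 1
        assert len(small_table.feature_names) == 708
        for band in ("delta", "theta", "alpha", "low_beta", "high_beta",
                     "low_gamma", "gamma", "high_gamma"):
            assert counts[band] == 10
        assert counts["wavelet_entropy"] == 10
        assert counts["hjorth_activity"] == counts["hjorth_mobility"] == 10
        assert counts["hjorth_complexity"] == 10
        assert counts["pac"] == 10
        assert counts["iaif"] == 30
        assert counts["pdc"] == 360  # 90 ordered pairs x 4 bands
        assert counts["pli"] == 180  # 45 pairs x 4 bands
        assert counts["gc"] == 8

    def test_conditions_partition_families(self, small_table):
        spectral = small_table.columns_for_condition("spectral")
        host = small_table.columns_for_condition("HOST")
        combined = small_table.columns_for_condition("combined")
        assert len(spectral) == 80
        assert len(host) == 708 - 80
        assert set(spectral) | set(host) == set(combined)
        assert not set(spectral) & set(host)
        with pytest.raises(ValueError):
            small_table.columns_for_condition("everything")

    def test_single_channel_columns(self, small_table):
        cols = small_table.columns_for_channel("CZ")
        assert len(cols) == 16  # 8 powers + WE + 3 Hjorth + PAC + 3 IAIF
        assert all(".CZ" in c or c.endswith(".CZ") for c in cols)

    def test_deterministic_rows(self, small_session):
        session, events, _ = small_session
        all_epochs = fm.extract_epochs(session, events, "delay", 1.0)
        epochs = ([e for e in all_epochs if e.outcome == "correct"][:2]
                  + [e for e in all_epochs if e.outcome == "incorrect"][:2])
        a = fm.extract_features(epochs).values
        b = fm.extract_features(epochs).values
        assert a.equals(b)

    def test_positive_class_is_incorrect(self, small_session, small_table):
        _, events, _ = small_session
        by_id = {e.trial_id: e.outcome for e in events}
        for tid, label in zip(small_table.values.index, small_table.labels):
            assert label == (1 if by_id[tid] == "incorrect" else 0)

    def test_both_classes_required(self, small_session):
        session, events, _ = small_session
        only_correct = [e for e in events if e.outcome == "correct"][:5]
        epochs = fm.extract_epochs(session, only_correct, "delay", 1.0)
        with pytest.raises(ValueError, match="both outcome classes"):
            fm.extract_features(epochs)

    def test_csv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "features.csv"
        small_table.to_csv(path)
        back = fm.FeatureTable.from_csv(path)
        np.testing.assert_allclose(
            back.values.to_numpy(), small_table.values.to_numpy(), rtol=1e-9
        )
        np.testing.assert_array_equal(back.labels, small_table.labels)
        assert back.registry == small_table.registry

    def test_all_values_finite_on_healthy_session(self, small_table):
        assert np.isfinite(small_table.values.to_numpy()).all()


class TestEffectRecovery:
    """On single-effect sessions the top-discriminating column belongs to a
    family/channel the generator reports as carrying the effect."""

    @pytest.mark.parametrize(
        "gains",
        [
            {"lowfreq_power_gain": 1.0},
            {"entropy_drop": 1.0},
            {"coupling_gain": 1.0},
        ],
        ids=["lowfreq", "entropy", "coupling"],
    )
    def test_top_r2_rank_in_effect_set(self, gains):
        from fatiguemark.classify import point_biserial_r2

        base = dict(lowfreq_power_gain=0, entropy_drop=0, coupling_gain=0)
        hits = 0
        for seed in range(60, 65):
            cfg = fm.GeneratorConfig(
                n_trials=60, seed=seed, target_incorrect_fraction=0.5,
                effect_sizes=fm.EffectSizes(**{**base, **gains}),
            )
            session, events, truth = fm.generate_session(cfg)
            epochs = fm.extract_epochs(session, events, "delay", 1.0)
            table = fm.extract_features(epochs)
            X = table.values.to_numpy(float)
            med = np.nanmedian(X, axis=0)
            bad = ~np.isfinite(X)
            X[bad] = np.broadcast_to(med, X.shape)[bad]
            r2 = point_biserial_r2(X, table.labels)
            top = table.feature_names[int(np.argmax(r2))]
            fam = table.family_of(top)
            chans = set(table.registry[top].channels)
            for info in truth.effects.values():
                affected = set(info.get("channels", []))
                affected |= {c for p in info.get("pairs", []) for c in p}
                if fam in info["families"] and (fam == "gc" or chans & affected):
                    hits += 1
                    break
        assert hits >= 4  # >= 80% of seeds
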