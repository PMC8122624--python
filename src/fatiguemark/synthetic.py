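"""Synthetic vigilance-task sessions with the statistical structure the
analysis pipeline assumes.

Real recordings of the task are not redistributable, so this module
generates sessions that carry the same class-conditional structure the
pipeline is designed to detect:

* a latent fatigue state drifting upward across trials (bounded random
  walk, logistic squashing) that drives a rising incorrect-trial rate;
* 1/f^α background activity per channel plus weak 10 Hz and 20 Hz
  oscillations;
* a mid-gamma (~50 Hz) bursty background component per channel, sitting
  in the 45-60 Hz gap between the canonical gamma bands;
* on incorrect trials, injected into the delay period only —
  (i) extra 1-10 Hz band-limited power on designated channels,
  (ii) suppression of the mid-gamma component on designated channels,
  which concentrates wavelet energy into the slow subbands (entropy and
  mobility drop) while remaining invisible to every band-power feature,
  (iii) a power-preserving delta-band substitution that makes one
  channel's slow activity partially predictable from another's past
  (strengthening directed coherence and phase locking without a power
  signature), and (iv) saccade-like biphasic ocular transients mixed
  through a frontal-dominant vector;
* trial delays drawn from N(2500 ms, 250 ms), truncated at 500 ms.

Every random draw goes through one seeded generator; the same seed gives
bit-identical output.  ``GroundTruth`` records the injected effects so
downstream tests can check that the pipeline recovers them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .biomarkers import ALL_FAMILIES
from .core import DEFAULT_CHANNELS, ChannelLayout, SessionRecording, TrialEvent

DEFAULT_ORDER = list(DEFAULT_CHANNELS)

#: class-balance regimes: target incorrect-trial fraction, matching the
#: two animals' mean per-session correct/incorrect counts (254/270 and
#: 202/518)
REGIMES = {
    "balanced": 270 / (254 + 270),
    "unbalanced": 518 / (202 + 518),
}


@dataclass(frozen=True)
class EffectSizes:
    """Dimensionless gains of the injected incorrect-trial effects.

    At gain 1, each added component's amplitude is of the same order as
    the background activity in its band, giving clearly separable but
    overlapping class distributions; 0 switches the effect off.
    """

    lowfreq_power_gain: float = 1.0
    entropy_drop: float = 1.0
    coupling_gain: float = 1.0
    artifact_amplitude: float = 0.0  # µV; ocular artifacts off by default

    def __post_init__(self) -> None:
        for name in (
            "lowfreq_power_gain",
            "entropy_drop",
            "coupling_gain",
            "artifact_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"effect size {name} must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_trials: int = 300
    fs: float = 508.6
    delay_mean_ms: float = 2500.0
    delay_sd_ms: float = 250.0
    #: latent fatigue drift per trial (logit scale)
    fatigue_slope: float = 0.012
    fatigue_walk_sd: float = 0.05
    #: P(incorrect | fatigue f) = logistic(intercept + gain * f)
    outcome_intercept: float = -2.0
    outcome_gain: float = 4.0
    #: if set, the intercept is re-solved per session so the expected
    #: incorrect fraction matches this target
    target_incorrect_fraction: float | None = None
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    #: background 1/f^alpha exponent and RMS (µV), plus oscillation
    #: amplitudes (µV) at fixed frequencies
    background_alpha: float = 1.5
    background_rms: float = 20.0
    oscillations: tuple[tuple[float, float], ...] = ((10.0, 2.5), (20.0, 1.5))
    #: slow per-channel log-normal amplitude modulation of the background
    #: (log-amplitude SD and correlation timescale); emulates the strong
    #: trial-to-trial amplitude nonstationarity of chronic ECoG
    amplitude_jitter_sd: float = 0.25
    amplitude_jitter_timescale_s: float = 30.0
    #: channel-specific bursty oscillations (RMS µV, envelope log-SD and
    #: timescale); their distinct frequencies and strong amplitude bursts
    #: give each electrode the individual, super-Gaussian character that
    #: makes the recordings separable by ICA
    burst_osc_rms: float = 20.0
    burst_env_sd: float = 1.2
    burst_env_timescale_s: float = 0.5
    #: mid-gamma background component (Hz, RMS µV, envelope log-SD); its
    #: frequency sits between the canonical gamma bands so its suppression
    #: is invisible to band-power features
    gamma_osc_freq: float = 50.0
    gamma_osc_rms: float = 8.0
    gamma_env_sd: float = 0.3
    #: acquisition-chain high-pass (Hz); removes sub-delta drift as the
    #: recording hardware would
    hp_cutoff_hz: float = 0.5
    #: channels / pair carrying each effect
    lowfreq_channels: tuple[str, ...] = ("FZ", "CZ")
    entropy_channels: tuple[str, ...] = ("LT", "RT")
    coupling_pair: tuple[str, str] = ("FZ", "CZ")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 20:
            raise ValueError("n_trials must be >= 20")
        if self.delay_sd_ms <= 0:
            raise ValueError("delay_sd_ms must be > 0")


@dataclass
class GroundTruth:
    """Record of what was injected, for recovery tests downstream.

    ``effects`` is keyed by injection mechanism (``lowfreq_power``,
    ``entropy``, ``coupling``); each entry lists the feature families the
    mechanism physically drives, the affected channels or ordered pairs,
    and the gain used — the generator's own account of where a detector
    should find signal.
    """

    fatigue: np.ndarray
    p_incorrect: np.ndarray
    effects: dict[str, dict]
    artifact_mixing: np.ndarray
    seed: int
    regime: str | None = None

    def __post_init__(self) -> None:
        for mech, info in self.effects.items():
            for family in info["families"]:
                if family not in ALL_FAMILIES:
                    raise ValueError(
                        f"effect {mech!r} names unknown feature family {family!r}"
                    )

    def effect_columns(self) -> list[str]:
        """Feature-table column names directly targeted by the injected
        effects."""
        cols: list[str] = []
        for info in self.effects.values():
            band = info.get("band", "delta")
            for family in info["families"]:
                if family == "pdc":
                    for src, dst in info.get("pairs", []):
                        cols.append(f"pdc.{src}→{dst}.{band}")
                elif family == "pli":
                    for src, dst in info.get("pairs", []):
                        a, b = sorted([src, dst], key=DEFAULT_ORDER.index)
                        cols.append(f"pli.{a}–{b}.{band}")
                elif family == "iaif":
                    cols.extend(f"iaif.{ch}.ia" for ch in info.get("channels", []))
                elif family == "gc":
                    cols.append(f"gc.all.{band}")
                else:
                    cols.extend(f"{family}.{ch}" for ch in info.get("channels", []))
        return cols


# ---------------------------------------------------------------------------
# building blocks


def one_over_f_noise(
    n: int, alpha: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum and given RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid div-by-zero at DC
    spec *= f ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n=n)
    x *= rms / max(np.sqrt(np.mean(x**2)), np.finfo(float).tiny)
    return x


def slow_envelope(
    n: int, fs: float, sd: float, timescale_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Slowly varying positive gain exp(sd·z(t)) with z a unit-variance
    Gaussian process of the given correlation timescale."""
    if sd <= 0:
        return np.ones(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * (f * timescale_s) ** 2)
    z = np.fft.irfft(spec, n=n)
    z_sd = z.std()
    if z_sd > 0:
        z /= z_sd
    return np.exp(sd * z)


def coupling_ar_coefficients(
    coupling: float = 2.0,
    f0: float = 3.0,
    radius: float = 0.93,
    fs: float = 508.6,
) -> np.ndarray:
    """AR(2) coefficient matrices of the injected two-channel process.

    Both channels resonate at ``f0`` Hz (pole radius ``radius``); channel 0
    drives channel 1 with lag-1 strength ``coupling`` and there is no
    feedback, so the system is stable for any coupling value.  Returns A
    with shape (2, 2, 2) usable directly by the analytic PDC oracle.
    """
    theta = 2 * np.pi * f0 / fs
    a1 = 2 * radius * np.cos(theta)
    a2 = -(radius**2)
    A = np.zeros((2, 2, 2))
    A[0] = [[a1, 0.0], [coupling, a1]]
    A[1] = [[a2, 0.0], [0.0, a2]]
    return A


def simulate_var(
    A: np.ndarray,
    n: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate a stable VAR process x_t = Σ_k A[k] x_{t-k-1} + e_t.

    Raises if the companion spectral radius is >= 1.
    """
    from .biomarkers import mvar_spectral_radius

    rho = mvar_spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(f"unstable AR coupling coefficients (spectral radius {rho:.3f})")
    p, c, _ = A.shape
    total = n + burn_in
    x = np.zeros((c, total))
    e = rng.standard_normal((c, total)) * noise_sd
    for t in range(p, total):
        acc = e[:, t].copy()
        for k in range(p):
            acc += A[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn_in:]


def _biphasic_artifact(fs: float, amplitude: float) -> np.ndarray:
    """Saccade-like transient: a 50-ms biphasic deflection followed by a
    300-ms low-frequency (2 Hz) drift burst."""
    n_spike = int(round(0.05 * fs))
    t = np.arange(n_spike) / fs
    spike = amplitude * np.sin(2 * np.pi * t / 0.05) * np.hanning(n_spike)
    n_drift = int(round(0.3 * fs))
    td = np.arange(n_drift) / fs
    drift = 0.6 * amplitude * np.sin(2 * np.pi * 2.0 * td) * np.hanning(n_drift)
    out = np.zeros(n_spike + n_drift)
    out[:n_spike] = spike
    out[n_spike:] += drift
    return out


#: relative ocular-artifact pickup per channel; ocular potentials fall
#: off steeply with distance from the orbits, so the lateral frontal
#: pair dominates and the medial/midline sites see only a fraction
ARTIFACT_MIXING = {
    "LFL": 1.0,
    "RFL": 0.9,
    "LFM": 0.3,
    "RFM": 0.28,
    "FZ": 0.12,
    "CZ": 0.05,
    "LT": 0.04,
    "RT": 0.04,
    "LO": 0.02,
    "RO": 0.02,
}


def _draw_delay_ms(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal delay draw truncated below at 500 ms."""
    while True:
        d = rng.normal(mean, sd)
        if d >= 500.0:
            return float(d)


def _fatigue_trajectory(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    g = -2.0
    out = np.empty(cfg.n_trials)
    for k in range(cfg.n_trials):
        g += cfg.fatigue_slope + rng.normal(0.0, cfg.fatigue_walk_sd)
        out[k] = 1.0 / (1.0 + np.exp(-g))
    return out


def _solve_intercept(fatigue: np.ndarray, gain: float, target: float) -> float:
    """Intercept a such that mean logistic(a + gain*f_k) = target (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        mean_p = np.mean(1.0 / (1.0 + np.exp(-(mid + gain * fatigue))))
        if mean_p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# session generation


def generate_session(
    config: GeneratorConfig | None = None,
    session_id: str = "synthetic",
) -> tuple[SessionRecording, list[TrialEvent], GroundTruth]:
    """Generate one session: continuous 10-channel signal, trial events,
    and the ground-truth record of injected effects."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    layout = ChannelLayout()
    fs = cfg.fs
    es = cfg.effect_sizes

    fatigue = _fatigue_trajectory(cfg, rng)
    a = cfg.outcome_intercept
    if cfg.target_incorrect_fraction is not None:
        a = _solve_intercept(fatigue, cfg.outcome_gain, cfg.target_incorrect_fraction)
    p_inc = 1.0 / (1.0 + np.exp(-(a + cfg.outcome_gain * fatigue)))
    incorrect = rng.random(cfg.n_trials) < p_inc

    # trial timeline
    events: list[TrialEvent] = []
    cursor = 1.0
    for k in range(cfg.n_trials):
        t_start = cursor
        t_target = t_start + rng.uniform(1.0, 1.4)
        t_cue = t_target + 1.0
        delay_ms = _draw_delay_ms(rng, cfg.delay_mean_ms, cfg.delay_sd_ms)
        t_go = t_cue + delay_ms / 1000.0
        if incorrect[k]:
            outcome = "incorrect"
            # half the errors are premature touches, half fixation breaks
            t_resp = (
                t_cue + rng.uniform(0.3, max(0.31, delay_ms / 1000.0))
                if rng.random() < 0.5
                else None
            )
        else:
            outcome = "correct"
            t_resp = t_go + rng.uniform(0.25, 0.45)
        events.append(
            TrialEvent(
                trial_id=k,
                t_trial_start=t_start,
                t_target_on=t_target,
                t_delay_cue=t_cue,
                t_go=t_go,
                t_response=t_resp,
                delay_ms=delay_ms,
                outcome=outcome,
                target_location=int(rng.integers(1, 10)),
            )
        )
        cursor = t_go + 1.5

    n_samples = int(round((cursor + 1.0) * fs))
    data = np.empty((layout.n_channels, n_samples))
    sos_hp = (
        sps.butter(2, cfg.hp_cutoff_hz, btype="highpass", fs=fs, output="sos")
        if cfg.hp_cutoff_hz > 0
        else None
    )
    burst_freqs = np.linspace(7.0, 24.0, layout.n_channels)
    t_axis = np.arange(n_samples) / fs
    for ci in range(layout.n_channels):
        bg = one_over_f_noise(n_samples, cfg.background_alpha, cfg.background_rms, rng)
        for f_osc, amp in cfg.oscillations:
            # narrowband noise with a bursty envelope, not a pure tone:
            # rhythms wax and wane, never share a constant phase across
            # channels, and the bursts make each source super-Gaussian
            # (hence ICA-separable)
            sos_osc = sps.butter(
                2, [max(0.5, f_osc - 1.5), f_osc + 1.5], btype="bandpass",
                fs=fs, output="sos",
            )
            osc = sps.sosfilt(sos_osc, rng.standard_normal(n_samples))
            osc *= slow_envelope(n_samples, fs, 0.7, 1.0, rng)
            bg += osc * amp / max(np.sqrt(np.mean(osc**2)), 1e-12)
        # per-channel envelope depth spans 0.6-1.4x the configured SD, so
        # channels differ in their amplitude dynamics (and with it their
        # non-Gaussianity) as real electrodes do
        bg *= slow_envelope(
            n_samples, fs,
            cfg.amplitude_jitter_sd * (0.6 + 0.8 * ci / (layout.n_channels - 1)),
            cfg.amplitude_jitter_timescale_s, rng,
        )
        if cfg.burst_osc_rms > 0:
            env = slow_envelope(
                n_samples, fs, cfg.burst_env_sd, cfg.burst_env_timescale_s, rng
            )
            osc = np.sin(2 * np.pi * burst_freqs[ci] * t_axis + rng.uniform(0, 2 * np.pi))
            osc *= env
            bg += osc * cfg.burst_osc_rms / max(np.sqrt(np.mean(osc**2)), 1e-12)
        if cfg.gamma_osc_rms > 0:
            genv = slow_envelope(n_samples, fs, cfg.gamma_env_sd, 1.0, rng)
            gosc = np.sin(2 * np.pi * cfg.gamma_osc_freq * t_axis + rng.uniform(0, 2 * np.pi))
            gosc *= genv
            bg += gosc * cfg.gamma_osc_rms / max(np.sqrt(np.mean(gosc**2)), 1e-12)
        if sos_hp is not None:
            bg = sps.sosfiltfilt(sos_hp, bg)
        data[ci] = bg

    mixing = np.array([ARTIFACT_MIXING[ch] for ch in layout.names])

    lowfreq_idx = [layout.index(c) for c in cfg.lowfreq_channels]
    entropy_idx = [layout.index(c) for c in cfg.entropy_channels]
    src_idx = layout.index(cfg.coupling_pair[0])
    dst_idx = layout.index(cfg.coupling_pair[1])
    sos_lowfreq = sps.butter(4, [1.0, 10.0], btype="bandpass", fs=fs, output="sos")
    # the suppression band brackets the mid-gamma component and stays clear
    # of the 30-45 and 60-90 Hz band-power features
    sos_midgamma = sps.butter(
        4, [cfg.gamma_osc_freq - 5.0, cfg.gamma_osc_freq + 7.0],
        btype="bandpass", fs=fs, output="sos",
    )
    # alpha-band substitution: ~10 cycles per 1-s epoch give stable phase
    # estimates, unlike the delta band where a 1-s window holds 1-4 cycles
    sos_alpha = sps.butter(4, [8.0, 13.0], btype="bandpass", fs=fs, output="sos")

    for ev, is_inc in zip(events, incorrect):
        if not is_inc:
            # occasional intrusive saccades on correct trials too
            if es.artifact_amplitude > 0 and rng.random() < 0.3:
                _add_artifact(data, mixing, ev, rng, fs, es.artifact_amplitude, n=1)
            continue
        i0 = int(round(ev.t_delay_cue * fs))
        i1 = int(round(ev.t_go * fs))
        n_win = i1 - i0
        if n_win <= 0 or i1 > n_samples:
            continue
        taper = sps.windows.tukey(n_win, alpha=0.2)

        if es.lowfreq_power_gain > 0:
            for ci in lowfreq_idx:
                burst = sps.sosfiltfilt(sos_lowfreq, rng.standard_normal(n_win * 2))[
                    n_win // 2 : n_win // 2 + n_win
                ]
                burst *= (es.lowfreq_power_gain * 10.0) / max(
                    np.sqrt(np.mean(burst**2)), 1e-12
                )
                data[ci, i0:i1] += burst * taper

        if es.entropy_drop > 0:
            # drain the mid-gamma component: wavelet energy concentrates in
            # the slow subbands (entropy and mobility drop) while every
            # defined band-power feature is blind to 45-60 Hz
            w = min(0.95, 0.8 * es.entropy_drop)
            for ci in entropy_idx:
                pad = min(n_win, int(round(0.5 * fs)))
                j0, j1 = max(0, i0 - pad), min(n_samples, i1 + pad)
                mg = sps.sosfiltfilt(sos_midgamma, data[ci, j0:j1])[i0 - j0 : i0 - j0 + n_win]
                data[ci, i0:i1] -= w * mg * taper

        if es.coupling_gain > 0:
            # power-preserving alpha substitution: part of the target's
            # alpha activity is replaced by the source's lagged alpha, so
            # directed coherence and phase locking rise while band power
            # stays put
            w = min(0.95, 0.85 * es.coupling_gain)
            lag = 3  # samples (~6 ms conduction-like delay)
            pad = min(n_win, int(round(1.0 * fs)))
            j0, j1 = max(0, i0 - pad), min(n_samples, i1 + pad)
            d_src = sps.sosfiltfilt(sos_alpha, data[src_idx, j0:j1])
            d_dst = sps.sosfiltfilt(sos_alpha, data[dst_idx, j0:j1])
            s_src = d_src[i0 - j0 - lag : i0 - j0 - lag + n_win]
            s_dst = d_dst[i0 - j0 : i0 - j0 + n_win]
            rms_src = max(np.sqrt(np.mean(s_src**2)), 1e-12)
            rms_dst = np.sqrt(np.mean(s_dst**2))
            repl = (np.sqrt(1 - w**2) - 1) * s_dst + w * (rms_dst / rms_src) * s_src
            data[dst_idx, i0:i1] += repl * taper

        if es.artifact_amplitude > 0:
            # a storm of intrusive saccades accompanies broken fixation
            _add_artifact(
                data, mixing, ev, rng, fs, es.artifact_amplitude,
                n=2 + int(rng.poisson(3.0)),
            )

    effects: dict[str, dict] = {}
    if es.lowfreq_power_gain > 0:
        # additive slow power also raises broadband variance and the delta
        # envelope, and tilts the spectral balance that the entropy and
        # mobility statistics measure, on the same channels
        effects["lowfreq_power"] = {
            "families": [
                "delta", "theta", "hjorth_activity", "hjorth_mobility",
                "hjorth_complexity", "wavelet_entropy", "iaif",
            ],
            "channels": list(cfg.lowfreq_channels),
            "size": es.lowfreq_power_gain,
        }
    if es.entropy_drop > 0:
        # mid-gamma suppression concentrates wavelet energy into the slow
        # subbands and lowers the mean-frequency statistics
        effects["entropy"] = {
            "families": ["wavelet_entropy", "hjorth_mobility", "hjorth_complexity"],
            "channels": list(cfg.entropy_channels),
            "size": es.entropy_drop,
        }
    if es.coupling_gain > 0:
        # alpha substitution raises directed coherence, phase locking and
        # the leading spatial mode in that band, with no power change
        effects["coupling"] = {
            "families": ["pdc", "pli", "gc"],
            "band": "alpha",
            "pairs": [list(cfg.coupling_pair)],
            "channels": list(cfg.coupling_pair),
            "size": es.coupling_gain,
        }

    session = SessionRecording(
        data=data, fs=fs, channels=layout, session_id=session_id
    )
    truth = GroundTruth(
        fatigue=fatigue,
        p_incorrect=p_inc,
        effects=effects,
        artifact_mixing=mixing,
        seed=cfg.seed,
    )
    return session, events, truth


def _add_artifact(
    data: np.ndarray,
    mixing: np.ndarray,
    ev: TrialEvent,
    rng: np.random.Generator,
    fs: float,
    amplitude: float,
    n: int,
) -> None:
    """Place ``n`` ocular transients inside the trial's delay window."""
    wave = _biphasic_artifact(fs, amplitude)
    n_samples = data.shape[1]
    lo = int(round(ev.t_delay_cue * fs))
    hi = int(round(ev.t_go * fs)) - wave.size
    if hi <= lo:
        return
    for _ in range(n):
        start = int(rng.integers(lo, hi))
        stop = min(start + wave.size, n_samples)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[:, start:stop] += sign * np.outer(mixing, wave[: stop - start])


def generate_cohort(
    config: GeneratorConfig | None = None,
    n_sessions: int = 10,
    regime: str = "balanced",
) -> list[tuple[SessionRecording, list[TrialEvent], GroundTruth]]:
    """Generate a cohort of sessions emulating one subject.

    Per-session trial counts are drawn around ``config.n_trials`` (SD =
    n_trials/5, floor 40) and the outcome intercept is re-solved per
    session so the expected incorrect fraction matches the regime:
    ``balanced`` ≈ 0.52 or ``unbalanced`` ≈ 0.72, mirroring the two
    animals' mean correct/incorrect counts.
    """
    cfg = config or GeneratorConfig()
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; have {sorted(REGIMES)}")
    master = np.random.default_rng(cfg.seed)
    out = []
    for s in range(n_sessions):
        n_trials = max(40, int(round(master.normal(cfg.n_trials, cfg.n_trials / 5))))
        sess_cfg = replace(
            cfg,
            n_trials=n_trials,
            target_incorrect_fraction=REGIMES[regime],
            seed=int(master.integers(0, 2**31 - 1)),
        )
        session, events, truth = generate_session(sess_cfg, session_id=f"synth-{s:02d}")
        truth.regime = regime
        out.append((session, events, truth))
    return out
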