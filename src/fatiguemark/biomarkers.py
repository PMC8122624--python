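"""Spectrotemporal and connectivity biomarkers of vigilance state.

Seventeen feature families are computed per trial epoch:

* band power in eight canonical bands (delta ... high gamma, 1-200 Hz);
* wavelet entropy — Shannon entropy of the relative energies of a 4-level
  'db4' discrete wavelet decomposition; low values mean the energy is
  concentrated in few subbands (drowsy, slow-wave-dominated epochs);
* the three Hjorth parameters (activity, mobility, complexity);
* phase-amplitude coupling (PAC) between the phase of the 3-7 Hz rhythm
  and the amplitude envelope of 70-130 Hz activity, quantified by the
  entropy-based modulation index;
* instantaneous amplitude over delta, instantaneous frequency over the
  4-14 Hz theta-alpha range, and their ratio (IAIF, 3 features/channel);
* partial directed coherence (PDC) between all ordered channel pairs in
  the delta, theta, alpha and beta bands, from a fitted multivariate
  autoregressive (MVAR) model;
* the phase-locking index (PLI) between all unordered channel pairs in
  the same four bands — the modulus of the mean phase-difference phasor;
* global coherence (GC): ratio of the largest eigenvalue of the
  multichannel cross-spectral matrix to the sum of all eigenvalues.

``extract_features`` assembles the trials x features table with a registry
mapping every column to its family, channel(s) and band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .bands import (
    BAND_REGISTRY,
    CONNECTIVITY_BANDS,
    IA_BAND,
    IF_BAND,
    PAC_AMP_BAND,
    PAC_PHASE_BAND,
    POWER_BANDS,
    BandDefinition,
    get_band,
)
from .core import ChannelLayout, TrialEpoch

logger = logging.getLogger(__name__)

SPECTRAL_FAMILIES = tuple(b.name for b in POWER_BANDS)
HOST_FAMILIES = (
    "wavelet_entropy",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "pac",
    "pdc",
    "iaif",
    "pli",
    "gc",
)
ALL_FAMILIES = SPECTRAL_FAMILIES + HOST_FAMILIES

#: families computed from a single channel (used for per-electrode models)
SINGLE_CHANNEL_FAMILIES = SPECTRAL_FAMILIES + (
    "wavelet_entropy",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "pac",
    "iaif",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature extractor."""

    n_pac_bins: int = 18  # 20-degree phase bins
    mvar_order: int = 5
    entropy_wavelet: str = "db4"
    entropy_levels: int = 4
    entropy_include_approx: bool = True  # 4 details + approximation (K=5)
    gc_bands: tuple[str, ...] = tuple(b.name for b in POWER_BANDS)
    connectivity_bands: tuple[str, ...] = CONNECTIVITY_BANDS
    gc_n_tapers: int = 3
    edge_trim: float = 0.1  # fraction trimmed per edge for Hilbert measures


# ---------------------------------------------------------------------------
# filtering helpers


@lru_cache(maxsize=64)
def _bandpass_sos(f_lo: float, f_hi: float, fs: float):
    # 4th-order zero-phase Butterworth; applied forward-backward downstream
    return sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    sos = _bandpass_sos(band.f_lo, band.f_hi, fs)
    return sps.sosfiltfilt(sos, x, axis=-1)


def _interior(n: int, trim: float) -> slice:
    k = int(round(n * trim))
    return slice(k, n - k if n - k > k else n)


# ---------------------------------------------------------------------------
# single-channel features


def band_power(x: np.ndarray, band: str | BandDefinition, fs: float) -> float:
    """Band power (µV²) from a Hann-windowed Welch periodogram of the epoch,
    integrated over the half-open interval [f_lo, f_hi)."""
    b = get_band(band) if isinstance(band, str) else band
    if b.f_hi > fs / 2:
        raise ValueError(f"band {b.name} [{b.f_lo},{b.f_hi}) exceeds Nyquist {fs/2}")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 2 * fs / b.f_lo:
        logger.debug("band_power(%s): epoch shorter than 2 cycles of f_lo", b.name)
    freqs, psd = sps.welch(x, fs=fs, nperseg=n, window="hann", detrend="constant")
    mask = (freqs >= b.f_lo) & (freqs < b.f_hi)
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[..., mask], axis=-1).squeeze() * df)


def _multi_band_power(x: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """All eight band powers for a channels x samples block in one pass."""
    n = x.shape[-1]
    freqs, psd = sps.welch(x, fs=fs, nperseg=n, window="hann", detrend="constant")
    df = freqs[1] - freqs[0]
    out = {}
    for b in POWER_BANDS:
        mask = (freqs >= b.f_lo) & (freqs < b.f_hi)
        out[b.name] = psd[..., mask].sum(axis=-1) * df
    return out


def wavelet_relative_energies(
    x: np.ndarray,
    wavelet: str = "db4",
    levels: int = 4,
    include_approx: bool = True,
) -> np.ndarray:
    """Relative energies of the wavelet subbands (they sum to 1).

    With ``include_approx`` the approximation band is kept alongside the
    ``levels`` detail bands (energy conservation, K = levels + 1 values);
    without it only the detail energies are renormalized.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2**levels:
        raise ValueError(f"epoch too short for a {levels}-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])  # [approx, dL..d1]
    if not include_approx:
        energies = energies[1:]
    total = energies.sum()
    if total <= 0:
        raise ValueError("all-zero epoch: relative wavelet energies undefined")
    return energies / total


def entropy_from_distribution(p: np.ndarray) -> float:
    """Shannon entropy (nats) with the p·ln p → 0 convention at p = 0."""
    p = np.asarray(p, dtype=np.float64)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def wavelet_entropy(
    x: np.ndarray, config: FeatureConfig | None = None
) -> float:
    """Shannon entropy of the relative wavelet energies, in [0, ln K]."""
    cfg = config or FeatureConfig()
    p = wavelet_relative_energies(
        x, cfg.entropy_wavelet, cfg.entropy_levels, cfg.entropy_include_approx
    )
    return entropy_from_distribution(p)


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    Activity is the signal variance; mobility sqrt(var(Δy)/var(y)) with Δ
    the first difference (a per-sample mean-frequency proxy); complexity is
    the mobility of Δy over the mobility of y.  A constant signal has
    activity 0 and undefined mobility/complexity (returned as NaN, treated
    as missing downstream).
    """
    x = np.asarray(x, dtype=np.float64)
    v0 = float(np.var(x))
    if v0 <= 0:
        return 0.0, float("nan"), float("nan")
    d1 = np.diff(x)
    v1 = float(np.var(d1))
    mob = np.sqrt(v1 / v0)
    v2 = float(np.var(np.diff(d1)))
    if v1 <= 0:
        return v0, float(mob), float("nan")
    comp = np.sqrt(v2 / v1) / mob
    return v0, float(mob), float(comp)


def modulation_index_from_distribution(p: np.ndarray) -> float:
    """Entropy-based modulation index (ln N − H(P))/ln N of a normalized
    phase-binned amplitude distribution P; 0 for uniform, 1 for a point
    mass."""
    p = np.asarray(p, dtype=np.float64)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 phase bins")
    mi = (np.log(n) - entropy_from_distribution(p)) / np.log(n)
    return float(min(1.0, max(0.0, mi)))


def pac_mi(
    x: np.ndarray,
    fs: float,
    n_bins: int = 18,
    phase_band: BandDefinition = PAC_PHASE_BAND,
    amp_band: BandDefinition = PAC_AMP_BAND,
    edge_trim: float = 0.1,
) -> float:
    """Phase-amplitude coupling modulation index of one channel.

    Phase comes from the analytic signal of the 3-7 Hz filtered trace,
    amplitude from the envelope of the 70-130 Hz trace; the mean envelope
    per phase bin, normalized to sum 1, is scored by its normalized
    entropy deficit.  Returns a value in [0, 1].
    """
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    x = np.asarray(x, dtype=np.float64)
    phase = np.angle(sps.hilbert(bandpass(x, phase_band, fs)))
    amp = np.abs(sps.hilbert(bandpass(x, amp_band, fs)))
    sl = _interior(x.shape[-1], edge_trim)
    return _mi_from_phase_amp(phase[sl], amp[sl], n_bins)


def _mi_from_phase_amp(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> float:
    bins = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    return modulation_index_from_distribution(mean_amp / total)


def ia_if(
    x: np.ndarray, fs: float, edge_trim: float = 0.1
) -> tuple[float, float, float]:
    """Mean instantaneous amplitude (delta band), mean instantaneous
    frequency (4-14 Hz), and their ratio.

    IA is the modulus of the analytic signal of the delta-filtered trace;
    IF is the time derivative of the unwrapped analytic phase of the
    theta-alpha trace, in Hz.  Both are averaged over the interior of the
    epoch (10% trimmed per edge).  A non-positive mean IF makes the ratio
    undefined (NaN).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    sl = _interior(n, edge_trim)
    ia = np.abs(sps.hilbert(bandpass(x, IA_BAND, fs)))[sl]
    phase = np.unwrap(np.angle(sps.hilbert(bandpass(x, IF_BAND, fs))))
    inst_f = np.diff(phase) * fs / (2 * np.pi)
    mean_ia = float(ia.mean())
    mean_if = float(inst_f[sl].mean())
    ratio = mean_ia / mean_if if mean_if > 0 else float("nan")
    return mean_ia, mean_if, ratio


# ---------------------------------------------------------------------------
# connectivity features


def fit_mvar(
    x: np.ndarray, order: int, safety: int = 2, allow_rank_deficient: bool = False
) -> np.ndarray:
    """Least-squares fit of an MVAR(p) model to a channels x samples block.

    Returns coefficient matrices A with shape (p, C, C) such that
    x_t ≈ Σ_k A[k] x_{t-k-1}.  Requires enough observations per equation
    (safety × C × p).  A rank-deficient regressor matrix raises by
    default; with ``allow_rank_deficient`` the minimum-norm least-squares
    solution is returned instead — ICA-cleaned sessions are rank-reduced
    by construction (one rank per removed component), and the feature
    pipeline uses this mode.
    """
    x = np.asarray(x, dtype=np.float64)
    c, n = x.shape
    n_params = c * order
    if n - order < safety * n_params:
        raise ValueError(
            f"epoch of {n} samples too short for MVAR order {order} on {c} "
            f"channels (need > {order + safety * n_params})"
        )
    # regressors: lagged copies, most recent lag first
    Y = x[:, order:].T  # (n-p, C)
    Z = np.hstack([x[:, order - k - 1 : n - k - 1].T for k in range(order)])
    coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)  # (C*p, C)
    if rank < n_params and not allow_rank_deficient:
        raise ValueError(f"singular MVAR regression (rank {rank} < {n_params})")
    return coef.T.reshape(c, order, c).transpose(1, 0, 2)


def mvar_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of MVAR coefficients
    (< 1 for a stable process)."""
    p, c, _ = A.shape
    comp = np.zeros((c * p, c * p))
    comp[:c] = A.transpose(1, 0, 2).reshape(c, c * p)
    if p > 1:
        comp[c:, :-c] = np.eye(c * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def pdc_from_coefficients(
    A: np.ndarray, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Squared partial directed coherence from MVAR coefficients.

    For B(f) = I − Σ_k A_k e^{−i2πf(k+1)/fs}, PDC²_ij(f) = |B_ij|² /
    (b_j* b_j) where b_j is the j-th column; column j is the source, row i
    the target, and Σ_i PDC²_ij(f) = 1 at every frequency.  Returns an
    array (n_freqs, C, C).
    """
    p, c, _ = A.shape
    freqs = np.asarray(freqs, dtype=np.float64)
    k = np.arange(1, p + 1)
    # phase factors (n_freqs, p)
    ph = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    B = np.eye(c)[None] - np.einsum("fk,kij->fij", ph, A.astype(complex))
    num = np.abs(B) ** 2
    denom = num.sum(axis=1, keepdims=True)  # column norms b_j* b_j
    return num / denom


def pdc(
    x: np.ndarray,
    fs: float,
    band: str | BandDefinition,
    order: int = 5,
    freq_step: float = 1.0,
) -> np.ndarray:
    """Band-averaged squared PDC matrix of a channels x samples epoch.

    Entry [i, j] is the mean over the band's 1-Hz frequency grid of the
    squared PDC from source channel j to target channel i.  The diagonal
    is retained here; feature assembly keeps only i ≠ j.
    """
    b = get_band(band) if isinstance(band, str) else band
    A = fit_mvar(x, order)
    freqs = b.frequencies(freq_step)
    return pdc_from_coefficients(A, fs, freqs).mean(axis=0)


def pli(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: str | BandDefinition,
    edge_trim: float = 0.1,
) -> float:
    """Phase-locking index |T⁻¹ Σ_t exp(iΔθ_t)| of two channels in a band.

    Δθ is the difference of the Hilbert phases of the band-filtered
    traces, edge-trimmed; 1 for a fixed lag, ~T_eff^{-1/2} for unrelated
    signals.
    """
    b = get_band(band) if isinstance(band, str) else band
    px = np.angle(sps.hilbert(bandpass(np.asarray(x, float), b, fs)))
    py = np.angle(sps.hilbert(bandpass(np.asarray(y, float), b, fs)))
    sl = _interior(px.shape[-1], edge_trim)
    return float(np.abs(np.mean(np.exp(1j * (px[sl] - py[sl])))))


def _phase_block(x: np.ndarray, fs: float, band_names, edge_trim: float):
    """Hilbert phases per band for a channels x samples block (shared by the
    pairwise PLI assembly)."""
    phases = {}
    for name in band_names:
        filt = bandpass(x, get_band(name), fs)
        phases[name] = np.angle(sps.hilbert(filt, axis=-1))
    return phases


def global_coherence(
    x: np.ndarray,
    fs: float,
    band: str | BandDefinition,
    n_tapers: int = 3,
    seg_seconds: float = 1.0,
) -> float:
    """Global coherence of a multichannel epoch in one band.

    The cross-spectral matrix at each frequency is averaged over DPSS
    multitaper estimates (3 tapers, NW = 2) on 50%-overlapping segments of
    about one second; GC(f) = λ_max / Σλ of that Hermitian matrix, and the
    band value is the mean over the band's frequency bins.  Bounded in
    [1/C, 1] for C channels; ≈1 when one spatial mode dominates.
    """
    b = get_band(band) if isinstance(band, str) else band
    gc = _global_coherence_spectrum(x, fs, n_tapers, seg_seconds)
    freqs, gcf = gc
    mask = (freqs >= b.f_lo) & (freqs < b.f_hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {b.name}")
    return float(gcf[mask].mean())


def _global_coherence_spectrum(
    x: np.ndarray, fs: float, n_tapers: int = 3, seg_seconds: float = 1.0
):
    x = np.asarray(x, dtype=np.float64)
    c, n = x.shape
    if c < 2:
        raise ValueError("global coherence needs at least 2 channels")
    nper = min(n, int(round(seg_seconds * fs)))
    step = max(1, nper // 2)
    starts = list(range(0, n - nper + 1, step))
    tapers = sps.windows.dpss(nper, NW=2, Kmax=n_tapers)  # (K, nper)
    nfft = nper
    segs = np.stack([x[:, s : s + nper] for s in starts])  # (S, C, nper)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    # tapered FFTs: (S, K, C, F)
    tf = np.fft.rfft(segs[:, None, :, :] * tapers[None, :, None, :], n=nfft, axis=-1)
    # cross-spectral matrices per frequency, averaged over segments and tapers
    S = np.einsum("skcf,skdf->fcd", tf, np.conj(tf)) / (len(starts) * n_tapers)
    evals = np.linalg.eigvalsh(S)  # (F, C), ascending
    tot = evals.sum(axis=1)
    tot[tot <= 0] = np.finfo(float).tiny
    gcf = evals[:, -1] / tot
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, gcf


# ---------------------------------------------------------------------------
# feature table assembly


@dataclass(frozen=True)
class FeatureInfo:
    family: str
    channels: tuple[str, ...]  # one name, an ordered/unordered pair, or all
    band: str | None = None


@dataclass
class FeatureTable:
    """Trials x named-features matrix with labels and a family registry.

    Labels are 1 for the positive class (incorrect trials), 0 for correct.
    """

    values: pd.DataFrame
    labels: np.ndarray
    registry: dict[str, FeatureInfo]
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trial_ids is None:
            self.trial_ids = np.asarray(self.values.index)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and feature rows disagree in length")
        unknown = [c for c in self.values.columns if c not in self.registry]
        if unknown:
            raise ValueError(f"columns missing from registry: {unknown[:5]} ...")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def family_of(self, column: str) -> str:
        return self.registry[column].family

    def columns_for_condition(self, condition: str) -> list[str]:
        """Candidate columns for a feature-set condition: ``spectral`` (the
        eight band powers), ``HOST`` (everything else), or ``combined``."""
        if condition == "spectral":
            fams = set(SPECTRAL_FAMILIES)
        elif condition == "HOST":
            fams = set(HOST_FAMILIES)
        elif condition == "combined":
            fams = set(ALL_FAMILIES)
        else:
            raise ValueError(
                f"unknown condition {condition!r}; expected spectral|HOST|combined"
            )
        return [c for c in self.values.columns if self.registry[c].family in fams]

    def columns_for_channel(self, channel: str) -> list[str]:
        """Single-channel feature columns of one electrode (connectivity and
        global families excluded)."""
        return [
            c
            for c, info in self.registry.items()
            if info.family in SINGLE_CHANNEL_FAMILIES and info.channels == (channel,)
        ]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            values=self.values[columns].copy(),
            labels=self.labels.copy(),
            registry={c: self.registry[c] for c in columns},
            trial_ids=self.trial_ids.copy(),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a sidecar ``<path>.registry.json``."""
        path = Path(path)
        out = self.values.copy()
        out.insert(0, "outcome", np.where(self.labels == 1, "incorrect", "correct"))
        out.to_csv(path, index_label="trial_id")
        reg = {
            c: {"family": i.family, "channels": list(i.channels), "band": i.band}
            for c, i in self.registry.items()
        }
        Path(str(path) + ".registry.json").write_text(json.dumps(reg, indent=0))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="trial_id")
        labels = (df.pop("outcome") == "incorrect").astype(int).to_numpy()
        reg_raw = json.loads(Path(str(path) + ".registry.json").read_text())
        registry = {
            c: FeatureInfo(v["family"], tuple(v["channels"]), v["band"])
            for c, v in reg_raw.items()
        }
        return cls(values=df, labels=labels, registry=registry)


def _epoch_feature_row(
    sig: np.ndarray, fs: float, layout: ChannelLayout, cfg: FeatureConfig
) -> dict[str, float]:
    names = layout.names
    n = sig.shape[-1]
    sl = _interior(n, cfg.edge_trim)
    row: dict[str, float] = {}

    powers = _multi_band_power(sig, fs)
    for bname, vals in powers.items():
        for ci, ch in enumerate(names):
            row[f"{bname}.{ch}"] = float(vals[ci])

    # PAC and IA/IF Hilbert transforms, batched over channels
    pac_phase = np.angle(sps.hilbert(bandpass(sig, PAC_PHASE_BAND, fs), axis=-1))
    pac_amp = np.abs(sps.hilbert(bandpass(sig, PAC_AMP_BAND, fs), axis=-1))
    ia_env = np.abs(sps.hilbert(bandpass(sig, IA_BAND, fs), axis=-1))
    if_phase = np.unwrap(
        np.angle(sps.hilbert(bandpass(sig, IF_BAND, fs), axis=-1)), axis=-1
    )
    inst_freq = np.diff(if_phase, axis=-1) * fs / (2 * np.pi)

    for ci, ch in enumerate(names):
        row[f"wavelet_entropy.{ch}"] = wavelet_entropy(sig[ci], cfg)
        act, mob, comp = hjorth(sig[ci])
        row[f"hjorth_activity.{ch}"] = act
        row[f"hjorth_mobility.{ch}"] = mob
        row[f"hjorth_complexity.{ch}"] = comp
        row[f"pac.{ch}"] = _mi_from_phase_amp(
            pac_phase[ci, sl], pac_amp[ci, sl], cfg.n_pac_bins
        )
        mean_ia = float(ia_env[ci, sl].mean())
        mean_if = float(inst_freq[ci, sl].mean())
        row[f"iaif.{ch}.ia"] = mean_ia
        row[f"iaif.{ch}.if"] = mean_if
        row[f"iaif.{ch}.ratio"] = mean_ia / mean_if if mean_if > 0 else float("nan")

    A = fit_mvar(sig, cfg.mvar_order, allow_rank_deficient=True)
    for bname in cfg.connectivity_bands:
        band = get_band(bname)
        M = pdc_from_coefficients(A, fs, band.frequencies()).mean(axis=0)
        for j, src in enumerate(names):
            for i, dst in enumerate(names):
                if i == j:
                    continue
                row[f"pdc.{src}→{dst}.{bname}"] = float(M[i, j])

    phases = _phase_block(sig, fs, cfg.connectivity_bands, cfg.edge_trim)
    sl = _interior(sig.shape[-1], cfg.edge_trim)
    for bname in cfg.connectivity_bands:
        ph = phases[bname][:, sl]
        phasors = np.exp(1j * ph)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                val = np.abs(np.mean(phasors[a] * np.conj(phasors[b])))
                row[f"pli.{names[a]}–{names[b]}.{bname}"] = float(val)

    freqs, gcf = _global_coherence_spectrum(sig, fs, cfg.gc_n_tapers)
    for bname in cfg.gc_bands:
        band = get_band(bname)
        mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
        row[f"gc.all.{bname}"] = float(gcf[mask].mean())

    return row


def _build_registry(layout: ChannelLayout, cfg: FeatureConfig) -> dict[str, FeatureInfo]:
    names = layout.names
    reg: dict[str, FeatureInfo] = {}
    for bname in SPECTRAL_FAMILIES:
        for ch in names:
            reg[f"{bname}.{ch}"] = FeatureInfo(bname, (ch,), bname)
    for ch in names:
        reg[f"wavelet_entropy.{ch}"] = FeatureInfo("wavelet_entropy", (ch,))
        reg[f"hjorth_activity.{ch}"] = FeatureInfo("hjorth_activity", (ch,))
        reg[f"hjorth_mobility.{ch}"] = FeatureInfo("hjorth_mobility", (ch,))
        reg[f"hjorth_complexity.{ch}"] = FeatureInfo("hjorth_complexity", (ch,))
        reg[f"pac.{ch}"] = FeatureInfo("pac", (ch,))
        for sub in ("ia", "if", "ratio"):
            reg[f"iaif.{ch}.{sub}"] = FeatureInfo("iaif", (ch,))
    for bname in cfg.connectivity_bands:
        for src in names:
            for dst in names:
                if src != dst:
                    reg[f"pdc.{src}→{dst}.{bname}"] = FeatureInfo(
                        "pdc", (src, dst), bname
                    )
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                reg[f"pli.{names[a]}–{names[b]}.{bname}"] = FeatureInfo(
                    "pli", (names[a], names[b]), bname
                )
    for bname in cfg.gc_bands:
        reg[f"gc.all.{bname}"] = FeatureInfo("gc", names, bname)
    return reg


def extract_features(
    epochs: list[TrialEpoch],
    config: FeatureConfig | None = None,
    layout: ChannelLayout | None = None,
) -> FeatureTable:
    """Compute the full feature table for a list of equal-length epochs.

    Degenerate values (constant-signal Hjorth, non-positive mean IF) are
    left as NaN; the classifier imputes them with training-fold medians so
    no test-fold statistic leaks into training.  A column with no finite
    value at all raises, naming the column.
    """
    cfg = config or FeatureConfig()
    layout = layout or ChannelLayout()
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    outcomes = {e.outcome for e in epochs}
    if outcomes != {"correct", "incorrect"}:
        raise ValueError(f"need both outcome classes, got {sorted(outcomes)}")
    rows = []
    for ep in epochs:
        rows.append(_epoch_feature_row(ep.signal, ep.fs, layout, cfg))
    df = pd.DataFrame(rows, index=[e.trial_id for e in epochs])
    registry = _build_registry(layout, cfg)
    df = df[[c for c in registry if c in df.columns]]
    all_nan = [c for c in df.columns if not np.isfinite(df[c]).any()]
    if all_nan:
        raise ValueError(f"feature columns entirely missing: {all_nan}")
    labels = np.array([1 if e.outcome == "incorrect" else 0 for e in epochs])
    return FeatureTable(values=df, labels=labels, registry=registry)


def mvar_order_scan(
    x: np.ndarray, fs: float, orders=range(1, 11)
) -> pd.DataFrame:
    """AIC of MVAR fits across model orders, for choosing the PDC order on a
    new dataset.  Returns a DataFrame with columns order and aic."""
    x = np.asarray(x, dtype=np.float64)
    c, n = x.shape
    recs = []
    for p in orders:
        try:
            A = fit_mvar(x, p)
        except ValueError:
            continue
        pred = np.zeros((c, n - p))
        for k in range(p):
            pred += A[k] @ x[:, p - k - 1 : n - k - 1]
        resid = x[:, p:] - pred
        sigma = np.cov(resid)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        n_eff = n - p
        aic = n_eff * logdet + 2 * p * c * c
        recs.append({"order": p, "aic": aic})
    return pd.DataFrame(recs)
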