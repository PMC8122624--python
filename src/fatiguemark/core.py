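"""Core data model: sessions, trial events, and epoch extraction.

A recording session is a 10-channel continuous ECoG signal sampled at
508.6 Hz, with electrodes over left/right occipital (LO, RO), temporal
(LT, RT), lateral/medial frontal (LFL, LFM, RFL, RFM) and midline (FZ, CZ)
sites.  Each trial of the vigilance task is described by a row of event
times (trial start, target onset, delay-cue onset, GO cue, response) plus
the behavioural outcome (correct / incorrect).

Conventions used throughout the package:

* event times are seconds from session start, stored as floats;
* sample indices are ``round(t * fs)``, 0-based;
* sample windows are half-open ``[start, start + n)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical channel order for the 10-electrode array.
DEFAULT_CHANNELS = ("LO", "RO", "LT", "RT", "LFL", "LFM", "RFL", "RFM", "FZ", "CZ")

#: Default sampling rate in Hz (hardware rate after down-sampling).
DEFAULT_FS = 508.6

#: The three evaluation periods of a trial.
PERIODS = ("pre_target", "target", "delay")

#: Allowed epoch lengths in seconds.
WINDOWS = (0.5, 1.0)


class ValidationError(ValueError):
    """Raised when a session or event table violates its invariants."""


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered electrode names plus the frontal / artifact-reference subsets.

    ``artifact_reference_set`` names the two channels (LFL, RFL) whose raw
    traces serve as the reference for identifying ocular-artifact ICA
    components; both lie in the frontal group closest to the eyes.
    """

    names: tuple[str, ...] = DEFAULT_CHANNELS
    frontal_set: frozenset[str] = frozenset({"LFL", "LFM", "RFL", "RFM"})
    artifact_reference_set: frozenset[str] = frozenset({"LFL", "RFL"})

    def __post_init__(self) -> None:
        if len(self.names) != 10 or len(set(self.names)) != 10:
            raise ValidationError(
                f"channel layout needs 10 unique names, got {self.names}"
            )
        if not self.artifact_reference_set <= self.frontal_set:
            raise ValidationError("artifact reference channels must be frontal")
        if not self.frontal_set <= set(self.names):
            raise ValidationError("frontal channels must be part of the layout")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Row index of channel ``name`` in the data matrix."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.names}") from None


@dataclass
class SessionRecording:
    """Continuous multichannel recording (µV) with its layout and rate."""

    data: np.ndarray  # channels x samples, float64 µV
    fs: float = DEFAULT_FS
    channels: ChannelLayout = field(default_factory=ChannelLayout)
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.channels.n_channels:
            raise ValidationError(
                f"data must be {self.channels.n_channels} x samples, "
                f"got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("session data contains non-finite samples")
        # the 100-200 Hz band must sit below Nyquist
        if self.fs <= 2 * 200.0:
            raise ValidationError(f"fs={self.fs} cannot support the 100-200 Hz band")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def copy(self) -> "SessionRecording":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class TrialEvent:
    """Timing and outcome of one vigilance-task trial.

    All times are seconds from session start.  ``t_response`` is None for
    trials without a registered touch (e.g. fixation breaks).
    """

    trial_id: int
    t_trial_start: float
    t_target_on: float
    t_delay_cue: float
    t_go: float
    outcome: str  # "correct" | "incorrect"
    t_response: float | None = None
    delay_ms: float | None = None
    target_location: int = 1

    def __post_init__(self) -> None:
        if self.outcome not in ("correct", "incorrect"):
            raise ValidationError(
                f"trial {self.trial_id}: outcome {self.outcome!r} not in "
                "{'correct', 'incorrect'}"
            )
        if not (self.t_trial_start <= self.t_target_on < self.t_delay_cue < self.t_go):
            raise ValidationError(
                f"trial {self.trial_id}: event times out of order "
                f"(start={self.t_trial_start}, target={self.t_target_on}, "
                f"delay_cue={self.t_delay_cue}, go={self.t_go})"
            )
        if self.delay_ms is not None and self.delay_ms <= 0:
            raise ValidationError(f"trial {self.trial_id}: delay_ms must be > 0")
        if not 1 <= int(self.target_location) <= 9:
            raise ValidationError(
                f"trial {self.trial_id}: target_location must be 1-9"
            )


@dataclass(frozen=True)
class TrialEpoch:
    """A fixed-length channels x samples slice of one trial."""

    signal: np.ndarray
    period: str
    window_s: float
    outcome: str
    trial_id: int
    fs: float = DEFAULT_FS

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def sample_index(t: float, fs: float) -> int:
    """Sample index of time ``t`` (seconds): round(t * fs), the one mapping
    between the time and index domains used everywhere in the package."""
    return int(round(t * fs))


def window_n_samples(window_s: float, fs: float) -> int:
    return int(round(window_s * fs))


def validate_events(
    events: list[TrialEvent], session: SessionRecording
) -> list[TrialEvent]:
    """Check event times against the recording length.

    Raises ValidationError naming the first offending trial whose anchor
    times fall beyond the end of the recording.
    """
    dur = session.duration_s
    for ev in events:
        t_max = max(ev.t_go, ev.t_response or 0.0)
        if t_max > dur:
            raise ValidationError(
                f"trial {ev.trial_id}: event time {t_max:.3f} s beyond recording "
                f"end {dur:.3f} s"
            )
    return events


def _epoch_start(ev: TrialEvent, period: str, window_s: float, fs: float) -> int:
    if period == "delay":
        return sample_index(ev.t_delay_cue, fs)
    if period == "target":
        return sample_index(ev.t_target_on, fs)
    if period == "pre_target":
        # fixed-length window ending at target onset, so all epochs share a length
        return sample_index(ev.t_target_on, fs) - window_n_samples(window_s, fs)
    raise ValidationError(f"unknown period {period!r}; expected one of {PERIODS}")


def extract_epochs(
    session: SessionRecording,
    events: list[TrialEvent],
    period: str = "delay",
    window_s: float = 1.0,
) -> list[TrialEpoch]:
    """Slice one fixed-length epoch per trial for a given evaluation period.

    Period anchors: ``delay`` starts at the delay-cue onset, ``target`` at
    target onset (analysis window 1 s in the original protocol, 0.5 s also
    accepted), ``pre_target`` ends at target onset.  Trials whose window
    falls outside the recording are dropped; the count is logged.

    Epochs are pure slices of the session matrix (copied), so every epoch
    sample equals the corresponding session sample exactly.
    """
    if period not in PERIODS:
        raise ValidationError(f"unknown period {period!r}; expected one of {PERIODS}")
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    n = window_n_samples(window_s, session.fs)
    epochs: list[TrialEpoch] = []
    n_dropped = 0
    for ev in events:
        start = _epoch_start(ev, period, window_s, session.fs)
        stop = start + n
        if start < 0 or stop > session.n_samples:
            n_dropped += 1
            continue
        epochs.append(
            TrialEpoch(
                signal=session.data[:, start:stop].copy(),
                period=period,
                window_s=window_s,
                outcome=ev.outcome,
                trial_id=ev.trial_id,
                fs=session.fs,
            )
        )
    if n_dropped:
        logger.info(
            "extract_epochs(%s, %.1fs): dropped %d/%d trials overrunning the recording",
            period,
            window_s,
            n_dropped,
            len(events),
        )
    return epochs
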