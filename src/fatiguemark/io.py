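"""Readers and writers for session signals and trial-event tables.

Two signal containers are supported:

* an HDF5 container (datasets ``/data`` float64 channels x samples in µV,
  ``/fs`` scalar Hz, ``/channels`` string array) — lossless, the native
  format of this package;
* 16-bit EDF for interchange with clinical/electrophysiology toolchains.
  Writing uses this package's EDF encoder; reading goes through MNE.
  EDF quantizes to 16 bits over the per-channel amplitude range and pads
  the final data record, so the EDF round trip is lossy by design.

Events travel as a TSV with the fixed header
``trial_id  t_trial_start  t_target_on  t_delay_cue  t_go  t_response
delay_ms  outcome  target_location``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    ChannelLayout,
    SessionRecording,
    TrialEvent,
    ValidationError,
    validate_events,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = (
    "trial_id",
    "t_trial_start",
    "t_target_on",
    "t_delay_cue",
    "t_go",
    "t_response",
    "delay_ms",
    "outcome",
    "target_location",
)


# ---------------------------------------------------------------------------
# HDF5 container


def write_session_h5(session: SessionRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=session.data)
        f.create_dataset("fs", data=float(session.fs))
        f.create_dataset(
            "channels", data=np.array(session.channels.names, dtype="S8")
        )
        f.attrs["session_id"] = session.session_id


def read_session_h5(path: str | Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=np.float64)
        fs = float(np.asarray(f["fs"]))
        names = [n.decode() for n in np.asarray(f["channels"])]
        session_id = str(f.attrs.get("session_id", Path(path).stem))
    data = _reorder_channels(data, names)
    return SessionRecording(data=data, fs=fs, session_id=session_id)


def _reorder_channels(data: np.ndarray, names: list[str]) -> np.ndarray:
    """Normalize rows to the canonical layout order, naming any absentee."""
    layout = ChannelLayout()
    order = []
    for want in layout.names:
        if want not in names:
            raise ValidationError(f"missing channel {want!r} in file (has {names})")
        order.append(names.index(want))
    return data[order]


# ---------------------------------------------------------------------------
# EDF (16-bit)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _record_duration(fs: float) -> tuple[float, int]:
    """Smallest record duration (in 0.5-s steps, ≤ 30 s) holding an integer
    number of samples at ``fs``; EDF stores samples per record as an int."""
    for half_steps in range(1, 61):
        dur = half_steps / 2.0
        spr = fs * dur
        if abs(spr - round(spr)) < 1e-9:
            return dur, int(round(spr))
    raise ValidationError(f"cannot express fs={fs} Hz as integer samples per record")


def write_session_edf(session: SessionRecording, path: str | Path) -> None:
    """Encode the session as EDF, one signal per channel, int16 data records.

    The last record is zero-padded; readers therefore see the length rounded
    up to a whole record.
    """
    dur, spr = _record_duration(session.fs)
    n_rec = math.ceil(session.n_samples / spr)
    n_sig = session.channels.n_channels

    phys_min, phys_max, scaled = [], [], []
    dmin, dmax = -32768, 32767
    for row in session.data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (dmax - dmin) / (hi - lo)
        dig = np.round((row - lo) * gain + dmin).astype(np.int16)
        padded = np.zeros(n_rec * spr, dtype=np.int16)
        padded[: row.size] = dig
        scaled.append(padded)

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(session.session_id, 80)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (1 + n_sig), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(f"{dur:g}", 8)
    hdr += _edf_field(n_sig, 4)

    def sig_block(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    names = session.channels.names
    hdr += sig_block(names, 16)  # labels
    hdr += sig_block(["ECoG"] * n_sig, 80)  # transducer
    hdr += sig_block(["uV"] * n_sig, 8)  # physical dimension
    hdr += sig_block([f"{v:.6g}"[:8] for v in phys_min], 8)
    hdr += sig_block([f"{v:.6g}"[:8] for v in phys_max], 8)
    hdr += sig_block([dmin] * n_sig, 8)
    hdr += sig_block([dmax] * n_sig, 8)
    hdr += sig_block([""] * n_sig, 80)  # prefiltering
    hdr += sig_block([spr] * n_sig, 8)
    hdr += sig_block([""] * n_sig, 32)  # reserved

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for ch in range(n_sig):
                f.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())


def read_session_edf(path: str | Path) -> SessionRecording:
    """Read an EDF file through MNE and return µV data in canonical order."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns Volts
    names = list(raw.ch_names)
    data = _reorder_channels(data, names)
    return SessionRecording(
        data=data, fs=float(raw.info["sfreq"]), session_id=Path(path).stem
    )


# ---------------------------------------------------------------------------
# Events TSV


def write_events_tsv(events: list[TrialEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "trial_id": ev.trial_id,
                "t_trial_start": ev.t_trial_start,
                "t_target_on": ev.t_target_on,
                "t_delay_cue": ev.t_delay_cue,
                "t_go": ev.t_go,
                "t_response": "" if ev.t_response is None else ev.t_response,
                "delay_ms": "" if ev.delay_ms is None else ev.delay_ms,
                "outcome": ev.outcome,
                "target_location": ev.target_location,
            }
        )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[TrialEvent]:
    """Parse the events table; trials with a missing outcome are dropped
    (and counted in the log), malformed timing raises with the trial id."""
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"events file {path} missing columns {missing_cols}")
    events: list[TrialEvent] = []
    n_no_outcome = 0
    for _, row in df.iterrows():
        outcome = row["outcome"]
        if not isinstance(outcome, str) or outcome not in ("correct", "incorrect"):
            n_no_outcome += 1
            continue
        t_resp = row["t_response"]
        delay_ms = row["delay_ms"]
        events.append(
            TrialEvent(
                trial_id=int(row["trial_id"]),
                t_trial_start=float(row["t_trial_start"]),
                t_target_on=float(row["t_target_on"]),
                t_delay_cue=float(row["t_delay_cue"]),
                t_go=float(row["t_go"]),
                t_response=None if pd.isna(t_resp) else float(t_resp),
                delay_ms=None if pd.isna(delay_ms) else float(delay_ms),
                outcome=outcome,
                target_location=int(row["target_location"]),
            )
        )
    if n_no_outcome:
        logger.info("read_events_tsv: dropped %d trials without outcome", n_no_outcome)
    return events


# ---------------------------------------------------------------------------
# Dispatch


def write_session(session: SessionRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_session_edf(session, path)
    else:
        write_session_h5(session, path)


def read_session(
    signal_path: str | Path, events_path: str | Path | None = None
) -> SessionRecording | tuple[SessionRecording, list[TrialEvent]]:
    """Load a session (EDF or HDF5 by extension) and, optionally, its events.

    Channel order is normalized to the canonical layout; event times are
    validated against the recording length.
    """
    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        session = read_session_edf(signal_path)
    else:
        session = read_session_h5(signal_path)
    if events_path is None:
        return session
    events = validate_events(read_events_tsv(events_path), session)
    return session, events
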