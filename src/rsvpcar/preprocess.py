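"""Raw-recording preprocessing: filtering, decimation, epoching, baseline.

The defaults mirror standard ERP-speller practice: a 0.1–30 Hz zero-phase
band-pass, decimation from 2000 to 200 Hz, epochs from −200 to +800 ms around
each stimulus onset, and baseline correction over −200..0 ms.  Filters are
4th-order Butterworth applied forward–backward (no phase distortion).
Sample-index convention: epoch sample 0 is the window start; stimulus onset
falls at index ``rate * |start| / 1000``; windows are half-open [start, end).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EpochSet, RawRecording


def bandpass_filter(
    rec: RawRecording, low: float = 0.1, high: float = 30.0, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass; removes DC and out-of-band power.

    ``0 < low < high < rate/2`` is required.
    """
    nyq = rec.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return RawRecording(out, rec.rate, list(rec.channel_names), list(rec.events))


def notch_filter(
    rec: RawRecording, freq: float = 50.0, quality: float = 30.0
) -> RawRecording:
    """Zero-phase IIR notch at ``freq`` Hz (power-line interference)."""
    if not (0 < freq < rec.rate / 2):
        raise ValueError(f"notch frequency {freq} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(freq, quality, fs=rec.rate)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return RawRecording(out, rec.rate, list(rec.channel_names), list(rec.events))


def rereference_ears(
    rec: RawRecording, ear_channels: tuple[str, str] = ("M1", "M2")
) -> RawRecording:
    """Re-reference to the mean of two ear/mastoid channels, when present.

    Synthetic cohorts are generated reference-free and skip this stage.
    """
    missing = [ch for ch in ear_channels if ch not in rec.channel_names]
    if missing:
        raise ValueError(f"ear channels not in recording: {missing}")
    idx = [rec.channel_names.index(ch) for ch in ear_channels]
    ref = rec.data[idx].mean(axis=0)
    return RawRecording(
        rec.data - ref, rec.rate, list(rec.channel_names), list(rec.events)
    )


def downsample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Decimate by an integer factor; event sample indices are rescaled.

    The signal must already be low-passed below ``target_rate / 2`` (the
    band-pass stage does this); no additional anti-alias filter is applied.
    """
    factor = rec.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"rate {rec.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return RawRecording(
            rec.data.copy(), rec.rate, list(rec.channel_names), list(rec.events)
        )
    data = rec.data[:, ::factor]
    events = [(idx // factor, sym, tgt) for idx, sym, tgt in rec.events]
    return RawRecording(data, target_rate, list(rec.channel_names), events)


def epoch_and_baseline(
    rec: RawRecording,
    window: tuple[float, float] = (-200.0, 800.0),
    baseline: tuple[float, float] | None = (-200.0, 0.0),
    subject_id: str = "",
) -> EpochSet:
    """Cut epochs around each event and subtract the per-epoch baseline mean.

    ``window`` and ``baseline`` are in ms relative to stimulus onset, half
    open.  An event whose window falls outside the recording raises an error
    naming the event.
    """
    start, end = window
    n_samples = int(round((end - start) * rec.rate / 1000.0))
    offset = int(round(start * rec.rate / 1000.0))
    n_events = len(rec.events)
    if n_events == 0:
        raise ValueError("recording has no events to epoch")
    data = np.empty((n_events, rec.n_channels, n_samples), dtype=np.float64)
    symbols = np.empty(n_events, dtype="U2")
    labels = np.zeros(n_events, dtype=np.int8)
    for j, (idx, sym, is_target) in enumerate(rec.events):
        lo = idx + offset
        hi = lo + n_samples
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"epoch window {window} ms for event {j} (symbol {sym!r} at "
                f"sample {idx}) exceeds recording bounds"
            )
        data[j] = rec.data[:, lo:hi]
        symbols[j] = sym
        labels[j] = int(is_target)
    epochs = EpochSet(
        subject_id=subject_id,
        data=data,
        labels=labels,
        symbols=symbols,
        rate=rec.rate,
        window=window,
        channel_names=list(rec.channel_names),
    )
    if baseline is not None:
        epochs = baseline_correct_epochs(epochs, baseline)
    return epochs


def baseline_correct_epochs(
    epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each epoch/channel's mean over the baseline segment.

    Idempotent: correcting twice equals correcting once.
    """
    lo = epochs.sample_index(baseline[0])
    hi = epochs.sample_index(baseline[1])
    if lo < 0 or hi > epochs.n_samples or hi <= lo:
        raise ValueError(
            f"baseline {baseline} ms outside epoch window {epochs.window}"
        )
    out = epochs.copy()
    means = out.data[:, :, lo:hi].mean(axis=2, keepdims=True)
    out.data = (out.data - means).astype(epochs.data.dtype)
    return out


def select_channels(epochs: EpochSet, names: list[str] | tuple[str, ...]) -> EpochSet:
    """Restrict and reorder the channel dimension to ``names``."""
    unknown = [ch for ch in names if ch not in epochs.channel_names]
    if unknown:
        raise ValueError(f"unknown channel name(s): {unknown}")
    idx = [epochs.channel_names.index(ch) for ch in names]
    out = epochs.copy()
    out.data = out.data[:, idx, :]
    out.channel_names = list(names)
    return out
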