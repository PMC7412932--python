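"""Core data containers shared across the pipeline.

Everything is a plain dataclass over numpy arrays: epoched EEG is small enough
(hundreds of MB at full study scale) that out-of-core storage is unnecessary,
and explicit arrays keep the provenance checks in the evaluation stage simple.
Units are microvolts for amplitudes, milliseconds for times, Hz for rates.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

#: The six posterior/midline channels used for all ERP analysis by default.
ANALYSIS_CHANNELS: tuple[str, ...] = ("FZ", "CZ", "PZ", "O1", "O2", "OZ")

#: The 26 speller symbols, presented A..Z within each round.
ALPHABET: tuple[str, ...] = tuple(string.ascii_uppercase)


def _ms_to_samples(t_ms: float, window_start_ms: float, rate: float) -> int:
    """Sample index of time ``t_ms`` in an epoch whose sample 0 sits at
    ``window_start_ms``.  All epoch windows are half-open ``[start, end)``."""
    return int(round((t_ms - window_start_ms) * rate / 1000.0))


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and structure of one RSVP speller session.

    A *round* is one sweep through all symbols; a *trial* repeats the sweep
    ``rounds_per_trial`` times for a single target letter; a *block* holds
    ``trials_per_block`` trials; a session holds ``n_blocks`` blocks.
    """

    n_symbols: int = 26
    flash_duration: float = 200.0  # ms the symbol is on screen
    off_duration: float = 100.0  # ms blank gap between symbols
    rounds_per_trial: int = 5
    trials_per_block: int = 8
    n_blocks: int = 20
    acquisition_rate: float = 2000.0  # Hz of the (emulated) amplifier
    symbol_order: Literal["sequential_A_to_Z", "random"] = "sequential_A_to_Z"

    def __post_init__(self) -> None:
        for name in ("n_symbols", "rounds_per_trial", "trials_per_block", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("flash_duration", "off_duration", "acquisition_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_symbols > len(ALPHABET):
            raise ValueError(f"n_symbols must be <= {len(ALPHABET)}")

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in ms (flash + off)."""
        return self.flash_duration + self.off_duration

    @property
    def symbols(self) -> tuple[str, ...]:
        return ALPHABET[: self.n_symbols]

    @property
    def epochs_per_session(self) -> int:
        return (
            self.n_blocks
            * self.trials_per_block
            * self.rounds_per_trial
            * self.n_symbols
        )

    @property
    def targets_per_session(self) -> int:
        """One target presentation per round."""
        return self.n_blocks * self.trials_per_block * self.rounds_per_trial

    def to_dict(self) -> dict:
        return {
            "n_symbols": self.n_symbols,
            "flash_duration": self.flash_duration,
            "off_duration": self.off_duration,
            "rounds_per_trial": self.rounds_per_trial,
            "trials_per_block": self.trials_per_block,
            "n_blocks": self.n_blocks,
            "acquisition_rate": self.acquisition_rate,
            "symbol_order": self.symbol_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmConfig":
        return cls(**d)


@dataclass
class RawRecording:
    """A continuous multichannel recording with stimulus events.

    ``events`` rows are ``(sample_index, symbol, is_target)``; sample indices
    refer to the current ``rate`` and are rescaled on decimation.
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    rate: float
    channel_names: list[str]
    events: list[tuple[int, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        n = self.data.shape[1]
        for idx, sym, _ in self.events:
            if not (0 <= idx < n):
                raise ValueError(f"event at sample {idx} ({sym!r}) outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """One subject's labeled, time-locked epochs.

    ``data`` is ``(n_epochs, n_channels, n_samples)`` in µV; ``window`` is
    ``(start_ms, end_ms)`` relative to stimulus onset, half-open, so
    ``n_samples == (end - start) / 1000 * rate``.  ``block_idx`` /
    ``trial_idx`` / ``round_idx`` record where each epoch sits in the session
    structure; they drive calibration splits and symbol-level scoring.
    """

    subject_id: str
    data: np.ndarray
    labels: np.ndarray  # 1 = target, 0 = nontarget
    symbols: np.ndarray  # per-epoch presented symbol
    rate: float
    window: tuple[float, float]
    channel_names: list[str]
    block_idx: np.ndarray | None = None
    trial_idx: np.ndarray | None = None
    round_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.symbols = np.asarray(self.symbols, dtype="U2")
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        n_epochs, n_channels, n_samples = self.data.shape
        if len(self.labels) != n_epochs or len(self.symbols) != n_epochs:
            raise ValueError("labels/symbols length must equal n_epochs")
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length must match data channels")
        start, end = self.window
        expected = (end - start) * self.rate / 1000.0
        if abs(expected - n_samples) > 1e-6:
            raise ValueError(
                f"window {self.window} at {self.rate} Hz implies "
                f"{expected} samples, data has {n_samples}"
            )
        for name in ("block_idx", "trial_idx", "round_idx"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int32)
                if len(v) != n_epochs:
                    raise ValueError(f"{name} length must equal n_epochs")
                setattr(self, name, v)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        start, _ = self.window
        return start + np.arange(self.n_samples) * 1000.0 / self.rate

    def sample_index(self, t_ms: float) -> int:
        return _ms_to_samples(t_ms, self.window[0], self.rate)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset epochs by boolean mask or integer index array."""
        mask = np.asarray(mask)
        sub = lambda v: None if v is None else v[mask]
        return EpochSet(
            subject_id=self.subject_id,
            data=self.data[mask],
            labels=self.labels[mask],
            symbols=self.symbols[mask],
            rate=self.rate,
            window=self.window,
            channel_names=list(self.channel_names),
            block_idx=sub(self.block_idx),
            trial_idx=sub(self.trial_idx),
            round_idx=sub(self.round_idx),
        )

    def copy(self) -> "EpochSet":
        return self.select(np.arange(self.n_epochs))


@dataclass
class ERPWaveform:
    """Per-subject coherently averaged responses (channels x samples, µV)."""

    subject_id: str
    target_mean: np.ndarray
    nontarget_mean: np.ndarray
    n_target_epochs: int
    n_nontarget_epochs: int
    rate: float
    window: tuple[float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.target_mean = np.asarray(self.target_mean, dtype=np.float64)
        self.nontarget_mean = np.asarray(self.nontarget_mean, dtype=np.float64)
        if self.target_mean.shape != self.nontarget_mean.shape:
            raise ValueError("target and nontarget means must share shape")
        if self.n_target_epochs < 1:
            raise ValueError("need at least one target epoch")

    def sample_index(self, t_ms: float) -> int:
        return _ms_to_samples(t_ms, self.window[0], self.rate)


@dataclass
class SimilarityMatrix:
    """Pairwise ERP similarity between subjects.

    Symmetric with unit diagonal; values in [-1, 1].  ``vectorization``
    records how waveforms were flattened (segment and channel order).
    """

    subject_ids: list[str]
    values: np.ndarray
    metric: Literal["cosine", "pearson"]
    vectorization: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n_subjects x n_subjects")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("similarity values must lie in [-1, 1]")


@dataclass
class SubjectRanking:
    """Donor subjects ordered by decreasing similarity to a test subject."""

    test_subject: str
    ranked_donors: list[tuple[str, float]]
    metric: str = "pearson"

    def __post_init__(self) -> None:
        rs = [r for _, r in self.ranked_donors]
        if any(b > a + 1e-12 for a, b in zip(rs, rs[1:])):
            raise ValueError("ranking similarities must be non-increasing")
        if any(sid == self.test_subject for sid, _ in self.ranked_donors):
            raise ValueError("test subject cannot appear among donors")

    @property
    def donor_ids(self) -> list[str]:
        return [sid for sid, _ in self.ranked_donors]

    def top(self, n: int) -> list[str]:
        return self.donor_ids[:n]
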