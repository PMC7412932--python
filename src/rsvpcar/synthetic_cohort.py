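"""Synthetic multi-subject RSVP EEG cohorts.

Each epoch follows the classic additive evoked-response model: a target epoch
is a subject-specific P300 template (a Gaussian bump over latency/amplitude/
width, projected through a per-channel topography) plus 1/f^alpha background
noise; a nontarget epoch is noise only.  Subjects are drawn as perturbations
of cluster-level archetypes, so inter-subject ERP similarity has a known
block structure that donor-ranking methods can be validated against.

Epochs are generated directly at the analysis sampling rate; continuous-record
synthesis is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ALPHABET, ANALYSIS_CHANNELS, EpochSet, ParadigmConfig

#: Relative P300 projection strength of the six default analysis channels
#: (parietal-maximal, typical of the component's posterior/midline topography).
DEFAULT_TOPOGRAPHY = {
    "FZ": 0.55,
    "CZ": 0.85,
    "PZ": 1.0,
    "O1": 0.45,
    "O2": 0.45,
    "OZ": 0.6,
}


@dataclass(frozen=True)
class SubjectArchetype:
    """Ground-truth generative parameters for one simulated subject."""

    subject_id: str
    cluster_id: int
    p300_latency: float  # ms post-stimulus, peak of the evoked bump
    p300_amplitude: float  # µV at the best channel
    p300_width: float  # ms, FWHM of the bump
    topography: np.ndarray  # one weight per channel, max |w| = 1
    noise_sd: float = 10.0  # µV per channel; 0 gives the noiseless limit
    pink_exponent: float = 1.0  # spectral slope alpha of 1/f^alpha noise

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "topography", np.asarray(self.topography, dtype=np.float64)
        )
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be >= 0")
        if self.p300_width <= 0:
            raise ValueError("p300_width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        topo = self.topography
        peak = np.max(np.abs(topo))
        if topo.ndim != 1 or peak == 0:
            raise ValueError("topography must be a non-zero 1-D weight vector")
        if abs(peak - 1.0) > 1e-9:
            object.__setattr__(self, "topography", topo / peak)


@dataclass(frozen=True)
class ClusterDispersion:
    """Between- or within-cluster standard deviations of archetype fields."""

    latency_sd: float = 0.0  # ms
    amplitude_sd: float = 0.0  # µV
    width_sd: float = 0.0  # ms
    topography_sd: float = 0.0  # unitless, per-channel


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible multi-subject cohort.

    The seed fully determines every archetype and every epoch; regenerating
    with the same spec is bit-identical.
    """

    n_subjects: int = 58
    n_clusters: int = 4
    between: ClusterDispersion = field(
        default_factory=lambda: ClusterDispersion(40.0, 1.5, 20.0, 0.15)
    )
    within: ClusterDispersion = field(
        default_factory=lambda: ClusterDispersion(10.0, 0.5, 8.0, 0.05)
    )
    seed: int = 0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    channel_names: tuple[str, ...] = ANALYSIS_CHANNELS
    rate: float = 200.0  # Hz of the generated epochs
    window: tuple[float, float] = (-200.0, 800.0)  # ms around stimulus onset
    base_latency: float = 360.0  # ms, cohort-level P300 peak
    base_amplitude: float = 5.0  # µV
    base_width: float = 150.0  # ms FWHM
    noise_sd: float = 10.0  # µV
    pink_exponent: float = 1.0
    line_noise_amplitude: float = 0.0  # µV, optional 50 Hz component
    line_noise_freq: float = 50.0  # Hz
    #: pin cluster-center latencies (ms) instead of drawing them; length must
    #: equal n_clusters.  Useful for cohorts with known separation.
    cluster_latencies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (1 <= self.n_clusters <= self.n_subjects):
            raise ValueError("need 1 <= n_clusters <= n_subjects")
        if self.cluster_latencies is not None and len(self.cluster_latencies) != self.n_clusters:
            raise ValueError("cluster_latencies length must equal n_clusters")


def p300_template(
    latency: float,
    amplitude: float,
    width: float,
    window: tuple[float, float] = (-200.0, 800.0),
    rate: float = 200.0,
) -> np.ndarray:
    """Single-channel evoked template: a Gaussian bump peaking at ``latency``.

    Parameters
    ----------
    latency, width
        Peak time and FWHM in ms.  ``latency`` must lie inside ``window``.
    amplitude
        Peak value in µV.
    window
        Epoch extent ``(start_ms, end_ms)`` relative to stimulus onset.
    rate
        Sampling rate in Hz.

    Returns
    -------
    ndarray of length ``(end - start)/1000 * rate``; identically zero in the
    pre-stimulus segment (t < 0).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if width <= 0:
        raise ValueError("width must be > 0")
    start, end = window
    if not (start <= latency < end):
        raise ValueError(f"latency {latency} ms outside epoch window {window}")
    n = int(round((end - start) * rate / 1000.0))
    t = start + np.arange(n) * 1000.0 / rate
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd
    wave = amplitude * np.exp(-0.5 * ((t - latency) / sigma) ** 2)
    wave[t < 0] = 0.0
    return wave


def _pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    rate: float,
    sd: float,
    exponent: float,
) -> np.ndarray:
    """1/f^alpha noise along the last axis, unit-calibrated to std ``sd``.

    White Gaussian noise is shaped in the frequency domain by f^(-alpha/2)
    (DC removed); the gain vector is normalized analytically so the output
    variance equals sd**2 in expectation, keeping generation deterministic
    without per-epoch renormalization.
    """
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    # variance of irfft(gain * rfft(white)) for unit white noise
    nyq = gain[-1] ** 2 if n_samples % 2 == 0 else 2 * gain[-1] ** 2
    var = (gain[0] ** 2 + 2 * np.sum(gain[1:-1] ** 2) + nyq) / n_samples
    gain *= sd / np.sqrt(var)
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1) * gain
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def generate_subject_epochs(
    archetype: SubjectArchetype,
    paradigm: ParadigmConfig | None = None,
    seed: int = 0,
    *,
    rate: float = 200.0,
    window: tuple[float, float] = (-200.0, 800.0),
    channel_names: tuple[str, ...] = ANALYSIS_CHANNELS,
    line_noise_amplitude: float = 0.0,
    line_noise_freq: float = 50.0,
) -> EpochSet:
    """Simulate one full session of labeled epochs for a subject.

    Every symbol presentation yields one epoch: the target symbol of the
    enclosing trial gets template + noise, every other symbol noise only.
    Epoch count is ``n_blocks * trials_per_block * rounds_per_trial *
    n_symbols`` with exactly one target per round.
    """
    paradigm = paradigm or ParadigmConfig()
    if len(archetype.topography) != len(channel_names):
        raise ValueError(
            f"topography has {len(archetype.topography)} weights for "
            f"{len(channel_names)} channels"
        )
    rng = np.random.default_rng(seed)
    syms = np.array(paradigm.symbols)
    n_sym = paradigm.n_symbols
    n_rounds = paradigm.rounds_per_trial
    n_trials = paradigm.trials_per_block
    n_blocks = paradigm.n_blocks
    n_epochs = paradigm.epochs_per_session
    n_samples = int(round((window[1] - window[0]) * rate / 1000.0))
    n_ch = len(channel_names)

    template = p300_template(
        archetype.p300_latency,
        archetype.p300_amplitude,
        archetype.p300_width,
        window,
        rate,
    )
    evoked = np.outer(archetype.topography, template)  # (ch, samples)

    # session structure: per block, draw the 8 target letters without
    # replacement; each round presents all symbols (A..Z or shuffled)
    symbols = np.empty(n_epochs, dtype="U2")
    labels = np.zeros(n_epochs, dtype=np.int8)
    block_idx = np.empty(n_epochs, dtype=np.int32)
    trial_idx = np.empty(n_epochs, dtype=np.int32)
    round_idx = np.empty(n_epochs, dtype=np.int32)
    pos = 0
    for b in range(n_blocks):
        targets = rng.choice(n_sym, size=min(n_trials, n_sym), replace=False)
        if n_trials > n_sym:  # degenerate configs: reuse letters
            extra = rng.integers(0, n_sym, size=n_trials - n_sym)
            targets = np.concatenate([targets, extra])
        for t in range(n_trials):
            target_sym = syms[targets[t]]
            for r in range(n_rounds):
                if paradigm.symbol_order == "random":
                    order = rng.permutation(n_sym)
                else:
                    order = np.arange(n_sym)
                sl = slice(pos, pos + n_sym)
                symbols[sl] = syms[order]
                labels[sl] = syms[order] == target_sym
                block_idx[sl] = b
                trial_idx[sl] = t
                round_idx[sl] = r
                pos += n_sym

    data = _pink_noise(
        rng,
        (n_epochs, n_ch),
        n_samples,
        rate,
        archetype.noise_sd,
        archetype.pink_exponent,
    ).astype(np.float32)
    if line_noise_amplitude > 0:
        t_s = (window[0] + np.arange(n_samples) * 1000.0 / rate) / 1000.0
        phases = rng.uniform(0, 2 * np.pi, size=n_epochs)
        line = line_noise_amplitude * np.sin(
            2 * np.pi * line_noise_freq * t_s[None, :] + phases[:, None]
        )
        data += line[:, None, :].astype(np.float32)
    data[labels == 1] += evoked.astype(np.float32)

    return EpochSet(
        subject_id=archetype.subject_id,
        data=data,
        labels=labels,
        symbols=symbols,
        rate=rate,
        window=window,
        channel_names=list(channel_names),
        block_idx=block_idx,
        trial_idx=trial_idx,
        round_idx=round_idx,
    )


def _draw_archetypes(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectArchetype]:
    base_topo = np.array(
        [DEFAULT_TOPOGRAPHY.get(ch, 0.5) for ch in spec.channel_names]
    )
    centers = []
    for c in range(spec.n_clusters):
        if spec.cluster_latencies is not None:
            lat_c = spec.cluster_latencies[c]
            rng.normal()  # keep the draw sequence aligned either way
        else:
            lat_c = spec.base_latency + rng.normal(0, spec.between.latency_sd)
        centers.append(
            dict(
                latency=lat_c,
                amplitude=max(
                    0.0, spec.base_amplitude + rng.normal(0, spec.between.amplitude_sd)
                ),
                width=max(
                    20.0, spec.base_width + rng.normal(0, spec.between.width_sd)
                ),
                topo=base_topo
                + rng.normal(0, spec.between.topography_sd, size=len(base_topo)),
            )
        )
    # round-robin cluster assignment keeps cluster sizes balanced
    archetypes = []
    width_digits = len(str(spec.n_subjects))
    for i in range(spec.n_subjects):
        c = i % spec.n_clusters
        ctr = centers[c]
        lat = ctr["latency"] + rng.normal(0, spec.within.latency_sd)
        amp = max(0.0, ctr["amplitude"] + rng.normal(0, spec.within.amplitude_sd))
        wid = max(20.0, ctr["width"] + rng.normal(0, spec.within.width_sd))
        topo = ctr["topo"] + rng.normal(
            0, spec.within.topography_sd, size=len(base_topo)
        )
        start, end = spec.window
        # keep the whole bump comfortably inside the post-stimulus segment
        lat = float(np.clip(lat, 120.0, end - 1000.0 / spec.rate - wid / 2))
        archetypes.append(
            SubjectArchetype(
                subject_id=f"S{i + 1:0{width_digits}d}",
                cluster_id=c,
                p300_latency=lat,
                p300_amplitude=amp,
                p300_width=wid,
                topography=np.where(np.abs(topo).max() > 0, topo, base_topo),
                noise_sd=spec.noise_sd,
                pink_exponent=spec.pink_exponent,
            )
        )
    return archetypes


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EpochSet], pd.DataFrame]:
    """Generate a full cohort: per-subject epoch sets plus the archetype table.

    Returns
    -------
    epoch_sets
        One :class:`EpochSet` per subject, in subject-id order.
    archetypes
        DataFrame with ground-truth cluster membership and generative
        parameters — the recoverable truth that donor-ranking evaluation
        checks itself against.
    """
    rng = np.random.default_rng(spec.seed)
    archetypes = _draw_archetypes(spec, rng)
    # independent per-subject epoch seeds, derived from the cohort seed
    epoch_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)
    epoch_sets = [
        generate_subject_epochs(
            a,
            spec.paradigm,
            seed=int(s),
            rate=spec.rate,
            window=spec.window,
            channel_names=spec.channel_names,
            line_noise_amplitude=spec.line_noise_amplitude,
            line_noise_freq=spec.line_noise_freq,
        )
        for a, s in zip(archetypes, epoch_seeds)
    ]
    table = pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in archetypes],
            "cluster_id": [a.cluster_id for a in archetypes],
            "p300_latency": [a.p300_latency for a in archetypes],
            "p300_amplitude": [a.p300_amplitude for a in archetypes],
            "p300_width": [a.p300_width for a in archetypes],
            "noise_sd": [a.noise_sd for a in archetypes],
            "pink_exponent": [a.pink_exponent for a in archetypes],
            "epoch_seed": epoch_seeds,
        }
    )
    table["topography"] = [a.topography.tolist() for a in archetypes]
    return epoch_sets, table


def matrix_like_spec(spec: CohortSpec) -> CohortSpec:
    """Emulate a matrix-speller cohort: same generator, ~3x larger
    between-subject dispersion (matrix paradigms show larger individual
    differences).  This is an emulation knob, not a physiological claim."""
    b = spec.between
    return replace(
        spec,
        between=ClusterDispersion(
            3 * b.latency_sd, 3 * b.amplitude_sd, 3 * b.width_sd, 3 * b.topography_sd
        ),
    )
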