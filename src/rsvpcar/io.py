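"""File I/O: epoch containers (HDF5), tabular outputs, configs, EDF.

The epoch container is a small HDF5 schema::

    /epochs     float32 (n_epochs, n_channels, n_samples), µV
    /labels     int8    (n_epochs,)
    /symbols    bytes   (n_epochs,)
    /block_idx, /trial_idx, /round_idx   int32, optional
    /meta       attrs: schema_version, subject_id, rate, window,
                channel_names

Tabular outputs (similarity matrices, evaluation results) are TSV with a
leading JSON metadata block in '#'-prefixed comment lines, so they remain
both machine- and spreadsheet-readable.  EDF ingestion goes through
``mne.io.read_raw_edf`` (optional dependency); a minimal 16-bit EDF writer is
provided for export and round-trip testing, since no supported writer exists
in the core dependency set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, ParadigmConfig, RawRecording, SimilarityMatrix

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# epoch containers


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to an HDF5 epoch container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset(
            "symbols", data=np.char.encode(epochs.symbols.astype("U2"), "ascii")
        )
        for name in ("block_idx", "trial_idx", "round_idx"):
            v = getattr(epochs, name)
            if v is not None:
                f.create_dataset(name, data=v)
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["subject_id"] = epochs.subject_id
        meta.attrs["rate"] = epochs.rate
        meta.attrs["window"] = list(epochs.window)
        meta.attrs["channel_names"] = list(epochs.channel_names)


def read_epochs(path: str | Path) -> EpochSet:
    """Read an HDF5 epoch container; errors on missing datasets or a
    schema-version mismatch (reporting both versions)."""
    with h5py.File(path, "r") as f:
        for required in ("epochs", "labels", "symbols", "meta"):
            if required not in f:
                raise ValueError(f"epoch container {path} is missing /{required}")
        meta = f["meta"].attrs
        version = str(meta.get("schema_version", "<absent>"))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"epoch container schema version {version!r} != "
                f"supported {SCHEMA_VERSION!r}"
            )
        opt = {
            name: f[name][()] if name in f else None
            for name in ("block_idx", "trial_idx", "round_idx")
        }
        return EpochSet(
            subject_id=str(meta["subject_id"]),
            data=f["epochs"][()],
            labels=f["labels"][()],
            symbols=np.char.decode(f["symbols"][()], "ascii"),
            rate=float(meta["rate"]),
            window=tuple(meta["window"]),
            channel_names=[str(c) for c in meta["channel_names"]],
            **opt,
        )


def write_cohort(
    epoch_sets: list[EpochSet],
    archetypes: pd.DataFrame,
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> Path:
    """Write one container per subject plus a JSON cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for ep in epoch_sets:
        fname = f"{ep.subject_id}.h5"
        write_epochs(ep, out_dir / fname)
        files[ep.subject_id] = fname
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "subjects": files,
        "archetypes": archetypes.to_dict(orient="records"),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out_dir / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> tuple[list[EpochSet], pd.DataFrame]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    eps = [read_epochs(root / fname) for fname in manifest["subjects"].values()]
    return eps, pd.DataFrame(manifest["archetypes"])


# ---------------------------------------------------------------------------
# tabular outputs


def write_tsv_with_meta(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """TSV with a '#'-prefixed JSON metadata header block ('.' decimals)."""
    path = Path(path)
    lines = []
    if meta:
        for line in json.dumps(meta, indent=2, default=float).splitlines():
            lines.append(f"# {line}")
    header = "\n".join(lines)
    with open(path, "w") as f:
        if header:
            f.write(header + "\n")
        df.to_csv(f, sep="\t", index=False, float_format="%.10g")


def read_tsv_with_meta(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta_lines = []
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                meta_lines.append(line.lstrip("# ").rstrip("\n"))
            else:
                break
    meta = json.loads("\n".join(meta_lines)) if meta_lines else {}
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, meta


def write_similarity(sim: SimilarityMatrix, path: str | Path, extra_meta: dict | None = None) -> None:
    df = pd.DataFrame(sim.values, columns=sim.subject_ids)
    df.insert(0, "subject_id", sim.subject_ids)
    meta = {"metric": sim.metric, "vectorization": sim.vectorization}
    if extra_meta:
        meta.update(extra_meta)
    write_tsv_with_meta(df, path, meta)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through JSON."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    n_subjects: int = 12
    n_clusters: int = 3
    seed: int = 0
    rate: float = 200.0
    window: tuple[float, float] = (-200.0, 800.0)
    baseline: tuple[float, float] = (-200.0, 0.0)
    channels: tuple[str, ...] = ("FZ", "CZ", "PZ", "O1", "O2", "OZ")
    similarity_segment: tuple[float, float] = (0.0, 800.0)
    similarity_threshold: float = 0.5
    feature_bin_width: float = 50.0
    models: tuple[str, ...] = ("random", "car")
    donor_counts: tuple[int, ...] = (1, 2, 4)
    calibration_blocks: int = 2
    random_reps: int = 10
    train_blocks: int = 2  # within-subject split used for the ITR stage
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_clusters", "seed", "calibration_blocks",
                     "random_reps", "train_blocks"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"config field {name!r} must be an integer, got {v!r}")
        for name in ("rate", "similarity_threshold", "feature_bin_width"):
            if not isinstance(getattr(self, name), (int, float)):
                raise ValueError(f"config field {name!r} must be numeric")
        if self.n_subjects < 2:
            raise ValueError("config field 'n_subjects' must be >= 2")
        bad = [m for m in self.models if m not in ("random", "car")]
        if bad:
            raise ValueError(f"config field 'models' has unknown entries: {bad}")

    def to_json(self) -> str:
        d = asdict(self)
        d["paradigm"] = self.paradigm.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON config: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "paradigm" in d:
            try:
                d["paradigm"] = ParadigmConfig.from_dict(d["paradigm"])
            except TypeError as exc:
                raise ValueError(f"invalid 'paradigm' section: {exc}") from exc
        for name in ("window", "baseline", "channels", "similarity_segment",
                     "models", "donor_counts"):
            if name in d:
                d[name] = tuple(d[name])
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config: {exc}") from exc

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    import zlib

    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


# ---------------------------------------------------------------------------
# EDF export / import


def write_edf(rec: RawRecording, path: str | Path, events_path: str | Path | None = None) -> None:
    """Minimal EDF export (16-bit, 1-second data records, physical unit µV).

    The recording is zero-padded to a whole number of 1 s records.  If
    ``events_path`` is given, an events sidecar TSV (onset_sample, symbol,
    is_target) is written alongside.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_records = int(np.ceil(rec.n_samples / spr))
    n_ch = rec.n_channels
    data = np.zeros((n_ch, n_records * spr))
    data[:, : rec.n_samples] = rec.data

    phys_min = np.floor(data.min(axis=1) - 1)
    phys_max = np.ceil(data.max(axis=1) + 1)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("EDF", 44),  # reserved; plain EDF
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, s
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(ch, 16) for ch in rec.channel_names],  # label
        [pad("EEG", 80)] * n_ch,  # transducer
        [pad("uV", 8)] * n_ch,  # physical dimension
        [pad(f"{phys_min[i]:g}", 8) for i in range(n_ch)],
        [pad(f"{phys_max[i]:g}", 8) for i in range(n_ch)],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,  # prefiltering
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,  # reserved
    ]
    with open(path, "wb") as f:
        f.write(header)
        for fld in fields:
            f.write(b"".join(fld))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())

    if events_path is not None:
        ev = pd.DataFrame(
            rec.events, columns=["onset_sample", "symbol", "is_target"]
        )
        ev.to_csv(events_path, sep="\t", index=False)


def read_edf_recording(
    path: str | Path, events_path: str | Path | None = None
) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (µV), attaching
    events from an optional sidecar TSV (onset_sample, symbol, is_target)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "EDF ingestion requires the optional 'mne' dependency "
            "(install rsvpcar[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads EEG in volts
    events: list[tuple[int, str, bool]] = []
    if events_path is not None:
        ev = pd.read_csv(events_path, sep="\t")
        for _, row in ev.iterrows():
            events.append(
                (int(row["onset_sample"]), str(row["symbol"]), bool(row["is_target"]))
            )
    return RawRecording(
        data=data_uv,
        rate=float(raw.info["sfreq"]),
        channel_names=[str(ch) for ch in raw.ch_names],
        events=events,
    )
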