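"""Readers, writers and run configuration shared by all modules.

Formats: hypnogram CSV (epoch_index, day, zt_hours, stage), cell-table and
ontology CSV, EDF recordings, JSON manifests/provenance, and a dense voxel
volume as raw float32 with a JSON header.  CSV dialect is UTF-8, comma,
mandatory header, '.' decimal.  Coordinates and radii are micrometres
throughout; hours are decimal zeitgeber hours.

EDF reading goes through mne; writing uses a minimal EDF implementation
(16-bit, one-second data records) because no installed library exports
EDF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sleepmap.hypnogram import ARTIFACT, Hypnogram, THREE_STATE, TWO_STATE
from sleepmap.spectral import Recording

VALID_STAGES = set(TWO_STATE) | set(THREE_STATE) | {ARTIFACT}


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


# ---------------------------------------------------------------------------
# hypnogram CSV


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    hours = hyp.epoch_start_hours()
    frame = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "day": (hours // 24).astype(int),
            "zt_hours": np.round(np.mod(hours, 24.0), 6),
            "stage": hyp.stages,
        }
    )
    frame.to_csv(path, index=False)


def read_hypnogram_csv(path, epoch_length: float = 8.0, timebase: str = "ZT") -> Hypnogram:
    """Read a hypnogram CSV, validating schema and stage labels.

    The epoch length is not stored in the CSV and must be supplied (config
    or CLI flag).
    """
    frame = pd.read_csv(path)
    required = ["epoch_index", "day", "zt_hours", "stage"]
    missing = set(required) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    stages = frame["stage"].astype(str).to_numpy()
    bad = np.where(~np.isin(stages, list(VALID_STAGES)))[0]
    if bad.size:
        row = int(bad[0])
        raise ParseError(
            f"{path}: unknown stage {stages[row]!r} at data row {row + 1}"
        )
    idx = frame["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(frame))):
        raise ParseError(f"{path}: epoch_index must be 0..n-1 without gaps")
    start_hour = float(frame["day"].iloc[0]) * 24.0 + float(frame["zt_hours"].iloc[0])
    return Hypnogram(
        stages=stages,
        epoch_length=epoch_length,
        start_hour=start_hour,
        timebase=timebase,
        subject_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# cell tables and ontology


def write_cell_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"x_um", "y_um", "z_um", "channel", "region"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "intensity" not in frame.columns:
        frame["intensity"] = 1.0
    return frame


def write_ontology_csv(ontology_table: pd.DataFrame, path) -> None:
    ontology_table.to_csv(path, index=False)


def read_ontology_csv(path):
    from sleepmap.cellmap import Ontology

    frame = pd.read_csv(path, keep_default_na=False)
    return Ontology(frame)


# ---------------------------------------------------------------------------
# EDF


def write_edf(
    rec: Recording,
    path,
    channel_labels: tuple[str, str] = ("EEG", "EMG"),
    physical_dim: str = "uV",
) -> None:
    """Write an EEG/EMG recording as 16-bit EDF with 1-s data records.

    The recording length must be an integer number of seconds.  Physical
    scaling covers the observed amplitude range, so a round trip is exact
    up to 16-bit quantization.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError("recording must cover an integer number of seconds")
    n_records = rec.n_samples // fs
    signals = [np.asarray(rec.eeg, dtype=float), np.asarray(rec.emg, dtype=float)]
    ns = len(signals)

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            fixed("0", 8),
            fixed("X X X X", 80),
            fixed("Startdate X X X X", 80),
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 * (1 + ns)), 8),
            fixed("EDF", 44),
            fixed(str(n_records), 8),
            fixed("1", 8),
            fixed(str(ns), 4),
        ]
    )
    phys_min, phys_max, scale, offsets = [], [], [], []
    for x in signals:
        lo = float(np.min(x)) if x.size else -1.0
        hi = float(np.max(x)) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scale.append((hi - lo) / (32767 - (-32768)))
        offsets.append(lo)

    def per_signal(values: list[str], width: int) -> bytes:
        return b"".join(fixed(v, width) for v in values)

    header += per_signal(list(channel_labels), 16)
    header += per_signal(["" for _ in signals], 80)  # transducer
    header += per_signal([physical_dim for _ in signals], 8)
    header += per_signal([f"{v:.7g}"[:8] for v in phys_min], 8)
    header += per_signal([f"{v:.7g}"[:8] for v in phys_max], 8)
    header += per_signal(["-32768" for _ in signals], 8)
    header += per_signal(["32767" for _ in signals], 8)
    header += per_signal(["" for _ in signals], 80)  # prefiltering
    header += per_signal([str(fs) for _ in signals], 8)
    header += per_signal(["" for _ in signals], 32)

    with open(path, "wb") as fh:
        fh.write(header)
        digital = []
        for x, lo, sc in zip(signals, offsets, scale):
            d = np.round((x - lo) / sc) + (-32768)
            digital.append(np.clip(d, -32768, 32767).astype("<i2"))
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs : (r + 1) * fs].tobytes())


def read_edf(
    path,
    channel_map: dict[str, str] = {"eeg": "EEG", "emg": "EMG"},
    expected_fs: float | None = None,
    strict: bool = True,
) -> Recording:
    """Read an EDF file into a Recording via mne.

    ``channel_map`` maps the roles "eeg"/"emg" onto channel labels in the
    file.  When ``expected_fs`` is given and disagrees with the header, an
    error (strict) or warning (non-strict) is raised.
    """
    import warnings as _warnings

    import mne

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        msg = f"{path}: header sampling rate {fs} != configured {expected_fs}"
        if strict:
            raise ValueError(msg)
        _warnings.warn(msg)
    missing = [lab for lab in channel_map.values() if lab not in raw.ch_names]
    if missing:
        raise ValueError(f"{path}: channels {missing} not present ({raw.ch_names})")
    data = {}
    for role, label in channel_map.items():
        picked = raw.get_data(picks=[label])[0]
        # mne rescales physical units to SI; EDFs written in uV come back in volts
        data[role] = picked * 1e6
    return Recording(eeg=data["eeg"], emg=data["emg"], fs=fs)


# ---------------------------------------------------------------------------
# voxel volumes


def write_voxel_volume(array: np.ndarray, origin, spacing: float, path_stem) -> None:
    """Dense float32 array on disk (.raw) with a JSON header (.json)."""
    stem = Path(path_stem)
    arr = np.asarray(array, dtype="<f4")
    arr.tofile(stem.with_suffix(".raw"))
    header = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "order": "C",
        "origin_um": [float(v) for v in origin],
        "spacing_um": float(spacing),
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_voxel_volume(path_stem) -> tuple[np.ndarray, dict]:
    stem = Path(path_stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    arr = np.fromfile(stem.with_suffix(".raw"), dtype=header["dtype"])
    return arr.reshape(header["shape"]), header


# ---------------------------------------------------------------------------
# run configuration and provenance


@dataclass
class RunConfig:
    """Serializable run configuration with the package's named windows."""

    epoch_length: float = 8.0
    fs: float = 128.0
    total_band: tuple[float, float | None] = (0.5, None)
    windows: dict = field(
        default_factory=lambda: {
            "rebound": [12.0, 24.0],
            "rebound_delta": [12.0, 15.0],
            "delta_rebound": [6.0, 12.0],
            "deprivation": [0.0, 6.0],
        }
    )
    coloc_radius_um: float = 16.0
    expansion_factor: float = 1.5
    exclude_regions: list = field(default_factory=lambda: ["CB"])
    stats_strict: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["total_band"] = tuple(data.get("total_band", (0.5, None)))
        return cls(**data)


def write_provenance(out_dir, config: RunConfig | None, seed: int | None, argv=None) -> Path:
    """Record enough to re-run a command bit-identically (deterministic paths)."""
    from sleepmap import __version__

    payload = dataclasses.asdict(config) if config else {}
    blob = json.dumps(payload, sort_keys=True).encode()
    record = {
        "package": "sleepmap",
        "version": __version__,
        "python": sys.version.split()[0],
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": payload,
        "seed": seed,
        "argv": list(argv) if argv is not None else sys.argv[1:],
    }
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2))
    return out
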