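"""File I/O: EDF and BrainVision recordings, epoch containers, sidecars.

Continuous recordings are written as 16-bit European Data Format (EDF)
with a tab-separated events sidecar (onset_sample, label) and a plain-text
montage file (name, x, y, z per line).  Reading goes through MNE, which
handles both EDF and BrainVision; units are converted to microvolts.
Epoched data round-trips losslessly through a NumPy .npz container with a
JSON metadata block.
"""

from __future__ import annotations

import fnmatch
import json
import zipfile
from pathlib import Path

import numpy as np

from .preprocessing import ContinuousEEG, EpochedEEG
from .synthetic import GroundTruth

EPOCHS_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# EDF writing (16-bit, physical units uV)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(cont: ContinuousEEG, path: str | Path) -> None:
    """Write a continuous recording as 16-bit EDF (1-second data records).

    The final record is zero-padded when the record length does not divide
    the sample count; the events sidecar carries the true sample count.
    """
    path = Path(path)
    fs = cont.sampling_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = cont.n_channels
    n_records = int(np.ceil(cont.n_samples / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, : cont.n_samples] = cont.samples

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    header = b"".join([
        _pad("0", 8),
        _pad("synthetic subject", 80),
        _pad("synthetic recording", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    sig = b""
    sig += b"".join(_pad(name, 16) for name in cont.channel_names)
    sig += b"".join(_pad("", 80) for _ in range(n_ch))  # transducer
    sig += b"".join(_pad("uV", 8) for _ in range(n_ch))
    sig += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in phys_min)
    sig += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in phys_max)
    sig += b"".join(_pad(str(dig_min), 8) for _ in range(n_ch))
    sig += b"".join(_pad(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 80) for _ in range(n_ch))  # prefiltering
    sig += b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 32) for _ in range(n_ch))

    digital = np.empty((n_ch, n_records * spr), dtype="<i2")
    for c in range(n_ch):
        digital[c] = np.round(
            (data[c] - phys_min[c]) * scale[c] + dig_min
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def write_events(events: list[tuple[int, str]], path: str | Path,
                 n_samples: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("onset_sample\tlabel\n")
        if n_samples is not None:
            fh.write(f"# n_samples={n_samples}\n")
        for onset, label in events:
            fh.write(f"{onset}\t{label}\n")


def read_events(path: str | Path) -> tuple[list[tuple[int, str]], int | None]:
    events: list[tuple[int, str]] = []
    n_samples = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("onset_sample"):
                continue
            if line.startswith("#"):
                if "n_samples=" in line:
                    n_samples = int(line.split("n_samples=")[1])
                continue
            onset, label = line.split("\t")
            events.append((int(onset), label))
    return events, n_samples


def write_montage(names: list[str], positions: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(names, positions):
            fh.write(f"{name}\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")


def read_montage(path: str | Path) -> tuple[list[str], np.ndarray]:
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, x, y, z = line.split()
            names.append(name)
            rows.append([float(x), float(y), float(z)])
    return names, np.asarray(rows)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# recording reader (EDF / BrainVision via MNE)
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    fmt: str | None = None,
    events_path: str | Path | None = None,
    montage_path: str | Path | None = None,
    drop_channel_pattern: str | None = None,
) -> ContinuousEEG:
    """Load a continuous recording from EDF or BrainVision into microvolts.

    Events come from the tab-separated sidecar when given, otherwise from
    embedded annotations.  ``drop_channel_pattern`` removes matching channels
    (e.g. ``"EOG*"`` to drop electro-oculogram channels).  Channel positions
    come from the montage file when given, otherwise a unit-sphere layout
    must be supplied downstream.
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    names = list(raw.ch_names)
    if drop_channel_pattern:
        keep = [n for n in names if not fnmatch.fnmatch(n, drop_channel_pattern)]
        raw = raw.pick(keep)
        names = keep
    samples = raw.get_data() * 1e6  # Volts -> uV

    events: list[tuple[int, str]] = []
    n_samples = None
    if events_path is not None:
        events, n_samples = read_events(events_path)
    elif len(raw.annotations):
        fs = raw.info["sfreq"]
        events = [(int(round(a["onset"] * fs)), str(a["description"]))
                  for a in raw.annotations]
    if not events:
        raise ValueError(
            "no events found; supply the tab-separated events sidecar "
            "(onset_sample, label)"
        )
    if n_samples is not None:
        samples = samples[:, :n_samples]

    if montage_path is not None:
        mnames, pos = read_montage(montage_path)
        index = {n: k for k, n in enumerate(mnames)}
        pos = np.stack([pos[index[n]] for n in names])
    else:
        # fall back to unit-normalized positions at regular ring angles
        ang = 2 * np.pi * np.arange(len(names)) / max(len(names), 1)
        pos = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)

    return ContinuousEEG(samples=samples, sampling_rate=float(raw.info["sfreq"]),
                         channel_names=names, channel_positions=pos, events=events)


# ---------------------------------------------------------------------------
# epoch container round trip
# ---------------------------------------------------------------------------

def write_epochs(ep: EpochedEEG, path: str | Path) -> None:
    meta = {
        "version": EPOCHS_FORMAT_VERSION,
        "t0_offset_ms": ep.t0_offset_ms,
        "sampling_rate": ep.sampling_rate,
        "channel_names": ep.channel_names,
        "subject_id": ep.subject_id,
        "session": ep.session,
        "task": ep.task,
        "bad_channels": list(ep.bad_channels),
    }
    np.savez_compressed(
        path,
        data=ep.data,
        channel_positions=ep.channel_positions,
        kept_epoch_indices=ep.kept_epoch_indices,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def read_epochs(path: str | Path) -> EpochedEEG:
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta.get("version") != EPOCHS_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported epochs container version {meta.get('version')}"
                )
            return EpochedEEG(
                data=z["data"],
                t0_offset_ms=meta["t0_offset_ms"],
                sampling_rate=meta["sampling_rate"],
                channel_names=meta["channel_names"],
                channel_positions=z["channel_positions"],
                subject_id=meta["subject_id"],
                session=meta["session"],
                task=meta["task"],
                kept_epoch_indices=z["kept_epoch_indices"],
                bad_channels=meta["bad_channels"],
            )
    except (OSError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as err:
        raise ValueError(f"corrupt or truncated epochs container {path}: {err}") from err
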