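"""Persistence and interchange: HDF5 run container, EDF/BrainVision access.

Reading standard EEG formats goes through MNE's native readers.  Because no
installed library writes these formats, two deliberately minimal writers
(16-bit EDF and an IEEE-float BrainVision triplet) are provided so round
trips can be exercised; they support plain continuous multichannel data in
microvolts and nothing more.  Run artifacts (epochs, grids, model weights)
live in a single HDF5 container per run.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core import ContinuousSignal, EpochedSignal

_MNE_UNIT = 1e-6  # MNE uses volts internally; this package uses microvolts


# ---------------------------------------------------------------------------
# standard formats
# ---------------------------------------------------------------------------

def read_eeg(path, fmt: str | None = None) -> ContinuousSignal:
    """Read an EDF or BrainVision recording into microvolt continuous data.

    ``fmt`` is "edf" or "brainvision"; when omitted it is inferred from the
    extension (.edf / .vhdr).  Malformed files raise a ValueError naming the
    file.
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer EEG format from {path.name!r}")
    if fmt not in ("edf", "brainvision"):
        raise ValueError(f"unsupported EEG format {fmt!r}")
    try:
        if fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed headers
        raise ValueError(f"failed to parse {path.name}: {exc}") from exc
    return ContinuousSignal(
        data=raw.get_data() / _MNE_UNIT,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def write_edf(signal: ContinuousSignal, path) -> None:
    """Minimal EDF writer: 1-second records, 16-bit samples, microvolt units.

    Supports integer sampling rates; a trailing partial second is dropped.
    Amplitudes are scaled per channel to the full digital range, so the
    round-trip error is bounded by the 16-bit quantization step.
    """
    fs = int(round(signal.fs_hz))
    if abs(fs - signal.fs_hz) > 1e-9:
        raise ValueError("EDF writer supports integer sampling rates only")
    n_ch = signal.n_channels
    n_rec = signal.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = signal.data[:, : n_rec * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min, dig_max,
    ).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),  # version
            f("X X X X", 80),  # patient id
            f("Startdate X X X X", 80),  # recording id
            f("01.01.00", 8), f("00.00.00", 8),  # date, time
            f(256 * (1 + n_ch), 8),  # header bytes
            f("", 44),
            f(n_rec, 8), f("1", 8),  # n records, record duration s
            f(n_ch, 4),
        ]
    )
    header += b"".join(f(name, 16) for name in signal.channel_names)
    header += b"".join(f("EEG", 80) for _ in range(n_ch))
    header += b"".join(f("uV", 8) for _ in range(n_ch))
    header += b"".join(f(f"{pm:.6g}"[:8], 8) for pm in phys_min)
    header += b"".join(f(f"{pm:.6g}"[:8], 8) for pm in phys_max)
    header += b"".join(f(dig_min, 8) for _ in range(n_ch))
    header += b"".join(f(dig_max, 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))
    header += b"".join(f(fs, 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * fs : (r + 1) * fs].tobytes())


def write_brainvision(signal: ContinuousSignal, path_vhdr) -> None:
    """Minimal BrainVision triplet writer (IEEE float32, multiplexed, uV)."""
    path_vhdr = Path(path_vhdr)
    stem = path_vhdr.with_suffix("")
    path_eeg, path_vmrk = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")
    interval_us = 1e6 / signal.fs_hz
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={path_eeg.name}",
        f"MarkerFile={path_vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={signal.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(signal.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    path_vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    path_vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\n"
        f"DataFile={path_eeg.name}\n\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    signal.data.T.astype("<f4").tofile(path_eeg)


# ---------------------------------------------------------------------------
# HDF5 run container
# ---------------------------------------------------------------------------

def save_epochs(path, epochs: EpochedSignal, name: str = "epochs") -> None:
    """Persist epochs under /<name>: /data, /fs, /t0_ms, /channels, /trials."""
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("fs", data=epochs.fs_hz)
        g.create_dataset("t0_ms", data=epochs.t0_ms)
        g.create_dataset("channels", data=np.array(epochs.channel_names, dtype="S"))
        g.create_dataset("trials", data=epochs.trial_indices)


def load_epochs(path, name: str = "epochs") -> EpochedSignal:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        return EpochedSignal(
            data=g["data"][()],
            fs_hz=float(g["fs"][()]),
            t0_ms=float(g["t0_ms"][()]),
            channel_names=[s.decode() for s in g["channels"][()]],
            trial_indices=g["trials"][()],
        )


def save_grid(path, grid, name: str = "grid") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("positions", data=grid.voxel_positions)
        g.create_dataset("leadfield", data=grid.leadfield)
        g.create_dataset("labels", data=np.array(grid.region_labels, dtype="S"))
        g.create_dataset("edge_mm", data=grid.voxel_edge_mm)
        if grid.sensor_positions is not None:
            g.create_dataset("sensors", data=grid.sensor_positions)


def load_grid(path, name: str = "grid"):
    from .sourceloc import SourceGrid

    with h5py.File(path, "r") as fh:
        g = fh[name]
        return SourceGrid(
            voxel_positions=g["positions"][()],
            voxel_edge_mm=float(g["edge_mm"][()]),
            leadfield=g["leadfield"][()],
            region_labels=np.array([s.decode() for s in g["labels"][()]], dtype=object),
            sensor_positions=g["sensors"][()] if "sensors" in g else None,
        )


def save_model(path, model, name: str = "model") -> None:
    """Persist network weights and shape; training history stays in CSV."""
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        for key in ("Wh", "bh", "Wo", "bo"):
            g.create_dataset(key, data=getattr(model, key))
        g.create_dataset("order", data=model.order)
        g.create_dataset("n_channels", data=model.n_channels)
        g.create_dataset("stop_epoch", data=model.stop_epoch)
        if model.mean is not None:
            g.create_dataset("mean", data=model.mean)
            g.create_dataset("sd", data=model.sd)


def load_model_weights(path, name: str = "model") -> dict:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        return {k: (g[k][()] if k in g else None)
                for k in ("Wh", "bh", "Wo", "bo", "order", "n_channels",
                          "stop_epoch", "mean", "sd")}
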