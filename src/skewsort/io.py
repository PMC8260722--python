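"""Reading and writing recordings, events and waveform matrices.

Recordings travel as flat little-endian binary (int16 or float32) plus a
JSON sidecar declaring ``fs``, ``dtype`` and ``scale`` (volts per count),
or as a single-column CSV of voltages.  Events and labels are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import SpikeEvents, WaveformSet
from .preprocess import ConfigurationError, RecordingSignal

_DTYPES = {"int16": "<i2", "float32": "<f4"}


def write_recording(path: str | Path, sig: RecordingSignal,
                    dtype: str = "float32", scale: float = 1.0) -> Path:
    """Write samples as flat binary and a JSON sidecar next to it."""
    path = Path(path)
    if dtype not in _DTYPES:
        raise ConfigurationError(f"unsupported dtype {dtype!r}")
    raw = (sig.samples / scale).astype(_DTYPES[dtype])
    raw.tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "fs": sig.fs, "dtype": dtype, "scale": scale, "channel": 0,
        "t0": sig.t0, "n": int(sig.samples.size),
    }))
    return sidecar


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> RecordingSignal:
    """Read a flat binary recording described by its JSON sidecar.

    The sidecar must declare ``fs`` and ``dtype``; ``scale`` multiplies the
    stored counts into voltage units (default 1.0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ConfigurationError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ConfigurationError("sidecar must declare 'fs'")
    dtype = meta.get("dtype", "float32")
    if dtype not in _DTYPES:
        raise ConfigurationError(f"unsupported dtype {dtype!r}")
    raw = np.fromfile(path, dtype=_DTYPES[dtype])
    n = meta.get("n")
    if n is not None and raw.size != int(n):
        raise IOError(f"expected {n} samples, file holds {raw.size} (truncated?)")
    samples = raw.astype(float) * float(meta.get("scale", 1.0))
    return RecordingSignal(samples, float(meta["fs"]), float(meta.get("t0", 0.0)))


def read_recording_csv(path: str | Path, fs: float) -> RecordingSignal:
    """Read a single-column CSV of voltages; ``fs`` comes from config."""
    samples = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(float)
    return RecordingSignal(samples, fs)


def write_events(path: str | Path, events: SpikeEvents) -> None:
    pd.DataFrame({"index": events.indices, "time_s": events.times_s}
                 ).to_csv(path, index=False)


def read_events(path: str | Path, fs: float) -> SpikeEvents:
    df = pd.read_csv(path)
    return SpikeEvents(df["index"].to_numpy(np.int64), fs)


def write_waveforms(path: str | Path, ws: WaveformSet,
                    pre_s: float | None = None, post_s: float | None = None) -> Path:
    """Waveforms as flat float32 row-major binary plus JSON sidecar."""
    path = Path(path)
    ws.W.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "n": ws.n, "T": ws.T, "fs": ws.fs, "pre": ws.pre,
        "sigma_n": ws.sigma_n, "pre_s": pre_s, "post_s": post_s,
        "event_indices": [int(i) for i in ws.event_indices],
    }))
    return sidecar


def read_waveforms(path: str | Path, sidecar: str | Path | None = None) -> WaveformSet:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    W = np.fromfile(path, dtype="<f4").reshape(int(meta["n"]), int(meta["T"]))
    return WaveformSet(W.astype(float), np.asarray(meta["event_indices"], np.int64),
                       float(meta["fs"]), int(meta["pre"]), float(meta["sigma_n"]))


def write_labels(path: str | Path, indices: np.ndarray, fs: float,
                 labels: np.ndarray) -> None:
    """Per-spike cluster labels, sorted by event time.

    Alignment may shift neighbouring events past each other, so the rows
    are sorted here rather than assuming monotone input.
    """
    indices = np.asarray(indices, np.int64)
    order = np.argsort(indices, kind="stable")
    pd.DataFrame({
        "event_index": indices[order],
        "time_s": indices[order] / fs,
        "cluster": np.asarray(labels, int)[order],
    }).to_csv(path, index=False)
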