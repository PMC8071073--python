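"""WAV audio, Raven-style selection tables, and dataset manifests.

All audio is handled as :class:`Waveform` objects: float samples in [-1, 1]
plus a sample rate.  Integer PCM (16/24/32-bit) is packed/unpacked with
numpy on top of the stdlib ``wave`` module; 24-bit — the bit depth of the
archived field recordings — has no numpy dtype and is assembled bytewise.
"""

from __future__ import annotations

import logging
import os
import wave
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "TrainSelection",
    "read_wav",
    "write_wav",
    "read_selection_table",
    "write_selection_table",
    "load_manifest",
]

#: Required columns of a Raven-style selection table.
BEGIN_COL = "Begin Time (s)"
END_COL = "End Time (s)"
#: Optional annotation columns carried through round trips.
LINEAGE_COL = "Lineage"
OVERLAP_COL = "Overlapped"


@dataclass(frozen=True)
class Waveform:
    """A mono pressure time series.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, nominally within [-1, 1].
    rate : float
        Sample rate in Hz.
    origin_time : float
        Offset (s) of the first sample within its source file.
    """

    samples: np.ndarray
    rate: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def slice(self, begin: float, end: float) -> "Waveform":
        """Half-open time slice [begin, end) in seconds from file start."""
        i0 = int(round((begin - self.origin_time) * self.rate))
        i1 = int(round((end - self.origin_time) * self.rate))
        i0 = max(i0, 0)
        return replace(self, samples=self.samples[i0:i1], origin_time=begin)


@dataclass(frozen=True)
class TrainSelection:
    """One click train delimited inside a recording, Raven-style."""

    file: str
    begin_s: float
    end_s: float
    lineage: str | None = None
    overlapped: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.begin_s < self.end_s):
            raise ValueError(
                f"invalid selection interval [{self.begin_s}, {self.end_s})"
            )


def _pcm_limits(bit_depth: int) -> int:
    if bit_depth not in (16, 24, 32):
        raise ValueError(f"unsupported bit depth {bit_depth} (use 16, 24 or 32)")
    return 2 ** (bit_depth - 1)


def read_wav(path: str | os.PathLike, channel: int | None = None) -> Waveform:
    """Read a PCM WAV file into a float waveform scaled to [-1, 1].

    Parameters
    ----------
    channel : int, optional
        Required for multichannel files; selects one channel.
    """
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            sampwidth = wf.getsampwidth()
            rate = wf.getframerate()
            n_frames = wf.getnframes()
            raw = wf.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise ValueError(f"{path}: not a readable PCM WAV file ({exc})") from exc

    if n_channels > 1 and channel is None:
        raise ValueError(
            f"{path}: {n_channels} channels present; a channel index is required"
        )
    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64)
    elif sampwidth == 4:
        data = np.frombuffer(raw, dtype="<i4").astype(np.float64)
    elif sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        # assemble little-endian 24-bit two's complement
        data = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        data = np.where(data >= 2**23, data - 2**24, data).astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported sample width {sampwidth} bytes")

    if n_channels > 1:
        data = data.reshape(-1, n_channels)[:, channel]
    full_scale = float(_pcm_limits(8 * sampwidth))
    return Waveform(samples=data / full_scale, rate=float(rate))


def write_wav(path: str | os.PathLike, w: Waveform, bit_depth: int = 24) -> None:
    """Write a waveform as integer PCM (RIFF/WAVE), default 24-bit.

    Samples outside [-1, 1] are clamped with a logged warning.
    """
    full_scale = _pcm_limits(bit_depth)
    samples = w.samples
    peak = float(np.max(np.abs(samples))) if samples.size else 0.0
    if peak > 1.0:
        logger.warning("write_wav %s: clipping input (peak %.3f), clamping", path, peak)
        samples = np.clip(samples, -1.0, 1.0)
    ints = np.round(samples * (full_scale - 1)).astype(np.int32)

    if bit_depth == 16:
        raw = ints.astype("<i2").tobytes()
    elif bit_depth == 32:
        raw = ints.astype("<i4").tobytes()
    else:  # 24-bit
        u = ints.astype(np.int64) & 0xFFFFFF
        b = np.empty((ints.size, 3), dtype=np.uint8)
        b[:, 0] = u & 0xFF
        b[:, 1] = (u >> 8) & 0xFF
        b[:, 2] = (u >> 16) & 0xFF
        raw = b.tobytes()

    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(bit_depth // 8)
        wf.setframerate(int(round(w.rate)))
        wf.writeframes(raw)


def read_selection_table(path: str | os.PathLike) -> list[TrainSelection]:
    """Parse a Raven-style tab-separated selection table.

    Requires "Begin Time (s)" and "End Time (s)"; carries through the
    optional Lineage and Overlapped annotation columns; any other Raven
    columns (Low Freq, Channel, ...) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (BEGIN_COL, END_COL) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required selection-table columns {missing}; "
            f"found {list(df.columns)}"
        )
    selections = []
    for i, row in df.iterrows():
        begin, end = float(row[BEGIN_COL]), float(row[END_COL])
        if not (0 <= begin < end):
            raise ValueError(f"{path}: row {i}: invalid interval [{begin}, {end})")
        selections.append(
            TrainSelection(
                file=str(row["File"]) if "File" in df.columns else str(path),
                begin_s=begin,
                end_s=end,
                lineage=(
                    str(row[LINEAGE_COL])
                    if LINEAGE_COL in df.columns and pd.notna(row[LINEAGE_COL])
                    else None
                ),
                overlapped=bool(int(row[OVERLAP_COL])) if OVERLAP_COL in df.columns else False,
            )
        )
    return selections


def write_selection_table(
    selections: list[TrainSelection], path: str | os.PathLike
) -> None:
    """Inverse of :func:`read_selection_table`; round-trips losslessly."""
    df = pd.DataFrame(
        {
            "File": [s.file for s in selections],
            BEGIN_COL: [s.begin_s for s in selections],
            END_COL: [s.end_s for s in selections],
            LINEAGE_COL: [s.lineage if s.lineage is not None else "" for s in selections],
            OVERLAP_COL: [int(s.overlapped) for s in selections],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load a dataset manifest CSV (columns: file, lineage[, overlapped]).

    File paths are resolved relative to the manifest's directory; missing
    files raise with the full list.  Unknown lineage labels are allowed
    (logged), since cluster labels such as Ispp1..k are legitimate.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and not {"file", "lineage"} <= set(df.columns):
        return pd.DataFrame(columns=["file", "lineage", "overlapped"])
    missing_cols = [c for c in ("file", "lineage") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: manifest missing columns {missing_cols}")
    if "overlapped" not in df.columns:
        df["overlapped"] = 0
    df["file"] = [str(path.parent / f) for f in df["file"]]
    missing = [f for f in df["file"] if not Path(f).is_file()]
    if missing:
        raise FileNotFoundError(f"{path}: missing audio files: {missing}")
    known = {"Ia", "Igg", "Igh", "Ispp"}
    for lab in sorted(set(df["lineage"]) - known):
        logger.info("manifest %s: non-standard lineage label %r", path, lab)
    return df
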