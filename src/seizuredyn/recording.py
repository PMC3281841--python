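"""Multichannel recording container and file I/O.

The canonical on-disk format is a delimited numeric matrix: ``#``-prefixed
metadata lines (sampling rate, units), a header row of channel names, and
one column per channel.  EDF files can be read when the optional ``mne``
dependency is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesRecording", "read_recording", "write_recording"]


@dataclass
class TimeSeriesRecording:
    """Channels x samples matrix with sampling-rate metadata."""

    channel_names: list[str]
    data: np.ndarray
    fs: float
    units: str = "a.u."

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match the channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def write_recording(rec: TimeSeriesRecording, path) -> None:
    """Write a recording as a delimited matrix with metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write(f"# units: {rec.units}\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.10g")


def _read_matrix(path: Path) -> TimeSeriesRecording:
    fs = None
    units = "a.u."
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            key = key.strip().lower()
            if key == "fs":
                fs = float(value)
            elif key == "units":
                units = value.strip()
    if fs is None:
        raise ValueError(f"{path}: missing 'fs' metadata line ('# fs: <Hz>')")
    try:
        df = pd.read_csv(path, sep="\t", skiprows=header_lines, header=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged rows or malformed table: {exc}") from exc
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at data row {row}, "
                f"column {col!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in data table")
    return TimeSeriesRecording(
        channel_names=[str(c) for c in df.columns],
        data=df.to_numpy().T,
        fs=fs,
        units=units,
    )


def _read_edf(path: Path) -> TimeSeriesRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return TimeSeriesRecording(
        channel_names=list(raw.ch_names),
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        units="V",
    )


def read_recording(path, format: str | None = None) -> TimeSeriesRecording:
    """Read a recording from a delimited matrix file or an EDF file.

    ``format`` is "matrix" or "edf"; when omitted it is inferred from the
    file extension (.edf -> EDF, everything else -> matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "matrix":
        return _read_matrix(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'matrix' or 'edf'")
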