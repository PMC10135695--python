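"""Signal ingestion and export.

CSV with one sample per line is the canonical interchange format; an
optional single header line is tolerated.  WFDB records (the header +
signal file layout used by the public physiological corpora) can be read
when the ``wfdb`` package is installed; its absence degrades gracefully
with a clear message rather than an import crash, so the rest of the
package works with zero downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class SignalParseError(ValueError):
    """A signal file contained an unparseable token."""


class MissingDependencyError(ImportError):
    """An optional dependency needed for this operation is not installed."""


@dataclass
class SignalRecord:
    """A one-dimensional signal with optional acquisition metadata."""

    samples: np.ndarray
    sampling_rate_hz: float | None = None
    source_id: str = ""


def read_signal_csv(path) -> SignalRecord:
    """Read a one-sample-per-line CSV file.

    Blank lines are skipped; a single non-numeric first line is treated
    as a header.  Any other non-numeric token raises
    :class:`SignalParseError` naming the offending line.
    """
    path = Path(path)
    samples: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip()
            if not token:
                continue
            try:
                samples.append(float(token))
            except ValueError:
                if lineno == 1 and not samples:
                    continue  # header line
                raise SignalParseError(
                    f"{path}: non-numeric value {token!r} on line {lineno}"
                ) from None
    if not samples:
        raise SignalParseError(f"{path}: no numeric samples found")
    return SignalRecord(samples=np.asarray(samples), source_id=path.stem)


def write_signal_csv(path, samples: np.ndarray) -> None:
    """Write one sample per line with full double precision."""
    arr = np.asarray(samples, dtype=float).ravel()
    with open(path, "w") as fh:
        for v in arr:
            fh.write(f"{float(v)!r}\n")


def read_wfdb_record(path, channel: int = 0) -> SignalRecord:
    """Read one channel of a WFDB record (optional capability).

    Requires the ``wfdb`` package; when it is not installed this raises
    :class:`MissingDependencyError` with installation advice instead of
    failing at import time.
    """
    try:
        import wfdb  # type: ignore
    except ImportError:
        raise MissingDependencyError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); CSV input needs no extra dependency"
        ) from None
    path = Path(path)
    try:
        record = wfdb.rdrecord(str(path))
    except FileNotFoundError as exc:
        raise IOError(f"WFDB record not found: {path}") from exc
    if not 0 <= channel < record.n_sig:
        raise IOError(
            f"channel {channel} out of range for {record.n_sig}-channel record"
        )
    return SignalRecord(
        samples=np.asarray(record.p_signal[:, channel], dtype=float),
        sampling_rate_hz=float(record.fs),
        source_id=path.stem,
    )
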