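"""Evaluation metrics for lossy bio-signal compression: CR, PRD, NCC, QS.

PRD is the percentage root-mean-square difference with the raw-signal
baseline, ``sqrt(sum (f-F)^2 / sum f^2) * 100`` — no mean removal or
amplitude offset (the mean-removed "PRDN" variant is deliberately not
provided).  CR is reported under sample-count accounting, original
samples over retained coefficients; a bit-level accounting that also
charges for the stored coefficient indices is available separately.  QS
is CR/PRD, the single-number quality/compression trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given inputs (e.g. zero variance)."""


def prd(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Percentage root-mean-square difference between two signals."""
    f = np.asarray(original, dtype=float).ravel()
    g = np.asarray(reconstructed, dtype=float).ravel()
    if f.size != g.size:
        raise ValueError(f"length mismatch: {f.size} vs {g.size}")
    denom = float(np.sum(f * f))
    if denom == 0.0:
        raise UndefinedMetricError("PRD undefined for an all-zero original signal")
    return float(np.sqrt(np.sum((f - g) ** 2) / denom) * 100.0)


def ncc(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Normalized (Pearson-form) cross-correlation, in [-1, 1]."""
    f = np.asarray(original, dtype=float).ravel()
    g = np.asarray(reconstructed, dtype=float).ravel()
    if f.size != g.size:
        raise ValueError(f"length mismatch: {f.size} vs {g.size}")
    if f.size < 2:
        raise ValueError("NCC needs at least two samples")
    df = f - f.mean()
    dg = g - g.mean()
    denom = np.sqrt(np.sum(df * df) * np.sum(dg * dg))
    if denom == 0.0:
        raise UndefinedMetricError("NCC undefined for a constant signal")
    return float(np.clip(np.sum(df * dg) / denom, -1.0, 1.0))


def cr(n_original: int, n_retained: int) -> float:
    """Compression ratio under sample-count accounting."""
    if n_original <= 0 or n_retained <= 0:
        raise ValueError("sample counts must be positive")
    return n_original / n_retained


def qs(cr_value: float, prd_value: float) -> float:
    """Quality score CR/PRD; higher is better."""
    if prd_value <= 0.0:
        raise UndefinedMetricError(
            "QS undefined at PRD = 0 (lossless reconstruction)"
        )
    return cr_value / prd_value


def bit_level_cr(
    n_samples: int,
    n_blocks: int,
    subset_size: int,
    sample_bits: int = 11,
    index_bits: int = 8,
    value_bits: int = 64,
) -> float:
    """Compression ratio under bit accounting.

    Charges the compressed stream for both the retained coefficient
    values and their in-block indices; the original is costed at
    ``sample_bits`` per sample (11 bits matches common ECG ADC depth).
    This is a secondary accounting — the headline CR above counts
    samples only.
    """
    if min(n_samples, n_blocks, subset_size) <= 0:
        raise ValueError("counts must be positive")
    original_bits = n_samples * sample_bits
    compressed_bits = n_blocks * subset_size * (index_bits + value_bits)
    return original_bits / compressed_bits


@dataclass(frozen=True)
class QualityReport:
    """CR, PRD, NCC and QS for one original/reconstructed pair.

    ``qs`` is None when PRD is exactly 0 (lossless)."""

    cr: float
    prd: float
    ncc: float
    qs: float | None

    def to_csv_row(self) -> str:
        qs_txt = "lossless" if self.qs is None else repr(self.qs)
        return f"{self.cr!r},{self.prd!r},{self.ncc!r},{qs_txt}"


def evaluate(
    original: np.ndarray,
    reconstructed: np.ndarray,
    n_original: int,
    n_retained: int,
) -> QualityReport:
    """Compute the full quality report for a signal pair."""
    p = prd(original, reconstructed)
    return QualityReport(
        cr=cr(n_original, n_retained),
        prd=p,
        ncc=ncc(original, reconstructed),
        qs=None if p == 0.0 else qs(cr(n_original, n_retained), p),
    )
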