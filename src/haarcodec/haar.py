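"""Orthonormal Haar wavelet kernel and block transforms.

The codec operates on fixed-length blocks of a one-dimensional signal.
Each block ``B`` (a row vector of length ``N``) is mapped to its Haar
coefficients by ``T = B A^T`` and recovered by ``R = T A``, where ``A``
is the N x N orthonormal Haar matrix: row 0 is the constant scaling
function ``1/sqrt(N)``, row 1 the mother wavelet, and the remaining rows
its dyadic dilations and translations.  Orthonormality (``A A^T = I``)
makes the two maps exact mutual inverses and preserves Euclidean norm
(Parseval), which is what lets coefficient energy stand in for
reconstruction error downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_VALID_ORDERS = (2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class HaarKernel:
    """An orthonormal Haar matrix together with its order.

    Attributes
    ----------
    order : int
        Block length N, a power of two in {2, 4, 8, 16, 32, 64}.
    matrix : numpy.ndarray
        The N x N orthonormal Haar matrix A.
    """

    order: int
    matrix: np.ndarray


def build_haar_matrix(order: int) -> HaarKernel:
    """Construct the orthonormal Haar kernel of the given order.

    Row ``i >= 1`` is indexed by its dyadic decomposition
    ``i = 2**j + k - 1`` with dilation level ``j`` and translation
    ``k = 1..2**j``: it takes the value ``+2**(j/2)/sqrt(N)`` on the
    first half of its support, the negated value on the second half,
    and zero elsewhere.

    Parameters
    ----------
    order : int
        Power of two in {2, 4, 8, 16, 32, 64}.

    Returns
    -------
    HaarKernel

    Raises
    ------
    ValueError
        If ``order`` is not a supported power of two.
    """
    if not isinstance(order, (int, np.integer)) or order not in _VALID_ORDERS:
        raise ValueError(
            f"order must be a power of two in {_VALID_ORDERS}, got {order!r}"
        )
    n = int(order)
    a = np.zeros((n, n))
    a[0, :] = 1.0 / np.sqrt(n)
    # midpoints of the unit-interval cells; avoids boundary ambiguity
    x = (np.arange(n) + 0.5) / n
    for i in range(1, n):
        j = int(np.floor(np.log2(i)))
        k = i - 2**j + 1
        amp = 2.0 ** (j / 2.0) / np.sqrt(n)
        lo = (k - 1) / 2.0**j
        mid = (k - 0.5) / 2.0**j
        hi = k / 2.0**j
        a[i, (x >= lo) & (x < mid)] = amp
        a[i, (x >= mid) & (x < hi)] = -amp
    return HaarKernel(order=n, matrix=a)


def forward_block(block: np.ndarray, kernel: HaarKernel) -> np.ndarray:
    """Forward transform of one block: ``T = B A^T``."""
    b = np.asarray(block, dtype=float)
    if b.ndim != 1 or b.shape[0] != kernel.order:
        raise ValueError(
            f"block length {b.shape} does not match kernel order {kernel.order}"
        )
    return b @ kernel.matrix.T


def inverse_block(coeffs: np.ndarray, kernel: HaarKernel) -> np.ndarray:
    """Inverse transform of one coefficient block: ``R = T A``."""
    t = np.asarray(coeffs, dtype=float)
    if t.ndim != 1 or t.shape[0] != kernel.order:
        raise ValueError(
            f"coefficient length {t.shape} does not match kernel order "
            f"{kernel.order}"
        )
    return t @ kernel.matrix


def partition_signal(signal: np.ndarray, order: int) -> tuple[np.ndarray, int]:
    """Split a signal into zero-padded blocks of length ``order``.

    Returns
    -------
    blocks : numpy.ndarray, shape (n_blocks, order)
    padding : int
        Number of trailing zeros appended to fill the last block;
        recorded so reassembly restores the exact original length.
    """
    s = np.asarray(signal, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("cannot partition an empty signal")
    n_blocks = -(-s.size // order)  # ceil division
    padding = n_blocks * order - s.size
    padded = np.concatenate([s, np.zeros(padding)])
    return padded.reshape(n_blocks, order), padding


def reassemble_signal(blocks: np.ndarray, padding: int) -> np.ndarray:
    """Concatenate blocks and strip the recorded padding."""
    flat = np.asarray(blocks, dtype=float).reshape(-1)
    if padding < 0 or padding >= flat.size:
        raise ValueError(f"padding {padding} inconsistent with {flat.size} samples")
    return flat[: flat.size - padding] if padding else flat
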