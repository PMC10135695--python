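"""The compression/decompression pipeline.

Compression partitions the signal into blocks of ``N`` samples,
transforms each block with the orthonormal Haar kernel, and keeps only
``SS`` of the ``N`` coefficients per block; the rest are set to zero.
Which ``SS`` positions to keep is chosen per block by the configured
selector:

``covidoa``
    the metaheuristic searches position space minimizing the block PRD
    (the default, and the method of record);
``exhaustive``
    brute force over all C(N, SS) subsets — an oracle for testing;
``magnitude``
    the SS largest-magnitude coefficients — optimal for an orthonormal
    transform by Parseval, the second oracle.

Decompression scatters the stored (position, value) pairs back into
zero-filled coefficient blocks, applies the inverse transform,
concatenates and strips padding.  The container serializes to a small
little-endian binary format (magic ``HWCO``) or to an equivalent JSON
dialect for debugging.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .covidoa import CovidoaConfig, optimize
from .haar import (
    HaarKernel,
    build_haar_matrix,
    forward_block,
    inverse_block,
    partition_signal,
    reassemble_signal,
)
from .metrics import prd as _prd_metric

_MAGIC = b"HWCO"
_FORMAT_VERSION = 1
_SELECTION_MODES = ("covidoa", "exhaustive", "magnitude")


class ContainerFormatError(ValueError):
    """A compressed container is malformed."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CompressionConfig:
    """Codec settings.

    ``subset_size`` may instead be derived from a percent-reduction value
    with :func:`subset_size_from_percent`.  The optimizer settings are the
    method's standard ones (population 30, 50 iterations, 2 proteins,
    shift 1, mutation rate 0.5) and rarely need changing.
    """

    block_order: int
    subset_size: int
    selection_mode: str = "covidoa"
    seed: int = 0
    population_size: int = 30
    max_iterations: int = 50
    num_proteins: int = 2
    shift_count: int = 1
    mutation_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.subset_size <= self.block_order:
            raise ValueError(
                f"subset_size must lie in [1, {self.block_order}], "
                f"got {self.subset_size}"
            )
        if self.selection_mode not in _SELECTION_MODES:
            raise ValueError(
                f"selection_mode must be one of {_SELECTION_MODES}, "
                f"got {self.selection_mode!r}"
            )

    def optimizer_config(self, seed: int) -> CovidoaConfig:
        return CovidoaConfig(
            dimension=self.subset_size,
            lower_bound=1.0,
            upper_bound=float(self.block_order),
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            num_proteins=self.num_proteins,
            shift_count=self.shift_count,
            mutation_rate=self.mutation_rate,
            rng_seed=seed,
        )


@dataclass
class CompressedSignal:
    """Retained (position, value) pairs per block plus header metadata.

    Positions are 1-based in-block coefficient indices, distinct and
    sorted ascending within each block.
    """

    block_order: int
    subset_size: int
    original_length: int
    padding: int
    seed: int
    positions: np.ndarray  # (n_blocks, SS) int, 1-based
    values: np.ndarray  # (n_blocks, SS) float64
    version: int = _FORMAT_VERSION

    @property
    def n_blocks(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        if self.positions.shape != self.values.shape:
            raise ContainerFormatError("positions/values shape mismatch")
        if self.n_blocks * self.block_order - self.padding != self.original_length:
            raise ContainerFormatError(
                "block count, padding and original_length are inconsistent"
            )
        for b in range(self.n_blocks):
            pos = self.positions[b]
            if pos.min(initial=1) < 1 or pos.max(initial=1) > self.block_order:
                raise ContainerFormatError(
                    f"block {b}: position out of range 1..{self.block_order}"
                )
            if len(set(pos.tolist())) != pos.size:
                raise ContainerFormatError(f"block {b}: duplicate positions")
            if not np.all(np.diff(pos) > 0):
                raise ContainerFormatError(f"block {b}: positions not sorted")

    # --- serialization -------------------------------------------------

    def to_bytes(self) -> bytes:
        head = struct.pack(
            "<4sBBBQBQI",
            _MAGIC,
            self.version,
            self.block_order,
            self.subset_size,
            self.original_length,
            self.padding,
            self.seed,
            self.n_blocks,
        )
        body = bytearray()
        for b in range(self.n_blocks):
            body += bytes(int(p) for p in self.positions[b])
            body += np.asarray(self.values[b], dtype="<f8").tobytes()
        return head + bytes(body)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CompressedSignal":
        head_size = struct.calcsize("<4sBBBQBQI")
        if len(blob) < head_size:
            raise ContainerFormatError("container truncated before header end")
        magic, version, n, ss, length, padding, seed, n_blocks = struct.unpack(
            "<4sBBBQBQI", blob[:head_size]
        )
        if magic != _MAGIC:
            raise ContainerFormatError(f"bad magic bytes {magic!r}")
        rec = ss + 8 * ss
        expected = head_size + n_blocks * rec
        if len(blob) != expected:
            raise ContainerFormatError(
                f"container size {len(blob)} != expected {expected}"
            )
        positions = np.empty((n_blocks, ss), dtype=int)
        values = np.empty((n_blocks, ss))
        off = head_size
        for b in range(n_blocks):
            positions[b] = np.frombuffer(blob[off : off + ss], dtype=np.uint8)
            off += ss
            values[b] = np.frombuffer(blob[off : off + 8 * ss], dtype="<f8")
            off += 8 * ss
        out = cls(
            block_order=n,
            subset_size=ss,
            original_length=length,
            padding=padding,
            seed=seed,
            positions=positions,
            values=values,
            version=version,
        )
        out.validate()
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "HWCO",
                "version": self.version,
                "block_order": self.block_order,
                "subset_size": self.subset_size,
                "original_length": self.original_length,
                "padding": self.padding,
                "seed": self.seed,
                "positions": self.positions.tolist(),
                "values": self.values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CompressedSignal":
        try:
            doc = json.loads(text)
            out = cls(
                block_order=doc["block_order"],
                subset_size=doc["subset_size"],
                original_length=doc["original_length"],
                padding=doc["padding"],
                seed=doc["seed"],
                positions=np.asarray(doc["positions"], dtype=int),
                values=np.asarray(doc["values"], dtype=float),
                version=doc.get("version", _FORMAT_VERSION),
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise ContainerFormatError(f"bad JSON container: {exc}") from exc
        out.validate()
        return out

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            path.write_bytes(self.to_bytes())

    @classmethod
    def load(cls, path) -> "CompressedSignal":
        path = Path(path)
        blob = path.read_bytes()
        if blob[:4] == _MAGIC:
            return cls.from_bytes(blob)
        return cls.from_json(blob.decode("utf-8"))


# --- subset-size arithmetic and genome decoding -------------------------


def subset_size_from_percent(percent_reduction: float, order: int) -> int:
    """Retained-subset size from a percent-reduction value.

    ``SS = round((1 - percent/100) * N)`` with half-up rounding, clamped
    to at least one retained coefficient.
    """
    if not 0.0 < percent_reduction < 100.0:
        raise ValueError("percent_reduction must lie strictly between 0 and 100")
    ss = _round_half_up((1.0 - percent_reduction / 100.0) * order)
    return max(ss, 1)


def decode_solution(genome: np.ndarray, order: int) -> np.ndarray:
    """Map a real genome to a sorted set of distinct 1-based positions.

    Entries are rounded half-up and clipped to [1, N]; duplicates are
    repaired deterministically, each (in genome order) replaced by the
    smallest position not yet used, so the output always has exactly
    ``len(genome)`` distinct positions.
    """
    g = np.asarray(genome, dtype=float).ravel()
    if g.size > order:
        raise ValueError(f"subset size {g.size} exceeds block order {order}")
    used: set[int] = set()
    for x in g:
        p = min(max(_round_half_up(x), 1), order)
        if p in used:
            p = next(q for q in range(1, order + 1) if q not in used)
        used.add(p)
    return np.array(sorted(used), dtype=int)


def _subset_prd(positions0: np.ndarray, coeff_sq: np.ndarray, denom: float) -> float:
    """PRD of keeping the 0-based ``positions0``, via Parseval."""
    if denom == 0.0:
        return 0.0
    kept = coeff_sq[positions0].sum()
    return math.sqrt(max(coeff_sq.sum() - kept, 0.0) / denom) * 100.0


def block_objective(
    genome: np.ndarray,
    coeffs: np.ndarray,
    block: np.ndarray,
    kernel: HaarKernel,
) -> float:
    """PRD between a block and its reconstruction from the decoded subset.

    This is the fitness the optimizer minimizes.  An all-zero block has a
    vanishing PRD denominator; it is reconstructed perfectly by any
    subset, so the objective is defined as 0 there.
    """
    denom = float(np.sum(np.asarray(block, dtype=float) ** 2))
    if denom == 0.0:
        return 0.0
    positions = decode_solution(genome, kernel.order)
    masked = np.zeros(kernel.order)
    masked[positions - 1] = np.asarray(coeffs, dtype=float)[positions - 1]
    return _prd_metric(block, inverse_block(masked, kernel))


# --- selectors -----------------------------------------------------------


def _select_covidoa(coeffs, block, config: CompressionConfig, kernel, seed):
    coeff_sq = coeffs**2
    denom = float(np.sum(np.asarray(block, dtype=float) ** 2))

    def objective(genome: np.ndarray) -> float:
        return _subset_prd(decode_solution(genome, kernel.order) - 1, coeff_sq, denom)

    trace = optimize(objective, config.optimizer_config(seed))
    return decode_solution(trace.best_solution.genome, kernel.order)


def _select_exhaustive(coeffs, block, config: CompressionConfig, kernel, seed):
    coeff_sq = coeffs**2
    denom = float(np.sum(np.asarray(block, dtype=float) ** 2))
    best_pos, best_val = None, math.inf
    for combo in combinations(range(kernel.order), config.subset_size):
        val = _subset_prd(np.asarray(combo), coeff_sq, denom)
        if val < best_val:
            best_pos, best_val = combo, val
    return np.asarray(best_pos, dtype=int) + 1


def _select_magnitude(coeffs, block, config: CompressionConfig, kernel, seed):
    order = np.argsort(np.abs(coeffs), kind="stable")[::-1]
    return np.sort(order[: config.subset_size]) + 1


_SELECTORS = {
    "covidoa": _select_covidoa,
    "exhaustive": _select_exhaustive,
    "magnitude": _select_magnitude,
}


# --- pipeline ------------------------------------------------------------


def compress_block(
    block: np.ndarray,
    config: CompressionConfig,
    kernel: HaarKernel,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform one block and select its retained coefficients.

    Returns the sorted 1-based positions and the coefficient values at
    those positions.
    """
    if kernel.order != config.block_order:
        raise ValueError("kernel order does not match configuration")
    if seed is None:
        seed = config.seed
    coeffs = forward_block(block, kernel)
    positions = _SELECTORS[config.selection_mode](coeffs, block, config, kernel, seed)
    return positions, coeffs[positions - 1]


def _block_seed(master_seed: int, block_index: int) -> int:
    # keeps per-block streams independent and the whole run reproducible
    return (master_seed ^ (block_index * 0x9E3779B1)) % (2**31)


def compress_signal(signal: np.ndarray, config: CompressionConfig) -> CompressedSignal:
    """Compress a full signal into a container."""
    kernel = build_haar_matrix(config.block_order)
    blocks, padding = partition_signal(signal, config.block_order)
    n_blocks = blocks.shape[0]
    positions = np.empty((n_blocks, config.subset_size), dtype=int)
    values = np.empty((n_blocks, config.subset_size))
    for b in range(n_blocks):
        positions[b], values[b] = compress_block(
            blocks[b], config, kernel, seed=_block_seed(config.seed, b)
        )
    return CompressedSignal(
        block_order=config.block_order,
        subset_size=config.subset_size,
        original_length=int(np.asarray(signal).ravel().size),
        padding=padding,
        seed=config.seed,
        positions=positions,
        values=values,
    )


def decompress_signal(compressed: CompressedSignal) -> np.ndarray:
    """Reconstruct a signal from its container."""
    compressed.validate()
    kernel = build_haar_matrix(compressed.block_order)
    n = compressed.block_order
    coeffs = np.zeros((compressed.n_blocks, n))
    rows = np.arange(compressed.n_blocks)[:, None]
    coeffs[rows, compressed.positions - 1] = compressed.values
    blocks = coeffs @ kernel.matrix  # R = T A, all blocks at once
    return reassemble_signal(blocks, compressed.padding)
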