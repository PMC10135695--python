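"""Codec pipeline: subset arithmetic, genome decoding, block selection
against brute-force and magnitude oracles, containers, and end-to-end
compression/decompression."""

import math
from itertools import combinations

import numpy as np
import pytest

from haarcodec import (
    CompressedSignal,
    CompressionConfig,
    ContainerFormatError,
    block_objective,
    build_haar_matrix,
    compress_block,
    compress_signal,
    decode_solution,
    decompress_signal,
    forward_block,
    generate_ecg,
    mitbih_like,
    prd,
    subset_size_from_percent,
)


class TestSubsetSize:
    @pytest.mark.parametrize(
        "percent,order,expected",
        [(87.5, 64, 8), (50.0, 8, 4), (96.875, 64, 2)],
    )
    def test_percent_reduction_mapping(self, percent, order, expected):
        assert subset_size_from_percent(percent, order) == expected

    def test_highest_ratio_case_keeps_two_of_64(self):
        ss = subset_size_from_percent(96.875, 64)
        assert 64 / ss == 32  # the top sample-count ratio the codec reaches

    def test_tiny_retention_clamps_to_one(self):
        assert subset_size_from_percent(99.9, 8) == 1

    @pytest.mark.parametrize("percent", [0.0, 100.0, -5.0, 150.0])
    def test_out_of_range_percent_rejected(self, percent):
        with pytest.raises(ValueError):
            subset_size_from_percent(percent, 64)


class TestDecodeSolution:
    def test_round_half_up_and_duplicate_repair(self):
        assert decode_solution([2.4, 7.6, 2.1], 8).tolist() == [1, 2, 8]

    def test_identity_case(self):
        assert decode_solution([1.0, 2.0, 3.0], 8).tolist() == [1, 2, 3]

    def test_full_genome_forces_complete_set(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.uniform(1, 8, size=8)
            assert decode_solution(g, 8).tolist() == list(range(1, 9))

    def test_clipping_to_block_range(self):
        assert decode_solution([0.2, 9.7], 8).tolist() == [1, 8]

    def test_oversized_genome_rejected(self):
        with pytest.raises(ValueError):
            decode_solution(np.ones(9), 8)


class TestBlockObjective:
    def test_full_subset_is_lossless(self, kernel8, rng):
        b = rng.normal(size=8)
        t = forward_block(b, kernel8)
        assert block_objective(np.arange(1.0, 9.0), t, b, kernel8) < 1e-10

    def test_matches_parseval_closed_form(self, kernel8, rng):
        """Objective equals sqrt(dropped coefficient energy / block
        energy) x 100, the orthonormal-transform identity."""
        for _ in range(50):
            b = rng.normal(size=8)
            t = forward_block(b, kernel8)
            genome = rng.uniform(1, 8, size=3)
            pos = decode_solution(genome, 8)
            dropped = np.setdiff1d(np.arange(1, 9), pos)
            expected = math.sqrt(np.sum(t[dropped - 1] ** 2) / np.sum(b * b)) * 100
            assert abs(block_objective(genome, t, b, kernel8) - expected) < 1e-9

    def test_all_zero_block_defined_as_zero(self, kernel8):
        z = np.zeros(8)
        assert block_objective([1.0, 2.0], z, z, kernel8) == 0.0


def exhaustive_optimum_prd(block, kernel, ss):
    """Brute-force oracle: best PRD over every C(N, SS) subset."""
    t = forward_block(block, kernel)
    best = math.inf
    for combo in combinations(range(kernel.order), ss):
        masked = np.zeros(kernel.order)
        masked[list(combo)] = t[list(combo)]
        best = min(best, prd(block, masked @ kernel.matrix))
    return best


class TestCompressBlock:
    def test_full_subset_reproduces_block(self, kernel8, rng):
        cfg = CompressionConfig(block_order=8, subset_size=8)
        b = rng.normal(size=8)
        pos, vals = compress_block(b, cfg, kernel8, seed=0)
        masked = np.zeros(8)
        masked[pos - 1] = vals
        assert np.abs(masked @ kernel8.matrix - b).max() < 1e-10

    def test_achieves_exhaustive_optimum_n8_ss3(self, kernel8, rng):
        cfg = CompressionConfig(block_order=8, subset_size=3)
        for seed in range(10):
            b = rng.normal(size=8)
            pos, _ = compress_block(b, cfg, kernel8, seed=seed)
            achieved = block_objective(pos.astype(float), forward_block(b, kernel8), b, kernel8)
            assert abs(achieved - exhaustive_optimum_prd(b, kernel8, 3)) < 1e-9

    def test_magnitude_selector_matches_exhaustive(self, kernel8, rng):
        """Keeping the largest-|T| coefficients is optimal for an
        orthonormal transform — checked against all 56 subsets."""
        mag = CompressionConfig(block_order=8, subset_size=3, selection_mode="magnitude")
        for _ in range(20):
            b = rng.normal(size=8)
            pos, _ = compress_block(b, mag, kernel8)
            achieved = block_objective(pos.astype(float), forward_block(b, kernel8), b, kernel8)
            assert abs(achieved - exhaustive_optimum_prd(b, kernel8, 3)) < 1e-9

    def test_exhaustive_selector_never_beaten(self, kernel8, rng):
        ex = CompressionConfig(block_order=8, subset_size=2, selection_mode="exhaustive")
        cov = CompressionConfig(block_order=8, subset_size=2)
        for seed in range(5):
            b = rng.normal(size=8)
            t = forward_block(b, kernel8)
            p_ex, _ = compress_block(b, ex, kernel8)
            p_cov, _ = compress_block(b, cov, kernel8, seed=seed)
            assert (
                block_objective(p_cov.astype(float), t, b, kernel8)
                >= block_objective(p_ex.astype(float), t, b, kernel8) - 1e-9
            )

    def test_kernel_mismatch_rejected(self, kernel8):
        cfg = CompressionConfig(block_order=64, subset_size=4)
        with pytest.raises(ValueError):
            compress_block(np.zeros(8), cfg, kernel8)


class TestConfigValidation:
    @pytest.mark.parametrize("ss", [0, 9])
    def test_subset_size_range(self, ss):
        with pytest.raises(ValueError):
            CompressionConfig(block_order=8, subset_size=ss)

    def test_unknown_selection_mode(self):
        with pytest.raises(ValueError):
            CompressionConfig(block_order=8, subset_size=2, selection_mode="best")


class TestSignalPipeline:
    def test_full_subset_round_trip(self, rng):
        sig = rng.normal(size=100)
        cfg = CompressionConfig(block_order=8, subset_size=8)
        rec = decompress_signal(compress_signal(sig, cfg))
        assert rec.size == 100
        assert np.abs(rec - sig).max() < 1e-10

    def test_constant_signal_compresses_to_one_coefficient(self):
        sig = np.full(64, 2.5)
        cfg = CompressionConfig(block_order=8, subset_size=1)
        rec = decompress_signal(compress_signal(sig, cfg))
        assert prd(sig, rec) < 1e-10

    def test_prd_non_increasing_in_subset_size(self):
        sig = generate_ecg(mitbih_like(duration_s=1.5, rng_seed=42))
        prds = []
        for ss in (2, 4, 8):
            cfg = CompressionConfig(block_order=8, subset_size=ss, seed=1)
            prds.append(prd(sig, decompress_signal(compress_signal(sig, cfg))))
        assert prds[0] >= prds[1] >= prds[2]

    def test_identical_seeds_give_bit_identical_containers(self, rng):
        sig = rng.normal(size=96)
        cfg = CompressionConfig(block_order=8, subset_size=3, seed=77)
        a = compress_signal(sig, cfg).to_bytes()
        b = compress_signal(sig, cfg).to_bytes()
        assert a == b


class TestContainer:
    def make_container(self, rng, mode="covidoa"):
        sig = rng.normal(size=50)
        cfg = CompressionConfig(block_order=8, subset_size=3, seed=5, selection_mode=mode)
        return sig, compress_signal(sig, cfg)

    def test_binary_round_trip_bit_identical(self, rng, tmp_path):
        sig, comp = self.make_container(rng)
        path = tmp_path / "sig.hwco"
        comp.save(path)
        loaded = CompressedSignal.load(path)
        assert np.array_equal(
            decompress_signal(loaded), decompress_signal(comp)
        )
        assert loaded.to_bytes() == comp.to_bytes()

    def test_json_dialect_round_trip(self, rng, tmp_path):
        sig, comp = self.make_container(rng, mode="magnitude")
        path = tmp_path / "sig.json"
        comp.save(path)
        loaded = CompressedSignal.load(path)
        assert np.array_equal(decompress_signal(loaded), decompress_signal(comp))

    def test_all_zero_values_decode_to_zero_signal(self, rng):
        _, comp = self.make_container(rng)
        comp.values[:] = 0.0
        rec = decompress_signal(comp)
        assert rec.size == comp.original_length and np.all(rec == 0.0)

    def test_corrupt_magic_rejected(self, rng):
        _, comp = self.make_container(rng)
        blob = b"XXXX" + comp.to_bytes()[4:]
        with pytest.raises(ContainerFormatError):
            CompressedSignal.from_bytes(blob)

    def test_out_of_range_position_names_block(self, rng):
        _, comp = self.make_container(rng)
        comp.positions[2, 0] = 99
        with pytest.raises(ContainerFormatError, match="block 2"):
            decompress_signal(comp)

    def test_duplicate_positions_name_block(self, rng):
        _, comp = self.make_container(rng)
        comp.positions[1] = [4, 4, 5]
        with pytest.raises(ContainerFormatError, match="block 1"):
            decompress_signal(comp)
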