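"""Entropy, avalanche, SP 800-22 subset, key-space accounting."""

import math

import numpy as np
import pytest
from scipy import stats

from helixcrypt import (EncryptionConfig, InvalidInputError, avalanche,
                        keyspace_accounting, keystream, nist_dft,
                        nist_frequency, nist_runs, shannon_entropy)
from helixcrypt.evaluate import evaluate_sequence
from helixcrypt.nucseq import Alphabet, NucSeq


class TestShannonEntropy:
    def test_uniform_maximum(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(2.0)

    def test_published_sample_rounds_to_two(self):
        h = shannon_entropy([0.24, 0.26, 0.25, 0.25])
        assert h == pytest.approx(1.99943, abs=1e-4)
        assert round(h, 2) == 2.00

    def test_degenerate_distribution(self):
        assert shannon_entropy([1, 0, 0, 0]) == 0.0

    def test_invalid_input_rejected(self):
        with pytest.raises(InvalidInputError):
            shannon_entropy([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(InvalidInputError):
            shannon_entropy([-0.1, 0.4, 0.4, 0.3])

    def test_strictly_below_two_unless_uniform(self, rng):
        for _ in range(20):
            p = rng.dirichlet([1, 1, 1, 1])
            h = shannon_entropy(p)
            assert h <= 2.0 + 1e-12
            if np.abs(p - 0.25).max() > 1e-3:
                assert h < 2.0


class TestAvalanche:
    def test_zero_flip_zero_fraction(self, key, fast_config):
        from helixcrypt.cipher import encrypt_with_key
        a = encrypt_with_key(b"same message", key, fast_config)
        b = encrypt_with_key(b"same message", key, fast_config)
        assert str(a.payload) == str(b.payload)

    def test_full_diffusion_expectations(self, fast_config):
        # uniform re-randomization: 1/2 of bits, 3/4 of nucleotides
        bit_f, nuc_f = avalanche("avalanche-pw", fast_config, n_trials=150,
                                 seed=42, message_bytes=256)
        assert bit_f == pytest.approx(0.50, abs=0.03)
        assert nuc_f == pytest.approx(0.75, abs=0.03)


class TestNistSubset:
    def test_frequency_balanced_alternating(self):
        bits = np.tile([0, 1], 64)
        assert nist_frequency(bits) == pytest.approx(1.0)

    def test_frequency_all_ones_rejected_strongly(self):
        assert nist_frequency(np.ones(1000, dtype=np.uint8)) < 1e-6

    def test_runs_hand_computed_example(self):
        # 1001101011: n=10, six ones, V=7 -> p = erfc(2.2/2.1466) = 0.1472
        bits = np.array([1, 0, 0, 1, 1, 0, 1, 0, 1, 1], dtype=np.uint8)
        assert nist_runs(bits, min_bits=10) == pytest.approx(0.147232, abs=1e-5)

    def test_short_input_rejected(self):
        with pytest.raises(InvalidInputError):
            nist_frequency(np.zeros(50, dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            nist_dft(np.zeros(500, dtype=np.uint8))

    def test_keystreams_pass_all_three(self, key):
        # ten independent keystreams of 1e5 bits; pass convention p > 0.01
        for nonce in range(10):
            symbols = keystream(key, nonce, 50_000)
            bits = np.empty(100_000, dtype=np.uint8)
            bits[0::2] = symbols >> 1
            bits[1::2] = symbols & 1
            assert nist_frequency(bits) > 0.01, nonce
            assert nist_runs(bits) > 0.01, nonce
            assert nist_dft(bits) > 0.01, nonce

    def test_pvalues_approximately_uniform_under_null(self, rng):
        # frequency and runs p-values over random streams are ~U(0,1)
        pf, pr = [], []
        for _ in range(200):
            bits = rng.integers(0, 2, 4096, dtype=np.uint8)
            pf.append(nist_frequency(bits))
            pr.append(nist_runs(bits))
        assert stats.kstest(pf, "uniform").pvalue > 0.001
        assert stats.kstest(pr, "uniform").pvalue > 0.001


class TestKeyspaceAccounting:
    def test_default_is_512_bits(self):
        rep = keyspace_accounting()
        assert rep.master_key_bits == 512
        assert rep.nucleotide_equivalents == 256
        assert rep.keyspace_log2 == 512

    def test_linear_in_key_bytes(self):
        rep = keyspace_accounting(master_key_bytes=32)
        assert rep.nucleotide_equivalents == 128

    def test_table_structure_reported_not_multiplied(self):
        rep = keyspace_accounting()
        assert rep.derived_table_bits == pytest.approx(math.log2(24))
        assert rep.keyspace_log2 == rep.master_key_bits  # tables excluded


class TestEvaluateSequence:
    def test_report_consistency(self, rng):
        seq = NucSeq.from_values(rng.integers(0, 4, 2048, dtype=np.uint8),
                                 Alphabet.RNA)
        rep = evaluate_sequence(seq)
        assert sum(rep.base_freqs) == pytest.approx(1.0)
        assert rep.entropy_bits_per_base == pytest.approx(
            shannon_entropy(rep.base_freqs), abs=1e-9)
        assert set(rep.test_pvalues) == {"frequency", "runs", "dft"}
        assert all(0 <= p <= 1 for p in rep.test_pvalues.values())
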