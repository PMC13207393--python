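"""Encryption layers: each is an exact inverse pair; the whole chain
round-trips; worked examples from the published tables hold."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixcrypt import (AlphabetError, FormatError,
                        InvalidInputError, NucSeq, Permutation, SBoxFamily,
                        apply_permutation, complement, decrypt,
                        diffuse_backward, dna_xor, encrypt, encrypt_with_key,
                        enumerate_tables, invert_permutation, transcribe,
                        undiffuse_backward, untranscribe)
from helixcrypt.nucseq import Alphabet

TABLE0 = enumerate_tables()[0]

dna_strings = st.text(alphabet="ACGT", max_size=64)


def dna(s):
    return NucSeq(s, Alphabet.DNA)


def rna(s):
    return NucSeq(s, Alphabet.RNA)


class TestComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("TAAG", "ATTC"),
        ("TTAA", "AATT"),
        ("TAGG", "ATCC"),
    ])
    def test_worked_examples(self, seq, expected):
        assert str(complement(dna(seq))) == expected

    @settings(derandomize=True, max_examples=50)
    @given(dna_strings)
    def test_involution(self, s):
        assert str(complement(complement(dna(s)))) == s

    def test_rna_rejected(self):
        with pytest.raises(AlphabetError):
            complement(rna("UUAA"))


class TestDnaXor:
    def test_zero_stream_is_identity(self):
        s = dna("TAAGCTTA")
        out = dna_xor(s, np.zeros(8, dtype=np.uint8), TABLE0)
        assert str(out) == str(s)

    def test_hand_worked_example(self):
        # TAAG under table 0 is 01 00 00 11; XOR (11,11,11,11) =
        # 10 11 11 00 -> CGGA (worked by hand)
        out = dna_xor(dna("TAAG"), np.array([3, 3, 3, 3], dtype=np.uint8),
                      TABLE0)
        assert str(out) == "CGGA"

    @settings(derandomize=True, max_examples=50)
    @given(dna_strings, st.integers(0, 23), st.integers(0, 2**32))
    def test_self_inverse(self, s, idx, seed):
        table = enumerate_tables()[idx]
        stream = np.random.default_rng(seed).integers(
            0, 4, len(s), dtype=np.uint8)
        assert str(dna_xor(dna_xor(dna(s), stream, table), stream, table)) == s

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            dna_xor(dna("ACGT"), np.zeros(3, dtype=np.uint8), TABLE0)


class TestPermutation:
    @pytest.mark.parametrize("seq,one_based,expected", [
        ("AATT", (4, 1, 3, 2), "TATA"),  # published gather-consistent row
        ("ATCC", (2, 3, 4, 1), "TCCA"),  # published gather-consistent row
    ])
    def test_worked_examples_gather_semantics(self, seq, one_based, expected):
        p = Permutation.from_one_based(one_based)
        assert str(apply_permutation(dna(seq), p)) == expected

    def test_identity(self):
        p = Permutation.identity(6)
        assert str(apply_permutation(dna("ACGTAC"), p)) == "ACGTAC"

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 200), st.integers(0, 2**32))
    def test_inverse_pair(self, n, seed):
        rng = np.random.default_rng(seed)
        p = Permutation(rng.permutation(n))
        s = NucSeq.from_values(rng.integers(0, 4, n, dtype=np.uint8),
                               Alphabet.DNA)
        assert str(invert_permutation(apply_permutation(s, p), p)) == str(s)
        assert np.array_equal(p.inverse().inverse().mapping, p.mapping)

    def test_non_bijection_rejected(self):
        with pytest.raises(InvalidInputError):
            Permutation(np.array([0, 0, 1]))


class TestTranscription:
    def test_identity_boxes_pure_t_to_u(self):
        fam = SBoxFamily.identity()
        assert str(transcribe(dna("TTAA"), fam)) == "UUAA"
        assert str(untranscribe(rna("UUAA"), fam)) == "TTAA"

    def test_keyed_boxes_are_bijections(self, key):
        fam = SBoxFamily.from_key(key)
        for direction in ("fwd", "bwd"):
            for ctx, box in fam.boxes(direction).items():
                assert sorted(box) == [0, 1, 2, 3], (direction, ctx)

    def test_round_trips_keyed(self, key, rng):
        fam = SBoxFamily.from_key(key)
        for _ in range(50):
            n = int(rng.integers(0, 300))
            s = NucSeq.from_values(rng.integers(0, 4, n, dtype=np.uint8),
                                   Alphabet.DNA)
            r = transcribe(s, fam)
            assert str(untranscribe(r, fam)) == str(s)
            d = diffuse_backward(r, fam)
            assert str(undiffuse_backward(d, fam)) == str(r)
            # transcribe of untranscribe is the identity on RNA too
            assert str(transcribe(untranscribe(r, fam), fam)) == str(r)

    def test_forward_chain_localizes_upstream(self, key):
        # in the forward-only pass, inputs differing at the last symbol
        # produce outputs identical before it
        fam = SBoxFamily.from_key(key)
        a = transcribe(dna("AAAA"), fam)
        b = transcribe(dna("AAAC"), fam)
        assert str(a)[:3] == str(b)[:3]
        assert str(a)[3] != str(b)[3]


class TestEncryptDecrypt:
    def test_round_trip_random_messages(self, fast_config, rng):
        for _ in range(25):
            n = int(rng.integers(0, 200))
            msg = rng.integers(0, 256, n, dtype=np.uint8).tobytes()
            salt = rng.integers(0, 256, 16, dtype=np.uint8).tobytes()
            ct = encrypt(msg, "pw", fast_config, salt=salt)
            assert decrypt(ct, "pw", fast_config) == msg

    def test_empty_plaintext(self, fast_config):
        ct = encrypt(b"", "pw", fast_config, salt=bytes(16))
        assert len(ct.payload) == 0
        assert decrypt(ct, "pw", fast_config) == b""

    def test_crypto_pre_transcription_length(self, key, fast_config):
        # 6 ASCII characters -> 48 bits -> 24 bases end to end (no ECC)
        ct = encrypt_with_key(b"CRYPTO", key, fast_config)
        assert ct.plaintext_bit_length == 48
        assert len(ct.payload) == 24

    def test_wrong_passphrase_yields_noise(self, fast_config):
        msg = b"attack at dawn, bring primers"
        ct = encrypt(msg, "right", fast_config, salt=bytes(16))
        assert decrypt(ct, "wrong", fast_config) != msg

    def test_truncated_payload_detected(self, key, fast_config):
        ct = encrypt_with_key(b"hello world", key, fast_config)
        truncated = dataclasses.replace(
            ct, payload=NucSeq(ct.payload.seq[:-4], Alphabet.RNA))
        with pytest.raises(FormatError):
            decrypt(truncated, "test-passphrase", fast_config)

    def test_ciphertext_base_frequencies_near_uniform(self, key, fast_config,
                                                      rng):
        msg = rng.integers(0, 256, 1024, dtype=np.uint8).tobytes()
        ct = encrypt_with_key(msg, key, fast_config)
        freqs = np.bincount(ct.payload.values(), minlength=4) / len(ct.payload)
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_payload_is_rna(self, key, fast_config):
        ct = encrypt_with_key(b"abc", key, fast_config)
        assert ct.payload.alphabet is Alphabet.RNA
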