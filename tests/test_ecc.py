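"""Reed-Solomon outer code: algebra, oracle equivalence, channel stress."""

import numpy as np
import pytest

from helixcrypt import CodeConfig, ConfigError, ECCDecodeError, rs_decode, rs_encode
from helixcrypt.ecc import _decode_block, _encode_block, _syndromes


class TestCodeConfig:
    def test_capacity(self):
        assert CodeConfig(n=255, k=223).t == 16
        assert CodeConfig(n=255, k=51).t == 102

    @pytest.mark.parametrize("n,k", [(255, 255), (10, 0), (256, 100), (5, 4)])
    def test_invalid_parameters_rejected(self, n, k):
        with pytest.raises(ConfigError):
            CodeConfig(n=n, k=k)


class TestCodewordAlgebra:
    def test_systematic_identity_and_zero_syndromes(self, rng):
        msg = rng.integers(0, 256, 30, dtype=np.uint8)
        cw = _encode_block(msg, 20)
        assert np.array_equal(cw[:30], msg)
        assert not _syndromes(cw, 20).any()

    def test_single_error_every_position(self, rng):
        msg = rng.integers(0, 256, 5, dtype=np.uint8)
        cw = _encode_block(msg, 4)
        for pos in range(cw.size):
            bad = cw.copy()
            bad[pos] ^= 0x5A
            assert np.array_equal(_decode_block(bad, 4), msg)

    def test_exact_t_errors_recovered(self, rng):
        # RS(15,5): t = 5
        for _ in range(50):
            msg = rng.integers(0, 256, 5, dtype=np.uint8)
            cw = _encode_block(msg, 10)
            bad = cw.copy()
            pos = rng.choice(15, 5, replace=False)
            bad[pos] ^= rng.integers(1, 256, 5, dtype=np.uint8)
            assert np.array_equal(_decode_block(bad, 10), msg)

    def test_beyond_capacity_flagged_or_wrong_never_silent(self, rng):
        # t+1 errors: the original is unreachable; decoder must either
        # raise or land on a different codeword
        for _ in range(50):
            msg = rng.integers(0, 256, 5, dtype=np.uint8)
            cw = _encode_block(msg, 10)
            bad = cw.copy()
            pos = rng.choice(15, 6, replace=False)
            bad[pos] ^= rng.integers(1, 256, 6, dtype=np.uint8)
            try:
                out = _decode_block(bad, 10)
            except ECCDecodeError:
                continue
            assert not np.array_equal(out, msg)

    def test_matches_exhaustive_nearest_codeword_oracle(self, rng):
        # RS(5,1) over GF(2^8): full codebook is enumerable; decoding must
        # agree with brute-force nearest-codeword search
        nsym = 4
        codebook = np.stack([_encode_block(np.array([m], dtype=np.uint8), nsym)
                             for m in range(256)])
        for _ in range(100):
            m = int(rng.integers(0, 256))
            bad = codebook[m].copy()
            ne = int(rng.integers(0, 3))
            pos = rng.choice(5, ne, replace=False)
            bad[pos] ^= rng.integers(1, 256, ne, dtype=np.uint8)
            nearest = int(np.argmin((codebook != bad).sum(axis=1)))
            assert nearest == m
            assert _decode_block(bad, nsym)[0] == m


class TestStreamCodec:
    def test_clean_round_trip_with_shortened_tail(self, rng):
        cfg = CodeConfig(n=255, k=223, interleave_depth=4)
        for size in [1, 100, 223, 224, 1000]:
            data = rng.integers(0, 256, size, dtype=np.uint8).tobytes()
            assert rs_decode(rs_encode(data, cfg), cfg) == data

    def test_empty_stream(self):
        cfg = CodeConfig()
        assert rs_encode(b"", cfg) == b""
        assert rs_decode(b"", cfg) == b""

    def test_burst_spread_by_interleaver(self, rng):
        # a contiguous burst of depth*t bytes must be corrected
        cfg = CodeConfig(n=255, k=223, interleave_depth=8)
        data = rng.integers(0, 256, 8 * 223, dtype=np.uint8).tobytes()
        coded = np.frombuffer(rs_encode(data, cfg), dtype=np.uint8).copy()
        start = 100
        burst = 8 * cfg.t
        coded[start:start + burst] ^= rng.integers(
            1, 256, burst, dtype=np.uint8)
        assert rs_decode(coded.tobytes(), cfg) == data

    def test_heavy_profile_survives_28_percent_byte_errors(self, rng):
        # per-byte rate induced by an 8% per-base substitution channel
        cfg = CodeConfig(n=255, k=51, interleave_depth=8)
        data = rng.integers(0, 256, 512, dtype=np.uint8).tobytes()
        coded = np.frombuffer(rs_encode(data, cfg), dtype=np.uint8).copy()
        mask = rng.random(coded.size) < 0.284
        coded[mask] ^= rng.integers(1, 256, int(mask.sum()), dtype=np.uint8)
        assert rs_decode(coded.tobytes(), cfg) == data

    def test_uncorrectable_stream_raises(self, rng):
        cfg = CodeConfig(n=255, k=223, interleave_depth=1)
        data = rng.integers(0, 256, 223, dtype=np.uint8).tobytes()
        coded = np.frombuffer(rs_encode(data, cfg), dtype=np.uint8).copy()
        pos = rng.choice(coded.size, 40, replace=False)  # >> t = 16
        coded[pos] ^= rng.integers(1, 256, 40, dtype=np.uint8)
        with pytest.raises(ECCDecodeError):
            rs_decode(coded.tobytes(), cfg)
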