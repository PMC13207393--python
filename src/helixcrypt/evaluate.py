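"""Security and randomness metrics for ciphertext sequences.

Per-base Shannon entropy from empirical base frequencies (plug-in
estimator, no bias correction), the avalanche effect at bit and nucleotide
level, a three-test subset of the SP 800-22 randomness battery (frequency /
monobit, runs, and the spectral DFT test), and key-space accounting.

Pass convention for the randomness tests: p > 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .cipher import encrypt_with_key
from .config import EncryptionConfig
from .errors import InvalidInputError
from .keyschedule import MASTER_KEY_BYTES, N_TABLES, derive_master_key
from .nucseq import NucSeq

PASS_PVALUE = 0.01


# ---------------------------------------------------------------- entropy

def base_frequencies(seq: NucSeq) -> np.ndarray:
    """Empirical frequencies of the four bases (A, C, G, T/U order)."""
    if len(seq) == 0:
        raise InvalidInputError("empty sequence has no base frequencies")
    return np.bincount(seq.values(), minlength=4) / len(seq)


def shannon_entropy(freqs) -> float:
    """H = -sum p log2 p over the four base frequencies; max 2 bits/base."""
    p = np.asarray(freqs, dtype=np.float64)
    if p.size != 4 or (p < 0).any():
        raise InvalidInputError("freqs must be four non-negative fractions")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidInputError("freqs must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def sequence_entropy(seq: NucSeq) -> float:
    """Plug-in per-base entropy of a sequence."""
    return shannon_entropy(base_frequencies(seq))


# --------------------------------------------------------------- avalanche

def avalanche(passphrase: str, config: EncryptionConfig | None = None,
              n_trials: int = 1000, seed: int = 0,
              message_bytes: int = 1024) -> tuple[float, float]:
    """Mean fraction of payload bits / nucleotides changed by one bit flip.

    Each trial encrypts a random message and the same message with one
    uniformly chosen bit flipped, under the same key, salt and nonce, and
    compares the payloads positionwise. A fully diffusing pipeline
    re-randomizes every symbol, giving 1/2 at bit level and 3/4 at
    nucleotide level in expectation.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    config = config or EncryptionConfig(kdf_iterations=1000)
    rng = np.random.default_rng(seed)
    salt = rng.integers(0, 256, 16, dtype=np.uint8).tobytes()
    key = derive_master_key(passphrase, salt, config.kdf_iterations)
    bit_fracs = np.empty(n_trials)
    nuc_fracs = np.empty(n_trials)
    for t in range(n_trials):
        msg = rng.integers(0, 256, message_bytes, dtype=np.uint8)
        flipped = msg.copy()
        b = int(rng.integers(0, 8 * message_bytes))
        flipped[b // 8] ^= 1 << (7 - b % 8)
        v1 = encrypt_with_key(msg.tobytes(), key, config).payload.values()
        v2 = encrypt_with_key(flipped.tobytes(), key, config).payload.values()
        xor = v1 ^ v2
        nuc_fracs[t] = np.count_nonzero(xor) / xor.size
        bit_fracs[t] = (np.count_nonzero(xor >> 1)
                        + np.count_nonzero(xor & 1)) / (2 * xor.size)
    return float(bit_fracs.mean()), float(nuc_fracs.mean())


# ------------------------------------------------------- SP 800-22 subset

def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1 or (arr > 1).any():
        raise InvalidInputError("bits must be a 1-D 0/1 sequence")
    return arr


def nist_frequency(bits, min_bits: int = 100) -> float:
    """Monobit frequency test: p = erfc(|S_n| / sqrt(2 n))."""
    b = _as_bits(bits)
    if b.size < min_bits:
        raise InvalidInputError(f"need at least {min_bits} bits")
    s = abs(int(2 * int(b.sum()) - b.size))
    return float(erfc(s / math.sqrt(2 * b.size)))


def nist_runs(bits, min_bits: int = 100) -> float:
    """Runs test: total number of runs against its expectation.

    p = erfc(|V - 2 n pi (1-pi)| / (2 sqrt(2 n) pi (1-pi))), with pi the
    ones proportion. Following the reference procedure, the test is not
    applicable when the monobit proportion is already far off (returns 0.0).
    """
    b = _as_bits(bits)
    n = b.size
    if n < min_bits:
        raise InvalidInputError(f"need at least {min_bits} bits")
    pi = float(b.mean())
    if abs(pi - 0.5) >= 2.0 / math.sqrt(n):
        return 0.0
    v = 1 + int(np.count_nonzero(np.diff(b)))
    num = abs(v - 2.0 * n * pi * (1 - pi))
    den = 2.0 * math.sqrt(2.0 * n) * pi * (1 - pi)
    return float(erfc(num / den))


def nist_dft(bits, min_bits: int = 1000) -> float:
    """Spectral (DFT) test: fraction of sub-threshold peaks.

    Threshold T = sqrt(n ln(1/0.05)); under randomness 95% of the first n/2
    DFT moduli fall below T; the normalized excess is compared to a normal
    reference: p = erfc(|d| / sqrt(2)).
    """
    b = _as_bits(bits)
    n = b.size
    if n < min_bits:
        raise InvalidInputError(f"need at least {min_bits} bits")
    x = 2.0 * b.astype(np.float64) - 1.0
    moduli = np.abs(np.fft.fft(x))[: n // 2]
    threshold = math.sqrt(n * math.log(1.0 / 0.05))
    n0 = 0.95 * n / 2.0
    n1 = int(np.count_nonzero(moduli < threshold))
    d = (n1 - n0) / math.sqrt(n * 0.95 * 0.05 / 4.0)
    return float(erfc(abs(d) / math.sqrt(2.0)))


# ----------------------------------------------------------- key space

@dataclass(frozen=True)
class KeySpaceReport:
    """Key-space accounting on a log2 scale.

    Only the master key is an independent secret; the encoding-table choice
    and the stream nonce are *derived* from it, so their sizes are reported
    as structure, not multiplied into the key space.
    """

    master_key_bits: int
    nucleotide_equivalents: float
    derived_table_bits: float
    kdf_iterations: int

    @property
    def keyspace_log2(self) -> float:
        return float(self.master_key_bits)


def keyspace_accounting(config: EncryptionConfig | None = None,
                        master_key_bytes: int = MASTER_KEY_BYTES) -> KeySpaceReport:
    """log2 of the master-key space plus derived (non-additive) structure."""
    config = config or EncryptionConfig()
    bits = 8 * master_key_bytes
    return KeySpaceReport(
        master_key_bits=bits,
        nucleotide_equivalents=bits / 2.0,
        derived_table_bits=math.log2(N_TABLES),
        kdf_iterations=config.kdf_iterations,
    )


# ---------------------------------------------------------------- report

@dataclass(frozen=True)
class EvalReport:
    """Bundle of the evaluation metrics for one ciphertext or experiment."""

    base_freqs: tuple[float, float, float, float]
    entropy_bits_per_base: float
    test_pvalues: dict[str, float] = field(default_factory=dict)
    avalanche_bit_fraction: float | None = None
    avalanche_nuc_fraction: float | None = None
    keyspace_log2: float | None = None
    n_trials: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "base_freqs": list(self.base_freqs),
            "entropy_bits_per_base": self.entropy_bits_per_base,
            "test_pvalues": dict(self.test_pvalues),
            "avalanche_bit_fraction": self.avalanche_bit_fraction,
            "avalanche_nuc_fraction": self.avalanche_nuc_fraction,
            "keyspace_log2": self.keyspace_log2,
            "n_trials": self.n_trials,
            "seed": self.seed,
        }


def evaluate_sequence(seq: NucSeq, config: EncryptionConfig | None = None,
                      seed: int = 0) -> EvalReport:
    """Sequence-level metrics (no key required): frequencies, entropy, and
    the randomness subset on the 2-bit expansion of the bases."""
    freqs = base_frequencies(seq)
    v = seq.values()
    bits = np.empty(2 * v.size, dtype=np.uint8)
    bits[0::2] = v >> 1
    bits[1::2] = v & 1
    pvals = {}
    if bits.size >= 100:
        pvals["frequency"] = nist_frequency(bits)
        pvals["runs"] = nist_runs(bits)
    if bits.size >= 1000:
        pvals["dft"] = nist_dft(bits)
    ks = keyspace_accounting(config)
    return EvalReport(
        base_freqs=tuple(float(f) for f in freqs),
        entropy_bits_per_base=shannon_entropy(freqs),
        test_pvalues=pvals,
        keyspace_log2=ks.keyspace_log2,
        seed=seed,
    )
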