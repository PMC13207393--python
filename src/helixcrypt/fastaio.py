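"""Ciphertext serialization (FASTA + JSON sidecar) and fixture generation.

The RNA payload is stored as a standard FASTA record (60-column wrapping,
so any FASTA tool can read it), with the header metadata mirrored compactly
in the description line; the authoritative copy of the metadata lives in a
JSON sidecar next to the sequence file (``<path>.json``).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cipher import CipherText
from .constraints import ConstraintLimits
from .ecc import CodeConfig
from .errors import FormatError, InvalidInputError
from .nucseq import Alphabet, NucSeq

_RECORD_ID = "helixcrypt"


def sidecar_path(path: str | pathlib.Path) -> pathlib.Path:
    path = pathlib.Path(path)
    return path.with_name(path.name + ".json")


def write_ciphertext(ct: CipherText, path: str | pathlib.Path) -> None:
    """Write ``<path>`` (FASTA) and ``<path>.json`` (header sidecar)."""
    path = pathlib.Path(path)
    desc = (f"salt={ct.salt.hex()} nonce={ct.stream_nonce} "
            f"bits={ct.plaintext_bit_length} v={ct.version}")
    record = SeqRecord(Seq(ct.payload.seq), id=_RECORD_ID, description=desc)
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "fasta")
    meta = {
        "version": ct.version,
        "salt": ct.salt.hex(),
        "kdf_iterations": ct.kdf_iterations,
        "stream_nonce": ct.stream_nonce,
        "plaintext_bit_length": ct.plaintext_bit_length,
        "code_params": None if ct.code_params is None else {
            "n": ct.code_params.n,
            "k": ct.code_params.k,
            "interleave_depth": ct.code_params.interleave_depth,
        },
        "constraint_counters": (None if ct.constraint_counters is None
                                else list(ct.constraint_counters)),
        "constraint_limits": None if ct.constraint_limits is None else {
            "gc_min": ct.constraint_limits.gc_min,
            "gc_max": ct.constraint_limits.gc_max,
            "max_homopolymer": ct.constraint_limits.max_homopolymer,
            "stem_min": ct.constraint_limits.stem_min,
            "loop_min": ct.constraint_limits.loop_min,
            "window": ct.constraint_limits.window,
            "max_attempts": ct.constraint_limits.max_attempts,
        },
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_ciphertext(path: str | pathlib.Path) -> CipherText:
    """Lossless inverse of :func:`write_ciphertext`."""
    path = pathlib.Path(path)
    try:
        record = SeqIO.read(str(path), "fasta")
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot read FASTA record from {path}: {exc}") from exc
    try:
        meta = json.loads(sidecar_path(path).read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"missing sidecar {sidecar_path(path)}") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar: {exc}") from exc

    for field in ("version", "salt", "kdf_iterations", "stream_nonce",
                  "plaintext_bit_length"):
        if field not in meta:
            raise FormatError(f"sidecar missing field {field!r}")
    payload = NucSeq(str(record.seq), Alphabet.RNA)

    # the compact description must agree with the sidecar
    desc = dict(item.split("=", 1) for item in record.description.split()
                if "=" in item)
    if desc.get("salt") != meta["salt"] or \
            int(desc.get("nonce", -1)) != meta["stream_nonce"] or \
            int(desc.get("bits", -1)) != meta["plaintext_bit_length"]:
        raise FormatError("FASTA description and sidecar metadata disagree")

    code = meta.get("code_params")
    lim = meta.get("constraint_limits")
    counters = meta.get("constraint_counters")
    return CipherText(
        payload=payload,
        salt=bytes.fromhex(meta["salt"]),
        kdf_iterations=int(meta["kdf_iterations"]),
        stream_nonce=int(meta["stream_nonce"]),
        plaintext_bit_length=int(meta["plaintext_bit_length"]),
        code_params=None if code is None else CodeConfig(**code),
        constraint_counters=None if counters is None else tuple(counters),
        constraint_limits=None if lim is None else ConstraintLimits(**lim),
        version=meta["version"],
    )


# ---------------------------------------------------------------- fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """Seeded random-message corpus mirroring the evaluation protocol:
    uniformly random messages with bit lengths drawn from a range, plus the
    literal benchmark string ``CRYPTO`` appended."""

    n_messages: int = 1000
    bit_length_range: tuple[int, int] = (128, 192)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bit_length_range
        if self.n_messages < 1 or not 8 <= lo <= hi:
            raise InvalidInputError("invalid fixture spec")


def generate_fixtures(spec: FixtureSpec) -> list[bytes]:
    """Reproducible corpus of ``n_messages`` random byte strings (bit
    lengths uniform over the whole-byte lengths in range) + ``b"CRYPTO"``."""
    rng = np.random.default_rng(spec.seed)
    lo_bytes = (spec.bit_length_range[0] + 7) // 8
    hi_bytes = spec.bit_length_range[1] // 8
    if hi_bytes < lo_bytes:
        raise InvalidInputError("bit range contains no whole-byte length")
    corpus = []
    for _ in range(spec.n_messages):
        n = int(rng.integers(lo_bytes, hi_bytes + 1))
        corpus.append(rng.integers(0, 256, n, dtype=np.uint8).tobytes())
    corpus.append(b"CRYPTO")
    return corpus
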