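"""Biochemical sequence constraints: GC balance, homopolymer cap, hairpins.

Sequences destined for DNA synthesis must keep GC content near 50%, avoid
long single-base runs, and avoid self-complementary stems that fold into
hairpins. This module reports those properties and *enforces* them on
ciphertexts without touching plaintext recoverability.

Enforcement strategy
--------------------
The payload is partitioned into blocks of ``window`` bases. Each block may
be re-randomized by XOR-ing a keyed mask selected by a small counter; the
counters are recorded in the ciphertext header, so decryption simply strips
the masks first. Blocks are fixed greedily left to right (checking every
constraint that the new block can complete: sliding GC windows ending in
it, runs crossing its junction, stems reaching back up to one window), with
chronological backtracking when a block's budget is exhausted. Masking is
positionwise, so channel errors remain local and the Reed-Solomon layer
underneath still sees at most one byte error per substituted base.

Whole-payload rejection (bumping the stream nonce) is not viable at scale:
a uniform 4096-base payload avoids homopolymers longer than 3 with
probability around e^-48, so some local re-randomization is required.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConstraintError, InvalidInputError
from .keyschedule import KeyMaterial
from .nucseq import Alphabet, NucSeq

_LABEL = b"helixcrypt/constraint"


@dataclass(frozen=True)
class ConstraintLimits:
    """Defaults follow common DNA-storage synthesis guidance: GC within
    45-55%, homopolymer runs of at most 3, and no self-complementary stem
    of 6+ bases separated by a 3+ base loop within a 100-base window."""

    gc_min: float = 0.45
    gc_max: float = 0.55
    max_homopolymer: int = 3
    stem_min: int = 6
    loop_min: int = 3
    window: int = 100
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_min < self.gc_max <= 1.0:
            raise InvalidInputError("require 0 <= gc_min < gc_max <= 1")
        if self.max_homopolymer < 1:
            raise InvalidInputError("max_homopolymer must be >= 1")
        if self.stem_min < 1 or self.loop_min < 0:
            raise InvalidInputError("invalid stem/loop limits")
        if self.window < 2 * self.stem_min + self.loop_min:
            raise InvalidInputError(
                "window must fit a stem-loop-stem structure")
        if self.max_attempts < 1:
            raise InvalidInputError("max_attempts must be >= 1")


# ---------------------------------------------------------------- reports

def gc_content(seq: NucSeq) -> float:
    """(G + C) / length."""
    if len(seq) == 0:
        raise InvalidInputError("GC content of an empty sequence is undefined")
    v = seq.values()
    return float(np.count_nonzero((v == 1) | (v == 2))) / len(seq)


def max_homopolymer(seq: NucSeq | str) -> int:
    """Length of the longest run of identical consecutive bases (0 if empty)."""
    s = str(seq)
    if not s:
        return 0
    v = np.frombuffer(s.encode(), dtype=np.uint8)
    return int(_max_run(v))


def _max_run(v: np.ndarray) -> int:
    if v.size == 0:
        return 0
    boundaries = np.flatnonzero(np.diff(v) != 0)
    edges = np.concatenate(([-1], boundaries, [v.size - 1]))
    return int(np.diff(edges).max())


def _kmer_codes(v: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every k-mer (empty if too short)."""
    if v.size < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(v.size - k + 1, dtype=np.int64)
    for q in range(k):
        codes += v[q:q + codes.size].astype(np.int64) << (2 * (k - 1 - q))
    return codes


def _rc_kmer_codes(v: np.ndarray, k: int) -> np.ndarray:
    """Code of the reverse complement of every k-mer."""
    return _kmer_codes((3 - v)[::-1], k)[::-1].copy() if v.size >= k \
        else np.empty(0, dtype=np.int64)


def hairpin_screen(seq: NucSeq, limits: ConstraintLimits | None = None) -> int:
    """Count self-complementary stem pairs within the sliding window.

    A hit is a pair (i, j) where the ``stem_min``-mer starting at j equals
    the reverse complement of the one starting at i, the loop between them
    is at least ``loop_min`` bases, and the whole structure spans at most
    ``window`` bases. Counting stem seeds of exactly ``stem_min`` detects
    every longer stem as well. The pairing relation is symmetric under
    reverse complement of the full sequence, so the screen is too.
    """
    limits = limits or ConstraintLimits()
    v = seq.values()
    k = limits.stem_min
    codes = _kmer_codes(v, k)
    rc = _rc_kmer_codes(v, k)
    if codes.size == 0:
        return 0
    hits = 0
    min_delta = k + limits.loop_min
    max_delta = limits.window - k
    for delta in range(min_delta, max_delta + 1):
        if delta >= codes.size:
            break
        hits += int(np.count_nonzero(codes[:-delta] == rc[delta:]))
    return hits


def violations(seq: NucSeq, limits: ConstraintLimits | None = None) -> list[str]:
    """Human-readable list of constraint violations with positions."""
    limits = limits or ConstraintLimits()
    out: list[str] = []
    if len(seq) == 0:
        return out
    gc = gc_content(seq)
    if not limits.gc_min <= gc <= limits.gc_max:
        out.append(f"global GC {gc:.3f} outside "
                   f"[{limits.gc_min}, {limits.gc_max}]")
    v = seq.values()
    gc_ind = ((v == 1) | (v == 2)).astype(np.int64)
    if v.size >= limits.window:
        cs = np.concatenate(([0], np.cumsum(gc_ind)))
        sums = cs[limits.window:] - cs[:-limits.window]
        lo = limits.gc_min * limits.window - 1e-9
        hi = limits.gc_max * limits.window + 1e-9
        bad = np.flatnonzero((sums < lo) | (sums > hi))
        for b in bad[:10]:
            out.append(f"window GC {sums[b] / limits.window:.3f} at "
                       f"[{b}, {b + limits.window})")
    run = _max_run(v)
    if run > limits.max_homopolymer:
        out.append(f"homopolymer run of {run} exceeds "
                   f"{limits.max_homopolymer}")
    hits = hairpin_screen(seq, limits)
    if hits:
        out.append(f"{hits} hairpin stem pair(s) within window")
    return out


# ------------------------------------------------------------- masking

def _block_mask(key: KeyMaterial, nonce: int, block: int, counter: int,
                length: int) -> np.ndarray:
    """Keyed 2-bit mask for one block; counter 0 is the identity mask."""
    if counter == 0:
        return np.zeros(length, dtype=np.uint8)
    n_bytes = (length + 3) // 4
    msg = (_LABEL + nonce.to_bytes(8, "big") + block.to_bytes(8, "big")
           + counter.to_bytes(8, "big"))
    chunks = []
    for i in range((n_bytes + 31) // 32):
        chunks.append(hmac.new(key.master_key, msg + i.to_bytes(4, "big"),
                               hashlib.sha256).digest())
    raw = np.frombuffer(b"".join(chunks)[:n_bytes], dtype=np.uint8)
    bits = np.unpackbits(raw)
    return (bits[0::2] * 2 + bits[1::2])[:length].astype(np.uint8)


def unmask(payload: NucSeq, key: KeyMaterial, nonce: int,
           counters: tuple[int, ...],
           limits: ConstraintLimits) -> NucSeq:
    """Strip the constraint-layer masks recorded in the header."""
    v = payload.values().copy()
    w = limits.window
    for b, ctr in enumerate(counters):
        s = b * w
        seg = v[s:s + w]
        if ctr:
            seg ^= _block_mask(key, nonce, b, ctr, seg.size)
    return NucSeq.from_values(v, payload.alphabet)


# ------------------------------------------------------------ enforcement

def _block_ok(cand: np.ndarray, s: int, e: int, total: int, gc_prefix: int,
              limits: ConstraintLimits) -> bool:
    """Check every constraint completed by block [s, e) of ``cand[:e]``."""
    w = limits.window
    mh = limits.max_homopolymer
    seg = cand[s:e]

    # homopolymer runs inside the segment and across the left junction
    j0 = max(0, s - mh)
    if _max_run(cand[j0:e]) > mh:
        return False

    gc_ind = (seg == 1) | (seg == 2)
    seg_gc = int(np.count_nonzero(gc_ind))

    # sliding GC windows that end inside this block
    if e >= w:
        a = max(0, s - w + 1)
        region = cand[a:e]
        gi = ((region == 1) | (region == 2)).astype(np.int64)
        cs = np.concatenate(([0], np.cumsum(gi)))
        # window ends (exclusive) from max(w, s+1) to e, in region coords
        first_end = max(w, s + 1) - a
        sums = cs[first_end:e - a + 1] - cs[first_end - w:e - a + 1 - w]
        lo = limits.gc_min * w - 1e-9
        hi = limits.gc_max * w + 1e-9
        if sums.size and ((sums < lo).any() or (sums > hi).any()):
            return False

    # final block also settles the whole-payload GC fraction
    if e == total:
        gc_total = gc_prefix + seg_gc
        frac = gc_total / total
        if not limits.gc_min - 1e-9 <= frac <= limits.gc_max + 1e-9:
            return False

    # hairpin stems whose downstream half reaches into this block
    k = limits.stem_min
    if e >= k:
        a = max(0, s + 1 - w)  # upstream stems can start this far back
        region = cand[a:e]
        codes = _kmer_codes(region, k)
        rc = _rc_kmer_codes(region, k)
        min_delta = k + limits.loop_min
        max_delta = w - k
        # only pairs whose downstream stem ends inside [s, e)
        j_min_global = max(0, s - k + 1)
        for delta in range(min_delta, max_delta + 1):
            if delta >= codes.size:
                break
            j_lo = max(j_min_global - a, delta)
            eq = codes[j_lo - delta:codes.size - delta] == rc[j_lo:]
            if eq.any():
                return False
    return True


def enforce_values(v: np.ndarray, key: KeyMaterial, nonce: int,
                   limits: ConstraintLimits) -> tuple[np.ndarray, tuple[int, ...]]:
    """Find per-block mask counters making ``v`` constraint-compliant.

    Greedy left-to-right with chronological backtracking; raises
    :class:`ConstraintError` when the budget is exhausted.
    """
    total = v.size
    if total == 0:
        return v, ()
    w = limits.window
    nblocks = (total + w - 1) // w
    counters = [0] * nblocks
    start_k = [0] * nblocks
    cand = v.copy()
    gc_prefix = [0] * (nblocks + 1)  # GC count of enforced prefix per block
    budget = limits.max_attempts * nblocks * 10
    spent = 0
    b = 0
    while b < nblocks:
        s, e = b * w, min((b + 1) * w, total)
        found = False
        for k in range(start_k[b], limits.max_attempts):
            spent += 1
            if spent > budget:
                raise ConstraintError(
                    f"constraint enforcement budget exhausted after "
                    f"{spent} attempts; best prefix reached block {b} "
                    f"of {nblocks}")
            seg = v[s:e] ^ _block_mask(key, nonce, b, k, e - s)
            cand[s:e] = seg
            if _block_ok(cand, s, e, total, gc_prefix[b], limits):
                counters[b] = k
                start_k[b] = k
                gc_prefix[b + 1] = gc_prefix[b] + int(
                    np.count_nonzero((seg == 1) | (seg == 2)))
                found = True
                break
        if found:
            b += 1
            if b < nblocks:
                start_k[b] = 0
        else:
            if b == 0:
                raise ConstraintError(
                    f"no compliant encoding for block 0 within "
                    f"{limits.max_attempts} attempts; violations of last "
                    f"attempt: {violations(NucSeq.from_values(cand[:e], Alphabet.RNA), limits)}")
            start_k[b] = 0
            b -= 1
            start_k[b] = counters[b] + 1
    return cand, tuple(counters)


def enforce(ct, key: KeyMaterial, limits: ConstraintLimits | None = None):
    """Return a constraint-compliant copy of a ciphertext.

    The payload is re-randomized blockwise with keyed masks whose counters
    are stored in the header; decryption strips them first, so the original
    plaintext remains exactly recoverable. A payload that is already
    compliant keeps its bases untouched (all counters zero).
    """
    limits = limits or ConstraintLimits()
    masked, counters = enforce_values(ct.payload.values(), key,
                                      ct.stream_nonce, limits)
    payload = NucSeq.from_values(masked, ct.payload.alphabet)
    if len(payload):
        bad = violations(payload, limits)
        if bad:  # safety net; unreachable if _block_ok is sound
            raise ConstraintError(f"enforcement left violations: {bad}")
    return replace(ct, payload=payload, constraint_counters=counters,
                   constraint_limits=limits)
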