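"""Simulated DNA synthesis/sequencing channel.

Per input base, independently: the base is deleted with ``del_rate``, or
substituted with ``sub_rate`` by a uniformly chosen *different* base; after
each input position a uniform base is inserted with ``ins_rate``. Events are
drawn from a seeded generator, so every corruption run is replayable.

Real platforms show correlated and context-dependent errors (nanopore
homopolymer bias, PCR recombination); this model only reproduces the
aggregate rates, which is what the error-resilience experiments sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nucseq import NucSeq


@dataclass(frozen=True)
class ChannelModel:
    """Per-base error probabilities plus the replay seed."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate > 1.0:
            raise ConfigError("sub + ins + del rates must not exceed 1")


def corrupt(seq: NucSeq, model: ChannelModel) -> NucSeq:
    """Pass a sequence through the channel (seeded, deterministic)."""
    rng = np.random.default_rng(model.seed)
    v = seq.values()
    n = v.size
    if n == 0:
        return seq
    u = rng.random(n)
    deleted = u < model.del_rate
    substituted = (~deleted) & (u < model.del_rate + model.sub_rate)
    # a substitution always lands on one of the other three bases
    offsets = rng.integers(1, 4, size=n, dtype=np.uint8)
    ins_mask = rng.random(n) < model.ins_rate
    ins_vals = rng.integers(0, 4, size=n, dtype=np.uint8)

    out_v = v.copy()
    out_v[substituted] = (v[substituted] + offsets[substituted]) % 4

    keep = ~deleted
    counts = keep.astype(np.int64) + ins_mask.astype(np.int64)
    starts = np.cumsum(counts) - counts
    out = np.zeros(int(counts.sum()), dtype=np.uint8)
    out[starts[keep]] = out_v[keep]
    ins_pos = starts + keep.astype(np.int64)
    out[ins_pos[ins_mask]] = ins_vals[ins_mask]
    return NucSeq.from_values(out, seq.alphabet)
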