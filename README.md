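# helixcrypt

DNA/RNA-inspired encryption for nucleotide data storage: a reversible
multi-layer cipher that turns arbitrary bytes into constraint-respecting
RNA sequences, a Reed-Solomon outer code against synthesis/sequencing
noise, and a built-in security-evaluation suite.

It is written for people who prototype DNA data-storage codecs and
bio-inspired ciphers in software: the molecules are strings over
{A, C, G, U}, the sequencing channel is simulated, and every experiment is
seeded and replayable.

## The scheme

A passphrase is stretched by PBKDF2-HMAC-SHA256 into a 512-bit master key
(256 nucleotide-equivalents). Encryption then chains five invertible
layers:

1. **Dynamic encoding** — bit pairs map to bases through one of 24
   key-selected tables (table 0: 00→A, 01→T, 10→C, 11→G);
2. **Complementary pairing** — the Watson-Crick involution A↔T, C↔G;
3. **DNA-XOR** — a one-time pad over 2-bit symbols from an HMAC-SHA256
   counter-mode keystream;
4. **Chaotic permutation** — a whole-message shuffle given by the ranking
   of logistic-map iterates x_{n+1} = r·x_n(1 − x_n), r = 3.99, seeded
   from the key;
5. **Transcription** — T→U plus two context-chained keyed S-box passes
   (forward, then reverse), which diffuse any single-symbol change over
   the entire payload in both directions.

Optionally, a systematic Reed-Solomon outer code over GF(2⁸) (default
RS(255, 51), t = 102, interleave depth 8) protects the emitted sequence,
and a constraint layer re-randomizes 100-base blocks with keyed masks
until the payload satisfies GC ∈ [45%, 55%], homopolymer runs ≤ 3, and a
clean hairpin screen — with the mask counters stored in the header, so
decryption is unaffected. Ciphertexts are serialized as standard FASTA
plus a JSON header sidecar. See `docs/methods.md` for the full model and
its assumptions.

## Worked example

```python
from helixcrypt import (EncryptionConfig, encrypt, decrypt,
                        enumerate_tables, text_to_bits, bits_to_dna)

cfg = EncryptionConfig(kdf_iterations=1000)   # 600k default; demo speed

bits = text_to_bits(b"CRYPTO")                # 48 bits
dna = bits_to_dna(bits, enumerate_tables()[0])
print(dna)                                    # TAAGTTACTTCTTTAATTTATAGG

ct = encrypt(b"CRYPTO", "correct horse", cfg, salt=bytes(16))
print(ct.payload)                             # CCACGACUUCUUAUUGUAGUAGGA
print(decrypt(ct, "correct horse", cfg))      # b'CRYPTO'
```

The 6-character message becomes 48 bits and 24 bases; under table 0 the
first character 'C' (ASCII 67, 01000011) encodes to TAAG. The encrypted
payload is an RNA string of the same length (no ECC here), uniformly
mixed: over 1 KB random plaintexts the per-base Shannon entropy comes out
at ~1.9995 bits/base against the theoretical maximum of 2, and flipping a
single plaintext bit changes ~50% of payload bits (~75% of nucleotides):

```python
from helixcrypt import avalanche, sequence_entropy
sequence_entropy(ct.payload)                  # entropy of one payload
avalanche("correct horse", cfg, n_trials=200, seed=0)
# (0.501, 0.751)  -> bit-level, nucleotide-level change fractions
```

From the shell, the same pipeline:

```
helixcrypt encrypt message.bin ct.fasta --passphrase-file pw.txt --seed 1
helixcrypt decrypt ct.fasta out.bin --passphrase-file pw.txt
helixcrypt analyze ct.fasta                   # entropy + randomness JSON
helixcrypt simulate --sub-rate 0.08           # channel recovery sweep
```

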