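# Methods

## Scope

helixcrypt turns arbitrary binary data into constraint-respecting RNA
sequences under a passphrase-derived key, and back. It is a software model
of a DNA-storage cryptosystem: the "molecules" are strings over {A, C, G,
U}, the synthesis/sequencing channel is simulated, and every biological
operation (complementary pairing, transcription) is realized as an exactly
invertible transformation. Nothing here authenticates data or resists
side-channel inspection; the package's security goals are confusion,
diffusion, statistical flatness of the ciphertext, and exact recovery.

## Key schedule

A passphrase is stretched with PBKDF2-HMAC-SHA256 (16-byte salt, default
600,000 iterations) into a 512-bit master key — 256 nucleotide-equivalents,
which is what the key-space accounting reports. All other material is
derived from the master key with domain-separated hashes:

* **Encoding table**: SHA-256(master key) mod 24 selects one of the 24
  bijections between bit pairs and bases. Table 0 is the canonical scheme
  00→A, 01→T, 10→C, 11→G; the rest enumerate the base-string permutations
  lexicographically (rotated so the canonical table is index 0).
* **Keystream**: HMAC-SHA256 in counter mode, chopped into 2-bit symbols.
  Counter mode gives the prefix property and deterministic replay, which
  the test harness requires of any keystream it measures.
* **Chaotic permutation**: the logistic map x_{n+1} = r·x_n(1−x_n) with
  r = 3.99, seeded from 8 key-derived bytes scaled into (0, 1) and clamped
  to [2⁻²⁰, 1−2⁻²⁰], 1000 burn-in iterations to leave the transient. The
  *ranking* of the next n iterates (stable argsort) is the shuffle; only
  the ranking matters, so last-ulp platform differences are harmless in
  practice, and the header carries a format version tag so a genuine
  mismatch is detectable rather than silent.

The domain-separation labels are this package's own choices; the scheme
only requires that the keystream, the permutation seed, the S-boxes and the
constraint masks be independent functions of the master key.

## Cipher pipeline

encode → complement → DNA-XOR → chaotic permutation → transcription
(T→U + forward chained S-box) → reverse chained S-box. Each layer is an
exact inverse pair and is tested as one.

The substitution layers deserve detail, because they carry all of the
diffusion. A substitution box over a 4-letter alphabet is one of only 24
bijections, and a chain whose context is merely the neighbouring symbol
cannot spread a change more than a few positions (a difference either
stops at the first coincidental agreement of two boxes, or never involves
positions upstream). To meet the strict avalanche requirement the S-box
index at position i combines:

* a keyed per-context base box (one of the 24 bijections per context
  symbol A/C/G/U plus a start sentinel), and
* a 64-bit rolling accumulator over every (input, output) symbol pair
  already processed (xorshift mixing with a key-derived seed).

Once two messages differ anywhere, their accumulators diverge and — because
the update is injective in the accumulator — never re-merge; every later
position is substituted through an effectively independent random box.
A second pass runs right-to-left with its own boxes and accumulator, so
upstream positions are re-randomized too. The result is the ideal
re-randomization profile for a quaternary alphabet: a one-bit plaintext
change flips each ciphertext nucleotide with probability 3/4 and each
payload bit with probability 1/2. The acceptance suite asserts both at
±3% over 1000 trials of 1 KB. We deliberately do **not** target the
printed 63.8% figure from the motivating experiments: it lies between the
bit-level (50%) and nucleotide-level (75%) ideals and its metric is
ambiguous; a fully diffusing cipher cannot produce it at either level.

Decryption inverts the chain layer by layer. There is no MAC: a wrong
passphrase produces noise, or an error-correction failure when the keyed
constraint layer is active (its masks then strip incorrectly and the
Reed-Solomon stream is corrupted beyond capacity, which surfaces as an
explicit decode error).

## Error-correcting outer code

Reed-Solomon over GF(2⁸) (primitive polynomial 0x11d, systematic encoding,
Berlekamp-Massey + Chien + Forney decoding, standard shortening of the
final block). The code is applied **outside** the cipher — ciphertext
bases are packed 4-per-byte, encoded, and unpacked back to bases — because
the cipher's diffusion layers amplify any post-encryption error into
whole-message noise; an inner code would therefore be useless against
channel errors, while an outer code sees them exactly as the channel made
them. Codewords are round-robin interleaved in groups of
``interleave_depth`` (default 8), so a burst of length B costs each
codeword about B/8 errors.

The default heavy-parity profile is RS(255, 51), t = 102. An 8% per-base
substitution channel induces a per-byte symbol error rate of
1 − 0.92⁴ ≈ 28.4%; a 255-byte codeword then sees ~72 ± 7 errors, leaving
more than a 4σ margin to capacity, so exact recovery at 8% is essentially
certain and the recoverable-rate sweep typically reads 8-9%. The lighter
RS(255, 223) profile is available for clean archival channels.

## Channel model

Per base, independently: deletion (del_rate), substitution (sub_rate,
uniform over the three other bases), then insertion of a uniform base
after the position (ins_rate). Events come from a seeded generator, so
every experiment is replayable. The model reproduces aggregate error rates
only — no bursts, no homopolymer-length bias, no platform asymmetries —
so resilience results transfer to real instruments only to the extent
their error processes resemble independent substitutions. Insertions and
deletions break byte framing and are out of the code's scope (a
synchronization code would be needed); the resilience experiments are
substitution-only, and the channel's indel support exists for exploratory
sweeps.

## Biochemical constraints

Reported properties: whole-payload and sliding-window GC fraction
(window 100), longest homopolymer run, and a hairpin screen that counts
pairs of ``stem_min``-mers (default 6) where the downstream k-mer is the
reverse complement of the upstream one, separated by at least ``loop_min``
(default 3) and spanning at most ``window`` bases. Counting stem *seeds*
of exactly ``stem_min`` detects every longer stem. This is a standard
combinatorial proxy for secondary-structure propensity; a thermodynamic
nearest-neighbour ΔG model is deliberately out of scope (the screen is the
hook where one would plug it in).

Enforcement re-randomizes the payload blockwise: each ``window``-sized
block may be XOR-ed with a keyed mask chosen by a counter; counters are
recorded in the header and stripped first at decryption. Blocks are fixed
greedily left to right — each candidate must satisfy the homopolymer cap
across its junction, every complete GC window ending inside it, the
whole-payload GC band when it is the last block, and contribute no hairpin
stem — with chronological backtracking when a block exhausts its attempt
budget (default 1000 per block). Whole-payload rejection sampling cannot
work at scale: a uniform 4096-base payload has no homopolymer run above 3
with probability about e⁻⁴⁸. Blockwise masking keeps the expected attempt
count per block in the tens, independent of payload length. Because masks
are positionwise, the layer neither harms Reed-Solomon correction nor
plaintext recoverability.

Typical compliant payloads sit at GC 46-54% with maximum run 3 and zero
stem hits at both the 200-base and 4 KB scales.

## Evaluation suite

* **Entropy**: plug-in estimator −Σp log₂p over empirical base
  frequencies (no bias correction, matching how such tables are usually
  printed). On 4 KB payloads the estimator's own bias bounds the
  observable value near 2 − 3/(2n ln 2) ≈ 1.9995 bits/base.
* **Avalanche**: paired encryptions under the same key/salt/nonce with a
  single flipped bit; reports bit-level and nucleotide-level mean change
  fractions, because the two ideals differ (1/2 vs 3/4) and conflating
  them is a common source of unreproducible "avalanche percentages".
* **Randomness**: the frequency (monobit), runs, and spectral DFT tests
  from the SP 800-22 battery, with the standard statistics and the usual
  p > 0.01 pass convention. Only these three are implemented. The runs
  test takes a ``min_bits`` keyword (default 100) so textbook-sized
  examples can be evaluated explicitly without weakening the default
  contract. The DFT test uses the published normal approximation, whose
  p-values are known to be slightly non-uniform under the null; the
  null-uniformity sanity check is therefore run on frequency and runs.
* **Key space**: log₂ accounting of the master key (512 bits = 256
  nucleotide-equivalents). The 24-table choice (log₂24 ≈ 4.6 bits) and
  the nonce are *derived* from the key, so they are reported as structure
  and never multiplied into the key space.

## Experiment scales and harness choices

The acceptance experiments use the evaluation protocol's sizes: 1000
random messages of 128-192 bits (drawn as whole bytes, 16-24), 50
repetitions at 1 KB, 50 × 512-byte messages for the channel sweep at
1-10%, and a 100-ciphertext constraint corpus (50 short, 50 at 1 KB). The
harness runs PBKDF2 at 1000 iterations: KDF hardness is a brute-force
cost knob, orthogonal to every measured quantity, and the production
default (600,000) remains unchanged.

## Known limitations

* No authentication or integrity tag (optional by design; the scheme as
  modeled has none). Wrong-key detection is a side effect of the keyed
  constraint layer, not a guarantee.
* Indel channel errors are not correctable; framing is fixed-length.
* The hairpin screen is combinatorial, not thermodynamic.
* Security rests on standard primitives (PBKDF2, HMAC-SHA256) arranged in
  a bio-inspired pipeline; the chaotic permutation and S-box chains add
  diffusion, not provable hardness, and no formal differential/linear
  cryptanalysis bounds are claimed.
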