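# Methods

## Problem and model

Exact duplicate removal treats a dataset of reads (or read pairs) as a
multiset of sequences and keeps the first occurrence of each distinct
element, in input order. The dedup key is the uppercased sequence text;
for pairs it is `upper(seq1) + 0x00 + upper(seq2)`. The separator byte
cannot occur in sequence text, so concatenation collisions such as
("AC","GT") vs ("ACG","T") are impossible. Headers and quality strings
never enter the key; reads containing N (or any other IUPAC letter) are
keyed literally.

Deliberate non-features of this duplicate definition: reverse-complement
reads are not duplicates (no strand canonicalisation), mate-swapped pairs
are not duplicates (the key is order-sensitive), and no prefix/suffix or
mismatch-tolerant clustering is attempted. These all change the semantics
from "exact copy" to some notion of near-duplicate, which is a different
tool.

## The cuckoo filter

Membership of previously-seen keys is tracked by a partial-key cuckoo
filter built from scratch in `cuckoodedup.cuckoo`:

- table of `m` buckets × `b` slots of `f`-bit fingerprints stored in a
  numpy `uint32` grid; slot value 0 is the empty sentinel, so fingerprints
  that hash to 0 are remapped to 1 (a branch-free emptiness test, at the
  cost of doubling the frequency of fingerprint 1 — negligible for f ≥ 8);
- two candidate buckets per item, `i1 = H(x) mod m` and
  `i2 = i1 XOR (H(fp) mod m)`; `m` is forced to a power of two so the XOR
  stays in range and is an involution (`alt(alt(i)) = i`), which is what
  allows evicted fingerprints to be relocated without knowing the original
  key;
- insertion tries both buckets, then performs up to `max_kicks` random
  evictions; a failed insert unwinds its eviction path (each kick is a
  swap, so replaying the swaps in reverse restores the table exactly) and
  reports the filter full rather than raising;
- deletion removes one matching fingerprint from a candidate bucket.
  Deleting a never-inserted item can evict a colliding fingerprint of
  another item — the standard hazard of all cuckoo filters — and is
  documented as caller responsibility.

Analytic false-positive rate: a negative query inspects at most `2b`
occupied slots, each matching with probability `~2^-f`, giving
`FPR ≈ 2b/2^f` at full load (and `load × 2b/2^f` below it). No false
negatives for items inserted and not deleted.

### Hashing

All hashing is keyed BLAKE2b (stdlib `hashlib`) truncated to 64 bits.
The user seed becomes the BLAKE2b key; a per-role personalisation string
(`bucket-index`, `fingerprint`, `alt-offset`) separates the three hash
streams so one seed drives the whole structure deterministically and
cross-platform. BLAKE2b is cryptographic-grade and C-backed, so it is both
a high-quality and a zero-dependency choice; a dedicated non-cryptographic
hash would be marginally faster but would add a dependency for no testable
benefit at this package's scale.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `fingerprint_bits` (f) | 16 | FPR ≈ 1.2×10⁻⁴: accidental loss of unique reads is negligible at typical dataset sizes |
| `bucket_slots` (b) | 4 | (2,4) tables reliably pack past 90% load (measured median ≈ 0.97) |
| `max_kicks` | 500 | standard relocation budget; failures below ~90% load are rare |
| design load | 0.90 | `make_filter` sizes `m` as the smallest power of two with `m·b ≥ expected/0.90` |
| `seed` | 42 | byte-reproducible runs by default |

### Full-filter policy

Fingerprints cannot be rehashed into a larger table (the original keys are
gone), so the dedup engine never grows a filter; on a failed insert it
chains a fresh filter of the same geometry with a tweaked seed. New keys
are inserted into the newest filter; membership consults the whole chain.
This preserves the no-false-negative contract without re-reading input, at
the cost of one extra lookup per chained filter. With no expected count
given, each filter is sized for 2²⁰ keys, avoiding a counting pre-pass on
possibly gzipped streams.

## FASTQ layer

Strict 4-line dialect, plain or gzip (reader autodetects by magic bytes;
writer gzips on a `.gz` suffix). Wrapped multi-line FASTQ is rejected, not
repaired — silent repair hides corruption. Format errors carry the 1-based
record index. Pairing is positional (record *k* with record *k*): that is
what synchronized pair files guarantee, it needs O(1) memory, and no
header-token convention has to be assumed. Unequal record counts (orphan
tails) are an error by default; `drop_tail` is an explicit opt-in that
yields the common prefix and logs the orphan count. Sequence case is
preserved on output; folding happens only inside key construction.

## Simulator

`cuckoodedup.simulate` emulates, at desk scale, what genome read
simulators do on real references, with just enough realism to exercise an
exact duplicate remover:

1. reference: i.i.d. uniform A/C/G/T (or any supplied string);
2. templates: `N0 = round(coverage · G / L)` single-end reads (paired:
   fragments yield two reads of length L, so the fragment count is halved),
   start positions uniform, forward strand; paired fragments draw their
   length from Normal(`insert_size_mean`=300, sd=30) clipped to `[L, G]`,
   with mate2 reverse-complemented from the far fragment end;
3. errors: per-base substitutions at `substitution_rate` (default 10⁻³, a
   typical short-read scale), applied once per template; a substituted base
   is always changed to a *different* base;
4. PCR duplication: each template is emitted `1 + extra` times, `extra`
   drawn from `none`, `poisson(λ)`, or `geometric(p) − 1` (so p = 1 and
   λ = 0 both degenerate to `none`); copies are made **after** the error
   step and are byte-identical — exactly the redundancy an exact-identity
   dedup must find;
5. the emitted order is globally shuffled (seeded), and the ground truth
   is computed *post hoc* by multiset-counting the dedup keys of what was
   actually emitted, which absorbs coincidental sequence collisions
   between distinct templates.

Qualities are a constant character (default `I`): dedup ignores qualities,
so quality realism buys nothing testable. Not modelled: platform error
profiles, indels, homopolymer errors, amplicon bias, reverse-strand
sampling, optical duplicates. Consequently, passing tests demonstrate
correctness of *exact-copy* removal under substitution noise — they say
nothing about near-duplicate or strand-collapsed definitions of
redundancy on real data.

`coverage_series` crosses one reference with several coverages
(default 100×/200×/300×, seeds `base+index`); three references × three
coverages reproduce the nine-dataset coverage-validation design at
whatever reference length the caller picks.

## Validation logic and problem sizes

The package's own acceptance logic mirrors the classic unique-read
conservation argument: after an exact dedup, the number of distinct
sequences must equal that of the raw input and every kept sequence must
appear exactly once; a filter-backed dedup may remove *more* than the
ground-truth redundancy but never less, and its excess must stay within
the binomial false-positive budget at rate `2b/2^f` over distinct-key
queries.

Problem sizes used by the test suite and `scripts/acceptance.py` were
chosen to make all stochastic checks statistically comfortable on a single
CPU: 102 simulated datasets (templates uniform in [10³, 10⁴], λ ∈ {0, 0.3,
1.0}, single and paired) for the dedup correctness and filter-fidelity
suites; 3 × 100 kb references at 100×/200×/300× for the coverage series;
10⁵-item insert/lookup runs, 2–3×10⁵ never-inserted probes for FP-rate
estimation, and 20-seed load experiments on a 256-bucket table for the
filter microbenchmarks. All randomness flows from explicit seeds; reruns
are byte-identical.

## Numerical and degenerate-input choices

- `removed_pct` is defined as 0 for empty input and reported to two
  decimals in JSON.
- `m = 1` tables are legal: both candidate buckets coincide and the filter
  degenerates gracefully.
- A discarded pair counts 2 toward `removed_reads`; pair atomicity
  guarantees the two output files always stay synchronized.
- The eviction RNG is `random.Random(seed)` per filter; chained filters
  tweak the seed by their chain index so their eviction paths differ.

## Known limitations

- Cuckoo mode can discard a novel read as a false positive (rate
  `~2b/2^f`); use `--mode exact` when zero loss matters more than memory.
- Deleting never-inserted items from the raw filter can evict other
  items' fingerprints (inherent to the structure; the dedup engine never
  deletes).
- Pairing is positional only; files paired by header token but not by
  position will be mis-paired silently.
- The simulator's ground truth is defined at the key level, so it counts
  coincidental inter-template collisions as redundancy — intentional, and
  the reason "exact removal" and "ground truth" agree identically.
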