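# cuckoodedup

Exact duplicate-read removal for FASTQ data, backed by a partial-key cuckoo
filter.

PCR amplification during library preparation leaves sequencing datasets with
byte-identical copies of reads ("redundancy"). These duplicates inflate
apparent coverage, create false overlaps in de novo assembly, and waste
compute downstream, so removing them is a standard first step in read
quality control. `cuckoodedup` removes exact duplicates from single-end or
paired-end FASTQ (plain or gzipped, any platform, uniform or mixed read
lengths) in one streaming pass. Instead of holding every sequence in memory,
it stores a short fingerprint of each sequence seen so far in a cuckoo
filter, so memory stays a small, nearly constant fraction of the input.

## The structure at the core

A cuckoo filter is a table of *m* buckets × *b* slots, each slot holding one
*f*-bit fingerprint. An item *x* has two candidate buckets,

    i1 = H(x) mod m,        i2 = i1 XOR (H(fp(x)) mod m),

where `fp(x)` is the low *f* bits of a hash of *x* (0 reserved for empty
slots, so 0 remaps to 1). Because *m* is a power of two and the alternate
index is an XOR, either bucket can compute the other from the fingerprint
alone — which is what lets insertion relocate ("kick") resident fingerprints
cuckoo-style when both buckets are full. The filter has **no false
negatives** for retained items and a false-positive rate of about

    FPR ≈ 2·b / 2^f         (≈ 1.2 × 10⁻⁴ at the defaults f=16, b=4),

so in dedup terms: no duplicate ever survives, and a novel read is
mistakenly discarded only at the FPR. An exact-set mode (`--mode exact`,
zero error, more memory) is built in as both a user option and the
verification oracle. When a filter fills (past ~95% load is hard to reach
before relocation fails), the engine transparently chains a fresh filter and
keeps going. Hashing is keyed BLAKE2b truncated to 64 bits; one seed drives
hashing and eviction, so runs are byte-reproducible.

Duplicates are defined as exact, order-sensitive, full-length sequence
matches — headers and qualities are ignored, case is folded, pairs are keyed
jointly (mate1 then mate2 with a separator byte). Reverse complements and
mate-swapped pairs are *not* duplicates.

The package also ships a read simulator with a controlled PCR-duplication
model and exact ground truth, plus a unique-read counter, so the whole
pipeline is testable end to end without external data.

## Worked example

Simulate a 50 kb reference at 20× coverage with Poisson(0.5) extra PCR
copies per template, then deduplicate and verify:

```sh
cuckoodedup simulate --reference-length 50000 --coverage 20 \
    --duplication-model poisson --duplication-param 0.5 --seed 11 \
    --out-dir sim --report sim.json
cuckoodedup dedup --in1 sim/sim.fastq --out1 dedup.fastq \
    --expected-items 20000 --report dedup.json
cuckoodedup count-unique --in1 dedup.fastq
```

The simulator reports the ground truth of the 15 032 reads it emitted:

```json
"ground_truth": {"total": 15032, "distinct": 9233,
                 "unique_once": 5156, "redundant": 5799}
```

The dedup report shows exactly the 5 799 redundant copies removed (38.58%
of reads), keeping 9 233 — one per distinct sequence, no false-positive
losses at these sizes:

```json
"total_reads": 15032, "kept_reads": 9233,
"removed_reads": 5799, "removed_pct": 38.58
```

and the final count confirms the conservation property every exact
duplicate remover must satisfy — the deduplicated file holds exactly the
raw dataset's unique sequences, each appearing once:

```json
"total": 9233, "distinct": 9233, "unique_once": 9233, "redundant": 0
```

Exit codes: 0 success, 1 usage error, 2 format/pairing error (e.g. orphan
mates under the default `--orphan-policy error`), 3 I/O error.

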