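"""Partial-key cuckoo filter: a compact approximate-membership structure.

The filter stores short *fingerprints* of items in a table of ``m`` buckets
with ``b`` slots each.  Every item has exactly two candidate buckets; the
second is derived from the first by XOR-ing with a hash of the fingerprint,
so it can be recomputed from table contents alone (the "partial-key" trick).
Insertion relocates resident fingerprints cuckoo-style when both candidate
buckets are full.  Lookups can return false positives (two distinct items may
share a fingerprint and a bucket) but never false negatives for items that
were inserted and not deleted.  The analytic false-positive rate is about
``2*b / 2**f`` for ``f``-bit fingerprints.

Hashing is done with a keyed BLAKE2b truncated to 64 bits; the key carries
the user seed and the personalization string separates the three hash roles
(bucket index, fingerprint derivation, alternate-bucket offset), so one seed
drives the whole structure reproducibly.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CuckooFilterParams",
    "CuckooFilter",
    "make_filter",
    "fingerprint_of",
    "candidate_buckets",
    "hash64",
]


def hash64(data: bytes, seed: int, role: bytes) -> int:
    """Seeded 64-bit hash of ``data``.

    ``role`` is a short personalization tag (max 16 bytes) that makes the
    item-index, fingerprint and alternate-index hash streams independent
    while sharing one seed.
    """
    h = hashlib.blake2b(
        data,
        digest_size=8,
        key=(seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little"),
        person=role,
    )
    return int.from_bytes(h.digest(), "little")


_ROLE_INDEX = b"bucket-index"
_ROLE_FPRINT = b"fingerprint"
_ROLE_ALT = b"alt-offset"


@dataclass(frozen=True)
class CuckooFilterParams:
    """Geometry and seeding of a cuckoo filter.

    fingerprint_bits
        ``f``, bits per stored fingerprint, 4..32.  FP rate ~ ``2*b/2**f``.
    bucket_slots
        ``b``, fingerprints per bucket.
    num_buckets
        ``m``, must be a power of two (required for the XOR alternate index).
    max_kicks
        Relocation attempts before an insert reports the filter full.
    seed
        Drives all hashing and the eviction RNG; fixed seed gives
        byte-reproducible behaviour.
    """

    fingerprint_bits: int = 16
    bucket_slots: int = 4
    num_buckets: int = 1
    max_kicks: int = 500
    seed: int = 42

    def __post_init__(self) -> None:
        f, b, m = self.fingerprint_bits, self.bucket_slots, self.num_buckets
        if not 4 <= f <= 32:
            raise ValueError(f"fingerprint_bits must be in [4, 32], got {f}")
        if b < 1:
            raise ValueError(f"bucket_slots must be >= 1, got {b}")
        if m < 1 or (m & (m - 1)) != 0:
            raise ValueError(f"num_buckets must be a positive power of two, got {m}")
        if self.max_kicks < 1:
            raise ValueError(f"max_kicks must be >= 1, got {self.max_kicks}")

    @property
    def capacity(self) -> int:
        return self.num_buckets * self.bucket_slots


def fingerprint_of(item: bytes, params: CuckooFilterParams) -> int:
    """Derive the ``f``-bit fingerprint of ``item``.

    The low ``f`` bits of the 64-bit hash, remapped to 1 when the masked
    value is 0 (0 is the empty-slot sentinel).  Deterministic for a fixed
    (item, f, seed).
    """
    if not item:
        raise ValueError("cannot fingerprint an empty item")
    mask = (1 << params.fingerprint_bits) - 1
    fp = hash64(item, params.seed, _ROLE_FPRINT) & mask
    return fp if fp != 0 else 1


def _alt_offset(fp: int, params: CuckooFilterParams) -> int:
    fp_bytes = fp.to_bytes(4, "little")
    return hash64(fp_bytes, params.seed, _ROLE_ALT) % params.num_buckets


def candidate_buckets(item: bytes, fp: int, params: CuckooFilterParams) -> tuple[int, int]:
    """The two candidate bucket indices of ``item``.

    ``i1 = H(item) mod m``; ``i2 = i1 XOR (H(fp) mod m)``.  Because ``m`` is a
    power of two, XOR keeps indices in range and the mapping is an involution:
    the alternate of the alternate is the original bucket, which is what lets
    eviction recompute destinations from fingerprints alone.
    """
    m = params.num_buckets
    i1 = hash64(item, params.seed, _ROLE_INDEX) % m
    i2 = i1 ^ _alt_offset(fp, params)
    return i1, i2


class CuckooFilter:
    """A cuckoo filter with insert / contains / delete.

    The table is an ``m x b`` uint32 grid; slot value 0 means empty.  A failed
    insert (``max_kicks`` exhausted) returns ``False`` and leaves the table
    exactly as it was — callers decide whether to chain a fresh filter.
    """

    def __init__(self, params: CuckooFilterParams) -> None:
        self.params = params
        self.table = np.zeros((params.num_buckets, params.bucket_slots), dtype=np.uint32)
        self.item_count = 0
        self._rng = random.Random(params.seed)

    # -- internal helpers -------------------------------------------------

    def _try_place(self, bucket: int, fp: int) -> bool:
        row = self.table[bucket]
        empty = np.flatnonzero(row == 0)
        if empty.size:
            row[empty[0]] = fp
            return True
        return False

    # -- public API --------------------------------------------------------

    def insert(self, item: bytes) -> bool:
        """Insert ``item``; returns False iff the filter is full.

        On success ``contains(item)`` is guaranteed true until a delete.  On
        failure the eviction path is unwound so the table holds exactly its
        pre-call contents.
        """
        params = self.params
        fp = fingerprint_of(item, params)
        i1, i2 = candidate_buckets(item, fp, params)
        if self._try_place(i1, fp) or self._try_place(i2, fp):
            self.item_count += 1
            return True

        rng = self._rng
        bucket = rng.choice((i1, i2))
        cur = fp
        path: list[tuple[int, int]] = []
        for _ in range(params.max_kicks):
            slot = rng.randrange(params.bucket_slots)
            path.append((bucket, slot))
            cur, self.table[bucket, slot] = int(self.table[bucket, slot]), cur
            bucket = bucket ^ _alt_offset(cur, params)
            if self._try_place(bucket, cur):
                self.item_count += 1
                return True
        # unwind: each step was a swap, so replaying swaps in reverse restores
        for bucket, slot in reversed(path):
            cur, self.table[bucket, slot] = int(self.table[bucket, slot]), cur
        return False

    def contains(self, item: bytes) -> bool:
        """Membership query; no false negatives for retained items."""
        params = self.params
        fp = fingerprint_of(item, params)
        i1, i2 = candidate_buckets(item, fp, params)
        return bool(np.any(self.table[i1] == fp) or np.any(self.table[i2] == fp))

    def delete(self, item: bytes) -> bool:
        """Remove one matching fingerprint if present; returns whether one was.

        Deleting an item that was never inserted may evict a colliding
        fingerprint of a *different* item (standard cuckoo-filter hazard):
        only delete items known to have been inserted.
        """
        params = self.params
        fp = fingerprint_of(item, params)
        i1, i2 = candidate_buckets(item, fp, params)
        for bucket in (i1, i2):
            row = self.table[bucket]
            hits = np.flatnonzero(row == fp)
            if hits.size:
                row[hits[0]] = 0
                self.item_count -= 1
                return True
        return False

    @property
    def load_factor(self) -> float:
        return self.item_count / self.params.capacity

    def __contains__(self, item: bytes) -> bool:
        return self.contains(item)

    def __len__(self) -> int:
        return self.item_count

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        p = self.params
        return (
            f"CuckooFilter(f={p.fingerprint_bits}, b={p.bucket_slots}, "
            f"m={p.num_buckets}, n={self.item_count}, load={self.load_factor:.3f})"
        )


def make_filter(expected_items: int, **overrides) -> CuckooFilter:
    """Build an empty filter sized for ``expected_items`` at <= 90% design load.

    ``m`` is the smallest power of two with ``m*b >= expected_items / 0.90``.
    Keyword overrides are CuckooFilterParams fields.
    """
    if expected_items < 0:
        raise ValueError(f"expected_items must be >= 0, got {expected_items}")
    probe = CuckooFilterParams(num_buckets=1, **{k: v for k, v in overrides.items() if k != "num_buckets"})
    if "num_buckets" in overrides:
        params = CuckooFilterParams(**overrides)
    else:
        b = probe.bucket_slots
        need = expected_items / 0.90
        m = 1
        while m * b < need:
            m *= 2
        params = CuckooFilterParams(num_buckets=m, **{k: v for k, v in overrides.items() if k != "num_buckets"})
    return CuckooFilter(params)
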