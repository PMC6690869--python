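"""Streaming exact-duplicate removal for reads and read pairs.

A *duplicate* here is an exact, order-sensitive, full-length sequence match:
the dedup key is the uppercased sequence (for pairs, the two uppercased
sequences joined by a 0x00 separator, mate1 first).  Headers and qualities
never enter the key; reverse complements and mate-swapped pairs are distinct
by design.  The first occurrence of each key is kept, in input order.

Two membership backends implement the keep/discard decision:

* ``CuckooBackend`` — a chain of cuckoo filters.  A full filter is never an
  error: a fresh filter (same geometry) is appended and inserted into, while
  all filters in the chain are consulted for membership, preserving the
  no-false-negative contract without re-reading input.  A false positive
  discards a genuinely novel read at rate ~``2b/2**f`` (~1.2e-4 at the
  default f=16, b=4).
* ``ExactBackend`` — a plain hash set; zero error in both directions.  Serves
  both as a user-selectable mode and as the verification oracle in tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

from .cuckoo import CuckooFilter, CuckooFilterParams, make_filter
from .fastq import FastqWriter, ReadPair, ReadRecord, paired_stream, read_fastq

logger = logging.getLogger(__name__)

__all__ = [
    "key_single",
    "key_paired",
    "DedupReport",
    "ExactBackend",
    "CuckooBackend",
    "deduplicate",
    "dedup_files",
]

DEFAULT_EXPECTED_ITEMS = 1 << 20  # per-filter capacity target when caller gives no count


def key_single(read: ReadRecord) -> bytes:
    """Dedup key of a single read: uppercased sequence bytes."""
    return read.sequence.upper().encode("ascii")


def key_paired(pair: ReadPair) -> bytes:
    """Dedup key of a pair: upper(seq1) + 0x00 + upper(seq2), order-sensitive.

    The separator byte (never a base letter) prevents concatenation
    collisions like ("AC","GT") vs ("ACG","T").
    """
    return (
        pair.mate1.sequence.upper().encode("ascii")
        + b"\x00"
        + pair.mate2.sequence.upper().encode("ascii")
    )


@dataclass
class DedupReport:
    """Counters of a dedup run.  Counts are reads (a discarded pair adds 2)."""

    total_reads: int = 0
    kept_reads: int = 0
    removed_reads: int = 0
    mode: str = "cuckoo"
    filter_params: Optional[CuckooFilterParams] = None
    filters_chained: int = 0

    @property
    def removed_pct(self) -> float:
        """Percentage of reads removed, 0 for empty input."""
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.removed_reads / self.total_reads

    def to_dict(self) -> dict:
        d = {
            "total_reads": self.total_reads,
            "kept_reads": self.kept_reads,
            "removed_reads": self.removed_reads,
            "removed_pct": round(self.removed_pct, 2),
            "mode": self.mode,
            "filters_chained": self.filters_chained,
        }
        if self.filter_params is not None:
            p = self.filter_params
            d["filter_params"] = {
                "fingerprint_bits": p.fingerprint_bits,
                "bucket_slots": p.bucket_slots,
                "num_buckets": p.num_buckets,
                "max_kicks": p.max_kicks,
                "seed": p.seed,
            }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        return (
            f"total={self.total_reads} kept={self.kept_reads} "
            f"removed={self.removed_reads} ({self.removed_pct:.2f}%) mode={self.mode}"
        )


class ExactBackend:
    """Exact key set: the zero-error membership oracle."""

    mode = "exact"

    def __init__(self) -> None:
        self._keys: set[bytes] = set()

    def contains(self, key: bytes) -> bool:
        return key in self._keys

    def add(self, key: bytes) -> None:
        self._keys.add(key)

    @property
    def filters_chained(self) -> int:
        return 0

    @property
    def filter_params(self) -> None:
        return None


class CuckooBackend:
    """Chain of cuckoo filters; grows by appending a filter when one fills.

    Growing an existing filter is impossible (fingerprints cannot be
    rehashed without the original keys), so overflow chains a new filter of
    the same geometry instead; membership consults every filter in the chain.
    """

    mode = "cuckoo"

    def __init__(
        self,
        expected_items: int = DEFAULT_EXPECTED_ITEMS,
        **param_overrides,
    ) -> None:
        self._expected = expected_items
        self._overrides = dict(param_overrides)
        self.filters: list[CuckooFilter] = [make_filter(expected_items, **param_overrides)]

    def contains(self, key: bytes) -> bool:
        return any(f.contains(key) for f in self.filters)

    def add(self, key: bytes) -> None:
        if self.filters[-1].insert(key):
            return
        logger.info(
            "cuckoo filter full at load %.3f; chaining filter #%d",
            self.filters[-1].load_factor,
            len(self.filters) + 1,
        )
        # fresh filter gets a tweaked seed so its eviction path differs
        overrides = dict(self._overrides)
        overrides["seed"] = self.filters[-1].params.seed + len(self.filters)
        nxt = make_filter(self._expected, **overrides)
        self.filters.append(nxt)
        if not nxt.insert(key):  # pragma: no cover - fresh filter cannot be full
            raise RuntimeError("insert failed on a fresh cuckoo filter")

    @property
    def filters_chained(self) -> int:
        return len(self.filters)

    @property
    def filter_params(self) -> CuckooFilterParams:
        return self.filters[0].params


Unit = Union[ReadRecord, ReadPair]
Writer = Callable[[ReadRecord], None]


def deduplicate(
    units: Iterable[Unit],
    backend,
    writer: Optional[Writer] = None,
    writer2: Optional[Writer] = None,
) -> DedupReport:
    """Keep the first occurrence of every dedup key, in input order.

    ``units`` is a stream of ReadRecords or ReadPairs.  For pairs both mates
    are written (mate1 via ``writer``, mate2 via ``writer2``) or neither;
    counters count reads, so a discarded pair adds 2 to ``removed_reads``.
    """
    report = DedupReport(mode=backend.mode)
    for unit in units:
        if isinstance(unit, ReadPair):
            key = key_paired(unit)
            nreads = 2
        else:
            key = key_single(unit)
            nreads = 1
        report.total_reads += nreads
        if backend.contains(key):
            report.removed_reads += nreads
            continue
        backend.add(key)
        report.kept_reads += nreads
        if writer is not None:
            if nreads == 2:
                writer(unit.mate1)
                if writer2 is None:
                    raise ValueError("paired input requires two writers")
                writer2(unit.mate2)
            else:
                writer(unit)
    report.filters_chained = backend.filters_chained
    report.filter_params = backend.filter_params
    return report


def dedup_files(
    in1: str | Path,
    out1: str | Path,
    in2: Optional[str | Path] = None,
    out2: Optional[str | Path] = None,
    mode: str = "cuckoo",
    orphan_policy: str = "error",
    expected_items: Optional[int] = None,
    **filter_overrides,
) -> DedupReport:
    """File-to-file dedup: single-end (in1→out1) or paired (in1,in2→out1,out2)."""
    if (in2 is None) != (out2 is None):
        raise ValueError("paired input requires both in2 and out2 (or neither)")
    if mode == "exact":
        backend = ExactBackend()
    elif mode == "cuckoo":
        backend = CuckooBackend(
            expected_items if expected_items is not None else DEFAULT_EXPECTED_ITEMS,
            **filter_overrides,
        )
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    if in2 is None:
        units: Iterable[Unit] = read_fastq(in1)
        with FastqWriter(out1) as w1:
            return deduplicate(units, backend, w1.write)
    units = paired_stream(in1, in2, orphan_policy=orphan_policy)
    with FastqWriter(out1) as w1, FastqWriter(out2) as w2:
        return deduplicate(units, backend, w1.write, w2.write)
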