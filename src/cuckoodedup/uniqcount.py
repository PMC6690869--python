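"""Exact multiset counting of read (or pair) sequence multiplicities.

The validation logic for any exact duplicate remover: after dedup, the
number of distinct sequences must equal that of the raw input, and every
kept sequence must appear exactly once.  Counting uses the same key rule as
the dedup engine (uppercased sequence; pairs keyed jointly, mate1 first) so
the conservation properties are directly comparable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .dedup import key_paired, key_single
from .fastq import ReadPair, ReadRecord, paired_stream, read_fastq

__all__ = ["UniqueCountReport", "count_records", "count_unique"]


@dataclass(frozen=True)
class UniqueCountReport:
    """Multiset summary of a dataset.

    total
        number of reads (or pairs, for paired input).
    distinct
        number of distinct keys.
    unique_once
        keys with multiplicity exactly one ("unique reads" in the validation
        sense).
    redundant
        total - distinct: the copies an exact dedup must remove.
    """

    total: int
    distinct: int
    unique_once: int

    @property
    def redundant(self) -> int:
        return self.total - self.distinct

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "distinct": self.distinct,
            "unique_once": self.unique_once,
            "redundant": self.redundant,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def count_records(units: Iterable[Union[ReadRecord, ReadPair]]) -> UniqueCountReport:
    """Count key multiplicities over an in-memory or streamed unit sequence."""
    counts: Counter[bytes] = Counter()
    for unit in units:
        counts[key_paired(unit) if isinstance(unit, ReadPair) else key_single(unit)] += 1
    total = sum(counts.values())
    unique_once = sum(1 for c in counts.values() if c == 1)
    return UniqueCountReport(total=total, distinct=len(counts), unique_once=unique_once)


def count_unique(path1: str | Path, path2: Optional[str | Path] = None) -> UniqueCountReport:
    """Count over a FASTQ file, or jointly over a synchronized pair of files."""
    if path2 is None:
        return count_records(read_fastq(path1))
    return count_records(paired_stream(path1, path2))
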