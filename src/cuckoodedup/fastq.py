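"""Streaming 4-line FASTQ I/O with gzip transparency and paired-file sync.

Readers autodetect gzip by magic bytes; writers gzip when the path ends in
``.gz``.  Only the modern 4-line dialect is accepted — wrapped (multi-line)
records are rejected as format errors rather than silently repaired.  Paired
files are synchronized positionally (record k with record k); unequal record
counts are either an error or an explicit drop of the orphan tail.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "ReadPair",
    "FastqFormatError",
    "PairingError",
    "read_fastq",
    "write_fastq",
    "FastqWriter",
    "paired_stream",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ: truncation, bad markers, or seq/qual length mismatch."""


class PairingError(ValueError):
    """Paired FASTQ files with unequal record counts under the ``error`` policy."""


@dataclass(slots=True)
class ReadRecord:
    """One FASTQ record: header (without '@'), sequence, '+'-line rest, quality."""

    read_id: str
    sequence: str
    plus_line: str = ""
    quality: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length {len(self.sequence)}"
            )


@dataclass(slots=True)
class ReadPair:
    mate1: ReadRecord
    mate2: ReadRecord


def _open_text_auto(path: str | Path) -> io.TextIOBase:
    """Open for reading, decompressing gzip if the magic bytes say so."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a plain or gzipped 4-line FASTQ file.

    Raises FastqFormatError (naming the 1-based record index) on truncated
    records, missing '@'/'+' markers, or sequence/quality length mismatch.
    """
    with _open_text_auto(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            record_index += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if seq == "" or plus == "" or qual == "":
                raise FastqFormatError(
                    f"{path}: truncated record {record_index} (EOF mid-record)"
                )
            header, seq, plus, qual = (
                header.rstrip("\r\n"),
                seq.rstrip("\r\n"),
                plus.rstrip("\r\n"),
                qual.rstrip("\r\n"),
            )
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {record_index} header does not start with '@'"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {record_index} separator does not start with '+'"
                    " (wrapped multi-line FASTQ is not supported)"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: record {record_index} sequence/quality length mismatch"
                    f" ({len(seq)} vs {len(qual)})"
                )
            if len(seq) == 0:
                raise FastqFormatError(f"{path}: record {record_index} has empty sequence")
            yield ReadRecord(header[1:], seq, plus[1:], qual)


def _format_record(rec: ReadRecord) -> str:
    return f"@{rec.read_id}\n{rec.sequence}\n+{rec.plus_line}\n{rec.quality}\n"


class FastqWriter:
    """Incremental FASTQ writer; gzips when the path ends in ``.gz``."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        try:
            if str(path).endswith(".gz"):
                self._fh = gzip.open(self.path, "wt")
            else:
                self._fh = open(self.path, "wt")
        except OSError as exc:
            raise OSError(f"cannot open {path} for writing: {exc}") from exc
        self.count = 0

    def write(self, rec: ReadRecord) -> None:
        self._fh.write(_format_record(rec))
        self.count += 1

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as canonical 4-line FASTQ; returns the count written.

    ``read_fastq(write_fastq(...))`` reproduces the records exactly.
    """
    with FastqWriter(path) as w:
        for rec in records:
            w.write(rec)
        return w.count


def paired_stream(
    path1: str | Path,
    path2: str | Path,
    orphan_policy: Literal["error", "drop_tail"] = "error",
) -> Iterator[ReadPair]:
    """Pair record k of ``path1`` with record k of ``path2`` (positional).

    On unequal record counts: ``error`` raises PairingError reporting both
    counts; ``drop_tail`` yields the common prefix and logs how many orphan
    records were dropped.
    """
    if orphan_policy not in ("error", "drop_tail"):
        raise ValueError(f"unknown orphan_policy: {orphan_policy!r}")
    it1, it2 = read_fastq(path1), read_fastq(path2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is not None and r2 is not None:
            n += 1
            yield ReadPair(r1, r2)
            continue
        if r1 is None and r2 is None:
            return
        # one side exhausted: count the orphan tail on the other
        orphans = 1
        for _ in it1 if r2 is None else it2:
            orphans += 1
        longer = path1 if r2 is None else path2
        if orphan_policy == "error":
            c1 = n + (orphans if r2 is None else 0)
            c2 = n + (orphans if r1 is None else 0)
            raise PairingError(
                f"paired files have unequal record counts: {c1} vs {c2} "
                f"({path1} vs {path2})"
            )
        logger.warning("dropped %d orphan record(s) from tail of %s", orphans, longer)
        return
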