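"""Synthetic FASTQ generator with controlled PCR duplication and ground truth.

Emulates at desk scale what read simulators like ART do on real genomes:
templates are drawn uniformly from a reference (forward strand), a per-base
substitution error model is applied once per template, and the PCR step is
mimicked by emitting each template ``1 + extra`` times, where ``extra`` comes
from a chosen duplication model.  Copies are made *after* the error step, so
duplicates are byte-identical — exactly the kind of redundancy an
exact-identity duplicate remover must find.  Ground truth is computed post
hoc by multiset counting of dedup keys on the emitted dataset, which also
absorbs coincidental collisions between distinct templates.

Not modelled (and out of scope for exact dedup): platform-specific quality
profiles, indels, homopolymer errors, amplicon bias, reverse-strand
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .fastq import ReadPair, ReadRecord, write_fastq
from .uniqcount import UniqueCountReport, count_records

__all__ = [
    "SimSpec",
    "SimResult",
    "simulate_reference",
    "simulate_reads",
    "coverage_series",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b

DUPLICATION_MODELS = ("none", "poisson", "geometric")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated dataset.

    read_length, coverage
        Template count is ``round(coverage * reference_length / read_length)``
        for single-end; paired fragments contribute two reads, so the
        template (fragment) count is halved.
    substitution_rate
        Per-base probability of a substitution error, applied once per
        template (defaults to 1e-3, a typical short-read scale).
    duplication_model / duplication_param
        Extra byte-identical copies per template: ``none``; ``poisson`` with
        mean lambda; ``geometric`` with success probability p (extras are
        geometric(p) - 1, so p=1 degenerates to none).
    quality_char
        Single Phred+33 symbol filling every quality string; qualities are
        ignored by dedup, so realism here buys nothing testable.
    """

    read_length: int = 100
    coverage: float = 100.0
    paired: bool = False
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    substitution_rate: float = 0.001
    duplication_model: str = "none"
    duplication_param: float = 0.0
    quality_char: str = "I"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")
        if not 0.0 <= self.substitution_rate <= 0.2:
            raise ValueError(
                f"substitution_rate must be in [0, 0.2], got {self.substitution_rate}"
            )
        if self.duplication_model not in DUPLICATION_MODELS:
            raise ValueError(
                f"duplication_model must be one of {DUPLICATION_MODELS}, "
                f"got {self.duplication_model!r}"
            )
        if self.duplication_model == "poisson" and self.duplication_param < 0:
            raise ValueError("poisson duplication needs lambda >= 0")
        if self.duplication_model == "geometric" and not 0 < self.duplication_param <= 1:
            raise ValueError("geometric duplication needs p in (0, 1]")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


@dataclass
class SimResult:
    """A generated dataset plus its ground-truth multiset summary."""

    spec: SimSpec
    paths: list[str]
    total_reads: int
    ground_truth: UniqueCountReport
    records: Optional[list[ReadRecord]] = None  # single-end, in-memory
    pairs: Optional[list[ReadPair]] = None  # paired, in-memory

    @property
    def units(self):
        """The emitted units (records or pairs) when kept in memory."""
        return self.pairs if self.pairs is not None else self.records


def simulate_reference(length: int, seed: int = 0) -> str:
    """I.i.d. uniform A/C/G/T reference sequence; deterministic per seed."""
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _extract_reads(ref: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """(n, length) uint8 matrix of substrings of ``ref`` at ``starts``."""
    return ref[starts[:, None] + np.arange(length)[None, :]]


def _apply_substitutions(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place substitution errors: each hit base becomes a different base."""
    if rate <= 0:
        return
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return
    # base index 0..3 shifted by 1..3 mod 4 never reproduces the original
    idx = np.searchsorted(_BASES, reads[mask])
    reads[mask] = _BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]


def _duplication_extras(model: str, param: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if model == "poisson" and param > 0:
        return rng.poisson(param, size=n)
    if model == "geometric":
        return rng.geometric(param, size=n) - 1
    return np.zeros(n, dtype=np.int64)


def simulate_reads(
    reference: str,
    spec: SimSpec,
    out_dir: Optional[str | Path] = None,
    prefix: str = "sim",
) -> SimResult:
    """Generate one dataset from ``reference`` under ``spec``.

    With ``out_dir`` set, FASTQ files (and a ground-truth JSON sidecar) are
    written there and the paths returned; otherwise records stay in memory on
    the result.  Identical (reference, spec) inputs give byte-identical
    output.
    """
    G = len(reference)
    L = spec.read_length
    if L > G:
        raise ValueError(f"read_length {L} exceeds reference length {G}")
    rng = np.random.default_rng(spec.seed)
    ref = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    qual = spec.quality_char * L

    if spec.paired:
        n_templates = max(1, round(spec.coverage * G / (2 * L)))
        frag = np.rint(
            rng.normal(spec.insert_size_mean, spec.insert_size_sd, size=n_templates)
        ).astype(np.int64)
        frag = np.clip(frag, L, G)
        starts = (rng.random(n_templates) * (G - frag + 1)).astype(np.int64)
        m1 = _extract_reads(ref, starts, L)
        # mate2 reads the far end of the fragment on the opposite strand
        m2 = _COMPLEMENT[_extract_reads(ref, starts + frag - L, L)][:, ::-1]
        _apply_substitutions(m1, spec.substitution_rate, rng)
        _apply_substitutions(m2, spec.substitution_rate, rng)
        seqs1 = [row.tobytes().decode("ascii") for row in m1]
        seqs2 = [row.tobytes().decode("ascii") for row in m2]
    else:
        n_templates = max(1, round(spec.coverage * G / L))
        starts = rng.integers(0, G - L + 1, size=n_templates)
        m1 = _extract_reads(ref, starts, L)
        _apply_substitutions(m1, spec.substitution_rate, rng)
        seqs1 = [row.tobytes().decode("ascii") for row in m1]

    extras = _duplication_extras(
        spec.duplication_model, spec.duplication_param, n_templates, rng
    )
    template_of = np.repeat(np.arange(n_templates), 1 + extras)
    order = rng.permutation(template_of.size)
    template_of = template_of[order]

    if spec.paired:
        pairs = [
            ReadPair(
                ReadRecord(f"{prefix}.{k}/1", seqs1[t], "", qual),
                ReadRecord(f"{prefix}.{k}/2", seqs2[t], "", qual),
            )
            for k, t in enumerate(template_of)
        ]
        total_reads = 2 * len(pairs)
        truth = count_records(pairs)
        result = SimResult(spec, [], total_reads, truth, pairs=pairs)
    else:
        records = [
            ReadRecord(f"{prefix}.{k}", seqs1[t], "", qual)
            for k, t in enumerate(template_of)
        ]
        total_reads = len(records)
        truth = count_records(records)
        result = SimResult(spec, [], total_reads, truth, records=records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if spec.paired:
            p1 = out_dir / f"{prefix}_1.fastq"
            p2 = out_dir / f"{prefix}_2.fastq"
            write_fastq((p.mate1 for p in result.pairs), p1)
            write_fastq((p.mate2 for p in result.pairs), p2)
            result.paths = [str(p1), str(p2)]
        else:
            p1 = out_dir / f"{prefix}.fastq"
            write_fastq(result.records, p1)
            result.paths = [str(p1)]
        (out_dir / f"{prefix}.truth.json").write_text(truth.to_json(indent=2) + "\n")
    return result


def coverage_series(
    reference: str,
    base_spec: SimSpec,
    coverages: Sequence[float] = (100, 200, 300),
    out_dir: Optional[str | Path] = None,
    prefix: str = "sim",
) -> list[SimResult]:
    """One dataset per coverage, seeds derived as ``base_spec.seed + index``.

    Three references crossed with coverages (100, 200, 300) reproduce the
    nine-dataset coverage-series validation design at whatever scale the
    reference length dictates.
    """
    results = []
    for i, cov in enumerate(coverages):
        spec = replace(base_spec, coverage=cov, seed=base_spec.seed + i)
        results.append(
            simulate_reads(reference, spec, out_dir=out_dir, prefix=f"{prefix}_cov{cov:g}")
        )
    return results
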