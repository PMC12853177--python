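"""FASTQ input/output, per-read quality metrics, and length/quality filtering.

Nanopore sequencers emit reads continuously during a run, so everything here
is streaming-safe: :func:`read_fastq` is lazy and :func:`qc_summary` makes a
single pass (keeping only the read-length multiset in memory, which is needed
for the median and N50).

Quality semantics follow the long-read QC convention (Filtlong, NanoPlot):
per-base PHRED scores are converted to error probabilities, averaged, and
converted back, so a read's "mean quality" is dominated by its worst bases
rather than inflated by its best ones.
"""

from __future__ import annotations

import gzip
import json
import math
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "FilterPolicy",
    "ReadQCSummary",
    "FilterReport",
    "FastqParseError",
    "WGS_PRESET",
    "AMPLICON_16S_PRESET",
    "read_fastq",
    "write_fastq",
    "mean_read_quality",
    "filter_reads",
    "qc_summary",
]

PHRED_MAX = 93  # highest score encodable in Sanger FASTQ ('~' = 33 + 93)


class FastqParseError(ValueError):
    """Raised for malformed FASTQ input; the message names the record index."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base PHRED qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        for q in self.qualities:
            if not 0 <= q <= PHRED_MAX:
                raise FastqParseError(
                    f"read {self.read_id!r}: PHRED value {q} outside [0, {PHRED_MAX}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterPolicy:
    """Length/quality thresholds applied to each read.

    Boundaries are kept: a read exactly at ``min_length``/``max_length`` or
    with mean quality exactly ``min_mean_quality`` passes ("shorter than" /
    "below" read as strict removal).
    """

    min_length: int = 0
    max_length: int | None = None  # None = unbounded
    min_mean_quality: float = 0.0

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


#: Whole-genome shotgun default: discard reads shorter than 2 kb or below Q10.
WGS_PRESET = FilterPolicy(min_length=2000, max_length=None, min_mean_quality=10.0)
#: Full-length 16S rRNA amplicon default: keep 1-2 kb reads at Q10 or better.
AMPLICON_16S_PRESET = FilterPolicy(min_length=1000, max_length=2000, min_mean_quality=10.0)


@dataclass(frozen=True)
class ReadQCSummary:
    """Batch-level quality statistics.

    ``mean_quality`` is the PHRED transform of the mean per-base error
    probability across all bases in the batch; ``quality_quartiles`` are the
    quartiles of the per-read mean qualities.  Means/medians are ``None`` for
    an empty batch.
    """

    n_reads: int
    total_bases: int
    mean_length: float | None
    median_length: float | None
    n50: int | None
    mean_quality: float | None
    quality_quartiles: tuple[float, float, float] | None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class FilterReport:
    """Per-category removal counts; categories partition the input."""

    n_input: int = 0
    n_kept: int = 0
    n_removed_short: int = 0
    n_removed_long: int = 0
    n_removed_quality: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily parse a FASTQ or FASTQ.GZ file (Sanger Phred+33).

    Gzip compression is auto-detected from the magic bytes.  Only the strict
    4-line dialect is accepted; a truncated record or a sequence/quality
    length mismatch raises :class:`FastqParseError` naming the record index.
    """
    handle = _open_maybe_gzip(path)
    index = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"{path}: record {index}: {exc}") from exc
            read_id = title.split()[0] if title else f"record_{index}"
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {index} ({read_id}): sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            qualities = []
            for ch in qual:
                code = ord(ch)
                if not 33 <= code <= 126:
                    raise FastqParseError(
                        f"{path}: record {index} ({read_id}): quality byte "
                        f"{code} outside printable Phred+33 range [33, 126]"
                    )
                qualities.append(code - 33)
            yield ReadRecord(read_id, seq.upper(), tuple(qualities))
            index += 1
    finally:
        handle.close()


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line Phred+33 FASTQ (gzipped if path ends in .gz).

    Returns the number of records written.  Round-trips with
    :func:`read_fastq` on (id, sequence, qualities).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt", encoding="ascii") as out:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def mean_read_quality(record: ReadRecord) -> float:
    """Error-probability-averaged PHRED score of one read.

    Returns ``-10*log10(mean_i 10^(-q_i/10))``; for a read with uniform
    per-base quality this equals that quality.
    """
    if len(record) == 0:
        raise ValueError(f"read {record.read_id!r} is empty")
    q = np.asarray(record.qualities, dtype=float)
    return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))


def _mean_error_probability(record: ReadRecord) -> float:
    q = np.asarray(record.qualities, dtype=float)
    return float(np.mean(10.0 ** (-q / 10.0)))


def filter_reads(
    reads: Iterable[ReadRecord], policy: FilterPolicy
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply the length/quality policy; each removed read is counted once.

    Rules are checked in the order short -> long -> quality, so a read that is
    both too short and low-quality counts as "short".
    """
    kept: list[ReadRecord] = []
    report = FilterReport()
    for rec in reads:
        report.n_input += 1
        length = len(rec)
        if length < policy.min_length:
            report.n_removed_short += 1
        elif policy.max_length is not None and length > policy.max_length:
            report.n_removed_long += 1
        elif length > 0 and mean_read_quality(rec) + 1e-9 < policy.min_mean_quality:
            # +1e-9 absorbs float error so a uniformly-Q10 read passes a Q10 bound
            report.n_removed_quality += 1
        else:
            kept.append(rec)
            report.n_kept += 1
    return kept, report


def qc_summary(reads: Iterable[ReadRecord]) -> ReadQCSummary:
    """Single-pass batch statistics: read counts, lengths, N50, qualities."""
    lengths: list[int] = []
    per_read_quality: list[float] = []
    error_sum = 0.0  # sum over bases of per-base error probability
    total_bases = 0
    for rec in reads:
        length = len(rec)
        lengths.append(length)
        total_bases += length
        if length:
            p = _mean_error_probability(rec)
            error_sum += p * length
            per_read_quality.append(-10.0 * math.log10(p))
    n = len(lengths)
    if n == 0:
        return ReadQCSummary(0, 0, None, None, None, None, None)
    mean_quality = (
        -10.0 * math.log10(error_sum / total_bases) if total_bases else None
    )
    quartiles = None
    if per_read_quality:
        q1, q2, q3 = np.percentile(per_read_quality, [25, 50, 75])
        quartiles = (float(q1), float(q2), float(q3))
    return ReadQCSummary(
        n_reads=n,
        total_bases=total_bases,
        mean_length=total_bases / n,
        median_length=float(statistics.median(lengths)),
        n50=_n50(lengths),
        mean_quality=mean_quality,
        quality_quartiles=quartiles,
    )


def _n50(lengths: Sequence[int]) -> int:
    """Length-weighted median: smallest L with cumulative bases of reads
    >= L covering at least half of the total."""
    total = sum(lengths)
    if total == 0:
        return 0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return 0  # unreachable
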