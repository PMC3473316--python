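"""FASTQ read cleaning for short pooled-transcriptome reads.

Cleaning rules, applied in order:

1. discard reads with more than ``max_missing`` missing calls ('N'), or whose
   mean quality over the first ``head_len`` bases is below ``head_min_mean_q``
   (the whole read if shorter);
2. trim the 3' end while the mean quality of the trailing window (up to
   ``tail_window`` bases) is below ``tail_min_mean_q``;
3. discard reads shorter than ``min_len`` after trimming.

The attrition report accounts every input read exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DISCARD_MISSING = "missing"
DISCARD_HEAD_QUALITY = "head_quality"
DISCARD_SHORT = "short"


@dataclass(frozen=True)
class CleanParams:
    max_missing: int = 2
    head_len: int = 10
    head_min_mean_q: float = 15.0
    tail_min_mean_q: float = 20.0
    tail_window: int = 10
    min_len: int = 30

    def __post_init__(self) -> None:
        if min(self.max_missing, self.head_len, self.min_len) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.tail_window < 1:
            raise ValueError("tail_window must be at least 1")


@dataclass
class Read:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QcReport:
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    discarded_missing: int = 0
    discarded_head_quality: int = 0
    discarded_short: int = 0

    @property
    def mean_len_out(self) -> float:
        return self.bases_out / self.reads_out if self.reads_out else 0.0

    def check(self) -> None:
        total = (self.reads_out + self.discarded_missing
                 + self.discarded_head_quality + self.discarded_short)
        if total != self.reads_in:
            raise AssertionError("QC attrition accounting does not sum")


def assess_read(read: Read, params: CleanParams = CleanParams()) -> tuple[bool, str | None]:
    """Keep/discard decision with reason (missing, head_quality, short)."""
    if len(read) == 0:
        return False, DISCARD_SHORT
    if read.bases.count("N") > params.max_missing:
        return False, DISCARD_MISSING
    head = read.quals[:params.head_len]
    if sum(head) / len(head) < params.head_min_mean_q:
        return False, DISCARD_HEAD_QUALITY
    return True, None


def trim_three_prime(read: Read, params: CleanParams = CleanParams()) -> Read:
    """Trim the 3' end while the trailing-window mean quality is too low.

    The last base is removed repeatedly while the mean quality of the trailing
    ``min(tail_window, length)`` bases falls below the threshold; the cut
    point is then refined by dropping any remaining trailing bases that are
    individually below the threshold, so the kept read never ends in a
    low-quality run.  The result may be empty.
    """
    quals = read.quals
    n = len(quals)
    w = params.tail_window
    while True:  # window trim + cut-point refinement, to a fixpoint
        n0 = n
        while n > 0:
            k = min(w, n)
            if sum(quals[n - k:n]) / k >= params.tail_min_mean_q:
                break
            n -= 1
        while n > 0 and quals[n - 1] < params.tail_min_mean_q:
            n -= 1
        if n == n0:
            break
    if n == len(quals):
        return read
    return Read(read.id, read.bases[:n], quals[:n])


def clean_reads(reads: Iterable[Read],
                params: CleanParams = CleanParams()) -> tuple[list[Read], QcReport]:
    """Apply the full cascade to an in-memory read iterable."""
    report = QcReport()
    kept: list[Read] = []
    for read in reads:
        report.reads_in += 1
        report.bases_in += len(read)
        keep, reason = assess_read(read, params)
        if not keep:
            if reason == DISCARD_MISSING:
                report.discarded_missing += 1
            elif reason == DISCARD_HEAD_QUALITY:
                report.discarded_head_quality += 1
            else:
                report.discarded_short += 1
            continue
        trimmed = trim_three_prime(read, params)
        if len(trimmed) < params.min_len:
            report.discarded_short += 1
            continue
        report.reads_out += 1
        report.bases_out += len(trimmed)
        kept.append(trimmed)
    report.check()
    return kept, report


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream a Sanger Phred+33 FASTQ file as :class:`Read` records."""
    with open(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {i}: length mismatch")
            yield Read(title.split()[0], seq, [ord(c) - 33 for c in qual])


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(33 + v) for v in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


def clean_fastq(in_path: str | Path, out_path: str | Path,
                params: CleanParams = CleanParams(),
                report_path: str | Path | None = None) -> QcReport:
    """Clean a FASTQ file to ``out_path`` and return the attrition report."""
    kept, report = clean_reads(read_fastq(in_path), params)
    write_fastq(kept, out_path)
    if report_path is not None:
        write_report(report, report_path)
    return report


def write_report(report: QcReport, path: str | Path) -> None:
    rows = [
        ("reads_in", report.reads_in),
        ("reads_out", report.reads_out),
        ("bases_in", report.bases_in),
        ("bases_out", report.bases_out),
        ("mean_len_out", round(report.mean_len_out, 2)),
        ("discarded_missing", report.discarded_missing),
        ("discarded_head_quality", report.discarded_head_quality),
        ("discarded_short", report.discarded_short),
    ]
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
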