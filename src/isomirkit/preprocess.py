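"""Adapter trimming and length filtering of raw small-RNA reads.

A 3' sequencing adapter is removed by finding the longest read suffix that
matches a prefix of the adapter, allowing substitutions only (no indels) at
a configurable error fraction with a minimum overlap of 3 nt; everything
from the match on is discarded.  Inserts shorter than 16 nt or longer than
30 nt are then removed (bounds inclusive: only strictly shorter/longer
reads are dropped).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

MIN_INSERT_LEN = 16
MAX_INSERT_LEN = 30
DEFAULT_MAX_ERROR_RATE = 0.1
MIN_OVERLAP = 3

FAIL_REASONS = ("too_short", "too_long", "no_insert")


def _mismatches_within(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings, or None once above limit."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def trim_adapter(
    seq: str,
    adapter: str,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    min_overlap: int = MIN_OVERLAP,
) -> str:
    """Remove a 3' adapter occurrence from ``seq``.

    Scans adapter start positions left to right (longest match wins) and
    accepts the first position whose overlap with the adapter prefix has at
    most ``floor(max_error_rate * overlap)`` substitutions.  Returns the
    insert (possibly empty); the read is returned unchanged when no match
    is found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not seq:
        return ""
    L = len(seq)
    for p in range(0, L - min_overlap + 1):
        ov = min(L - p, len(adapter))
        allowed = int(max_error_rate * ov)
        if _mismatches_within(seq[p : p + ov], adapter[:ov], allowed) is not None:
            return seq[:p]
    return seq


def classify_length(insert: str) -> str | None:
    """Return the fail reason for a trimmed insert, or None if it passes."""
    if not insert:
        return "no_insert"
    if len(insert) < MIN_INSERT_LEN:
        return "too_short"
    if len(insert) > MAX_INSERT_LEN:
        return "too_long"
    return None


@dataclass
class ReadBatch:
    """Trimmed reads with pass/fail bookkeeping."""

    read_ids: list[str] = field(default_factory=list)
    seqs: list[str] = field(default_factory=list)
    fail_reasons: dict[str, str] = field(default_factory=dict)  # read_id -> reason

    def passing(self) -> Iterable[tuple[str, str]]:
        for rid, seq in zip(self.read_ids, self.seqs):
            if rid not in self.fail_reasons:
                yield rid, seq

    def summary(self) -> dict[str, int]:
        counts = {r: 0 for r in FAIL_REASONS}
        for reason in self.fail_reasons.values():
            counts[reason] += 1
        total = len(self.read_ids)
        return {
            "input": total,
            "trimmed": total - sum(counts.values()),
            **counts,
        }


def length_filter(batch: ReadBatch) -> ReadBatch:
    """Flag trimmed reads outside the [16, 30] nt insert window."""
    for rid, seq in zip(batch.read_ids, batch.seqs):
        if rid in batch.fail_reasons:
            continue
        reason = classify_length(seq)
        if reason is not None:
            batch.fail_reasons[rid] = reason
    return batch


def process_reads(
    reads: Iterable[tuple[str, str]],
    adapter: str,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> ReadBatch:
    """Trim and length-filter (read_id, seq) pairs.

    Identical raw sequences are trimmed once and the result reused, which
    keeps deep simulated libraries cheap without changing any result.
    """
    batch = ReadBatch()
    cache: dict[str, str] = {}
    for rid, seq in reads:
        seq = seq.upper().replace("U", "T")
        insert = cache.get(seq)
        if insert is None:
            insert = trim_adapter(seq, adapter, max_error_rate)
            cache[seq] = insert
        batch.read_ids.append(rid)
        batch.seqs.append(insert)
    return length_filter(batch)


def process_fastq(
    fastq_path: str | Path,
    out_path: str | Path,
    adapter: str,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    summary_path: str | Path | None = None,
) -> dict[str, int]:
    """Trim and filter a FASTQ file, writing passing inserts and a JSON summary."""
    with pysam.FastxFile(str(fastq_path)) as fh:
        batch = process_reads(((rec.name, rec.sequence) for rec in fh), adapter,
                              max_error_rate)
    out_path = Path(out_path)
    opener = gzip.open if out_path.suffix == ".gz" else open
    with opener(out_path, "wt") as out:
        for rid, seq in batch.passing():
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    summary = batch.summary()
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary
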