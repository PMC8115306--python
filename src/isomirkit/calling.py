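"""Arm alignment and isomiR labelling.

Preprocessed inserts are slid over every annotated arm plus a window of
hairpin flank.  A placement is accepted with at most one substitution and
no indels; the maximal run of trailing mismatches (up to 2 nt, including
any overhang past the hairpin end) is peeled off as a non-templated 3'
addition (NTA).  A trailing base that matches the template is therefore
always absorbed as templated extension — an NTA must mismatch the template.
Reads whose best score is reached by more than one distinct (miRNA, start)
placement are ambiguous and excluded from labelling.

Scoring prefers, in order: fewest remaining mismatches, then fewest
non-templated bases.  This resolves the terminal ambiguity between "one
mismatch at the last base" and "one non-templated base" in favour of the
NTA reading, which is what makes label recovery exact on error-free data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .labels import IsomirLabel
from .reference import ArmReference, normalize_seq

_VALID_SEQ = re.compile(r"^[ACGTUN]+$")

DEFAULT_WINDOW = 6
MAX_MISMATCH = 1
MAX_NTA = 2


@dataclass(frozen=True)
class ArmAlignment:
    """A read placed on a hairpin; coordinates 0-based half-open."""

    read_id: str
    mirna_name: str
    align_start: int
    align_end: int
    n_mismatch: int
    nta: str
    ambiguous: bool = False


class ArmAligner:
    """Exhaustive no-indel aligner over all arms of a reference."""

    def __init__(
        self,
        ref: ArmReference,
        window: int = DEFAULT_WINDOW,
        max_mismatch: int = MAX_MISMATCH,
        max_nta: int = MAX_NTA,
    ):
        self.ref = ref
        self.window = window
        self.max_mismatch = max_mismatch
        self.max_nta = max_nta
        self._arms = [(a.mirna_name, a.hairpin_seq, a.arm_start) for a in ref]
        self._cache: dict[str, tuple | None] = {}

    # ------------------------------------------------------------- scoring

    def _placements(self, seq: str):
        """Yield (mm, nta_len, name, start, end) for all admissible placements."""
        L = len(seq)
        limit = self.max_mismatch + self.max_nta
        for name, hp, arm_start in self._arms:
            hp_len = len(hp)
            lo = max(0, arm_start - self.window)
            hi = min(arm_start + self.window, hp_len - 1)
            for start in range(lo, hi + 1):
                over = start + L - hp_len
                if over > self.max_nta:
                    continue
                o = max(0, over)
                aligned = L - o
                if aligned < 8:
                    continue
                t = hp[start : start + aligned]
                s = seq[:aligned]
                if s == t:
                    mism: list[int] | None = []
                else:
                    mism = []
                    for i in range(aligned):
                        if s[i] != t[i]:
                            mism.append(i)
                            if len(mism) > limit:
                                mism = None
                                break
                if mism is None:
                    continue
                # maximal trailing mismatch run within the aligned part
                run = 0
                while run < len(mism) and mism[-1 - run] == aligned - 1 - run:
                    run += 1
                k = min(run, self.max_nta - o)
                mm = len(mism) - k
                if mm > self.max_mismatch:
                    continue
                nta_len = o + k
                yield mm, nta_len, name, start, start + aligned - k

    def align(self, seq: str, read_id: str = "") -> ArmAlignment | None:
        """Align one insert; returns None when no admissible placement exists."""
        seq = normalize_seq(seq)
        if not _VALID_SEQ.match(seq):
            raise ValueError(f"invalid characters in read sequence {seq!r}")
        hit = self._cache.get(seq)
        if hit is None and seq not in self._cache:
            hit = self._align_uncached(seq)
            self._cache[seq] = hit
        if hit is None:
            return None
        name, start, end, mm, nta_len, ambiguous = hit
        return ArmAlignment(
            read_id=read_id,
            mirna_name=name,
            align_start=start,
            align_end=end,
            n_mismatch=mm,
            nta=seq[len(seq) - nta_len :] if nta_len else "",
            ambiguous=ambiguous,
        )

    def _align_uncached(self, seq: str) -> tuple | None:
        best_key: tuple[int, int] | None = None
        hits: list[tuple] = []
        for mm, nta_len, name, start, end in self._placements(seq):
            key = (mm, nta_len)
            if best_key is None or key < best_key:
                best_key = key
                hits = [(name, start, end)]
            elif key == best_key:
                hits.append((name, start, end))
        if best_key is None:
            return None
        placements = {(name, start) for name, start, _ in hits}
        if len(placements) > 1:
            name, start, end = hits[0]
            return (name, start, end, best_key[0], best_key[1], True)
        name, start, end = hits[0]
        return (name, start, end, best_key[0], best_key[1], False)


def label_alignment(aln: ArmAlignment, ref: ArmReference) -> IsomirLabel:
    """Translate an unambiguous placement into its |d5|d3(+NTA) label."""
    if aln.ambiguous:
        raise ValueError(f"read {aln.read_id}: ambiguous alignments carry no label")
    arm = ref[aln.mirna_name]
    return IsomirLabel(
        mirna_name=aln.mirna_name,
        d5=aln.align_start - arm.arm_start,
        d3=aln.align_end - arm.arm_end,
        nta=aln.nta,
    )


# ----------------------------------------------------------------- calling


def call_reads(
    reads: Iterable[tuple[str, str]],
    aligner: ArmAligner,
    ref: ArmReference,
) -> pd.DataFrame:
    """Label an iterable of (read_id, insert).

    Returns one row per read with columns read_id, label, mirna_name,
    n_mismatch, nta and status in {labelled, ambiguous, unaligned}.
    """
    rows = []
    for rid, seq in reads:
        aln = aligner.align(seq, rid)
        if aln is None:
            rows.append((rid, "", "", 0, "", "unaligned"))
        elif aln.ambiguous:
            rows.append((rid, "", "", aln.n_mismatch, "", "ambiguous"))
        else:
            label = label_alignment(aln, ref)
            rows.append((rid, label.render(), aln.mirna_name, aln.n_mismatch,
                         aln.nta, "labelled"))
    return pd.DataFrame(
        rows, columns=["read_id", "label", "mirna_name", "n_mismatch", "nta", "status"]
    )


def call_fastq(fastq_path: str | Path, aligner: ArmAligner, ref: ArmReference) -> pd.DataFrame:
    with pysam.FastxFile(str(fastq_path)) as fh:
        return call_reads(((rec.name, rec.sequence) for rec in fh), aligner, ref)


def count_labels(calls: pd.DataFrame, strict: bool = False) -> pd.Series:
    """Per-label read counts for one sample; strict keeps 0-mismatch reads only."""
    ok = calls[calls.status == "labelled"]
    if strict:
        ok = ok[ok.n_mismatch == 0]
    return ok.label.value_counts().sort_index()


def build_count_matrix(per_sample_counts: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Label x sample integer count matrix from per-sample count Series."""
    mat = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    mat = mat.loc[sorted(mat.index), list(per_sample_counts)]
    mat.index.name = "label"
    return mat


def classify_orphans(counts: pd.DataFrame) -> set[str]:
    """Labels whose miRNA has no canonical (|0|0) read anywhere in the dataset.

    Detection of the canonical form in any single sample suffices to clear
    a miRNA; orphan labels are excluded from ratio and panel computations.
    """
    totals = counts.sum(axis=1)
    canonical_seen: set[str] = set()
    by_mirna: dict[str, list[str]] = {}
    for lab, total in totals.items():
        parsed = IsomirLabel.parse(lab)
        by_mirna.setdefault(parsed.mirna_name, []).append(lab)
        if parsed.is_canonical and total > 0:
            canonical_seen.add(parsed.mirna_name)
    orphans: set[str] = set()
    for mirna, labs in by_mirna.items():
        if mirna not in canonical_seen:
            orphans.update(l for l in labs if totals[l] > 0)
    return orphans
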