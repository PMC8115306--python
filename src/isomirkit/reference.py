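"""miRNA hairpin/arm reference: the coordinate frame for all isomiR calls.

Each hairpin carries one annotated mature arm.  Arm coordinates are 0-based
half-open on the hairpin; the canonical mature sequence is the hairpin slice
``hairpin_seq[arm_start:arm_end]`` in mature 5'->3' orientation.  Sequences
are stored as uppercase DNA (U -> T) so that read matching is alphabet-free.

On disk the reference is a hairpin FASTA plus a GFF3 arm annotation
(1-based inclusive coordinates, per the format).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MIN_MATURE_LEN = 16
MAX_MATURE_LEN = 30


def normalize_seq(seq: str) -> str:
    """Uppercase and U->T normalize a nucleotide string."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MirnaArm:
    """A mature miRNA arm located on its hairpin precursor."""

    mirna_name: str
    hairpin_id: str
    hairpin_seq: str
    arm_start: int
    arm_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "hairpin_seq", normalize_seq(self.hairpin_seq))
        if not (0 <= self.arm_start < self.arm_end <= len(self.hairpin_seq)):
            raise ValueError(
                f"{self.mirna_name}: arm interval [{self.arm_start}, {self.arm_end}) "
                f"outside hairpin of length {len(self.hairpin_seq)}"
            )
        n = self.arm_end - self.arm_start
        if not (MIN_MATURE_LEN <= n <= MAX_MATURE_LEN):
            raise ValueError(
                f"{self.mirna_name}: canonical length {n} outside "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )

    @property
    def canonical_seq(self) -> str:
        return self.hairpin_seq[self.arm_start : self.arm_end]

    @property
    def canonical_length(self) -> int:
        return self.arm_end - self.arm_start


class ArmReference:
    """An ordered collection of :class:`MirnaArm`, indexable by miRNA name."""

    def __init__(self, arms: list[MirnaArm]):
        names = [a.mirna_name for a in arms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate miRNA names in reference")
        self.arms = list(arms)
        self._by_name = {a.mirna_name: a for a in arms}

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self) -> Iterator[MirnaArm]:
        return iter(self.arms)

    def __getitem__(self, name: str) -> MirnaArm:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.mirna_name for a in self.arms]

    # ---------------------------------------------------------------- I/O

    def write(self, fasta_path: str | Path, gff3_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(a.hairpin_seq), id=a.hairpin_id, description="")
            for a in self.arms
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        lines = ["##gff-version 3"]
        for a in self.arms:
            attrs = f"ID={a.mirna_name};Derives_from={a.hairpin_id}"
            lines.append(
                "\t".join(
                    [
                        a.hairpin_id,
                        "isomirkit",
                        "miRNA",
                        str(a.arm_start + 1),  # GFF3 is 1-based inclusive
                        str(a.arm_end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
            )
        Path(gff3_path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, fasta_path: str | Path, gff3_path: str | Path) -> "ArmReference":
        hairpins = {
            rec.id: normalize_seq(str(rec.seq))
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        cols = [
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ]
        gff = pd.read_csv(
            gff3_path, sep="\t", comment="#", header=None, names=cols,
            dtype={"start": int, "end": int},
        )
        arms = []
        for row in gff.itertuples():
            if row.type != "miRNA":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            name = attrs.get("ID")
            if name is None:
                raise ValueError(f"GFF3 miRNA feature without ID: {row.attributes!r}")
            if row.seqid not in hairpins:
                raise ValueError(f"{name}: hairpin {row.seqid} missing from FASTA")
            arms.append(
                MirnaArm(
                    mirna_name=name,
                    hairpin_id=row.seqid,
                    hairpin_seq=hairpins[row.seqid],
                    arm_start=int(row.start) - 1,
                    arm_end=int(row.end),
                )
            )
        return cls(arms)
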