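"""IsomiR offset nomenclature.

A mature miRNA variant is annotated relative to its canonical (miRBase) form as

    ``name|d5|d3``            e.g. ``hsa-miR-125a-5p|0|-2``
    ``name|d5|d3|+<bases>``   when a non-templated 3' addition is present

``d5`` and ``d3`` are signed shifts of the 5' and 3' termini on the mature
5'->3' frame: a negative sign moves the terminus in the 5' direction, a
positive sign in the 3' direction.  ``d3 = -2`` is therefore a 2-nt 3' trim
and ``d3 = +1`` a 1-nt templated 3' extension.  Zero means the canonical
terminus.  The variant length obeys

    len(variant) = len(canonical) - d5 + d3 + len(nta)
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Unicode minus occasionally appears in rendered tables; accept it on parse.
_MINUS = "−"

_LABEL_RE = re.compile(
    r"^(?P<name>.+)\|(?P<d5>[+\-−]?\d+)\|(?P<d3>[+\-−]?\d+)"
    r"(?:\|\+(?P<nta>[ACGTUacgtu]+))?$"
)


def _fmt_offset(d: int) -> str:
    return "0" if d == 0 else f"{d:+d}"


@dataclass(frozen=True, order=True)
class IsomirLabel:
    """The |d5|d3(+NTA) annotation of a mature miRNA variant."""

    mirna_name: str
    d5: int
    d3: int
    nta: str = ""

    def __post_init__(self) -> None:
        if self.nta and not re.fullmatch(r"[ACGTU]+", self.nta.upper()):
            raise ValueError(f"non-nucleotide NTA {self.nta!r}")
        object.__setattr__(self, "nta", self.nta.upper())

    @property
    def is_canonical(self) -> bool:
        return self.d5 == 0 and self.d3 == 0 and not self.nta

    def render(self) -> str:
        base = f"{self.mirna_name}|{_fmt_offset(self.d5)}|{_fmt_offset(self.d3)}"
        return f"{base}|+{self.nta}" if self.nta else base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "IsomirLabel":
        m = _LABEL_RE.match(text.strip())
        if m is None:
            raise ValueError(f"unparseable isomiR label {text!r}")
        d5 = int(m.group("d5").replace(_MINUS, "-"))
        d3 = int(m.group("d3").replace(_MINUS, "-"))
        return cls(m.group("name"), d5, d3, m.group("nta") or "")

    def variant_length(self, canonical_length: int) -> int:
        """Length of the variant given the canonical mature length."""
        n = canonical_length - self.d5 + self.d3 + len(self.nta)
        if n <= 0:
            raise ValueError(
                f"label {self.render()} yields non-positive length from "
                f"canonical length {canonical_length}"
            )
        return n

    def canonical_label(self) -> "IsomirLabel":
        return IsomirLabel(self.mirna_name, 0, 0)

    def apply_to(self, canonical_seq: str) -> str:
        """Derive the variant sequence from the canonical sequence alone.

        Only trims (d5 >= 0, d3 <= 0) and non-templated additions are
        realizable without the hairpin template; templated extensions
        (d5 < 0 or d3 > 0) raise ``ValueError``.
        """
        seq = canonical_seq.upper()
        if self.d5 < 0 or self.d3 > 0:
            raise ValueError(
                f"label {self.render()} requires hairpin template sequence; "
                "not derivable from the canonical sequence alone"
            )
        if self.d5 >= len(seq) or -self.d3 >= len(seq):
            raise ValueError(f"label {self.render()} trims away the whole sequence")
        end = len(seq) + self.d3
        out = seq[self.d5 : end] + self.nta
        if not out:
            raise ValueError(f"label {self.render()} yields an empty sequence")
        return out
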