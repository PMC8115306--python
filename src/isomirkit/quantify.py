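"""RPM normalization, isomiR/canonical ratios, panel and heterogeneity summary.

Abundances are expressed in reads per million (RPM): the denominator of a
sample is the total of qualifying arm-aligned reads of that same sample, so
RPM columns conserve to 1e6 exactly.  Orphan isomiRs (their canonical form
undetected in the whole dataset) are excluded before normalization and from
all ratio computations.  Ratio-table values are rendered truncated to two
decimals (17.0873 -> 17.08); full precision is retained internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import classify_orphans
from .labels import IsomirLabel

RPM_SCALE = 1_000_000.0


def truncate2(x: float) -> float:
    """Truncate (not round) towards zero to two decimals, as in report tables."""
    return math.trunc(x * 100.0) / 100.0


@dataclass
class IsomirProfile:
    """Counts and RPM keyed by isomiR label, with group metadata."""

    counts: pd.DataFrame                 # label x sample, non-orphan labels
    rpm: pd.DataFrame                    # label x sample, columns sum to 1e6
    groups: pd.Series                    # sample -> group
    orphan_flags: set[str] = field(default_factory=set)
    orphan_counts: pd.DataFrame | None = None


def rpm_normalize(
    counts: pd.DataFrame, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Scale counts to reads-per-million per sample.

    ``totals`` overrides the per-sample denominator (e.g. the strict
    0-mismatch aligned-read totals); by default the denominator is the
    column sum of ``counts`` itself, so numerator and denominator use the
    same read set and columns conserve to 1e6.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if totals is None:
        totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {', '.join(map(str, zero.index))}")
    return counts * (RPM_SCALE / totals)


def build_profile(
    counts: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    strict_totals: pd.Series | None = None,
) -> IsomirProfile:
    """Classify orphans, drop them, and RPM-normalize the rest."""
    groups = pd.Series(groups)
    orphans = classify_orphans(counts)
    kept = counts.drop(index=[l for l in orphans if l in counts.index])
    kept = kept[kept.sum(axis=1) > 0]
    rpm = rpm_normalize(kept, totals=strict_totals)
    return IsomirProfile(
        counts=kept,
        rpm=rpm,
        groups=groups.loc[kept.columns],
        orphan_flags=orphans,
        orphan_counts=counts.loc[sorted(orphans)] if orphans else None,
    )


# ------------------------------------------------------------------ ratios


@dataclass(frozen=True)
class RatioRecord:
    """One isomiR with its canonical comparison, means in RPM over all samples."""

    label: str
    mean_isomir: float
    mean_canonical: float

    @property
    def ratio(self) -> float:
        return self.mean_isomir / self.mean_canonical

    @property
    def ratio_rendered(self) -> float:
        return truncate2(self.ratio)


def mean_and_ratio(profile: IsomirProfile) -> pd.DataFrame:
    """Per-isomiR unweighted RPM mean across all samples and ratio to canonical.

    Orphans are excluded upstream; a non-canonical label whose canonical
    mean is zero would be an orphan and raises if encountered.
    """
    means = profile.rpm.mean(axis=1)
    canonical_mean: dict[str, float] = {}
    for lab, m in means.items():
        parsed = IsomirLabel.parse(lab)
        if parsed.is_canonical:
            canonical_mean[parsed.mirna_name] = float(m)
    rows = []
    for lab, m in means.items():
        parsed = IsomirLabel.parse(lab)
        if parsed.is_canonical:
            continue
        cm = canonical_mean.get(parsed.mirna_name, 0.0)
        if cm <= 0:
            raise ValueError(
                f"{lab}: canonical mean is zero — orphan labels must be "
                "excluded before ratio computation"
            )
        rows.append(
            {
                "label": lab,
                "mirna_name": parsed.mirna_name,
                "mean_isomir": float(m),
                "mean_canonical": cm,
                "ratio": float(m) / cm,
            }
        )
    df = pd.DataFrame(rows, columns=["label", "mirna_name", "mean_isomir",
                                     "mean_canonical", "ratio"])
    if len(df):
        for col in ("mean_isomir", "mean_canonical", "ratio"):
            df[f"{col}_rendered"] = df[col].map(truncate2)
        df = df.sort_values("ratio", ascending=False).reset_index(drop=True)
    return df


def ratio_from_means(mean_isomir: float, mean_canonical: float) -> RatioRecord:
    """Build a :class:`RatioRecord` directly from mean RPM values."""
    if mean_canonical <= 0:
        raise ValueError("undefined ratio: canonical mean must be positive")
    return RatioRecord("", float(mean_isomir), float(mean_canonical))


def high_abundance_panel(records: pd.DataFrame, min_ratio: float = 3.0) -> pd.DataFrame:
    """IsomiRs at least ``min_ratio``-fold more abundant than their canonical
    form, sorted by descending ratio (no upper bound)."""
    panel = records[records.ratio >= min_ratio]
    return panel.sort_values("ratio", ascending=False).reset_index(drop=True)


# ------------------------------------------------------------ heterogeneity


def summarize_heterogeneity(profile: IsomirProfile) -> dict[str, int]:
    """Partition the detected label universe.

    A miRNA is "with isomiRs" when at least one detected non-canonical,
    non-orphan label exists for it; miRNAs whose only detected label is the
    canonical form are canonical-only.  Orphan labels are counted separately.
    """
    detected = profile.counts.sum(axis=1)
    with_isomirs: set[str] = set()
    seen_mirnas: set[str] = set()
    n_isomirs = 0
    for lab, total in detected.items():
        if total <= 0:
            continue
        parsed = IsomirLabel.parse(lab)
        seen_mirnas.add(parsed.mirna_name)
        if not parsed.is_canonical:
            with_isomirs.add(parsed.mirna_name)
            n_isomirs += 1
    return {
        "n_mirnas_with_isomirs": len(with_isomirs),
        "n_isomirs": n_isomirs,
        "n_canonical_only": len(seen_mirnas - with_isomirs),
        "n_orphans": len(profile.orphan_flags),
    }


# --------------------------------------------------------------------- I/O


def write_ratio_table(records: pd.DataFrame, path: str | Path) -> None:
    out = records[["label", "mean_isomir_rendered", "mean_canonical_rendered",
                   "ratio_rendered"]] if len(records) else records
    out = out.rename(
        columns={
            "mean_isomir_rendered": "isomir_expression_mean",
            "mean_canonical_rendered": "canonical_expression_mean",
            "ratio_rendered": "ratio_isomir_canonical",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_heterogeneity(summary: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")


def per_group_means(profile: IsomirProfile) -> pd.DataFrame:
    """Additional per-group RPM means (for isoform-vs-canonical comparisons)."""
    return profile.rpm.T.groupby(profile.groups).mean().T
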