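"""Synthetic small-RNA study generator.

Emulates the statistical structure of a 24-sample melanoma small RNA-seq
cohort (benign nevi / single melanomas / paired first and second primaries
from the same patients) with a known isomiR composition:

* per-miRNA isomiR offset distributions concentrated at the 3' end
  (d3 in -2..+4, d5 almost always 0),
* non-templated 3' additions with a U-rich base bias,
* orphan miRNAs that emit only non-canonical forms,
* 3' sequencing-adapter contamination (TruSeq small-RNA layout),
* uniform per-base substitution sequencing error.

Reads are emitted as DNA with the adapter appended at the 3' end and a
constant high-quality string; every emitted read is recorded in a truth
table holding its pre-error label, so every downstream stage can be checked
against ground truth.  All outputs are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import IsomirLabel
from .reference import ArmReference, MirnaArm

# Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
# Sequencer cycle count after which a read is truncated.
DEFAULT_READ_LEN = 50

GROUPS = ("nevus", "single", "MPM-1st", "MPM-2nd")

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """A simulation configuration that is not realizable against a reference."""


@dataclass
class SimulationConfig:
    """Everything that determines a simulated small-RNA study.

    ``offset_dist`` maps each miRNA name to a probability map over (d5, d3)
    offset pairs; it must sum to 1 per miRNA.  ``abundance`` holds relative
    per-miRNA expression weights and ``group_fold`` optional multiplicative
    group effects keyed by (miRNA, group), which create the differential
    expression the contrast stages are exercised on.
    """

    n_mirnas: int
    depth: int
    group_design: dict[str, str]           # sample -> group
    offset_dist: dict[str, dict[tuple[int, int], float]]
    nta_prob: float = 0.1
    nta_base_dist: dict[str, float] = field(default_factory=lambda: {"T": 0.7, "A": 0.3})
    orphan_mirnas: frozenset[str] = frozenset()
    adapter_seq: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    seed: int = 0
    read_len: int = DEFAULT_READ_LEN
    abundance: dict[str, float] = field(default_factory=dict)
    group_fold: dict[tuple[str, str], float] = field(default_factory=dict)
    pairing: dict[str, str] = field(default_factory=dict)   # sample -> patient

    def samples(self) -> list[str]:
        return list(self.group_design)


@dataclass
class SimulationResult:
    fastq_paths: dict[str, Path]
    truth: pd.DataFrame
    config: SimulationConfig

    def truth_label_counts(self) -> pd.Series:
        labels = self.truth.apply(
            lambda r: IsomirLabel(r.mirna_name, int(r.d5), int(r.d3), r.nta or "").render(),
            axis=1,
        )
        return labels.value_counts().sort_index()


# --------------------------------------------------------------- reference


def build_reference(
    n_mirnas: int,
    seed: int,
    arm_len_range: tuple[int, int] = (20, 24),
    flank: int = 10,
) -> ArmReference:
    """Generate random hairpins, each with one annotated mature arm.

    The hairpin extends ``flank`` nt (>= 6) beyond the arm on both sides so
    that templated offsets up to +/-4 are resolvable.  Deterministic for a
    fixed seed; arms are redrawn until all canonical sequences are distinct.
    """
    if n_mirnas < 1:
        raise ValueError(f"n_mirnas must be >= 1, got {n_mirnas}")
    if flank < 6:
        raise ValueError("flank must be >= 6 to resolve +/-4 templated offsets")
    rng = np.random.default_rng([int(seed), 0x5EED])
    arms: list[MirnaArm] = []
    seen: set[str] = set()
    for i in range(n_mirnas):
        while True:
            n = int(rng.integers(arm_len_range[0], arm_len_range[1] + 1))
            hairpin = "".join(rng.choice(_BASES, size=n + 2 * flank))
            canonical = hairpin[flank : flank + n]
            if canonical not in seen:
                seen.add(canonical)
                break
        arms.append(
            MirnaArm(
                mirna_name=f"syn-miR-{i + 1}-5p",
                hairpin_id=f"syn-mir-{i + 1}",
                hairpin_seq=hairpin,
                arm_start=flank,
                arm_end=flank + n,
            )
        )
    return ArmReference(arms)


# ---------------------------------------------------------------- defaults


def default_group_design() -> tuple[dict[str, str], dict[str, str]]:
    """The 24-sample three-group cohort layout: 3 nevi, 4 single melanomas
    and 17 multiple-primary melanomas (8 patients with a first/second pair,
    plus one unpaired first tumor).  Returns (sample->group, sample->patient).
    """
    design: dict[str, str] = {}
    pairing: dict[str, str] = {}
    for i in range(1, 4):
        design[f"BN_{i}"] = "nevus"
    for i in range(1, 5):
        design[f"CM_{i}"] = "single"
    for p in range(1, 9):
        design[f"MPM_p{p}_1st"] = "MPM-1st"
        design[f"MPM_p{p}_2nd"] = "MPM-2nd"
        pairing[f"MPM_p{p}_1st"] = f"p{p}"
        pairing[f"MPM_p{p}_2nd"] = f"p{p}"
    design["MPM_p9_1st"] = "MPM-1st"
    return design, pairing


# Offset archetypes, all concentrated at the 3' end (d3 in -2..+4).  The
# isomiR-dominant ones loosely mirror the observed 3-to-23-fold
# isomiR/canonical ratio range; they are illustrative, not calibrated.
_ARCHETYPES: list[dict[tuple[int, int], float]] = [
    # canonical-dominant
    {(0, 0): 0.70, (0, -1): 0.12, (0, -2): 0.08, (0, 1): 0.06, (0, 2): 0.04},
    # 3'-trim dominant (miR-125a-5p|0|-2 style, ratio ~12.5x)
    {(0, 0): 0.06, (0, -2): 0.75, (0, -1): 0.10, (0, 1): 0.05, (0, 2): 0.04},
    # templated 3'-extension dominant (miR-30 family style)
    {(0, 0): 0.10, (0, 1): 0.45, (0, 2): 0.30, (0, -1): 0.10, (0, 3): 0.05},
    # canonical only
    {(0, 0): 1.0},
    # long-tail extensions up to +4 with a minor 5' variant
    {(0, 0): 0.55, (0, 3): 0.15, (0, 4): 0.10, (0, -1): 0.10, (1, -1): 0.10},
]
# Orphan archetype: the canonical form is never emitted.
_ORPHAN_DIST: dict[tuple[int, int], float] = {(0, -1): 0.6, (0, -2): 0.4}


def default_config(
    ref: ArmReference,
    depth: int = 100_000,
    seed: int = 0,
    error_rate: float = 0.005,
    group_design: dict[str, str] | None = None,
    pairing: dict[str, str] | None = None,
) -> SimulationConfig:
    """Study-condition defaults for a given reference.

    Archetypes are assigned cyclically; every tenth miRNA (at least one when
    the panel has >= 10 miRNAs) is an orphan.  Per-miRNA abundances are
    log-normal; a third of miRNAs carry a 2-fold melanoma-vs-single effect
    and a fifth a 1.6-fold first-vs-second-tumor effect.
    """
    if group_design is None:
        group_design, pairing_d = default_group_design()
        pairing = pairing_d if pairing is None else pairing
    pairing = pairing or {}
    rng = np.random.default_rng([int(seed), 0xC0F])
    names = ref.names
    offset_dist: dict[str, dict[tuple[int, int], float]] = {}
    orphans: set[str] = set()
    for i, name in enumerate(names):
        if len(names) >= 10 and i % 10 == 9:
            offset_dist[name] = dict(_ORPHAN_DIST)
            orphans.add(name)
        else:
            offset_dist[name] = dict(_ARCHETYPES[i % len(_ARCHETYPES)])
    abundance = {n: float(w) for n, w in zip(names, rng.lognormal(0.0, 1.2, len(names)))}
    group_fold: dict[tuple[str, str], float] = {}
    for i, name in enumerate(names):
        if i % 3 == 0:
            f = 2.0 if rng.random() < 0.5 else 0.5
            group_fold[(name, "MPM-1st")] = f
            group_fold[(name, "MPM-2nd")] = f
        if i % 5 == 1:
            group_fold[(name, "MPM-2nd")] = group_fold.get((name, "MPM-2nd"), 1.0) * 1.6
    return SimulationConfig(
        n_mirnas=len(names),
        depth=depth,
        group_design=dict(group_design),
        offset_dist=offset_dist,
        orphan_mirnas=frozenset(orphans),
        error_rate=error_rate,
        seed=seed,
        abundance=abundance,
        group_fold=group_fold,
        pairing=dict(pairing),
    )


# --------------------------------------------------------------- validation


def validate_config(ref: ArmReference, cfg: SimulationConfig) -> None:
    if cfg.depth <= 0:
        raise ConfigurationError("depth must be > 0")
    if not (0.0 <= cfg.error_rate < 1.0) or not (0.0 <= cfg.nta_prob <= 1.0):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    for g in cfg.group_design.values():
        if g not in GROUPS:
            raise ConfigurationError(f"unknown group {g!r}; expected one of {GROUPS}")
    for name, dist in cfg.offset_dist.items():
        if name not in ref:
            raise ConfigurationError(f"offset_dist names unknown miRNA {name!r}")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
            raise ConfigurationError(f"{name}: offset probabilities must sum to 1")
        arm = ref[name]
        for d5, d3 in dist:
            start, end = arm.arm_start + d5, arm.arm_end + d3
            if not (0 <= start < end <= len(arm.hairpin_seq)):
                raise ConfigurationError(
                    f"{name}: offset pair ({d5:+d}, {d3:+d}) not realizable "
                    f"within its hairpin"
                )
    for name in cfg.orphan_mirnas:
        dist = cfg.offset_dist.get(name, {})
        if dist.get((0, 0), 0.0) > 0:
            raise ConfigurationError(f"orphan miRNA {name} emits canonical reads")


# --------------------------------------------------------------- simulation


def _sample_weights(cfg: SimulationConfig, names: list[str], group: str) -> np.ndarray:
    w = np.array([cfg.abundance.get(n, 1.0) * cfg.group_fold.get((n, group), 1.0)
                  for n in names])
    return w / w.sum()


def simulate_reads(
    ref: ArmReference, cfg: SimulationConfig, out_dir: str | Path, gzip_fastq: bool = False
) -> SimulationResult:
    """Emit one FASTQ per sample plus the truth table (TSV-writable).

    Each read is an arm substring shifted by a sampled (d5, d3), an optional
    non-templated 3' addition, then the 3' adapter, truncated to the read
    length; substitution errors are applied last.  The truth table records
    the pre-error label.  Non-templated bases are resampled to differ from
    the templated base at their position, so truth labels are exact.
    """
    validate_config(ref, cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ref.names
    arms = {n: ref[n] for n in names}
    # Precompute variant inserts per (miRNA, d5, d3).
    variant_seq: dict[str, list[str]] = {}
    offset_pairs: dict[str, list[tuple[int, int]]] = {}
    offset_cdf: dict[str, np.ndarray] = {}
    for n in names:
        dist = cfg.offset_dist[n]
        pairs = sorted(dist)
        arm = arms[n]
        variant_seq[n] = [
            arm.hairpin_seq[arm.arm_start + d5 : arm.arm_end + d3] for d5, d3 in pairs
        ]
        offset_pairs[n] = pairs
        offset_cdf[n] = np.cumsum([dist[p] for p in pairs])
    nta_bases = sorted(cfg.nta_base_dist)
    nta_p = np.array([cfg.nta_base_dist[b] for b in nta_bases], dtype=float)
    nta_p = nta_p / nta_p.sum()

    fastq_paths: dict[str, Path] = {}
    truth_rows: list[tuple] = []
    for s_idx, (sample, group) in enumerate(cfg.group_design.items()):
        rng = np.random.default_rng([int(cfg.seed), 1000 + s_idx])
        weights = _sample_weights(cfg, names, group)
        mirna_idx = rng.choice(len(names), size=cfg.depth, p=weights)
        u_offset = rng.random(cfg.depth)
        u_nta = rng.random(cfg.depth)
        lines: list[str] = []
        for i in range(cfg.depth):
            name = names[mirna_idx[i]]
            arm = arms[name]
            k = int(np.searchsorted(offset_cdf[name], u_offset[i], side="right"))
            k = min(k, len(offset_pairs[name]) - 1)
            d5, d3 = offset_pairs[name][k]
            insert = variant_seq[name][k]
            nta = ""
            if u_nta[i] < cfg.nta_prob:
                nta_len = 1 if rng.random() < 0.8 else 2
                pos = arm.arm_end + d3
                chars = []
                for j in range(nta_len):
                    templ = arm.hairpin_seq[pos + j] if pos + j < len(arm.hairpin_seq) else None
                    b = nta_bases[int(rng.choice(len(nta_bases), p=nta_p))]
                    if b == templ:
                        # must mismatch the template to be non-templated
                        others = [x for x in nta_bases if x != templ] or ["C"]
                        b = others[int(rng.integers(len(others)))]
                    chars.append(b)
                nta = "".join(chars)
                insert = insert + nta
            read = (insert + cfg.adapter_seq)[: cfg.read_len]
            if cfg.error_rate > 0:
                n_err = rng.binomial(len(read), cfg.error_rate)
                if n_err:
                    pos_err = rng.choice(len(read), size=n_err, replace=False)
                    chars = list(read)
                    for p in pos_err:
                        alts = [b for b in "ACGT" if b != chars[p]]
                        chars[p] = alts[int(rng.integers(3))]
                    read = "".join(chars)
            rid = f"{sample}:r{i:06d}"
            lines.append(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
            truth_rows.append((rid, sample, group, name, d5, d3, nta, insert))
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        data = "".join(lines).encode()
        if gzip_fastq:
            with gzip.GzipFile(path, "wb", mtime=0) as fh:
                fh.write(data)
        else:
            path.write_bytes(data)
        fastq_paths[sample] = path

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "group", "mirna_name", "d5", "d3", "nta", "insert_seq"],
    )
    return SimulationResult(fastq_paths=fastq_paths, truth=truth, config=cfg)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_metadata(cfg: SimulationConfig, path: str | Path) -> None:
    rows = [
        {"sample": s, "group": g, "patient": cfg.pairing.get(s, "")}
        for s, g in cfg.group_design.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
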