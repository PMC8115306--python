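"""miRNA target-site prediction and canonical-vs-isoform target divergence.

This is a desk-scale stand-in for a pattern-based target predictor: a
seed-complementarity scan over the 5'UTR, CDS and 3'UTR (Watson-Crick and
G:U pairs, at most one single-nucleotide bulge inside the seed), a
nearest-neighbour RNA:RNA hybrid minimum free energy, and an empirical
p-value from dinucleotide-preserving shuffles of the site.  Targets pass
with energy < -16 kcal/mol and p < 0.01 by default.

The energy model is a compact Turner-style parameterization (stacking terms
for all WC and G:U pair combinations, affine bulge/internal-loop penalties,
duplex initiation and terminal AU/GU penalties) with dangling-end bonuses
deliberately excluded: every structure available to a 3'-trimmed miRNA is
then also available to the full-length one at the same energy, so trimming
can never make the reported minimum energy more negative.  That monotone
substructure property is what makes trimmed-isoform target loss a
well-defined set difference.  Magnitudes are representative of RNA duplex
thermodynamics but the -16 kcal/mol gate is calibrated on this model's own
scale, not on any external predictor's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

try:  # jit-compiled DP core; the pure-Python twin is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

REGIONS = ("five_prime_utr", "cds", "three_prime_utr")

SEED_START, SEED_END = 1, 8          # miRNA positions 2-8, 0-based half-open
MAXL = 6                              # max unpaired run on either side of a loop
INIT_ENERGY = 4.09                    # duplex initiation, kcal/mol
TERMINAL_AU = 0.45                    # per AU/GU helix-end penalty

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
# pair indices: 0 AU, 1 UA, 2 CG, 3 GC, 4 GU, 5 UG
_PAIR_OF = {
    (0, 3): 0, (3, 0): 1, (1, 2): 2, (2, 1): 3, (2, 3): 4, (3, 2): 5,
}
_WOBBLE = {4, 5}

# 5'-p1.p2-3' stacking energies (kcal/mol); Turner-style magnitudes.
_STACK = np.array(
    [   # AU     UA     CG     GC     GU     UG
        [-0.93, -1.10, -2.24, -2.08, -0.55, -1.36],   # AU
        [-1.33, -0.93, -2.35, -2.11, -1.00, -1.27],   # UA
        [-2.11, -2.08, -3.26, -2.36, -1.41, -2.11],   # CG
        [-2.35, -2.24, -3.42, -3.26, -1.53, -2.51],   # GC
        [-1.27, -1.36, -2.51, -2.11, -0.50, -0.30],   # GU
        [-1.00, -0.55, -1.53, -1.41, -0.30, -0.50],   # UG
    ]
)
_TERM = np.array([TERMINAL_AU, TERMINAL_AU, 0.0, 0.0, TERMINAL_AU, TERMINAL_AU])


def _loop_table(maxl: int = MAXL) -> np.ndarray:
    loop = np.full((maxl + 1, maxl + 1), np.inf)
    for l1 in range(maxl + 1):
        for l2 in range(maxl + 1):
            if l1 == 0 and l2 == 0:
                continue  # stacking handled separately
            if min(l1, l2) == 0:    # bulge
                loop[l1, l2] = 3.1 + 0.55 * (l1 + l2)
            else:                   # internal loop with asymmetry penalty
                loop[l1, l2] = 1.7 + 0.55 * (l1 + l2) + 0.4 * abs(l1 - l2)
    return loop


_LOOP = _loop_table()


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from exc


def pair_code(x: str, y: str) -> str | None:
    """'WC', 'GU' or None for two RNA bases facing each other."""
    idx = _PAIR_OF.get((_BASE_INDEX.get(x, -1), _BASE_INDEX.get(y, -1)))
    if idx is None:
        return None
    return "GU" if idx in _WOBBLE else "WC"


# ----------------------------------------------------------------- duplex DP


def _duplex_dp_py(a: np.ndarray, br: np.ndarray) -> float:
    """Hybrid MFE over all antiparallel, non-crossing intermolecular
    structures; ``br`` is the site reversed so both indices ascend."""
    n, m = len(a), len(br)
    pair = np.full((n, m), -1, dtype=np.int64)
    for i in range(n):
        for k in range(m):
            pair[i, k] = _PAIR_OF.get((int(a[i]), int(br[k])), -1)
    W = np.full((n, m), np.inf)
    best = np.inf
    for i in range(n):
        for k in range(m):
            pi = pair[i, k]
            if pi < 0:
                continue
            e = INIT_ENERGY + _TERM[pi]
            for l1 in range(min(MAXL, i - 1) + 1):
                ii = i - 1 - l1
                if ii < 0:
                    break
                for l2 in range(min(MAXL, k - 1) + 1):
                    kk = k - 1 - l2
                    if kk < 0:
                        break
                    w = W[ii, kk]
                    if not np.isfinite(w):
                        continue
                    pj = pair[ii, kk]
                    cost = _STACK[pj, pi] if (l1 == 0 and l2 == 0) else _LOOP[l1, l2]
                    if w + cost < e:
                        e = w + cost
            W[i, k] = e
            closed = e + _TERM[pi]
            if closed < best:
                best = closed
    return float(best) if np.isfinite(best) else 0.0


if _HAVE_NUMBA:

    @njit(cache=False)
    def _duplex_dp_nb(a, br, pair_of, stack, loop, term, init, maxl):  # pragma: no cover
        n, m = len(a), len(br)
        pair = np.full((n, m), -1, dtype=np.int64)
        for i in range(n):
            for k in range(m):
                pair[i, k] = pair_of[a[i], br[k]]
        W = np.full((n, m), np.inf)
        best = np.inf
        for i in range(n):
            for k in range(m):
                pi = pair[i, k]
                if pi < 0:
                    continue
                e = init + term[pi]
                for l1 in range(maxl + 1):
                    ii = i - 1 - l1
                    if ii < 0:
                        break
                    for l2 in range(maxl + 1):
                        kk = k - 1 - l2
                        if kk < 0:
                            break
                        w = W[ii, kk]
                        if w == np.inf:
                            continue
                        pj = pair[ii, kk]
                        if l1 == 0 and l2 == 0:
                            cost = stack[pj, pi]
                        else:
                            cost = loop[l1, l2]
                        if w + cost < e:
                            e = w + cost
                W[i, k] = e
                closed = e + term[pi]
                if closed < best:
                    best = closed
        if best == np.inf:
            return 0.0
        return best

    _PAIR_MAT = np.full((4, 4), -1, dtype=np.int64)
    for (x, y), idx in _PAIR_OF.items():
        _PAIR_MAT[x, y] = idx


def duplex_energy(mirna_seq: str, site_seq: str) -> float:
    """Minimum free energy (kcal/mol) of the miRNA:site RNA hybrid.

    Deterministic; returns 0.0 when no base pair can form (no duplex).
    Sequences longer than 60 nt are rejected.
    """
    m, s = to_rna(mirna_seq), to_rna(site_seq)
    if len(m) > 60 or len(s) > 60:
        raise ValueError("duplex sequences must be <= 60 nt")
    if not m or not s:
        return 0.0
    a, br = _encode(m), _encode(s)[::-1].copy()
    if _HAVE_NUMBA:
        e = float(_duplex_dp_nb(a, br, _PAIR_MAT, _STACK, _LOOP, _TERM,
                                INIT_ENERGY, MAXL))
    else:
        e = _duplex_dp_py(a, br)
    return min(e, 0.0)


# ------------------------------------------------------------- transcripts


@dataclass
class TranscriptRecord:
    """A mature transcript split into 5'UTR / CDS / 3'UTR regions."""

    transcript_id: str
    regions: dict[str, str]

    def __post_init__(self) -> None:
        self.regions = {r: to_rna(self.regions.get(r, "")) for r in REGIONS}

    @property
    def full_seq(self) -> str:
        return "".join(self.regions[r] for r in REGIONS)


@dataclass
class TargetSite:
    """A predicted binding site on one transcript region (0-based half-open)."""

    transcript_id: str
    region: str
    site_start: int
    site_end: int
    pairing: tuple[str, ...]          # seed-window codes, miRNA positions 2-8
    seed_match_start: int             # window start of the seed match
    energy: float = 0.0
    p_emp: float = float("nan")
    site_seq: str = ""


# ------------------------------------------------------------- seed scanning


def _seed_window_match(seed: str, window: str) -> tuple[str, ...] | None:
    """Pairing codes if `window` (transcript 5'->3') pairs the 7-nt seed with
    only WC/GU pairs and at most one internal 1-nt bulge; else None."""
    wrev = window[::-1]
    lw = len(window)
    if lw == 7:
        codes = []
        for i in range(7):
            c = pair_code(seed[i], wrev[i])
            if c is None:
                return None
            codes.append(c)
        return tuple(codes)
    if lw == 8:  # bulged nucleotide on the target side
        for bp in range(1, 7):
            codes = []
            for i in range(7):
                c = pair_code(seed[i], wrev[i if i < bp else i + 1])
                if c is None:
                    break
                codes.append(c)
            else:
                return tuple(codes[:bp] + ["bulge"] + codes[bp:])
        return None
    if lw == 6:  # bulged nucleotide on the miRNA side
        for bp in range(1, 6):
            codes = []
            ok = True
            for i in range(6):
                c = pair_code(seed[i if i < bp else i + 1], wrev[i])
                if c is None:
                    ok = False
                    break
                codes.append(c)
            if ok:
                return tuple(codes[:bp] + ["bulge"] + codes[bp:])
        return None
    return None


def find_seed_sites(mirna_seq: str, transcript: TranscriptRecord) -> list[TargetSite]:
    """Scan all three regions for seed-complementary windows.

    Matching depends only on miRNA positions 2-8, so 3'-end length variants
    of the same miRNA share identical candidate loci.  Each seed window is
    extended to a full-duplex candidate covering the remaining miRNA length
    plus a small margin for loops.
    """
    m = to_rna(mirna_seq)
    if not (16 <= len(m) <= 30):
        raise ValueError(f"miRNA length {len(m)} outside [16, 30]")
    seed = m[SEED_START:SEED_END]
    tail = len(m) - SEED_END           # miRNA 3' portion pairing upstream
    sites: list[TargetSite] = []
    seen: set[tuple[str, int, int]] = set()
    for region in REGIONS:
        rseq = transcript.regions[region]
        for lw in (7, 8, 6):           # exact windows first, then bulged
            for p in range(0, len(rseq) - lw + 1):
                codes = _seed_window_match(seed, rseq[p : p + lw])
                if codes is None:
                    continue
                start = max(0, p - tail - 4)
                end = min(len(rseq), p + lw + 2)
                key = (region, start, end)
                if key in seen:
                    continue
                seen.add(key)
                sites.append(
                    TargetSite(
                        transcript_id=transcript.transcript_id,
                        region=region,
                        site_start=start,
                        site_end=end,
                        pairing=codes,
                        seed_match_start=p,
                        site_seq=rseq[start:end],
                    )
                )
    return sites


# ------------------------------------------------------- empirical p-values


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide composition."""
    chars = list(seq)
    if len(chars) < 3 or len(set(chars)) == 1:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        succ.setdefault(a, []).append(b)
    first, last = chars[0], chars[-1]
    vertices = list(succ)
    # pick terminal (last-used) edges forming an in-tree toward `last`
    while True:
        term = {
            v: succ[v][int(rng.integers(len(succ[v])))] for v in vertices if v != last
        }
        ok = True
        for v in vertices:
            u, hops = v, 0
            while u != last and u in term and hops <= len(vertices):
                u, hops = term[u], hops + 1
            if u != last:
                ok = False
                break
        if ok:
            break
    walk_edges: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v != last:
            edges.remove(term[v])
        order = rng.permutation(len(edges))
        edges = [edges[i] for i in order]
        if v != last:
            edges.append(term[v])
        walk_edges[v] = edges
    out = [first]
    v = first
    while walk_edges.get(v):
        v = walk_edges[v].pop(0)
        out.append(v)
    return "".join(out)


def site_pvalue(
    mirna_seq: str,
    site_seq: str,
    n_shuffles: int = 1000,
    seed: int = 0,
    return_null: bool = False,
):
    """Empirical significance of a site energy against dinucleotide shuffles.

    p_emp = (1 + #{shuffles with energy <= observed}) / (n_shuffles + 1);
    deterministic for a fixed seed.
    """
    site = to_rna(site_seq)
    if len(site) < 6:
        raise ValueError("site shorter than 6 nt")
    observed = duplex_energy(mirna_seq, site)
    rng = np.random.default_rng([int(seed), 0xD15C])
    null = np.array(
        [duplex_energy(mirna_seq, dinucleotide_shuffle(site, rng))
         for _ in range(n_shuffles)]
    )
    p = (1.0 + float((null <= observed).sum())) / (n_shuffles + 1.0)
    if return_null:
        return p, observed, null
    return p


# ----------------------------------------------------------- target calling


def evaluate_sites(
    mirna_seq: str,
    transcript: TranscriptRecord,
    energy_cut: float = -16.0,
    p_cut: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[TargetSite]:
    """Score all candidate sites of one transcript; energies always filled,
    p-values only computed for sites inside the energy gate (p_cut >= 1
    disables the significance gate)."""
    sites = find_seed_sites(mirna_seq, transcript)
    for s_idx, site in enumerate(sites):
        site.energy = duplex_energy(mirna_seq, site.site_seq)
        if site.energy < energy_cut and p_cut < 1.0:
            site.p_emp = site_pvalue(
                mirna_seq, site.site_seq, n_shuffles=n_shuffles,
                seed=int(np.random.SeedSequence([seed, s_idx]).generate_state(1)[0]
                         % 2**31),
            )
    return sites


def _passes(site: TargetSite, energy_cut: float, p_cut: float) -> bool:
    if not site.energy < energy_cut:
        return False
    return True if p_cut >= 1.0 else site.p_emp < p_cut


def predict_targets(
    mirna_seq: str,
    transcriptome: list[TranscriptRecord],
    energy_cut: float = -16.0,
    p_cut: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All sites passing both gates, one row per site; the target gene set
    is the distinct transcript_id values."""
    rows = []
    for t_idx, tr in enumerate(transcriptome):
        sites = evaluate_sites(
            mirna_seq, tr, energy_cut, p_cut, n_shuffles,
            seed=int(np.random.SeedSequence([seed, t_idx]).generate_state(1)[0]
                     % 2**31),
        )
        for site in sites:
            if _passes(site, energy_cut, p_cut):
                rows.append(
                    {
                        "transcript_id": site.transcript_id,
                        "region": site.region,
                        "site_start": site.site_start,
                        "site_end": site.site_end,
                        "energy": site.energy,
                        "p_emp": site.p_emp,
                    }
                )
    return pd.DataFrame(
        rows, columns=["transcript_id", "region", "site_start", "site_end",
                       "energy", "p_emp"],
    )


def best_site_energies(
    mirna_seq: str, transcriptome: list[TranscriptRecord]
) -> dict[str, float]:
    """Per-transcript minimum candidate-site energy (0.0 when no candidate)."""
    out = {}
    for tr in transcriptome:
        energies = [duplex_energy(mirna_seq, s.site_seq)
                    for s in find_seed_sites(mirna_seq, tr)]
        out[tr.transcript_id] = min(energies) if energies else 0.0
    return out


def compare_isoform_targets(
    canonical_seq: str,
    isoform_label,
    transcriptome: list[TranscriptRecord],
    energy_cut: float = -16.0,
    p_cut: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Target sets of the canonical miRNA and one isoform at identical gates.

    The isoform sequence is derived from the canonical one by label algebra
    (trims and non-templated additions only).  Returns lost / retained /
    gained transcript sets with each gene's best candidate-site energy under
    both forms.
    """
    iso_seq = isoform_label.apply_to(to_rna(canonical_seq))
    can = predict_targets(canonical_seq, transcriptome, energy_cut, p_cut,
                          n_shuffles, seed)
    iso = predict_targets(iso_seq, transcriptome, energy_cut, p_cut,
                          n_shuffles, seed)
    can_set = set(can.transcript_id)
    iso_set = set(iso.transcript_id)
    e_can = best_site_energies(canonical_seq, transcriptome)
    e_iso = best_site_energies(iso_seq, transcriptome)
    return {
        "canonical_seq": to_rna(canonical_seq),
        "isoform_seq": iso_seq,
        "isoform_label": isoform_label.render(),
        "lost": sorted(can_set - iso_set),
        "retained": sorted(can_set & iso_set),
        "gained": sorted(iso_set - can_set),
        "energies": {
            tid: {"canonical": e_can.get(tid, 0.0), "isoform": e_iso.get(tid, 0.0)}
            for tid in sorted(can_set | iso_set)
        },
    }


# ---------------------------------------------------- synthetic transcriptome


_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement_rna(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(to_rna(seq)))


def _non_pairing_base(mirna_base: str) -> str:
    """A base that neither WC- nor GU-pairs the given miRNA base."""
    y = _BASE_INDEX[mirna_base]
    for b, x in _BASE_INDEX.items():
        if _PAIR_OF.get((y, x)) is None:
            return b
    raise AssertionError("unreachable")


def make_transcriptome(
    mirna_seq: str,
    n_transcripts: int = 30,
    seed: int = 0,
    region_lens: tuple[int, int, int] = (60, 120, 120),
) -> list[TranscriptRecord]:
    """Toy transcripts with planted sites of graded complementarity.

    Most transcripts carry, in a random region, the full reverse complement
    of the miRNA degraded by 0-8 central mismatches (positions pairing
    miRNA 9 .. len-4; the seed and the 3'-terminal pairing are kept intact),
    so best-site energies grade smoothly across any energy gate while the
    miRNA 3' end still contributes pairing — which is what makes 3'-trimmed
    isoforms lose the marginal targets.  The last five transcripts carry no
    planted site.
    """
    m = to_rna(mirna_seq)
    rng = np.random.default_rng([int(seed), 0x7A6])
    bases = np.array(list("ACGU"))
    out = []
    n_planted = max(0, n_transcripts - 5)
    mutable = list(range(SEED_END + 1, len(m) - 3))  # miRNA positions 10..len-3
    for i in range(n_transcripts):
        regions = {
            r: "".join(rng.choice(bases, size=n))
            for r, n in zip(REGIONS, region_lens)
        }
        if i < n_planted:
            n_mut = round(i * 8 / max(1, n_planted - 1))
            site = list(reverse_complement_rna(m))
            step = max(1, len(mutable) // max(1, n_mut)) if n_mut else 1
            for j in mutable[::step][:n_mut]:
                site[len(m) - 1 - j] = _non_pairing_base(m[j])
            site = "".join(site)
            region = REGIONS[int(rng.integers(len(REGIONS)))]
            rseq = regions[region]
            pos = int(rng.integers(0, len(rseq) - len(site)))
            regions[region] = rseq[:pos] + site + rseq[pos + len(site):]
        out.append(TranscriptRecord(transcript_id=f"TX{i + 1:03d}", regions=regions))
    return out


# --------------------------------------------------------------------- I/O


def write_transcriptome(
    transcripts: list[TranscriptRecord],
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    records, rows = [], []
    for tr in transcripts:
        records.append(
            SeqRecord(Seq(tr.full_seq), id=tr.transcript_id, description="")
        )
        pos = 0
        for region in REGIONS:
            n = len(tr.regions[region])
            rows.append((tr.transcript_id, region, pos, pos + n))
            pos += n
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows, columns=["transcript_id", "region", "start", "end"]).to_csv(
        sidecar_path, sep="\t", index=False
    )


def read_transcriptome(
    fasta_path: str | Path, sidecar_path: str | Path
) -> list[TranscriptRecord]:
    seqs = {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sidecar = pd.read_csv(sidecar_path, sep="\t")
    out = []
    for tid, grp in sidecar.groupby("transcript_id", sort=True):
        regions = {
            row.region: seqs[tid][int(row.start):int(row.end)]
            for row in grp.itertuples()
        }
        out.append(TranscriptRecord(transcript_id=str(tid), regions=regions))
    return out
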