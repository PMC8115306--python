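# Methods

## The analysis model

A mature miRNA variant (isomiR) is described relative to its canonical form
by the offset label `name|d5|d3`, optionally `|+<bases>` for a non-templated
3' addition (NTA).  Offsets are signed shifts of the 5' and 3' termini on
the mature 5'→3' frame: negative toward the 5' direction, positive toward
the 3' direction, zero for the canonical terminus.  The defining identity is

    len(variant) = len(canonical) − d5 + d3 + |NTA|

so `|0|-2` on a 24-nt canonical is a 22-nt 3'-trimmed isoform.  All calls are
made against an *arm reference*: hairpin precursor sequences with one
annotated mature arm each (0-based half-open coordinates; GFF3 on disk).
Sequences are held as uppercase DNA (U→T) internally.

## Synthetic study generator

The generator emulates the statistical structure of a 24-sample melanoma
small RNA-seq cohort: 3 benign nevi, 4 single melanomas and 17 multiple
primary melanomas (8 patients contributing a first/second pair plus one
unpaired first tumor).  Reads are drawn per sample as: miRNA (log-normal
abundance weights, σ=1.2, with optional multiplicative group effects — a
third of miRNAs get a 2-fold melanoma effect, a fifth a 1.6-fold
first-vs-second effect, which is what the contrast stages are exercised
against), then a (d5, d3) offset from the miRNA's offset distribution, then
an NTA with probability 0.1 (length 1 w.p. 0.8, else 2; bases 0.7 U / 0.3 A,
reflecting the dominance of uridylation/adenylation).  Offset archetypes are
3'-concentrated (d3 ∈ −2…+4, d5 almost always 0), spanning
canonical-dominant, trim-dominant (ratio ≈ 12×), extension-dominant and
canonical-only cases; every tenth miRNA is an *orphan* that never emits its
canonical form.  These are illustrative settings matched to the observed
3-to-23-fold isomiR/canonical ratio range, not calibrated estimates — no
per-miRNA isomiR frequency distribution is published beyond panel-level
ratios.

Each insert is followed by the TruSeq small-RNA 3' adapter
(`TGGAATTCTCGGGTGCCAAGG`) and truncated at 50 cycles; substitution errors
are applied uniformly at `error_rate` per base, after the truth table
records the pre-error label.  Two generator details keep truth labels exact:
an NTA base is resampled to differ from the templated base at its position
(otherwise it would *be* templated), and quality strings are constant
placeholders (quality-aware trimming is out of scope; the pipeline relies on
adapter/length filters).  Fixed seed ⇒ byte-identical FASTQ and truth
table.  Not modelled: ligation bias, PCR duplicates, indels, UMIs.

## Preprocessing

Adapter removal finds the longest read suffix matching a prefix of the
adapter with substitutions only, minimum overlap 3, tolerance
`floor(0.1·overlap)` mismatches (the conventional defaults of the standard
trimming tool; the tolerance is exposed as a flag since no published value
exists).  Inserts outside 16–30 nt are removed; 16 and 30 are retained since
only strictly shorter/longer reads are excluded.  Per-sample JSON summaries
count `input / trimmed / too_short / too_long / no_insert`, and those four
categories partition the input exactly.

## IsomiR calling

Each insert is slid over every arm ±6 nt of hairpin flank (window chosen to
cover the observed −2…+4 offset range with margin).  A placement is
admissible with ≤1 substitution and no indels.  The maximal run of trailing
mismatches — up to 2 nt, including any overhang past the hairpin end — is
peeled off as NTA; a trailing base that matches the template is therefore
always absorbed as templated extension, i.e. an NTA must mismatch the
template.  Candidates are ranked by (remaining mismatches, NTA length); if
more than one distinct (miRNA, start) placement attains the best score the
read is ambiguous and excluded from labelling.

Two consequences are worth making explicit.  First, ranking
mismatches-before-NTA means a read ending in a single non-templated base is
read as an NTA isomiR rather than as a templated variant with a terminal
mismatch; this is what makes label recovery *exact* on error-free data.
Second, the converse ambiguity is irreducible: a genuine terminal
sequencing error is indistinguishable from a 1-nt NTA, so at a 0.5%
substitution rate about 0.5% of labelled reads are necessarily mislabelled;
reads with ≥2 insert errors are rejected (no label) by the ≤1-mismatch
contract itself.  The mismatch position is recorded but no seed-specific
rule is applied to it.

## Quantification

RPM[l,s] = counts[l,s] · 10⁶ / Σ_l counts[l,s].  "Qualifying reads" is read
as *unambiguously aligned under the calling criteria*, so numerator and
denominator use the same read set and every sample column sums to 10⁶
exactly; a strict mode that restricts the denominator to 0-mismatch
alignments is available (`quantify.denominator: strict`) because the
published wording ("aligned exactly") is ambiguous on this point.  Orphan
labels — those of miRNAs with zero canonical (|0|0) count across the whole
dataset — are flagged and excluded before normalization, ratio computation
and the panel.  Detection of one canonical read in one sample clears a
miRNA, which makes orphan status fragile at high depth with sequencing
error: a terminal error on a trimmed read can regenerate the canonical
sequence and "un-orphan" a miRNA with a spuriously tiny canonical mean and
hence an extreme ratio.  This is inherent to a threshold-free detection
rule and is left as-is.

Per-isomiR means are unweighted averages over *all* samples (per-group
means are additionally emitted for isoform-vs-canonical comparisons).  The
ratio is mean_isomiR / mean_canonical.  Report tables render values
truncated — not rounded — to two decimals (17.0873 → 17.08), matching how
the reference panel's ratios reproduce from their printed means; full
precision is kept internally.  The high-abundance panel keeps ratio ≥ 3
with no upper bound (the published panel itself contains ratios up to 23).

## Differential expression

Counts are normalized by median-of-ratios size factors (factor_s = median
over features nonzero in all samples of counts[f,s]/geometric-mean_f), then
log2(x+1); the pseudocount is configurable.  Two-group contrasts use an
empirical-Bayes moderated t: per-feature pooled variances s²_f with d
residual dof are squeezed toward a prior, s̃² = (d₀s₀² + d·s²)/(d₀+d), with
(d₀, s₀²) moment-matched on log variances via digamma/trigamma moments of
the scaled-F distribution (trigamma inverse by Newton).  When the observed
log-variance spread does not exceed its sampling expectation, d₀ is capped
at 10⁶ ("infinite" shrinkage) and s₀² is the arithmetic mean of the
variances.  The statistic uses s̃ with d₀+d dof, capped at the summed
residual dof actually present in the data; BH adjustment is applied over
all features.  Gates are conjunctive and direction-symmetric: |FC| > 1.5
(linear scale) and adjusted p < 0.05 for the unpaired contrast; the paired
first-vs-second contrast uses the classical paired t with |FC| > 1.2 and
raw p < 0.05.  With d₀ = 0 the statistic reduces exactly to the ordinary
pooled t.  An installed R implementation of the same empirical-Bayes
moderation serves as an independent oracle in the test suite.

Unpaired two-group helpers apply Welch's correction when an F-test on the
variances rejects at 0.05, with Mann–Whitney available for non-normal data.
Ordination is PCA of samples on centered features; clustering is
agglomerative with Manhattan (L1) distance and average linkage on both axes
("Manhattan similarity" is read as city-block distance; both linkage and
metric are exposed).  qPCR relative expression is 2^−(mean Cq_target − mean
Cq_ref) with triplicates averaged first and missing replicates dropped with
a warning; reference-gene selection by minimal cross-sample variance is
provided rather than hard-coding any particular miRNA.

## Target analysis

This stage reproduces the *structure* of a region-wide target search —
seed scan, energy gate, significance gate, set comparison — at desk scale;
it is not a re-implementation of any published pattern-discovery predictor,
and its empirical shuffle p-value is a different null from any such tool's.

Candidate sites are windows in the 5'UTR/CDS/3'UTR whose pairing to miRNA
positions 2–8 uses only Watson–Crick or G:U pairs with at most one
single-nucleotide bulge on either strand; windows are extended to
full-duplex candidates covering the remaining miRNA length plus a 4-nt
loop margin upstream and 2 nt downstream.  Site finding depends only on
positions 2–8, so 3'-length variants share candidate loci by construction.

Duplex energy is the minimum over all antiparallel non-crossing
intermolecular structures of: initiation (+4.09) + stacking terms for
adjacent pairs (compact Turner-style table over all WC and G:U pair
combinations) + affine bulge (3.1 + 0.55·len) and internal-loop
(1.7 + 0.55·len + 0.4·asymmetry) penalties (runs capped at 6 nt per side)
+ 0.45 per AU/GU helix end.  Dangling-end and coaxial bonuses are
deliberately excluded: every structure available to a 3'-trimmed miRNA is
then available to the full-length miRNA at identical energy, so trimming
can never make the reported minimum more negative — the monotone
substructure property on which the lost-target analysis rests.  Magnitudes
are representative of RNA duplex thermodynamics, but the −16 kcal/mol gate
is calibrated on this model's own scale (whether published "binding
energies" include initiation terms is unstated; ours do).  The dynamic
program is O(n·m·49); a jitted core is used when available, with a pure
NumPy/Python twin kept as fallback and cross-checked in tests against
exhaustive structure enumeration.

Site significance is p_emp = (1 + #{shuffled sites with energy ≤ observed})
/ (n_shuffles + 1), shuffling the site with an exact
dinucleotide-preserving (Euler-path) shuffle; deterministic per seed, and
uniform under the null since an i.i.d. site is exchangeable with its
shuffle orbit.  Targets pass with energy < −16 kcal/mol and p < 0.01;
p-values are only computed for sites already inside the energy gate, and
`p_cut ≥ 1` disables the significance gate (used for the pure-energy
monotonicity analyses).  The synthetic transcriptome plants full-length
complementary sites degraded by 0–8 central mismatches (seed and 3'-terminal
pairing intact) so best-site energies grade smoothly across the gate and a
3'-trim isoform genuinely loses the marginal targets.

## Pipeline and determinism

Stages run in order simulate? → preprocess → call → quantify → diffexp →
targets, each writing to its own subdirectory; a manifest records a sha256
per artifact, and identical config+seed reproduce identical hashes
(including figures).  Each stage draws from its own RNG stream derived from
the master seed salted with the stage name, so stages are independently
reproducible.  Unknown config keys are rejected, and referenced paths are
checked before any stage runs.

## Problem sizes and numerical choices

Default test/demo problem sizes — 10–20 miRNAs, 4–24 samples, depths
1.5×10³–10⁵, 30-transcript target fixtures, 50–1000 shuffles — were chosen
as the smallest sizes at which the statistical behaviour under test
(binomial/KS calibration bands, exact recovery, gate power) is resolvable.
Ties in alignment scoring resolve as described above; all-zero count
columns, empty transcripts, zero-difference pairs and zero-variance
features take explicit code paths (error, empty result, p=1, and prior
collapse respectively).  p-values are floored at the smallest positive
float; two-decimal truncation is applied only at the reporting layer.

## What passing tests do and do not show

The generator's reads differ from real FFPE small-RNA libraries in known
ways: no ligation/PCR bias, no indel errors, uniform error rate, constant
qualities, a single annotated arm per hairpin, and offset distributions
that are stylized archetypes.  Passing the recovery and calibration tests
therefore demonstrates correctness of the algorithms under their stated
contracts — not that real-cohort quantities (total detected miRNAs, counts
of differentially expressed miRNAs, genome-scale target-set sizes) would be
reproduced; those require the original cohort reads, genome-scale
references and external predictors, and are out of scope.
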