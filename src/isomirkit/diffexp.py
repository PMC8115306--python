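"""Normalization and statistical contrasts for expression matrices.

The stack is: median-of-ratios size factors -> log2(x + pseudocount) ->
per-feature tests.  Two-group contrasts use an empirical-Bayes moderated
t-test: per-feature sample variances are shrunk toward a pooled prior
s0^2 with d0 prior degrees of freedom,

    s~^2_f = (d0 * s0^2 + d_f * s^2_f) / (d0 + d_f),

where (d0, s0^2) are estimated by moment matching on the log sample
variances (digamma/trigamma moments of the scaled-F distribution that the
variances follow under the hierarchical model).  The moderated t uses s~
with d0 + d_f degrees of freedom, and Benjamini-Hochberg adjustment is
applied over all features.  Paired designs use the classical paired t on
log2 values.  A fold-change gate and a significance gate are conjunctive.

Also here: Welch/Mann-Whitney two-group helpers, PCA + Manhattan-distance
average-linkage clustering for sample/feature ordination, and 2^-deltaCt
relative quantification for qPCR tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

D0_CAP = 1e6  # "infinite" shrinkage, kept finite for stable arithmetic


# ----------------------------------------------------------- normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_s = median over features f (nonzero in every sample) of
    counts[f, s] / geometric_mean_f.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    log_mat = np.log(mat[all_pos])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Size-factor normalize then log2(x + pseudocount)."""
    factors = size_factors(counts)
    return np.log2(counts / factors + pseudocount)


# ------------------------------------------------- empirical-Bayes variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-feature sample variances with df dof.

    Works on z = log s^2: under the hierarchical model
    E[z] = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    (sign conventions folded below) and
    Var[z] = trigamma(df/2) + trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.where(s2 <= 0, 1e-300, s2)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    # with no detectable excess spread the prior is "infinitely" informative
    # and its scale is the plain mean of the variances
    if n < 2:
        return D0_CAP, float(s2.mean())
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return D0_CAP, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def squeeze_variances(
    s2: np.ndarray, df: float, d0: float | None = None, s0_sq: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward the estimated prior."""
    if d0 is None or s0_sq is None:
        d0, s0_sq = estimate_prior(s2, df)
    if d0 == 0:
        return np.asarray(s2, dtype=float), 0.0, s0_sq if s0_sq is not None else 0.0
    tilde = (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)
    return tilde, d0, s0_sq


# --------------------------------------------------------------- contrasts


def _group_columns(groups: pd.Series, matrix: pd.DataFrame, g: str) -> pd.DataFrame:
    cols = groups.index[groups == g]
    cols = [c for c in cols if c in matrix.columns]
    return matrix[cols]


def moderated_t(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per feature (log2 input expected).

    log2fc is mean(A) - mean(B).  ``d0_override=0`` disables shrinkage and
    reduces to the ordinary pooled two-sample t-test.
    """
    groups = pd.Series(groups)
    a = _group_columns(groups, matrix, group_a)
    b = _group_columns(groups, matrix, group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {group_a}: {na}, {group_b}: {nb}"
        )
    am, bm = a.mean(axis=1).to_numpy(), b.mean(axis=1).to_numpy()
    df = na + nb - 2
    pooled = (a.sub(a.mean(axis=1), axis=0).pow(2).sum(axis=1)
              + b.sub(b.mean(axis=1), axis=0).pow(2).sum(axis=1)).to_numpy() / df
    if d0_override is not None:
        tilde, d0, _ = squeeze_variances(pooled, df, d0=d0_override,
                                         s0_sq=float(np.median(pooled)))
    else:
        tilde, d0, _ = squeeze_variances(pooled, df)
    se = np.sqrt(tilde * (1.0 / na + 1.0 / nb))
    se = np.where(se <= 0, np.nan, se)
    t = (am - bm) / se
    # total dof cannot exceed the information actually present in the data
    dof = min(d0 + df, len(matrix) * df, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame(
        {"log2fc": am - bm, "t_stat": np.nan_to_num(t), "p": p}, index=matrix.index
    )
    out["p_adj"] = multipletests(out.p.to_numpy(), method="fdr_bh")[1]
    out.index.name = "feature"
    return out


def paired_t(
    matrix: pd.DataFrame,
    pairing: Mapping[str, str] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Classical paired t-test per feature on log2 values (two-tailed).

    ``pairing`` maps sample -> patient; each patient must contribute exactly
    one sample in each of the two groups.  log2fc is mean over pairs of
    (A - B).
    """
    pairing = pd.Series(pairing)
    groups = pd.Series(groups)
    pairs: dict[str, dict[str, str]] = {}
    for sample, patient in pairing.items():
        if sample not in matrix.columns:
            continue
        g = groups.get(sample)
        if g in (group_a, group_b):
            pairs.setdefault(patient, {})[g] = sample
    bad = sorted(p for p, d in pairs.items() if len(d) != 2)
    if bad:
        raise ValueError(f"incomplete pairs for patient(s): {', '.join(bad)}")
    if len(pairs) < 2:
        raise ValueError("need >= 2 complete pairs")
    a_cols = [pairs[p][group_a] for p in sorted(pairs)]
    b_cols = [pairs[p][group_b] for p in sorted(pairs)]
    diffs = matrix[a_cols].to_numpy() - matrix[b_cols].to_numpy()
    n = diffs.shape[1]
    mean_d = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    # zero-difference features: t undefined, no evidence against the null
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame(
        {"log2fc": mean_d, "t_stat": np.nan_to_num(t), "p": p}, index=matrix.index
    )
    out["p_adj"] = multipletests(out.p.to_numpy(), method="fdr_bh")[1]
    out.index.name = "feature"
    return out


def de_filter(
    results: pd.DataFrame,
    fc_threshold: float,
    alpha: float,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Conjunctive gates: |fold-change| > threshold (linear scale, either
    direction) AND (adjusted) p < alpha.  Adds a boolean ``passes`` column."""
    out = results.copy()
    fc = np.power(2.0, np.abs(out.log2fc.to_numpy()))
    pcol = out.p_adj if use_adjusted else out.p
    out["passes"] = (fc > fc_threshold) & (pcol.to_numpy() < alpha)
    return out


# ---------------------------------------------------- two-group small helpers


def two_group_test(x: np.ndarray, y: np.ndarray, mode: str = "auto"):
    """Unpaired comparison: t-test with Welch correction when an F-test on
    the variances rejects at 0.05, or Mann-Whitney for non-normal mode."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if mode == "mannwhitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(stat), float(p), "mannwhitney"
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    p_var = 2.0 * min(stats.f.sf(f, dfx, dfy), stats.f.cdf(f, dfx, dfy))
    welch = p_var < 0.05
    stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(stat), float(p), "welch" if welch else "student"


# ---------------------------------------------------------------- ordination


@dataclass
class OrdinationResult:
    pca_coords: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray
    sample_order: list[str]
    feature_order: list[str]


def ordination_and_clustering(
    matrix: pd.DataFrame,
    n_components: int = 2,
    linkage_method: str = "average",
    metric: str = "cityblock",
) -> OrdinationResult:
    """PCA of samples on centered features plus L1 (Manhattan) agglomerative
    clustering with average linkage on both axes."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.T.to_numpy(dtype=float)          # samples x features
    k = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=k)
    coords = pca.fit_transform(x - x.mean(axis=0))
    slink = hierarchy.linkage(x, method=linkage_method, metric=metric)
    flink = hierarchy.linkage(matrix.to_numpy(dtype=float), method=linkage_method,
                              metric=metric)
    s_order = [matrix.columns[i] for i in hierarchy.leaves_list(slink)]
    f_order = [matrix.index[i] for i in hierarchy.leaves_list(flink)]
    return OrdinationResult(
        pca_coords=pd.DataFrame(
            coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        sample_linkage=slink,
        feature_linkage=flink,
        sample_order=s_order,
        feature_order=f_order,
    )


# --------------------------------------------------------------------- qPCR


def delta_ct(cq_target, cq_ref) -> float:
    """Relative expression 2^-(mean Cq_target - mean Cq_ref).

    Triplicates are averaged first; missing replicates (NaN) are dropped
    with a warning.
    """
    t = np.asarray(cq_target, dtype=float)
    r = np.asarray(cq_ref, dtype=float)
    if np.isnan(t).any() or np.isnan(r).any():
        warnings.warn("missing Cq replicate(s); computing on available values")
    t, r = t[~np.isnan(t)], r[~np.isnan(r)]
    if len(t) == 0 or len(r) == 0:
        raise ValueError("no Cq replicates available")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("Cq values must be positive")
    return float(2.0 ** -(t.mean() - r.mean()))


def select_reference_feature(matrix: pd.DataFrame) -> str:
    """Reference gene choice by minimal cross-sample variance (stability)."""
    return str(matrix.var(axis=1).idxmin())
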