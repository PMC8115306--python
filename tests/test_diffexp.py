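"""Size factors, moderated/paired t, gates, ordination and 2^-deltaCt."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from isomirkit import diffexp as de


@pytest.fixture()
def two_groups():
    return pd.Series({f"s{i}": "A" if i < 5 else "B" for i in range(10)})


def test_size_factors_identical_columns_are_one():
    counts = pd.DataFrame({"a": [10, 5, 30], "b": [10, 5, 30], "c": [10, 5, 30]})
    assert np.allclose(de.size_factors(counts), 1.0)


def test_size_factors_scale_equivariance():
    counts = pd.DataFrame({"a": [10, 5, 30], "b": [20, 10, 60]})
    f = de.size_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_hand_computed_fixture():
    counts = pd.DataFrame(
        {"s1": [100, 8, 40, 3], "s2": [200, 16, 80, 6], "s3": [50, 4, 20, 9]}
    )
    # manual median-of-ratios with explicit loops
    import math

    mat = counts.to_numpy(float)
    expected = []
    geo = [math.exp(sum(math.log(v) for v in row) / 3) for row in mat]
    for j in range(3):
        ratios = sorted(mat[i][j] / geo[i] for i in range(4))
        expected.append((ratios[1] + ratios[2]) / 2)
    assert de.size_factors(counts).tolist() == pytest.approx(expected)


def test_size_factors_error_when_no_common_feature():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        de.size_factors(counts)


def test_moderated_t_reduces_to_classic_when_d0_zero(two_groups):
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(0, 1, (300, 10)), columns=two_groups.index)
    res = de.moderated_t(mat, two_groups, "A", "B", d0_override=0)
    classic = stats.ttest_ind(mat.iloc[:, :5], mat.iloc[:, 5:], axis=1)
    assert np.allclose(res.t_stat, classic.statistic, atol=1e-10)


def test_moderated_t_matches_limma(two_groups, tmp_path):
    """Independent oracle: limma lmFit/eBayes via Rscript, both d0 regimes."""
    rng = np.random.default_rng(7)
    sd = rng.lognormal(0, 0.6, 150)
    mat = pd.DataFrame(
        rng.normal(0, 1, (150, 10)) * sd[:, None],
        index=[f"g{i}" for i in range(150)], columns=two_groups.index,
    )
    mat.iloc[:15, 5:] += 1.0
    mat_path = tmp_path / "mat.tsv"
    mat.to_csv(mat_path, sep="\t")
    out_path = tmp_path / "limma.tsv"
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.table("{mat_path}", header=TRUE, row.names=1, sep="\\t"))
        design <- model.matrix(~0+factor(c(rep("A",5),rep("B",5))))
        colnames(design) <- c("A","B")
        fit <- eBayes(contrasts.fit(lmFit(m, design),
                                    makeContrasts(A-B, levels=design)))
        write.table(data.frame(t=fit$t, p=fit$p.value), "{out_path}",
                    sep="\\t", quote=FALSE)
        """
    )
    rfile = tmp_path / "limma.R"
    rfile.write_text(script)
    subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
    limma = pd.read_csv(out_path, sep="\t")
    limma.columns = ["t", "p"]
    res = de.moderated_t(mat, two_groups, "A", "B")
    assert np.allclose(res.t_stat, limma.t, atol=1e-4)
    assert np.allclose(res.p, limma.p, atol=1e-4)


def test_shrinkage_consistency_equal_variances(two_groups):
    """With one shared true variance the squeezed variances collapse to it."""
    rng = np.random.default_rng(1)
    sigma = 0.7
    mat = pd.DataFrame(rng.normal(0, sigma, (2000, 10)), columns=two_groups.index)
    a, b = mat.iloc[:, :5], mat.iloc[:, 5:]
    pooled = (
        a.sub(a.mean(axis=1), axis=0).pow(2).sum(axis=1)
        + b.sub(b.mean(axis=1), axis=0).pow(2).sum(axis=1)
    ).to_numpy() / 8
    tilde, d0, s0 = de.squeeze_variances(pooled, 8)
    assert d0 > 50  # far more prior than the 8 residual dof
    assert s0 == pytest.approx(sigma**2, rel=0.1)
    # squeezed values collapse towards the common prior variance
    assert np.abs(tilde - s0).max() < 0.15 * s0
    assert np.abs(tilde - s0).max() < 0.2 * np.abs(pooled - s0).max()


def test_moderated_t_requires_two_per_group():
    mat = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
    with pytest.raises(ValueError):
        de.moderated_t(mat, {"a": "A", "b": "A", "c": "B"}, "A", "B")


def test_bh_adjustment_monotone(two_groups):
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.normal(0, 1, (400, 10)), columns=two_groups.index)
    res = de.moderated_t(mat, two_groups, "A", "B")
    assert (res.p_adj >= res.p - 1e-12).all()
    assert (res.p_adj <= 1.0).all()
    ordered = res.sort_values("p")
    assert (np.diff(ordered.p_adj.to_numpy()) >= -1e-12).all()


# ------------------------------------------------------------------ paired


def _paired_setup(n_pairs=6, n_feat=50, shift=0.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    first = rng.normal(5, 1, (n_feat, n_pairs))
    second = first + shift + rng.normal(0, noise, (n_feat, n_pairs))
    cols_a = [f"p{i}_1" for i in range(n_pairs)]
    cols_b = [f"p{i}_2" for i in range(n_pairs)]
    mat = pd.DataFrame(np.hstack([first, second]), columns=cols_a + cols_b)
    pairing = pd.Series({c: c.split("_")[0] for c in cols_a + cols_b})
    groups = pd.Series({**{c: "MPM-1st" for c in cols_a},
                        **{c: "MPM-2nd" for c in cols_b}})
    return mat, pairing, groups


def test_paired_t_zero_differences_no_rejections():
    mat, pairing, groups = _paired_setup(noise=0.0, shift=0.0)
    res = de.paired_t(mat, pairing, groups, "MPM-1st", "MPM-2nd")
    assert (res.p == 1.0).all()
    assert (res.t_stat == 0.0).all()


def test_paired_t_constant_shift_degenerate():
    mat, pairing, groups = _paired_setup(noise=0.0, shift=-0.8)
    res = de.paired_t(mat, pairing, groups, "MPM-2nd", "MPM-1st")
    assert np.allclose(res.log2fc, -0.8)  # second = first - 0.8
    assert (res.p <= 1e-12).all()


def test_paired_t_matches_closed_form():
    mat, pairing, groups = _paired_setup(shift=0.4, seed=3)
    res = de.paired_t(mat, pairing, groups, "MPM-1st", "MPM-2nd")
    d = mat.iloc[0, :6].to_numpy() - mat.iloc[0, 6:].to_numpy()
    t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.t_stat.iloc[0] == pytest.approx(t_manual, abs=1e-10)
    t_scipy = stats.ttest_rel(mat.iloc[:, :6], mat.iloc[:, 6:], axis=1)
    assert np.allclose(res.t_stat, t_scipy.statistic, atol=1e-10)
    assert np.allclose(res.p, t_scipy.pvalue, atol=1e-12)


def test_paired_t_incomplete_pair_lists_patients():
    mat, pairing, groups = _paired_setup()
    groups = groups.drop("p2_2")
    with pytest.raises(ValueError, match="p2"):
        de.paired_t(mat.drop(columns=["p2_2"]), pairing.drop("p2_2"),
                    groups, "MPM-1st", "MPM-2nd")


# ------------------------------------------------------------------- gates


def test_de_filter_gate_conjunction():
    res = pd.DataFrame(
        {
            "log2fc": [np.log2(1.4), np.log2(2.0), np.log2(1.6), -np.log2(1.8)],
            "t_stat": [1, 1, 1, 1],
            "p": [0.001, 0.001, 0.001, 0.001],
            "p_adj": [0.001, 0.2, 0.01, 0.01],
        },
        index=list("abcd"),
    )
    out = de.de_filter(res, 1.5, 0.05, use_adjusted=True)
    assert out.passes.tolist() == [False, False, True, True]


def test_de_filter_matches_bruteforce_on_spiked_matrix(two_groups):
    rng = np.random.default_rng(11)
    n_cols = two_groups.index
    mat = pd.DataFrame(rng.normal(8, 0.4, (500, 10)), columns=n_cols)
    mat.iloc[:20, 5:] += 1.0  # 2x shift
    res = de.moderated_t(mat, two_groups, "A", "B")
    out = de.de_filter(res, 1.5, 0.05, use_adjusted=True)
    brute = (np.abs(res.log2fc) > np.log2(1.5) + 0) & (res.p_adj < 0.05)
    brute = (2.0 ** np.abs(res.log2fc) > 1.5) & (res.p_adj < 0.05)
    assert (out.passes == brute).all()


def test_de_filter_direction_symmetric(two_groups):
    rng = np.random.default_rng(12)
    mat = pd.DataFrame(rng.normal(8, 0.4, (100, 10)), columns=two_groups.index)
    mat.iloc[:10, 5:] += 1.2
    ab = de.de_filter(de.moderated_t(mat, two_groups, "A", "B"), 1.5, 0.05)
    ba = de.de_filter(de.moderated_t(mat, two_groups, "B", "A"), 1.5, 0.05)
    assert np.allclose(ab.log2fc, -ba.log2fc)
    assert (ab.passes == ba.passes).all()


# -------------------------------------------------------------- ordination


def test_identical_samples_merge_first():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 1, 30)
    mat = pd.DataFrame(
        {"a": base, "b": base, "c": base + rng.normal(0, 2, 30),
         "d": base + rng.normal(0, 3, 30)}
    )
    res = de.ordination_and_clustering(mat)
    first_merge = res.sample_linkage[0]
    assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
    assert first_merge[2] == pytest.approx(0.0)


def test_three_groups_recovered_at_large_effect():
    rng = np.random.default_rng(8)
    centers = {"g1": 0.0, "g2": 6.0, "g3": -6.0}
    cols, labels = {}, []
    for g, mu in centers.items():
        for i in range(5):
            cols[f"{g}_{i}"] = rng.normal(mu, 0.5, 40)
            labels.append(g)
    mat = pd.DataFrame(cols)
    res = de.ordination_and_clustering(mat)
    found = hierarchy.fcluster(res.sample_linkage, t=3, criterion="maxclust")
    assert adjusted_rand_score(labels, found) == 1.0


def test_rank_one_matrix_pca_explains_everything():
    u = np.arange(1, 11, dtype=float)
    v = np.array([1.0, 2.0, 3.0, 4.0])
    mat = pd.DataFrame(np.outer(u, v), columns=list("abcd"))
    res = de.ordination_and_clustering(mat)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_ordination_needs_two_samples():
    with pytest.raises(ValueError):
        de.ordination_and_clustering(pd.DataFrame({"only": [1.0, 2.0]}))


# -------------------------------------------------------------------- qPCR


def test_delta_ct_identity():
    assert de.delta_ct([24.0, 24.0, 24.0], [24.0, 24.0, 24.0]) == pytest.approx(1.0)


def test_delta_ct_one_cycle_halves():
    assert de.delta_ct([25.0], [24.0]) == pytest.approx(0.5)


def test_delta_ct_triplicates_hand_computed():
    assert de.delta_ct([24.1, 24.3, 24.2], [20.1, 20.3, 20.2]) == pytest.approx(0.0625)


def test_delta_ct_missing_replicate_warns():
    with pytest.warns(UserWarning):
        v = de.delta_ct([24.0, np.nan, 24.0], [23.0, 23.0, 23.0])
    assert v == pytest.approx(0.5)


def test_two_group_test_switches_to_welch():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 6, 30)
    _, _, method = de.two_group_test(x, y)
    assert method == "welch"
    _, _, method2 = de.two_group_test(x, rng.normal(0, 1, 30))
    assert method2 == "student"
    _, p, method3 = de.two_group_test(x, y, mode="mannwhitney")
    assert method3 == "mannwhitney" and 0 < p <= 1


def test_reference_feature_is_least_variable():
    mat = pd.DataFrame(
        {"s1": [1.0, 5.0], "s2": [1.1, 9.0], "s3": [0.9, 2.0]},
        index=["stable", "wobbly"],
    )
    assert de.select_reference_feature(mat) == "stable"
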