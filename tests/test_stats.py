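import math

import numpy as np
import pandas as pd
import pytest

from utailor import (
    argonaute_parse,
    category_enrichment,
    differential_abundance,
    tissue_specificity,
)


def _cpm(rows, samples):
    return pd.DataFrame(rows, columns=samples,
                        index=[f"f{i}" for i in range(len(rows))])


SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]
GROUPS = {s: s[0] for s in SAMPLES}


def test_identical_groups_not_significant():
    mat = _cpm([[100, 110, 90, 100, 110, 90]], SAMPLES)
    res = differential_abundance(mat, GROUPS, "a", "b")
    assert res["log2fc_abundance"].iloc[0] == pytest.approx(0.0)
    assert not res["significant"].any()


def test_fourfold_change_detected():
    mat = _cpm(
        [
            [100, 100, 100, 400, 400, 401],
            [50, 52, 48, 51, 49, 50],  # stable feature
        ],
        SAMPLES,
    )
    res = differential_abundance(mat, GROUPS, "a", "b", fdr_threshold=0.05)
    assert res.loc["f0", "log2fc_abundance"] == pytest.approx(2.0, abs=0.02)
    assert bool(res.loc["f0", "significant"])
    assert not bool(res.loc["f1", "significant"])


def test_degenerate_equal_constant_groups_p_one():
    mat = _cpm([[100, 100, 100, 100, 100, 100]], SAMPLES)
    res = differential_abundance(mat, GROUPS, "a", "b")
    assert res["p"].iloc[0] == 1.0


def test_fdr_is_benjamini_hochberg():
    """BH recomputed by hand (p * m / rank, cumulative min from the top)."""
    rng = np.random.default_rng(3)
    mat = _cpm(rng.lognormal(5, 1, size=(12, 6)), SAMPLES)
    res = differential_abundance(mat, GROUPS, "a", "b")
    p = res["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    assert res["fdr"].to_numpy() == pytest.approx(adj)
    # the frozen textbook example for the same hand oracle
    ps = np.array([0.01, 0.02, 0.03, 0.04])
    hand = [min(ps[j] * 4 / (j + 1) for j in range(k, 4)) for k in range(4)]
    assert hand == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_type_one_error_controlled_under_null():
    rng = np.random.default_rng(11)
    mat = _cpm(rng.lognormal(4, 0.5, size=(200, 6)), SAMPLES)
    res = differential_abundance(mat, GROUPS, "a", "b", fdr_threshold=0.05)
    assert res["significant"].mean() <= 0.05


def test_needs_replicates():
    with pytest.raises(ValueError, match="replicates"):
        differential_abundance(_cpm([[1, 2, 3]], ["a1", "a2", "b1"]),
                               {"a1": "a", "a2": "a", "b1": "b"}, "a", "b")


# -------------------------------------------------------------- Argonaute


def _freqs():
    return pd.DataFrame(
        {"species_id": ["s1", "s2", "s3", "s4"],
         "pooled_u_freq": [0.10, 0.20, 0.30, 0.40]}
    )


def test_multi_argonaute_membership():
    assoc = pd.DataFrame(
        {"species_id": ["s1", "s1", "s2", "zz"],
         "argonaute": ["CSR-1", "WAGO-1", "CSR-1", "CSR-1"]}
    )
    out = argonaute_parse(_freqs(), assoc)
    assert out.loc["CSR-1", "n_species"] == 2  # s1 and s2; zz ignored
    assert out.loc["CSR-1", "mean_u_freq"] == pytest.approx(0.15)
    assert out.loc["WAGO-1", "mean_u_freq"] == pytest.approx(0.10)
    assert out.loc["not_enriched", "n_species"] == 2  # s3, s4
    assert out.loc["not_enriched", "mean_u_freq"] == pytest.approx(0.35)


def test_empty_association_table():
    assoc = pd.DataFrame({"species_id": [], "argonaute": []})
    out = argonaute_parse(_freqs(), assoc)
    assert list(out.index) == ["not_enriched"]
    assert out.loc["not_enriched", "n_species"] == 4


def test_association_order_invariance():
    assoc = pd.DataFrame(
        {"species_id": ["s1", "s2", "s3"], "argonaute": ["X", "X", "Y"]}
    )
    a = argonaute_parse(_freqs(), assoc)
    b = argonaute_parse(_freqs(), assoc.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------- tissue specificity


def _jsd_sqrt(p, q):
    """Independent numeric oracle: sqrt of Jensen-Shannon divergence,
    log base 2, computed from the definition."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return math.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))


def test_single_tissue_gene_scores_one():
    expr = pd.DataFrame([[0, 5.0, 0]], columns=["germ", "neuron", "muscle"],
                        index=["g1"])
    out = tissue_specificity(expr)
    assert out.loc["g1", "S_neuron"] == pytest.approx(1.0)
    assert out.loc["g1", "category"] == "neuron"


def test_two_tissue_uniform_value():
    expr = pd.DataFrame([[0.5, 0.5]], columns=["t1", "t2"], index=["g"])
    out = tissue_specificity(expr)
    expected = 1 - _jsd_sqrt([0.5, 0.5], [1.0, 0.0])
    assert out.loc["g", "S_t1"] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(1 - math.sqrt(0.311278), abs=1e-5)
    assert out.loc["g", "category"] == "ubiquitous"  # max S < 0.6


def test_s_index_matches_direct_jsd_to_1e9():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.gamma(2, 10, size=(25, 5)),
                        columns=[f"t{i}" for i in range(5)])
    out = tissue_specificity(expr)
    for gi in range(25):
        p = expr.iloc[gi].to_numpy()
        p = p / p.sum()
        for ti in range(5):
            e = np.zeros(5)
            e[ti] = 1.0
            assert out.iloc[gi, ti] == pytest.approx(1 - _jsd_sqrt(p, e),
                                                     abs=1e-9)


def test_permutation_symmetry_and_zero_gene():
    expr = pd.DataFrame([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]],
                        columns=["a", "b", "c"], index=["g1", "g2"])
    out = tissue_specificity(expr)
    perm = tissue_specificity(expr[["c", "a", "b"]])
    assert out.loc["g1", "S_a"] == pytest.approx(perm.loc["g1", "S_a"])
    assert out.loc["g2", "category"] == "unclassified"


# ------------------------------------------------------------- enrichment


def test_chi2_matches_hand_formula():
    """2x2 chi-square (no correction) recomputed from the formula on a
    table with all expected cells >= 5."""
    bg = pd.Series(
        ["germ"] * 30 + ["other"] * 270,
        index=[f"g{i}" for i in range(300)],
    )
    target = bg.iloc[list(range(20)) + list(range(30, 110))]  # 20 germ, 80 other
    out = category_enrichment(target, bg)
    a, b, c, d = 20, 80, 10, 190
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert out.loc["germ", "chi2"] == pytest.approx(chi2)
    assert out.loc["germ", "direction"] == "enriched"


def test_extreme_enrichment_detected():
    bg = pd.Series(["x"] * 50 + ["y"] * 50, index=[f"g{i}" for i in range(100)])
    target = bg[bg == "x"].iloc[:25]
    out = category_enrichment(target, bg)
    assert bool(out.loc["x", "significant"])
    assert out.loc["x", "direction"] == "enriched"


def test_small_expected_cells_flagged_and_corrected():
    bg = pd.Series(["rare"] * 4 + ["common"] * 96,
                   index=[f"g{i}" for i in range(100)])
    target = bg.iloc[:10]
    out = category_enrichment(target, bg)
    assert bool(out.loc["rare", "small_expected"])


def test_uniform_target_rarely_significant():
    rng = np.random.default_rng(29)
    bg = pd.Series(rng.choice(["a", "b", "c", "d"], size=400),
                   index=[f"g{i}" for i in range(400)])
    n_any = 0
    for _ in range(20):
        target = bg.sample(60, random_state=int(rng.integers(1e6)))
        out = category_enrichment(target, bg)
        n_any += int(out["significant"].any())
    assert n_any <= 3


def test_target_must_be_subset():
    bg = pd.Series(["a"], index=["g1"])
    with pytest.raises(ValueError, match="subset"):
        category_enrichment(pd.Series(["a"], index=["g9"]), bg)
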