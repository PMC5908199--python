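"""Nonparametric tests, correlations, and BH feature selection.

Oracles here are independent of the implementations they check: the
Mann-Whitney exact p is recomputed by enumerating all group labelings,
and the BH adjustment by a literal hand step-up pass.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from fcserology import (
    DegenerateInputError,
    InputError,
    bh_adjust,
    correlation_matrix,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_posthoc,
    select_features,
    spearman,
)
from fcserology.synthetic import CohortConfig, generate_cohort


def enumerate_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by brute-force label enumeration."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(x, y):
        return sum(1 for xi in x for yi in y if xi > yi)

    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def hand_bh(p):
    """Literal BH step-up: sort, p(i)*m/i, enforce monotone from the top."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * m / rank, prev)
        adjusted[i] = min(val, 1.0)
        prev = adjusted[i]
    return adjusted


def test_mann_whitney_separated_groups_exact():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res["U"] == 0.0
    assert res["p_two_sided"] == pytest.approx(0.1)
    assert res["method"] == "exact"


def test_mann_whitney_symmetry_and_no_separation(rng):
    a = rng.normal(size=6).tolist()
    b = rng.normal(size=5).tolist()
    assert mann_whitney_u(a, b)["p_two_sided"] == pytest.approx(
        mann_whitney_u(b, a)["p_two_sided"])
    x = [1.0, 2.0, 3.0, 4.0]
    assert mann_whitney_u(x, x)["p_two_sided"] == pytest.approx(1.0, abs=0.05)
    with pytest.raises(InputError):
        mann_whitney_u([], [1.0])


def test_mann_whitney_exact_matches_enumeration(rng):
    """Exact p equals the brute-force enumeration over labelings for
    tie-free samples with combined n <= 10."""
    for _ in range(40):
        na = int(rng.integers(2, 6))
        nb = int(rng.integers(2, 11 - na))
        pooled = rng.permutation(rng.uniform(0, 1, na + nb))
        a, b = pooled[:na], pooled[na:]
        res = mann_whitney_u(a, b)
        assert res["method"] == "exact"
        assert res["p_two_sided"] == pytest.approx(enumerate_mw_p(a, b),
                                                   abs=1e-12)


def test_kruskal_wallis_identical_and_two_group_equivalence(rng):
    assert kruskal_wallis([[3, 3], [3, 3, 3], [3]]) == {"H": 0.0, "p": 1.0}
    # two groups: KW chi-square p ~ MW normal approximation p
    a = rng.normal(0, 1, 30).tolist()
    b = rng.normal(0.5, 1, 30).tolist()
    kw = kruskal_wallis([a, b])
    mw = mann_whitney_u(a, b)
    assert kw["p"] == pytest.approx(mw["p_two_sided"], rel=0.05)
    assert kw["H"] >= 0.0


def test_pairwise_posthoc_properties(rng):
    idents = [[1.0, 1.0, 1.0]] * 3
    out = pairwise_posthoc(idents)
    assert (out["adjusted_p"] == 1.0).all()
    groups = [rng.normal(m, 1, 8).tolist() for m in (0, 1, 2)]
    out = pairwise_posthoc(groups)
    assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()
    with pytest.raises(InputError):
        pairwise_posthoc([[1.0, 2.0], [3.0, 4.0]])


def test_pairwise_posthoc_separated_groups(rng):
    """Three well-separated groups are all flagged.

    Rank tests saturate: with n=10 per group, complete separation of
    adjacent groups caps the Dunn z at 10/sqrt(15.5) ~ 2.54 (p ~ 0.011),
    so the attainable bound is p < 0.05 for adjacent pairs and p < 0.01
    for the extreme pair.
    """
    groups = [rng.normal(m, 0.1, 10).tolist() for m in (0, 5, 10)]
    for method in ("holm", "bonferroni", "tukey"):
        out = pairwise_posthoc(groups, method=method)
        assert (out["adjusted_p"] < 0.05).all(), method
        extreme = out[(out["group_a"] == 0) & (out["group_b"] == 2)]
        assert (extreme["adjusted_p"] < 0.01).all(), method


def test_spearman_examples():
    r = spearman([1, 2, 3], [10, 20, 30])
    assert r.rho == pytest.approx(1.0)
    r = spearman([1, 2, 3, 4], [8, 6, 4, 2])
    assert r.rho == pytest.approx(-1.0)
    # hand rank computation: d^2 = 1+1+1+1+0 -> rho = 1 - 24/120 = 0.8
    r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert r.rho == pytest.approx(0.8)
    with pytest.raises(DegenerateInputError):
        spearman([1, 1, 1], [1, 2, 3])


def test_spearman_exact_permutation_p_close_to_t_approx(rng):
    x = rng.normal(size=7)
    y = x + rng.normal(scale=0.8, size=7)
    approx = spearman(x, y).p_value
    exact = spearman(x, y, exact=True).p_value
    assert abs(exact - approx) < 0.12


def test_correlation_matrix_structure(rng):
    df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
    df["const"] = 1.0
    out = correlation_matrix(df)
    rho = out["rho"]
    assert np.allclose(rho.to_numpy(), rho.to_numpy().T, equal_nan=True)
    assert (np.diag(rho) == 1.0).all()
    assert rho["const"].drop("const").isna().all()
    assert not out["concordant"].to_numpy()[np.eye(5, dtype=bool)].any()


def test_bh_adjust_matches_hand_step_up(rng):
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.37]) == pytest.approx([0.37])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    for _ in range(25):
        p = rng.uniform(0, 1, int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), hand_bh(p), atol=1e-12)
    with pytest.raises(InputError):
        bh_adjust([0.5, 1.5])


def test_bh_adjust_permutation_invariant_and_monotone(rng):
    p = rng.uniform(0, 1, 15)
    perm = rng.permutation(15)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))
    bumped = p.copy()
    bumped[3] = min(1.0, bumped[3] + 0.2)
    assert (bh_adjust(bumped) >= bh_adjust(p) - 1e-12).all()
    assert (bh_adjust(p) >= p - 1e-12).all()


def test_select_features_perfect_feature_is_selected(rng):
    n = 20
    label = np.array(["bNAb"] * 10 + ["no-bNAb"] * 10)
    df = pd.DataFrame({
        "perfect": (label == "bNAb").astype(float),
        "noise1": rng.normal(size=n),
        "noise2": rng.normal(size=n),
        "group": label,
    })
    out = select_features(df, fdr=0.05)
    sel = dict(zip(out["feature"], out["selected"]))
    assert sel["perfect"]
    assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()
    with pytest.raises(InputError):
        select_features(df.assign(group="one-class"))


def test_select_features_structural_17_of_29(rng):
    """A cohort with 17 shifted and 12 null features recovers the
    shifted set at FDR 5% (the screen's intended behaviour)."""
    n1, n0 = 13, 10
    label = np.array(["bNAb"] * n1 + ["no-bNAb"] * n0)
    data = {}
    for i in range(17):
        x = rng.normal(size=n1 + n0)
        x[:n1] += 2.5
        data[f"shifted{i}"] = x
    for i in range(12):
        data[f"null{i}"] = rng.normal(size=n1 + n0)
    df = pd.DataFrame(data)
    df["group"] = label
    out = select_features(df, fdr=0.05)
    selected = set(out.loc[out["selected"], "feature"])
    assert {f"shifted{i}" for i in range(17)} <= selected
    assert len(selected - {f"shifted{i}" for i in range(17)}) <= 3
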