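"""Signed-rank machinery, BH adjustment, complex calls and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chimeracomplex import stability as st
from chimeracomplex.annotation import compendium_from_mapping


def brute_force_signed_rank_p(x, y, alternative="greater"):
    """Exhaustive sign-flip enumeration of the positive-rank-sum null."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=len(d))]
    sums = np.array(sums)
    if alternative == "greater":
        return np.mean(sums >= w_obs - 1e-9)
    if alternative == "less":
        return np.mean(sums <= w_obs + 1e-9)
    tail = min(np.mean(sums >= w_obs - 1e-9), np.mean(sums <= w_obs + 1e-9))
    return min(1.0, 2 * tail)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_equal_vectors_are_degenerate_p_one():
    res = st.wilcoxon_signed_rank_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.pvalue == 1.0 and res.n_used == 0


def test_uniform_shift_n6_exact_p():
    y = np.arange(6, dtype=float)
    res = st.wilcoxon_signed_rank_paired(y + 1.0, y, alternative="greater")
    assert res.pvalue == pytest.approx(1.0 / 64.0)


@pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
def test_exact_p_matches_sign_flip_enumeration(rng, alternative):
    for _ in range(30):
        n = int(rng.integers(3, 11))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.5:  # provoke tied |differences|
            x = np.round(x - y, 1) + y
        res = st.wilcoxon_signed_rank_paired(x, y, alternative=alternative)
        expected = brute_force_signed_rank_p(x, y, alternative)
        assert res.pvalue == pytest.approx(expected, abs=1e-12)


def test_large_n_matches_scipy_normal_approximation(rng):
    n = 40
    x = rng.normal(0.3, 1.0, size=n)
    y = rng.normal(0.0, 1.0, size=n)
    res = st.wilcoxon_signed_rank_paired(x, y, alternative="greater")
    ref = stats.wilcoxon(x, y, alternative="greater", method="approx",
                         correction=False)
    assert res.method == "approx"
    assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_step_up_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_single_p_unchanged_and_empty():
    assert st.bh_adjust([0.03])[0] == pytest.approx(0.03)
    assert len(st.bh_adjust([])) == 0


def test_bh_hand_computed_example():
    adj = st.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_definitional_oracle(rng):
    for _ in range(20):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 30)))
        assert np.allclose(st.bh_adjust(p), bh_step_up_oracle(p))
        assert (st.bh_adjust(p) >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# Complex-level calls
# ---------------------------------------------------------------------------

def _epd_frames(rng, compendium, shift=None):
    proteins = sorted(compendium.subunits)
    ctrl = pd.Series(rng.uniform(10, 50, len(proteins)), index=proteins)
    exp = ctrl + rng.normal(0, 1, len(proteins))
    if shift:
        for cid, amount in shift.items():
            for p in compendium.members[cid]:
                exp[p] += amount
    return exp, ctrl


def test_call_unstable_flags_only_shifted_complex(rng):
    comp = compendium_from_mapping(
        {f"C{i}": {f"P{i}_{j}" for j in range(8)} for i in range(6)})
    exp, ctrl = _epd_frames(rng, comp, shift={"C0": 80.0})
    calls = st.call_unstable_complexes(exp, ctrl, comp, n_min=5)
    calls = calls.set_index("complex_id")
    assert bool(calls.loc["C0", "unstable"])
    assert calls["tested"].all()
    assert calls["p_adj"].between(calls["p_raw"] - 1e-12, 1.0).all()


def test_call_unstable_invariant_to_input_order(rng):
    comp = compendium_from_mapping(
        {f"C{i}": {f"P{i}_{j}" for j in range(7)} for i in range(4)})
    exp, ctrl = _epd_frames(rng, comp, shift={"C2": 60.0})
    a = st.call_unstable_complexes(exp, ctrl, comp, n_min=5)
    perm = np.random.default_rng(0).permutation(len(exp))
    b = st.call_unstable_complexes(exp.iloc[perm], ctrl.iloc[perm], comp, n_min=5)
    pd.testing.assert_frame_equal(a, b)


def test_small_complexes_reported_untested(rng):
    comp = compendium_from_mapping({"Cbig": {f"P{j}" for j in range(8)},
                                    "Csmall": {"Q1", "Q2"}})
    exp, ctrl = _epd_frames(rng, comp)
    calls = st.call_unstable_complexes(exp, ctrl, comp, n_min=5)
    calls = calls.set_index("complex_id")
    assert not calls.loc["Csmall", "tested"]
    assert not calls.loc["Csmall", "unstable"]


def test_excluding_replaced_subunits(toy_annot, rng):
    # C1 entirely on replaced chromosomes -> untested; C2 untouched -> identical
    comp = compendium_from_mapping({"C1": {"P5", "P6"}, "C2": {"P1", "P2", "P3"}})
    exp, ctrl = _epd_frames(rng, comp)
    full = st.call_unstable_complexes(exp, ctrl, comp, n_min=2)
    excl = st.call_unstable_excluding_replaced(exp, ctrl, comp, toy_annot,
                                               {16}, n_min=2)
    excl = excl.set_index("complex_id")
    assert not excl.loc["C1", "tested"]
    assert excl.loc["C2", "p_raw"] == pytest.approx(
        full.set_index("complex_id").loc["C2", "p_raw"])


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def test_kruskal_matches_rank_formula():
    groups = {"a": [1.0, 2.0], "b": [3.0, 4.0]}
    res = st.kruskal_wallis(groups)
    # closed-form on ranks 1..4 without ties
    N = 4
    mean_rank = (N + 1) / 2
    H = 12.0 / (N * (N + 1)) * (2 * (1.5 - mean_rank) ** 2
                                + 2 * (3.5 - mean_rank) ** 2)
    assert res.H == pytest.approx(H)
    assert res.df == 1


def test_kruskal_all_identical_is_degenerate_error():
    with pytest.raises(st.StabilityError):
        st.kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0]})


def test_dunn_identical_groups_p_one_and_bonferroni_cap(rng):
    vals = rng.normal(size=12)
    groups = {"a": vals, "b": vals, "c": vals + 50.0}
    out = st.dunn_pairwise(groups).set_index(["group_a", "group_b"])
    assert out.loc[("a", "b"), "p_adj"] == 1.0
    for row in out.itertuples():
        assert row.p_adj == pytest.approx(min(1.0, row.p_raw * 3))


def test_dunn_detects_only_the_shifted_group(rng):
    base = rng.normal(size=40)
    groups = {"a": base, "b": base + rng.normal(0, 1e-3, 40), "c": base + 30.0}
    out = st.dunn_pairwise(groups).set_index(["group_a", "group_b"])
    assert out.loc[("a", "b"), "p_adj"] > 0.05
    assert out.loc[("a", "c"), "p_adj"] < 0.05
    assert out.loc[("b", "c"), "p_adj"] < 0.05
    letters = st.compact_letter_display(out.reset_index(), ["a", "b", "c"])
    assert letters["a"] == letters["b"] != letters["c"]


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for the 2x2 table with fixed margins."""
    from math import comb
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    hi = min(row1, col1)
    return sum(comb(row1, k) * comb(row2, col1 - k)
               for k in range(a, hi + 1)) / comb(n, col1)


def _calls_frame(flags_chr, flags_nonchr):
    rows = []
    for i, f in enumerate(flags_chr):
        rows.append(dict(complex_id=f"R{i}", unstable=f, tested=True))
    for i, f in enumerate(flags_nonchr):
        rows.append(dict(complex_id=f"N{i}", unstable=f, tested=True))
    return pd.DataFrame(rows)


def _enrichment_setup(n_chr, n_nonchr):
    annot = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(2 * (n_chr + n_nonchr))],
        "protein_id": [f"P{i}" for i in range(2 * (n_chr + n_nonchr))],
        "chromosome": ([16] * 2 * n_chr) + ([1] * 2 * n_nonchr),
    })
    members = {}
    for i in range(n_chr):
        members[f"R{i}"] = {f"P{2 * i}", f"P{2 * i + 1}"}
    off = 2 * n_chr
    for i in range(n_nonchr):
        members[f"N{i}"] = {f"P{off + 2 * i}", f"P{off + 2 * i + 1}"}
    return compendium_from_mapping(members), annot


def test_fisher_perfect_association_p():
    comp, annot = _enrichment_setup(3, 3)
    calls = _calls_frame([True] * 3, [False] * 3)
    odds, p, table = st.enrichment_fisher(calls, comp, annot, {16})
    assert p == pytest.approx(1.0 / 20.0)
    assert table.tolist() == [[3, 0], [0, 3]]


def test_fisher_degenerate_margin_p_one():
    comp, annot = _enrichment_setup(2, 2)
    calls = _calls_frame([True] * 2, [True] * 2)
    _, p, _ = st.enrichment_fisher(calls, comp, annot, {16})
    assert p == 1.0


def test_fisher_matches_hypergeometric_enumeration(rng):
    for _ in range(15):
        n_chr = int(rng.integers(2, 6))
        n_nonchr = int(rng.integers(2, 6))
        comp, annot = _enrichment_setup(n_chr, n_nonchr)
        flags_chr = rng.random(n_chr) < 0.5
        flags_nonchr = rng.random(n_nonchr) < 0.5
        calls = _calls_frame(list(flags_chr), list(flags_nonchr))
        a = int(flags_chr.sum())
        b = int(flags_nonchr.sum())
        c = n_chr - a
        d = n_nonchr - b
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        _, p, _ = st.enrichment_fisher(calls, comp, annot, {16})
        assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), rel=1e-9)
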