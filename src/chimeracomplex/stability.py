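"""Complex-level stability inference from EPD tables.

A complex is called unstable when the EPD values of its quantified subunits in
the experimental set (replacement line vs reference) are significantly higher
than the same proteins' EPD values in the same-species control set, by a
one-sided paired Wilcoxon signed-rank test with Benjamini-Hochberg correction
across all testable complexes at FDR q = 0.05.

The signed-rank test here follows the classical treatment: zero differences
are dropped before ranking, tied absolute differences share mid-ranks, and the
one-sided p-value is exact (distribution of the positive-rank sum over all
2^n sign assignments, computed by dynamic programming over doubled mid-ranks,
so ties are handled exactly) for n <= ``exact_n_max``; beyond that a normal
approximation with tie-corrected variance is used.

Group-level contrasts (complex vs non-complex vs chr-complex proteins) use the
Kruskal-Wallis H test with Dunn's pairwise z tests and Bonferroni correction;
enrichment of replaced-chromosome subunits among destabilized complexes uses a
one-sided Fisher exact test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ComplexCompendium, protein_chromosome_map, _replaced_set

logger = logging.getLogger(__name__)


class StabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float          # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int               # pairs remaining after dropping zero differences
    degenerate: bool = False  # all differences were zero
    method: str = "exact"


def _exact_signed_rank_p(ranks2: np.ndarray, w2_obs: int, alternative: str) -> float:
    """P-value from the exact null distribution of the positive-rank sum.

    ``ranks2`` are doubled mid-ranks (integers even with ties).  The count of
    sign assignments reaching each possible doubled rank-sum is accumulated by
    dynamic programming; complexity O(n * total), exact for any tie pattern.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    if alternative == "greater":
        return float(counts[w2_obs:].sum())
    if alternative == "less":
        return float(counts[: w2_obs + 1].sum())
    # two-sided: double the smaller tail, capped at 1
    tail = min(counts[w2_obs:].sum(), counts[: w2_obs + 1].sum())
    return float(min(1.0, 2.0 * tail))


def wilcoxon_signed_rank_paired(x, y, alternative: str = "greater",
                                exact_n_max: int = 15) -> WilcoxonResult:
    """Paired signed-rank test of H1: x - y shifted per ``alternative``.

    ``alternative='greater'`` tests whether x values are systematically larger
    than their paired y values.  Zero differences are dropped (all-zero input
    returns p = 1 with a degenerate flag); ties share mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StabilityError("paired samples differ in length")
    if alternative not in ("greater", "less", "two-sided"):
        raise StabilityError(f"bad alternative {alternative!r}")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0,
                              degenerate=True, method="degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(np.rint(2 * w_pos))
        p = _exact_signed_rank_p(ranks2, w2, alternative)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return WilcoxonResult(statistic=w_pos, pvalue=1.0, n_used=n,
                                  degenerate=True, method="degenerate")
        z = (w_pos - mean) / np.sqrt(var)
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
        method = "approx"
    return WilcoxonResult(statistic=w_pos, pvalue=p, n_used=n, method=method)


def bh_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise StabilityError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Complex-level paired tests
# ---------------------------------------------------------------------------

def _as_value_series(table) -> pd.Series:
    """Accept a Series indexed by protein_id or a DataFrame with a value column."""
    if isinstance(table, pd.Series):
        return table.astype(float)
    for col in ("epd", "log2_ratio", "value"):
        if col in table.columns:
            return table.set_index("protein_id")[col].astype(float) \
                if "protein_id" in table.columns else table[col].astype(float)
    raise StabilityError("expected a Series or a frame with epd/log2_ratio/value")


def paired_complex_test(values_exp, values_ctrl, compendium: ComplexCompendium,
                        n_min: int = 5, q: float = 0.05,
                        alternative: str = "greater",
                        members_override: Mapping[str, frozenset] | None = None
                        ) -> pd.DataFrame:
    """Shared machinery for complex-level paired Wilcoxon tests.

    For each complex, paired values (one per subunit quantified in both the
    experimental and control table) are tested one-sidedly; BH adjustment runs
    across all testable complexes (those with >= ``n_min`` shared subunits).
    Complexes below ``n_min`` are reported with ``tested=False``.
    """
    exp = _as_value_series(values_exp)
    ctrl = _as_value_series(values_ctrl)
    shared = exp.index.intersection(ctrl.index)
    members = members_override if members_override is not None else compendium.members
    rows = []
    for cid in sorted(members):
        subunits = sorted(set(members[cid]) & set(shared))
        n = len(subunits)
        if n < n_min:
            rows.append(dict(complex_id=cid, n=n, W=np.nan, p_raw=np.nan,
                             tested=False, degenerate=False))
            continue
        res = wilcoxon_signed_rank_paired(exp.loc[subunits].to_numpy(),
                                          ctrl.loc[subunits].to_numpy(),
                                          alternative=alternative)
        rows.append(dict(complex_id=cid, n=n, W=res.statistic, p_raw=res.pvalue,
                         tested=True, degenerate=res.degenerate))
    calls = pd.DataFrame(rows, columns=["complex_id", "n", "W", "p_raw",
                                        "tested", "degenerate"])
    calls["p_adj"] = np.nan
    tested = calls["tested"]
    if tested.any():
        calls.loc[tested, "p_adj"] = bh_adjust(calls.loc[tested, "p_raw"], q=q)
    else:
        logger.warning("no complex reaches n_min=%d quantified subunits", n_min)
    calls["significant"] = (calls["p_adj"] < q).fillna(False)
    return calls


def call_unstable_complexes(epd_exp, epd_ctrl, compendium: ComplexCompendium,
                            n_min: int = 5, q: float = 0.05) -> pd.DataFrame:
    """Call complexes whose subunit EPDs exceed the same-species control.

    One-sided alternative "experimental > control"; BH across all testable
    complexes in this comparison set.  ``unstable`` flags adjusted p < q.
    """
    calls = paired_complex_test(epd_exp, epd_ctrl, compendium, n_min=n_min,
                                q=q, alternative="greater")
    calls = calls.rename(columns={"significant": "unstable"})
    return calls


def call_unstable_excluding_replaced(epd_exp, epd_ctrl,
                                     compendium: ComplexCompendium,
                                     annot: pd.DataFrame, replaced,
                                     n_min: int = 5, q: float = 0.05) -> pd.DataFrame:
    """Robustness re-analysis: drop replaced-chromosome subunits before testing."""
    rep = _replaced_set(replaced)
    chrom = protein_chromosome_map(annot)
    members = {
        cid: frozenset(p for p in ms if chrom.get(p) not in rep)
        for cid, ms in compendium.members.items()
    }
    calls = paired_complex_test(epd_exp, epd_ctrl, compendium, n_min=n_min,
                                q=q, alternative="greater",
                                members_override=members)
    return calls.rename(columns={"significant": "unstable"})


# ---------------------------------------------------------------------------
# Group comparisons (Kruskal-Wallis + Dunn)
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    groups: list
    H: float
    df: int
    pvalue: float
    pairwise: pd.DataFrame | None = None


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis H test (tie-corrected) across labeled value sets."""
    names = list(groups)
    if len(names) < 2:
        raise StabilityError("need >=2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise StabilityError(f"group {g!r} has <2 values")
    if np.unique(np.concatenate(arrays)).size == 1:
        # zero tie-correction denominator: the statistic is undefined
        raise StabilityError("degenerate Kruskal-Wallis input: all values identical")
    H, p = stats.kruskal(*arrays)
    if not np.isfinite(H):
        raise StabilityError("degenerate Kruskal-Wallis input")
    return GroupTestResult(groups=names, H=float(H), df=len(names) - 1,
                           pvalue=float(p))


def dunn_pairwise(groups: Mapping[str, Sequence[float]],
                  correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled ranks, tie-corrected.

    Returns one row per group pair with the z statistic, raw two-sided normal
    p, and Bonferroni-adjusted p (multiplier = number of pairs).
    """
    if correction not in ("bonferroni", "none"):
        raise StabilityError(f"unsupported correction {correction!r}")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise StabilityError(f"group {g!r} has <2 values")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for g, a in zip(names, arrays):
        mean_ranks[g] = float(ranks[pos:pos + a.size].mean())
        sizes[g] = a.size
        pos += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts ** 3 - counts).sum())
    A = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        se = np.sqrt(A * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        if se == 0:
            raise StabilityError("zero rank variance (all values identical)")
        z = (mean_ranks[ga] - mean_ranks[gb]) / se
        p_raw = float(min(1.0, 2 * stats.norm.sf(abs(z))))
        p_adj = p_raw if correction == "none" else float(min(1.0, p_raw * n_pairs))
        rows.append(dict(group_a=ga, group_b=gb, z=float(z),
                         p_raw=p_raw, p_adj=p_adj))
    return pd.DataFrame(rows)


def compact_letter_display(pairwise: pd.DataFrame, groups: Sequence[str],
                           alpha: float = 0.05) -> dict[str, str]:
    """Assign shared letters to groups that are not significantly different.

    Groups sharing at least one letter are statistically indistinguishable at
    ``alpha`` (on the adjusted p).  Letters come from maximal cliques of the
    non-significance graph, feasible exhaustively for the handful of groups
    compared here.
    """
    groups = list(groups)
    nonsig = {frozenset((r.group_a, r.group_b))
              for r in pairwise.itertuples() if r.p_adj > alpha}

    def is_clique(subset):
        return all(frozenset(pair) in nonsig
                   for pair in itertools.combinations(subset, 2))

    cliques: list[tuple[str, ...]] = []
    for size in range(len(groups), 0, -1):
        for subset in itertools.combinations(groups, size):
            if is_clique(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


# ---------------------------------------------------------------------------
# Enrichment of replaced-chromosome subunits among destabilized complexes
# ---------------------------------------------------------------------------

def enrichment_fisher(calls: pd.DataFrame, compendium: ComplexCompendium,
                      annot: pd.DataFrame, replaced,
                      call_column: str = "unstable"):
    """One-sided Fisher exact test on {unstable, stable} x {chr-subunit, not}.

    Tests whether destabilized complexes are enriched for complexes containing
    a replaced-chromosome subunit.  Returns (odds_ratio, p, table).
    """
    from .annotation import complexes_on_chromosomes

    tested = calls.loc[calls["tested"]] if "tested" in calls.columns else calls
    if tested.empty:
        raise StabilityError("no tested complexes")
    chr_cplx = complexes_on_chromosomes(compendium, annot, replaced)
    has_chr = tested["complex_id"].isin(chr_cplx)
    unstable = tested[call_column].astype(bool)
    table = np.array([
        [int((unstable & has_chr).sum()), int((unstable & ~has_chr).sum())],
        [int((~unstable & has_chr).sum()), int((~unstable & ~has_chr).sum())],
    ])
    if table[0].sum() == 0 or table[1].sum() == 0 or \
            table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return np.nan, 1.0, table  # degenerate margin
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p), table
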