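"""Soluble-abundance analysis from SILAC ratios and protein-transcript coupling.

The per-protein SILAC ratio is log2(sum light / sum heavy) over the
concentration-corrected fractions; in the experimental mixes the light channel
is the replacement line, so ratios below the control's indicate reduced
soluble abundance.  Complex-level abundance reduction reuses the paired
signed-rank machinery of :mod:`chimeracomplex.stability` with the one-sided
alternative "experimental < control".

Group-wise protein-transcript coupling is quantified by Spearman correlations
between SILAC ratios and transcript log2 fold-changes, and correlations are
compared across disjoint protein groups with Fisher's r-to-z statistic

    z = (atanh(r_A) - atanh(r_B)) / sqrt(1/(n_A-3) + 1/(n_B-3)).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ComplexCompendium, protein_gene_map
from .cofractionation import HEAVY, LIGHT, TIDY_COLUMNS
from .stability import StabilityError, paired_complex_test

logger = logging.getLogger(__name__)


def summarize_ratios(table: pd.DataFrame, comparison_set: str | None = None) -> pd.DataFrame:
    """One log2(light/heavy) ratio per protein from a tidy intensity table.

    The table should already be concentration-corrected.  Proteins with a zero
    total in either channel are excluded with a logged reason.
    """
    missing = set(TIDY_COLUMNS) - set(table.columns)
    if missing:
        raise StabilityError(f"intensity table missing columns: {sorted(missing)}")
    totals = table.groupby(["protein_id", "channel"])["intensity"].sum().unstack(
        "channel", fill_value=0.0)
    for ch in (HEAVY, LIGHT):
        if ch not in totals.columns:
            totals[ch] = 0.0
    ok = (totals[HEAVY] > 0) & (totals[LIGHT] > 0)
    dropped = totals.index[~ok]
    if len(dropped):
        logger.info("excluded %d proteins lacking signal in one channel", len(dropped))
    totals = totals.loc[ok]
    out = pd.DataFrame({
        "protein_id": totals.index,
        "log2_ratio": np.log2(totals[LIGHT].to_numpy() / totals[HEAVY].to_numpy()),
    }).set_index("protein_id", drop=False)
    out.index.name = None
    if comparison_set is not None:
        out["comparison_set"] = comparison_set
    return out


def complex_abundance_test(ratios_exp, ratios_ctrl, compendium: ComplexCompendium,
                           n_min: int = 5, q: float = 0.05) -> pd.DataFrame:
    """Call complexes with reduced soluble abundance (exp ratios < control)."""
    calls = paired_complex_test(ratios_exp, ratios_ctrl, compendium,
                                n_min=n_min, q=q, alternative="less")
    return calls.rename(columns={"significant": "reduced"})


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-rank ties; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StabilityError("vectors differ in length")
    if x.size < 3:
        raise StabilityError("need >=3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise StabilityError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def fisher_r_to_z(rho_a: float, n_a: int, rho_b: float, n_b: int):
    """Compare two independent correlation coefficients; returns (z, p)."""
    for rho in (rho_a, rho_b):
        if abs(rho) >= 1:
            raise StabilityError("|rho| must be < 1 for the z transform")
    if min(n_a, n_b) < 4:
        raise StabilityError("need n >= 4 in both groups")
    z = (np.arctanh(rho_a) - np.arctanh(rho_b)) / np.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return float(z), p


def protein_transcript_correlation(ratios, transcript_fc: pd.Series,
                                   groups: pd.Series, annot: pd.DataFrame,
                                   min_n: int = 4):
    """Per-group Spearman rho between protein ratios and transcript log2FC.

    ``ratios`` is a Series (or summarize_ratios frame) indexed by protein_id;
    ``transcript_fc`` a Series indexed by gene_id; ``groups`` a protein_id ->
    group label Series.  Returns (per-group frame, pairwise r-to-z frame).
    Groups with fewer than ``min_n`` paired observations are skipped with a
    warning.
    """
    if isinstance(ratios, pd.DataFrame):
        ratios = ratios.set_index("protein_id")["log2_ratio"] \
            if "protein_id" in ratios.columns else ratios["log2_ratio"]
    gene_of = protein_gene_map(annot)
    paired = pd.DataFrame({"ratio": ratios})
    paired["gene_id"] = gene_of.reindex(paired.index)
    paired["transcript"] = transcript_fc.reindex(paired["gene_id"]).to_numpy()
    paired["group"] = groups.reindex(paired.index)
    paired = paired.dropna(subset=["transcript", "group", "ratio"])

    per_group = []
    for g, sub in paired.groupby("group"):
        if len(sub) < min_n:
            logger.warning("group %s has n=%d < %d; skipped", g, len(sub), min_n)
            continue
        per_group.append(dict(group=g, n=len(sub),
                              rho=spearman(sub["ratio"], sub["transcript"])))
    rho_df = pd.DataFrame(per_group, columns=["group", "n", "rho"])

    comparisons = []
    for a, b in itertools.combinations(rho_df["group"], 2):
        ra = rho_df.set_index("group").loc[a]
        rb = rho_df.set_index("group").loc[b]
        if ra["rho"] == rb["rho"]:  # equal correlations need no transform
            z, p = 0.0, 1.0
        else:
            try:
                z, p = fisher_r_to_z(ra["rho"], int(ra["n"]),
                                     rb["rho"], int(rb["n"]))
            except StabilityError as exc:
                logger.warning("skipping %s vs %s: %s", a, b, exc)
                continue
        comparisons.append(dict(group_a=a, group_b=b, rho_a=ra["rho"],
                                rho_b=rb["rho"], n_a=int(ra["n"]),
                                n_b=int(rb["n"]), z=z, p=p))
    cmp_df = pd.DataFrame(comparisons, columns=["group_a", "group_b", "rho_a",
                                                "rho_b", "n_a", "n_b", "z", "p"])
    return rho_df, cmp_df
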