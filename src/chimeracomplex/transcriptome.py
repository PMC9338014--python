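"""Differential-expression classification and stress-signature correlation.

Per-line fold-change tables (log2FC of a replacement line vs the parent, with
an adjusted p per gene) are consumed as computed upstream.  A gene is
differentially expressed in a line when its linear fold-change exceeds 1.5 in
either direction with adjusted p < 0.05.  Genes on a line's replaced
chromosomes are masked for that line.  Common-response genes are those DE in
the same direction in at least four lines with no opposite-direction call;
genes DE in at least four lines with mixed directions are excluded as
bidirectional.

The environmental stress response (ESR) signature is quantified by Spearman
correlation between the median log2FC of ESR genes across lines and each
stress condition's ESR expression profile.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import _replaced_set
from .abundance import spearman
from .stability import StabilityError

logger = logging.getLogger(__name__)

UP, DOWN, NS, MASKED = "up", "down", "ns", "masked"
COMMON_UP, COMMON_DOWN = "common_up", "common_down"
EXCLUDED_BIDIRECTIONAL, NOT_COMMON = "excluded_bidirectional", "not_common"

LONG_COLUMNS = ["gene_id", "line", "log2fc", "padj"]


def classify_de(log2fc, padj, fold_change: float = 1.5,
                alpha: float = 0.05):
    """Classify log2 fold-change + adjusted p into up / down / ns.

    The threshold applies on the linear scale: up when 2^log2fc > fold_change,
    down when 2^log2fc < 1/fold_change, both requiring padj < alpha.  Missing
    values yield ns.  Accepts scalars or aligned arrays/Series.
    """
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(padj, dtype=float)
    thr = np.log2(fold_change)
    ok = ~(np.isnan(fc) | np.isnan(p))
    status = np.full(fc.shape, NS, dtype=object)
    status[ok & (fc > thr) & (p < alpha)] = UP
    status[ok & (fc < -thr) & (p < alpha)] = DOWN
    if status.shape == ():
        return str(status)
    return status


def de_status_matrix(fc_long: pd.DataFrame, annot: pd.DataFrame | None = None,
                     replaced_by_line: Mapping[str, set] | None = None,
                     fold_change: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Gene x line matrix of DE statuses with replaced-chromosome masking.

    ``fc_long`` has columns gene_id, line, log2fc, padj.  When annotation and
    per-line replaced chromosome sets are supplied, each gene on a line's
    replaced chromosomes gets status ``masked`` for that line and never
    contributes a DE call.
    """
    missing = set(LONG_COLUMNS) - set(fc_long.columns)
    if missing:
        raise StabilityError(f"fold-change table missing columns: {sorted(missing)}")
    status = pd.Series(
        classify_de(fc_long["log2fc"], fc_long["padj"],
                    fold_change=fold_change, alpha=alpha),
        index=fc_long.index)
    mat = (pd.DataFrame({"gene_id": fc_long["gene_id"], "line": fc_long["line"],
                         "status": status})
           .pivot_table(index="gene_id", columns="line", values="status",
                        aggfunc="first"))
    mat = mat.fillna(NS)
    if annot is not None and replaced_by_line:
        gene_chrom = annot.set_index("gene_id")["chromosome"]
        for line, replaced in replaced_by_line.items():
            if line not in mat.columns:
                continue
            rep = _replaced_set(replaced)
            on_rep = gene_chrom.reindex(mat.index).isin(rep)
            mat.loc[on_rep.fillna(False), line] = MASKED
    return mat


def common_response(status: pd.DataFrame, k: int = 4) -> pd.Series:
    """Classify each gene's cross-line response pattern.

    common_up: up in >= k lines and down in none; common_down symmetric;
    excluded_bidirectional: DE in >= k lines with both directions present;
    not_common otherwise.  Any opposite-direction call disqualifies "common"
    status regardless of count (strict purity).
    """
    n_up = (status == UP).sum(axis=1)
    n_down = (status == DOWN).sum(axis=1)
    out = pd.Series(NOT_COMMON, index=status.index, name="response_class")
    out[(n_up >= k) & (n_down == 0)] = COMMON_UP
    out[(n_down >= k) & (n_up == 0)] = COMMON_DOWN
    out[(n_up + n_down >= k) & (n_up > 0) & (n_down > 0)] = EXCLUDED_BIDIRECTIONAL
    return out


def median_fold_change(fc_long: pd.DataFrame) -> pd.Series:
    """Median log2FC per gene across replacement lines (NaN-aware)."""
    return fc_long.groupby("gene_id")["log2fc"].median()


def esr_correlation(fc_long: pd.DataFrame, esr_profiles: pd.DataFrame,
                    min_overlap: int = 10) -> pd.Series:
    """Spearman rho between median ESR-gene log2FC and each stress profile.

    ``esr_profiles`` is a gene x condition frame of ESR expression responses
    under reference stresses.  Errors when fewer than ``min_overlap`` ESR
    genes are shared with the fold-change table.
    """
    med = median_fold_change(fc_long)
    shared = esr_profiles.index.intersection(med.dropna().index)
    if len(shared) < min_overlap:
        raise StabilityError(
            f"only {len(shared)} shared ESR genes (< {min_overlap})")
    med = med.loc[shared]
    out = {}
    for cond in esr_profiles.columns:
        out[cond] = spearman(med.to_numpy(), esr_profiles.loc[shared, cond].to_numpy())
    return pd.Series(out, name="rho")
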