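"""Elution patterns and the elution pattern difference (EPD) statistic.

A co-fractionation run separates native protein assemblies over a
size-exclusion column; each protein's per-fraction MS intensity in the heavy
(reference) and light (experimental) SILAC channel is recorded.  After pooling
raw fractions in triples (81 -> 27), correcting intensities by per-fraction
peptide concentration, and normalizing each channel to percentages that sum to
100 (the *elution pattern*), the EPD of a protein is the L1 distance between
its heavy and light patterns:

    EPD = sum_{f=1}^{27} |p_f(heavy) - p_f(light)|

EPD is 0 when the two channels co-elute identically and reaches 200 when the
patterns have disjoint support.  Because patterns are percentages, EPD is
invariant to rescaling either channel's total intensity.

Intensity tables are tidy DataFrames with columns
``protein_id, channel, fraction, intensity`` (1-based fraction index; missing
entries mean "not detected" and are treated as 0 before normalization).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEAVY = "heavy"
LIGHT = "light"
TIDY_COLUMNS = ["protein_id", "channel", "fraction", "intensity"]


class CofractionationError(ValueError):
    pass


def _check_tidy(table: pd.DataFrame) -> None:
    missing = set(TIDY_COLUMNS) - set(table.columns)
    if missing:
        raise CofractionationError(f"intensity table missing columns: {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise CofractionationError("negative intensities present")


def read_intensity_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"protein_id": str, "channel": str})
    _check_tidy(table)
    table["fraction"] = table["fraction"].astype(int)
    return table


def read_concentration_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"fraction", "concentration"} <= set(df.columns):
        raise CofractionationError("concentration table needs fraction, concentration")
    return df.set_index(df["fraction"].astype(int))["concentration"].astype(float)


def pool_fractions(table: pd.DataFrame, width: int = 3) -> pd.DataFrame:
    """Sum every ``width`` sequential fractions into one pooled fraction.

    Fraction indices must be 1-based and the maximum index divisible by
    ``width``.  Total intensity per (protein, channel) is conserved exactly.
    """
    _check_tidy(table)
    if table.empty:
        return table.copy()
    fmax = int(table["fraction"].max())
    if table["fraction"].min() < 1:
        raise CofractionationError("fraction indices must start at 1")
    if fmax % width != 0:
        raise CofractionationError(f"F={fmax} not divisible by pooling width {width}")
    pooled = table.copy()
    pooled["fraction"] = (pooled["fraction"] - 1) // width + 1
    pooled = (pooled.groupby(["protein_id", "channel", "fraction"], sort=True,
                             as_index=False)["intensity"].sum())
    return pooled[TIDY_COLUMNS]


def concentration_correct(table: pd.DataFrame, conc: pd.Series) -> pd.DataFrame:
    """Multiply intensities by the peptide concentration of their fraction."""
    _check_tidy(table)
    conc = pd.Series(conc).astype(float)
    occupied = set(table["fraction"].unique())
    missing = occupied - set(conc.index)
    if missing:
        raise CofractionationError(f"no concentration for fractions {sorted(missing)}")
    if (conc.loc[sorted(occupied)] <= 0).any():
        raise CofractionationError("concentrations must be positive")
    out = table.copy()
    out["intensity"] = out["intensity"].to_numpy() * conc.loc[out["fraction"]].to_numpy()
    return out


def to_matrix(table: pd.DataFrame, n_fractions: int | None = None) -> pd.DataFrame:
    """Pivot a tidy table to a (protein_id, channel) x fraction matrix.

    Undetected (protein, channel, fraction) combinations become 0.
    """
    _check_tidy(table)
    if n_fractions is None:
        n_fractions = int(table["fraction"].max()) if len(table) else 0
    mat = table.pivot_table(index=["protein_id", "channel"], columns="fraction",
                            values="intensity", aggfunc="sum", fill_value=0.0)
    mat = mat.reindex(columns=range(1, n_fractions + 1), fill_value=0.0)
    mat.columns.name = "fraction"
    return mat.astype(float)


def normalize_pattern(table: pd.DataFrame, n_fractions: int | None = None,
                      min_detected: int = 1) -> pd.DataFrame:
    """Convert intensities into elution patterns (percentages summing to 100).

    Each (protein, channel) row is divided by its own total and scaled to
    percent.  Rows with zero total, or detected in fewer than ``min_detected``
    fractions, cannot form a pattern and are dropped with a logged reason.
    """
    if set(TIDY_COLUMNS) <= set(table.columns):
        mat = to_matrix(table, n_fractions=n_fractions)
    else:  # already a (protein, channel) x fraction matrix
        mat = table.astype(float)
    totals = mat.sum(axis=1)
    detected = (mat > 0).sum(axis=1)
    bad = (totals <= 0) | (detected < min_detected)
    if bad.any():
        logger.info("dropping %d (protein, channel) rows with no usable signal",
                    int(bad.sum()))
    mat = mat.loc[~bad]
    pattern = mat.div(mat.sum(axis=1), axis=0) * 100.0
    return pattern


def epd(heavy, light) -> float:
    """L1 distance between two elution patterns on the same fraction grid."""
    h = np.asarray(heavy, dtype=float)
    l = np.asarray(light, dtype=float)
    if h.shape != l.shape:
        raise CofractionationError(f"fraction grids differ: {h.shape} vs {l.shape}")
    return float(np.abs(h - l).sum())


def pattern_difference(pattern: pd.DataFrame, protein_id: str) -> pd.Series:
    """Signed per-fraction differences d_f = heavy% - light% for one protein."""
    try:
        h = pattern.loc[(protein_id, HEAVY)]
        l = pattern.loc[(protein_id, LIGHT)]
    except KeyError as exc:
        raise CofractionationError(f"{protein_id} lacks a channel pattern") from exc
    return h - l


def epd_table(pattern: pd.DataFrame, comparison_set: str | None = None) -> pd.DataFrame:
    """Per-protein EPD from a pattern matrix holding both channels.

    Proteins quantified in only one channel are excluded (both patterns are
    required); their count is logged.  Returns a DataFrame with columns
    ``protein_id, epd`` (plus ``comparison_set`` when given), indexed by
    protein_id.
    """
    by_channel = {ch: pattern.xs(ch, level="channel")
                  for ch in pattern.index.get_level_values("channel").unique()}
    if HEAVY not in by_channel or LIGHT not in by_channel:
        shared = pd.Index([])
    else:
        shared = by_channel[HEAVY].index.intersection(by_channel[LIGHT].index)
    n_total = pattern.index.get_level_values("protein_id").nunique()
    if len(shared) < n_total:
        logger.info("excluded %d proteins quantified in a single channel",
                    n_total - len(shared))
    h = by_channel.get(HEAVY, pd.DataFrame()).reindex(shared)
    l = by_channel.get(LIGHT, pd.DataFrame()).reindex(shared)
    values = np.abs(h.to_numpy() - l.to_numpy()).sum(axis=1) if len(shared) else []
    out = pd.DataFrame({"protein_id": shared, "epd": values}).set_index(
        "protein_id", drop=False)
    out.index.name = None
    if comparison_set is not None:
        out["comparison_set"] = comparison_set
    return out


def epd_excluding_replaced(epd_df: pd.DataFrame, annot: pd.DataFrame,
                           replaced) -> pd.DataFrame:
    """Robustness re-analysis input: drop proteins encoded on replaced chromosomes."""
    from .annotation import protein_chromosome_map, _replaced_set

    rep = _replaced_set(replaced)
    chrom = protein_chromosome_map(annot)
    on_replaced = epd_df["protein_id"].map(chrom).isin(rep)
    return epd_df.loc[~on_replaced.fillna(False)].copy()
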