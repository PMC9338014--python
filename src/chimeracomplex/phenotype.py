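"""Growth, sporulation and aggregation phenotypes, and their coupling to
complex counts.

Doubling times come from sliding-window log-linear fits to OD curves read
every 10 minutes; the fitness defect of a line under a treatment is the
difference of doubling times (treated minus untreated).  Sporulation
sensitivity is 1 - (frequency with Hsp90-inhibitor pre-treatment / frequency
without).  Aggregation load is the percentage of cells with Hsp104 foci
(flagged when counted from fewer than 500 cells).  Each phenotype is
correlated across lines with the number of complexes having subunits on the
line's replaced chromosomes (Spearman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability import StabilityError

logger = logging.getLogger(__name__)


class PhenotypeError(ValueError):
    pass


@dataclass
class GrowthFit:
    mu_max: float            # per minute
    doubling_time: float     # minutes; inf when mu_max <= 0
    window_start: float      # minutes, start of the best window
    degenerate: bool = False


def max_growth_rate(time_min, od, window: int = 11, od_floor: float = 0.02,
                    blank: float = 0.0) -> GrowthFit:
    """Maximum specific growth rate from a sliding log-linear window.

    The slope of ln(OD - blank) vs time is fitted in every run of ``window``
    consecutive points whose OD exceeds ``od_floor``; mu_max is the largest
    slope, and the doubling time ln(2)/mu_max.  The default window of 11
    points (110 min at 10-min reads) keeps the max-over-windows estimator's
    upward bias below a few percent at 1% multiplicative OD noise; shorter
    windows track sharper growth transitions at the cost of noise.  A curve with no growing window
    (mu_max ~ 0) is returned with an infinite doubling time and a degenerate
    flag; no window above the floor at all is an error.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(od, dtype=float) - blank
    if t.size != y.size:
        raise PhenotypeError("time and OD differ in length")
    if np.any(np.diff(t) <= 0):
        raise PhenotypeError("time points must be strictly increasing")
    if window < 2 or t.size < window:
        raise PhenotypeError("window must be >=2 and <= number of points")
    best = -np.inf
    best_start = np.nan
    ok = y > od_floor
    logy = np.where(ok, np.log(np.where(ok, y, 1.0)), np.nan)
    for i in range(t.size - window + 1):
        if not ok[i:i + window].all():
            continue
        slope = np.polyfit(t[i:i + window], logy[i:i + window], 1)[0]
        if slope > best:
            best, best_start = slope, t[i]
    if not np.isfinite(best):
        raise PhenotypeError("no window of OD readings above the noise floor")
    if best <= 1e-12:
        return GrowthFit(mu_max=float(max(best, 0.0)), doubling_time=np.inf,
                         window_start=float(best_start), degenerate=True)
    return GrowthFit(mu_max=float(best), doubling_time=float(np.log(2) / best),
                     window_start=float(best_start))


def fitness_defect(dt_treated: float, dt_untreated: float) -> float:
    """Doubling-time difference (minutes); may be negative."""
    if not (np.isfinite(dt_treated) and np.isfinite(dt_untreated)):
        raise PhenotypeError("doubling times must be finite")
    return float(dt_treated - dt_untreated)


def sporulation_sensitivity(freq_gda: float, freq_ctrl: float) -> float:
    """1 - (sporulation frequency with pre-treatment / without)."""
    for f in (freq_gda, freq_ctrl):
        if not 0 <= f <= 1:
            raise PhenotypeError("frequencies must lie in [0, 1]")
    if freq_ctrl == 0:
        raise PhenotypeError("control sporulation frequency is zero")
    return float(1.0 - freq_gda / freq_ctrl)


def foci_percent(n_foci_cells: int, n_total: int, min_cells: int = 500):
    """Percentage of cells with aggregation foci; returns (percent, low_n_flag)."""
    if n_total < 1:
        raise PhenotypeError("need at least one counted cell")
    if n_foci_cells > n_total:
        raise PhenotypeError("more foci-positive cells than cells counted")
    if n_foci_cells < 0:
        raise PhenotypeError("negative count")
    low_n = n_total < min_cells
    if low_n:
        logger.warning("foci percentage from only %d cells (<%d)", n_total, min_cells)
    return 100.0 * n_foci_cells / n_total, low_n


def phenotype_complex_correlation(records: pd.DataFrame, phenotype_field: str,
                                  count_field: str = "complex_count",
                                  min_lines: int = 5):
    """Spearman correlation of a per-line phenotype with the complex count.

    Returns (rho, p).  Errors on a constant phenotype or fewer than
    ``min_lines`` lines.
    """
    for col in (phenotype_field, count_field):
        if col not in records.columns:
            raise PhenotypeError(f"records lack column {col!r}")
    sub = records[[count_field, phenotype_field]].dropna()
    if len(sub) < min_lines:
        raise PhenotypeError(f"need >= {min_lines} lines, got {len(sub)}")
    if sub[phenotype_field].nunique() == 1:
        raise PhenotypeError("phenotype is constant across lines")
    rho, p = stats.spearmanr(sub[count_field], sub[phenotype_field])
    return float(rho), float(p)


def one_sided_t(group_a, group_b, alternative: str = "greater",
                equal_var: bool = False):
    """One-sided t test of group A against group B (Welch by default).

    Returns (t, p).  Identical degenerate groups (zero variance, equal means)
    return p = 0.5 with t = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PhenotypeError("need n >= 2 per group")
    if alternative not in ("greater", "less"):
        raise PhenotypeError(f"bad alternative {alternative!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 0.5
    t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(t), float(p)
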