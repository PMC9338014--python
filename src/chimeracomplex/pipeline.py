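"""End-to-end orchestration: simulate (or load) inputs, compute elution
patterns and EPDs, call unstable and abundance-reduced complexes, classify the
transcriptome response, fit phenotypes, and emit a machine-readable summary.

Every stage is a pure function of its inputs plus the config; all randomness
flows from the single config seed through named substreams, so reruns with the
same config are identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import annotation as an
from . import cofractionation as cf
from . import phenotype as ph
from . import simulate as sim
from . import stability as st
from . import transcriptome as tr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run-level parameters wrapping a simulation config.

    ``q`` is the BH FDR level, ``n_min`` the minimum quantified subunits per
    testable complex, ``k_common`` the common-response line threshold and
    ``fold_change`` the linear DE threshold.
    """

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    q: float = 0.05
    n_min: int = 5
    k_common: int = 4
    fold_change: float = 1.5
    de_alpha: float = 0.05
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = sim.SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim_cfg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def process_cofractionation(table: pd.DataFrame, conc: pd.Series,
                            pre_pooled: bool, comparison_set: str):
    """Raw tidy intensities -> (EPD table, SILAC ratio table)."""
    if pre_pooled:
        table = cf.pool_fractions(table, width=3)
    corrected = cf.concentration_correct(table, conc)
    pattern = cf.normalize_pattern(corrected)
    epd_df = cf.epd_table(pattern, comparison_set=comparison_set)
    ratios = ab.summarize_ratios(corrected, comparison_set=comparison_set)
    return epd_df, ratios


def run_pipeline(config: RunConfig) -> dict:
    """Simulate all inputs, run every analysis stage, return a summary dict.

    When ``config.outdir`` is set, per-stage tables (TSV) and the summary
    (JSON) are written there.
    """
    cfg = config.sim
    summary: dict = {"seed": cfg.seed, "parameters": {
        "q": config.q, "n_min": config.n_min, "k_common": config.k_common,
        "fold_change": config.fold_change, "replaced": list(cfg.replaced)}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- synthetic inputs -------------------------------------------------
    annot, compendium = sim.simulate_annotation_and_compendium(cfg)
    cof = sim.simulate_cofractionation(annot, compendium, cfg)
    trs = sim.simulate_transcriptome(annot, cfg)
    phs = sim.simulate_phenotypes(annot, compendium, cfg)
    summary["n_genes"] = int(len(annot))
    summary["n_complexes"] = compendium.n_complexes
    summary["n_planted_unstable"] = int(cof.truth["planted_unstable"].sum())

    # --- co-fractionation -> EPD -----------------------------------------
    epd_exp, ratios_exp = process_cofractionation(
        cof.experimental, cof.concentrations, cfg.pre_pool, "experimental")
    epd_ctrl, ratios_ctrl = process_cofractionation(
        cof.control, cof.concentrations, cfg.pre_pool, "control")
    summary["n_proteins_epd_experimental"] = int(len(epd_exp))
    summary["n_proteins_epd_control"] = int(len(epd_ctrl))

    # --- stability calls --------------------------------------------------
    calls = st.call_unstable_complexes(epd_exp, epd_ctrl, compendium,
                                       n_min=config.n_min, q=config.q)
    truth = cof.truth.set_index("complex_id")
    merged = calls.set_index("complex_id").join(
        truth[["planted_unstable", "contains_replaced"]])
    called = merged.loc[merged["unstable"].fillna(False)]
    n_called = int(len(called))
    n_true = int(called["planted_unstable"].sum())
    n_planted_testable = int(
        (merged["tested"] & merged["planted_unstable"]).sum())
    summary["stability"] = {
        "n_testable": int(calls["tested"].sum()),
        "n_unstable_called": n_called,
        "n_true_positive": n_true,
        "false_discovery_proportion": (n_called - n_true) / n_called if n_called else 0.0,
        "recovery": n_true / n_planted_testable if n_planted_testable else np.nan,
    }
    calls_excl = st.call_unstable_excluding_replaced(
        epd_exp, epd_ctrl, compendium, annot, cfg.replaced,
        n_min=config.n_min, q=config.q)
    summary["stability"]["n_unstable_excluding_replaced"] = int(
        calls_excl["unstable"].sum())
    try:
        odds, p_enrich, table = st.enrichment_fisher(calls, compendium, annot,
                                                     cfg.replaced)
        summary["stability"]["enrichment_odds_ratio"] = (
            odds if np.isfinite(odds) else None)
        summary["stability"]["enrichment_p"] = p_enrich
    except st.StabilityError:
        summary["stability"]["enrichment_p"] = None

    # --- group comparisons (EPD by protein class) -------------------------
    quantified = epd_exp.index.intersection(epd_ctrl.index)
    groups_lab = an.assign_protein_groups(list(quantified), compendium, annot,
                                          cfg.replaced)
    epd_vals = epd_exp.loc[quantified, "epd"]
    group_values = {}
    complex_mask = groups_lab != an.NON_COMPLEX
    if complex_mask.sum() >= 2:
        group_values["complex"] = epd_vals[complex_mask.to_numpy()].to_numpy()
    for lab in (an.NON_COMPLEX, an.CHR_COMPLEX, an.NON_CHR_COMPLEX):
        vals = epd_vals[(groups_lab == lab).to_numpy()]
        if len(vals) >= 2:
            group_values[lab] = vals.to_numpy()
    summary["groups"] = {k: int(len(v)) for k, v in group_values.items()}
    if len(group_values) >= 2:
        try:
            kw = st.kruskal_wallis(group_values)
            dunn = st.dunn_pairwise(group_values)
            letters = st.compact_letter_display(dunn, list(group_values))
            summary["group_test"] = {"H": kw.H, "df": kw.df, "p": kw.pvalue,
                                     "letters": letters}
        except st.StabilityError as exc:
            summary["group_test"] = {"degenerate": str(exc)}
            dunn = None
    else:
        dunn = None

    # --- abundance --------------------------------------------------------
    ab_calls = ab.complex_abundance_test(ratios_exp, ratios_ctrl, compendium,
                                         n_min=config.n_min, q=config.q)
    summary["abundance"] = {
        "n_testable": int(ab_calls["tested"].sum()),
        "n_reduced_called": int(ab_calls["reduced"].sum()),
    }
    transcript_med = tr.median_fold_change(trs.fold_changes)
    try:
        rho_df, cmp_df = ab.protein_transcript_correlation(
            ratios_exp, transcript_med, groups_lab, annot)
        summary["abundance"]["protein_transcript_rho"] = {
            r.group: r.rho for r in rho_df.itertuples()}
    except st.StabilityError as exc:
        summary["abundance"]["protein_transcript_rho"] = None
        rho_df = cmp_df = None

    # --- transcriptome ----------------------------------------------------
    status = tr.de_status_matrix(trs.fold_changes, annot=annot,
                                 replaced_by_line=trs.lines,
                                 fold_change=config.fold_change,
                                 alpha=config.de_alpha)
    common = tr.common_response(status, k=config.k_common)
    class_counts = common.value_counts().to_dict()
    summary["transcriptome"] = {
        "n_common_up": int(class_counts.get(tr.COMMON_UP, 0)),
        "n_common_down": int(class_counts.get(tr.COMMON_DOWN, 0)),
        "n_excluded_bidirectional": int(class_counts.get(tr.EXCLUDED_BIDIRECTIONAL, 0)),
    }
    try:
        esr_rho = tr.esr_correlation(trs.fold_changes, trs.esr_profiles)
        summary["transcriptome"]["esr_rho_median"] = float(esr_rho.median())
    except st.StabilityError:
        summary["transcriptome"]["esr_rho_median"] = None

    # --- phenotypes -------------------------------------------------------
    fitted = []
    for (line, cond), grp in phs.growth.groupby(["line", "condition"]):
        fit = ph.max_growth_rate(grp["time_min"].to_numpy(), grp["od"].to_numpy())
        fitted.append(dict(line=line, condition=cond,
                           doubling_time_min=fit.doubling_time))
    fits = pd.DataFrame(fitted).pivot(index="line", columns="condition",
                                      values="doubling_time_min")
    records = phs.records.set_index("line")
    records["fitted_defect_min"] = fits["gda"] - fits["untreated"]
    records = records.reset_index()
    summary["phenotype"] = {}
    for fieldname in ("fitted_defect_min", "foci_percent",
                      "sporulation_sensitivity"):
        try:
            rho, p = ph.phenotype_complex_correlation(records, fieldname)
            summary["phenotype"][fieldname] = {"rho": rho, "p": p}
        except ph.PhenotypeError as exc:
            summary["phenotype"][fieldname] = {"degenerate": str(exc)}

    # --- outputs ----------------------------------------------------------
    if outdir:
        annot.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        compendium.membership_frame().to_csv(outdir / "compendium.tsv",
                                             sep="\t", index=False)
        epd_exp.to_csv(outdir / "epd_experimental.tsv", sep="\t", index=False)
        epd_ctrl.to_csv(outdir / "epd_control.tsv", sep="\t", index=False)
        calls.to_csv(outdir / "stability_calls.tsv", sep="\t", index=False)
        calls_excl.to_csv(outdir / "stability_calls_excluding_replaced.tsv",
                          sep="\t", index=False)
        ab_calls.to_csv(outdir / "abundance_calls.tsv", sep="\t", index=False)
        if dunn is not None:
            dunn.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        if cmp_df is not None:
            cmp_df.to_csv(outdir / "correlation_report.tsv", sep="\t", index=False)
        common.rename("response_class").to_csv(outdir / "common_response.tsv",
                                               sep="\t")
        records.to_csv(outdir / "phenotype_records.tsv", sep="\t", index=False)
        cof.truth.to_csv(outdir / "truth_complexes.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        default=float))
    return summary
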