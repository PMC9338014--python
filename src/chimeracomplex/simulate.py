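"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with known truth: a gene/protein
annotation over 16 chromosomes, a disjoint complex compendium, co-fractionation
SILAC intensity tables with planted destabilization (mixing-fraction loss) and
degradation (total-intensity loss) in complexes carrying replaced-chromosome
subunits, fold-change matrices with common-response and stress-signature
structure, and per-line phenotypes linearly coupled to complex counts.

Elution model: each complex elutes at a peak fraction determined by its size
(larger assemblies elute earlier on a size-exclusion column; the fixed
monotone map puts the largest complexes at fraction 3 and monomers at fraction
24).  A subunit's noiseless profile is a two-component Gaussian mixture,
``alpha * G(complex peak, sigma) + (1 - alpha) * G(monomer peak, sigma)``
discretized over the 27 fractions.  The reference (heavy) channel uses the
assembled fraction ``alpha_ref``; in planted-unstable complexes the light
channel's assembled fraction drops to ``alpha_ref * (1 - delta)`` and its
total is scaled by ``gamma``.  Multiplicative log-normal noise of a given CV
is applied per fraction, and intensities below the dropout threshold are set
to zero (intensity-dependent missingness).  The control comparison is two
independent noisy draws of the reference model.

All randomness flows from the single config seed through named per-stage
substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import ComplexCompendium, compendium_from_mapping
from .cofractionation import HEAVY, LIGHT, TIDY_COLUMNS

logger = logging.getLogger(__name__)

MONOMER_PEAK = 24
LARGEST_PEAK = 3
_SIZE_AT_LARGEST = 30  # complexes at or above this size elute at LARGEST_PEAK

_STAGES = {"annotation": 1, "lines": 2, "cofractionation": 3,
           "transcriptome": 4, "phenotype": 5}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All generator knobs; defaults emulate a scaled-down study design.

    27 fractions, 16 chromosomes, 11 replacement lines, a 1.5-fold DE
    threshold with common response in >= 4 lines, and a complex-count/
    phenotype coupling of the magnitude seen in hybrid replacement lines.
    """

    seed: int = 0
    # annotation / compendium
    n_genes: int = 2400
    n_chromosomes: int = 16
    n_complexes: int = 150
    complex_size_min: int = 2
    complex_size_max: int = 15
    complex_size_p: float = 0.35     # geometric decay of sizes above the minimum
    # co-fractionation
    n_fractions: int = 27
    pre_pool: bool = False           # emit 81 raw fractions instead of 27
    alpha_ref: float = 0.9           # assembled fraction in the reference channel
    delta: float = 0.7               # destabilization: light alpha = alpha_ref*(1-delta)
    gamma: float = 1.0               # degradation: light total scaled by gamma
    sigma: float = 1.2               # elution peak spread (fractions)
    noise_cv: float = 0.2            # log-normal multiplicative noise CV
    base_intensity: float = 1e6
    intensity_sigma: float = 1.0     # log-sd of per-protein abundance
    dropout_threshold: float = 1e3
    replaced: tuple = (16,)
    planted_fraction: float = 0.3    # fraction of chr-complexes planted unstable
    n_planted: int | None = None     # exact planted count (overrides fraction)
    planted_min_size: int = 2
    conc_log_sd: float = 0.2         # per-fraction peptide-concentration spread
    # transcriptome
    n_lines: int = 11
    lines: Mapping[str, tuple] | None = None
    fc_null_sd: float = 0.3
    common_effect: float = 1.0       # log2FC added to planted common-response genes
    n_common_up: int = 40
    n_common_down: int = 40
    common_min_lines: int = 4
    n_esr: int = 150
    esr_loading_sd: float = 0.3
    stress_intensity_low: float = 0.3
    stress_intensity_high: float = 1.0
    n_stress_conditions: int = 6
    esr_profile_noise: float = 0.2
    # phenotype
    phen_slope: float = 0.6          # minutes of fitness defect per complex
    phen_noise_sd: float = 10.0      # minutes
    base_doubling_min: float = 90.0
    growth_od0: float = 0.05
    growth_noise_cv: float = 0.01
    growth_hours: float = 16.0

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def validate(self) -> None:
        for name in ("alpha_ref", "delta", "planted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if not 0 < self.gamma <= 1:
            raise SimulationError(f"gamma={self.gamma} outside (0, 1]")
        if self.complex_size_min < 2:
            raise SimulationError("complex_size_min must be >= 2")
        if self.n_complexes * self.complex_size_max > self.n_genes:
            raise SimulationError(
                f"{self.n_complexes} complexes of up to {self.complex_size_max} "
                f"subunits cannot be drawn disjointly from {self.n_genes} genes")


def stage_rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    """Named substream of the config seed for one pipeline stage."""
    return np.random.default_rng([int(cfg.seed) % (2 ** 31), _STAGES[stage]])


# ---------------------------------------------------------------------------
# Annotation and compendium
# ---------------------------------------------------------------------------

def simulate_annotation_and_compendium(cfg: SimulationConfig):
    """Uniform gene->chromosome annotation plus a disjoint complex compendium."""
    cfg.validate()
    rng = stage_rng(cfg, "annotation")
    width = len(str(cfg.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    proteins = [f"P{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    chroms = rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_genes)
    annot = pd.DataFrame({"gene_id": genes, "protein_id": proteins,
                          "chromosome": chroms})
    span = cfg.complex_size_max - cfg.complex_size_min
    sizes = cfg.complex_size_min + np.minimum(
        rng.geometric(cfg.complex_size_p, size=cfg.n_complexes) - 1, span)
    order = rng.permutation(cfg.n_genes)
    members: dict[str, frozenset] = {}
    pos = 0
    for i, s in enumerate(sizes, start=1):
        members[f"C{i:03d}"] = frozenset(proteins[j] for j in order[pos:pos + s])
        pos += s
    compendium = compendium_from_mapping(members)
    return annot, compendium


def generate_lines(cfg: SimulationConfig) -> dict[str, tuple]:
    """Replacement-line definitions: each line replaces one or two chromosomes."""
    if cfg.lines is not None:
        return {name: tuple(reps) for name, reps in cfg.lines.items()}
    rng = stage_rng(cfg, "lines")
    lines: dict[str, tuple] = {}
    while len(lines) < cfg.n_lines:
        k = int(rng.integers(1, 3))
        reps = tuple(sorted(rng.choice(cfg.n_chromosomes, size=k, replace=False) + 1))
        name = "+".join(str(c) for c in reps) + "L"
        if name not in lines:
            lines[name] = reps
    return lines


# ---------------------------------------------------------------------------
# Co-fractionation
# ---------------------------------------------------------------------------

def peak_fraction(size: int) -> int:
    """Fixed monotone size -> SEC peak map (monomer 24, largest complexes 3)."""
    s = min(max(int(size), 1), _SIZE_AT_LARGEST)
    peak = MONOMER_PEAK - (MONOMER_PEAK - LARGEST_PEAK) * (s - 1) / (_SIZE_AT_LARGEST - 1)
    return int(np.clip(round(peak), LARGEST_PEAK, MONOMER_PEAK))


def _gaussian_profiles(n_fractions: int, sigma: float) -> np.ndarray:
    """Row p-1 = discretized unit-mass Gaussian centered at fraction p."""
    grid = np.arange(1, n_fractions + 1, dtype=float)
    peaks = grid[:, None]
    if sigma < 1e-9:
        mat = (np.abs(grid[None, :] - peaks) < 0.5).astype(float)
    else:
        mat = np.exp(-0.5 * ((grid[None, :] - peaks) / sigma) ** 2)
    return mat / mat.sum(axis=1, keepdims=True)


@dataclass
class CofractionationSim:
    experimental: pd.DataFrame   # tidy intensity table, heavy + light
    control: pd.DataFrame        # two independent reference draws
    concentrations: pd.Series    # per (pooled) fraction peptide concentration
    truth: pd.DataFrame          # per-complex planted flags and effects
    annot: pd.DataFrame = None
    compendium: ComplexCompendium = None


def simulate_cofractionation(annot: pd.DataFrame, compendium: ComplexCompendium,
                             cfg: SimulationConfig) -> CofractionationSim:
    cfg.validate()
    rng = stage_rng(cfg, "cofractionation")
    proteins = list(annot["protein_id"])
    index = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)

    # per-protein complex membership (disjoint by construction)
    complex_of = np.full(n, -1)
    cids = sorted(compendium.members)
    for ci, cid in enumerate(cids):
        for p in compendium.members[cid]:
            complex_of[index[p]] = ci

    chrom = annot.set_index("protein_id")["chromosome"]
    rep = set(int(c) for c in cfg.replaced)
    contains_replaced = np.array([
        any(int(chrom[p]) in rep for p in compendium.members[cid]) for cid in cids])
    sizes = np.array([len(compendium.members[cid]) for cid in cids])

    eligible = np.flatnonzero(contains_replaced & (sizes >= cfg.planted_min_size)
                              & (sizes >= 2))
    planted = np.zeros(len(cids), dtype=bool)
    if cfg.delta > 0 or cfg.gamma < 1:
        if cfg.n_planted is not None:
            if len(eligible) < cfg.n_planted:
                raise SimulationError(
                    f"only {len(eligible)} eligible complexes for "
                    f"{cfg.n_planted} planted effects")
            planted[rng.choice(eligible, size=cfg.n_planted, replace=False)] = True
        elif len(eligible):
            planted[eligible] = rng.random(len(eligible)) < cfg.planted_fraction

    truth = pd.DataFrame({
        "complex_id": cids,
        "n_subunits": sizes,
        "contains_replaced": contains_replaced,
        "planted_unstable": planted,
        "delta": np.where(planted, cfg.delta, 0.0),
        "gamma": np.where(planted, cfg.gamma, 1.0),
    })

    F = 81 if cfg.pre_pool else cfg.n_fractions
    if cfg.pre_pool:
        gauss = _gaussian_profiles(F, 3.0 * cfg.sigma)

        def comp_vec(peak27):
            return gauss[3 * peak27 - 2]  # pooled fraction k <- raw 3k-1 center
    else:
        gauss = _gaussian_profiles(F, cfg.sigma)

        def comp_vec(peak27):
            return gauss[peak27 - 1]

    monomer = comp_vec(MONOMER_PEAK)
    comp_peaks = np.array([peak_fraction(s) for s in sizes])

    abundance = cfg.base_intensity * rng.lognormal(0.0, cfg.intensity_sigma, size=n)

    def noiseless(alpha_per_protein: np.ndarray, scale: np.ndarray) -> np.ndarray:
        prof = np.tile(monomer, (n, 1)) * (1.0 - alpha_per_protein)[:, None]
        in_complex = complex_of >= 0
        if in_complex.any():
            peaks = comp_peaks[complex_of[in_complex]]
            prof[in_complex] += (alpha_per_protein[in_complex, None]
                                 * gauss[(3 * peaks - 2 if cfg.pre_pool else peaks - 1)])
        return prof * (abundance * scale)[:, None]

    def noisy(profile: np.ndarray) -> np.ndarray:
        if cfg.noise_cv > 0:
            s = np.sqrt(np.log1p(cfg.noise_cv ** 2))
            profile = profile * rng.lognormal(-0.5 * s * s, s, size=profile.shape)
        if cfg.dropout_threshold > 0:
            profile = np.where(profile < cfg.dropout_threshold, 0.0, profile)
        return profile

    alpha_ref = np.where(complex_of >= 0, cfg.alpha_ref, 0.0)
    alpha_light = alpha_ref.copy()
    scale_light = np.ones(n)
    planted_protein = (complex_of >= 0) & planted[np.clip(complex_of, 0, None)]
    alpha_light[planted_protein] = cfg.alpha_ref * (1.0 - cfg.delta)
    scale_light[planted_protein] = cfg.gamma

    ones = np.ones(n)
    channels = {
        ("experimental", HEAVY): noisy(noiseless(alpha_ref, ones)),
        ("experimental", LIGHT): noisy(noiseless(alpha_light, scale_light)),
        ("control", HEAVY): noisy(noiseless(alpha_ref, ones)),
        ("control", LIGHT): noisy(noiseless(alpha_ref, ones)),
    }

    conc = pd.Series(
        rng.lognormal(0.0, cfg.conc_log_sd, size=cfg.n_fractions),
        index=pd.Index(range(1, cfg.n_fractions + 1), name="fraction"),
        name="concentration")
    if cfg.pre_pool:
        conc_div = np.repeat(conc.to_numpy(), 3)  # raw fraction shares its pool's c_f
    else:
        conc_div = conc.to_numpy()

    def tidy(mat: np.ndarray, channel: str) -> pd.DataFrame:
        raw = mat / conc_div[None, :]  # emitted as measured; correction restores
        prot_idx, frac_idx = np.nonzero(raw)
        return pd.DataFrame({
            "protein_id": np.array(proteins, dtype=object)[prot_idx],
            "channel": channel,
            "fraction": frac_idx + 1,
            "intensity": raw[prot_idx, frac_idx],
        })

    experimental = pd.concat([tidy(channels[("experimental", HEAVY)], HEAVY),
                              tidy(channels[("experimental", LIGHT)], LIGHT)],
                             ignore_index=True)[TIDY_COLUMNS]
    control = pd.concat([tidy(channels[("control", HEAVY)], HEAVY),
                         tidy(channels[("control", LIGHT)], LIGHT)],
                        ignore_index=True)[TIDY_COLUMNS]
    return CofractionationSim(experimental=experimental, control=control,
                              concentrations=conc, truth=truth,
                              annot=annot, compendium=compendium)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeSim:
    fold_changes: pd.DataFrame    # gene_id, line, log2fc, padj (masked -> NaN)
    esr_profiles: pd.DataFrame    # ESR gene x stress condition expected log2FC
    truth: pd.DataFrame           # gene_id, planted_class
    lines: dict = field(default_factory=dict)


def simulate_transcriptome(annot: pd.DataFrame, cfg: SimulationConfig) -> TranscriptomeSim:
    from statsmodels.stats.multitest import multipletests

    cfg.validate()
    rng = stage_rng(cfg, "transcriptome")
    lines = generate_lines(cfg)
    genes = list(annot["gene_id"])
    gene_chrom = annot.set_index("gene_id")["chromosome"]
    n, L = len(genes), len(lines)
    line_names = list(lines)

    n_special = cfg.n_common_up + cfg.n_common_down + cfg.n_esr
    if n_special > n:
        raise SimulationError("more planted genes than genes available")
    special = rng.choice(n, size=n_special, replace=False)
    up_idx = special[:cfg.n_common_up]
    down_idx = special[cfg.n_common_up:cfg.n_common_up + cfg.n_common_down]
    esr_idx = special[cfg.n_common_up + cfg.n_common_down:]

    effects = np.zeros((n, L))
    for idx, sign in ((up_idx, 1.0), (down_idx, -1.0)):
        for g in idx:
            m = int(rng.integers(cfg.common_min_lines, L + 1))
            cols = rng.choice(L, size=m, replace=False)
            effects[g, cols] += sign * cfg.common_effect

    loadings = np.zeros(n)
    if cfg.n_esr:
        signs = np.where(np.arange(len(esr_idx)) % 2 == 0, 1.0, -1.0)
        loadings[esr_idx] = signs * np.abs(rng.normal(1.0, cfg.esr_loading_sd,
                                                      size=len(esr_idx)))
        theta = rng.uniform(cfg.stress_intensity_low, cfg.stress_intensity_high,
                            size=L)
        effects += loadings[:, None] * theta[None, :]

    observed = effects + rng.normal(0.0, cfg.fc_null_sd, size=(n, L))
    z = observed / cfg.fc_null_sd
    from scipy import stats as _st
    pvals = 2.0 * _st.norm.sf(np.abs(z))

    mask = np.zeros((n, L), dtype=bool)
    for j, name in enumerate(line_names):
        rep = set(int(c) for c in lines[name])
        mask[:, j] = gene_chrom.loc[genes].isin(rep).to_numpy()

    rows = []
    for j, name in enumerate(line_names):
        keep = ~mask[:, j]
        padj = np.full(n, np.nan)
        if keep.any():
            padj[keep] = multipletests(np.clip(pvals[keep, j], 1e-300, 1.0),
                                       method="fdr_bh")[1]
        fc = observed[:, j].copy()
        fc[mask[:, j]] = np.nan
        rows.append(pd.DataFrame({"gene_id": genes, "line": name,
                                  "log2fc": fc, "padj": padj}))
    fc_long = pd.concat(rows, ignore_index=True)

    cond_names = [f"stress_{i + 1}" for i in range(cfg.n_stress_conditions)]
    esr_genes = [genes[g] for g in esr_idx]
    phi = rng.uniform(0.5, 1.5, size=cfg.n_stress_conditions)
    profiles = (loadings[esr_idx][:, None] * phi[None, :]
                + rng.normal(0.0, cfg.esr_profile_noise,
                             size=(len(esr_idx), cfg.n_stress_conditions)))
    esr_profiles = pd.DataFrame(profiles, index=pd.Index(esr_genes, name="gene_id"),
                                columns=cond_names)

    planted_class = np.full(n, "null", dtype=object)
    planted_class[up_idx] = "common_up"
    planted_class[down_idx] = "common_down"
    planted_class[esr_idx] = np.where(loadings[esr_idx] > 0, "esr_up", "esr_down")
    truth = pd.DataFrame({"gene_id": genes, "planted_class": planted_class})
    return TranscriptomeSim(fold_changes=fc_long, esr_profiles=esr_profiles,
                            truth=truth, lines=lines)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSim:
    records: pd.DataFrame       # one row per line
    growth: pd.DataFrame        # line, condition, time_min, od
    truth: dict


def simulate_phenotypes(annot: pd.DataFrame, compendium: ComplexCompendium,
                        cfg: SimulationConfig) -> PhenotypeSim:
    from .annotation import count_complexes_on_chromosomes

    cfg.validate()
    rng = stage_rng(cfg, "phenotype")
    lines = generate_lines(cfg)
    counts = {name: count_complexes_on_chromosomes(compendium, annot, reps)
              for name, reps in lines.items()}

    records, growth_rows = [], []
    t = np.arange(0.0, cfg.growth_hours * 60.0 + 1, 10.0)
    for name, reps in lines.items():
        count = counts[name]
        dt_untreated = cfg.base_doubling_min + rng.normal(0.0, 3.0)
        defect = cfg.phen_slope * count + rng.normal(0.0, cfg.phen_noise_sd)
        dt_treated = max(30.0, dt_untreated + defect)

        for cond, dt in (("untreated", dt_untreated), ("gda", dt_treated)):
            mu = np.log(2) / dt
            od = 1.0 * cfg.growth_od0 * np.exp(mu * t) / (
                1.0 + cfg.growth_od0 * (np.exp(mu * t) - 1.0))
            if cfg.growth_noise_cv > 0:
                s = np.sqrt(np.log1p(cfg.growth_noise_cv ** 2))
                od = od * rng.lognormal(-0.5 * s * s, s, size=od.shape)
            growth_rows.append(pd.DataFrame({"line": name, "condition": cond,
                                             "time_min": t, "od": od}))

        freq_ctrl = float(rng.uniform(0.4, 0.7))
        sens = float(np.clip(0.004 * count + rng.normal(0.0, 0.03), 0.0, 0.95))
        freq_gda = freq_ctrl * (1.0 - sens)
        foci = float(np.clip(2.0 + 0.05 * count + rng.normal(0.0, 1.0), 0.0, 100.0))
        n_cells = 800
        records.append(dict(line=name, complex_count=count,
                            doubling_untreated_min=dt_untreated,
                            doubling_gda_min=dt_treated,
                            fitness_defect_min=dt_treated - dt_untreated,
                            sporulation_freq_ctrl=freq_ctrl,
                            sporulation_freq_gda=freq_gda,
                            sporulation_sensitivity=sens,
                            foci_percent=foci, n_cells=n_cells))
    records_df = pd.DataFrame(records)
    growth_df = pd.concat(growth_rows, ignore_index=True)
    truth = dict(slope=cfg.phen_slope, noise_sd=cfg.phen_noise_sd,
                 complex_counts=counts, lines=lines)
    return PhenotypeSim(records=records_df, growth=growth_df, truth=truth)
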