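"""Generator determinism, distributional sanity and planted-effect identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chimeracomplex import cofractionation as cf
from chimeracomplex import phenotype as ph
from chimeracomplex import pipeline as pl
from chimeracomplex import simulate as sim


def small_cfg(**kwargs):
    base = dict(seed=7, n_genes=400, n_complexes=25, complex_size_max=12)
    base.update(kwargs)
    return sim.SimulationConfig(**base)


def test_same_seed_gives_identical_outputs():
    cfg = small_cfg()
    a_annot, a_comp = sim.simulate_annotation_and_compendium(cfg)
    b_annot, b_comp = sim.simulate_annotation_and_compendium(cfg)
    pd.testing.assert_frame_equal(a_annot, b_annot)
    assert a_comp.members == b_comp.members
    a = sim.simulate_cofractionation(a_annot, a_comp, cfg)
    b = sim.simulate_cofractionation(b_annot, b_comp, cfg)
    pd.testing.assert_frame_equal(a.experimental, b.experimental)
    pd.testing.assert_frame_equal(a.control, b.control)
    ta = sim.simulate_transcriptome(a_annot, cfg)
    tb = sim.simulate_transcriptome(b_annot, cfg)
    pd.testing.assert_frame_equal(ta.fold_changes, tb.fold_changes)


def test_different_seeds_differ():
    cfg = small_cfg()
    annot, comp = sim.simulate_annotation_and_compendium(cfg)
    a = sim.simulate_cofractionation(annot, comp, cfg)
    b = sim.simulate_cofractionation(annot, comp, cfg.with_(seed=8))
    assert not a.experimental["intensity"].equals(b.experimental["intensity"])


def test_complex_sizes_within_bounds():
    cfg = small_cfg(complex_size_min=3, complex_size_max=9)
    _, comp = sim.simulate_annotation_and_compendium(cfg)
    sizes = [len(m) for m in comp.members.values()]
    assert min(sizes) >= 3 and max(sizes) <= 9
    assert comp.n_complexes == cfg.n_complexes


def test_chromosome_occupancy_roughly_uniform():
    cfg = sim.SimulationConfig(seed=11, n_genes=8000, n_complexes=10,
                               complex_size_max=5)
    annot, _ = sim.simulate_annotation_and_compendium(cfg)
    counts = annot["chromosome"].value_counts().reindex(range(1, 17),
                                                        fill_value=0)
    _, p = stats.chisquare(counts)
    assert p > 1e-3


def test_config_validation_errors():
    with pytest.raises(sim.SimulationError):
        small_cfg(n_genes=50).validate()  # 25 complexes x 12 > 50
    with pytest.raises(sim.SimulationError):
        small_cfg(delta=1.5).validate()
    with pytest.raises(sim.SimulationError):
        small_cfg(gamma=0.0).validate()


def test_peak_map_monotone_and_bounded():
    peaks = [sim.peak_fraction(s) for s in range(1, 40)]
    assert peaks[0] == sim.MONOMER_PEAK
    assert peaks[-1] == sim.LARGEST_PEAK
    assert all(a >= b for a, b in zip(peaks, peaks[1:]))


def _epd_tables(cfg):
    annot, comp = sim.simulate_annotation_and_compendium(cfg)
    cof = sim.simulate_cofractionation(annot, comp, cfg)
    epd_exp, _ = pl.process_cofractionation(cof.experimental,
                                            cof.concentrations,
                                            cfg.pre_pool, "exp")
    epd_ctrl, _ = pl.process_cofractionation(cof.control, cof.concentrations,
                                             cfg.pre_pool, "ctrl")
    return epd_exp, epd_ctrl, cof, annot, comp


def test_noiseless_null_gives_zero_epd_everywhere():
    cfg = small_cfg(delta=0.0, gamma=1.0, noise_cv=0.0, dropout_threshold=0.0)
    epd_exp, epd_ctrl, cof, _, _ = _epd_tables(cfg)
    assert not cof.truth["planted_unstable"].any()
    assert epd_exp["epd"].max() < 1e-9
    assert epd_ctrl["epd"].max() < 1e-9


def test_total_destabilization_has_closed_form_epd():
    """delta=1, sigma->0: planted subunit EPD = 2 * alpha_ref * 100."""
    cfg = small_cfg(delta=1.0, gamma=1.0, noise_cv=0.0, sigma=0.0,
                    dropout_threshold=0.0, planted_fraction=1.0,
                    alpha_ref=0.9, replaced=(8, 15))
    epd_exp, _, cof, annot, comp = _epd_tables(cfg)
    planted = cof.truth.loc[cof.truth["planted_unstable"], "complex_id"]
    assert len(planted) > 0
    epd = epd_exp.set_index("protein_id")["epd"]
    for cid in planted:
        for p in comp.members[cid]:
            assert epd.loc[p] == pytest.approx(180.0, abs=1e-9)


def test_pre_pool_emits_81_fractions_that_pool_cleanly():
    cfg = small_cfg(pre_pool=True, noise_cv=0.1)
    annot, comp = sim.simulate_annotation_and_compendium(cfg)
    cof = sim.simulate_cofractionation(annot, comp, cfg)
    assert cof.experimental["fraction"].max() > 27
    pooled = cf.pool_fractions(cof.experimental, width=3)
    assert pooled["fraction"].max() <= 27
    assert pooled["intensity"].sum() == pytest.approx(
        cof.experimental["intensity"].sum())


def test_masked_genes_are_nan_on_their_own_line():
    cfg = small_cfg()
    annot, _ = sim.simulate_annotation_and_compendium(cfg)
    trs = sim.simulate_transcriptome(annot, cfg)
    gene_chrom = annot.set_index("gene_id")["chromosome"]
    for line, replaced in trs.lines.items():
        sub = trs.fold_changes[trs.fold_changes["line"] == line]
        on_rep = sub["gene_id"].map(gene_chrom).isin(set(replaced))
        assert sub.loc[on_rep, "log2fc"].isna().all()
        assert sub.loc[~on_rep, "log2fc"].notna().all()


def test_generated_lines_are_deterministic_and_sized():
    cfg = small_cfg(n_lines=11)
    lines_a = sim.generate_lines(cfg)
    lines_b = sim.generate_lines(cfg)
    assert lines_a == lines_b
    assert len(lines_a) == 11
    assert all(1 <= len(reps) <= 2 for reps in lines_a.values())


def test_noise_free_phenotype_correlates_perfectly():
    cfg = small_cfg(phen_noise_sd=0.0, n_lines=8)
    annot, comp = sim.simulate_annotation_and_compendium(cfg)
    phs = sim.simulate_phenotypes(annot, comp, cfg)
    counts = phs.records["complex_count"]
    if counts.nunique() > 1:
        rho, _ = ph.phenotype_complex_correlation(phs.records,
                                                  "fitness_defect_min")
        assert rho == pytest.approx(1.0)


def test_zero_slope_phenotype_decorrelates():
    rhos = []
    for seed in range(30):
        cfg = small_cfg(seed=seed, phen_slope=0.0, phen_noise_sd=10.0,
                        n_lines=11)
        annot, comp = sim.simulate_annotation_and_compendium(cfg)
        phs = sim.simulate_phenotypes(annot, comp, cfg)
        rho, _ = ph.phenotype_complex_correlation(phs.records,
                                                  "fitness_defect_min")
        rhos.append(rho)
    assert abs(np.mean(rhos)) < 0.2
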