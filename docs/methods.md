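# Methods

`chimeracomplex` implements a statistical pipeline for deciding, from
SEC–SILAC co-fractionation proteomics, which multi-protein complexes are
destabilized in yeast hybrid chromosome-replacement lines, together with the
downstream analyses that connect complex destabilization to soluble-protein
abundance, transcriptome stress signatures, and organismal phenotypes. A
synthetic-data module generates every input with planted ground truth so the
full stack is testable without any external data.

## Elution patterns and the EPD statistic

A native lysate is separated on a size-exclusion column; assembled complexes
elute in early (high-molecular-weight) fractions and free subunits in late
fractions. Two samples (a reference strain grown in heavy SILAC medium and an
experimental line in light medium) are mixed and measured together, giving
each protein a per-fraction intensity in each channel over 27 analyzed
fractions (81 raw fractions pooled in triples).

Processing order: (1) pool raw fractions in triples when 81 are supplied,
conserving totals exactly; (2) multiply intensities by the per-fraction
peptide concentration; (3) normalize each (protein, channel) vector to
percentages summing to 100 — the *elution pattern*. Undetected fractions are
treated as zero intensity (intensity-dependent missingness, as in standard
search-engine outputs); a channel with no signal at all cannot form a pattern
and drops the protein from that comparison with a logged reason.

The elution pattern difference for a protein is the L1 distance

    EPD = sum_{f=1}^{27} | p_f(heavy) - p_f(light) |,

ranging from 0 (identical co-elution) to 200 (disjoint support). Percentages
(not proportions) are the canonical unit, so the 0–200 scale is part of the
contract. EPD is symmetric, satisfies the triangle inequality, and is
invariant to rescaling either channel's total intensity. Correction by
per-fraction concentration happens after pooling; a global rescaling of the
concentration vector cancels in the normalization.

## Complex-level stability inference

A complex is *testable* when at least `n_min` (default 5) of its subunits
have EPD values in both the experimental set and the same-species control
set. For each testable complex the paired subunit EPDs are compared with a
one-sided Wilcoxon signed-rank test (alternative: experimental > control);
p-values are Benjamini–Hochberg adjusted across all testable complexes within
one comparison set, and complexes with adjusted p < 0.05 are called unstable.

The signed-rank test drops zero differences before ranking (all-zero input
returns p = 1 with a degenerate flag) and assigns mid-ranks to tied absolute
differences. For n ≤ 15 the p-value is exact: the null distribution of the
positive-rank sum over all 2^n sign assignments is computed by dynamic
programming over doubled mid-ranks, which stays exact under any tie pattern.
For larger n a normal approximation with tie-corrected variance (and no
continuity correction) is used. `n_min = 5` is the smallest size at which a
one-sided exact test can reach p < 0.05 (floor 1/32).

The exact-test floor matters for power planning: a complex of n subunits can
never achieve p below 2^-n, so with r planted effects among m testable
complexes BH can only call a size-n complex when 2^-n ≤ q·r/m. For 10
planted complexes that include 6-subunit members (floor 1/64) this bounds the
testable family at m ≲ 32 for q = 0.05. The planted-recovery study in the
acceptance suite is sized accordingly (30 complexes of 6–20 subunits); a
larger family is analytically incapable of full recovery at that complex
size, regardless of effect magnitude.

A robustness re-analysis repeats the calls after removing subunits encoded on
the replaced chromosomes, to exclude the possibility that divergent orthologs
alone (rather than complex-wide destabilization) drive the signal.

Group-level contrasts compare EPD distributions between protein classes:
*chr-complex* proteins (members of at least one complex containing a
replaced-chromosome subunit), *non-chr-complex* proteins (members only of
untouched complexes), and non-complex proteins. A protein belonging to both
kinds of complexes is labelled chr-complex by default — any such membership
exposes it to a chimeric assembly — with the precedence configurable. The
omnibus test is Kruskal–Wallis (tie-corrected; all-identical input is an
error, since the tie-correction denominator vanishes), followed by Dunn's
pairwise z tests on pooled mean ranks with Bonferroni correction and a
compact letter display (groups sharing a letter are indistinguishable).
Enrichment of replaced-chromosome complexes among the unstable calls is a
one-sided Fisher exact test on the 2×2 table {unstable, stable} ×
{contains replaced subunit, does not}; degenerate margins return p = 1.

## Abundance and protein–transcript coupling

The per-protein SILAC ratio is log2(total light / total heavy) over the
corrected fractions. Complex-level abundance reduction reuses the identical
paired machinery with alternative "experimental < control" — a shared code
path asserted by tests. Protein–transcript coupling is the Spearman
correlation between SILAC ratios and transcript log2 fold-changes per protein
group; correlations of disjoint groups are compared with the independent-
samples Fisher r-to-z statistic
`z = (atanh(r_A) − atanh(r_B)) / sqrt(1/(n_A−3) + 1/(n_B−3))`. Equal
correlations compare trivially (z = 0) without the transform, which is
undefined at |rho| = 1.

## Transcriptome response

Upstream differential-expression estimation is consumed, not computed: inputs
are per-line log2 fold-changes vs the parent with adjusted p-values. A gene is
DE when its linear fold-change exceeds 1.5 (|log2FC| > log2 1.5 ≈ 0.585) with
adjusted p < 0.05. Genes on a line's replaced chromosomes are masked for that
line and never contribute calls. *Common-response* genes are DE in the same
direction in ≥ k (default 4) lines with no opposite call anywhere (strict
purity); genes DE in ≥ k lines with mixed directions are excluded as
bidirectional. The purity rule is one fixed reading of an ambiguous
convention and is configurable. The environmental-stress-response signature
is the Spearman correlation between the median log2FC of ESR genes across
lines and each reference stress profile (≥ 10 shared genes required).

## Phenotypes

Doubling times come from the maximum slope of ln(OD) over sliding windows of
consecutive 10-minute plate-reader readings above an OD floor of 0.02. The
default window is 11 points (110 min): the max-over-windows estimator is
biased upward by window noise, and at 1% multiplicative OD noise an 11-point
window keeps the doubling-time error near 2% where a 5-point window errs by
~15%. Fitness defect is doubling time treated minus untreated; sporulation
sensitivity is 1 − (frequency with inhibitor pre-treatment / without);
aggregation load is the percentage of cells with Hsp104 foci, flagged when
counted from fewer than 500 cells. Per-line phenotypes are correlated with
the number of complexes containing replaced-chromosome subunits (Spearman,
≥ 5 lines). Group means are compared with a one-sided Welch t test — Welch
rather than pooled-variance Student because replicate variances differ
between lines; a pooled-variance mode is available.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Annotation and compendium.** Genes (default 2400) are assigned uniformly to
16 chromosomes; complexes (default 150) draw their sizes from a truncated
geometric distribution (min 2, max 15, p = 0.35) and sample members
*disjointly* from the gene pool. Real compendia overlap; disjointness is a
deliberate simplification that makes planted truth and group labels
unambiguous. Eleven replacement lines each carry one or two replaced
chromosomes.

**Co-fractionation.** Each complex elutes at a peak fraction given by a fixed
monotone size map (monomers at fraction 24, the largest complexes at fraction
3 — larger species elute earlier). A subunit's noiseless profile is the
mixture `alpha·G(complex peak, sigma) + (1−alpha)·G(monomer peak, sigma)`
discretized over the fraction grid (sigma default 1.2 fractions), scaled by a
log-normal per-protein abundance (median 1e6, log-sd 1). The reference
channel uses assembled fraction `alpha_ref = 0.9`. Planted-unstable complexes
reduce the light channel's assembled fraction to `alpha_ref·(1−delta)` and
scale its total by `gamma` (degradation). Multiplicative log-normal noise of
CV 0.2 (mean-corrected) is applied per fraction; intensities below 1e3 are
set to zero (thresholded dropout — intensity-dependent, matching real
missingness better than uniform random dropout; a probabilistic mode is not
needed for the properties tested). Emitted intensities are divided by the
per-fraction peptide concentration so that the correction step of the
pipeline is exercised; the control comparison is two independent noisy draws
of the reference model. With delta = 1, sigma → 0 and no noise, the EPD of an
affected subunit is exactly 2·alpha_ref·100 — a closed-form identity used as
an oracle.

**Transcriptome.** Observed log2FC = planted effect + N(0, 0.3). Planted
common-response genes (40 up, 40 down) receive ±1 log2 units in ≥ 4 randomly
chosen lines; 150 ESR genes share a latent stress factor (per-gene loadings
±|N(1, 0.3)|, per-line stress intensities U(0.3, 1)); reference stress
profiles are loadings × condition intensity + noise. P-values come from the
known null scale (z = fc/0.3) with per-line BH adjustment, and genes on a
line's replaced chromosomes are emitted as missing for that line.

**Phenotypes.** Fitness defect = 0.6 min × complex count + N(0, 10 min).
With the default compendium the per-line counts have sd ≈ 15, so the planted
association has Spearman rho ≈ 0.7 — the magnitude of the count–phenotype
correlations this kind of experiment reports. Growth curves are logistic
(carrying capacity 1.0, initial OD 0.05) with 1% multiplicative noise read
every 10 min for 16 h; sporulation and foci phenotypes receive analogous
weak couplings.

**What the generator does not emulate.** Overlapping complex membership,
correlated noise between subunits of one complex (the tests treat subunits as
exchangeable, as the analysis itself does), peptide-level effects, retention
drift, channel cross-talk, and biological covariance between transcriptome
and proteome beyond the planted structure. Passing recovery and FDR tests
therefore certify the statistical machinery under the assumed noise model,
not performance on real spectra.

## Numerical and design choices

- All randomness flows from one config seed through named per-stage
  substreams; identical configs give byte-identical outputs.
- Elution patterns must sum to 100 within 1e-6; EPD uses plain float sums
  (no compensated summation needed at 27 terms).
- BH families are per comparison set (each experimental line adjusted
  separately), matching per-set reporting.
- The exact signed-rank DP uses doubled mid-ranks to stay integral under
  ties; the normal branch matches the standard tie-corrected variance without
  continuity correction.
- Degenerate cases are explicit: all-zero differences → p = 1 with a flag;
  all-identical Kruskal–Wallis input → error; degenerate Fisher margins →
  p = 1; constant vectors → Spearman error; identical zero-variance t-test
  groups → p = 0.5.
- Problem sizes in the validation suite (600–1000 genes, 25–60 complexes,
  200 null replicates, 100 phenotype panels) are desk-scale choices that keep
  each study in seconds while leaving the binomial confidence intervals tight
  enough for the stated bounds.

## Known limitations

- The pairing of experimental and control EPDs assumes the same proteins
  are quantified in both; proteins missing from either set are
  excluded from that complex's test, which can reduce n below `n_min`.
- The exact-test floor 2^-n makes BH conservative and bounds attainable
  recovery for small complexes in large testable families (see the power
  note above).
- Reproduce-mode on real supplementary tables is supported by the readers
  and CLI, but no real data ship with the package.
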