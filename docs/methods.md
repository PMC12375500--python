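# Methods

This note records the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions, so results can be interpreted and the design
decisions audited.

## Differential binding (eCLIP)

**Model.** Cluster-level read counts from a 2×2 factorial — assay (IP vs
size-matched input) × treatment — with replicate libraries per cell.
Counts are normalised to reads per million mapped reads (RPM) using each
library's total mapped reads. Two quantities are computed per cluster:

1. *Interaction p-value.* A classical two-way fixed-effects ANOVA on the
   RPM values, testing the assay × treatment interaction. Internally this
   is a model-comparison F between the additive model and the full
   cell-means model, F = (RSS_additive − RSS_full) / (RSS_full / (N − 4))
   with 1 and N − 4 degrees of freedom. For balanced designs this is
   algebraically the textbook interaction sum-of-squares test (verified in
   the suite against `statsmodels.anova_lm` to ≥ 10 significant digits);
   the model-comparison form remains well defined for unbalanced
   replication. The ANOVA runs on raw RPM by default — not log-RPM —
   because the differential-binding procedure being reproduced is defined
   on RPM values; a `log=True` option exists for users who prefer variance
   stabilisation, and it changes which clusters are borderline.
2. *Effect size.* ΔLFC = log₂((m_IP,t + ε)/(m_in,t + ε)) −
   log₂((m_IP,u + ε)/(m_in,u + ε)) from the four cell mean RPMs.

A cluster is a differentially bound peak (DBP) when interaction p < 0.05
(raw, no multiplicity correction — that is the procedure of record; a BH
option is provided and clearly marked as an extra) and |ΔLFC| > 0.5.

**Degenerate inputs.** Zero residual variance with zero interaction SS
(e.g. all eight values identical) gives p = 1 — such a cluster can never
be called, which is the conservative choice and avoids NaN propagation.
Zero residual variance with a non-zero interaction gives p = 0. An
all-zero cluster gets ΔLFC = 0 via the ε floor and raises a warning.

**Peak significance vs input.** Reads are pooled over the IP libraries and
over the input libraries of one treatment arm. Enrichment is
log₂(((ip+pc)/ip_lib)/((in+pc)/in_lib)); the p-value is the one-sided
hypergeometric tail of the 2×2 table of in-peak vs out-of-peak reads
(identical to a one-sided Fisher exact test, used as the oracle in the
suite). Thresholds default to log₂ enrichment ≥ 3 and p ≤ 0.001. The
source protocols state the enrichment cutoff both as "fold-enrichment ≥ 3"
and "log₂ fold enrichment > 3"; the log₂ reading — the standard eCLIP
input-normalisation convention — is the default, and both the threshold
and its scale are configurable.

**Defaults.** ε = 0.1 RPM (log-ratio floor), pseudocount = 1 read (peak
calling); both are free parameters because the upstream protocol is silent
about zeros. Gene assignment is by maximal overlap, ties to the
lexicographically smallest gene id for determinism; region ties within a
gene follow a fixed precedence starting at 3'UTR. Strand "." matches
either strand. A gene is "bound" in a condition when it owns ≥ 1
significant peak there; the Venn-style overlap summary compares these
per-condition bound-gene sets.

## Differential expression (RNA-seq)

A deliberately minimal negative-binomial test so the bespoke filter and
the downstream integration can be exercised self-contained:

* genes with total count < 10 over all samples are removed first;
* size factors: median-of-ratios over genes with all-positive counts,
  rescaled to geometric mean 1;
* dispersion: per-gene method of moments on size-factor-normalised counts
  (on that scale Var(K/s) = μ/s + αμ²), pooled within groups, floored at
  10⁻⁸, with no shrinkage toward a trend;
* log₂FC between group means with a 0.5 pseudo-normalised-count guard;
* Wald statistic log₂FC / SE with the SE propagated from the NB variance,
  referred to a t distribution with n₁ + n₂ − 2 degrees of freedom. The t
  reference (rather than the normal) is a small-sample correction: the
  plug-in dispersion makes the statistic behave like a pooled-variance t,
  and with triplicates the normal reference would be anti-conservative.
  Calibration is regression-tested (KS uniformity on 2,000 null genes);
* BH adjustment across tested genes.

No numerical agreement with full-featured DE packages is claimed — no
dispersion shrinkage, no outlier replacement, no independent filtering.
The significance filter, padj < 0.05 **and** baseMean > 5 **and**
|log₂FC| > 5/√baseMean + 0.6, can also be applied to an externally
produced (baseMean, log₂FC, padj) table (`rbpomics de --external-stats`).
The threshold function is strictly decreasing in baseMean and tends to
0.6, so the implied minimum fold change tends to 2^0.6 ≈ 1.52 for highly
expressed genes and reaches ≈ 7-fold at baseMean = 5. The padj default is
0.05; downstream gene-list cutoffs of the |log₂FC| > 0.5 style are a
separate, coarser convention and are exposed independently (they are never
conflated with the baseMean-dependent rule).

## Proteomics (LFQ)

Filtering keeps proteins with non-zero LFQ intensity in all eight samples,
≥ 3 peptides, and no reverse/contaminant/identified-by-site flag. Missing
values are encoded as intensity 0 (matching the "non-zero LFQ" filter
semantics) and are removed by the filter by construction — there is no
imputation.

The test statistic on log₂ intensities is d = (m₁ − m₂)/(SE_pooled + s₀).
s₀ defaults to 0, making d exactly the classical equal-variance two-sample
t — fidelity to the described "two-sample t test" — while a positive s₀
is available to damp low-variance artefacts. FDR is SAM-style: for each
protein, q = median over balanced label permutations of the count of
permuted |d| ≥ |d_i|, divided by the observed count, clipped to [0, 1] and
monotonised (q never decreases as |d| decreases). With 4 vs 4 samples all
C(8,4) = 70 balanced relabelings are enumerated, so the result is
deterministic and seed-independent; sampled permutations (default 250) are
used only when more than 1000 distinct relabelings exist. The exact
Perseus FDR variant is not published; this SAM-style median-ratio
estimator is the documented choice, with BH on the pooled permutation
p-values available behind `method="bh"`.

## CETSA melt curves

The soluble fraction after a 3-minute heat pulse, normalised to the lowest
temperature, is fit per replicate with a descending Boltzmann sigmoid
f(T) = bottom + (top − bottom)/(1 + e^((T−Tm)/slope)). Tm is the
inflection — the temperature at which half the protein has been lost.
Free top and bottom are retained because real blots rarely reach exactly 1
and 0. Initialisation: top/bottom from the data extremes, slope 2 °C, and
every observed temperature tried as a Tm start with the best
residual-sum-of-squares fit kept (the suite checks the final RSS never
exceeds the best grid start). The 95% CI on Tm is asymptotic, from the fit
covariance with a t critical value at n − 4 df; a residual bootstrap is
available behind a flag. Degenerate inputs error out: fewer than 5 points,
constant fractions, or monotone-increasing fractions (no melting). Fits
whose Tm falls outside the measured range are rejected rather than
extrapolated. Replicates are fit separately by default (averaging first
would understate the CI); a condition is called stabilised when the Tm
shift is positive and the CIs do not overlap.

## Cross-omic integration

The gene-level binding score is the mean ΔLFC over a gene's DBPs. Genes
with mixed-direction DBPs are excluded from the quadrant table and
reported separately: coordination is empirically very high (the
multi-DBP coordination summary), so the mean is representative for
coordinated genes while mixed genes have no meaningful sign. Concordance
uses (a) a chi-square test with 1 df and no continuity correction on the
2×2 binding-direction × RNA-sign table and (b) a Mann–Whitney U test —
the standard reading of a "Mann-Whitney unpaired t-test" — comparing RNA
log₂FC between binding-up and binding-down genes. By default all jointly
observed genes enter the comparison; `--sig-only` restricts to significant
RNA changes. Gene-set enrichment is hypergeometric over-representation
(upper tail, sets intersected with the universe first) with BH across
sets; ranked-list GSEA is out of scope.

## Synthetic data: what it emulates and what it does not

The generator plants truth at every layer, with defaults mirroring the
emulated study design: duplicate eCLIP (2 IP + 2 input per treatment),
triplicate RNA-seq, 4-vs-4 proteomics, and a 37–58 °C thermal gradient
(8 points, 3 replicates, vehicle Tm 45.6 °C vs treated 47.7 °C, slope
1.5 °C).

* Counts are negative binomial, Var = μ + αμ², α = 0.05 — a standard
  sequencing-noise level. eCLIP cluster means are library_size/10⁶ ×
  base_RPM × enrichment(assay, treatment); base RPM is lognormal (median
  20, σ_log 1), IP log₂ enrichment ~ N(4, 1) clipped at 0.5, library sizes
  1.5–2.5 M reads.
* Clusters per gene ~ 1 + Poisson(3.3) (≈ 4.3 clusters/gene) and region
  composition 72% 3'UTR / 20% CDS / 5% 5'UTR / 3% intron, the regime of a
  3'UTR-binding RBP.
* Exactly round(frac_dbp × n) clusters are differentially bound
  (frac_dbp = 0.25); the planted interaction multiplies only the
  treated-IP mean by 2^ΔLFC with |ΔLFC| ~ Uniform(2, 5) and 60% of effects
  negative. The magnitude range models site-level, near-on/off switching
  of binding — an inhibitor displacing the RBP from a site largely
  abolishes its crosslink signal rather than modulating it — and places
  the generator in the regime where the duplicate design recovers ≥ 90% of
  planted effects: a power analysis of the interaction F-test (1 and 4 df)
  shows per-cluster power ≈ 0.53 at |ΔLFC| = 1, ≈ 0.89 at 2, and a ceiling
  of ≈ 0.95–0.97 however large the effect, because the four-df residual
  variance estimate occasionally balloons. Subtler regimes can be
  simulated by overriding `dbp_delta_lfc_range`.
* Coupling: true RNA log₂FC = coupling_rna × (mean planted ΔLFC over the
  gene's clusters, zeros included), coupling_rna = 1; true protein log₂FC
  = coupling_protein × RNA log₂FC, coupling_protein = 0.8. The gene-level
  dilution (averaging over non-DBP clusters) means typical RNA effects are
  well below the cluster-level ΔLFC, which is why only a minority of genes
  clear the strict baseMean-dependent filter — as intended.
* LFQ: log₂ intensities Gaussian (base ~ N(25, 2), replicate noise σ =
  0.3), 30% of genes observed as proteins, 10% of entries zeroed as
  missing, peptide counts 1 + Poisson(5).

All generators are pure functions of the configuration (the seed is part
of it); separate deterministic streams per omic layer keep the layers
independently reproducible.

**Not emulated:** read-level artefacts (PCR duplicates, crosslink-site
biases, mappability), peak discovery itself (clusters are given, as after
upstream peak calling), sequence or motif content, overdispersion trends
that vary with expression, RNA-seq batch effects, LFQ
missing-not-at-random structure and match-between-runs artefacts, and
melt-curve baseline drift. Passing the suite therefore demonstrates that
the statistics are implemented correctly and recover planted structure
under their own model assumptions — not that the pipeline is robust to
every pathology of real data.

## Problem sizes and runtime

The regression suite uses 120–1,200 genes (≈ 500–5,000 clusters), 10,000
null clusters for ANOVA calibration, 1,000–2,000 genes/proteins for the
null-calibration checks, and 50 noisy melt fits; the whole suite runs in
well under a minute on one CPU, and the acceptance script in a few
seconds. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the suite fast; everything scales to
larger simulations through `SimConfig`.

## Known limitations

* The DE module is a minimal NB test; effect-size shrinkage and dispersion
  trends are intentionally absent, so its padj values will differ from
  full-featured DE packages on real data (the bespoke filter accepts
  external stats tables for exactly this reason).
* The interaction ANOVA on raw RPM inherits the heteroscedasticity of
  count data; with duplicate libraries its power is modest for |ΔLFC| ≲ 2
  and its per-cluster power ceiling is ≈ 0.95. This is a property of the
  reproduced procedure, not of the implementation.
* The SAM-style q-value is a point estimate of FDR; with few proteins it
  is granular (steps of 1/#{|d| ≥ |d_i|}).
* CETSA CIs are asymptotic; with 8 temperature points they can be
  optimistic, hence the bootstrap option.
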