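# Methods

This note documents the statistical models behind `toxpod`, the choices
made where the design was genuinely open, the synthetic-data generator's
assumptions, and the package's known limitations.

## Dose metrics

Concentrations convert between compound mass (µg/mL), constituent-metal
mass (µg/mL Me), molar metal (µM Me) and particle surface area (cm²/mL).
Molar masses are assembled from IUPAC 2021 standard atomic weights stored
to four decimals; hydrate salts convert via the hydrate molar mass (e.g.
NiCl₂·6H₂O = 237.683 g/mol).  Surface-area concentration is
conc × SSA × 0.01 with SSA in m²/g; when only a manufacturer range is
available the arithmetic mean of the range is used.

## Viability statistics

Percent viability is 100·white/(white+blue); it enters testing through
arcsin(pv/100) — the transform as conventionally printed for this assay.
The classical variance-stabilizing arcsin(√(pv/100)) is available behind
the `sqrt=True` flag; the difference is immaterial at the viabilities seen
here but the printed form is the default for fidelity.  Viable-cell
densities are compared as √density.  Many-to-one comparisons use Dunnett's
procedure within each timepoint, delegated to SciPy's implementation of
the equicorrelated multivariate-t distribution with a seeded integration
rng so adjusted p-values are reproducible.  The factor structure (Dunnett
within timepoint on the concentration factor) is a choice; a two-way
interaction model would need the original design details.

## Differential expression

The test statistic per gene is Fs = MS_between / s̃² with
s̃² = (ν·s²_g + ν₀·s²₀)/(ν+ν₀): s²_g the pooled two-group residual
variance on ν degrees of freedom, s²₀ the mean residual variance over all
genes.  ν₀ defaults to the median residual df across genes (equal to ν in
a uniform design) and is configurable; ν₀ = 0 recovers the classical F.

Significance uses sample-label permutations shared across genes, with two
deliberate properties:

* **Pooled null.**  p_i = (1 + #{Fs*(g, π) ≥ Fs_i over all genes g and
  permutations π}) / (1 + G·n_perm).  At n = 2–4 replicates the per-gene
  permutation distribution has too few distinct splits (35 at 4 vs 4, 10
  at 3 vs 3) for FDR-adjusted calls; pooling across genes is the standard
  small-sample device (as in SAM-type microarray tests).  Permutation
  p-values therefore lie in [1/(1+G·n_perm), 1].
* **Observed-partition exclusion.**  Permutations that reproduce the
  observed two-group partition are excluded from the null: they carry the
  full treatment signal and, at 3 vs 3, are 10% of all permutations —
  enough to put an ≈0.1 floor under every adjusted p.  Empirical null FDR
  (mean fraction of adjusted p < 0.05 on pure-noise matrices) stays below
  the nominal 0.05 in the seeded simulations of the test suite.

Fold change is the signed transform of the least-squares-means difference:
2^Δ for Δ ≥ 0, −2^(−Δ) otherwise, so |fc| ≥ 1 and the sign is the
direction.  DEG = (adjusted p < 0.05, strict) AND (|fc| ≥ 1.5, inclusive).

## Enrichment, z-scores, clustering

Enrichment is the exact one-sided hypergeometric upper tail of the
DEG/set overlap against the measured-gene universe (the defensible
background for an assay; the genome is not used).  Significance:
−log₁₀ p > 1.3 and ≥ 3 overlapping DEGs.  The activation z-score is the
unweighted sign-concordance statistic (N_c − N_d)/√(N_c+N_d) over
direction-annotated DEG members and is absent when no annotated member is
a DEG.  DEG lists larger than 8000 are split at |fc| = 2 (boundary to the
high list, so the two lists partition); a pathway enriched by either list
counts once for that sample in the commonly-enriched ranking
(descending count, alphabetical tie-break).

Clustering operates on the zero-filled sample × pathway z matrix.
Uncentered Pearson similarity is the cosine of the raw profiles — it
respects the meaningful zero of the z scale, unlike centered correlation.
It is undefined on all-zero rows, so such samples are excluded and
reported, mirroring how samples without directional enrichment are left
out of heatmaps.  Linkage is unweighted-average (UPGMA) via SciPy; the
default cut at k = 4 reflects the number of metal families in the
reference design and is configurable.  The engine is reused for gene-level
fold-change heatmaps (zero-filled for non-DEGs).

## Biomarker scoring

score = mean |fc| over samples where the gene is a significant DEG
+ 100 × (count of those samples with |fc| > 5), computed only over samples
in which the focal pathway is enriched.  Absolute fold changes are the
default: signed averaging would let opposed responses cancel, contradicting
the intent of rewarding consistently strong responders (signed mode is
available).  "|fc| > 5" is strict.  Panels take the top k = 10 by score
with alphabetical tie-break.  The coverage–viability association uses
Spearman's rho with midranks; for n ≤ 9 the p-value is the exact two-sided
enumeration over all pairings, otherwise the t approximation.

## Benchmark concentration modeling

**Williams' trend prefilter.** The statistic is the larger-direction
departure of the isotonic (pool-adjacent-violators, replicate-weighted)
amalgamated top-dose mean from the control mean, standardized by the
pooled within-group SD with 1/n_k + 1/n₀ scaling.  The permutation p
(within-series label permutation, add-one convention) lies in
[1/(n_perm+1), 1]; 100 permutations give a 1/101 floor and a near-nominal
type-I error at α = 0.05.  Probes additionally need a maximal group-mean
fold change ≥ 1.5.

**Model suite.** linear, poly2, poly3, power (exponent restricted to
[1, 18]), hill, and the EPA exponential family exp2–exp5 (sign of the
exponential direction fixed by the isotonic trend).  Constant-variance
Gaussian ML: polynomials by closed-form least squares, the rest by bounded
least squares with analytic Jacobians, data-derived starts and a seeded
jitter (max 250 function evaluations).  AIC = 2(p+1) − 2·loglik counts the
variance parameter.  The lack-of-fit "fit p" is the F test of the model
against the saturated cell-means model; models with as many mean
parameters as dose groups are flagged saturated and never selected.

**BMC.** The benchmark response is k = 1 residual SD; the SD used is the
degrees-of-freedom-corrected √(RSS/(N−p)) rather than the ML √(RSS/N),
which is noticeably biased low on 4-replicate designs and would drag BMCs
toward zero.  The BMC is the smallest dose in (0, 100 × max dose] where
|µ(d) − µ(0)| crosses the benchmark, found by a geometric grid scan plus
Brent root refinement.  Confidence bounds: seeded parametric bootstrap
(default 250 refits; the pipeline uses 60 per probe) — simulate from the
fitted mean with the df-corrected SD, refit the same model warm-started,
re-derive the BMC, take the 2.5/97.5 percentiles, and widen minimally if
needed so bmcl ≤ bmc ≤ bmcu.  A profile-likelihood interval was considered
and rejected: it needs a per-model reparameterization of nine nonlinear
families, while the bootstrap is uniform and robust at parameter bounds.
Model selection walks converged, non-saturated fits in (AIC, complexity)
order and takes the first with a defined, finite interval.

**Filters and tPOD.** Per-probe results are removed when lack-of-fit
p < 0.1 (NaN is not evidence of misfit and passes), BMCU/BMCL ≥ 40 or the
interval is undefined, BMC exceeds the top tested dose, or the probe lacks
a gene annotation.  Genes collapse probe values by the median; the tPOD is
the 25th-ranked gene's BMC (ties by BMCL then name) and is reported as
undefined with a reason when fewer than 25 genes pass.

**Hybrid extra-risk viability BMC.** With a decreasing-adverse response,
the abnormal cutoff is c = µ(0) − Φ⁻¹(1−p₀)·σ(0) with tail probability
p₀ = 0.01 by default (configurable; the conventional choice for this
approach), P(d) = Φ((c − µ(d))/σ(d)), and the BMC solves
(P(d) − p₀)/(1 − p₀) = 0.5.  σ(d) is constant by default; a power-of-mean
variance (log-variance on log-mean regression across dose groups) is
available.  For the linear case µ = 1000 − 20d, σ = 100, p₀ = 0.01 this
reduces to the closed form bmc = (Φ⁻¹(0.99) + Φ⁻¹(0.505))·σ/|b| ≈ 11.69.

**Potency ranking.** Compounds sort by BMC; two are equivalent when their
confidence intervals intersect.  Equivalence is reflexive and symmetric
but not transitive, so results are reported as a chain (A ~ B > C), never
forced into a total order.  Mixed concentration units are rejected; the
pipeline models doses as µg/mL constituent metal by default, with compound
mass and SSA (cm²/mL) modes available.

## Synthetic data generator

The generator emulates a multi-compound particle-toxicity study: several
compounds with 3–4 strictly increasing concentrations, a shared medium
control per timepoint, timepoints {2, 24, 48} h and 3–4 replicates.
Expression is emitted as already-normalized log2 ratios — upstream
intensity-level normalization of two-colour arrays is intentionally not
simulated.  Per-gene responses are Hill curves
direction·emax·θ_c·d^h/(ac50^h+d^h), scaled by a timepoint factor
({2 h: 0.25, 24 h: 1.0, 48 h: 1.25} by default — responses grow with
exposure time, functional form unspecified, so a simple multiplier), plus
Gaussian noise with σ = 0.25 log2 units (a free choice in the absence of a
stated array noise level).  emax ~ U(0.8, 4): the low end deliberately
leaves weak responders below the 1.5-fold DEG threshold so that hub
coverage discriminates between compounds instead of saturating.

Each compound carries a latent toxicity θ ∈ [0, 1] that multiplies every
programmed effect size and shrinks the viability EC50
(ec50 = 0.8·(1.1 − θ)·max dose), so hub-pathway coverage and viability
decline are rank-anticorrelated by construction — the recovery target of
the end-to-end tests.  One designated hub stress set (default 198 genes)
responds to every compound; every other set is tied to one metal and its
members respond only to that metal's compounds, giving metal-specific
signatures that drive the co-clustering behavior.  Trypan counts: total ~
Poisson(200) per hemocytometer read (manual-counting variance), live ~
Binomial(total, f0/(1+(d_eff/ec50)^slope)) with d_eff = dose × time
factor; viable-cell density is baseline × live/total.

What the generator does **not** emulate: probe-level array artifacts,
dye-swap structure, correlated gene–gene noise, compositional or
batch effects, partial dissolution kinetics.  Passing tests therefore
demonstrate that the pipeline recovers programmed dose–response structure
under idealized noise, not that it is robust to every artifact of real
microarray data.

## Problem sizes used in validation

The automated checks run on one CPU and size their simulations
accordingly: the end-to-end fixture uses 4 compounds × (4 doses + control)
× 2 timepoints × 4 replicates over 300 genes with a 60-gene hub and 8
gene sets, with BMC modeling at 24 h in compound mass units (the unit in
which the latent-toxicity ordering is programmed) and 60 bootstrap refits
per probe; BMC recovery uses 200 programmed hill probes at σ = 0.2 with 4
replicates over doses {0, 6.25, 12.5, 25, 50, 100}; Williams calibration
uses 1000 null series; the determinism check reruns a 60-gene pipeline
twice and compares file hashes.  Defaults in the library itself are larger
(198-gene hub, 250 bootstrap refits, 1000 DEG permutations).

## Known limitations

* Permutation granularity: even pooled, p-values at n = 2 replicates are
  heavily discretized; results at n = 2 should be treated as exploratory.
* The tPOD is a low-rank order statistic of noisy per-gene BMC estimates
  and is therefore biased toward lower concentrations: ranking prefers
  genes whose estimation noise pushed the BMC down.  In seeded
  simulations at σ = 0.2 the 25th-gene tPOD sits roughly 15–35% below its
  noise-free counterpart; the quality filters reduce but do not remove
  this selection effect.  Comparisons between compounds are unaffected to
  first order because the bias is shared.
* The bootstrap CI is percentile-based; its small-sample coverage in the
  seeded simulations is ≈0.87 at nominal 0.95 for the hybrid viability
  BMC, adequate for interval-overlap potency calls but not for strict
  coverage guarantees.
* The full BMDS "recommended/questionable" model-recommendation taxonomy
  is reduced to the documented AIC + saturation + defined-interval rule.
* Enrichment assumes an unstructured background; gene-length or
  expression-level bias corrections are out of scope.
* The activation z-score is unweighted; literature-derived edge weights
  are not modeled.
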