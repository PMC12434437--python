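# Methods notes

## Scope and model

`grazeniche` quantifies density-dependent resource partitioning in a
multi-species grazer assemblage from dung eDNA metabarcoding. The pipeline
takes per-PCR-replicate read tables (real or simulated), produces
per-individual diet profiles, and asks two questions: *what does each species
select?* (Jacobs' D against surveyed plant availability) and *does niche
overlap respond to herbivore density?* (beta regressions of pairwise Pianka
overlap on census-derived population energy expenditure).

## The synthetic study

The generator emulates the sampling design of a November dung-collection
campaign in a fenced reserve: 15 samples per species per year (5 per
sub-area), 4 PCR replicates per sample, one 96-well library per species-year
holding the 60 sample replicates plus 12 blanks, 8 extraction, 8 negative and
8 positive controls (a 10-taxon assembly with strictly increasing
concentrations, default geometric ratio 1.5).

**Diet model.** Each diet species has a preference vector over the plant
community (availability^0.7 times a lognormal species tilt, sd 0.8; geese
1.6, making their diet the most distinct). Individual diets are Dirichlet
draws around the preference with concentration α₀ (default 40). For the
affected species (red deer), α₀ is scaled by `exp(−c·z)` with z the
standardized October red deer count and c the density-breadth coefficient
(default 0.7). High deer density therefore disperses individual deer diets,
which lowers deer-deer and deer-X pairwise overlap — the package's
operationalization of individuals diversifying their diets under
intraspecific competition. Defaults were chosen so expected intraspecific
overlap spans roughly 0.75-0.90 across the census range, the magnitude seen
in grazing assemblages of this kind.

**Noise model.** Replicate depth is Poisson (default 5000 reads).
Contamination: two dedicated contaminant taxa, absent from all true diets and
the survey, receive 2% of sample-well reads and 100% of (shallow)
blank/extraction/negative wells — making the contaminant-removal rule
exactly verifiable. Sequencing error: 10% of each taxon's reads land on two
fixed single-substitution variants, which the denoiser must fold back.
Tag switching: each read is reassigned to a uniformly random well of its
library with probability 0.2%. Junk amplicons outside the 10-220 bp marker
range take 0.5% of reads. Marker sequences are random 40-140 bp strings kept
below 90% pairwise identity so 97% clustering cannot merge distinct taxa.

**Census model.** Discrete logistic growth `N(t+1) = N + r·ε·N(1 − N/K)`
with lognormal noise ε on the growth increment (so r = 0 is exactly
constant). The default long-term reserve census starts from the documented
introductions (32 cattle 1983, 18 horses 1984, 44 red deer 1992) with K and
r chosen to approach the documented 2017 population sizes, then switches to
a fixed culling-era table for 2018-2021 in which deer fluctuate high-low
(2800/1900/2600/1700), horses decline, cattle rise and geese stay nearly
flat. Goose counts are deliberately uncorrelated with the deer cycle: geese
forage largely outside the fence and are not management-driven, and an
accidental correlation would confound the energy-variant AIC comparison.

**What the generator does not emulate:** amplification bias and
chimera formation, seasonal vegetation change (the survey is fixed across
years, as in the motivating study), spatial structure beyond the sub-area
label, goose-species identity of dung (pooled, as in the field), and
reference-database incompleteness. Passing tests therefore demonstrate the
pipeline's correctness and statistical power under these idealized but
field-sized conditions, not robustness to marker bias or taxonomic gaps.

## Filtering cascade: numerical choices

* Order: length → per-cell min reads → denoise → cluster → assign →
  contaminants → tag leaks → low-depth replicates → merge. Contaminants are
  removed before tag-leak calibration because they would otherwise dominate
  the blanks.
* Length bounds are a closed interval [10, 220]; the cell filter is strict
  (`< 10` reads dropped, 10 kept).
* Sequence identity is computed on the Levenshtein-optimal global alignment
  (edlib): identity = (columns − distance)/columns. For the
  substitution-dominated divergence relevant near the 97% threshold this
  equals matches/aligned-columns.
* Denoising folds a sequence into its most abundant neighbour at edit
  distance 1 (strictly more abundant; ties by lexicographic sequence order;
  chains resolve to the head by processing in descending abundance).
  Clustering is greedy and abundance-ordered: first centroid at ≥97% wins,
  otherwise a new OTU is founded. Both conserve total read mass.
* Contaminant rule: an OTU is removed iff its maximum within-well *relative*
  abundance over blank/extraction/negative wells exceeds its maximum over
  sample wells (relative, because control wells are systematically shallow;
  maxima for conservatism; positive controls excluded — they contain real
  plant DNA by design).
* Tag-leak rule: per library, τ = the largest share of any OTU's
  library-wide reads observed in a blank; cells holding ≤ τ of their OTU's
  library total are zeroed. Normalizing by the OTU's library total (rather
  than within-well) is what makes blanks informative: post-contaminant
  blanks hold a handful of reads, so their within-well proportions are
  degenerate, but their share of an OTU's total directly estimates the
  switching rate.
* Low-depth replicate threshold defaults to 100 retained reads (no published
  value exists; configurable). FOO is defined over retained replicates only;
  individuals with no retained replicate are dropped and logged, never
  imputed.

## Selectivity and overlap

The nine-category extended Braun-Blanquet scale (r, +, 1, 2m, 2a, 2b, 3, 4, 5
with upper bounds 0.1, 1, 5, 5, 12.5, 25, 50, 75, 100% cover) converts to
availability by category midpoints, averaged over quadrats and renormalized.
Group selectivity uses r = mean RRA over the species-year's individuals
(the per-individual mean of D values is available as an alternative mode —
the two differ because D is nonlinear). Taxa eaten but absent from the
survey get p = 0, D = 1, and a `survey_absent` flag. Classification uses a
±0.1 neutral band (no published cutoff; configurable).

Pianka overlap is computed on unnormalized FOO vectors (the index is scale
invariant per vector; this is asserted numerically in the tests), for
unordered within-year pairs only; each year's taxon set is the union over
its individuals, absent taxa contributing zeros. Vectors are pre-scaled by
their maximum before squaring to avoid underflow.

## Energetics

Individual DEE: 140·M^0.75 for large herbivores and 2.55·417·M^0.71 for
geese, times a residence fraction (1.0 ungulates, 0.5 geese — the halving is
applied exactly once; the "/2" printed in the goose allometry and the
textual halving describe the same correction). Masses: cattle 420, horse
375, red deer 120, greylag 3.3, barnacle 1.9 kg. The two goose species are
computed independently and summed into the pooled "geese" energy predictor.
Energy totals use October counts (matching November dung); the numeric
scale follows the allometries as printed and the unit label (default
kJ/day) is configuration metadata, since sources disagree on kJ vs kcal
labelling. Community mean body mass includes geese by default with an
ungulates-only flag; the long-term trend analyses reported by the
acceptance script use the ungulates-only May series, because synthetic
goose trajectories are unconstrained by any published count and a
pooled mean would be dominated by them.

## Beta regressions

Overlap records are modelled as Beta(μφ, (1−μ)φ) with logit(μ) = Xβ.
Boundary values (Pianka can hit 0 and 1) are compressed by
y′ = (y(n−1)+0.5)/n, applied only when boundaries occur and recorded in the
fit metadata.

* Designs: `interaction/year` expands to interaction main effects (treatment
  contrasts, alphabetical reference) plus one dummy per interaction ×
  non-reference year (10 + 30 columns for 10 interactions × 4 years);
  `interaction/energy` gives 10 intercept columns + 10 interaction-specific
  slopes on the z-standardized energy covariate (scaling stored for
  prediction). Rank is checked and aliased columns reported.
* The GLM maximizes the likelihood by L-BFGS-B with analytic gradients from
  a least-squares-on-logit start; standard errors come from the numerically
  differentiated observed information. Model 1 is fixed-effects only, per
  its formula.
* Model 2 adds a Gaussian year random intercept, integrated by a Laplace
  approximation: per-group scalar modes by Newton iteration (warm-started
  between outer steps), outer L-BFGS-B over (β, log φ, log σ). σ̂ below 1e-3
  is flagged as a boundary fit, where the model provably coincides with the
  GLM. The implementation reproduces glmmTMB's estimates to ≥5 significant
  figures on simulated data, and the quadrature-oracle test bounds the
  Laplace error directly.
* Observations sharing a design row and group share μ, so the likelihood is
  evaluated on per-cell sufficient statistics (n, Σlog y, Σlog(1−y)); a
  7080-record Model 2 collapses to ~40 cells, making each fit ~1 s.
* Overlap records share individuals and are pseudo-replicated; they are fit
  as independent observations (matching standard practice for this design),
  which inflates precision — slope signs and AIC rankings, the quantities
  interpreted here, are robust to this, but p-values on overlap models
  should be read cautiously.
* The AIC race reports AIC − AIC(total-energy variant); non-converged
  variants are excluded and flagged. Correlations of Model-1 predictions
  with deer counts report Pearson r, OLS slope and raw plus Holm-adjusted
  p-values (family = the 10 interactions).

## Problem sizes

The test suite exercises the full field design (240 individuals, 960 sample
wells, 7080 overlap records per run). Monte-Carlo checks use 15-100 seeds
per property as noted in each test; the end-to-end sign-recovery test runs
40 seeds and the acceptance script 100 seeds, both at the full design, with
a ≥80% success criterion. The whole suite runs in ~2.5 min and the
acceptance script in ~4 min on one CPU.

## Known limitations

* Taxonomic assignment is exact/threshold matching against a user-supplied
  reference FASTA; building reference databases and ranked taxonomy are out
  of scope.
* The Dirichlet diet model has no covariance structure between taxa (no
  co-occurring plant guilds), so it understates between-taxon correlation
  seen in real diets.
* Only four diet groups and a single grassland stratum are modelled; the
  marsh habitat and within-reserve movement are not.
* NMDS ordination and figure generation are intentionally excluded; the
  Bray-Curtis matrices are exported for external ordination tools.
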