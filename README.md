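# grazeniche

Density-dependent resource partitioning of temperate grazers, quantified from
dung eDNA metabarcoding.

## The problem

In fenced, predator-free grazing reserves (the motivating system holds Heck
cattle, Konik horses, red deer and wintering geese), herbivore populations are
regulated bottom-up by food. Whether density changes — natural fluctuation or
culling — reshape each species' diet and the overlap between species is a
central question for rewilding management. `grazeniche` implements the full
analysis chain for answering it from dung metabarcoding data:

1. **Metabarcode filtering** — per-PCR-replicate read tables are cleaned by a
   cascade: marker length filter (10-220 bp), <10-reads-per-replicate cell
   filter, single-mismatch denoising, greedy centroid clustering at 97%
   identity, reference assignment (≥97%), contaminant removal (control vs
   sample relative abundance), per-library tag-leak removal calibrated on
   blanks, low-depth replicate removal, and merging of replicates into
   per-individual diet profiles on three bases: presence/absence (P/A),
   frequency of occurrence (FOO) and relative read abundance (RRA).
2. **Selectivity** — Jacobs' index per species, year and plant taxon,

   D = (r − p) / (r + p − 2rp),

   where r is the taxon's mean RRA in the diet and p its availability from a
   Braun-Blanquet quadrat survey (category midpoints, renormalized);
   D ∈ [−1, 1], negative = avoidance, positive = selection.
3. **Niche overlap** — Pianka's index for every within-year pair of
   individuals j, k over taxa i,

   O_jk = Σᵢ p_ij p_ik / √(Σᵢ p²_ij · Σᵢ p²_ik),

   computed on FOO vectors and labelled by species interaction (10 pair types
   for 4 species).
4. **Energetics** — census counts become population daily energy expenditure
   via DEE = 140·M^0.75 (large herbivores) and DEE = 2.55·417·M^0.71 × ½
   (geese, which forage in the reserve only half the time), plus the
   count-weighted community mean body mass and its linear time trend.
5. **Density models** — beta regressions on pairwise overlap:
   Model 1 `overlap ~ interaction/year` (fixed effects) and Model 2
   `overlap ~ interaction/energy + (1|year)` (interaction-specific slopes on
   z-scored population energy, year random intercept, fitted by a Laplace
   approximation). An AIC race refits Model 2 with each species' energy as
   the covariate to ask *whose* density drives overlap.

A synthetic-community generator reproduces the full field design (15 dung
samples × 4 species × 4 years × 4 PCR replicates; 12 blanks and 8/8/8
extraction/negative/positive controls per library; contamination, sequencing
error and tag switching) with a density-dependent diet-breadth mechanism, so
every stage is testable without sequencing data.

## Worked example

```python
from grazeniche import jacobs_d, pianka
pianka([0.5, 0.5, 0.0], [0.0, 0.5, 0.5])   # 0.5   — half-shared diets
jacobs_d(0.2, 0.1)                         # 0.3846 — mild selection

from grazeniche.config import PipelineConfig
from grazeniche.pipeline import run_all
summary = run_all(PipelineConfig.model_validate({"seed": 1}))
```

The run directory then holds the diet profiles, selectivity table, overlap
records, energy tables and model outputs as CSV (each with a JSON schema
sidecar) plus a manifest of input/output hashes. For seed 1 the summary
prints:

```
n_individuals 240          # 15 samples x 4 species x 4 years
n_otus 25                  # all simulated taxa recovered, contaminants gone
retained_reads 5210023
deer_deer_corr_r -0.986    # deer-deer overlap falls as deer count rises
aic_delta {'total': 0.0, 'red_deer': -28.6, 'cattle': 423.9,
           'horse': 447.3, 'geese': 739.5}
deer-deer slope (total-energy model): -0.593
```

The AIC race ranks the red-deer-energy model far above the cattle, horse and
geese variants — the signature of deer-driven density dependence the
generator plants — and the strongly negative deer-deer slope shows deer
individuals diversifying their diets at high deer density.

The same pipeline runs from the shell:

```bash
grazeniche run-all --seed 1 --out my_run
grazeniche simulate --seed 2 --out sim    # write raw inputs only
grazeniche filter --reads sim/reads.tsv --sequences sim/sequences.fasta \
    --reference sim/reference.fasta --out profiles.csv
```

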