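# saprocom

Community-assembly analysis for saproxylic (deadwood-dependent) beetle
surveys: a reusable implementation of the statistical pipeline used to
study how beetle assemblages on decomposing logs change over a decade of
decay — who arrives, how abundance collapses as the resource pulse is
consumed, whether the number of species is explained by abundance alone,
how strongly early assemblages are filtered toward functionally similar
species, and when the community turns over.

## Who this is for

Ecologists analysing long-format emergence records — `(log, year,
species, count)` tables from stem emergence traps on experimental
deadwood — together with a species trait table (mixed continuous and
categorical traits), a reference phylogeny (Newick), and per-log
metadata (tree species, coordinates, exposure start year). Everything
is also exercisable without field data through a bundled
synthetic-community generator with known ground truth.

## The statistics at the core

* **Trend models.** Abundance, species number, species richness
  (species number controlled for abundance via a log-abundance
  covariate — the *more-individuals hypothesis* test) and functional
  diversity are modelled as penalized additive models:
  a tree-species fixed effect, one penalized smooth of years-since-
  exposure per tree species (`s(year, by=tree)`), and an isotropic
  spatial smooth of the log coordinates. Counts use a negative-binomial
  family (dispersion θ estimated by profile likelihood); smoothing
  parameters minimize a working-model REML criterion. Residual spatial
  structure is checked with Moran's I on inverse-distance weights.

* **Functional–phylogenetic diversity.** Species distances blend a
  Gower matrix *F* (mixed traits) and a cophenetic matrix *P*, each
  rescaled by its maximum:
  `d_ij(a) = (a·P_ij^p + (1−a)·F_ij^p)^(1/p)`, so `a=0` is purely
  functional and `a=1` purely phylogenetic. Assemblage dispersion is
  mean pairwise distance (MPD); habitat filtering is the standardized
  effect size (SES) of MPD against a tip-shuffling null
  (999 randomizations by default) — negative SES means clustering.

* **Model selection and trait importance.** The blend weight `a` is
  scanned over [0, 1] in steps of 0.025; the SES trend model with the
  highest adjusted R² selects `a`. Each trait's contribution is the
  change in adjusted R² when it is dropped from the Gower computation
  (ΔR² ≤ −0.03 counts as a substantial loss).

* **Compositional succession.** Bray–Curtis dissimilarity among
  assemblages with ≥ 4 species, non-metric MDS rotated to principal
  axes, sequential PERMANOVA (tree species, then year; 999
  permutations), and a conditional-inference tree segmenting the first
  ordination axis over years.

* **Temporal niches.** Per species, the abundance-weighted mean year
  of emergence and the weighted standard deviation around it (niche
  breadth), with a ≥ 3 individuals/year display filter.

## Worked example

Run the synthetic demo end to end (60-species pool, 21 logs, 8 years):

```bash
saprocom run --seed 1 --out demo/
```

The report printed at the end (abridged; numbers from this exact
command) is:

```
"overlap": {"total_species": 60, "total_individuals": 2218, "shared_all": 29},
"selected_a": 0.0,
"models": {
  "abundance": {"adj_r2": 0.692, "stars": {"s(year):spruce": "***", ...}},
  "ses_mfpd":  {"adj_r2": 0.317, ...}
},
"permanova": {"tree_species": {"r2": 0.119, "p": 0.005},
              "exposure_year": {"r2": 0.216, "p": 0.005}},
"ctree_groups": [[1], [2], [3], [4], [5], [6, 7]]
```

Reading it: all 60 simulated species were observed, but host-tree
filtering left only 29 emerging from all three tree species; the
blend-weight scan put the best SES-MFPD trend model at the functional
end (`a = 0`, adjusted R² 0.317) — the generator's early filter acts on
trait space; the year smooths of the abundance model are highly
significant (the simulated resource pulse declines at 0.35/yr); both
tree species and exposure year structure composition (PERMANOVA R²
0.12 and 0.22, both p = 0.005 at 199 permutations); and the inference
tree separates each early year before merging the late-succession
years. Every
stage also writes CSV/JSON artifacts (`scan_a.csv`, `ses_mfpd.csv`,
`pred_*.csv`, `ablation.csv`, `nmds_scores.csv`, `niche.csv`, ...)
into `demo/`.

The same stages are importable as a library:

```python
from saprocom.synthetic import SimulationConfig, simulate_dataset
from saprocom.traits import gower_distance, preprocess_traits
from saprocom.phylo import cophenetic_distance
from saprocom.diversity import blend_distances, ses_mpd

tree, traits, schema, design, community, truth = simulate_dataset(
    SimulationConfig(), seed=1)
F = gower_distance(preprocess_traits(traits, schema), schema)
P = cophenetic_distance(tree, sorted(traits.index))
ses = ses_mpd(sites, blend_distances(F, P, a=0.35), n_rand=999, seed=1)
```

## Layout

```
src/saprocom/
  data_model.py    survey design, community table, overlap, filters
  synthetic.py     generator: phylogeny, traits, emergence + ground truth
  traits.py        preprocessing, VIF, Gower distance
  phylo.py         Newick IO, grafting, cophenetic distances
  diversity.py     FPDist blend, MPD, tip-shuffling SES null
  trends.py        penalized additive models, Moran's I
  assembly.py      a-grid scan, trait ablation
  composition.py   Bray-Curtis, NMDS, PERMANOVA, inference tree
  niche.py         temporal niche position/breadth
  pipeline.py      stage orchestration and artifacts
  cli.py           `saprocom` command-line interface
docs/methods.md    model and generator documentation
```
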