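# flyatlas

Quantitative cross-species comparison of *Drosophila* blastoderm gene
expression atlases.

During the blastoderm stage, ~5,000–6,000 nuclei form a monolayer on the
embryo surface while the anterior–posterior (AP) patterning network — gap,
terminal and pair-rule genes — lays out the body plan. Cellular-resolution
expression atlases record, for each (virtual) nucleus, its 3D position and
the mean expression of each gene across six time cohorts staged by %
membrane invagination. `flyatlas` implements the comparative machinery for
such atlases, for researchers in evolutionary developmental biology and
gene-regulatory-network modelling:

- **Binary cell-type analysis.** A gene is "on" in a nucleus when its level
  exceeds a species/gene/time-point threshold `mode(values) + sd(values)`;
  a *cell type* is the subset of panel genes on. On a 9-gene panel there are
  2⁹ = 512 possible types; combinations in < 0.1% of nuclei are discarded
  as noise, and each (species, cohort) becomes a vector of cell-type
  proportions.
- **Expression distance score.** Per-time-point max-normalized cells are
  compared by the squared Euclidean distance over all genes *g* and cohorts
  *t*, `D(i,j) = Σ_{g,t} (E(i,g,t) − E(j,g,t))²` — squared so it is additive
  across genes and time points. Cells are matched spatially (atlases scaled
  to unit egg length, centered on their centers of mass) and by a local
  search over the 30 nearest target cells; displacement to the best match
  is the inverse-distance-weighted average position of the 10 lowest-D
  candidates.
- **Morphology.** Surface area as the summed area of the triangular mesh
  defined by the nucleus neighbor relation; local nuclear density in 15 µm
  disks; cylindrical (AP × angle) density maps averaged per cohort; egg
  length and shape profiles.
- **Developmental time matching.** Cohort-by-cohort Euclidean distances
  between cell-type proportion vectors, traversed by a greedy monotone path
  ("no steps backward in time"), plus the hourglass curve: mean ± SEM of
  all pairwise species distances per cohort.
- **Atlas building.** Per-embryo gain/offset estimation and
  closest-nucleus averaging of registered pointclouds, with the mean
  inter-embryo standard deviation as a per-gene quality metric.
- **Synthetic atlas generator.** Multi-species atlases with nuclei packed
  on an ellipsoid of revolution (furrow-shaped low-density regions
  included), gap/terminal/pair-rule-like AP patterns sharpening over six
  cohorts, and recorded ground truth (domain shifts, temporal offsets,
  per-embryo gains) — so the full pipeline runs and validates with no
  downloads.

## Worked example

Two synthetic species share identical embryo geometry, but the second one's
expression domains sit 2% of egg length more posterior:

```python
import numpy as np
from flyatlas import (SyntheticSpec, generate_atlas, normalize_expression,
                      local_best_match, displacement_field)

spec = SyntheticSpec(
    seed=21, n_species=2, species_names=("ref", "tgt"),
    egg_length=(400.0, 400.0), max_radius=(80.0, 80.0),
    n_nuclei=(1500, 1500), shift_field=(0.0, 0.02), temporal_offset=(0, 0))
ref = normalize_expression(generate_atlas(spec, 0)[0])
tgt = normalize_expression(generate_atlas(spec, 1)[0])

res = local_best_match(ref, tgt, k=30, m=10)
print(np.median(res.spatial_dist))      # 1.714
print(np.median(res.local_best_dist))   # 0.0041

field = displacement_field(res, ref)
print(np.median(field["ap_component"]) / tgt.egg_length)  # +0.0199
```

The nearest *spatial* match looks divergent (median score 1.71 in squared
normalized-expression units) because every cell's counterpart has moved.
Letting each cell match the best of its 30 nearest neighbors collapses the
median score to 0.004 — an equivalent cell exists a few diameters away —
and the median AP component of the displacement field, +0.0199 EL, recovers
the generative +0.02 EL shift. The same pattern read on real atlases is the
signature of conserved cell states rearranged in space.

`examples/` contains one short script per capability (synthetic atlases,
atlas building, morphology, cell types, expression distance, time
matching); each prints the numbers it computes and what they mean. A thin
CLI mirrors the stages:

```sh
flyatlas demo --out out/ --seed 1           # end-to-end on synthetic data
flyatlas synth | build | morph | celltypes | dist | timewarp --help
```

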