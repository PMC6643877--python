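# Methods

This note documents the models, conventions and numerical choices behind
`flyatlas`, in the order data flows through the pipeline.

## Data model and coordinate conventions

A **pointcloud** is one embryo: per-nucleus 3D coordinates (µm), expression
levels (arbitrary fluorescence units, finite and ≥ 0), and a symmetric
neighbor relation that triangulates the blastoderm surface. An **atlas** is
one species: positions and mean expression `E(i, g, t)` (optionally a std
tensor `S`) over six time cohorts, with nucleus row `i` denoting the same
virtual nucleus in every cohort (an explicit injective correspondence map
is accepted for files that store a non-trivial linking).

Cohorts are staged by % membrane invagination with half-open bins
[0,4), [4,9), [9,26), [26,51), [51,76), [76,100]. The published cohort
descriptions overlap at 50%; we resolve 50% into cohort 4 and treat 100%
as cohort 6.

The AP axis is the first principal component of the nucleus coordinates —
a rotation-invariant choice, since no axis convention is stored in the
files. `ap ∈ [0, 1]` is the normalized projection (anterior = 0); the sign
of the axis comes from an anterior marker when one is present (synthetic
data always records one), otherwise from a fixed deterministic rule, since
anterior cannot be inferred from geometry alone. `phi ∈ [−π, π)` is
measured from the dorsal reference (metadata, else +z) and increases
dorsal → left → ventral → right. Degenerate (collinear) geometry and a
dorsal reference parallel to the AP axis are rejected.

File formats: a tabular CSV dialect (`id, x, y, z, <genes…>, neighbors`
with `# key: value` metadata headers; one-sided neighbor lists are
symmetrized on read) and a best-effort whitespace-delimited reader for
BDTNP-style pointcloud text, validated on synthetic fixtures only. Floats
are written with shortest round-trip repr and parsed with round-trip
precision, so write→read is bit-exact.

## Synthetic study conditions

The generator's defaults are the study conditions and are not tuned per
analysis: five species with egg lengths 393.8–457.4 µm and target nucleus
counts 5,081–6,115 (the measured species averages), a shared 9-gene panel
(4 gap-like, 2 terminal-like, 3 pair-rule-like) over 6 cohorts.

**Geometry.** Nuclei are placed on a prolate ellipsoid of revolution
(semi-axes `egg_length/2`, `max_radius`, `max_radius`) by variable-radius
Poisson-disk dart throwing: candidates are sampled area-uniformly
(sphere-to-ellipsoid map with rejection by the area magnification factor)
and accepted when no prior nucleus lies within the mean of the two local
radii. The base radius is set from the RSA saturation density
(coverage ≈ 0.547) with a 25% margin so sampling stops at exactly the
target count; a count that would require spacing below `min_spacing`
(2 µm) raises. Furrow precursors are Gaussian density depressions
(amplitude 0.35; a cephalic ring at ap = 0.32 and a ventral stripe around
phi = π), implemented by locally enlarging the acceptance radius. The
neighbor relation is the 3D convex-hull triangulation of the nuclei — the
surface is convex (furrows modulate density, not shape), so the hull is an
exact, watertight surface mesh with none of the seam/pole bookkeeping an
unrolled-plane Delaunay would need. Nucleus placement is seeded by
(seed, geometry), so species differing only in expression parameters share
nuclei and have an identity ground-truth cell correspondence.

**Expression.** Gap-like genes are products of logistic boundary functions
of `ap` (scale = "width"), terminal-like genes single logistics at a pole,
pair-rule-like genes sums of 7 Gaussian stripes; stripe spans of the three
pair-rule-like genes are mutually offset so their overlap is large early
and shrinks as widths sharpen (per-cohort width factors 1.5 → 0.7) and
amplitudes ramp on (0.7 → 1.0). Species-level evolution enters as a single
AP shift of all domains (default 0–2% EL across the five species) and an
integer temporal offset of the dynamic program (cohort `t` uses dynamics
`clip(t − offset, 1, 6)`). Both are recorded as ground truth.

**Embryo sets.** An embryo at cohort `t` is
`gain_e,g × E(·,g,t) + offset_e,g + ε`, clipped at 0, with lognormal gains
(log-sd 0.2), offsets uniform in 1–5% of each gene's max, and per-nucleus
Gaussian noise with sd 1% of the max — modest inter-embryo variability of
the kind gain/offset correction is meant to remove. Offsets are kept
positive and well above the noise sd so the non-negativity clip is
essentially inactive and recovery tests are unbiased.

All randomness flows through one seeded `numpy` generator; identical
(spec, seed) gives bit-identical output.

What the generator does **not** emulate: real nuclear packing mechanics
(only blue-noise spacing), dorsoventral pattern modulation (patterns are
functions of `ap` alone), gene–gene regulatory dynamics, nuclear movement
between cohorts, and registration error between embryos (embryos share the
atlas indexing exactly). Passing tests therefore demonstrate correctness
of the *algorithms* under realistic geometry and noise, not robustness to
registration artefacts or DV structure in real atlases.

## Atlas building

Gains and offsets are estimated per embryo *per gene* (whether the
original estimation was per-gene or global per embryo is not recorded; the
per-gene choice is strictly more expressive). The model is
`raw_e = gain_e·consensus + offset_e`, fit by alternating (a) consensus =
per-nucleus mean of inverse-corrected embryos and (b) per-embryo OLS of
raw against consensus, for 5 rounds or until the parameters change by
< 1e-8 relative. The affine gauge is fixed by constraining the mean gain
to 1 and mean offset to 0 (degenerate, constant-expression embryos are
pinned at gain 1 with a warning and excluded from the gauge). Consequently
recovered gains equal true gains only up to the true gains' sample mean,
and the built atlas matches the generative mean up to one affine map —
recovery tests normalize accordingly. Non-positive fitted gains (a failed
embryo) are clamped to 1 with a warning. The cohort slice is the
per-nucleus mean of corrected embryos; `S` is the sample sd (ddof = 1,
undefined for a single embryo); the per-gene quality metric is `S`
averaged over nuclei, then cohorts.

## Morphology

Mesh faces are the 3-cliques of the neighbor graph, minus cliques that
merely cover an interior degree-3 vertex (whose three surrounding
triangles are the real faces); a 4-vertex tetrahedron keeps all four
faces. The result must be a triangulated manifold, possibly with boundary
(each edge in 1–2 faces); an edge in > 2 faces or in none raises an error
listing the offending edges. Surface area is the summed face area — the
surface through nucleus centers, a slight underestimate of the smooth
surface (O((spacing/radius)²), ≈ 0.1% at blastoderm scales).

The 15 µm density disk is implemented as the 3D Euclidean ball intersected
with the surface nuclei; the chord-vs-geodesic discrepancy is < 1% at
~100 µm curvature radii, and whether the original used geodesic distance
is unrecorded. The center nucleus counts in its own disk (an isolated
nucleus has density 1/(π·15²), not 0); the convention is configurable.
Density maps resample per-nucleus density onto a regular (ap × phi) grid —
default 100 × 16, a grid size that is a display choice — by
nearest-nucleus lookup with phi treated circularly (phi embedded on a
circle of radius 1/2π so the two axes weigh comparably), then average over
the cohort's embryos.

## Cell-type analysis

The on/off threshold is mode + sd per (species, gene, cohort). "Mode" of
near-continuous data is ill-defined, so: if > 50% of values are exactly
equal, that value; otherwise the center of the fullest of 100 equal-width
bins over [min, max], ties to the lower bin. The sd is the sample (n−1)
convention; "on" means strictly greater, so an all-identical gene/cohort
calls everything off. All three conventions are configurable, and the
exact observed-type count on real atlases is sensitive to them.

Rare combinations are filtered at pooled frequency < 0.1% (strictly less:
exactly 0.1% is retained), pooled globally across species, cohorts and
nuclei, because the observed type universe is defined genus-wide; a
per-(species, cohort) scope is available. Proportions are over **all**
nuclei and are not renormalized after filtering. Gene-count distributions
support restricted panels (e.g. the two-gene pair-rule overlap analysis).

## Expression distance and matching

Expression is normalized per gene per cohort to max 1 over nuclei
(all-zero combinations are left unchanged with a warning). `D` is the
squared Euclidean distance over the panel × cohorts, additive by
construction. Spatial frames divide by egg length and center on the center
of mass; positions default to the final cohort (the conventional rendering
cohort; configurable). The local candidate set is the k = 30 target nuclei
nearest to the query's mapped position — the neighborhood lives where the
candidates live — and `D` is evaluated by brute force over all candidates,
so the spatial match (the 1-NN) is always included and
`local_best ≤ spatial` holds identically. Displacement uses weights
`1/(D + 1e-12)` over the m = 10 best candidates; exact matches (D = 0)
short-circuit to the unweighted centroid of the zero-D candidates.
Displacements are reported in target-atlas µm. No one-to-one assignment is
attempted: with differing cell counts, expansion/contraction of a cell
population is the signal, not an error.

Per-nucleus displacement directions are noisy wherever `D` is locally flat
(between stripes, at the poles), because the 10 best candidates then
spread tangentially; the shift signal lives in the aggregate (mean or
median) field, which is how the recovery tests read it.

## Time matching and the hourglass curve

Profile vectors are aligned over the union of observed types (absent
types = 0) and compared by plain Euclidean distance — deliberately not the
squared distance used for cells. The matching path starts at cohort 1 ↦ 1
and greedily takes the minimum-distance target cohort at or after the
previous match; ties break to the earliest cohort (preserving maximal
future flexibility); the per-step exhaustive scan *is* the algorithm, and
a target cohort may absorb many reference cohorts. The hourglass curve is
the per-cohort mean ± SEM (sample sd / √n_pairs) over all unordered
species pairs — 10 pairs for five species.

## Problem sizes and verification

The test suite and acceptance script run entirely on synthetic data:
atlases of 200–1,500 nuclei for unit and property tests (200-nucleus toys
for brute-force oracles), 3,000 for parameter-recovery runs, and 5,535–
6,000 for the geometry oracles — sizes at which every oracle bound has
comfortable margin while the whole suite stays fast. Deterministic
fixtures are seeded; hypothesis tests run derandomized. Known limitations:
the BDTNP-style reader is validated only on synthetic fixtures; counts of
observed cell types on real atlases depend on the unrecorded mode
estimator; and real-data quantities (genus-wide type counts, measured
morphometrics) require the deposited atlases, which this package does not
download.
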