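"""Developmental time matching and the hourglass divergence curve.

Five synthetic species are staged by the same morphological clock, but one
of them runs its expression program one cohort late. Matching cohorts by
cell-type profile distance exposes the lag; averaging all pairwise profile
distances per cohort gives the cross-species divergence curve.
"""

import numpy as np

from flyatlas import (
    SyntheticSpec, binarize, enumerate_cell_types, generate_atlas,
    hourglass_curve, match_timepoints, profile_distance_matrix,
)

spec = SyntheticSpec(seed=1, n_nuclei=(1000,) * 5,
                     temporal_offset=(0, 0, 0, 0, 1))
atlases = [generate_atlas(spec, s)[0] for s in range(5)]
calls = [binarize(a) for a in atlases]
profiles, _ = enumerate_cell_types(calls)

ref = profiles[0]
print(f"monotone time-point paths from {ref.species}:")
for p in profiles[1:]:
    path = match_timepoints(profile_distance_matrix(ref, p)).path
    lag = " <- runs one cohort late" if p.species == "synE" else ""
    print(f"  -> {p.species}: {path.tolist()}{lag}")
print("(a path above the diagonal means the target's expression program "
      "lags its morphological clock)")

hg = hourglass_curve(profiles)
print(f"\nhourglass curve over {hg['n_pairs']} species pairs per cohort:")
for t, (m, s) in enumerate(zip(hg["mean"], hg["sem"]), start=1):
    print(f"  cohort {t}: mean profile distance {m:.4f} +/- {s:.4f} (SEM)")
print("(decreasing distance = species converging toward the phylotypic "
      "period as cellularization proceeds)")
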