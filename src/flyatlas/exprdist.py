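"""Expression distance scoring between species atlases.

Each cell is described by the vector of its (per-time-point max-normalized)
expression levels over all panel genes and all six cohorts; two cells are
compared by the *expression distance score*

    D(i, j) = sum over genes g and cohorts t of (E_i(g, t) - E_j(g, t))^2,

the squared Euclidean distance, chosen because it is additive across genes
and time points. Two matchings are computed between a reference and a
target atlas:

- *spatial match*: embryos are scaled to unit egg length and centered on
  their centers of mass; each reference cell is scored against its nearest
  target cell in that shared frame;
- *local best match*: the score is minimised over the k (default 30)
  target cells nearest to the query's mapped position — a local search of
  roughly 3-4 cell diameters that absorbs small morphological rearrangements
  without requiring one-to-one assignment.

The displacement to the best match is estimated as the inverse-distance-
weighted average of the 3D locations of the m (default 10) lowest-scoring
candidates, reported in target-atlas um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from flyatlas.atlas_io import Atlas, to_cylindrical
from flyatlas.morphology import egg_length as _egg_length

__all__ = ["MatchResult", "normalize_expression", "expression_distance",
           "spatial_match", "local_best_match", "weighted_displacement",
           "displacement_field"]

#: Regulariser added to expression distances in inverse-distance weights.
EPSILON = 1e-12


@dataclass
class MatchResult:
    """Per-reference-nucleus matching of one atlas pair.

    All arrays are indexed by reference nucleus. ``spatial_dist`` is the
    expression distance score to the nearest spatial neighbor,
    ``local_best_dist`` the minimum over the local candidate set (always
    <= spatial), ``displacement`` the 3-vector (um, target frame) from the
    query's mapped position to the weighted best-match location
    ``weighted_target``.
    """

    query_index: np.ndarray
    spatial_index: np.ndarray
    spatial_dist: np.ndarray
    local_best_index: np.ndarray
    local_best_dist: np.ndarray
    displacement: np.ndarray
    weighted_target: np.ndarray
    query_position: np.ndarray  # query mapped into target um frame


def normalize_expression(atlas: Atlas) -> Atlas:
    """Scale each (gene, cohort) so the maximum over nuclei is 1.

    All-zero gene/cohort combinations are left unchanged with a warning.
    """
    E = atlas.E.copy()
    maxes = E.max(axis=0)  # (genes, T)
    zero = maxes == 0
    if zero.any():
        warnings.warn(
            f"{atlas.species}: {int(zero.sum())} all-zero gene/cohort "
            "combination(s) left unnormalized", stacklevel=2)
    scale = np.where(zero, 1.0, maxes)
    E /= scale
    return Atlas(
        species=atlas.species, positions=atlas.positions, E=E,
        genes=list(atlas.genes), S=atlas.S, egg_length=atlas.egg_length,
        correspondence=atlas.correspondence, neighbors=atlas.neighbors,
        dorsal=atlas.dorsal, anterior=atlas.anterior,
    )


def expression_distance(
    ref: Atlas, i: int, target: Atlas, j: int,
    genes: list[str] | None = None, cohorts: list[int] | None = None,
) -> float:
    """Expression distance score D(i, j) between two cells.

    Sums squared differences over the requested genes and cohorts (defaults:
    the reference's full panel and all cohorts). Both atlases should already
    be max-normalized so levels are comparable.
    """
    genes = genes if genes is not None else list(ref.genes)
    vi = ref.expression_vectors(genes, cohorts)[i]
    vj = target.expression_vectors(genes, cohorts)[j]
    return float(((vi - vj) ** 2).sum())


def _scaled_positions(atlas: Atlas, cohort: int | None = None) -> np.ndarray:
    """Positions at the chosen cohort (default final), unit-EL, COM-centered."""
    pos = atlas.positions[(cohort - 1) if cohort else -1]
    el = atlas.egg_length if atlas.egg_length else _egg_length(pos)
    return (pos - pos.mean(axis=0)) / el


def spatial_match(
    ref: Atlas, target: Atlas, cohort: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest target nucleus for each reference nucleus in the shared frame.

    Both atlases are scaled to unit egg length and centered on their
    centers of mass; matching is plain nearest-neighbor in that space.
    Returns (target indices, spatial distances in EL units).
    """
    q = _scaled_positions(ref, cohort)
    t = _scaled_positions(target, cohort)
    dist, idx = cKDTree(t).query(q)
    return idx, dist


def weighted_displacement(
    cand_positions: np.ndarray, cand_dists: np.ndarray,
    query_position: np.ndarray, m: int = 10,
) -> np.ndarray:
    """Displacement to the inverse-distance-weighted best-match location.

    Averages the 3D positions of the ``m`` candidates with the smallest
    expression distance, weighted by 1/(D + epsilon); exact matches (D = 0)
    short-circuit to the unweighted centroid of the zero-D candidates.
    Returns ``weighted location - query_position``.
    """
    cand_positions = np.asarray(cand_positions, dtype=float)
    cand_dists = np.asarray(cand_dists, dtype=float)
    if cand_positions.ndim != 2 or len(cand_positions) == 0:
        raise ValueError("need at least one candidate")
    m = min(m, len(cand_dists))
    sel = np.argpartition(cand_dists, m - 1)[:m]
    d = cand_dists[sel]
    p = cand_positions[sel]
    if np.any(d == 0):
        loc = p[d == 0].mean(axis=0)
    else:
        w = 1.0 / (d + EPSILON)
        loc = (w[:, None] * p).sum(axis=0) / w.sum()
    return loc - np.asarray(query_position, dtype=float)


def local_best_match(
    ref: Atlas, target: Atlas,
    genes: list[str] | None = None, cohorts: list[int] | None = None,
    k: int = 30, m: int = 10, cohort: int | None = None,
) -> MatchResult:
    """Score every reference cell against its local target neighborhood.

    Candidates are the ``k`` target nuclei nearest (unit-EL, centered
    space) to the query's mapped position; the expression distance score is
    evaluated by brute force over all of them. The candidate set contains
    the spatial match, so ``local_best_dist <= spatial_dist`` everywhere.
    Displacements are reported in target-atlas um.
    """
    genes = genes if genes is not None else list(ref.genes)
    if target.n_nuclei < k:
        warnings.warn(
            f"target atlas has only {target.n_nuclei} nuclei (< k={k}); "
            "using all of them", stacklevel=2)
        k = target.n_nuclei
    q_scaled = _scaled_positions(ref, cohort)
    t_scaled = _scaled_positions(target, cohort)
    tree = cKDTree(t_scaled)
    _, neigh = tree.query(q_scaled, k=k)  # (n_ref, k), nearest-first
    if k == 1:
        neigh = neigh[:, None]

    R = ref.expression_vectors(genes, cohorts)      # (n_ref, GT)
    T = target.expression_vectors(genes, cohorts)   # (n_tgt, GT)
    # D to every candidate: (n_ref, k)
    diffs = T[neigh] - R[:, None, :]
    D = (diffs ** 2).sum(axis=-1)

    spatial_idx = neigh[:, 0]
    spatial_dist = D[:, 0]
    best_col = D.argmin(axis=1)
    rows = np.arange(len(q_scaled))
    local_idx = neigh[rows, best_col]
    local_dist = D[rows, best_col]

    el_t = target.egg_length if target.egg_length else _egg_length(
        target.positions[(cohort - 1) if cohort else -1])
    t_pos_um = target.positions[(cohort - 1) if cohort else -1]
    com_t = t_pos_um.mean(axis=0)
    q_um = q_scaled * el_t + com_t  # query mapped into the target um frame

    displacement = np.empty((len(rows), 3))
    weighted = np.empty((len(rows), 3))
    for i in rows:
        disp = weighted_displacement(t_pos_um[neigh[i]], D[i], q_um[i], m=m)
        displacement[i] = disp
        weighted[i] = q_um[i] + disp

    return MatchResult(
        query_index=rows,
        spatial_index=spatial_idx,
        spatial_dist=spatial_dist,
        local_best_index=local_idx,
        local_best_dist=local_dist,
        displacement=displacement,
        weighted_target=weighted,
        query_position=q_um,
    )


def displacement_field(
    result: MatchResult, ref: Atlas, cohort: int | None = None
) -> dict[str, np.ndarray]:
    """Cylindrical-projection displacement table for quiver-style plots.

    Per reference nucleus: its (ap, phi) position, the displacement's 3D
    magnitude (um — which may exceed the length of its 2D projection), its
    component along the AP axis (um, positive toward posterior) and the
    in-plane direction angle atan2(tangential, AP).
    """
    if len(result.displacement) == 0:
        raise ValueError("empty match result")
    t_idx = (cohort - 1) if cohort else -1
    coords = ref.positions[t_idx]
    cyl = to_cylindrical(ref, cohort=(cohort or ref.n_cohorts))
    from flyatlas.atlas_io import principal_axis
    axis = principal_axis(coords, ref.anterior)
    disp = result.displacement
    mag = np.linalg.norm(disp, axis=1)
    ap_comp = disp @ axis
    tang = np.linalg.norm(disp - np.outer(ap_comp, axis), axis=1)
    direction = np.arctan2(tang, ap_comp)
    return {"ap": cyl.ap, "phi": cyl.phi, "magnitude": mag,
            "ap_component": ap_comp, "direction": direction}
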