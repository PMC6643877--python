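"""Developmental time-point matching and the hourglass divergence curve.

Species are staged by a morphological clock (% membrane invagination), but
their gene-expression programs need not progress at the same rate. To
compare expression-defined time against morphological time, each (species,
cohort) is summarised as a cell-type proportion vector; cohorts of two
species are compared by the Euclidean distance between their vectors; and
a reference species' cohorts are mapped onto a target's by a greedy
monotone path through the distance matrix: cohort 1 maps to cohort 1, and
each later cohort maps to the minimum-distance target cohort at or after
the previous match ("no steps backward in time"). The per-step exhaustive
scan is the algorithm, by construction.

The hourglass curve averages, per cohort, the pairwise profile distances
over all unordered species pairs (mean +/- standard error of the mean);
with five species that is 10 comparisons per time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from flyatlas.celltypes import CellTypeProfile

__all__ = ["TimepointMatching", "profile_distance_matrix", "match_timepoints",
           "hourglass_curve", "align_profiles"]


@dataclass
class TimepointMatching:
    """Monotone map from reference cohorts to target cohorts.

    ``path[t]`` (1-based cohorts) is the target cohort matched to reference
    cohort ``t+1``; ``dist_matrix[a, b]`` the profile distance between
    reference cohort ``a+1`` and target cohort ``b+1``.
    """

    path: np.ndarray
    dist_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64)
        if self.path[0] != 1 or np.any(np.diff(self.path) < 0):
            raise ValueError("path must start at 1 and be monotone non-decreasing")


def align_profiles(profiles: list[CellTypeProfile]) -> list[np.ndarray]:
    """Re-index proportion matrices over the union of observed types.

    Types absent from a species get proportion 0. Returns one (T, n_union)
    matrix per profile, with a common column order.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    universe = profiles[0].universe
    for p in profiles[1:]:
        if p.universe != universe:
            raise ValueError("profiles use different gene panels")
    union: list[tuple[str, ...]] = sorted(
        {t for p in profiles for t in p.types},
        key=lambda t: (len(t), tuple(universe.index(g) for g in t)))
    col = {t: k for k, t in enumerate(union)}
    out = []
    for p in profiles:
        M = np.zeros((p.proportions.shape[0], len(union)))
        for k, t in enumerate(p.types):
            M[:, col[t]] = p.proportions[:, k]
        out.append(M)
    return out


def profile_distance_matrix(ref: CellTypeProfile,
                            target: CellTypeProfile) -> np.ndarray:
    """Euclidean distances between cohort proportion vectors.

    Entry (a, b) compares reference cohort a+1 with target cohort b+1;
    vectors are aligned over the union of the two species' observed types
    (absent types contribute 0). Plain Euclidean distance — unlike the
    squared distance used for per-cell expression scoring.
    """
    R, Tm = align_profiles([ref, target])
    diff = R[:, None, :] - Tm[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def match_timepoints(dist_matrix: np.ndarray) -> TimepointMatching:
    """Greedy monotone time-point matching through a distance matrix.

    ``path(1) = 1``; for each later reference cohort the match is the
    argmin over target cohorts >= the previous match, ties broken toward
    the earliest target cohort.
    """
    D = np.asarray(dist_matrix, dtype=float)
    if D.ndim != 2 or not np.all(np.isfinite(D)):
        raise ValueError("dist_matrix must be a finite 2D matrix")
    n_ref, n_tgt = D.shape
    path = np.empty(n_ref, dtype=np.int64)
    path[0] = 1
    for t in range(1, n_ref):
        lo = path[t - 1] - 1
        best, best_d = lo, np.inf
        for b in range(lo, n_tgt):  # exhaustive scan; ties -> earliest
            if D[t, b] < best_d:
                best, best_d = b, D[t, b]
        path[t] = best + 1
    return TimepointMatching(path=path, dist_matrix=D)


def hourglass_curve(
    profiles: list[CellTypeProfile],
) -> dict[str, np.ndarray]:
    """Per-cohort mean (+/- SEM) profile distance over all species pairs.

    Returns arrays ``mean``, ``sem`` (sd/sqrt(n_pairs), sample sd) and the
    raw per-pair ``distances`` of shape (n_pairs, T), plus ``n_pairs``.
    """
    if len(profiles) < 2:
        raise ValueError("hourglass curve needs >= 2 species")
    aligned = align_profiles(profiles)
    T = aligned[0].shape[0]
    pairs = list(combinations(range(len(profiles)), 2))
    dists = np.empty((len(pairs), T))
    for r, (i, j) in enumerate(pairs):
        dists[r] = np.sqrt(((aligned[i] - aligned[j]) ** 2).sum(axis=1))
    mean = dists.mean(axis=0)
    sd = dists.std(axis=0, ddof=1) if len(pairs) > 1 else np.zeros(T)
    return {"mean": mean, "sem": sd / np.sqrt(len(pairs)),
            "distances": dists, "n_pairs": len(pairs)}
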