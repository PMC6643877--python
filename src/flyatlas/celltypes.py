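"""Threshold-based binary cell-type analysis.

A gene is called "on" in a nucleus when its expression exceeds a species-,
gene- and time-point-specific threshold equal to mode(values) + sd(values),
where the values are all nuclei's levels for that gene at that time point.
A *cell type* is the subset of panel genes on in a nucleus at a time point.
Types observed in less than a small fraction of nuclei (default 0.1%,
pooled over species, cohorts and nuclei) are treated as measurement noise
and removed. Each (species, cohort) is then summarised as a vector of
cell-type proportions over all nuclei — the input to developmental
time-point matching.

Conventions (each of which is configurable):

- mode of near-continuous values: if more than half the values are exactly
  equal, that value; otherwise the center of the fullest of 100 equal-width
  histogram bins over [min, max], ties broken toward the lower bin;
- standard deviation: sample (n-1);
- "on" means strictly greater than the threshold, so an all-identical
  gene/time point calls every nucleus off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from flyatlas.atlas_io import Atlas

__all__ = ["BinaryCalls", "CellTypeProfile", "threshold", "binarize",
           "enumerate_cell_types", "gene_count_distribution",
           "possible_cell_types"]


def possible_cell_types(n_genes: int, size: int | None = None) -> int:
    """Number of possible cell types on a panel of ``n_genes`` genes.

    All subsets (2**n) when ``size`` is None, else subsets of that size.
    """
    from math import comb
    if size is None:
        return 2 ** n_genes
    return comb(n_genes, size)


def estimate_mode(values: np.ndarray, n_bins: int = 100) -> float:
    """Mode estimate for near-continuous data.

    If > 50% of values are exactly equal, that value is the mode; otherwise
    the center of the fullest of ``n_bins`` equal-width bins over
    [min, max] (ties -> lower bin).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take the mode of no values")
    uniq, counts = np.unique(values, return_counts=True)
    top = counts.argmax()
    if counts[top] > values.size / 2:
        return float(uniq[top])
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    b = int(hist.argmax())  # argmax takes the first = lower bin on ties
    return float(0.5 * (edges[b] + edges[b + 1]))


def threshold(values: np.ndarray, ddof: int = 1, n_bins: int = 100) -> float:
    """On/off threshold for one (species, gene, time point): mode + sd.

    All-identical values yield threshold = value (sd 0) with a warning;
    under the strict ">" on-rule no nucleus is called on in that case.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("threshold needs at least 2 values")
    if np.ptp(values) == 0:
        warnings.warn("all expression values identical; threshold equals the "
                      "common value and every nucleus is called off",
                      stacklevel=2)
        return float(values[0])
    return estimate_mode(values, n_bins=n_bins) + float(values.std(ddof=ddof))


@dataclass
class BinaryCalls:
    """On/off calls for one species: boolean (n, n_genes, T) plus thresholds."""

    species: str
    calls: np.ndarray        # bool (n, genes, T)
    thresholds: np.ndarray   # (genes, T)
    genes: list[str]

    @property
    def n_cohorts(self) -> int:
        return self.calls.shape[2]

    def restrict(self, panel: list[str]) -> "BinaryCalls":
        idx = [self.genes.index(g) for g in panel]
        return BinaryCalls(self.species, self.calls[:, idx],
                           self.thresholds[idx], list(panel))


def binarize(atlas: Atlas, genes: list[str] | None = None,
             ddof: int = 1) -> BinaryCalls:
    """Apply the mode+sd threshold per (gene, cohort) across all nuclei."""
    genes = list(genes) if genes is not None else list(atlas.genes)
    gi = [atlas.gene_index(g) for g in genes]
    n, _, T = atlas.E.shape
    calls = np.zeros((n, len(genes), T), dtype=bool)
    thr = np.zeros((len(genes), T))
    for a, g in enumerate(gi):
        for t in range(T):
            vals = atlas.E[:, g, t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thr[a, t] = threshold(vals, ddof=ddof)
            calls[:, a, t] = vals > thr[a, t]
    return BinaryCalls(atlas.species, calls, thr, genes)


@dataclass
class CellTypeProfile:
    """Cell-type proportion vectors for one species.

    ``types`` is the ordered list of retained gene subsets (tuples of gene
    names); ``proportions[t, k]`` is the fraction of the species' nuclei in
    cohort ``t+1`` whose on-gene set equals ``types[k]``. Proportions are
    over *all* nuclei, so after rare-type filtering they may sum to
    slightly less than 1.
    """

    species: str
    types: list[tuple[str, ...]]
    proportions: np.ndarray  # (T, n_types)
    universe: list[str]

    def vector(self, cohort: int) -> np.ndarray:
        return self.proportions[cohort - 1]


def _masks(calls: BinaryCalls) -> np.ndarray:
    """Bitmask of on-genes per (nucleus, cohort)."""
    n, G, T = calls.calls.shape
    weights = (1 << np.arange(G)).astype(np.int64)
    return np.tensordot(calls.calls.astype(np.int64), weights, axes=([1], [0]))


def enumerate_cell_types(
    calls_by_species: list[BinaryCalls],
    min_frac: float = 0.001,
    filter_scope: str = "global",
) -> tuple[list[CellTypeProfile], list[tuple[str, ...]]]:
    """Enumerate observed cell types and per-(species, cohort) proportions.

    Every nucleus x cohort is assigned the subset of on genes; subsets whose
    pooled frequency (over all species, cohorts and nuclei when
    ``filter_scope="global"``; per species x cohort when ``"per_cohort"``)
    is strictly below ``min_frac`` are removed. Proportions are computed
    over all nuclei of each (species, cohort) and are *not* renormalized
    after filtering. Returns the per-species profiles and the retained
    type list (ordered by subset size, then by gene panel order).
    """
    if not calls_by_species:
        raise ValueError("need at least one species")
    genes = calls_by_species[0].genes
    for c in calls_by_species[1:]:
        if c.genes != genes:
            raise ValueError("all species must share the gene panel")
    G = len(genes)
    T = calls_by_species[0].n_cohorts

    masks = [_masks(c) for c in calls_by_species]  # each (n, T)
    pooled = np.concatenate([m.ravel() for m in masks])
    vals, counts = np.unique(pooled, return_counts=True)

    if filter_scope == "global":
        keep = set(vals[counts / pooled.size >= min_frac].tolist())
    elif filter_scope == "per_cohort":
        keep = set()
        for m in masks:
            n = m.shape[0]
            for t in range(T):
                v, c = np.unique(m[:, t], return_counts=True)
                keep.update(v[c / n >= min_frac].tolist())
    else:
        raise ValueError(f"unknown filter_scope {filter_scope!r}")

    def subset(mask: int) -> tuple[str, ...]:
        return tuple(g for b, g in enumerate(genes) if mask >> b & 1)

    order = sorted(keep, key=lambda m: (bin(m).count("1"), m))
    types = [subset(m) for m in order]
    col = {m: k for k, m in enumerate(order)}

    profiles = []
    for c, m in zip(calls_by_species, masks):
        n = m.shape[0]
        P = np.zeros((T, len(order)))
        for t in range(T):
            v, cnt = np.unique(m[:, t], return_counts=True)
            for mask, k in zip(v, cnt):
                if mask in col:
                    P[t, col[mask]] = k / n
        profiles.append(CellTypeProfile(c.species, types, P, list(genes)))
    return profiles, types


def gene_count_distribution(
    calls: BinaryCalls, panel: list[str] | None = None
) -> np.ndarray:
    """Per-cohort proportions of nuclei with 0..k panel genes on.

    Returns shape (T, k+1); each row sums to 1. Restricting ``panel`` to a
    gene pair (e.g. the two alternating pair-rule stripes) reproduces the
    both-on / one-on / none-on dynamics analysis.
    """
    c = calls.restrict(panel) if panel is not None else calls
    if not c.genes:
        raise ValueError("panel must be non-empty")
    n, G, T = c.calls.shape
    counts = c.calls.sum(axis=1)  # (n, T)
    out = np.zeros((T, G + 1))
    for t in range(T):
        binc = np.bincount(counts[:, t], minlength=G + 1)
        out[t] = binc / n
    return out
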