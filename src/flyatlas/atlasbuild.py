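"""Atlas construction from registered pointclouds.

Builds a species atlas cohort slice from a set of individual-embryo
pointclouds that share nucleus indexing: estimates a per-embryo (per-gene)
multiplicative gain and additive offset so that inverse-corrected embryos
agree as closely as possible, averages the corrected embryos per nucleus,
and summarises inter-embryo reproducibility as the mean standard deviation
of expression per gene (the atlas quality metric).

The gain/offset model is ``raw_e = gain_e * consensus + offset_e``; fitting
alternates (a) consensus = per-nucleus mean of inverse-corrected embryos
and (b) per-embryo ordinary least squares of the raw values against the
consensus, with the scale indeterminacy fixed by constraining the mean
gain to 1. The alternation runs a fixed small number of rounds or until
the fit stops changing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from flyatlas.atlas_io import Atlas, Pointcloud

__all__ = ["GainOffset", "estimate_gain_offset", "average_embryos",
           "expression_quality", "build_atlas_cohort"]

_MAX_ITER = 5
_REL_TOL = 1e-8


@dataclass
class GainOffset:
    """Affine intensity correction for one embryo and one gene.

    The raw measurement is modelled as ``gain * consensus + offset``; the
    corrected value is ``(raw - offset) / gain``. Gains are clamped positive.
    """

    gain: float
    offset: float

    def correct(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, float) - self.offset) / self.gain


def _check_shared_indexing(embryos: list[Pointcloud]) -> None:
    if len(embryos) < 1:
        raise ValueError("need at least one embryo")
    n0 = embryos[0].n_nuclei
    for e in embryos[1:]:
        if e.n_nuclei != n0 or not np.array_equal(e.ids, embryos[0].ids):
            raise ValueError("embryos must share nucleus indexing")


def estimate_gain_offset(embryos: list[Pointcloud], gene: str) -> list[GainOffset]:
    """Estimate per-embryo gain/offset corrections for one gene.

    Requires >= 2 embryos with shared nucleus indexing. A constant-expression
    embryo has no identifiable gain: it gets gain 1 and an offset equal to
    its mean difference from the consensus, with a warning. Negative fitted
    gains (a failed embryo) are clamped to 1 with a warning.
    """
    _check_shared_indexing(embryos)
    if len(embryos) < 2:
        raise ValueError("gain/offset estimation needs >= 2 embryos")
    V = np.stack([e.expr[:, e.genes.index(gene)] for e in embryos])  # (E, n)
    nE = V.shape[0]
    gains = np.ones(nE)
    offsets = np.zeros(nE)
    degenerate = np.array([np.ptp(v) == 0 for v in V])
    if degenerate.any():
        warnings.warn(
            f"gene {gene!r}: {int(degenerate.sum())} constant-expression "
            "embryo(s); gain fixed to 1", stacklevel=2)

    prev = None
    for _ in range(_MAX_ITER):
        corrected = (V - offsets[:, None]) / gains[:, None]
        consensus = corrected.mean(axis=0)
        cvar = consensus.var()
        for e in range(nE):
            if degenerate[e] or cvar == 0:
                gains[e] = 1.0
                offsets[e] = float(V[e].mean() - consensus.mean())
                continue
            g = float(np.cov(consensus, V[e], ddof=0)[0, 1] / cvar)
            if g <= 0:
                warnings.warn(
                    f"gene {gene!r}: embryo {e} fitted a non-positive gain "
                    f"({g:.3g}); clamped to 1", stacklevel=2)
                g = 1.0
            gains[e] = g
            offsets[e] = float(V[e].mean() - g * consensus.mean())
        # gauge fixing: mean gain 1, mean offset 0 (degenerate embryos are
        # pinned at gain 1 and excluded from the scale)
        free = ~degenerate
        if free.any():
            gains[free] /= gains[free].mean()
            offsets[free] -= offsets[free].mean()
        cur = np.concatenate([gains, offsets])
        if prev is not None:
            denom = max(float(np.abs(prev).max()), 1e-30)
            if float(np.abs(cur - prev).max()) / denom < _REL_TOL:
                break
        prev = cur.copy()
    return [GainOffset(float(g), float(b)) for g, b in zip(gains, offsets)]


def average_embryos(
    embryos: list[Pointcloud],
    corrections: list[list[GainOffset]] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average corrected embryos into an atlas cohort slice.

    ``corrections[g][e]`` is the :class:`GainOffset` of embryo ``e`` for
    gene index ``g`` (as returned by :func:`estimate_gain_offset` per gene);
    ``None`` applies no correction. Returns ``(E, S)``: the per-nucleus mean
    and sample standard deviation (ddof=1) of corrected expression, shape
    (n, n_genes). With a single embryo ``S`` is None (undefined).
    """
    _check_shared_indexing(embryos)
    genes = embryos[0].genes
    n, G = embryos[0].expr.shape
    stack = np.empty((len(embryos), n, G))
    for e, pc in enumerate(embryos):
        if pc.genes != genes:
            raise ValueError("embryos must share the gene panel")
        stack[e] = pc.expr
    if corrections is not None:
        if len(corrections) != G:
            raise ValueError("need one correction list per gene")
        for g in range(G):
            if len(corrections[g]) != len(embryos):
                raise ValueError("need one correction per embryo")
            for e, go in enumerate(corrections[g]):
                stack[e, :, g] = go.correct(stack[e, :, g])
    E = stack.mean(axis=0)
    S = stack.std(axis=0, ddof=1) if len(embryos) > 1 else None
    return E, S


def expression_quality(S: np.ndarray | Atlas) -> np.ndarray:
    """Per-gene atlas quality: mean inter-embryo standard deviation.

    Accepts either a cohort-slice ``S`` of shape (n, n_genes) — averaged
    over nuclei — or a full :class:`Atlas` carrying its std tensor, in
    which case the mean is taken over nuclei and then over cohorts.
    Returns one scalar per gene (lower is better).
    """
    if isinstance(S, Atlas):
        if S.S is None:
            raise ValueError("atlas carries no standard-deviation tensor")
        return S.S.mean(axis=0).mean(axis=-1)
    S = np.asarray(S, dtype=float)
    if S.ndim == 2:
        return S.mean(axis=0)
    if S.ndim == 3:  # (n, genes, cohorts)
        return S.mean(axis=0).mean(axis=-1)
    raise ValueError("S must be (n, genes) or (n, genes, cohorts)")


def build_atlas_cohort(
    embryos: list[Pointcloud], normalize: bool = True
) -> tuple[np.ndarray, np.ndarray | None, list[list[GainOffset]] | None]:
    """Convenience: estimate corrections for every gene, then average.

    Returns ``(E, S, corrections)`` for one cohort.
    """
    _check_shared_indexing(embryos)
    corrections = None
    if normalize and len(embryos) > 1:
        corrections = [estimate_gain_offset(embryos, g) for g in embryos[0].genes]
    E, S = average_embryos(embryos, corrections)
    return E, S, corrections
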