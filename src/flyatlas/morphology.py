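"""Embryo morphology: mesh surface area, local nuclear density, density maps.

The blastoderm is a monolayer of nuclei on the embryo surface, so the
neighbor relation of a pointcloud triangulates that surface. Surface area
is the summed area of the triangular faces — the surface passing through
nucleus centers, not the egg shell. Local nuclear density uses a disk of
15 um radius around each nucleus (count in the disk, including the center
nucleus, divided by the disk area); the disk is realised as the 3D
Euclidean 15 um ball intersected with the surface nuclei, which differs
from a geodesic disk by well under 1% at blastoderm curvatures. Density
maps resample per-nucleus densities onto a regular cylindrical (ap, phi)
grid and average them across the embryos of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from flyatlas.atlas_io import Atlas, Pointcloud, principal_axis, to_cylindrical

__all__ = ["DISK_RADIUS_UM", "DensityMap", "surface_area", "mesh_faces",
           "local_density", "density_map", "egg_length", "shape_profile",
           "MeshError"]

#: Radius of the density disk, in um.
DISK_RADIUS_UM = 15.0


class MeshError(ValueError):
    """Raised when the neighbor relation is not a manifold triangulation."""

    def __init__(self, message: str, offending_edges: list[tuple[int, int]]):
        super().__init__(message)
        self.offending_edges = offending_edges


@dataclass
class DensityMap:
    """Cohort-averaged nuclear density on a regular cylindrical grid.

    ``values[i, j]`` is nuclei/um^2 at ap bin i (covering [0, 1]) and phi
    bin j (covering [-pi, pi)); bin centers in ``ap_centers``/``phi_centers``.
    """

    values: np.ndarray
    ap_centers: np.ndarray
    phi_centers: np.ndarray
    cohort: int
    n_embryos: int


def _adjacency_of(obj: Pointcloud | Atlas) -> tuple[np.ndarray, list[np.ndarray]]:
    if isinstance(obj, Pointcloud):
        coords, adj = obj.coords, obj.neighbors
    else:
        coords, adj = obj.positions[-1], obj.neighbors
    if not adj:
        raise ValueError("object carries no neighbor relation")
    return coords, adj


def mesh_faces(neighbors: list[np.ndarray]) -> np.ndarray:
    """Triangular faces implied by the neighbor relation.

    Faces are the 3-cliques of the neighbor graph, except cliques that
    merely *cover* an interior degree-3 vertex (whose three neighbors are
    mutually adjacent): there the three small triangles around the vertex
    are the faces and the covering clique is discarded (a 4-vertex
    tetrahedron is exempt — all four of its triangles are faces). The
    result must be a triangulated manifold, possibly with boundary: every
    edge in one or two faces; otherwise a :class:`MeshError` lists the
    offending edges.
    """
    nbr_sets = [set(a.tolist()) for a in neighbors]
    n = len(nbr_sets)
    faces = []
    for i, si in enumerate(nbr_sets):
        for j in si:
            if j <= i:
                continue
            for k in (si & nbr_sets[j]):
                if k <= j:
                    continue
                # drop the clique covering an interior degree-3 vertex
                covered = n > 4 and any(
                    len(nbr_sets[v]) == 3 and {i, j, k} <= nbr_sets[v]
                    for v in (si & nbr_sets[j] & nbr_sets[k]))
                if not covered:
                    faces.append((i, j, k))
    edge_count: dict[tuple[int, int], int] = {}
    for i, j, k in faces:
        for e in ((i, j), (i, k), (j, k)):
            edge_count[e] = edge_count.get(e, 0) + 1
    bad = [e for e, c in edge_count.items() if c > 2]
    bad += [e for i, a in enumerate(nbr_sets) for e in
            (((i, j) for j in a if j > i))
            if e not in edge_count]
    if bad:
        raise MeshError(
            f"neighbor relation is not a manifold triangulation: "
            f"{len(bad)} offending edge(s), e.g. {bad[:5]}", bad)
    return np.array(faces, dtype=np.int64)


def surface_area(obj: Pointcloud | Atlas) -> float:
    """Surface area (um^2) of the triangular mesh through nucleus centers."""
    coords, adj = _adjacency_of(obj)
    faces = mesh_faces(adj)
    A = coords[faces[:, 0]]
    B = coords[faces[:, 1]]
    C = coords[faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(B - A, C - A), axis=1).sum())


def local_density(obj: Pointcloud | Atlas | np.ndarray,
                  radius: float = DISK_RADIUS_UM,
                  include_center: bool = True) -> np.ndarray:
    """Per-nucleus density (nuclei/um^2) in a disk of ``radius`` um.

    Counts nuclei within the 3D ball of ``radius`` around each nucleus
    (the center nucleus included by default) and divides by pi * radius^2.
    """
    if isinstance(obj, Pointcloud):
        coords = obj.coords
    elif isinstance(obj, Atlas):
        coords = obj.positions[-1]
    else:
        coords = np.asarray(obj, dtype=float)
    tree = cKDTree(coords)
    counts = np.array([len(ix) for ix in
                       tree.query_ball_point(coords, r=radius)], dtype=float)
    if not include_center:
        counts -= 1.0
    return counts / (np.pi * radius * radius)


def density_map(
    embryos: list[Pointcloud],
    cohort: int,
    grid: tuple[int, int] = (100, 16),
    radius: float = DISK_RADIUS_UM,
) -> DensityMap:
    """Cohort density map: per-embryo cylindrical resampling, then mean.

    Each embryo's per-nucleus densities are resampled onto the regular
    (ap x phi) grid by nearest-nucleus lookup (phi treated circularly),
    then averaged over the embryos of the cohort.
    """
    members = [pc for pc in embryos if pc.cohort == cohort]
    if not members:
        raise ValueError(f"no embryos in cohort {cohort}")
    n_ap, n_phi = grid
    ap_edges = np.linspace(0.0, 1.0, n_ap + 1)
    phi_edges = np.linspace(-np.pi, np.pi, n_phi + 1)
    ap_c = 0.5 * (ap_edges[:-1] + ap_edges[1:])
    phi_c = 0.5 * (phi_edges[:-1] + phi_edges[1:])
    AP, PHI = np.meshgrid(ap_c, phi_c, indexing="ij")

    acc = np.zeros((n_ap, n_phi))
    for pc in members:
        dens = local_density(pc, radius=radius)
        cyl = to_cylindrical(pc)
        # nearest nucleus in (ap, phi), phi circular: embed phi on a circle
        # whose radius matches the ap scale so both axes weigh comparably
        r_phi = 0.5 / np.pi
        feats = np.column_stack([cyl.ap,
                                 r_phi * np.cos(cyl.phi),
                                 r_phi * np.sin(cyl.phi)])
        tree = cKDTree(feats)
        q = np.column_stack([AP.ravel(),
                             r_phi * np.cos(PHI.ravel()),
                             r_phi * np.sin(PHI.ravel())])
        _, idx = tree.query(q)
        acc += dens[idx].reshape(n_ap, n_phi)
    return DensityMap(values=acc / len(members), ap_centers=ap_c,
                      phi_centers=phi_c, cohort=cohort, n_embryos=len(members))


def egg_length(obj: Pointcloud | Atlas | np.ndarray, cohort: int = None) -> float:
    """Extent (um) of the nucleus cloud along its first principal axis."""
    if isinstance(obj, Pointcloud):
        coords = obj.coords
    elif isinstance(obj, Atlas):
        coords = obj.positions[(cohort - 1) if cohort else -1]
    else:
        coords = np.asarray(obj, dtype=float)
    axis = principal_axis(coords)
    t = coords @ axis
    return float(t.max() - t.min())


def shape_profile(
    obj: Pointcloud | Atlas | np.ndarray, n_bins: int = 50
) -> dict[str, np.ndarray]:
    """Embryo outline summaries along the AP axis.

    Returns per-ap-bin arrays: ``ap`` (bin centers, fraction EL),
    ``mean_radius`` (um, the cross-section radius), ``dorsal_extent`` and
    ``ventral_extent`` (um, signed distance from the axis toward the dorsal
    reference — together the lateral outline). Empty bins hold NaN.
    """
    if isinstance(obj, Pointcloud):
        coords, dorsal, anterior = obj.coords, obj.dorsal, obj.anterior
    elif isinstance(obj, Atlas):
        coords, dorsal, anterior = obj.positions[-1], obj.dorsal, obj.anterior
    else:
        coords, dorsal, anterior = np.asarray(obj, dtype=float), None, None
    axis = principal_axis(coords, anterior)
    center = coords.mean(axis=0)
    rel = coords - center
    t = rel @ axis
    ap = (t - t.min()) / (t.max() - t.min())
    radial = rel - np.outer(t, axis)
    r = np.linalg.norm(radial, axis=1)
    d = np.asarray(dorsal, float) if dorsal is not None else np.array([0.0, 0.0, 1.0])
    d_perp = d - np.dot(d, axis) * axis
    d_perp /= np.linalg.norm(d_perp)
    dv = radial @ d_perp

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(ap, edges) - 1, 0, n_bins - 1)
    mean_r = np.full(n_bins, np.nan)
    dors = np.full(n_bins, np.nan)
    vent = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            mean_r[b] = r[m].mean()
            dors[b] = dv[m].max()
            vent[b] = dv[m].min()
    return {"ap": 0.5 * (edges[:-1] + edges[1:]), "mean_radius": mean_r,
            "dorsal_extent": dors, "ventral_extent": vent}
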