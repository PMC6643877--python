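"""Synthetic multi-species blastoderm atlas generator with recorded ground truth.

The generator emulates the structure of cellular-resolution expression
atlases of the early fly embryo:

- nuclei packed on the surface of a prolate ellipsoid of revolution
  (~390-460 um long, ~5000-6100 nuclei per species), sampled by
  variable-radius Poisson-disk dart throwing so packing has the blue-noise
  character of a nuclear monolayer;
- low-density depressions where the cephalic and ventral furrows will form;
- anterior-posterior expression patterns: gap-like genes as products of
  logistic boundary functions of AP position, pair-rule-like genes as sums
  of 7 Gaussian stripes, terminal-like genes as single logistic domains at
  the poles;
- six time cohorts with per-cohort boundary sharpening and amplitude ramps;
- species-level AP shifts of all domains and integer temporal offsets of the
  dynamic program, both recorded as ground truth;
- per-embryo multiplicative gain and additive offset plus per-nucleus noise
  for embryo-set generation.

Every random draw flows through one seeded :class:`numpy.random.Generator`;
identical (spec, seed) yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import expit

from flyatlas.atlas_io import Atlas, COHORT_EDGES, Pointcloud

__all__ = [
    "GeneSpec",
    "FurrowSpec",
    "NoiseSpec",
    "SyntheticSpec",
    "generate_atlas",
    "generate_embryo_set",
    "ellipsoid_area",
]


def ellipsoid_area(a: float, b: float) -> float:
    """Surface area of an ellipsoid of revolution with semi-axes (a, b, b).

    Exact prolate/oblate closed forms; returns the sphere area when a == b.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if math.isclose(a, b, rel_tol=1e-12):
        return 4.0 * math.pi * a * a
    if a > b:  # prolate
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * b * b * (1.0 + (a / b) * math.asin(e) / e)
    e = math.sqrt(1.0 - (a / b) ** 2)  # oblate
    return 2.0 * math.pi * b * b * (1.0 + (a / b) ** 2 * math.atanh(e) / e)


@dataclass(frozen=True)
class GeneSpec:
    """Pattern parameters for one synthetic gene.

    ``role`` is ``"gap"`` (product of logistic boundaries between
    ``boundaries[0]`` and ``boundaries[1]``, either may be None for a
    half-open domain), ``"terminal"`` (single logistic domain; ``polarity``
    ``"anterior"`` or ``"posterior"``) or ``"pair_rule"`` (sum of
    ``n_stripes`` Gaussian stripes spanning ``stripe_span``). Positions are
    fractions of egg length; widths are logistic scales / Gaussian sd in the
    same units.
    """

    name: str
    role: str
    boundaries: tuple[float | None, float | None] = (None, None)
    width: float = 0.02
    amplitude: float = 1.0
    polarity: str = "posterior"
    n_stripes: int = 7
    stripe_span: tuple[float, float] = (0.25, 0.85)

    def __post_init__(self) -> None:
        if self.role not in ("gap", "terminal", "pair_rule"):
            raise ValueError(f"unknown gene role {self.role!r}")
        if self.width <= 0:
            raise ValueError("boundary width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for b in self.boundaries:
            if b is not None and not 0.0 <= b <= 1.0:
                raise ValueError("boundary positions must be in [0, 1]")

    def pattern(self, ap: np.ndarray, width_factor: float = 1.0) -> np.ndarray:
        """Evaluate the unit-amplitude pattern at AP positions ``ap``."""
        w = self.width * width_factor
        if self.role == "pair_rule":
            centers = np.linspace(*self.stripe_span, self.n_stripes)
            out = np.zeros_like(ap)
            for c in centers:
                out += np.exp(-0.5 * ((ap - c) / w) ** 2)
            return np.clip(out, 0.0, 1.0)
        if self.role == "terminal":
            b = self.boundaries[0] if self.boundaries[0] is not None else 0.9
            s = (b - ap) if self.polarity == "anterior" else (ap - b)
            return expit(s / w)
        lo, hi = self.boundaries
        out = np.ones_like(ap)
        if lo is not None:
            out *= expit((ap - lo) / w)
        if hi is not None:
            out *= expit((hi - ap) / w)
        return out


@dataclass(frozen=True)
class FurrowSpec:
    """A low-density depression in the nuclear packing.

    Gaussian in ap and/or phi; a ``None`` sd makes the depression uniform
    along that axis (e.g. the cephalic furrow is a ring over all phi).
    """

    amplitude: float
    ap_center: float = 0.5
    ap_sd: float | None = None
    phi_center: float = 0.0
    phi_sd: float | None = None

    def factor(self, ap: np.ndarray, phi: np.ndarray) -> np.ndarray:
        g = np.full_like(ap, self.amplitude)
        if self.ap_sd is not None:
            g = g * np.exp(-0.5 * ((ap - self.ap_center) / self.ap_sd) ** 2)
        if self.phi_sd is not None:
            dphi = np.angle(np.exp(1j * (phi - self.phi_center)))
            g = g * np.exp(-0.5 * (dphi / self.phi_sd) ** 2)
        return g


@dataclass(frozen=True)
class NoiseSpec:
    """Per-embryo and per-nucleus measurement noise.

    ``gain_sigma`` is the log-sd of the per-embryo-per-gene lognormal gain;
    ``offset_range`` the uniform range of the additive offset as a fraction
    of each gene's maximum atlas expression; ``nucleus_sd`` the sd of
    per-nucleus additive Gaussian noise, again as a fraction of the max.
    """

    gain_sigma: float = 0.2
    offset_range: tuple[float, float] = (0.01, 0.05)
    nucleus_sd: float = 0.01


def _default_genes() -> list[GeneSpec]:
    # 9-gene panel mirroring the field's canonical AP set:
    # 4 gap-like, 2 terminal-like, 3 pair-rule-like.
    return [
        GeneSpec("hb", "gap", boundaries=(None, 0.47), width=0.025),
        GeneSpec("gt", "gap", boundaries=(0.58, 0.78), width=0.02),
        GeneSpec("Kr", "gap", boundaries=(0.40, 0.60), width=0.02),
        GeneSpec("kni", "gap", boundaries=(0.62, 0.76), width=0.018),
        GeneSpec("tll", "terminal", boundaries=(0.85, None), width=0.02,
                 polarity="posterior"),
        GeneSpec("hkb", "terminal", boundaries=(0.08, None), width=0.015,
                 polarity="anterior"),
        GeneSpec("eve", "pair_rule", width=0.022, stripe_span=(0.25, 0.85)),
        GeneSpec("ftz", "pair_rule", width=0.022, stripe_span=(0.30, 0.90)),
        GeneSpec("odd", "pair_rule", width=0.022, stripe_span=(0.285, 0.885)),
    ]


def _default_furrows() -> list[FurrowSpec]:
    return [
        FurrowSpec(amplitude=0.35, ap_center=0.32, ap_sd=0.035),  # cephalic
        FurrowSpec(amplitude=0.35, ap_center=0.55, ap_sd=0.22,
                   phi_center=math.pi, phi_sd=0.45),  # ventral
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic multi-species study.

    Defaults emulate the five-species study conditions: egg lengths and
    nucleus counts on the scale of the measured species averages, a 9-gene
    shared panel over 6 cohorts, boundary sharpening over developmental
    time, small species-level AP domain shifts, and modest per-embryo
    gain/offset variability.
    """

    n_species: int = 5
    species_names: tuple[str, ...] = ("synA", "synB", "synC", "synD", "synE")
    egg_length: tuple[float, ...] = (393.8, 416.2, 450.9, 394.1, 457.4)
    max_radius: tuple[float, ...] = (80.0, 83.0, 88.0, 76.0, 92.0)
    n_nuclei: tuple[int, ...] = (5974, 5894, 6115, 5081, 5535)
    genes: tuple[GeneSpec, ...] = field(default_factory=lambda: tuple(_default_genes()))
    shift_field: tuple[float, ...] = (0.0, 0.005, 0.01, 0.015, 0.02)
    temporal_offset: tuple[int, ...] = (0, 0, 0, 0, 0)
    width_factors: tuple[float, ...] = (1.5, 1.3, 1.1, 0.95, 0.8, 0.7)
    amp_factors: tuple[float, ...] = (0.7, 0.85, 1.0, 1.0, 1.0, 1.0)
    furrow_depressions: tuple[FurrowSpec, ...] = field(
        default_factory=lambda: tuple(_default_furrows()))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    min_spacing: float = 2.0  # um; nuclei cannot pack tighter than this
    n_cohorts: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("species_names", "egg_length", "max_radius", "n_nuclei",
                     "shift_field", "temporal_offset"):
            if len(getattr(self, name)) < self.n_species:
                raise ValueError(f"{name} must have >= n_species entries")
        if len(self.width_factors) != self.n_cohorts:
            raise ValueError("width_factors must have one entry per cohort")
        if len(self.amp_factors) != self.n_cohorts:
            raise ValueError("amp_factors must have one entry per cohort")
        for s in self.shift_field[: self.n_species]:
            if not -1.0 <= s <= 1.0:
                raise ValueError("shift_field entries must be in [-1, 1] EL")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def with_(self, **kw) -> "SyntheticSpec":
        """Return a copy with fields replaced (convenience wrapper)."""
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

# Random sequential adsorption of disks of radius r/2 saturates at coverage
# ~0.547, i.e. n_sat ~ 0.696 A / r^2.  We pick r so saturation sits ~25%
# above the target count and stop dart throwing exactly at the target.
_RSA_COVERAGE = 0.547
_SAT_MARGIN = 1.25


def _sample_ellipsoid_surface(rng: np.random.Generator, a: float, b: float,
                              n: int) -> np.ndarray:
    """Area-uniform points on the ellipsoid (a, b, b) via rejection sampling."""
    pts = np.empty((0, 3))
    while len(pts) < n:
        u = rng.normal(size=(2 * (n - len(pts)) + 16, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # area magnification of the sphere->ellipsoid map, up to a constant
        m = np.sqrt(b * b * u[:, 0] ** 2 + a * a * (1.0 - u[:, 0] ** 2))
        keep = rng.uniform(0.0, 1.0, size=len(u)) < m / max(a, b)
        pts = np.concatenate([pts, u[keep]])
    u = pts[:n]
    return np.column_stack([a * u[:, 0], b * u[:, 1], b * u[:, 2]])


def _density_factor(spec: SyntheticSpec, ap: np.ndarray,
                    phi: np.ndarray) -> np.ndarray:
    f = np.ones_like(ap)
    for fur in spec.furrow_depressions:
        f = f - fur.factor(ap, phi)
    return np.clip(f, 0.25, None)


def _dart_throw_surface(spec: SyntheticSpec, s: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Poisson-disk dart throwing on the embryo ellipsoid.

    The acceptance radius is modulated by the furrow density field
    (low density -> larger spacing). Stops at exactly the target count;
    raises if the count is infeasible at the implied spacing.
    """
    a = spec.egg_length[s] / 2.0
    b = spec.max_radius[s]
    n_target = spec.n_nuclei[s]
    area = ellipsoid_area(a, b)
    r_base = math.sqrt(_RSA_COVERAGE * 4.0 * area
                       / (math.pi * _SAT_MARGIN * n_target))
    if r_base < spec.min_spacing:
        raise ValueError(
            f"infeasible nucleus count {n_target} for surface area "
            f"{area:.0f} um^2 at minimum spacing {spec.min_spacing} um")

    batch = 4096
    max_attempts = 120 * n_target
    r_max = r_base / math.sqrt(0.25)
    cell = r_max
    grid: dict[tuple[int, int, int], list[int]] = {}
    accepted = np.empty((n_target, 3))
    radii = np.empty(n_target)
    n_acc = 0
    attempts = 0
    while n_acc < n_target:
        if attempts >= max_attempts:
            raise ValueError(
                f"infeasible nucleus count {n_target} for surface area "
                f"{area:.0f} um^2 at minimum spacing {r_base:.2f} um")
        cand = _sample_ellipsoid_surface(rng, a, b, batch)
        ap = (cand[:, 0] + a) / (2.0 * a)
        phi = np.arctan2(cand[:, 1], cand[:, 2])  # dorsal +z, left +y
        r_loc = r_base / np.sqrt(_density_factor(spec, ap, phi))
        for p, rp in zip(cand, r_loc):
            attempts += 1
            key = (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for idx in grid.get((key[0] + dx, key[1] + dy,
                                             key[2] + dz), ()):
                            q = accepted[idx]
                            lim = 0.5 * (rp + radii[idx])
                            d0 = p[0] - q[0]
                            d1 = p[1] - q[1]
                            d2 = p[2] - q[2]
                            if d0 * d0 + d1 * d1 + d2 * d2 < lim * lim:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                accepted[n_acc] = p
                radii[n_acc] = rp
                grid.setdefault(key, []).append(n_acc)
                n_acc += 1
                if n_acc == n_target:
                    break
    return accepted


def _hull_adjacency(points: np.ndarray) -> list[np.ndarray]:
    """Neighbor relation from the convex-hull surface triangulation."""
    hull = ConvexHull(points)
    n = len(points)
    sets: list[set[int]] = [set() for _ in range(n)]
    for i, j, k in hull.simplices:
        sets[i].update((j, k))
        sets[j].update((i, k))
        sets[k].update((i, j))
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


# ---------------------------------------------------------------------------
# atlas / embryo generation
# ---------------------------------------------------------------------------

def _expression_tensor(spec: SyntheticSpec, s: int, ap: np.ndarray) -> np.ndarray:
    """E(i, g, t) for species ``s`` at AP positions ``ap`` (fraction EL)."""
    n = len(ap)
    T = spec.n_cohorts
    E = np.empty((n, len(spec.genes), T))
    shift = spec.shift_field[s]
    off = spec.temporal_offset[s]
    for t in range(T):
        td = int(np.clip(t - off, 0, T - 1))
        wf = spec.width_factors[td]
        af = spec.amp_factors[td]
        for g, gene in enumerate(spec.genes):
            E[:, g, t] = np.clip(
                gene.amplitude * af * gene.pattern(ap - shift, wf), 0.0, None)
    return E


def generate_atlas(spec: SyntheticSpec, species_index: int) -> tuple[Atlas, dict]:
    """Generate one species atlas plus its ground-truth record.

    Nuclei are identical across cohorts (identity correspondence); the
    ground truth records the applied AP shift, temporal offset, and every
    gene's domain parameters.
    """
    if not 0 <= species_index < spec.n_species:
        raise ValueError("species_index out of range")
    s = species_index
    # Seed nucleus placement by the geometry, not the species index: species
    # sharing (egg length, radius, count) get identical nuclei, so a pair
    # differing only in expression parameters has an identity ground-truth
    # cell correspondence.
    rng = np.random.default_rng([
        spec.seed, 7919, spec.n_nuclei[s],
        int(round(spec.egg_length[s] * 1000)),
        int(round(spec.max_radius[s] * 1000))])
    points = _dart_throw_surface(spec, s, rng)
    a = spec.egg_length[s] / 2.0
    ap = (points[:, 0] + a) / (2.0 * a)
    E = _expression_tensor(spec, s, ap)
    atlas = Atlas(
        species=spec.species_names[s],
        positions=np.tile(points, (spec.n_cohorts, 1, 1)),
        E=E,
        genes=spec.gene_names,
        egg_length=spec.egg_length[s],
        neighbors=_hull_adjacency(points),
        dorsal=np.array([0.0, 0.0, 1.0]),
        anterior=np.array([-a, 0.0, 0.0]),
    )
    truth = {
        "species": spec.species_names[s],
        "shift_field": spec.shift_field[s],
        "temporal_offset": spec.temporal_offset[s],
        "egg_length": spec.egg_length[s],
        "max_radius": spec.max_radius[s],
        "n_nuclei": spec.n_nuclei[s],
        "boundaries": {
            g.name: {"role": g.role, "boundaries": list(g.boundaries),
                     "width": g.width, "amplitude": g.amplitude}
            for g in spec.genes
        },
    }
    return atlas, truth


def generate_embryo_set(
    spec: SyntheticSpec,
    n_embryos: int,
    cohort: int,
    species_index: int = 0,
    atlas: Atlas | None = None,
) -> tuple[list[Pointcloud], dict]:
    """Generate individual-embryo pointclouds around one atlas cohort.

    Each embryo's expression is ``gain * atlas_mean + offset + noise``
    (clipped at 0), sharing the atlas's nucleus indexing. Returns the
    embryos and a truth dict with per-embryo-per-gene ``gains`` and
    ``offsets`` (arrays of shape (n_embryos, n_genes)) and the noise sd
    actually used per gene.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    if not 1 <= cohort <= spec.n_cohorts:
        raise ValueError(f"cohort must be in 1..{spec.n_cohorts}")
    if atlas is None:
        atlas, _ = generate_atlas(spec, species_index)
    rng = np.random.default_rng([spec.seed, 104729, species_index, cohort])
    mean = atlas.E[:, :, cohort - 1]  # (n, g)
    gmax = mean.max(axis=0)
    gmax = np.where(gmax > 0, gmax, 1.0)
    ns = spec.noise
    G = len(atlas.genes)
    gains = rng.lognormal(mean=0.0, sigma=ns.gain_sigma, size=(n_embryos, G))
    offsets = rng.uniform(*ns.offset_range, size=(n_embryos, G)) * gmax
    sd = ns.nucleus_sd * gmax
    lo, hi = COHORT_EDGES[cohort - 1], COHORT_EDGES[cohort]
    embryos = []
    for e in range(n_embryos):
        noise = rng.normal(0.0, 1.0, size=mean.shape) * sd
        expr = np.clip(gains[e] * mean + offsets[e] + noise, 0.0, None)
        stage = float(rng.uniform(lo, min(hi - 1e-9, 100.0)))
        embryos.append(Pointcloud(
            species=atlas.species,
            stage=stage,
            cohort=cohort,
            ids=np.arange(atlas.n_nuclei),
            coords=atlas.positions[cohort - 1].copy(),
            expr=expr,
            genes=list(atlas.genes),
            neighbors=list(atlas.neighbors) if atlas.neighbors else [],
            dorsal=atlas.dorsal,
            anterior=atlas.anterior,
        ))
    truth = {"gains": gains, "offsets": offsets, "noise_sd": sd,
             "cohort": cohort, "species": atlas.species}
    return embryos, truth
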