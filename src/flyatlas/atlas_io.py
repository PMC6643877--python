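"""Data model and file IO for pointclouds and atlases.

A *pointcloud* holds one embryo: per-nucleus 3D coordinates (in um),
expression levels for a set of genes, and the symmetric neighbor relation
that triangulates the blastoderm surface. An *atlas* holds one species:
mean (and optionally standard-deviation) expression per nucleus, gene and
time cohort, with nucleus correspondence across the six cohorts.

Two on-disk dialects are supported:

``tabular``
    One CSV per embryo (or per atlas cohort) with columns
    ``id, x, y, z, <gene...>, neighbors`` where ``neighbors`` is a
    semicolon-separated list of nucleus ids.  Metadata (species, stage,
    cohort, dorsal and anterior markers) is carried in ``# key: value``
    header comment lines.

``bdtnp``
    A best-effort reader for whitespace-delimited pointcloud text with a
    single column-header line (``id x y z <gene...> [neighbors]``), in the
    spirit of the published virtual-embryo pointcloud files.  Validated on
    synthetic fixtures only.

Coordinate conventions: all positions are in um. The anterior-posterior
(AP) axis is the first principal axis of the nucleus coordinates; ``ap`` is
the position along it as a fraction of egg length in [0, 1] with 0 at the
anterior. The angular coordinate ``phi`` is measured in the plane orthogonal
to the AP axis, with phi = 0 at the dorsal midline and increasing through
left, ventral, right (display row order D, L, V, R).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Nucleus",
    "Pointcloud",
    "Atlas",
    "CylindricalCoords",
    "COHORT_EDGES",
    "cohort_of_stage",
    "read_pointcloud",
    "write_pointcloud",
    "read_atlas",
    "write_atlas",
    "to_cylindrical",
    "principal_axis",
]

#: Half-open %-membrane-invagination bins for the six time cohorts.
#: A stage of exactly 50% falls in cohort 4; 100% belongs to cohort 6.
COHORT_EDGES = (0.0, 4.0, 9.0, 26.0, 51.0, 76.0, 100.0)


def cohort_of_stage(stage: float) -> int:
    """Map % membrane invagination in [0, 100] to a cohort number 1-6."""
    if not 0.0 <= stage <= 100.0:
        raise ValueError(f"stage must be in [0, 100], got {stage}")
    if stage == 100.0:
        return 6
    return int(np.searchsorted(COHORT_EDGES, stage, side="right"))


@dataclass
class Nucleus:
    """A single nucleus: position, expression and surface neighbors."""

    id: int
    x: float
    y: float
    z: float
    expr: dict[str, float]
    neighbors: list[int]


@dataclass
class CylindricalCoords:
    """Per-nucleus cylindrical surface coordinates.

    ``ap`` is the fraction of egg length in [0, 1] (0 = anterior);
    ``phi`` is the angle around the AP axis in [-pi, pi), 0 = dorsal.
    """

    ap: np.ndarray
    phi: np.ndarray


@dataclass
class Pointcloud:
    """One embryo: coordinates, expression and the surface neighbor graph.

    ``neighbors`` is an adjacency list over *positional* indices (row order),
    always stored symmetric; file ids live in ``ids``.
    """

    species: str
    stage: float
    cohort: int
    ids: np.ndarray
    coords: np.ndarray
    expr: np.ndarray  # (n, n_genes)
    genes: list[str]
    neighbors: list[np.ndarray] = field(default_factory=list)
    dorsal: np.ndarray | None = None
    anterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        n = len(self.ids)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n, 3)")
        if self.expr.shape != (n, len(self.genes)):
            raise ValueError("expr must have shape (n, n_genes)")
        if len(np.unique(self.ids)) != n:
            raise ValueError("nucleus ids must be unique")
        if not np.all(np.isfinite(self.expr)) or np.any(self.expr < 0):
            raise ValueError("expression levels must be finite and non-negative")
        if self.cohort != cohort_of_stage(self.stage):
            raise ValueError(
                f"cohort {self.cohort} inconsistent with stage {self.stage}% "
                f"(expected cohort {cohort_of_stage(self.stage)})"
            )
        if self.neighbors:
            if len(self.neighbors) != n:
                raise ValueError("neighbors adjacency must have one entry per nucleus")
            self.neighbors = _symmetrize(self.neighbors, n)
        if self.dorsal is not None:
            self.dorsal = np.asarray(self.dorsal, dtype=float)
        if self.anterior is not None:
            self.anterior = np.asarray(self.anterior, dtype=float)

    @property
    def n_nuclei(self) -> int:
        return len(self.ids)

    def nucleus(self, i: int) -> Nucleus:
        """Return nucleus at positional index ``i`` as a :class:`Nucleus` view."""
        nbrs = self.ids[self.neighbors[i]].tolist() if self.neighbors else []
        return Nucleus(
            id=int(self.ids[i]),
            x=float(self.coords[i, 0]),
            y=float(self.coords[i, 1]),
            z=float(self.coords[i, 2]),
            expr=dict(zip(self.genes, self.expr[i])),
            neighbors=nbrs,
        )

    def equals(self, other: "Pointcloud", rtol: float = 1e-9) -> bool:
        """Structural equality up to floating-point round-trip."""
        if self.species != other.species or self.genes != other.genes:
            return False
        if self.cohort != other.cohort or not np.isclose(self.stage, other.stage):
            return False
        if not np.array_equal(self.ids, other.ids):
            return False
        if not np.allclose(self.coords, other.coords, rtol=rtol, atol=0):
            return False
        if not np.allclose(self.expr, other.expr, rtol=rtol, atol=1e-12):
            return False
        if len(self.neighbors) != len(other.neighbors):
            return False
        for a, b in zip(self.neighbors, other.neighbors):
            if not np.array_equal(np.sort(a), np.sort(b)):
                return False
        return True


def _symmetrize(adjacency: list, n: int) -> list[np.ndarray]:
    """Return a symmetric adjacency list of sorted index arrays."""
    sets: list[set[int]] = [set(np.asarray(a, dtype=int).tolist()) for a in adjacency]
    for i, nbrs in enumerate(sets):
        for j in nbrs:
            if not 0 <= j < n:
                raise ValueError(f"neighbor index {j} of nucleus {i} out of range")
            if j == i:
                raise ValueError(f"nucleus {i} lists itself as neighbor")
    for i in range(n):
        for j in list(sets[i]):
            sets[j].add(i)
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


@dataclass
class Atlas:
    """One species: mean expression over six time cohorts.

    ``positions`` has shape (T, n, 3) in um and ``E`` shape (n, n_genes, T);
    nucleus row ``i`` refers to the same (virtual) nucleus in every cohort,
    i.e. the cross-cohort correspondence is by row. ``correspondence``
    optionally carries explicit injective per-consecutive-pair index maps
    for atlases whose files store a non-trivial linking; when ``None`` the
    identity linking implied by the shared row order is used.
    """

    species: str
    positions: np.ndarray
    E: np.ndarray
    genes: list[str]
    S: np.ndarray | None = None
    egg_length: float | None = None
    correspondence: list[np.ndarray] | None = None
    neighbors: list[np.ndarray] | None = None
    dorsal: np.ndarray | None = None
    anterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (T, n, 3)")
        T, n, _ = self.positions.shape
        if n == 0:
            raise ValueError("each cohort must contain at least one nucleus")
        if self.E.shape != (n, len(self.genes), T):
            raise ValueError("E must have shape (n, n_genes, T)")
        if not np.all(np.isfinite(self.E)) or np.any(self.E < 0):
            raise ValueError("E must be finite and non-negative")
        if self.S is not None:
            self.S = np.asarray(self.S, dtype=float)
            if self.S.shape != self.E.shape:
                raise ValueError("S must match E's shape")
        if self.correspondence is not None:
            if len(self.correspondence) != T - 1:
                raise ValueError("need one correspondence map per consecutive pair")
            for t, m in enumerate(self.correspondence):
                m = np.asarray(m, dtype=np.int64)
                if len(np.unique(m)) != len(m):
                    raise ValueError(f"correspondence map {t} is not injective")
        if self.dorsal is not None:
            self.dorsal = np.asarray(self.dorsal, dtype=float)
        if self.anterior is not None:
            self.anterior = np.asarray(self.anterior, dtype=float)

    @property
    def n_cohorts(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.positions.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in atlas ({self.species})") from None

    def expression_vectors(self, genes: list[str] | None = None,
                           cohorts: list[int] | None = None) -> np.ndarray:
        """Per-nucleus expression stacked over (gene, cohort) -> (n, G*T)."""
        genes = genes if genes is not None else self.genes
        gi = [self.gene_index(g) for g in genes]
        ti = ([t - 1 for t in cohorts] if cohorts is not None
              else list(range(self.n_cohorts)))
        for t in ti:
            if not 0 <= t < self.n_cohorts:
                raise KeyError(f"cohort {t + 1} not in atlas")
        return self.E[:, gi][:, :, ti].reshape(self.n_nuclei, -1)


# ---------------------------------------------------------------------------
# cylindrical projection
# ---------------------------------------------------------------------------

def principal_axis(coords: np.ndarray, anterior: np.ndarray | None = None) -> np.ndarray:
    """First principal axis of ``coords``, oriented anterior -> posterior.

    With an ``anterior`` marker point the sign is fixed so the marker
    projects to the minimum; without one the sign is fixed (arbitrarily but
    deterministically) so the axis component of largest magnitude is positive.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 nuclei to define an axis")
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[1] / evals[-1] < 1e-12:
        raise ValueError("degenerate geometry: nuclei are (nearly) collinear")
    axis = evecs[:, -1]
    if anterior is not None:
        if float(np.dot(np.asarray(anterior, float) - center, axis)) > 0:
            axis = -axis
    elif axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def to_cylindrical(
    obj: "Atlas | Pointcloud | np.ndarray",
    cohort: int | None = None,
    dorsal: np.ndarray | None = None,
    anterior: np.ndarray | None = None,
) -> CylindricalCoords:
    """Project nucleus coordinates onto the (ap, phi) cylindrical system.

    ``ap`` is the normalized projection on the first principal axis
    (anterior 0, posterior 1); ``phi`` is the angle in the orthogonal plane
    with 0 at the dorsal midline, increasing dorsal -> left -> ventral ->
    right, in [-pi, pi).

    For an :class:`Atlas`, ``cohort`` (1-6) selects which cohort's positions
    to project.  The dorsal reference is taken from the argument, then from
    the object's metadata, then defaults to +z.
    """
    if isinstance(obj, Atlas):
        if cohort is None or not 1 <= cohort <= obj.n_cohorts:
            raise ValueError(f"cohort must be in 1..{obj.n_cohorts}")
        coords = obj.positions[cohort - 1]
        dorsal = dorsal if dorsal is not None else obj.dorsal
        anterior = anterior if anterior is not None else obj.anterior
    elif isinstance(obj, Pointcloud):
        coords = obj.coords
        dorsal = dorsal if dorsal is not None else obj.dorsal
        anterior = anterior if anterior is not None else obj.anterior
    else:
        coords = np.asarray(obj, dtype=float)

    axis = principal_axis(coords, anterior)
    center = coords.mean(axis=0)
    rel = coords - center
    t = rel @ axis
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("degenerate geometry: zero extent along AP axis")
    ap = (t - t.min()) / span

    d = np.asarray(dorsal, dtype=float) if dorsal is not None else np.array([0.0, 0.0, 1.0])
    d_perp = d - np.dot(d, axis) * axis
    nrm = np.linalg.norm(d_perp)
    if nrm < 1e-9:
        raise ValueError("dorsal reference is parallel to the AP axis")
    d_perp /= nrm
    left = np.cross(d_perp, axis)

    radial = rel - np.outer(t, axis)
    phi = np.arctan2(radial @ left, radial @ d_perp)
    phi = np.where(phi >= np.pi, phi - 2 * np.pi, phi)  # keep in [-pi, pi)
    return CylindricalCoords(ap=ap, phi=phi)


# ---------------------------------------------------------------------------
# pointcloud file IO
# ---------------------------------------------------------------------------

_MAGIC = "# flyatlas-pointcloud v1"


def write_pointcloud(pc: Pointcloud, path: str | Path) -> None:
    """Write a pointcloud in the tabular CSV dialect.

    Floats are written with shortest round-trip repr, so a read-back
    reproduces coordinates and expression bit-exactly.
    """
    if not pc.genes:
        raise ValueError("cannot write a pointcloud with an empty gene list")
    path = Path(path)
    lines = [_MAGIC,
             f"# species: {pc.species}",
             f"# stage: {pc.stage!r}",
             f"# cohort: {pc.cohort}"]
    if pc.dorsal is not None:
        lines.append("# dorsal: " + " ".join(repr(float(v)) for v in pc.dorsal))
    if pc.anterior is not None:
        lines.append("# anterior: " + " ".join(repr(float(v)) for v in pc.anterior))
    df = pd.DataFrame(pc.coords, columns=["x", "y", "z"])
    df.insert(0, "id", pc.ids)
    for g, col in zip(pc.genes, pc.expr.T):
        df[g] = col
    if pc.neighbors:
        df["neighbors"] = [";".join(str(int(pc.ids[j])) for j in nbrs)
                           for nbrs in pc.neighbors]
    else:
        df["neighbors"] = ""
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        # shortest round-trip repr -> bit-exact read-back of float64 columns
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def _parse_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_pointcloud(
    path: str | Path,
    dialect: str = "tabular",
    expected_genes: list[str] | None = None,
    unknown_gene: str = "ignore",
) -> Pointcloud:
    """Read a pointcloud file.

    ``dialect`` is ``"tabular"`` (CSV, the package's native format) or
    ``"bdtnp"`` (whitespace-delimited with one header line). A one-sided
    neighbor relation in the file is symmetrized on read. ``expected_genes``
    with ``unknown_gene="fail"`` rejects files carrying unexpected gene
    columns; ``"ignore"`` drops them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("tabular", "bdtnp"):
        raise ValueError(f"unknown dialect {dialect!r}")

    meta = _parse_meta(path)
    try:
        if dialect == "tabular":
            df = pd.read_csv(path, comment="#", dtype={"neighbors": str},
                             float_precision="round_trip")
        else:
            df = pd.read_csv(path, comment="#", sep=r"\s+",
                             dtype={"neighbors": str},
                             float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed pointcloud file {path}: {exc}") from exc

    required = ["id", "x", "y", "z"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    genes = [c for c in df.columns if c not in required + ["neighbors"]]
    if expected_genes is not None:
        extra = [g for g in genes if g not in expected_genes]
        if extra and unknown_gene == "fail":
            raise ValueError(f"{path}: unknown gene columns {extra}")
        genes = [g for g in expected_genes if g in genes]
        missing = [g for g in expected_genes if g not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing gene columns {missing}")

    ids = df["id"].to_numpy(dtype=np.int64)
    id_to_idx = {int(v): i for i, v in enumerate(ids)}
    n = len(ids)
    adjacency: list[np.ndarray] = []
    if "neighbors" in df.columns:
        raw = df["neighbors"].fillna("").astype(str).tolist()
        for lineno, cell in enumerate(raw):
            idxs = []
            for tok in cell.split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                try:
                    j = id_to_idx[int(tok)]
                except (ValueError, KeyError):
                    raise ValueError(
                        f"{path}: row {lineno + 1}: bad neighbor id {tok!r}"
                    ) from None
                idxs.append(j)
            adjacency.append(np.array(idxs, dtype=np.int64))
        if all(len(a) == 0 for a in adjacency):
            adjacency = []

    stage = float(meta.get("stage", 0.0))
    cohort = int(meta.get("cohort", cohort_of_stage(stage)))
    dorsal = (np.array([float(v) for v in meta["dorsal"].split()])
              if "dorsal" in meta else None)
    anterior = (np.array([float(v) for v in meta["anterior"].split()])
                if "anterior" in meta else None)

    try:
        return Pointcloud(
            species=meta.get("species", path.stem),
            stage=stage,
            cohort=cohort,
            ids=ids,
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            expr=df[genes].to_numpy(dtype=float),
            genes=genes,
            neighbors=adjacency if adjacency else [],
            dorsal=dorsal,
            anterior=anterior,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# atlas directory IO
# ---------------------------------------------------------------------------

def write_atlas(atlas: Atlas, out_dir: str | Path) -> None:
    """Write an atlas as a directory of per-cohort CSVs plus meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "species": atlas.species,
        "genes": atlas.genes,
        "n_cohorts": atlas.n_cohorts,
        "egg_length": atlas.egg_length,
        "has_std": atlas.S is not None,
        "dorsal": None if atlas.dorsal is None else list(map(float, atlas.dorsal)),
        "anterior": None if atlas.anterior is None else list(map(float, atlas.anterior)),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    stage_mid = [2.0, 6.0, 17.0, 38.0, 63.0, 88.0]
    for t in range(atlas.n_cohorts):
        pc = Pointcloud(
            species=atlas.species,
            stage=stage_mid[t] if t < 6 else 88.0,
            cohort=min(t + 1, 6),
            ids=np.arange(atlas.n_nuclei),
            coords=atlas.positions[t],
            expr=atlas.E[:, :, t],
            genes=atlas.genes,
            neighbors=atlas.neighbors if (atlas.neighbors and t == atlas.n_cohorts - 1) else [],
            dorsal=atlas.dorsal,
            anterior=atlas.anterior,
        )
        write_pointcloud(pc, out / f"cohort_{t + 1}.csv")
        if atlas.S is not None:
            pd.DataFrame(atlas.S[:, :, t], columns=atlas.genes).to_csv(
                out / f"cohort_{t + 1}_sd.csv", index=False)
    rows = []
    for t in range(atlas.n_cohorts - 1):
        m = (atlas.correspondence[t] if atlas.correspondence is not None
             else np.arange(atlas.n_nuclei))
        for i, j in enumerate(np.asarray(m)):
            rows.append((t + 1, i, int(j)))
    pd.DataFrame(rows, columns=["cohort", "from_id", "to_id"]).to_csv(
        out / "correspondence.csv", index=False)


def read_atlas(in_dir: str | Path) -> Atlas:
    """Read an atlas directory written by :func:`write_atlas`."""
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    T = int(meta["n_cohorts"])
    positions, E, S, neighbors = [], [], [], None
    for t in range(1, T + 1):
        pc = read_pointcloud(src / f"cohort_{t}.csv", expected_genes=meta["genes"])
        positions.append(pc.coords)
        E.append(pc.expr)
        if pc.neighbors:
            neighbors = pc.neighbors
        sd_path = src / f"cohort_{t}_sd.csv"
        if meta.get("has_std") and sd_path.exists():
            S.append(pd.read_csv(sd_path)[meta["genes"]].to_numpy(dtype=float))
    corr = None
    corr_path = src / "correspondence.csv"
    if corr_path.exists():
        cdf = pd.read_csv(corr_path)
        if len(cdf):
            corr = [cdf.loc[cdf["cohort"] == t + 1].sort_values("from_id")["to_id"]
                    .to_numpy(dtype=np.int64) for t in range(T - 1)]
    atlas = Atlas(
        species=meta["species"],
        positions=np.stack(positions),
        E=np.stack(E, axis=-1),
        genes=list(meta["genes"]),
        S=np.stack(S, axis=-1) if S else None,
        egg_length=meta.get("egg_length"),
        correspondence=corr,
        neighbors=neighbors,
        dorsal=None if meta.get("dorsal") is None else np.asarray(meta["dorsal"]),
        anterior=None if meta.get("anterior") is None else np.asarray(meta["anterior"]),
    )
    return atlas
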