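"""Synthetic protein-like surface benchmark generator.

Real surface-retrieval benchmarks are built from NMR ensembles: each PDB
entry contributes tens of conformers, entries group into species and
protein-level classes, and sequences within a class are near-identical
while cross-class identity is low.  This module emulates that structure
so the whole retrieval pipeline can be exercised without downloads:

* a *pseudo-structure* is a connected cluster of soft spheres ("blobs")
  with an attached amino-acid sequence;
* its surface is the level set of a sum of Gaussian kernels (metaballs),
  triangulated by marching cubes — a smooth stand-in for the solvent
  excluded surface, preserving the globular, bumpy character of protein
  surfaces;
* a benchmark arranges classes hierarchically (protein > species >
  domain/entry > conformer), with smooth low-frequency deformations
  separating species, small atom-level jitter separating conformers, and
  optional two-domain *hinge* classes whose conformers sweep a large
  inter-domain angle, emulating calmodulin-like open/closed motions.

Everything is deterministic given the single benchmark seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .mesh import TriangleMesh, ensure_outward, _n_components
from .retrieval import ClassHierarchy

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PseudoStructure",
    "SyntheticBenchmark",
    "generate_pseudo_structure",
    "blobby_surface",
    "generate_hierarchy_benchmark",
    "icosphere",
    "export_benchmark",
]


class EmptySurfaceError(ValueError):
    """The requested iso-level does not intersect the scalar field."""


@dataclass
class PseudoStructure:
    """A connected cluster of soft spheres with a sequence and class labels."""

    centers: np.ndarray          # (n, 3) Angstrom
    radii: np.ndarray            # (n,) Angstrom, in [1, 3]
    sequence: str
    labels: tuple[str, str, str] = ("", "", "")   # (protein, species, domain)
    conformer_index: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.min() < 1.0 - 1e-9 or self.radii.max() > 3.0 + 1e-9:
            raise ValueError("blob radii must lie in [1, 3] Angstrom")
        if len(self.sequence) < 20:
            raise ValueError("sequence must have length >= 20")

    @property
    def n_atoms(self) -> int:
        return len(self.centers)


@dataclass
class SyntheticBenchmark:
    """Meshes + class hierarchy + sequences + generation parameters."""

    ids: list[str]
    meshes: dict[str, TriangleMesh]
    hierarchy: ClassHierarchy
    sequences: dict[str, str]
    params: dict
    seed: int
    hinge_classes: list[str] = field(default_factory=list)
    structures: dict[str, PseudoStructure] = field(default_factory=dict)


def generate_pseudo_structure(n_blobs: int, seed: int,
                              spacing: float = 2.2) -> PseudoStructure:
    """Grow a connected blob cluster by sequential attachment.

    Each new blob is placed a bond-like distance from a uniformly chosen
    existing blob, which guarantees the connectivity invariant.  The
    sequence has length ``3 * n_blobs`` (at least 20) drawn uniformly from
    the 20-letter alphabet.  Deterministic for a fixed seed.
    """
    if n_blobs < 5:
        raise ValueError("n_blobs must be >= 5")
    rng = np.random.default_rng(seed)
    radii = rng.uniform(1.4, 2.6, size=n_blobs)
    centers = np.zeros((n_blobs, 3))
    for i in range(1, n_blobs):
        anchor = rng.integers(0, i)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = spacing * 0.5 * (radii[anchor] + radii[i])
        centers[i] = centers[anchor] + dist * direction
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=max(20, 3 * n_blobs)))
    return PseudoStructure(centers, radii, sequence)


def gaussian_field(structure: PseudoStructure, points: np.ndarray) -> np.ndarray:
    """Sum of per-blob Gaussians exp(-|x - c_i|^2 / r_i^2) at ``points``."""
    d2 = ((points[:, None, :] - structure.centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / structure.radii[None, :] ** 2).sum(axis=1)


def blobby_surface(structure: PseudoStructure, grid_resolution: int = 64,
                   iso_level: float = math.exp(-1),
                   keep_largest: bool = False) -> TriangleMesh:
    """Triangulate the metaball iso-surface of a pseudo-structure.

    The Gaussian field is sampled on a ``grid_resolution``^3 lattice padded
    well past the blob support and surfaced by marching cubes at
    ``iso_level`` (default e^-1, so a single blob of radius r yields the
    sphere of radius r).  The result is closed and outward oriented;
    multi-component surfaces are accepted but logged, or reduced to the
    largest component when ``keep_largest`` is set (small satellite
    components would break spectral descriptors, which require a
    connected surface).
    """
    if grid_resolution < 32:
        raise ValueError("grid_resolution must be >= 32")
    pad = structure.radii.max() * 3.0
    lo = structure.centers.min(axis=0) - pad
    hi = structure.centers.max(axis=0) + pad
    axes = [np.linspace(lo[k], hi[k], grid_resolution) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # chunked evaluation keeps peak memory modest on fine grids
    vals = np.empty(len(grid))
    step = 200_000
    for s in range(0, len(grid), step):
        vals[s:s + step] = gaussian_field(structure, grid[s:s + step])
    volume = vals.reshape(grid_resolution, grid_resolution, grid_resolution)
    if not (0.0 < iso_level < volume.max()):
        raise EmptySurfaceError(
            f"iso level {iso_level} outside (0, {volume.max():.4g})")
    spacing = tuple((hi - lo) / (grid_resolution - 1))
    verts, faces, _, _ = marching_cubes(volume, level=iso_level, spacing=spacing)
    verts = verts + lo
    mesh = TriangleMesh(verts, faces.astype(np.int64))
    mesh, _ = ensure_outward(mesh)
    n_comp = _n_components(mesh)
    if n_comp > 1:
        if keep_largest:
            mesh = _largest_component(mesh)
            logger.debug("kept largest of %d surface components", n_comp)
        else:
            logger.warning("blobby surface has %d connected components", n_comp)
    return mesh


def _largest_component(mesh: TriangleMesh) -> TriangleMesh:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    f = mesh.faces
    n = mesh.n_vertices
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    keep_label = np.bincount(labels).argmax()
    vmask = labels == keep_label
    new_index = -np.ones(n, dtype=np.int64)
    new_index[vmask] = np.arange(vmask.sum())
    fmask = vmask[f].all(axis=1)
    return TriangleMesh(mesh.vertices[vmask], new_index[f[fmask]])


def _radial_lobe_deform(structure: PseudoStructure, scale: float,
                        rng: np.random.Generator) -> PseudoStructure:
    """Smooth species-level deformation: 3 random directional lobes push or
    pull atoms radially, so species differ in shape rather than roughness."""
    c0 = structure.centers.mean(axis=0)
    rel = structure.centers - c0
    r = np.linalg.norm(rel, axis=1)
    r[r == 0] = 1.0
    xhat = rel / r[:, None]
    lobes = rng.normal(size=(3, 3))
    lobes /= np.linalg.norm(lobes, axis=1, keepdims=True)
    weights = rng.normal(size=3)
    g = sum(w * (xhat @ v) ** 2 for w, v in zip(weights, lobes))
    g = g / max(np.abs(g).max(), 1e-12)    # bounded: |displacement| <= scale
    new_centers = c0 + rel + scale * g[:, None] * xhat
    return PseudoStructure(new_centers, structure.radii.copy(), structure.sequence,
                           structure.labels, structure.conformer_index)


def _jitter(structure: PseudoStructure, scale: float,
            rng: np.random.Generator) -> PseudoStructure:
    noise = rng.normal(scale=scale, size=structure.centers.shape)
    return PseudoStructure(structure.centers + noise, structure.radii.copy(),
                           structure.sequence, structure.labels,
                           structure.conformer_index)


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    seq = list(sequence)
    for i in range(len(seq)):
        if rng.random() < rate:
            seq[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(seq)


def _hinge_base(n_blobs: int, rng: np.random.Generator
                ) -> tuple[PseudoStructure, np.ndarray, np.ndarray, int]:
    """Two blob clusters joined by a 3-atom linker along +x.

    Returns (structure, hinge_point, hinge_axis, moving_start): atoms from
    ``moving_start`` on (distal linker atom + second cluster) are the ones
    rotated across conformers about the hinge axis through the middle
    linker atom; rotating the distal linker atom with the cluster keeps
    every link distance fixed, so the surface stays connected at any angle.
    """
    half = max(5, n_blobs // 2)
    a = generate_pseudo_structure(half, int(rng.integers(2**31)))
    b = generate_pseudo_structure(half, int(rng.integers(2**31)))
    r_link = 1.8
    ia = int(np.argmax(a.centers[:, 0]))
    start = a.centers[ia] + np.array([a.radii[ia] + r_link, 0.0, 0.0])
    step = np.array([2.0 * r_link, 0.0, 0.0])
    linker_c = np.array([start, start + step, start + 2 * step])
    ib = int(np.argmin(b.centers[:, 0]))
    shift = linker_c[2] + np.array([r_link + b.radii[ib], 0.0, 0.0]) - b.centers[ib]
    centers = np.vstack([a.centers, linker_c, b.centers + shift])
    radii = np.concatenate([a.radii, np.full(3, r_link), b.radii])
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=3 * len(radii)))
    hinge_point = linker_c[1]
    hinge_axis = np.array([0.0, 0.0, 1.0])
    struct = PseudoStructure(centers, radii, seq)
    return struct, hinge_point, hinge_axis, half + 2


def _rotate_about(points: np.ndarray, point: np.ndarray, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    return (points - point) @ R.T + point


def generate_hierarchy_benchmark(
    n_protein: int,
    n_species_per: int,
    n_conformers: int,
    deformation_scales: tuple[float, float] = (3.0, 0.25),
    hinge_fraction: float = 0.0,
    seed: int = 0,
    n_blobs: int = 14,
    grid_resolution: int = 48,
    species_mutation_rate: float = 0.10,
    hinge_sweep_deg: float = 150.0,
) -> SyntheticBenchmark:
    """Build a hierarchical benchmark of metaball surfaces.

    One base pseudo-structure per protein class; each species applies a
    smooth radial deformation of magnitude ``species_scale``; each
    conformer adds atom-level jitter of magnitude ``conformer_scale``
    (both in Angstrom).  A fraction ``hinge_fraction`` of the protein
    classes is built as two domains joined by a 3-atom linker, with the
    inter-domain angle swept evenly over ``hinge_sweep_deg`` degrees
    across conformers.  Sequences mutate at ``species_mutation_rate`` per
    site between species and are shared by the conformers of one entry.
    """
    species_scale, conformer_scale = deformation_scales
    if species_scale <= 0 or conformer_scale <= 0:
        raise ValueError("deformation scales must be positive")
    if n_protein < 2 or n_species_per < 2 or n_conformers < 2:
        raise ValueError("need at least 2 classes per level and 2 conformers")
    if not 0.0 <= hinge_fraction <= 1.0:
        raise ValueError("hinge_fraction must lie in [0, 1]")

    root = np.random.SeedSequence(seed)
    class_seeds = root.spawn(n_protein)
    n_hinge = int(round(hinge_fraction * n_protein))

    ids: list[str] = []
    meshes: dict[str, TriangleMesh] = {}
    sequences: dict[str, str] = {}
    structures: dict[str, PseudoStructure] = {}
    protein_map: dict[str, str] = {}
    species_map: dict[str, str] = {}
    domain_map: dict[str, str] = {}
    hinge_classes: list[str] = []

    for p in range(n_protein):
        rng = np.random.default_rng(class_seeds[p])
        protein_label = f"P{p:02d}"
        is_hinge = p < n_hinge
        if is_hinge:
            base, hinge_point, hinge_axis, moving_start = _hinge_base(n_blobs, rng)
            hinge_classes.append(protein_label)
        else:
            base = generate_pseudo_structure(n_blobs, int(rng.integers(2**31)))
            hinge_point = hinge_axis = None
            moving_start = 0
        base_seq = base.sequence
        for s in range(n_species_per):
            species_label = f"{protein_label}.S{s:02d}"
            domain_label = f"{species_label}.D00"
            spec_struct = _radial_lobe_deform(base, species_scale, rng)
            spec_seq = _mutate(base_seq, species_mutation_rate, rng)
            sweep = math.radians(hinge_sweep_deg)
            for c in range(n_conformers):
                mesh_id = f"p{p:02d}_s{s:02d}_c{c:02d}"
                struct = _jitter(spec_struct, conformer_scale, rng)
                if is_hinge:
                    angle = -sweep / 2 + sweep * c / max(n_conformers - 1, 1)
                    moving = slice(moving_start, None)
                    centers = struct.centers.copy()
                    centers[moving] = _rotate_about(centers[moving], hinge_point,
                                                    hinge_axis, angle)
                    struct = PseudoStructure(centers, struct.radii, spec_seq,
                                             (protein_label, species_label,
                                              domain_label), c)
                else:
                    struct = PseudoStructure(struct.centers, struct.radii, spec_seq,
                                             (protein_label, species_label,
                                              domain_label), c)
                ids.append(mesh_id)
                structures[mesh_id] = struct
                meshes[mesh_id] = blobby_surface(struct, grid_resolution,
                                                 keep_largest=True)
                sequences[mesh_id] = spec_seq
                protein_map[mesh_id] = protein_label
                species_map[mesh_id] = species_label
                domain_map[mesh_id] = domain_label

    hierarchy = ClassHierarchy(levels={
        "protein": protein_map, "species": species_map, "domain": domain_map})
    params = dict(n_protein=n_protein, n_species_per=n_species_per,
                  n_conformers=n_conformers,
                  species_scale=species_scale, conformer_scale=conformer_scale,
                  hinge_fraction=hinge_fraction, n_blobs=n_blobs,
                  grid_resolution=grid_resolution,
                  species_mutation_rate=species_mutation_rate,
                  hinge_sweep_deg=hinge_sweep_deg)
    return SyntheticBenchmark(ids=ids, meshes=meshes, hierarchy=hierarchy,
                              sequences=sequences, params=params, seed=seed,
                              hinge_classes=hinge_classes, structures=structures)


def plant_homolog_pair(benchmark: SyntheticBenchmark,
                       query_id: str | None = None,
                       target_id: str | None = None,
                       seed: int = 0) -> tuple[str, str]:
    """Plant a distant-surficial-homolog pair into a benchmark, in place.

    Two entries from different protein classes get byte-identical meshes
    while the target's sequence is replaced by an unrelated random one,
    emulating convergent surface shapes with divergent sequences.  The
    modified pair is the ground truth the consensus search should recover.
    """
    rng = np.random.default_rng(seed)
    if query_id is None:
        query_id = benchmark.ids[0]
    if target_id is None:
        q_class = benchmark.hierarchy.levels["protein"][query_id]
        target_id = next(i for i in benchmark.ids
                         if benchmark.hierarchy.levels["protein"][i] != q_class)
    if (benchmark.hierarchy.levels["protein"][query_id]
            == benchmark.hierarchy.levels["protein"][target_id]):
        raise ValueError("planted pair must span two protein classes")
    mesh = benchmark.meshes[query_id]
    benchmark.meshes[target_id] = TriangleMesh(mesh.vertices.copy(),
                                               mesh.faces.copy())
    n = len(benchmark.sequences[target_id])
    benchmark.sequences[target_id] = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    return query_id, target_id


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Geodesic sphere: 20 * 4^subdivisions faces, vertices at ``radius``."""
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in [0, 6]")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    mesh, _ = ensure_outward(mesh)
    # re-project exactly onto the sphere: the descriptor tests rely on it
    norms = np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    return TriangleMesh(mesh.vertices / norms * radius, mesh.faces)


def export_benchmark(benchmark: SyntheticBenchmark, out_dir, fmt: str = "ply") -> None:
    """Write one mesh file per entry, a tab-separated class file and a FASTA."""
    from pathlib import Path
    from .mesh import write_mesh

    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    for mesh_id in benchmark.ids:
        write_mesh(benchmark.meshes[mesh_id], out / "meshes" / f"{mesh_id}.{fmt}", fmt)
    with open(out / "classes.tsv", "w") as fh:
        fh.write("id\tprotein\tspecies\tdomain\n")
        for mesh_id in benchmark.ids:
            levels = benchmark.hierarchy.levels
            fh.write(f"{mesh_id}\t{levels['protein'][mesh_id]}\t"
                     f"{levels['species'][mesh_id]}\t{levels['domain'][mesh_id]}\n")
    with open(out / "sequences.fasta", "w") as fh:
        for mesh_id in benchmark.ids:
            fh.write(f">{mesh_id}\n{benchmark.sequences[mesh_id]}\n")
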