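"""Synthetic cortical geometry.

Two hemispheric source meshes (recursively subdivided octahedra projected to
spherical shells placed inside the inner skull) and a surrogate 68-region
parcellation built by nearest-seed partition, with the six pleasantness
regions of interest (rostral anterior cingulate, medial and lateral
orbitofrontal cortex, both hemispheres) pinned to canonical inferior-frontal
positions.

All positions are in metres in a head-centred frame: +x right, +y anterior,
+z superior, origin at the centre of the concentric-shell head model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

# Head-model constants (metres). Brain / skull / scalp outer radii of the
# three-shell conductor; the hemisphere meshes must stay inside BRAIN_RADIUS.
BRAIN_RADIUS = 0.087
SKULL_RADIUS = 0.092
SCALP_RADIUS = 0.100

# Each hemisphere is a sphere of this radius centred at (+/-HEMI_X, 0, HEMI_Z).
HEMI_RADIUS = 0.038
HEMI_X = 0.040
HEMI_Z = 0.008

#: The 34 cortical region names of the standard 68-region parcellation
#: (34 per hemisphere).
DK_REGION_NAMES = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: Regions carrying pleasantness-related activity, per hemisphere.
PLEASANTNESS_ROI_BASENAMES = (
    "rostralanteriorcingulate", "medialorbitofrontal", "lateralorbitofrontal",
)

#: Fixed feature-table ROI order (region-major, left before right).
PLEASANTNESS_ROIS = tuple(
    f"{name}-{hemi}" for name in PLEASANTNESS_ROI_BASENAMES for hemi in ("lh", "rh")
)

#: Default region used for velocity-locked (confound) activity; far from the
#: frontal ROIs.
DEFAULT_CONFOUND_REGION = "postcentral-lh"

# Canonical seed directions in the hemisphere-local frame
# (medial, anterior, superior); medial is the +x direction for the left
# hemisphere and -x for the right. These pin the regions the pipeline
# depends on to fixed, anatomically sensible spots.
_CANONICAL_LOCAL_DIRECTIONS = {
    "rostralanteriorcingulate": (0.55, 0.80, -0.23),
    "medialorbitofrontal": (0.45, 0.62, -0.64),
    "lateralorbitofrontal": (-0.52, 0.62, -0.59),
    "postcentral": (-0.35, -0.45, 0.82),
    "superiorfrontal": (0.25, 0.55, 0.79),
}

_OCTAHEDRON_VERTICES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)
_OCTAHEDRON_FACES = np.array(
    [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
     [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]],
    dtype=int,
)


@dataclass
class SourceSpace:
    """Discrete dipole locations on two closed hemispheric meshes.

    Attributes
    ----------
    vertices : (n, 3) array of positions in metres.
    orientations : (n, 3) unit outward normals (dipole orientations are fixed
        perpendicular to the mesh surface).
    hemispheres : (n,) int array, 0 = left, 1 = right. Left-hemisphere
        vertices come first.
    level : subdivision level; each hemisphere has ``4**level + 2`` vertices.
    faces : (m, 3) int array of triangles per hemisphere, indexing into the
        global vertex array.
    """

    vertices: np.ndarray
    orientations: np.ndarray
    hemispheres: np.ndarray
    level: int
    faces: tuple[np.ndarray, np.ndarray] = field(repr=False)

    @property
    def n_sources(self) -> int:
        return len(self.vertices)

    @property
    def n_per_hemisphere(self) -> int:
        return self.n_sources // 2

    def hemisphere_indices(self, hemi: int) -> np.ndarray:
        return np.flatnonzero(self.hemispheres == hemi)


@dataclass
class AtlasLabels:
    """A 68-region labelling of a :class:`SourceSpace`.

    ``labels[v]`` is the region id of vertex ``v``; ``region_names[r]`` the
    name of region ``r`` ("<region>-lh" / "<region>-rh"). Left-hemisphere
    regions occupy ids 0-33, right-hemisphere ids 34-67.
    """

    labels: np.ndarray
    region_names: tuple[str, ...]
    seed: int

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_id(self, name: str) -> int:
        return self.region_names.index(name)

    def vertices_of(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == self.region_id(name))


def _subdivide(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint subdivision of a closed triangulated sphere mesh."""
    verts = list(map(tuple, vertices))
    midpoint_cache: dict[tuple[int, int], int] = {}
    new_faces = []

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in midpoint_cache:
            m = (vertices[i] + vertices[j]) / 2.0
            m /= np.linalg.norm(m)
            midpoint_cache[key] = len(verts)
            verts.append(tuple(m))
        return midpoint_cache[key]

    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return np.array(verts, dtype=float), np.array(new_faces, dtype=int)


def unit_sphere_mesh(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided octahedron on the unit sphere with ``4**level + 2`` vertices."""
    if level < 1:
        raise InvalidParameterError(f"subdivision level must be >= 1, got {level}")
    vertices, faces = _OCTAHEDRON_VERTICES.copy(), _OCTAHEDRON_FACES.copy()
    for _ in range(level - 1):
        vertices, faces = _subdivide(vertices, faces)
    return vertices, faces


def build_source_space(level: int) -> SourceSpace:
    """Build the two-hemisphere source space at subdivision ``level``.

    Each hemisphere mesh is a closed subdivided-octahedron sphere of radius
    ``HEMI_RADIUS`` centred at ``(-/+HEMI_X, 0, HEMI_Z)``, i.e. entirely
    inside the brain shell of the spherical head model. ``level=6`` yields
    4098 vertices per hemisphere.
    """
    if level < 1:
        raise InvalidParameterError(f"subdivision level must be >= 1, got {level}")
    if level > 7:
        raise InvalidParameterError(
            f"subdivision level {level} exceeds the supported maximum of 7"
        )
    unit_vertices, faces = unit_sphere_mesh(level)
    n = len(unit_vertices)

    all_vertices, all_orientations, all_faces = [], [], []
    for hemi, sign in ((0, -1.0), (1, 1.0)):
        centre = np.array([sign * HEMI_X, 0.0, HEMI_Z])
        all_vertices.append(centre + HEMI_RADIUS * unit_vertices)
        all_orientations.append(unit_vertices)  # radial => outward unit normal
        all_faces.append(faces + hemi * n)

    hemispheres = np.repeat([0, 1], n)
    return SourceSpace(
        vertices=np.vstack(all_vertices),
        orientations=np.vstack(all_orientations),
        hemispheres=hemispheres,
        level=level,
        faces=(all_faces[0], all_faces[1]),
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _hemisphere_seed_directions(hemi: int, seed: int) -> tuple[np.ndarray, list[str]]:
    """34 seed directions (hemisphere-local sphere) and their region names."""
    n_regions = len(DK_REGION_NAMES)
    directions = _fibonacci_directions(n_regions)
    names: list[str | None] = [None] * n_regions
    used = np.zeros(n_regions, dtype=bool)

    medial_sign = 1.0 if hemi == 0 else -1.0
    for region, (m, a, s) in _CANONICAL_LOCAL_DIRECTIONS.items():
        d = np.array([medial_sign * m, a, s])
        d /= np.linalg.norm(d)
        # replace the nearest unused generic direction with the canonical one
        scores = directions @ d
        scores[used] = -np.inf
        j = int(np.argmax(scores))
        directions[j] = d
        names[j] = region
        used[j] = True

    remaining = [r for r in DK_REGION_NAMES if r not in _CANONICAL_LOCAL_DIRECTIONS]
    rng = np.random.default_rng(np.random.SeedSequence([seed, hemi]))
    rng.shuffle(remaining)
    it = iter(remaining)
    for j in range(n_regions):
        if names[j] is None:
            names[j] = next(it)
    return directions, [str(x) for x in names]


def build_atlas(space: SourceSpace, seed: int = 0) -> AtlasLabels:
    """Partition a source space into 68 regions by nearest seed direction.

    Per hemisphere, 34 seed points (fixed by ``seed``; the canonical regions
    pinned to fixed coordinates) induce a Voronoi partition of the mesh in
    geodesic (angular) distance. Empty regions are repaired by reassigning
    the vertex closest to the empty region's seed from a donor region with
    at least two members, so every region is non-empty whenever the vertex
    count permits.
    """
    n_regions_total = 2 * len(DK_REGION_NAMES)
    if space.n_sources < n_regions_total:
        raise InvalidParameterError(
            f"source space has {space.n_sources} vertices; "
            f"need at least {n_regions_total} for a {n_regions_total}-region atlas"
        )

    labels = np.empty(space.n_sources, dtype=int)
    region_names: list[str] = []
    for hemi in (0, 1):
        directions, names = _hemisphere_seed_directions(hemi, seed)
        region_names.extend(f"{r}-{'lh' if hemi == 0 else 'rh'}" for r in names)
        idx = space.hemisphere_indices(hemi)
        # orientation == hemisphere-local unit direction of each vertex
        local = space.orientations[idx]
        # angular nearest seed == max cosine
        nearest = np.argmax(local @ directions.T, axis=1)
        nearest = _repair_empty_regions(nearest, local, directions)
        labels[idx] = nearest + hemi * len(DK_REGION_NAMES)

    return AtlasLabels(labels=labels, region_names=tuple(region_names), seed=seed)


def _repair_empty_regions(
    assign: np.ndarray, points: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """Guarantee every seed owns >= 1 point (deterministic greedy repair)."""
    assign = assign.copy()
    n_seeds = len(seeds)
    for _ in range(n_seeds):  # each pass fills at least one empty region
        counts = np.bincount(assign, minlength=n_seeds)
        empty = np.flatnonzero(counts == 0)
        if empty.size == 0:
            break
        for r in empty:
            cos = points @ seeds[r]
            donor_ok = counts[assign] >= 2
            if not donor_ok.any():
                break
            cos[~donor_ok] = -np.inf
            v = int(np.argmax(cos))
            counts[assign[v]] -= 1
            assign[v] = r
            counts[r] += 1
    return assign
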