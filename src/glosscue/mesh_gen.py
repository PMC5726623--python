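"""Test-object mesh generation.

Subdivided icospheres displaced along their normals by a seeded 3-D
gradient-noise ("clouds") texture produce the blob-shaped test objects;
analytic sphere and cylinder primitives support the cross-section /
separability analyses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TriangleMesh",
    "DisplacementParams",
    "BLOB_PARAMS",
    "make_icosphere",
    "perlin3",
    "clouds_value",
    "displace_mesh",
    "make_sphere",
    "make_cylinder",
    "make_blob",
    "recompute_vertex_normals",
    "scale_to_vertical_extent",
    "save_obj",
    "load_obj",
]


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with per-vertex unit normals.

    Attributes
    ----------
    vertices : (V, 3) float array of positions in scene units.
    faces : (F, 3) int array of vertex indices (counter-clockwise
        when seen from outside).
    vertex_normals : (V, 3) float array of unit normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.vertex_normals = np.asarray(
            self.vertex_normals, dtype=np.float64
        ).reshape(-1, 3)
        if self.vertex_normals.shape != self.vertices.shape:
            raise ValueError("one normal per vertex required")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.vertex_normals.copy()
        )


@dataclass(frozen=True)
class DisplacementParams:
    """Parameters of the noise-texture displacement.

    ``nabla`` is the texture's gradient step; it has no effect when the
    texture is only sampled as a scalar and is retained for config
    fidelity only.
    """

    strength: float = 1.0
    size: float = 1.0
    depth: int = 0
    nabla: float = 0.03
    midlevel: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("size must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.midlevel <= 1.0:
            raise ValueError("midlevel must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "strength": self.strength,
                "size": self.size,
                "depth": self.depth,
                "nabla": self.nabla,
                "midlevel": self.midlevel,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DisplacementParams":
        return cls(**json.loads(text))


#: Displacement presets for the three blob shapes: (strength, texture size,
#: target vertical extent in scene degrees at 1 unit viewing distance).
BLOB_PARAMS = {
    "blob1": {"strength": 1.0, "size": 1.0, "extent_deg": 4.2},
    "blob2": {"strength": 1.0, "size": 0.7, "extent_deg": 4.0},
    "blob3": {"strength": 0.5, "size": 0.4, "extent_deg": 4.3},
}


# ---------------------------------------------------------------------------
# icosphere


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return verts, faces


def make_icosphere(resolution: int) -> TriangleMesh:
    """Unit icosphere by recursive 4-way subdivision.

    ``resolution=1`` is the raw icosahedron; each further level splits
    every triangle into four and projects the new vertices onto the unit
    sphere, so the face count is ``20 * 4**(resolution - 1)``.
    """
    if not isinstance(resolution, (int, np.integer)) or resolution < 1:
        raise ValueError("resolution must be an integer >= 1")
    verts, faces = _icosahedron()
    for _ in range(resolution - 1):
        verts, faces = _subdivide(verts, faces)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMesh(verts, faces, normals)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    verts = list(map(tuple, verts))
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = cache.get(key)
        if idx is None:
            p = np.array(verts[i]) + np.array(verts[j])
            p /= np.linalg.norm(p)
            idx = len(verts)
            verts.append(tuple(p))
            cache[key] = idx
        return idx

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.array(verts, dtype=np.float64), np.array(new_faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# noise texture

_GRAD3 = np.array(
    [
        (1, 1, 0), (-1, 1, 0), (1, -1, 0), (-1, -1, 0),
        (1, 0, 1), (-1, 0, 1), (1, 0, -1), (-1, 0, -1),
        (0, 1, 1), (0, -1, 1), (0, 1, -1), (0, -1, -1),
    ],
    dtype=np.float64,
)

_PERM_CACHE: dict[int, np.ndarray] = {}


def _perm_table(seed: int) -> np.ndarray:
    table = _PERM_CACHE.get(seed)
    if table is None:
        rng = np.random.default_rng(seed)
        p = rng.permutation(256)
        table = np.concatenate([p, p, p]).astype(np.int64)
        _PERM_CACHE[seed] = table
    return table


def _fade(t: np.ndarray) -> np.ndarray:
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin3(point, seed: int = 0):
    """Improved 3-D gradient noise in [-1, 1], zero on the integer lattice.

    Accepts a single 3-vector or an (N, 3) array; deterministic for a
    fixed seed.
    """
    pts = np.asarray(point, dtype=np.float64)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    perm = _perm_table(seed)

    pi = np.floor(pts).astype(np.int64)
    pf = pts - pi
    pi &= 255

    u, v, w = _fade(pf[:, 0]), _fade(pf[:, 1]), _fade(pf[:, 2])

    def grad_dot(dx: int, dy: int, dz: int) -> np.ndarray:
        h = perm[perm[perm[pi[:, 0] + dx] + pi[:, 1] + dy] + pi[:, 2] + dz] % 12
        g = _GRAD3[h]
        off = pf - np.array([dx, dy, dz], dtype=np.float64)
        return np.einsum("ij,ij->i", g, off)

    def lerp(a, b, t):
        return a + t * (b - a)

    x00 = lerp(grad_dot(0, 0, 0), grad_dot(1, 0, 0), u)
    x10 = lerp(grad_dot(0, 1, 0), grad_dot(1, 1, 0), u)
    x01 = lerp(grad_dot(0, 0, 1), grad_dot(1, 0, 1), u)
    x11 = lerp(grad_dot(0, 1, 1), grad_dot(1, 1, 1), u)
    y0 = lerp(x00, x10, v)
    y1 = lerp(x01, x11, v)
    out = np.clip(lerp(y0, y1, w), -1.0, 1.0)
    return float(out[0]) if scalar else out


def clouds_value(point, params: DisplacementParams):
    """Scalar clouds texture in [0, 1].

    With ``depth=0`` this is a single noise octave evaluated at
    ``point / size`` and remapped from [-1, 1] to [0, 1]; higher depths
    add halved-amplitude, doubled-frequency octaves (normalized fBm).
    """
    pts = np.asarray(point, dtype=np.float64)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    total = np.zeros(len(pts))
    amp, freq, norm = 1.0, 1.0, 0.0
    for octave in range(params.depth + 1):
        total += amp * perlin3(pts * (freq / params.size), seed=params.seed + octave)
        norm += amp
        amp *= 0.5
        freq *= 2.0
    value = np.clip((total / norm + 1.0) / 2.0, 0.0, 1.0)
    return float(value[0]) if scalar else value


# ---------------------------------------------------------------------------
# displacement


def recompute_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted average of incident face normals, normalized."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    fn = np.cross(v1 - v0, v2 - v0)  # length = 2 * area, weighting built in
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    return normals / lengths


def displace_mesh(mesh: TriangleMesh, params: DisplacementParams) -> TriangleMesh:
    """Move every vertex along its normal by ``strength * (texture - midlevel)``."""
    offsets = params.strength * (clouds_value(mesh.vertices, params) - params.midlevel)
    verts = mesh.vertices + mesh.vertex_normals * offsets[:, None]
    normals = recompute_vertex_normals(verts, mesh.faces)
    return TriangleMesh(verts, mesh.faces.copy(), normals)


# ---------------------------------------------------------------------------
# primitives


def make_sphere(radius: float, resolution: int = 32) -> TriangleMesh:
    """UV sphere; ``resolution`` latitude bands, twice as many meridians."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    n_lat, n_lon = resolution, 2 * resolution
    verts = [(0.0, radius, 0.0)]
    for i in range(1, n_lat):
        theta = math.pi * i / n_lat
        for j in range(n_lon):
            phi = 2.0 * math.pi * j / n_lon
            verts.append(
                (
                    radius * math.sin(theta) * math.sin(phi),
                    radius * math.cos(theta),
                    -radius * math.sin(theta) * math.cos(phi),
                )
            )
    verts.append((0.0, -radius, 0.0))
    south = len(verts) - 1

    def ring(i: int, j: int) -> int:
        return 1 + (i - 1) * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append((0, ring(1, j), ring(1, j + 1)))
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces += [(a, c, d), (a, d, b)]
    for j in range(n_lon):
        faces.append((south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)))

    verts = np.array(verts)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMesh(verts, np.array(faces, dtype=np.int64), normals)


def make_cylinder(radius: float, height: float, segments: int = 48) -> TriangleMesh:
    """Closed vertical cylinder; lateral normals are purely radial.

    Cap rims duplicate the lateral rings so that lateral vertex normals
    keep a zero axial component.
    """
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be > 0")
    if segments < 3:
        raise ValueError("segments must be >= 3")
    half = height / 2.0
    angles = 2.0 * math.pi * np.arange(segments) / segments
    # Rotate so the first sample faces the camera direction (-z).
    ring = np.stack([np.sin(angles), np.zeros(segments), -np.cos(angles)], axis=1)
    top = ring * radius + np.array([0.0, half, 0.0])
    bot = ring * radius + np.array([0.0, -half, 0.0])

    verts = [top, bot]
    normals = [ring, ring]
    faces = []
    for j in range(segments):
        a, b = j, (j + 1) % segments
        c, d = segments + j, segments + (j + 1) % segments
        faces += [(a, c, d), (a, d, b)]

    base = 2 * segments
    verts += [top, bot, np.array([[0.0, half, 0.0], [0.0, -half, 0.0]])]
    up = np.array([0.0, 1.0, 0.0])
    normals += [np.tile(up, (segments, 1)), np.tile(-up, (segments, 1)),
                np.array([up, -up])]
    top_center, bot_center = base + 2 * segments, base + 2 * segments + 1
    for j in range(segments):
        a, b = base + j, base + (j + 1) % segments
        faces.append((top_center, b, a))
        c, d = base + segments + j, base + segments + (j + 1) % segments
        faces.append((bot_center, c, d))

    return TriangleMesh(
        np.vstack(verts), np.array(faces, dtype=np.int64), np.vstack(normals)
    )


# ---------------------------------------------------------------------------
# blob assembly and scaling


def scale_to_vertical_extent(
    mesh: TriangleMesh, extent_deg: float = 4.2, distance: float = 1.0
) -> TriangleMesh:
    """Uniformly scale so the vertical (y) extent subtends ``extent_deg``
    degrees at the given viewing distance."""
    target = 2.0 * distance * math.tan(math.radians(extent_deg / 2.0))
    span = mesh.vertices[:, 1].max() - mesh.vertices[:, 1].min()
    if span <= 0:
        raise ValueError("mesh has no vertical extent")
    return TriangleMesh(
        mesh.vertices * (target / span), mesh.faces.copy(), mesh.vertex_normals.copy()
    )


def make_blob(
    name: str,
    resolution: int = 6,
    seed: int = 0,
    extent_deg: float | None = None,
    distance: float = 1.0,
) -> TriangleMesh:
    """Icosphere displaced with the preset parameters for blob1..blob3,
    scaled to its target angular size."""
    preset = BLOB_PARAMS[name]
    params = DisplacementParams(
        strength=preset["strength"], size=preset["size"], seed=seed
    )
    mesh = displace_mesh(make_icosphere(resolution), params)
    if extent_deg is None:
        extent_deg = preset["extent_deg"]
    return scale_to_vertical_extent(mesh, extent_deg, distance)


# ---------------------------------------------------------------------------
# OBJ I/O


def save_obj(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for n in mesh.vertex_normals:
            fh.write(f"vn {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0]+1}//{f[0]+1} {f[1]+1}//{f[1]+1} {f[2]+1}//{f[2]+1}\n")


def load_obj(path) -> TriangleMesh:
    verts, normals, faces = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "vn":
                normals.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    verts = np.array(verts)
    faces = np.array(faces, dtype=np.int64)
    if normals:
        normals = np.array(normals)
    else:
        normals = recompute_vertex_normals(verts, faces)
    return TriangleMesh(verts, faces, normals)
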