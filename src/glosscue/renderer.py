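"""Ray-cast renderer for the three-point-light gloss scenes.

Shading is diffuse + GGX microfacet specular with Schlick Fresnel and a
Smith height-correlated visibility term. Three white point lights sit on a
radius-5 arc in the horizontal plane; their angular spread is controlled
by a single parameter alpha in [0, 1] (0 = coincident with the central
light, 1 = 90 degrees away from it). A constant ambient term models the
environment light. Luminance images are linear; optional hard clipping at
1.0 emulates the display ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh_gen import TriangleMesh

__all__ = [
    "PointLight",
    "Material",
    "Camera",
    "Scene",
    "RenderedImage",
    "LIGHT_DISTANCE",
    "LIGHT_RANGE",
    "LUMA_WEIGHTS",
    "place_lights",
    "make_lights",
    "smoothness_to_roughness",
    "ggx_ndf",
    "fresnel_schlick",
    "smith_visibility",
    "attenuation",
    "shade",
    "render",
    "render_stereo",
    "default_camera",
    "default_stereo_cameras",
    "build_scene",
]

#: Distance of every point light from the object center (scene units).
LIGHT_DISTANCE = 5.0
#: Distance at which light intensity reaches zero.
LIGHT_RANGE = 10.0
#: Rec. 709 luma weights applied to linear rgb.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

_EPS = 1e-12


@dataclass
class PointLight:
    position: np.ndarray
    color: np.ndarray = field(default_factory=lambda: np.ones(3))
    intensity: float = 1.5
    range: float = LIGHT_RANGE

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.color = np.asarray(self.color, dtype=np.float64).reshape(3)
        if self.range <= 0:
            raise ValueError("range must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class Material:
    """Surface material; roughness is always derived from smoothness.

    ``specular_scale`` multiplies the Cook-Torrance specular term; 1 is
    the normalized microfacet form, pi emulates the game-engine
    (Torrance-Sparrow) specular convention relative to a Lambert
    albedo/pi diffuse.
    """

    albedo: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    smoothness: float = 0.4
    metallic: float = 0.0
    f0: float = 0.04
    disney_diffuse: bool = False
    specular_scale: float = 1.0

    def __post_init__(self) -> None:
        self.albedo = np.asarray(self.albedo, dtype=np.float64).reshape(3)
        if not 0.0 <= self.smoothness <= 1.0:
            raise ValueError("smoothness must be in [0, 1]")

    @property
    def roughness(self) -> float:
        return smoothness_to_roughness(self.smoothness)


@dataclass
class Camera:
    """Pinhole camera. ``fov`` is the vertical field of view in degrees."""

    position: np.ndarray
    target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fov: float = 6.0
    image_size: tuple[int, int] = (128, 128)  # (rows, cols)
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.target = np.asarray(self.target, dtype=np.float64).reshape(3)
        self.up = np.asarray(self.up, dtype=np.float64).reshape(3)
        if not 0.0 < self.fov < 180.0:
            raise ValueError("fov must be in (0, 180)")
        rows, cols = self.image_size
        if rows <= 0 or cols <= 0:
            raise ValueError("image size must be positive")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        forward = self.target - self.position
        forward = forward / np.linalg.norm(forward)
        right = np.cross(self.up, forward)
        right = right / np.linalg.norm(right)
        up = np.cross(forward, right)
        return forward, right, up


@dataclass
class Scene:
    mesh: TriangleMesh
    material: Material
    lights: list[PointLight]
    ambient_color: np.ndarray = field(default_factory=lambda: np.ones(3))
    ambient_intensity: float = 0.6
    spread_alpha: float = 0.0

    def __post_init__(self) -> None:
        self.ambient_color = np.asarray(self.ambient_color, dtype=np.float64).reshape(3)


@dataclass
class RenderedImage:
    """Linear-luminance image plus foreground mask.

    ``n_views`` is 1 for a monocular render and 2 for a side-by-side
    stereo pair. ``clipped_count`` counts foreground pixels that reached
    the clip ceiling (0 when clipping was off).
    """

    luminance: np.ndarray
    foreground_mask: np.ndarray
    rgb: np.ndarray | None = None
    clipped_count: int = 0
    n_views: int = 1
    clip: bool = False
    clip_ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.foreground_mask.shape != self.luminance.shape:
            raise ValueError("mask shape must equal luminance shape")


# ---------------------------------------------------------------------------
# light placement


def place_lights(alpha: float) -> np.ndarray:
    """Positions of the three point lights for spread ``alpha``.

    Returns a (3, 3) array ``[central, left, right]``. The central light
    is fixed at (0, 0, -5); the lateral lights sit on the radius-5 arc in
    the horizontal plane at +-(alpha * 90 degrees) from it.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    theta = alpha * math.pi / 2.0
    s, c = math.sin(theta), math.cos(theta)
    return LIGHT_DISTANCE * np.array(
        [(0.0, 0.0, -1.0), (-s, 0.0, -c), (s, 0.0, -c)], dtype=np.float64
    )


def make_lights(
    alpha: float, intensity: float, color=(1.0, 1.0, 1.0)
) -> list[PointLight]:
    return [
        PointLight(p, color=np.asarray(color, dtype=float), intensity=intensity)
        for p in place_lights(alpha)
    ]


# ---------------------------------------------------------------------------
# shading terms


def smoothness_to_roughness(s: float) -> float:
    """roughness = (1 - smoothness)^2."""
    if np.any(np.asarray(s) < 0) or np.any(np.asarray(s) > 1):
        raise ValueError("smoothness must be in [0, 1]")
    return (1.0 - s) ** 2


_ROUGHNESS_FLOOR = 1e-4


def ggx_ndf(n_dot_h, roughness):
    """GGX normal distribution, shape parameter a = roughness.

    A roughness of exactly 0 is floored at 1e-4 to keep the lobe finite.
    """
    ndh = np.asarray(n_dot_h, dtype=np.float64)
    if np.any(ndh < -1e-9) or np.any(ndh > 1 + 1e-9):
        raise ValueError("n_dot_h must be in [0, 1]")
    a = max(float(roughness), _ROUGHNESS_FLOOR)
    a2 = a * a
    denom = ndh * ndh * (a2 - 1.0) + 1.0
    return a2 / (math.pi * denom * denom)


def fresnel_schlick(v_dot_h, f0: float = 0.04):
    """Schlick approximation F0 + (1 - F0)(1 - v.h)^5."""
    vdh = np.clip(np.asarray(v_dot_h, dtype=np.float64), 0.0, 1.0)
    return f0 + (1.0 - f0) * (1.0 - vdh) ** 5


def smith_visibility(n_dot_l, n_dot_v, roughness):
    """Height-correlated Smith visibility term V = G / (4 (n.l)(n.v))."""
    a = max(float(roughness), _ROUGHNESS_FLOOR)
    a2 = a * a
    ndl = np.asarray(n_dot_l, dtype=np.float64)
    ndv = np.asarray(n_dot_v, dtype=np.float64)
    lv = ndl * np.sqrt(np.maximum(ndv * ndv * (1.0 - a2) + a2, _EPS))
    vl = ndv * np.sqrt(np.maximum(ndl * ndl * (1.0 - a2) + a2, _EPS))
    return 0.5 / np.maximum(lv + vl, _EPS)


def attenuation(distance, range_: float = LIGHT_RANGE):
    """Windowed falloff: 1 at the source, exactly 0 at ``range_``.

    f(d) = (1 - (d / range)^4)^2, clamped. A smooth window of this form
    (rather than a normalized inverse-square law) is used so that the
    three lights at their fixed 5-unit distance contribute on the order
    of the ambient term; a 1/d^2 factor would scale every light by 0.04
    and intensity clipping could never occur.
    """
    if range_ <= 0:
        raise ValueError("range must be > 0")
    d = np.asarray(distance, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    x = np.clip(d / range_, 0.0, 1.0)
    out = (1.0 - x**4) ** 2
    return float(out) if np.isscalar(distance) else out


def _disney_diffuse_factor(ndl, ndv, ldh, roughness):
    # Burley retro-reflective diffuse, normalized to 1 at normal incidence.
    fd90 = 0.5 + 2.0 * roughness * ldh * ldh
    fl = (1.0 - ndl) ** 5
    fv = (1.0 - ndv) ** 5
    return (1.0 + (fd90 - 1.0) * fl) * (1.0 + (fd90 - 1.0) * fv)


def _shade_batch(
    points: np.ndarray,
    normals: np.ndarray,
    view_dirs: np.ndarray,
    lights: list[PointLight],
    material: Material,
    ambient_color: np.ndarray,
    ambient_intensity: float,
) -> np.ndarray:
    """Vectorized shading of N surface samples; returns (N, 3) radiance."""
    n = normals
    v = view_dirs
    ndv = np.einsum("ij,ij->i", n, v)
    rough = material.roughness
    diffuse_color = material.albedo * (1.0 - material.metallic) / math.pi

    out = np.tile(ambient_intensity * ambient_color * material.albedo, (len(points), 1))
    lit = ndv > 0.0
    if not np.any(lit):
        return out
    for light in lights:
        to_light = light.position - points
        dist = np.linalg.norm(to_light, axis=1)
        l = to_light / np.maximum(dist, _EPS)[:, None]
        ndl = np.einsum("ij,ij->i", n, l)
        active = lit & (ndl > 0.0)
        if not np.any(active):
            continue
        h = l + v
        h /= np.maximum(np.linalg.norm(h, axis=1), _EPS)[:, None]
        ndh = np.clip(np.einsum("ij,ij->i", n, h), 0.0, 1.0)
        vdh = np.clip(np.einsum("ij,ij->i", v, h), 0.0, 1.0)
        ldh = vdh  # l.h == v.h for the half vector

        d = ggx_ndf(ndh, rough)
        f = fresnel_schlick(vdh, material.f0)
        vis = smith_visibility(np.maximum(ndl, 0.0), np.maximum(ndv, 0.0), rough)
        spec = (material.specular_scale * d * f * vis)[:, None] * np.ones(3)

        diff = np.tile(diffuse_color, (len(points), 1))
        if material.disney_diffuse:
            diff = diff * _disney_diffuse_factor(
                np.maximum(ndl, 0.0), np.maximum(ndv, 0.0), ldh, rough
            )[:, None]

        contrib = (
            (diff + spec)
            * light.color
            * (light.intensity * attenuation(dist, light.range) * np.maximum(ndl, 0.0))[
                :, None
            ]
        )
        contrib[~active] = 0.0
        out += contrib
    return np.maximum(out, 0.0)


def shade(
    point,
    normal,
    view_dir,
    lights: list[PointLight],
    material: Material,
    ambient_color=(1.0, 1.0, 1.0),
    ambient_intensity: float = 0.6,
) -> np.ndarray:
    """Outgoing rgb radiance at one surface point.

    ``view_dir`` points from the surface toward the viewer. When the
    viewer is below the surface horizon (n.v <= 0) only the ambient term
    is returned.
    """
    return _shade_batch(
        np.atleast_2d(np.asarray(point, dtype=float)),
        np.atleast_2d(np.asarray(normal, dtype=float)),
        np.atleast_2d(np.asarray(view_dir, dtype=float)),
        lights,
        material,
        np.asarray(ambient_color, dtype=float),
        ambient_intensity,
    )[0]


# ---------------------------------------------------------------------------
# ray casting


def _camera_rays(camera: Camera) -> np.ndarray:
    rows, cols = camera.image_size
    forward, right, up = camera.basis()
    tan_half = math.tan(math.radians(camera.fov) / 2.0)
    aspect = cols / rows
    xs = ((np.arange(cols) + 0.5) / cols * 2.0 - 1.0) * tan_half * aspect
    ys = (1.0 - (np.arange(rows) + 0.5) / rows * 2.0) * tan_half
    dirs = (
        forward[None, None, :]
        + xs[None, :, None] * right[None, None, :]
        + ys[:, None, None] * up[None, None, :]
    )
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    return dirs.reshape(-1, 3)


def _raycast(
    origin: np.ndarray, dirs: np.ndarray, mesh: TriangleMesh, camera: Camera
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-hit intersection of all camera rays with the mesh.

    Triangles are binned by their projected screen bounding box, so each
    triangle is only tested against the rays that can hit it. Returns
    (t, face index, u, v) per ray, with face index -1 for misses.
    """
    rows, cols = camera.image_size
    n_rays = rows * cols
    forward, right, up = camera.basis()
    tan_half = math.tan(math.radians(camera.fov) / 2.0)
    aspect = cols / rows

    rel = mesh.vertices - origin
    cz = rel @ forward
    cz = np.maximum(cz, 1e-9)
    px = (rel @ right / (cz * tan_half * aspect) + 1.0) / 2.0 * cols - 0.5
    py = (1.0 - rel @ up / (cz * tan_half)) / 2.0 * rows - 0.5

    t_buf = np.full(n_rays, np.inf)
    face_buf = np.full(n_rays, -1, dtype=np.int64)
    u_buf = np.zeros(n_rays)
    v_buf = np.zeros(n_rays)

    tri = mesh.faces
    fx = px[tri]
    fy = py[tri]
    c0 = np.clip(np.floor(fx.min(axis=1)).astype(int) - 1, 0, cols - 1)
    c1 = np.clip(np.ceil(fx.max(axis=1)).astype(int) + 1, 0, cols - 1)
    r0 = np.clip(np.floor(fy.min(axis=1)).astype(int) - 1, 0, rows - 1)
    r1 = np.clip(np.ceil(fy.max(axis=1)).astype(int) + 1, 0, rows - 1)
    # Skip triangles whose projection misses the image entirely.
    on_screen = (fx.max(axis=1) >= -1) & (fx.min(axis=1) <= cols) & (
        fy.max(axis=1) >= -1
    ) & (fy.min(axis=1) <= rows)

    verts = mesh.vertices
    eps = 1e-12
    for fi in np.nonzero(on_screen)[0]:
        a, b, c = tri[fi]
        rr0, rr1, cc0, cc1 = r0[fi], r1[fi], c0[fi], c1[fi]
        pix_rows = np.arange(rr0, rr1 + 1)
        pix_cols = np.arange(cc0, cc1 + 1)
        idx = (pix_rows[:, None] * cols + pix_cols[None, :]).ravel()
        d = dirs[idx]

        v0 = verts[a]
        e1 = verts[b] - v0
        e2 = verts[c] - v0
        tvec = origin - v0
        qvec = np.cross(tvec, e1)
        pvec = np.cross(d, e2)
        det = pvec @ e1
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        u = (pvec @ tvec) * inv
        v = (d @ qvec) * inv
        t = (qvec @ e2) * inv
        ok &= (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9) & (t > 1e-9)
        ok &= t < t_buf[idx]
        if not np.any(ok):
            continue
        hit_idx = idx[ok]
        t_buf[hit_idx] = t[ok]
        face_buf[hit_idx] = fi
        u_buf[hit_idx] = u[ok]
        v_buf[hit_idx] = v[ok]
    return t_buf, face_buf, u_buf, v_buf


def render(scene: Scene, camera: Camera, clip: bool = True) -> RenderedImage:
    """Render the scene: per-pixel nearest-hit ray cast plus local shading.

    Background pixels are excluded from the foreground mask and have zero
    luminance. With ``clip=True`` rgb channels are limited to 1.0 and the
    number of foreground pixels at the ceiling is recorded.
    """
    if scene.mesh.n_faces == 0:
        raise ValueError("cannot render an empty mesh")
    rows, cols = camera.image_size
    dirs = _camera_rays(camera)
    t, face, u, v = _raycast(camera.position, dirs, scene.mesh, camera)

    hit = face >= 0
    rgb = np.zeros((rows * cols, 3))
    if np.any(hit):
        fi = face[hit]
        tri = scene.mesh.faces[fi]
        w0 = (1.0 - u[hit] - v[hit])[:, None]
        w1 = u[hit][:, None]
        w2 = v[hit][:, None]
        normals = (
            w0 * scene.mesh.vertex_normals[tri[:, 0]]
            + w1 * scene.mesh.vertex_normals[tri[:, 1]]
            + w2 * scene.mesh.vertex_normals[tri[:, 2]]
        )
        normals /= np.maximum(np.linalg.norm(normals, axis=1), _EPS)[:, None]
        points = camera.position + t[hit][:, None] * dirs[hit]
        rgb[hit] = _shade_batch(
            points,
            normals,
            -dirs[hit],
            scene.lights,
            scene.material,
            scene.ambient_color,
            scene.ambient_intensity,
        )

    ceiling = 1.0
    clipped_count = 0
    if clip:
        at_ceiling = hit & np.any(rgb >= ceiling - 1e-12, axis=1)
        clipped_count = int(at_ceiling.sum())
        rgb = np.minimum(rgb, ceiling)

    luminance = rgb @ LUMA_WEIGHTS
    luminance[~hit] = 0.0
    return RenderedImage(
        luminance=luminance.reshape(rows, cols),
        foreground_mask=hit.reshape(rows, cols),
        rgb=rgb.reshape(rows, cols, 3),
        clipped_count=clipped_count,
        n_views=1,
        clip=clip,
        clip_ceiling=ceiling,
    )


def render_stereo(
    scene: Scene, left_cam: Camera, right_cam: Camera, clip: bool = True
) -> RenderedImage:
    """Side-by-side stereo render (left half-image first)."""
    if left_cam.image_size != right_cam.image_size:
        raise ValueError("stereo cameras must share the same image size")
    left = render(scene, left_cam, clip=clip)
    right = render(scene, right_cam, clip=clip)
    return RenderedImage(
        luminance=np.hstack([left.luminance, right.luminance]),
        foreground_mask=np.hstack([left.foreground_mask, right.foreground_mask]),
        rgb=np.concatenate([left.rgb, right.rgb], axis=1),
        clipped_count=left.clipped_count + right.clipped_count,
        n_views=2,
        clip=clip,
        clip_ceiling=left.clip_ceiling,
    )


# ---------------------------------------------------------------------------
# scene helpers


def default_camera(image_size=(128, 128), fov: float = 6.0) -> Camera:
    """Monocular camera at the cyclopean position (0, 0, -1)."""
    return Camera(position=(0.0, 0.0, -1.0), image_size=image_size, fov=fov)


def default_stereo_cameras(image_size=(128, 128), fov: float = 6.0):
    left = Camera(position=(-0.03, 0.0, -1.0), image_size=image_size, fov=fov)
    right = Camera(position=(0.03, 0.0, -1.0), image_size=image_size, fov=fov)
    return left, right


def build_scene(
    mesh: TriangleMesh,
    smoothness: float,
    alpha: float,
    intensity: float,
    albedo: float = 0.5,
    ambient_intensity: float = 0.6,
    disney_diffuse: bool = False,
) -> Scene:
    """Scene with the standard geometry: three white lights placed by
    ``alpha`` on the radius-5 arc and a white ambient source."""
    material = Material(
        albedo=np.full(3, albedo), smoothness=smoothness, disney_diffuse=disney_diffuse
    )
    return Scene(
        mesh=mesh,
        material=material,
        lights=make_lights(alpha, intensity),
        ambient_intensity=ambient_intensity,
        spread_alpha=alpha,
    )
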