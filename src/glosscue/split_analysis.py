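"""Analytic superposition of specular lobes and split detection.

A 1-D cross-section model: all lights, cameras and the object centre are
coplanar, so the specular intensity along an equatorial circle of given
curvature radius captures how the three per-light lobes superpose. A
Rayleigh-style dip criterion decides when the merged highlight resolves
into separate ones, and a bisection finds the smallest light spread
alpha* at which that happens for a given smoothness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .renderer import (
    LIGHT_RANGE,
    Material,
    RenderedImage,
    attenuation,
    fresnel_schlick,
    ggx_ndf,
    place_lights,
    smith_visibility,
    smoothness_to_roughness,
)

__all__ = [
    "LobeProfile",
    "SplitCriterion",
    "SplitResult",
    "lobe_profile",
    "detect_split",
    "find_alpha_star",
    "image_split_detect",
]

#: dip_fraction presets for the colour criteria of the adjustment task;
#: only the dip threshold differs between them.
CRITERION_PRESETS = {
    "rayleigh": 0.26,
    "gap": 0.9,
    "all_colors": 0.26,
    "no_red": 0.1,
}


@dataclass
class LobeProfile:
    """Specular intensity along a circular surface cross-section.

    ``angles`` are surface-tangent angles (radians, 0 = point facing the
    camera); ``geometry`` records the generating configuration.
    """

    angles: np.ndarray
    intensity: np.ndarray
    geometry: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class SplitCriterion:
    """Rayleigh-style resolvability rule.

    ``min_peaks`` is the number of local maxima required before the dip
    rule applies (2 for generic two-lobe profiles; the critical-spread
    search raises it to 3 so the merged central highlight cannot be
    mistaken for a resolved group).
    """

    dip_fraction: float = 0.26
    min_peak_prominence: float = 1e-3
    min_peaks: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.dip_fraction < 1.0:
            raise ValueError("dip_fraction must be in (0, 1)")
        if self.min_peaks < 2:
            raise ValueError("min_peaks must be >= 2")


@dataclass
class SplitResult:
    n_peaks: int
    dip_depths: list[float]
    resolved: bool


def lobe_profile(
    curvature_radius: float,
    smoothness: float,
    alpha: float,
    n_samples: int = 2001,
    intensity: float = 1.5,
    camera_position=(0.0, 0.0, -1.0),
    max_angle: float = math.pi / 3,
) -> LobeProfile:
    """Summed specular term of the three lights along the equator of a
    circle of the given curvature radius, using the standard scene
    geometry (lights on the radius-5 arc placed by ``alpha``).

    The angular domain is limited to ``[-max_angle, max_angle]``
    (default +-60 degrees): the mirror reflections of the three lights
    fall within about +-45 degrees for any spread, and the cut excludes
    the grazing Fresnel rim, which is not part of the highlight group.
    """
    if curvature_radius <= 0:
        raise ValueError("curvature_radius must be > 0")
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError("smoothness must be in [0, 1]")
    rough = smoothness_to_roughness(smoothness)
    cam = np.asarray(camera_position, dtype=np.float64)
    lights = place_lights(alpha)

    theta = np.linspace(-max_angle, max_angle, n_samples)
    normals = np.stack(
        [np.sin(theta), np.zeros_like(theta), -np.cos(theta)], axis=1
    )
    points = curvature_radius * normals

    v = cam - points
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    ndv = np.einsum("ij,ij->i", normals, v)

    total = np.zeros(n_samples)
    for lp in lights:
        to_light = lp - points
        dist = np.linalg.norm(to_light, axis=1)
        l = to_light / dist[:, None]
        ndl = np.einsum("ij,ij->i", normals, l)
        h = l + v
        h /= np.linalg.norm(h, axis=1, keepdims=True)
        ndh = np.clip(np.einsum("ij,ij->i", normals, h), 0.0, 1.0)
        vdh = np.clip(np.einsum("ij,ij->i", v, h), 0.0, 1.0)
        spec = (
            ggx_ndf(ndh, rough)
            * fresnel_schlick(vdh)
            * smith_visibility(np.maximum(ndl, 0.0), np.maximum(ndv, 0.0), rough)
        )
        lit = (ndl > 0.0) & (ndv > 0.0)
        total += np.where(
            lit, spec * intensity * attenuation(dist, LIGHT_RANGE) * ndl, 0.0
        )

    geometry = {
        "curvature_radius": curvature_radius,
        "smoothness": smoothness,
        "alpha": alpha,
        "camera_position": tuple(cam),
        "light_positions": [tuple(p) for p in lights],
    }
    return LobeProfile(
        angles=theta,
        intensity=total,
        geometry=geometry,
        degenerate=not np.any(total > 0),
    )


def detect_split(
    profile: LobeProfile | np.ndarray, criterion: SplitCriterion = SplitCriterion()
) -> SplitResult:
    """Count peaks and inter-peak dips on a (max-normalized) profile.

    A dip between two adjacent peaks has depth
    ``1 - min_between / lower_adjacent_peak``. The pattern is resolved
    when there are at least two peaks and every dip is at least
    ``dip_fraction`` deep. Scale-invariant by construction.
    """
    y = profile.intensity if isinstance(profile, LobeProfile) else np.asarray(profile)
    if not np.any(y > 0):
        raise ValueError("all-zero profile")
    y = y / y.max()
    peaks, _ = find_peaks(y, prominence=criterion.min_peak_prominence)
    if len(peaks) < 2:
        return SplitResult(n_peaks=len(peaks), dip_depths=[], resolved=False)
    depths = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        trough = y[left : right + 1].min()
        lower = min(y[left], y[right])
        depths.append(float(1.0 - trough / lower))
    resolved = (
        len(peaks) >= criterion.min_peaks
        and min(depths) >= criterion.dip_fraction
    )
    return SplitResult(n_peaks=len(peaks), dip_depths=depths, resolved=resolved)


def find_alpha_star(
    curvature_radius: float,
    smoothness: float,
    criterion: SplitCriterion = SplitCriterion(),
    tol: float = 1e-3,
    n_samples: int = 4001,
) -> float | None:
    """Smallest light spread at which the highlight group is resolved.

    Returns None when even alpha = 1 leaves the group unresolved (the
    "not feasible" outcome). Bisection to the given tolerance. All three
    lights' peaks must be present (min_peaks is raised to 3), so a deep
    dip between the two lateral highlights alone does not count as a
    resolved group.
    """
    import dataclasses

    criterion = dataclasses.replace(
        criterion, min_peaks=max(criterion.min_peaks, 3)
    )

    def resolved(alpha: float) -> bool:
        prof = lobe_profile(curvature_radius, smoothness, alpha, n_samples=n_samples)
        if prof.degenerate:
            return False
        return detect_split(prof, criterion).resolved

    if not resolved(1.0):
        return None
    if resolved(0.0):
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if resolved(mid):
            hi = mid
        else:
            lo = mid
    return hi


def image_split_detect(
    image: RenderedImage,
    roi: tuple[int, int, int, int] | None = None,
    criterion: SplitCriterion = SplitCriterion(),
) -> SplitResult:
    """Split detection on a rendered image.

    The luminance inside ``roi`` (row0, row1, col0, col1; half-open) is
    max-projected across its short axis and passed to ``detect_split``.
    Background pixels are excluded; an roi without foreground is an
    error.
    """
    if roi is None:
        roi = (0, image.luminance.shape[0], 0, image.luminance.shape[1])
    r0, r1, c0, c1 = roi
    sub = image.luminance[r0:r1, c0:c1]
    fg = image.foreground_mask[r0:r1, c0:c1]
    if not np.any(fg):
        raise ValueError("roi contains no foreground pixels")
    masked = np.where(fg, sub, 0.0)
    if sub.shape[0] <= sub.shape[1]:  # short axis = rows
        profile = masked.max(axis=0)
        keep = fg.any(axis=0)
    else:
        profile = masked.max(axis=1)
        keep = fg.any(axis=1)
    return detect_split(profile[keep], criterion)
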