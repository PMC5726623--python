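import numpy as np
import pytest

from glosscue.cli_io import DEFAULT_RADIUS
from glosscue.mesh_gen import make_blob, make_sphere
from glosscue.renderer import (
    Material,
    PointLight,
    Scene,
    build_scene,
    default_camera,
    render,
)


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_sphere(DEFAULT_RADIUS, resolution=48)


@pytest.fixture(scope="session")
def blob_mesh():
    # reduced resolution for test speed; statistics-level behaviour only
    return make_blob("blob1", resolution=4, seed=1)


@pytest.fixture(scope="session")
def camera96():
    return default_camera(image_size=(96, 96), fov=6.0)


@pytest.fixture(scope="session")
def camera64():
    return default_camera(image_size=(64, 64), fov=6.0)


@pytest.fixture(scope="session")
def glossy_sphere_image(sphere_mesh, camera96):
    """Single-light glossy sphere, smoothness 0.6, clip off."""
    scene = Scene(
        mesh=sphere_mesh,
        material=Material(smoothness=0.6),
        lights=[PointLight((0.0, 0.0, -5.0), intensity=1.5)],
        ambient_intensity=0.6,
    )
    return render(scene, camera96, clip=False)


@pytest.fixture(scope="session")
def ambient_only_image(sphere_mesh, camera64):
    scene = Scene(
        mesh=sphere_mesh,
        material=Material(smoothness=0.4),
        lights=[],
        ambient_intensity=0.6,
    )
    return render(scene, camera64, clip=False)


def specular_sphere_image(sphere_mesh, camera, smoothness, alpha, intensity=1.5):
    """Specular-dominated render used by layer-geometry tests."""
    scene = build_scene(
        sphere_mesh, smoothness, alpha, intensity, albedo=0.0, ambient_intensity=0.6
    )
    return render(scene, camera, clip=False)


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Brute-force 8-connected labelling oracle (BFS flood fill)."""
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    current = 0
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or labels[r, c]:
                continue
            current += 1
            stack = [(r, c)]
            labels[r, c] = current
            while stack:
                rr, cc = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < rows
                            and 0 <= nc < cols
                            and mask[nr, nc]
                            and not labels[nr, nc]
                        ):
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels, current
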