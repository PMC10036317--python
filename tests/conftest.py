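import numpy as np
import pytest

from anthrobench.mesh import AnthropometricMesh

# Unit box triangulation (12 faces, outward orientation).
_BOX_VERTS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
_BOX_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (-z)
        [4, 5, 6], [4, 6, 7],  # top (+z)
        [0, 1, 5], [0, 5, 4],  # -y
        [1, 2, 6], [1, 6, 5],  # +x
        [2, 3, 7], [2, 7, 6],  # +y
        [3, 0, 4], [3, 4, 7],  # -x
    ]
)


def box_mesh(size=1.0, offset=(0.0, 0.0, 0.0)):
    """Watertight axis-aligned box: vertices, faces."""
    size = np.broadcast_to(np.asarray(size, dtype=float), 3)
    return _BOX_VERTS * size + np.asarray(offset, dtype=float), _BOX_FACES.copy()


def mesh_with_landmarks(landmark_points, units="raw", size=1.0, offset=(0.0, 0.0, 0.0)):
    """Box mesh with extra isolated vertices serving as named landmarks.

    Landmark vertices are appended after the box vertices, so the carrier
    surface (and hence volume/watertightness) is unaffected.
    """
    verts, faces = box_mesh(size=size, offset=offset)
    landmarks = {}
    extra = []
    for role, point in landmark_points.items():
        landmarks[role] = len(verts) + len(extra)
        extra.append(np.asarray(point, dtype=float))
    if extra:
        verts = np.vstack([verts, extra])
    return AnthropometricMesh(verts, faces, landmarks, units=units)


def full_landmark_box(height=170.0, units="cm"):
    """Box with all eight landmark roles for exercising the whole chain."""
    points = {
        "left_eye_inner": (1.0, 10.0, height - 10.0),
        "left_eye_outer": (5.0, 10.0, height - 10.0),
        "right_eye_inner": (-1.0, 10.0, height - 10.0),
        "right_eye_outer": (-5.0, 10.0, height - 10.0),
        "head_apex": (0.0, 0.0, height),
        "foot_a": (0.0, 0.0, 0.0),
        "foot_b": (1.0, 0.0, 0.0),
        "foot_c": (0.0, 1.0, 0.0),
    }
    return mesh_with_landmarks(points, units=units)


@pytest.fixture(scope="session")
def male_mesh():
    """Jitter-free male template at the male cohort means (58 ms to build)."""
    from anthrobench.synthetic import generate_body_mesh

    return generate_body_mesh(176.1, 78.4, "male", resolution=48, seed=0)


@pytest.fixture(scope="session")
def female_mesh():
    from anthrobench.synthetic import generate_body_mesh

    return generate_body_mesh(161.1, 60.9, "female", resolution=48, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    from anthrobench.synthetic import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_female=4, n_male=3), seed=7)
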