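"""Shared fixtures: small reference meshes, a default-calibration bank,
and the full leave-one-out simulation (computed once per session)."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meniscus3d.mesh_model import Laterality, MeniscusMesh, Side
from meniscus3d.synthetic import PopulationParams, generate_bank, generate_base_mesh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_box_mesh(
    lx: float,
    ly: float,
    lz: float,
    patient_id: str = "box",
    side: Side = Side.MEDIAL,
    roots_on_x: bool = True,
) -> MeniscusMesh:
    """Axis-aligned rectangular box mesh with roots on the two x-extreme
    (or y-extreme) face centers."""
    import trimesh

    tm = trimesh.creation.box(extents=[lx, ly, lz])
    if roots_on_x:
        ra = np.array([-lx / 2, 0.0, 0.0])
        rp = np.array([lx / 2, 0.0, 0.0])
    else:
        ra = np.array([0.0, -ly / 2, 0.0])
        rp = np.array([0.0, ly / 2, 0.0])
    return MeniscusMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        patient_id=patient_id,
        side=side,
        laterality=Laterality.RIGHT,
        root_anterior=ra,
        root_posterior=rp,
    )


def make_tetrahedron(patient_id: str = "tet") -> MeniscusMesh:
    """Smallest closed mesh; landmarks on two vertices."""
    v = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [5.0, 8.0, 0.0], [5.0, 3.0, 7.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return MeniscusMesh(
        vertices=v,
        faces=f,
        patient_id=patient_id,
        side=Side.MEDIAL,
        laterality=Laterality.RIGHT,
        root_anterior=v[0],
        root_posterior=v[1],
    )


def make_sphere_mesh(radius: float, patient_id: str) -> MeniscusMesh:
    """Icosphere with roots on two well-separated surface vertices."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    v = np.asarray(tm.vertices, dtype=float)
    return MeniscusMesh(
        vertices=v,
        faces=np.asarray(tm.faces, dtype=np.int64),
        patient_id=patient_id,
        side=Side.MEDIAL,
        laterality=Laterality.RIGHT,
        root_anterior=v[np.argmin(v[:, 0])],
        root_posterior=v[np.argmax(v[:, 0])],
    )


def small_meniscus(seed: int, patient_id: str | None = None,
                   amplitude: float = 1.2, dims=(30.0, 45.0, 9.0),
                   side: Side = Side.MEDIAL) -> MeniscusMesh:
    """Coarse synthetic meniscus for oracle-scale tests (~200 faces)."""
    return generate_base_mesh(
        *dims, side, shape_seed=seed, perturb_amplitude=amplitude,
        n_arc=12, n_section=8, patient_id=patient_id or f"S{seed}",
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=rng)


@pytest.fixture(scope="session")
def default_bank():
    """The study-scale bank: 50 bilateral + 40 unilateral virtual
    patients at default population parameters, seed 1 (140 menisci per
    side, 100 of them the validation group)."""
    params = PopulationParams(seed=1)
    bank, patients = generate_bank(params, n_bilateral=50, n_unilateral=40)
    return bank, patients


@pytest.fixture(scope="session")
def full_validation(default_bank):
    """Full leave-one-out simulation on the default bank at 1 point/mm^2
    sampling (the dominant cost of the suite; computed once)."""
    from meniscus3d.surface_distance import SurfaceDistanceEngine
    from meniscus3d.validation import ValidationConfig, run_validation, diversity_stats

    bank, _ = default_bank
    engine = SurfaceDistanceEngine(density=1.0, tol=1e-4, icp_max_points=400)
    config = ValidationConfig(seed=1, n_bilateral=50, n_unilateral=40, density=1.0)
    comparisons, summary = run_validation(bank, config, engine=engine)
    diversity = diversity_stats(bank, engine=engine)
    return comparisons, summary, diversity
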