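"""Shared fixtures: small analytic meshes and session-scoped cohorts."""

import numpy as np
import pytest

from lastrain import LabeledSurfaceMesh, generate_anatomy
from lastrain.synthetic import CohortSpec, generate_cohort


def make_strip(nx=21, ny=6, lx=2.0, ly=0.5):
    """Flat rectangular strip in the z=0 plane, regular triangulation."""
    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(0.0, ly, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    labels = np.full(len(verts), "body", dtype="U12")
    mesh = LabeledSurfaceMesh(verts, np.asarray(faces), labels)
    left = np.where(verts[:, 0] == 0.0)[0]
    right = np.where(verts[:, 0] == lx)[0]
    return mesh, left, right


@pytest.fixture
def strip():
    return make_strip()


@pytest.fixture(scope="session")
def la_mesh():
    """One labeled LA anatomy at 80 mL body volume."""
    mesh = generate_anatomy(subject_seed=1, target_volume_ml=80.0)
    mesh.validate()
    return mesh


@pytest.fixture(scope="session")
def la_uac(la_mesh):
    from lastrain import build_uac

    return build_uac(la_mesh)


@pytest.fixture(scope="session")
def la_regions(la_mesh, la_uac):
    from lastrain import assign_regions

    return assign_regions(la_mesh, la_uac)


@pytest.fixture(scope="session")
def af47():
    """47-subject AF cohort: (subjects, truth table)."""
    spec = CohortSpec.preset("AF", 47, seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def af47_features(af47):
    from lastrain.features import SubjectRecord, build_feature_table

    subjects, _ = af47
    records = [
        SubjectRecord(
            s.subject_id, s.truth["regional_curves"], s.motion.frame_times,
            s.truth["global_curve"], s.truth["lav_max_ml"], s.truth["laef_pct"],
            s.truth["severe"], s.truth["enhancement_pct"],
        )
        for s in subjects
    ]
    return build_feature_table(records)


@pytest.fixture(scope="session")
def healthy_cohort():
    """Healthy reference cohort at the study's sample size."""
    spec = CohortSpec.preset("healthy", 41, seed=2)
    return generate_cohort(spec)
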