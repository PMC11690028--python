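import numpy as np
import pytest

from musclesect import Ellipsoid, PhantomSpec, make_phantom_exam


@pytest.fixture(scope="session")
def coarse_exam():
    """A small two-ellipsoid exam (5 mm voxels) for I/O and plumbing tests."""
    spec = PhantomSpec(
        muscles={
            1: Ellipsoid(center=(-5.0, -25.0, 4.0), semi_axes=(55.0, 20.0, 24.0)),
            2: Ellipsoid(center=(-5.0, 25.0, 4.0), semi_axes=(52.0, 19.0, 23.0)),
        },
        spacing=(5.0, 5.0, 5.0),
        y_plane_x=-30.0,
        seed=42,
    )
    return make_phantom_exam(spec)


@pytest.fixture()
def saved_exam(coarse_exam, tmp_path):
    from musclesect import save_exam

    paths = (tmp_path / "ct.nii.gz", tmp_path / "labels.nii.gz",
             tmp_path / "landmarks.json")
    save_exam(coarse_exam.volume, coarse_exam.labels, coarse_exam.landmarks,
              *paths)
    return paths
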