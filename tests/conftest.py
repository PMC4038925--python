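import numpy as np
import pytest

from multipeak import PeakField, ScalarField


def build_uniform_field(
    direction=(1.0, 0.0, 0.0),
    dims=(20, 7, 7),
    voxel_size=1.0,
    n_slots=1,
    magnitude=1.0,
):
    """Peak field with the same single peak in every voxel, plus an f=1 map."""
    data = np.zeros(dims + (3 * n_slots,))
    data[..., :3] = np.asarray(direction, float) * magnitude
    affine = np.diag([voxel_size] * 3 + [1.0])
    field = PeakField(data=data, affine=affine)
    fmap = ScalarField(data=np.ones(dims), affine=affine)
    return field, fmap


@pytest.fixture
def uniform_x_field():
    return build_uniform_field()


@pytest.fixture
def straight_phantom():
    from multipeak import preset_phantom

    return preset_phantom("straight")


@pytest.fixture
def crossing_phantom():
    from multipeak import preset_phantom

    return preset_phantom("crossing90")


@pytest.fixture(scope="session")
def fibercup():
    from multipeak import preset_phantom

    return preset_phantom("fibercup7")
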