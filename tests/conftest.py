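import numpy as np
import pytest

from amynet.metrics import NetworkVoxelSet
from amynet.synthetic import SubjectRecord, generate_cohort, single_network_design
from amynet.volumes import VolumeMap


def make_subject(z_values, pib_values, gm_value=0.7, subject_id="s1",
                 group="control", voxel_size=(2.0, 2.0, 2.0), suvr=1.0):
    """Hand-built single-network subject for unit tests."""
    z = VolumeMap(np.asarray(z_values, float), voxel_size)
    pib = VolumeMap(np.asarray(pib_values, float), voxel_size)
    gm = VolumeMap(np.full(z.shape, gm_value), voxel_size)
    return SubjectRecord(subject_id=subject_id, group=group,
                         connectivity_maps={"net": z}, pib_map=pib, gm_map=gm,
                         age=65.0, gender="F", neocortical_suvr=suvr)


def make_voxel_set(mask, x, y, voxel_size=(2.0, 2.0, 2.0),
                   subject_id="s1", network="net"):
    """NetworkVoxelSet from a boolean mask plus per-voxel value vectors."""
    idx = np.argwhere(mask)
    return NetworkVoxelSet(subject_id=subject_id, network_name=network,
                           voxel_indices=idx, ifc_values=np.asarray(x, float),
                           pib_values=np.asarray(y, float),
                           grid_dims=mask.shape, voxel_size_mm=voxel_size)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Small single-network cohort with both couplings injected."""
    design = single_network_design(8, 6, b_global_patient=0.6,
                                   c_local_patient=0.05, pib_elevated=True,
                                   seed=7)
    return design, generate_cohort(design)


@pytest.fixture(scope="session")
def null_cohort():
    """Small single-network cohort with no couplings and no group effects."""
    design = single_network_design(10, 10, seed=11)
    return design, generate_cohort(design)
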