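import numpy as np
import pytest

from isfcpipe import synthgen as sg


@pytest.fixture
def small_config():
    """A small but non-degenerate cohort configuration."""
    return sg.CohortConfig(n_subjects=8, n_networks=3, n_voxels=12,
                           n_frames=120, intrinsic_loading=0.0, seed=42)


def make_series(config, model, cohort=None):
    """Generate all subjects' time series for a config + coupling model."""
    if cohort is None:
        cohort = sg.generate_cohort(config)
    stimulus = sg.generate_stimulus(config)
    series = {
        row.subject_id: sg.generate_subject_data(
            int(i), float(row.age), stimulus, model, config, row.subject_id)
        for i, row in cohort.iterrows()
    }
    return cohort, series


@pytest.fixture
def small_dataset(small_config):
    model = sg.constant_coupling_model(small_config.n_networks,
                                       small_config.n_voxels, 0.3, 0.3)
    cohort, series = make_series(small_config, model)
    return small_config, model, cohort, series


def coupled_edges(model):
    """Boolean (K, V) matrix marking each voxel's own-network edge."""
    k = model.n_networks
    return model.voxel_assignment[None, :] == np.arange(k)[:, None]
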