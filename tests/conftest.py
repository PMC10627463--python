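import numpy as np
import pytest

from habnet import synthetic as syn
from habnet.network import DispersalParams, interpatch_costs, build_network
from habnet.occurrence import sampling_intensity, assign_occurrence_state
from habnet.patches import Patch, PatchSet, binarize, delineate_patches


def make_patchset(entries, cell_size=1.0):
    """Build a PatchSet from (patch_id, area, hsi) triples.

    Each patch occupies one synthetic grid cell; geometry-free tests
    (network assembly, metrics, occupancy simulation) only need ids and
    attributes.
    """
    labels = np.zeros((len(entries), 1), dtype=int)
    patches = []
    for k, (pid, area, hsi) in enumerate(entries):
        labels[k, 0] = pid
        patches.append(
            Patch(
                patch_id=pid,
                rows=np.array([k]),
                cols=np.array([0]),
                area=float(area),
                hsi=float(hsi),
            )
        )
    return PatchSet(patches=patches, labels=labels, cell_size=cell_size)


def build_study(landscape_seed=1, occupancy_seed=1, sampling_seed=1,
                beta_connectivity=2.0, **landscape_kwargs):
    """Full synthetic study: patches, cost table, truth network, occupancy,
    observation records."""
    land = syn.LandscapeConfig(seed=landscape_seed, **landscape_kwargs)
    suit = syn.generate_suitability(land)
    mask = syn.generate_mask(land)
    patches = delineate_patches(binarize(suit, 0.6), mask, suit)
    costs = interpatch_costs(patches, cost_cap=10000.0)
    truth_cfg = syn.OccupancyTruthConfig(
        seed=occupancy_seed, beta_connectivity=beta_connectivity
    )
    truth_net = build_network(
        patches, costs, DispersalParams(d0=truth_cfg.true_d0), max_dispersal_distance=4000.0
    )
    occupancy = syn.generate_true_occupancy(patches, truth_net, truth_cfg)
    obs = syn.generate_observations(
        patches, occupancy, syn.SamplingConfig(seed=sampling_seed)
    )
    return {
        "landscape": land,
        "suitability": suit,
        "mask": mask,
        "patches": patches,
        "costs": costs,
        "truth_net": truth_net,
        "occupancy": occupancy,
        "observations": obs,
    }


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic study (~400 patches) shared across tests."""
    return build_study()


@pytest.fixture(scope="session")
def labelled_data(default_study):
    """Occurrence-state labels for the default study (threshold 2 visits)."""
    counts = sampling_intensity(
        default_study["observations"], default_study["patches"], "focal"
    )
    table = assign_occurrence_state(counts, 2)
    return table["state"].dropna()
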