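"""Shared fixtures: desk-scale phantoms and (session-scoped) trained models.

Training fixtures are session-scoped so that the recovery experiments, the
workflow tests and the acceptance tests share one training run each.
"""

import numpy as np
import pytest

from cinestrain.grids import VolumeGrid
from cinestrain.phantom import PhantomParams, render_sequence


@pytest.fixture(scope="session")
def desk_phantom():
    """One reduced-scale phantom (64x64x8, 5 frames) with ground truth."""
    params = PhantomParams.desk(seed=7, n_frames=5)
    seq, truth = render_sequence(params)
    return params, seq, truth


@pytest.fixture(scope="session")
def phantom_128():
    """Full-radius phantom on a 128x128x16 grid (strain-oracle substrate)."""
    params = PhantomParams(
        seed=3, n_frames=5,
        grid=VolumeGrid((128, 128, 16), (1.25, 1.25, 7.0)))
    seq, truth = render_sequence(params)
    return params, seq, truth


@pytest.fixture(scope="session")
def motion_corpus():
    """Training corpus: 10 phantoms -> 20 pairs (5 frames each: training
    uses only the ED and ES frames)."""
    return [render_sequence(PhantomParams.desk(seed=100 + i, n_frames=5))
            for i in range(10)]


@pytest.fixture(scope="session")
def held_out_phantoms():
    """Phantoms never seen in training, for recovery evaluation."""
    return [render_sequence(PhantomParams.desk(seed=990 + i, n_frames=5))
            for i in range(5)]


@pytest.fixture(scope="session")
def trained_motion(motion_corpus):
    """Motion network trained at desk scale with the default loss weights.

    Returns (final net, loss history, epoch-100 snapshot) — the snapshot
    supports a matched-epoch comparison against the ablated training run.
    """
    from cinestrain.nn.backbone import NetworkConfig, make_network
    from cinestrain.training import TrainConfig, motion_dataset, train_network

    data = motion_dataset(motion_corpus)
    cfg = TrainConfig(seed=0, epochs=200, batch_size=5, learning_rate=3e-3)
    ncfg = NetworkConfig(base_filters=4, depth=3)
    dr = motion_corpus[0][0].grid.spacing
    snapshot = {}

    def snap(epoch, net):
        if epoch == 99:
            snapshot["arrays"] = [a.copy() for a in net.state_arrays()]

    net, history = train_network("motion", data, cfg, net_config=ncfg, dr=dr,
                                 on_epoch_end=snap)
    net100 = make_network("motion", ncfg)
    net100.load_state_arrays(snapshot["arrays"])
    net100.eval()
    return net, history, net100


@pytest.fixture(scope="session")
def trained_segment(motion_corpus):
    """Segmentation network trained 50 epochs on phantom slices."""
    from cinestrain.nn.backbone import NetworkConfig
    from cinestrain.training import TrainConfig, segment_dataset, train_network

    data = segment_dataset(motion_corpus)
    cfg = TrainConfig(seed=0, epochs=50, batch_size=80, learning_rate=3e-3)
    ncfg = NetworkConfig(base_filters=4, depth=3)
    net, history = train_network("segment", data, cfg, net_config=ncfg)
    return net, history


@pytest.fixture(scope="session")
def trained_center(motion_corpus):
    """Centering network trained on whole desk-scale volumes."""
    from cinestrain.nn.backbone import NetworkConfig
    from cinestrain.training import TrainConfig, train_network, center_dataset

    data = center_dataset(motion_corpus[:5], sigma_mm=10.0)
    cfg = TrainConfig(seed=0, epochs=300, batch_size=80, learning_rate=1e-2)
    ncfg = NetworkConfig(base_filters=4, depth=2)
    net, history = train_network("center", data, cfg, net_config=ncfg)
    return net, history
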