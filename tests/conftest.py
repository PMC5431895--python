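import numpy as np
import pytest

import memstate as ms
from memstate.featurize import FeatureMatrix
from memstate.systems import Topology, Trajectory


def make_topology(entries):
    """Build a Topology from (name, resname, resnum, role) tuples."""
    names = [e[0] for e in entries]
    resnames = [e[1] for e in entries]
    resnums = np.array([e[2] for e in entries])
    roles = np.array([e[3] for e in entries], dtype=object)
    return Topology(names, resnames, resnums, roles)


@pytest.fixture(scope="session")
def two_well_cvs():
    """A modest two-well Langevin dataset shared across tests."""
    cfg = ms.two_well_config(seed=42, n_trajectories=60, frames_per_trajectory=300)
    return cfg, ms.sample_langevin(cfg)


@pytest.fixture(scope="session")
def two_well_states(two_well_cvs):
    """tICA -> k-means -> state sequences for the shared dataset."""
    cfg, cvs = two_well_cvs
    feats = [FeatureMatrix(t, ["d", "theta"], cvs.frame_interval)
             for t in cvs.trajectories]
    model = ms.fit_tica(feats, lag_time=2.0, gamma=1e-4, n_components=2)
    tics = [ms.transform(model, f) for f in feats]
    km = ms.fit_minibatch_kmeans(tics, k=60, seed=7)
    states = ms.assign(km, tics)
    return cfg, cvs, states


@pytest.fixture(scope="session")
def embedded_system():
    """A small embedded atomistic system (10 frames)."""
    rng = np.random.default_rng(11)
    pts = np.column_stack([rng.uniform(0.8, 2.2, 10), rng.uniform(-50, 50, 10)])
    cvs = ms.CVTrajectorySet([pts], frame_interval=0.25)
    cfg = ms.EmbedConfig(seed=3, water_bulk_density=2.0, n_lipids_per_leaflet=36)
    topo, trajs = ms.embed_frames(cvs, cfg)
    return cfg, pts, topo, trajs[0]
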