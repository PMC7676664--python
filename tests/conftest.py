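import numpy as np
import pytest

from nmburst import (
    ModelParams,
    SimConfig,
    background_state,
    detect_spikes,
    integrate,
    lfp,
    segment_bursts,
    z_diagram,
)
from nmburst.continuation import continue_branch, detect_bifurcations


@pytest.fixture(scope="session")
def table_params():
    """Background-activity parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def b_branch():
    """Equilibrium branch in the SOM+ gain B over [0, 45] at G = 35."""
    return continue_branch("B", (0.0, 45.0))


@pytest.fixture(scope="session")
def b_bifurcations(b_branch):
    return detect_bifurcations(b_branch)


@pytest.fixture(scope="session")
def zcurve():
    """Fast-subsystem equilibrium diagram versus v2, Table parameters."""
    return z_diagram()


@pytest.fixture(scope="session")
def burst_run():
    """Deterministic bursting run of the full model at B = 10, G = 35."""
    params = ModelParams(B=10.0, G=35.0)
    cfg = SimConfig(dt=1e-4, duration=20.0, transient=5.0)
    traj = integrate("full", background_state(params), cfg, params)
    x = lfp(traj)
    post = traj.after(cfg.transient)
    xp = x[len(x) - len(post.times):]
    spikes = detect_spikes(xp, cfg.dt, t0=cfg.transient)
    bursts = segment_bursts(spikes)
    return {"params": params, "config": cfg, "trajectory": traj,
            "lfp": x, "spikes": spikes, "bursts": bursts}
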