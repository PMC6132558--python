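"""Shared fixtures: small phantoms and acquisitions reused across modules."""

import numpy as np
import pytest

import mocorr as mc


@pytest.fixture(scope="session")
def tiny_phantom():
    """32-voxel thorax phantom with defect and stenosis."""
    return mc.build_phantom(mc.PhantomConfig(
        matrix=32, defect=mc.DefectSpec(), stenosis=mc.StenosisSpec()))


@pytest.fixture(scope="session")
def small_phantom():
    """64-voxel phantom at the default desk-scale geometry."""
    return mc.build_phantom(mc.PhantomConfig(
        matrix=64, defect=mc.DefectSpec(), stenosis=mc.StenosisSpec()))


@pytest.fixture(scope="session")
def tiny_static_acq(tiny_phantom):
    """Static, noiseless, single-coil fully sampled acquisition at 32^3."""
    ph = tiny_phantom
    traj = mc.make_trajectory((32, 32), 32)
    trace = mc.simulate_breathing(traj.n_interleaves, amplitude=0.0,
                                  deep_breath_prob=0.0, seed=0)
    coils = mc.simulate_coils(ph.shape, 1)
    ksp, inavs = mc.acquire_cmra(ph, mc.MotionModel(trace), trace, traj,
                                 coils, noise_sd=0.0, seed=0)
    return dict(phantom=ph, traj=traj, trace=trace, coils=coils,
                kspace=ksp, inavs=inavs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def static_motion_table(n):
    return mc.MotionTable(fh_mm=np.zeros(n), rl_mm=np.zeros(n),
                          score=np.ones(n), reference_beat=0)
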