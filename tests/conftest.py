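import numpy as np
import pytest

from granuletrack import SimulationConfig, simulate
from granuletrack.detect import Spot


def truth_to_spots(syn, min_fluo=0.0):
    """Convert ground-truth granule records into per-frame spot lists
    (noiseless 'perfect detector'), remembering the truth id of each
    spot for association scoring."""
    n_frames = syn.stack.shape[0]
    spots = [[] for _ in range(n_frames)]
    origin = {}
    for g in syn.truth:
        for k in range(g.birth_frame, g.death_frame + 1):
            i = k - g.birth_frame
            if g.fluorescence[i] < min_fluo:
                continue
            s = Spot(frame=k, x=float(g.positions[i, 0]),
                     y=float(g.positions[i, 1]), quality=10.0,
                     fluorescence=float(g.fluorescence[i]), radius=0.5)
            origin[(k, round(s.x, 9), round(s.y, 9))] = g.granule_id
            spots[k].append(s)
    return spots, origin


@pytest.fixture(scope="session")
def small_movie():
    """A small seeded life-cycle simulation used by several suites."""
    cfg = SimulationConfig(cell_radius=15.0, nucleation_rate=3.0,
                           mean_lifetime=12.0, lifetime_sd=2.0,
                           n_frames=60, rng_seed=1)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sparse_movie():
    """Well-separated granules (low density, no fusion, no diffusion)."""
    cfg = SimulationConfig(cell_radius=15.0, nucleation_rate=0.6,
                           mean_lifetime=10.0, lifetime_sd=1.5,
                           diffusion_coeff=0.0, fusion_radius=0.05,
                           photon_scale=5.0, n_frames=50, rng_seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def recovery_movie():
    """Low-density simulation for exact tracker-recovery checks.

    The density is low enough that granules are well separated except
    when fusing; tests verify this separation precondition explicitly
    before asserting exact recovery.
    """
    cfg = SimulationConfig(cell_radius=18.0, zone_width=12.0,
                           nucleation_rate=1.2, mean_lifetime=12.0,
                           lifetime_sd=2.0, diffusion_coeff=0.003,
                           n_frames=60, rng_seed=5)
    return simulate(cfg)


def deaths_are_isolated(syn, gate_um=1.0):
    """True iff no non-merge death position lies within ``gate_um`` of
    any other granule's next-frame position (the precondition for the
    tracker to introduce no spurious merge or gap edges at deaths)."""
    for g in syn.truth:
        if g.merged_into is not None:
            continue
        f_end = g.death_frame
        p_end = g.positions[-1]
        for other in syn.truth:
            if other.granule_id == g.granule_id:
                continue
            if other.birth_frame <= f_end + 1 <= other.death_frame:
                q = other.positions[f_end + 1 - other.birth_frame]
                if np.linalg.norm(p_end - q) <= gate_um:
                    return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
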