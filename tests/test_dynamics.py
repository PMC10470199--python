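"""Integrator contracts: NVE limit, thermostat, determinism, neighbor lists."""

import numpy as np
import pytest

import polyfold as pf
from polyfold import _kernels, forcefield as ff
from polyfold.dynamics import DynamicsParams, kinetic_energy, run, tau_from_diffusion
from polyfold.prep import compress, push_off, random_placement, target_box_side


def _prepared(topo, ffp, dp, seed=5):
    state = random_placement(topo, 4 * target_box_side(topo.n_beads),
                             np.random.default_rng(seed))
    state.seed_seq = np.random.SeedSequence(seed)
    push_off(state, topo, ffp, dp)
    compress(state, topo, ffp, dp, target_box_side(topo.n_beads))
    return state


def test_tau_from_diffusion_reference_and_scaling():
    assert tau_from_diffusion(10.0, 5.0) == pytest.approx(20.0)     # 10 nm bead
    assert tau_from_diffusion(20.0, 5.0) == pytest.approx(80.0)     # quadratic in sigma
    # one MD step at defaults = 0.012 tau = 0.24 us
    dp = DynamicsParams()
    assert dp.dt * dp.tau_physical_us == pytest.approx(0.24)
    assert dp.steps_for_seconds(100.0) == pytest.approx(4.1667e8, rel=1e-4)


def test_tau_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        tau_from_diffusion(-1.0, 5.0)


def test_nve_limit_conserves_energy(chain60, ffp, dp):
    """With friction and noise off the integrator is plain velocity Verlet."""
    state = _prepared(chain60, ffp, dp)
    # thermalize, then switch the thermostat off
    run(state, chain60, ffp, dp, 2000, 2001)
    dpn = dp.with_(dt=0.005)
    e0 = ff.total_energy(state, chain60, ffp) + kinetic_energy(state.velocities)
    run(state, chain60, ffp, dpn, 10_000, 10_001, noise_on=False, gamma=0.0)
    e1 = ff.total_energy(state, chain60, ffp) + kinetic_energy(state.velocities)
    assert abs(e1 - e0) / abs(e0) < 1e-3


def test_equipartition(equilibrated):
    """Thermostatted run: mean kinetic energy per bead -> (3/2) kBT within 5%."""
    traj = equilibrated["traj"]
    n = traj.positions.shape[1]
    ke = 0.5 * np.sum(traj.velocities ** 2, axis=(1, 2)) / n
    mean_ke = ke[ke.size // 4:].mean()
    assert mean_ke == pytest.approx(1.5, rel=0.05)


def test_velocity_components_are_maxwellian(equilibrated):
    """Component variance = kBT/m in every direction (fluctuation-dissipation)."""
    v = equilibrated["traj"].velocities[-100:]
    var = v.reshape(-1, 3).var(axis=0)
    assert np.allclose(var, 1.0, rtol=0.06)


def test_identical_seeds_give_bitwise_identical_trajectories(chain60, ffp, dp):
    state = _prepared(chain60, ffp, dp, seed=9)
    a = state.copy()
    b = state.copy()
    ta = run(a, chain60, ffp, dp, 500, 100)
    tb = run(b, chain60, ffp, dp, 500, 100)
    assert np.array_equal(ta.positions, tb.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_different_seeds_diverge(chain60, ffp, dp):
    state = _prepared(chain60, ffp, dp, seed=9)
    a, b = state.copy(), state.copy()
    run(a, chain60, ffp, dp, 500, 501, seed=1)
    run(b, chain60, ffp, dp, 500, 501, seed=2)
    assert not np.array_equal(a.positions, b.positions)


def test_sampling_stride_contract(chain60, ffp, dp):
    state = _prepared(chain60, ffp, dp, seed=4)
    assert run(state, chain60, ffp, dp, 5, 100).n_frames == 0   # stride > n_steps
    t = run(state, chain60, ffp, dp, 10, 1)
    assert t.n_frames == 10
    assert t.step_index[-1] == state.step_count
    with pytest.raises(ValueError):
        run(state, chain60, ffp, dp, 0, 1)


def test_neighbor_list_forces_match_brute_force(chain60, ffp, dp):
    """Verlet-list and all-pairs paths produce identical forces."""
    state = _prepared(chain60, ffp, dp, seed=13)
    run(state, chain60, ffp, dp, 3000, 3001)    # roughen the configuration
    pos, box = state.positions, state.box_side
    topo = pf.assign_prc1(chain60, 1.0, np.random.default_rng(0))
    f_brute = ff.total_forces(state, topo, ffp)
    cutoff = max(2 ** (1 / 6), ffp.bind_cutoff) + 0.3
    pi, pj = _kernels.build_pairs(pos, box, cutoff)
    f_nlist = np.zeros_like(f_brute)
    err = np.zeros(2, np.int64)
    _kernels.conservative_forces(
        pos, box, pi, pj, topo.bonds, topo.angles,
        topo.bound_pre_mask, topo.methyl_mask,
        ffp.sigma, ffp.fene_k, ffp.fene_r0, ffp.bend_k, ffp.ev_eps,
        ffp.bind_eps, ffp.bind_cutoff, False, 0.0, ffp.soft_cutoff,
        f_nlist, err,
    )
    assert np.abs(f_brute - f_nlist).max() < 1e-10


def test_minimum_image_round_trip():
    """Wrapping coordinates into the box never changes minimum-image distances."""
    rng = np.random.default_rng(0)
    box = 13.0
    pos = rng.uniform(-40, 40, size=(30, 3))
    wrapped = pos - box * np.floor(pos / box)
    for _ in range(50):
        i, j = rng.integers(30, size=2)
        d1 = pos[i] - pos[j]
        d1 -= box * np.round(d1 / box)
        d2 = wrapped[i] - wrapped[j]
        d2 -= box * np.round(d2 / box)
        assert np.allclose(np.linalg.norm(d1), np.linalg.norm(d2), atol=1e-9)
        assert np.linalg.norm(d1) <= box * np.sqrt(3) / 2 + 1e-9
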