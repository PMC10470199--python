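"""System preparation: placement, soft push-off, compression, equilibration.

The pipeline mirrors standard practice for dense bead-spring systems:

1. ``random_placement`` -- grow the chain as a random walk with ~0.97 sigma
   steps inside a box several times larger than the target (self-crossings
   allowed at this stage).
2. ``push_off`` -- replace the excluded volume by the bounded soft potential
   and ramp its amplitude A from 0 to 40 kBT over a short run, then relax at
   zero temperature until no *non-bonded* pair sits closer than sigma
   (bonded pairs equilibrate near 0.97 sigma by construction).
3. ``compress`` -- geometric affine rescale of box and coordinates over a
   short run down to the target density (24 sigma box for the 360-mer,
   volume fraction N/24^3 = 0.026, close to the nuclear filling 0.021).
4. ``equilibrate`` -- thermostatted run with the attraction switched off
   until the locus Rg is stationary and the center of mass diffuses.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .dynamics import DynamicsParams, SystemState, Trajectory, run
from .forcefield import ForceFieldParams
from .topology import PolymerTopology

BOND_INIT = 0.97  # initial bond length, sigma


def target_box_side(n_beads: int, volume_fraction: float = 0.026) -> float:
    """Box side giving the nucleus-calibrated counting fraction n/L^3."""
    return (n_beads / volume_fraction) ** (1.0 / 3.0)


def random_placement(topo: PolymerTopology, box_large: float, rng) -> SystemState:
    """Random-walk chain with BOND_INIT steps, centered in a large box."""
    rng_ = np.random.default_rng(rng)
    n = topo.n_beads
    steps = rng_.normal(size=(n - 1, 3))
    steps *= BOND_INIT / np.linalg.norm(steps, axis=1)[:, None]
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    pos -= pos.mean(axis=0)          # center; box is periodic so no clipping needed
    return SystemState(pos, np.zeros((n, 3)), float(box_large),
                       seed_seq=np.random.SeedSequence(int(rng_.integers(2 ** 31))))


def push_off(state: SystemState, topo: PolymerTopology, ffp: ForceFieldParams,
             dp: DynamicsParams, ramp_steps: int = 1000,
             min_separation: float | None = None) -> SystemState:
    """Resolve overlaps: soft-potential ramp then zero-temperature descent.

    Raises if non-bonded pairs remain closer than ``min_separation``
    (default sigma) after the ramp + descent, suggesting a longer ramp.
    """
    if min_separation is None:
        min_separation = ffp.sigma
    run(state, topo, ffp, dp, ramp_steps, ramp_steps + 1,
        soft_on=True, soft_amp0=0.0, soft_amp1=ffp.soft_amp, neighbor_list=False)
    # zero-temperature damped descent on the real force field pushes residual
    # near-contacts out to the WCA minimum (> sigma)
    pi, pj = _kernels.all_pairs(topo.n_beads)
    err = np.zeros(2, dtype=np.int64)
    for _ in range(40):
        if _kernels.min_nonbonded_distance(state.positions, state.box_side, topo.bonds) >= min_separation:
            break
        _kernels.descend(
            state.positions, state.box_side, pi, pj, topo.bonds, topo.angles,
            topo.bound_pre_mask, topo.methyl_mask,
            ffp.sigma, ffp.fene_k, ffp.fene_r0, ffp.bend_k, ffp.ev_eps,
            0.0, ffp.bind_cutoff, False, 0.0, ffp.soft_cutoff,
            1e-3, 200, err,
        )
        if err[0] != _kernels.ERR_OK:
            raise RuntimeError("descent failed during push-off")
    final = _kernels.min_nonbonded_distance(state.positions, state.box_side, topo.bonds)
    if final < min_separation * (1 - 1e-6):
        raise RuntimeError(
            f"residual overlap after push-off (min non-bonded distance {final:.3f} sigma);"
            " try a longer ramp"
        )
    state.velocities[:] = 0.0
    return state


def compress(state: SystemState, topo: PolymerTopology, ffp: ForceFieldParams,
             dp: DynamicsParams, target_side: float, steps: int = 500) -> SystemState:
    """Shrink box and coordinates geometrically to the target side over ``steps``."""
    if target_side > state.box_side:
        raise ValueError("compress expects target_side <= current box side")
    if target_side == state.box_side:
        return state
    run(state, topo, ffp, dp, steps, steps + 1,
        box_final=target_side, neighbor_list=False)
    return state


def equilibrate(state: SystemState, topo: PolymerTopology, ffp: ForceFieldParams,
                dp: DynamicsParams, steps: int = 2_000_000,
                sample_stride: int | None = None) -> Trajectory:
    """Relax with the attraction off; returns the sampled relaxation trajectory.

    Convergence diagnostic: the locus Rg series should be stationary over the
    second half (a warning, not an error, if it is not) and the center of
    mass should have moved.
    """
    if sample_stride is None:
        sample_stride = max(1, steps // 100)
    traj = run(state, topo, ffp.with_(bind_eps=0.0), dp, steps, sample_stride)
    if traj.n_frames >= 20:
        from .analysis import locus_volumes
        v = locus_volumes(traj, topo)
        half = v.size // 2
        a, b = v[half: half + half // 2], v[half + half // 2:]
        # crude stationarity check: second-half segment means within 3 pooled sd
        if abs(a.mean() - b.mean()) > 3 * np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size):
            import warnings
            warnings.warn("locus Rg not stationary at end of equilibration", stacklevel=2)
    return traj


def prepare(topo: PolymerTopology, ffp: ForceFieldParams, dp: DynamicsParams,
            seed: int, *, volume_fraction: float = 0.026,
            ramp_steps: int = 1000, compress_steps: int = 500,
            equil_steps: int = 200_000) -> SystemState:
    """Full pipeline: place -> push off -> compress -> equilibrate; returns the state."""
    target = target_box_side(topo.n_beads, volume_fraction)
    state = random_placement(topo, 4.0 * target, np.random.default_rng(seed))
    state.seed_seq = np.random.SeedSequence(seed)
    push_off(state, topo, ffp, dp, ramp_steps)
    compress(state, topo, ffp, dp, target, compress_steps)
    equilibrate(state, topo, ffp, dp, equil_steps)
    return state
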