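"""Langevin dynamics: equation of motion, time-scale mapping, trajectories.

Each bead obeys the Langevin equation

    m d2r/dt2 = -m*Gamma dr/dt + F(r) + W(t),

integrated with velocity Verlet plus a Langevin thermostat whose white-noise
amplitude satisfies the fluctuation-dissipation balance at kBT.  Reduced
units: sigma = kBT = m = tau = 1; the physical time unit follows from the
bead diffusion constant, tau = sigma^2 / D = 20 us for a 10 nm bead with
D = 5 um^2/s.

The damping constant Gamma = 0.5 / tau and the step dt = 0.012 tau are taken
as primary; the diffusion constant implied by Einstein's relation in reduced
units (kBT / (m Gamma) = 2 sigma^2/tau) is reported, not enforced, since the
two stated relations are not simultaneously consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams


def tau_from_diffusion(sigma_nm: float = 10.0, D_um2_s: float = 5.0) -> float:
    """MD time unit tau = sigma^2 / D, returned in microseconds."""
    if sigma_nm <= 0 or D_um2_s <= 0:
        raise ValueError("sigma and D must be positive")
    # sigma^2 in um^2, divided by um^2/s -> seconds -> us
    return (sigma_nm * 1e-3) ** 2 / D_um2_s * 1e6


@dataclass(frozen=True)
class DynamicsParams:
    """Thermostat and integration settings (reduced units unless noted)."""

    kBT: float = 1.0
    mass: float = 1.0
    gamma: float = 0.5          # damping rate, tau^-1
    dt: float = 0.012           # integration step, tau
    diffusion: float = 5.0      # physical bead diffusion constant, um^2/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.kBT <= 0 or self.mass <= 0:
            raise ValueError("kBT and mass must be positive")

    @property
    def tau_physical_us(self) -> float:
        """Physical duration of one tau in microseconds (20 us at defaults)."""
        return tau_from_diffusion(10.0, self.diffusion)

    def steps_for_seconds(self, seconds: float, scale: float = 1.0) -> int:
        """Step count for a physical duration, with a desk-scale multiplier."""
        steps = seconds / (self.dt * self.tau_physical_us * 1e-6) * scale
        return max(1, int(round(steps)))

    def with_(self, **kw) -> "DynamicsParams":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Positions/velocities (unwrapped, sigma and sigma/tau), box and rng stream."""

    positions: np.ndarray
    velocities: np.ndarray
    box_side: float
    step_count: int = 0
    seed_seq: np.random.SeedSequence = field(default_factory=lambda: np.random.SeedSequence(0))

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have matching shapes")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        # the child keeps an independent continuation of the parent's stream
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.box_side,
            self.step_count, np.random.SeedSequence(self.seed_seq.entropy,
                                                    spawn_key=self.seed_seq.spawn_key,
                                                    n_children_spawned=self.seed_seq.n_children_spawned),
        )

    def next_seed(self) -> int:
        """Deterministically advance the state's seed stream (counter split)."""
        return int(self.seed_seq.spawn(1)[0].generate_state(1, np.uint32)[0] % (2 ** 31))


@dataclass
class Trajectory:
    """Sampled frames: positions (F, N, 3), step indices and times in tau."""

    positions: np.ndarray
    velocities: np.ndarray
    step_index: np.ndarray
    time_tau: np.ndarray
    box_side: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            np.concatenate([self.positions, other.positions]),
            np.concatenate([self.velocities, other.velocities]),
            np.concatenate([self.step_index, other.step_index]),
            np.concatenate([self.time_tau, other.time_tau]),
            other.box_side,
        )


def _run_kernel(state: SystemState, topo, ffp: ForceFieldParams, dp: DynamicsParams,
                n_steps: int, sample_stride: int, *,
                noise_on: bool = True, gamma: float | None = None,
                soft_on: bool = False, soft_amp0: float = 0.0, soft_amp1: float = 0.0,
                box_final: float | None = None,
                neighbor_list: bool | None = None, skin: float = 0.3,
                mobile: np.ndarray | None = None,
                seed: int | None = None) -> Trajectory:
    n = state.n_beads
    if n != topo.n_beads:
        raise ValueError("state and topology bead counts differ")
    if gamma is None:
        gamma = dp.gamma
    if box_final is None:
        box_final = state.box_side
    if neighbor_list is None:
        neighbor_list = n > 128 and not (box_final != state.box_side)
    if mobile is None:
        mobile = np.ones(n, dtype=np.bool_)
    if seed is None:
        seed = state.next_seed()
    n_samples = n_steps // sample_stride
    samples_pos = np.empty((n_samples, n, 3))
    samples_vel = np.empty((n_samples, n, 3))
    err = np.zeros(2, dtype=np.int64)
    aflag = topo.bound_pre_mask.astype(np.bool_)
    mflag = topo.methyl_mask.astype(np.bool_)

    new_box = _kernels.integrate(
        state.positions, state.velocities, mobile, float(state.box_side),
        topo.bonds, topo.angles, aflag, mflag,
        ffp.sigma, ffp.fene_k, ffp.fene_r0, ffp.bend_k, ffp.ev_eps,
        ffp.bind_eps, ffp.bind_cutoff,
        soft_on, soft_amp0, soft_amp1, ffp.soft_cutoff,
        dp.kBT, dp.mass, gamma, dp.dt, noise_on, seed,
        n_steps, sample_stride, float(box_final),
        neighbor_list, skin,
        samples_pos, samples_vel, err,
    )
    if err[0] == _kernels.ERR_FENE:
        b = topo.bonds[err[1]]
        raise RuntimeError(f"FENE bond {err[1]} ({b[0]}-{b[1]}) reached maximum extension R0")
    if err[0] == _kernels.ERR_NONFINITE:
        raise RuntimeError(f"non-finite coordinate on bead {err[1]} after step")
    start = state.step_count
    state.box_side = float(new_box)
    state.step_count += n_steps
    steps = start + sample_stride * np.arange(1, n_samples + 1)
    return Trajectory(samples_pos, samples_vel, steps, steps * dp.dt, state.box_side)


def langevin_step(state: SystemState, topo, ffp: ForceFieldParams, dp: DynamicsParams,
                  **kw) -> SystemState:
    """Advance the state by a single thermostatted velocity-Verlet step."""
    _run_kernel(state, topo, ffp, dp, 1, 2, **kw)
    return state


def run(state: SystemState, topo, ffp: ForceFieldParams, dp: DynamicsParams,
        n_steps: int, sample_stride: int, **kw) -> Trajectory:
    """Advance ``n_steps`` and return every ``sample_stride``-th frame.

    The state is advanced in place (positions, velocities, step_count, rng
    stream); the returned trajectory carries step indices and times in tau.
    A stride larger than ``n_steps`` yields an empty sample list.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return _run_kernel(state, topo, ffp, dp, n_steps, sample_stride, **kw)


def kinetic_energy(velocities: np.ndarray, mass: float = 1.0) -> float:
    return float(0.5 * mass * np.sum(velocities ** 2))
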