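"""Many-particle binding simulation calibrating epsilon against KD.

One immobile binding site sits in a periodic box surrounded by diffusing
binder particles at a fixed molar concentration (450 particles in a 52 sigma
box ~= 5 uM at full scale).  For each attraction strength epsilon the bound
fraction pb is estimated as the fraction of uncorrelated frames in which at
least one particle center lies within the attraction range (2.5 sigma) of
the site; the epsilon at which pb crosses 0.5 is the simulation-side
calibration of the dissociation constant (the full-scale run crosses near
3.94 kBT at 5 uM).

Binder particles interact with each other by excluded volume only; no
occupancy cap is imposed, so several particles may crowd the site -- one of
the reasons the simulation calibration lands below the closed-form estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import AVOGADRO
from .dynamics import DynamicsParams, SystemState, run
from .forcefield import ForceFieldParams
from .topology import PolymerTopology


@dataclass(frozen=True)
class CalibrationSetup:
    """Particle count, box, epsilon grid and sampling plan."""

    n_particles: int = 450
    box_side: float = 52.0          # sigma
    n_sites: int = 1
    eps_grid: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)
    frames: int = 500               # samples per replicate
    replicates: int = 4
    bound_radius: float = 2.5       # sigma; the attraction range
    sample_stride: int = 10_000     # MD steps between samples
    equil_steps: int = 50_000

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_sites != 1:
            raise ValueError("need >= 1 particle and exactly one site")
        if not self.eps_grid:
            raise ValueError("eps_grid must be non-empty")
        if self.frames * self.replicates < 100:
            raise ValueError("need >= 100 total frames for crossing estimation")

    @property
    def concentration_molar(self) -> float:
        """Implied molar binder concentration for sigma = 10 nm beads."""
        # box side in sigma, sigma = 10 nm -> cm, cm^3 -> L
        box_litre = (self.box_side * 10.0 * 1e-7) ** 3 / 1e3
        return self.n_particles / (AVOGADRO * box_litre)


def box_side_for_concentration(n_particles: int, molar: float) -> float:
    """Box side (sigma, 10 nm beads) realizing a molar particle concentration."""
    box_litre = n_particles / (AVOGADRO * molar)
    return (box_litre * 1e3) ** (1.0 / 3.0) * 1e7 / 10.0


def _gas_topology(n_total: int) -> PolymerTopology:
    """Unbonded particle gas: bead 0 is the (attracting) site, the rest binders."""
    types = np.ones(n_total, dtype=np.int64) * 1      # METH: attractable binders
    types[0] = 2                                      # PRE: the binding site
    bound = np.zeros(n_total, dtype=np.bool_)
    bound[0] = True
    return PolymerTopology(types, bound, (1, n_total), chain=False)


def _init_box(setup: CalibrationSetup, ffp: ForceFieldParams, dp: DynamicsParams,
              seed: int) -> tuple[SystemState, PolymerTopology, np.ndarray]:
    n = setup.n_particles + 1
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, setup.box_side, size=(n, 3))
    pos[0] = setup.box_side / 2.0
    topo = _gas_topology(n)
    state = SystemState(pos, np.zeros((n, 3)), setup.box_side,
                        seed_seq=np.random.SeedSequence(seed))
    mobile = np.ones(n, dtype=np.bool_)
    mobile[0] = False
    # soft push-off resolves random-placement overlaps
    run(state, topo, ffp, dp, 500, 501, soft_on=True, soft_amp0=0.0,
        soft_amp1=ffp.soft_amp, mobile=mobile, neighbor_list=False)
    return state, topo, mobile


def _bound_fraction_frames(frames: np.ndarray, box: float, radius: float) -> np.ndarray:
    """Per-frame indicator: any binder center within ``radius`` of the site."""
    site = frames[:, :1, :]
    d = frames[:, 1:, :] - site
    d -= box * np.round(d / box)
    dist2 = np.sum(d * d, axis=-1)
    return (dist2.min(axis=1) <= radius * radius).astype(float)


def binding_simulation(setup: CalibrationSetup, ffp: ForceFieldParams,
                       dp: DynamicsParams, seed: int = 0) -> pd.DataFrame:
    """Estimate the bound fraction across the epsilon grid.

    Returns a tidy frame with one row per (epsilon, replicate): columns
    ``eps``, ``replicate``, ``pb``, ``stderr`` (binomial over frames) and the
    implied molar concentration.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for rep, rep_seq in enumerate(root.spawn(setup.replicates)):
        seeds = rep_seq.generate_state(len(setup.eps_grid) + 1, np.uint32) % (2 ** 31)
        for k, eps in enumerate(setup.eps_grid):
            p = ffp.with_(bind_eps=float(eps))
            state, topo, mobile = _init_box(setup, p, dp, int(seeds[0]) + 7 * k)
            run(state, topo, p, dp, setup.equil_steps, setup.equil_steps + 1,
                mobile=mobile, seed=int(seeds[k + 1]))
            traj = run(state, topo, p, dp, setup.frames * setup.sample_stride,
                       setup.sample_stride, mobile=mobile,
                       seed=int(seeds[k + 1]) + 1)
            ind = _bound_fraction_frames(traj.positions, state.box_side, setup.bound_radius)
            pb = float(ind.mean())
            se = math.sqrt(max(pb * (1 - pb), 1.0 / ind.size) / ind.size)
            rows.append({"eps": float(eps), "replicate": rep, "pb": pb,
                         "stderr": se, "n_frames": int(ind.size),
                         "concentration_M": setup.concentration_molar})
    return pd.DataFrame(rows)


def find_crossing(eps_values, pb_values, level: float = 0.5) -> float:
    """Epsilon at which pb crosses ``level``, by linear interpolation.

    ``pb_values`` must bracket the level; with several crossings the first
    (lowest-epsilon) bracketing interval is used.
    """
    e = np.asarray(eps_values, dtype=float)
    p = np.asarray(pb_values, dtype=float)
    order = np.argsort(e)
    e, p = e[order], p[order]
    hits = np.flatnonzero(p == level)
    if hits.size:
        return float(e[hits[0]])
    for i in range(len(e) - 1):
        if (p[i] - level) * (p[i + 1] - level) < 0:
            t = (level - p[i]) / (p[i + 1] - p[i])
            return float(e[i] + t * (e[i + 1] - e[i]))
    raise ValueError("level not crossed by the supplied pb values")


def crossing_from_results(df: pd.DataFrame, level: float = 0.5):
    """Crossing of the replicate-mean curve plus the per-replicate spread."""
    mean_curve = df.groupby("eps")["pb"].mean()
    est = find_crossing(mean_curve.index.to_numpy(), mean_curve.to_numpy(), level)
    per_rep = []
    for _, sub in df.groupby("replicate"):
        try:
            per_rep.append(find_crossing(sub["eps"].to_numpy(), sub["pb"].to_numpy(), level))
        except ValueError:
            pass
    return est, per_rep
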