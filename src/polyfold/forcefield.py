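"""Bead-spring chromatin force field.

The chromatin fiber is a Kremer-Grest-style semi-flexible self-avoiding
polymer of 10 nm (nucleosome-sized) beads:

* stretching  -- FENE (Warner) springs between consecutive beads,
* bending     -- ``K_theta (1 - cos theta)`` over consecutive bond pairs,
* excluded volume -- WCA (truncated-shifted Lennard-Jones) on all pairs,
* binding     -- a truncated-shifted Lennard-Jones attraction acting only
  between PRC1-bound PRE beads and H3K27-trimethylated beads,
* soft push-off -- a bounded cosine ramp used during system preparation.

Internally sigma = 1 (one bead diameter, physically 10 nm), energies are in
kBT and the bead mass is 1, the standard reduced-unit choice for this model
class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels

RMIN_FACTOR = 2.0 ** (1.0 / 6.0)  # location of the Lennard-Jones minimum / sigma


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction constants in reduced units (lengths in sigma, energies kBT).

    Parameters
    ----------
    sigma : bead diameter (internal unit; physically 10 nm).
    fene_k : FENE spring strength Ks.
    fene_r0 : FENE maximum extension R0.
    bend_k : bending constant K_theta; the theoretical persistence length is
        ``bend_k * sigma / kBT`` (3 sigma at the default).
    ev_eps : WCA excluded-volume strength.
    bind_eps : depth parameter epsilon of the PRC1-H3K27me3 attraction.
    bind_cutoff : attraction interaction range r_int.
    soft_amp : end point A of the soft push-off ramp.
    soft_cutoff : soft-potential range r_c.
    """

    sigma: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.5
    bend_k: float = 3.0
    ev_eps: float = 1.0
    bind_eps: float = 5.1
    bind_cutoff: float = 2.5
    soft_amp: float = 40.0
    soft_cutoff: float = 2.5

    def __post_init__(self) -> None:
        for name in ("sigma", "fene_k", "fene_r0", "bend_k", "ev_eps", "bind_cutoff", "soft_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bind_eps < 0:
            raise ValueError("bind_eps must be >= 0")
        if self.soft_amp < 0:
            raise ValueError("soft_amp must be >= 0")
        if self.fene_r0 <= self.sigma:
            raise ValueError("fene_r0 must exceed one bead diameter")
        if self.bind_cutoff <= RMIN_FACTOR * self.sigma:
            raise ValueError("bind_cutoff must lie beyond the Lennard-Jones minimum 2^(1/6) sigma")

    @property
    def rmin(self) -> float:
        """Distance of the Lennard-Jones minimum, 2^(1/6) sigma."""
        return RMIN_FACTOR * self.sigma

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


def _lj(r: np.ndarray, eps: float, sigma: float) -> np.ndarray:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def fene_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """FENE bond energy in kBT; infinite at and beyond the maximum extension R0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.full(r.shape, np.inf)
    ok = r < p.fene_r0
    ratio2 = (r[ok] / p.fene_r0) ** 2
    out[ok] = -0.5 * p.fene_k * (p.fene_r0 / p.sigma) ** 2 * np.log1p(-ratio2)
    return out if out.shape else float(out)


def bend_energy(theta, p: ForceFieldParams = ForceFieldParams()):
    """Bending energy ``K_theta (1 - cos theta)``; minimum at collinear bonds."""
    theta = np.asarray(theta, dtype=float)
    out = p.bend_k * (1.0 - np.cos(theta))
    return out if out.shape else float(out)


def wca_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """Purely repulsive excluded volume: LJ cut at 2^(1/6) sigma, shifted by ev_eps."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = np.zeros(r.shape)
    inside = r <= p.rmin
    out[inside] = _lj(r[inside], p.ev_eps, p.sigma) + p.ev_eps
    return out if out.shape else float(out)


def bind_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """PRC1-H3K27me3 attraction: LJ truncated at r_int and shifted to zero there."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = np.zeros(r.shape)
    inside = r <= p.bind_cutoff
    shift = _lj(np.array([p.bind_cutoff]), p.bind_eps, p.sigma)[0]
    out[inside] = _lj(r[inside], p.bind_eps, p.sigma) - shift
    return out if out.shape else float(out)


def soft_energy(r, A: float = 40.0, rc: float = 2.5):
    """Bounded push-off potential ``A (1 + cos(pi r / rc))`` for r < rc."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.zeros(r.shape)
    inside = r < rc
    out[inside] = A * (1.0 + np.cos(np.pi * r[inside] / rc))
    return out if out.shape else float(out)


def well_depth(eps: float, cutoff: float, sigma: float = 1.0) -> float:
    """Binding well depth Eb = V_LJ(rmin) - V_LJ(cutoff), in kBT.

    At cutoff 2.0 sigma this evaluates to -0.9385 eps (the coefficient used by
    the dissociation-constant calibration); at the dynamics attraction range
    2.5 sigma it is -0.9837 eps.  Both are exposed because the calibration
    algebra and the MD cutoff use different printed conventions.
    """
    rmin = RMIN_FACTOR * sigma
    if cutoff <= rmin:
        raise ValueError("cutoff must lie beyond the Lennard-Jones minimum")
    if eps == 0:
        return 0.0
    return float(_lj(np.array([rmin]), eps, sigma)[0] - _lj(np.array([cutoff]), eps, sigma)[0])


# ---------------------------------------------------------------------------
# Whole-system evaluation (wrappers over the numba kernels)
# ---------------------------------------------------------------------------

def _interaction_masks(topo):
    aflag = np.asarray(topo.bound_pre_mask, dtype=np.bool_)
    mflag = np.asarray(topo.methyl_mask, dtype=np.bool_)
    return aflag, mflag


def total_forces(state, topo, p: ForceFieldParams, soft_on: bool = False,
                 soft_amp: float | None = None) -> np.ndarray:
    """Per-bead conservative force vectors in kBT/sigma.

    Sums FENE bonds, bending triplets, WCA on all pairs (bonded included) and
    the binding attraction on (PRC1-bound PRE, methylated) pairs, under the
    minimum-image convention.  Internal forces sum to the zero vector.
    """
    pos = np.asarray(state.positions, dtype=float)
    n = pos.shape[0]
    if n != topo.n_beads:
        raise ValueError("state and topology bead counts differ")
    pi, pj = _kernels.all_pairs(n)
    aflag, mflag = _interaction_masks(topo)
    forces = np.zeros((n, 3))
    err = np.zeros(2, dtype=np.int64)
    _kernels.conservative_forces(
        pos, float(state.box_side), pi, pj, topo.bonds, topo.angles, aflag, mflag,
        p.sigma, p.fene_k, p.fene_r0, p.bend_k, p.ev_eps, p.bind_eps, p.bind_cutoff,
        soft_on, p.soft_amp if soft_amp is None else soft_amp, p.soft_cutoff,
        forces, err,
    )
    if err[0] == _kernels.ERR_FENE:
        b = topo.bonds[err[1]]
        raise RuntimeError(f"FENE bond {err[1]} ({b[0]}-{b[1]}) at or beyond maximum extension R0")
    return forces


def total_energy(state, topo, p: ForceFieldParams, soft_on: bool = False,
                 soft_amp: float | None = None) -> float:
    """Total potential energy in kBT (infinite for an overstretched bond)."""
    pos = np.asarray(state.positions, dtype=float)
    n = pos.shape[0]
    pi, pj = _kernels.all_pairs(n)
    aflag, mflag = _interaction_masks(topo)
    return float(_kernels.potential_energy(
        pos, float(state.box_side), pi, pj, topo.bonds, topo.angles, aflag, mflag,
        p.sigma, p.fene_k, p.fene_r0, p.bend_k, p.ev_eps, p.bind_eps, p.bind_cutoff,
        soft_on, p.soft_amp if soft_amp is None else soft_amp, p.soft_cutoff,
    ))
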