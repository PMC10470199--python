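"""Numba kernels: pair forces, energies and the Langevin velocity-Verlet loop.

All kernels work in reduced units (sigma-scaled lengths, kBT energies, tau
times).  Distances use the minimum-image convention in a cubic periodic box;
positions themselves are kept unwrapped.  Pair interactions are evaluated over
an explicit (i, j) candidate list so the same kernel serves both the
brute-force all-pairs path and the Verlet neighbor-list path.

Error protocol: ``err`` is an int64[2] scratch array.  err[0] codes
0 = ok, 1 = FENE bond at or beyond maximum extension (err[1] = bond index),
2 = non-finite coordinate encountered (err[1] = bead index).
"""

import numpy as np
from numba import njit

ERR_OK = 0
ERR_FENE = 1
ERR_NONFINITE = 2


@njit(cache=True, inline="always")
def _mi(d, box):
    # minimum image for one coordinate difference
    return d - box * np.round(d / box)


@njit(cache=True)
def conservative_forces(
    pos, box, pi, pj, bonds, angles, aflag, mflag,
    sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
    soft_on, soft_amp, soft_cut,
    forces, err,
):
    """Accumulate conservative forces into ``forces`` (overwritten)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    err[0] = ERR_OK
    err[1] = -1

    s2 = sigma * sigma
    rmin2 = 2.0 ** (1.0 / 3.0) * s2          # (2^(1/6) sigma)^2, WCA cutoff
    bind2 = bind_cut * bind_cut
    soft2 = soft_cut * soft_cut

    # --- non-bonded pair terms over the candidate list ---
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if soft_on:
            if r2 < soft2 and r2 > 0.0:
                r = np.sqrt(r2)
                # V = A (1 + cos(pi r / rc)); -dV/dr = A pi/rc sin(pi r/rc)
                fr = soft_amp * np.pi / soft_cut * np.sin(np.pi * r / soft_cut) / r
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
            continue
        if r2 < rmin2:
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            fr = 24.0 * ev_eps * sr6 * (2.0 * sr6 - 1.0) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        if bind_eps != 0.0 and r2 < bind2:
            if (aflag[i] and mflag[j]) or (aflag[j] and mflag[i]):
                sr2 = s2 / r2
                sr6 = sr2 * sr2 * sr2
                fr = 24.0 * bind_eps * sr6 * (2.0 * sr6 - 1.0) / r2
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz

    # --- FENE bonds ---
    r02 = fene_r0 * fene_r0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            err[0] = ERR_FENE
            err[1] = k
            return
        # -dV/dr / r with V = -1/2 Ks (R0/sigma)^2 ln(1 - (r/R0)^2)
        fr = -fene_k / (s2 * (1.0 - r2 / r02))
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    # --- bending over bonded triplets ---
    for k in range(angles.shape[0]):
        a = angles[k, 0]
        b = angles[k, 1]
        c = angles[k, 2]
        b1x = _mi(pos[b, 0] - pos[a, 0], box)
        b1y = _mi(pos[b, 1] - pos[a, 1], box)
        b1z = _mi(pos[b, 2] - pos[a, 2], box)
        b2x = _mi(pos[c, 0] - pos[b, 0], box)
        b2y = _mi(pos[c, 1] - pos[b, 1], box)
        b2z = _mi(pos[c, 2] - pos[b, 2], box)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        inv = 1.0 / (n1 * n2)
        ct = (b1x * b2x + b1y * b2y + b1z * b2z) * inv
        # g = dE/db with E = K (1 - cos theta)
        g1x = -bend_k * (b2x * inv - ct * b1x / (n1 * n1))
        g1y = -bend_k * (b2y * inv - ct * b1y / (n1 * n1))
        g1z = -bend_k * (b2z * inv - ct * b1z / (n1 * n1))
        g2x = -bend_k * (b1x * inv - ct * b2x / (n2 * n2))
        g2y = -bend_k * (b1y * inv - ct * b2y / (n2 * n2))
        g2z = -bend_k * (b1z * inv - ct * b2z / (n2 * n2))
        forces[a, 0] += g1x
        forces[a, 1] += g1y
        forces[a, 2] += g1z
        forces[b, 0] += g2x - g1x
        forces[b, 1] += g2y - g1y
        forces[b, 2] += g2z - g1z
        forces[c, 0] -= g2x
        forces[c, 1] -= g2y
        forces[c, 2] -= g2z


@njit(cache=True)
def potential_energy(
    pos, box, pi, pj, bonds, angles, aflag, mflag,
    sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
    soft_on, soft_amp, soft_cut,
):
    """Total potential energy in kBT; +inf on FENE overextension."""
    s2 = sigma * sigma
    rmin2 = 2.0 ** (1.0 / 3.0) * s2
    bind2 = bind_cut * bind_cut
    soft2 = soft_cut * soft_cut
    # binding shift so V_bind(bind_cut) = 0
    sc2 = s2 / bind2
    sc6 = sc2 * sc2 * sc2
    vshift = 4.0 * bind_eps * (sc6 * sc6 - sc6)

    e = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if soft_on:
            if r2 < soft2:
                r = np.sqrt(r2)
                e += soft_amp * (1.0 + np.cos(np.pi * r / soft_cut))
            continue
        if r2 < rmin2:
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            e += 4.0 * ev_eps * (sr6 * sr6 - sr6) + ev_eps
        if bind_eps != 0.0 and r2 < bind2:
            if (aflag[i] and mflag[j]) or (aflag[j] and mflag[i]):
                sr2 = s2 / r2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * bind_eps * (sr6 * sr6 - sr6) - vshift

    r02 = fene_r0 * fene_r0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return np.inf
        e += -0.5 * fene_k * r02 / s2 * np.log(1.0 - r2 / r02)

    for k in range(angles.shape[0]):
        a = angles[k, 0]
        b = angles[k, 1]
        c = angles[k, 2]
        b1x = _mi(pos[b, 0] - pos[a, 0], box)
        b1y = _mi(pos[b, 1] - pos[a, 1], box)
        b1z = _mi(pos[b, 2] - pos[a, 2], box)
        b2x = _mi(pos[c, 0] - pos[b, 0], box)
        b2y = _mi(pos[c, 1] - pos[b, 1], box)
        b2z = _mi(pos[c, 2] - pos[b, 2], box)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        ct = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        e += bend_k * (1.0 - ct)
    return e


@njit(cache=True)
def build_pairs(pos, box, cutoff):
    """O(N^2) scan building the (i, j) Verlet pair list within ``cutoff``."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    pi = np.empty(count, np.int64)
    pj = np.empty(count, np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            if dx * dx + dy * dy + dz * dz < c2:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True)
def all_pairs(n):
    m = n * (n - 1) // 2
    pi = np.empty(m, np.int64)
    pj = np.empty(m, np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            pi[k] = i
            pj[k] = j
            k += 1
    return pi, pj


@njit(cache=True)
def integrate(
    pos, vel, mobile, box, bonds, angles, aflag, mflag,
    sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
    soft_on, soft_amp0, soft_amp1, soft_cut,
    kT, mass, gamma, dt, noise_on, seed,
    n_steps, stride, box_final,
    use_nlist, skin,
    samples_pos, samples_vel, err,
):
    """Langevin velocity-Verlet loop; returns the final box side.

    The thermostat adds -m*gamma*v plus Gaussian noise of per-component
    variance 2*m*gamma*kT/dt to the conservative force, so gamma=0 with
    noise_on=False is plain (energy-conserving) velocity Verlet.

    ``soft_amp`` ramps linearly soft_amp0 -> soft_amp1 across the run
    (push-off); ``box_final`` != box applies a geometric per-step affine
    rescale of box and coordinates (compression).  Samples are stored every
    ``stride`` steps into the pre-allocated ``samples_pos``/``samples_vel``.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))

    if use_nlist:
        cutoff = max(2.0 ** (1.0 / 6.0) * sigma, bind_cut)
        if soft_on:
            cutoff = max(cutoff, soft_cut)
        cutoff += skin
        pi, pj = build_pairs(pos, box, cutoff)
        pos_build = pos.copy()
    else:
        pi, pj = all_pairs(n)
        pos_build = pos  # unused

    scale = 1.0
    if box_final != box:
        scale = (box_final / box) ** (1.0 / n_steps)

    noise_amp = np.sqrt(2.0 * mass * gamma * kT / dt)
    soft_amp = soft_amp0
    noise = np.zeros((n, 3))

    conservative_forces(
        pos, box, pi, pj, bonds, angles, aflag, mflag,
        sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
        soft_on, soft_amp, soft_cut, forces, err,
    )
    if err[0] != ERR_OK:
        return box

    half = 0.5 * dt / mass
    isample = 0
    for step in range(n_steps):
        # one noise draw per step, applied in both half-kicks: the step has
        # no hidden state, so short runs compose exactly like long ones
        if noise_on:
            for i in range(n):
                if mobile[i]:
                    noise[i, 0] = noise_amp * np.random.normal(0.0, 1.0)
                    noise[i, 1] = noise_amp * np.random.normal(0.0, 1.0)
                    noise[i, 2] = noise_amp * np.random.normal(0.0, 1.0)
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * (forces[i, 0] - mass * gamma * vel[i, 0] + noise[i, 0])
                vel[i, 1] += half * (forces[i, 1] - mass * gamma * vel[i, 1] + noise[i, 1])
                vel[i, 2] += half * (forces[i, 2] - mass * gamma * vel[i, 2] + noise[i, 2])
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]
        if scale != 1.0:
            box *= scale
            for i in range(n):
                pos[i, 0] *= scale
                pos[i, 1] *= scale
                pos[i, 2] *= scale
        if soft_on and soft_amp1 != soft_amp0:
            soft_amp = soft_amp0 + (soft_amp1 - soft_amp0) * (step + 1) / n_steps

        if use_nlist:
            dmax2 = 0.0
            for i in range(n):
                ddx = pos[i, 0] - pos_build[i, 0]
                ddy = pos[i, 1] - pos_build[i, 1]
                ddz = pos[i, 2] - pos_build[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > dmax2:
                    dmax2 = d2
            if dmax2 > 0.25 * skin * skin:
                cutoff = max(2.0 ** (1.0 / 6.0) * sigma, bind_cut)
                if soft_on:
                    cutoff = max(cutoff, soft_cut)
                cutoff += skin
                pi, pj = build_pairs(pos, box, cutoff)
                pos_build = pos.copy()

        conservative_forces(
            pos, box, pi, pj, bonds, angles, aflag, mflag,
            sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
            soft_on, soft_amp, soft_cut, forces, err,
        )
        if err[0] != ERR_OK:
            return box
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * (forces[i, 0] - mass * gamma * vel[i, 0] + noise[i, 0])
                vel[i, 1] += half * (forces[i, 1] - mass * gamma * vel[i, 1] + noise[i, 1])
                vel[i, 2] += half * (forces[i, 2] - mass * gamma * vel[i, 2] + noise[i, 2])

        if (step + 1) % stride == 0 and isample < samples_pos.shape[0]:
            for i in range(n):
                if not (
                    np.isfinite(pos[i, 0])
                    and np.isfinite(pos[i, 1])
                    and np.isfinite(pos[i, 2])
                ):
                    err[0] = ERR_NONFINITE
                    err[1] = i
                    return box
                samples_pos[isample, i, 0] = pos[i, 0]
                samples_pos[isample, i, 1] = pos[i, 1]
                samples_pos[isample, i, 2] = pos[i, 2]
                samples_vel[isample, i, 0] = vel[i, 0]
                samples_vel[isample, i, 1] = vel[i, 1]
                samples_vel[isample, i, 2] = vel[i, 2]
            isample += 1
    return box


@njit(cache=True)
def descend(
    pos, box, pi, pj, bonds, angles, aflag, mflag,
    sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
    soft_on, soft_amp, soft_cut,
    step_size, n_steps, err,
):
    """Damped (zero-temperature) relaxation: x += step_size * F, force-capped.

    Used after the soft push-off ramp to drive residual non-bonded overlaps
    past sigma without thermal noise.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    for _ in range(n_steps):
        conservative_forces(
            pos, box, pi, pj, bonds, angles, aflag, mflag,
            sigma, fene_k, fene_r0, bend_k, ev_eps, bind_eps, bind_cut,
            soft_on, soft_amp, soft_cut, forces, err,
        )
        if err[0] != ERR_OK:
            return
        for i in range(n):
            for d in range(3):
                f = forces[i, d]
                if f > 50.0:
                    f = 50.0
                elif f < -50.0:
                    f = -50.0
                pos[i, d] += step_size * f


@njit(cache=True)
def min_nonbonded_distance(pos, box, bonds):
    """Smallest minimum-image distance over non-bonded pairs."""
    n = pos.shape[0]
    bonded = np.zeros((n, n), np.bool_)
    for k in range(bonds.shape[0]):
        bonded[bonds[k, 0], bonds[k, 1]] = True
        bonded[bonds[k, 1], bonds[k, 0]] = True
    best = 1.0e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            if bonded[i, j]:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < best:
                best = d
    return best
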