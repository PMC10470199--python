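"""Closed-form binding algebra linking occupancy, concentration, KD and epsilon.

A site exposed to free binder concentration ``c`` with dissociation constant
``KD`` is occupied with probability ``pb = c / (c + KD)`` (pseudo-first-order
kinetics).  Statistical mechanics relates KD to the attraction well depth Eb
through a standard-state concentration c0 (one binder per bead-sized cube,
1.66 mM for sigma = 10 nm):

    KD = c0 * exp(Eb / kBT),   Eb ~= -0.938 * eps

where 0.938 is the well-depth coefficient of the truncated-shifted
Lennard-Jones attraction evaluated with a 2.0 sigma cutoff (the value used
by the printed calibration chain; the exact 2.5 sigma evaluation, 0.9837,
is selectable via ``well_coeff``).  All concentrations are molar.
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23
#: printed well-depth coefficient (2.0 sigma cutoff evaluation)
WELL_COEFF_PRINTED = 0.938
#: exact coefficient at the dynamics attraction range r_int = 2.5 sigma
WELL_COEFF_EXACT_25 = 0.983683108864
#: standard state quoted alongside the calibration chain (rounded from 1.6605 mM)
C0_PRINTED = 1.67e-3


def pb_bound(c: float, kd: float) -> float:
    """Occupancy probability ``c / (c + KD)``; monotone in both arguments."""
    if c < 0 or kd < 0:
        raise ValueError("concentrations must be non-negative")
    if c == 0 and kd == 0:
        raise ValueError("pb undefined for c = KD = 0")
    return c / (c + kd)


def kd_for_pb(pb: float, c: float) -> float:
    """Dissociation constant producing occupancy ``pb`` at binder concentration ``c``."""
    if not 0.0 < pb <= 1.0:
        raise ValueError("pb must lie in (0, 1]")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return c * (1.0 - pb) / pb


def standard_state(sigma_nm: float = 10.0) -> float:
    """Concentration of one particle per sigma^3 cube, in molar (1.66 mM at 10 nm)."""
    if sigma_nm <= 0:
        raise ValueError("sigma must be positive")
    volume_litre = (sigma_nm * 1e-7) ** 3 / 1e3  # nm -> cm, cm^3 -> L
    return 1.0 / (AVOGADRO * volume_litre)


def kd_from_eps(eps: float, c0: float = C0_PRINTED, well_coeff: float = WELL_COEFF_PRINTED) -> float:
    """KD implied by an attraction strength: ``c0 * exp(-well_coeff * eps)``."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return c0 * math.exp(-well_coeff * eps)


def eps_from_kd(kd: float, c0: float = C0_PRINTED, well_coeff: float = WELL_COEFF_PRINTED) -> float:
    """Attraction strength matching a target KD: ``(1/well_coeff) * ln(c0/KD)`` (kBT)."""
    if not 0.0 < kd <= c0:
        raise ValueError("need 0 < KD <= c0 for a non-negative attraction")
    return math.log(c0 / kd) / well_coeff


def eps_consensus(eps_sim: float, eps_theory: float) -> float:
    """Arithmetic mean of the simulation and theory calibrations (5.07 kBT here)."""
    if eps_sim < 0 or eps_theory < 0:
        raise ValueError("attraction strengths must be >= 0")
    return 0.5 * (eps_sim + eps_theory)


_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def parse_concentration(text: str) -> float:
    """Parse '200 nM', '5uM', '1.67 mM' ... into molar."""
    s = text.strip()
    for suffix in sorted(_UNITS, key=len, reverse=True):
        if s.endswith(suffix):
            return float(s[: -len(suffix)].strip()) * _UNITS[suffix]
    return float(s)
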