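"""Calibrate the PRC1-H3K27me3 attraction strength against a dissociation constant.

Two independent routes: the closed-form statistical-mechanics estimate and a
scaled many-particle binding simulation (one immobile site, diffusing
binders at 5 uM).  The consensus of the two is the attraction used in the
chromatin simulations.
"""

import polyfold as pf
from polyfold import binding as bm
from polyfold.calibration import binding_simulation, crossing_from_results

# --- theory: eps from KD through the well-depth / standard-state relation ---
kd = 5e-6          # molar; the measured PRC1-H3K27me3 affinity scale
eps_theory = pf.eps_from_kd(kd, bm.C0_PRINTED)
print(f"standard state c0           : {pf.standard_state(10.0) * 1e3:.2f} mM")
print(f"well depth per unit eps     : {pf.well_depth(1.0, 2.0):.4f} kBT")
print(f"theory eps for KD = 5 uM    : {eps_theory:.2f} kBT")

# --- simulation: bound fraction across an eps grid, crossing at pb = 0.5 ---
setup = pf.make_fixture("calibration-box-small")   # 50 binders at 5 uM
print(f"\nsimulating {setup.n_particles} binders in a {setup.box_side:.1f} sigma box "
      f"({setup.concentration_molar * 1e6:.1f} uM) ...")
df = binding_simulation(setup, pf.ForceFieldParams(), pf.DynamicsParams(), seed=3)
print(df.groupby("eps")["pb"].mean().rename("bound fraction").to_string())
eps_sim, per_rep = crossing_from_results(df)
print(f"simulation eps at pb = 0.5  : {eps_sim:.2f} kBT (full-scale reference: 3.94)")

# --- consensus ---
print(f"consensus attraction        : {pf.eps_consensus(eps_sim, eps_theory):.2f} kBT "
      "(the chromatin simulations use 5.1)")
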