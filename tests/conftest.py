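"""Shared fixtures: parameters, small systems, and session-scoped simulations.

The heavier session fixtures (an equilibrated chain trajectory, the
desk-scale folding study, the binding-calibration curve) are computed once
and shared across the tests that interrogate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import polyfold as pf
from polyfold.dynamics import DynamicsParams
from polyfold.forcefield import ForceFieldParams
from polyfold.mcmd import (ExperimentPlan, mcmd_cycle, pre_background_gap,
                           reference_volumes, run_controls)
from polyfold.analysis import distance_map, locus_volumes
from polyfold.prep import prepare


@pytest.fixture(scope="session")
def ffp() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture(scope="session")
def dp() -> DynamicsParams:
    return DynamicsParams()


@pytest.fixture()
def chain60():
    return pf.make_fixture("chain60")


@pytest.fixture(scope="session")
def equilibrated(ffp, dp):
    """Prepared 60-mer plus a no-attraction production run (>=1e5 bond samples)."""
    topo = pf.make_fixture("chain60")
    state = prepare(topo, ffp, dp, seed=42, equil_steps=150_000)
    traj = pf.run(state, topo, ffp.with_(bind_eps=0.0), dp, 180_000, 100)
    return {"topo": topo, "state": state, "traj": traj}


# desk-scale study conditions for the folding / clustering checks
FOLD_PLAN = ExperimentPlan(
    pb_pre_values=(0.0, 0.5, 1.0), replicates=6, cycle_duration_s=100.0,
    scale=6e-4, cycles_per_replicate=2, equil_steps=150_000,
    sample_stride=10_000, discard_fraction=0.5,
    n_beads=60, pre_indices=(26, 34), seed=11,
)


@pytest.fixture(scope="session")
def folding_study(ffp, dp):
    """pb_pre scan + controls on the 60-mer, with pb=1 distance-map statistics."""
    plan = FOLD_PLAN
    topo = pf.build_default(plan.n_beads, list(plan.pre_indices))
    ref_vols = reference_volumes(plan, ffp, dp)
    v_ref = float(ref_vols.mean())

    rows = []
    gap_rows = []
    pooled_map = None
    seeds = np.random.SeedSequence([plan.seed, 1]).generate_state(plan.replicates,
                                                                  np.uint32)
    for rep, seed in enumerate(int(s % 2**31) for s in seeds):
        state = prepare(topo, ffp, dp, seed, equil_steps=plan.equil_steps)
        for pb in plan.pb_pre_values:
            s = state.copy()
            s.seed_seq = np.random.SeedSequence([seed, int(1e6 * pb)])
            vols = []
            frames = []
            for _ in range(plan.cycles_per_replicate):
                traj, drawn = mcmd_cycle(s, topo, pb, ffp, dp, plan)
                keep = slice(int(plan.discard_fraction * traj.n_frames), None)
                vols.append(locus_volumes(traj, drawn)[keep])
                if pb == 1.0:
                    frames.append(traj.positions[keep])
            v = np.concatenate(vols)
            rows.append({"pb_pre": pb, "replicate": rep,
                         "V_over_Vref": float(v.mean() / v_ref)})
            if pb == 1.0:
                sub = pf.Trajectory(np.concatenate(frames),
                                    np.zeros((sum(f.shape[0] for f in frames), 1, 1)),
                                    np.zeros(sum(f.shape[0] for f in frames)),
                                    np.zeros(sum(f.shape[0] for f in frames)),
                                    s.box_side)
                m = distance_map(sub, topo)
                pooled_map = m if pooled_map is None else pooled_map.combine(m)
                g = pre_background_gap(m, topo)
                gap_rows.append(float(g["gap"].mean()))

    import pandas as pd
    controls = run_controls(plan, ffp, dp, pb_pre=1.0, v_ref=v_ref)
    return {
        "plan": plan, "topo": topo, "v_ref": v_ref, "ref_vols": ref_vols,
        "scan": pd.DataFrame(rows), "controls": controls,
        "gaps": np.array(gap_rows), "pb1_map": pooled_map,
    }


@pytest.fixture(scope="session")
def calibration_study(ffp, dp):
    """Scaled bound-fraction curve at 5 uM-equivalent concentration."""
    from polyfold.calibration import binding_simulation
    setup = pf.make_fixture("calibration-box-small")
    df = binding_simulation(setup, ffp, dp, seed=3)
    return {"setup": setup, "df": df}
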