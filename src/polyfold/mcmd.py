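"""The Monte Carlo-molecular dynamics protocol and experiment drivers.

One MC-MD cycle = (i) draw PRC1 occupancy of every PRE with probability
``pb_pre``, (ii) run Langevin dynamics for the PRC1 residence time (100 s of
physical time at full scale) with the binding attraction active for bound
PREs, sampling configurations at regular intervals, (iii) clear the
occupancy.  Averages are taken over uncorrelated snapshots *and* repeated
occupancy draws at fixed ``pb_pre``.

Drivers reproduce the study designs: the pb_pre folding scan (relative locus
volume V/Vref against a PRE-free reference), the epsilon scan at pb_pre = 1
(distance maps, with epsilon = 0 as negative control), the
replication-dilution experiment (folding under 50% / 25% demethylation), the
PRE-repositioned *inv-en* layout, and the no-PRE / no-methylation controls.

Full-scale settings (150-400 replicates, 100 s cycles ~ 4e8 MD steps) match
the original HPC runs; the ``scale`` multiplier and desk-scale defaults make
the same pipeline runnable on one CPU with qualitatively preserved ordering
of conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import topology as tp
from .analysis import DistanceMap, distance_map, locus_volumes, summarize, boxplot_stats
from .dynamics import DynamicsParams, SystemState, Trajectory, run
from .forcefield import ForceFieldParams
from .prep import prepare


@dataclass(frozen=True)
class ExperimentPlan:
    """Conditions and problem sizes for the MC-MD experiments."""

    pb_pre_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)
    eps_values: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.1, 6.2)
    dilution_fractions: tuple[float, ...] = (0.0, 0.25, 0.5)   # fraction of METH removed
    dilution_pb_values: tuple[float, ...] = (0.89, 0.98, 0.997)
    replicates: int = 12
    cycle_duration_s: float = 100.0
    cycles_per_replicate: int = 5
    scale: float = 0.0024           # step-count multiplier; 1.0 = full scale
    equil_steps: int = 200_000
    sample_stride: int = 20_000
    discard_fraction: float = 0.5   # initial fraction of each cycle's samples dropped
    n_beads: int = 360
    pre_indices: tuple[int, ...] | None = None
    volume_fraction: float = 0.026
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.pb_pre_values + self.dilution_pb_values:
            if not 0.0 <= p <= 1.0:
                raise ValueError("binding probabilities must lie in [0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for interval estimates")

    @property
    def cycle_steps(self) -> int:
        return DynamicsParams().steps_for_seconds(self.cycle_duration_s, self.scale)

    def with_(self, **kw) -> "ExperimentPlan":
        return replace(self, **kw)


def _replicate_seeds(plan: ExperimentPlan, salt: int = 0) -> list[int]:
    root = np.random.SeedSequence([plan.seed, salt])
    return [int(s % (2 ** 31)) for s in root.generate_state(plan.replicates, np.uint32)]


def mcmd_cycle(state: SystemState, topo: tp.PolymerTopology, pb_pre: float,
               ffp: ForceFieldParams, dp: DynamicsParams, plan: ExperimentPlan,
               rng=None) -> tuple[Trajectory, tp.PolymerTopology]:
    """One occupancy draw + dynamics round; returns samples and the drawn topology.

    The state is advanced in place; occupancy is conceptually cleared at the
    cycle end (the returned topology records what was drawn).
    """
    if rng is None:
        rng = np.random.default_rng(state.next_seed())
    drawn = tp.assign_prc1(topo, pb_pre, rng)
    traj = run(state, drawn, ffp, dp, plan.cycle_steps, plan.sample_stride)
    return traj, drawn


def _cycles_volumes(state, topo, pb_pre, ffp, dp, plan) -> np.ndarray:
    """Locus volumes pooled over cycles, dropping each cycle's transient."""
    vols = []
    for _ in range(plan.cycles_per_replicate):
        traj, drawn = mcmd_cycle(state, topo, pb_pre, ffp, dp, plan)
        v = locus_volumes(traj, drawn)
        vols.append(v[int(plan.discard_fraction * v.size):])
    return np.concatenate(vols)


def _prepared_state(topo, ffp, dp, plan, seed) -> SystemState:
    return prepare(topo, ffp, dp, seed, volume_fraction=plan.volume_fraction,
                   equil_steps=plan.equil_steps)


def _base_topologies(plan: ExperimentPlan):
    main = tp.build_default(plan.n_beads, list(plan.pre_indices) if plan.pre_indices else None)
    ref = tp.build_default(plan.n_beads, [])          # no-PRE reference
    return main, ref


def reference_volumes(plan: ExperimentPlan, ffp: ForceFieldParams, dp: DynamicsParams,
                      seeds=None) -> np.ndarray:
    """Per-replicate mean locus volume of the PRE-free reference polymer."""
    _, ref = _base_topologies(plan)
    if seeds is None:
        seeds = _replicate_seeds(plan, salt=999)
    out = []
    for seed in seeds:
        state = _prepared_state(ref, ffp, dp, plan, seed)
        v = _cycles_volumes(state, ref, 0.0, ffp, dp, plan)
        out.append(v.mean())
    return np.array(out)


def run_pbpre_scan(plan: ExperimentPlan, ffp: ForceFieldParams = ForceFieldParams(),
                   dp: DynamicsParams = DynamicsParams(),
                   topo: tp.PolymerTopology | None = None,
                   v_ref: float | None = None) -> pd.DataFrame:
    """V/Vref across the pb_pre grid; one row per (pb_pre, replicate).

    ``v_ref`` (mean reference volume) is computed from PRE-free reference
    runs when not supplied.
    """
    main, _ = _base_topologies(plan)
    if topo is not None:
        main = topo
    if v_ref is None:
        v_ref = float(reference_volumes(plan, ffp, dp).mean())
    rows = []
    seeds = _replicate_seeds(plan, salt=1)
    for rep, seed in enumerate(seeds):
        state = _prepared_state(main, ffp, dp, plan, seed)
        for pb in plan.pb_pre_values:
            s = state.copy()
            s.seed_seq = np.random.SeedSequence([seed, int(1e6 * pb)])
            v = _cycles_volumes(s, main, pb, ffp, dp, plan)
            rows.append({"pb_pre": pb, "replicate": rep, "V": float(v.mean()),
                         "V_over_Vref": float(v.mean() / v_ref), "Vref": v_ref})
    return pd.DataFrame(rows)


def summarize_scan(df: pd.DataFrame, by: str = "pb_pre") -> pd.DataFrame:
    """Mean V/Vref with 95% t-intervals per condition."""
    rows = []
    for key, sub in df.groupby(by):
        mean, (lo, hi) = summarize(sub["V_over_Vref"].to_numpy())
        rows.append({by: key, "mean": mean, "ci_low": lo, "ci_high": hi,
                     "n": len(sub)})
    return pd.DataFrame(rows)


def run_eps_scan(plan: ExperimentPlan, ffp: ForceFieldParams = ForceFieldParams(),
                 dp: DynamicsParams = DynamicsParams(),
                 topo: tp.PolymerTopology | None = None):
    """Distance maps per epsilon at pb_pre = 1 (epsilon = 0 = negative control).

    Returns ``(maps, volumes)``: a dict epsilon -> DistanceMap over all
    replicate snapshots, and a tidy per-replicate volume frame.
    """
    main, _ = _base_topologies(plan)
    if topo is not None:
        main = topo
    maps: dict[float, DistanceMap] = {}
    rows = []
    seeds = _replicate_seeds(plan, salt=2)
    for rep, seed in enumerate(seeds):
        state = _prepared_state(main, ffp, dp, plan, seed)
        for eps in plan.eps_values:
            p = ffp.with_(bind_eps=float(eps))
            s = state.copy()
            s.seed_seq = np.random.SeedSequence([seed, int(1e3 * eps)])
            frames = []
            vols = []
            for _ in range(plan.cycles_per_replicate):
                traj, drawn = mcmd_cycle(s, main, 1.0, p, dp, plan)
                keep = slice(int(plan.discard_fraction * traj.n_frames), None)
                frames.append(traj.positions[keep])
                vols.append(locus_volumes(traj, drawn)[keep])
            sub = Trajectory(np.concatenate(frames), np.concatenate(frames) * 0,
                             np.zeros(sum(f.shape[0] for f in frames)),
                             np.zeros(sum(f.shape[0] for f in frames)), s.box_side)
            m = distance_map(sub, main, condition={"eps": eps})
            maps[eps] = m.combine(maps[eps]) if eps in maps else m
            rows.append({"eps": eps, "replicate": rep,
                         "V": float(np.concatenate(vols).mean())})
    return maps, pd.DataFrame(rows)


def run_dilution(plan: ExperimentPlan, ffp: ForceFieldParams = ForceFieldParams(),
                 dp: DynamicsParams = DynamicsParams(),
                 v_ref: float | None = None):
    """Folding under post-replication dilution of methylated beads.

    For each (pb_pre, fraction removed) condition: V/Vref per replicate, a
    boxplot summary, and a two-sided Mann-Whitney p-value against the
    undiluted condition at the same pb_pre.
    """
    main, _ = _base_topologies(plan)
    if v_ref is None:
        v_ref = float(reference_volumes(plan, ffp, dp).mean())
    rows = []
    seeds = _replicate_seeds(plan, salt=3)
    for rep, seed in enumerate(seeds):
        for frac in plan.dilution_fractions:
            diluted = tp.demethylate(main, frac, np.random.default_rng([seed, int(100 * frac)]))
            state = _prepared_state(diluted, ffp, dp, plan, seed + int(1e4 * frac))
            for pb in plan.dilution_pb_values:
                s = state.copy()
                s.seed_seq = np.random.SeedSequence([seed, int(1e6 * pb), int(100 * frac)])
                v = _cycles_volumes(s, diluted, pb, ffp, dp, plan)
                rows.append({"pb_pre": pb, "fraction_removed": frac, "replicate": rep,
                             "V_over_Vref": float(v.mean() / v_ref)})
    df = pd.DataFrame(rows)
    summaries = []
    for (pb, frac), sub in df.groupby(["pb_pre", "fraction_removed"]):
        box = boxplot_stats(sub["V_over_Vref"].to_numpy())
        base = df[(df.pb_pre == pb) & (df.fraction_removed == 0.0)]["V_over_Vref"]
        if frac == 0.0 or base.empty:
            pval = np.nan
        else:
            pval = float(sps.mannwhitneyu(sub["V_over_Vref"], base,
                                          alternative="two-sided").pvalue)
        summaries.append({"pb_pre": pb, "fraction_removed": frac,
                          "p_vs_undiluted": pval, **box})
    return df, pd.DataFrame(summaries)


def run_controls(plan: ExperimentPlan, ffp: ForceFieldParams = ForceFieldParams(),
                 dp: DynamicsParams = DynamicsParams(),
                 pb_pre: float = 1.0, v_ref: float | None = None) -> pd.DataFrame:
    """No-PRE and no-methylation layouts: V/Vref should stay at 1.

    The controls are run at a strongly folding ``pb_pre`` so any residual
    attraction pathway would show up as a ratio below 1.
    """
    no_pre = tp.build_default(plan.n_beads, [])
    no_meth = tp.build_no_meth(plan.n_beads,
                               list(plan.pre_indices) if plan.pre_indices else None)
    if v_ref is None:
        v_ref = float(reference_volumes(plan, ffp, dp).mean())
    rows = []
    seeds = _replicate_seeds(plan, salt=4)
    for salt, (name, control) in enumerate((("no_pre", no_pre), ("no_meth", no_meth))):
        for rep, seed in enumerate(seeds):
            state = _prepared_state(control, ffp, dp, plan, seed + 131 * (salt + 1))
            v = _cycles_volumes(state, control, pb_pre, ffp, dp, plan)
            rows.append({"control": name, "replicate": rep,
                         "V_over_Vref": float(v.mean() / v_ref)})
    return pd.DataFrame(rows)


def run_inv_en(plan: ExperimentPlan, ffp: ForceFieldParams = ForceFieldParams(),
               dp: DynamicsParams = DynamicsParams(), pb_pre: float = 1.0,
               relative_positions=(0.02, 0.10, 0.90, 0.98)):
    """MC-MD on the *inv-en*-like PRE arrangement; returns (map, curves, valleys)."""
    from .analysis import pre_proximity_curves
    topo = tp.build_inv_en(relative_positions, plan.n_beads)
    seeds = _replicate_seeds(plan, salt=5)
    frames = []
    for seed in seeds:
        state = _prepared_state(topo, ffp, dp, plan, seed)
        for _ in range(plan.cycles_per_replicate):
            traj, _drawn = mcmd_cycle(state, topo, pb_pre, ffp, dp, plan)
            keep = slice(int(plan.discard_fraction * traj.n_frames), None)
            frames.append(traj.positions[keep])
    pooled = Trajectory(np.concatenate(frames), np.concatenate(frames) * 0,
                        np.zeros(sum(f.shape[0] for f in frames)),
                        np.zeros(sum(f.shape[0] for f in frames)), 0.0)
    dmap = distance_map(pooled, topo, condition={"layout": "inv-en", "pb_pre": pb_pre})
    curves, valleys = pre_proximity_curves(pooled, topo)
    return dmap, curves, valleys


def pre_background_gap(dmap: DistanceMap, topo: tp.PolymerTopology) -> pd.DataFrame:
    """PRE-PRE mean 3D distance vs the same-linear-separation background.

    For each PRE pair at linear separation s, the background is the mean map
    entry over all non-PRE-pair bead pairs (i, i+s) inside the methylated
    locus.  Negative ``gap`` = the off-diagonal-spot signature.
    """
    pres0 = np.flatnonzero(topo.types == tp.PRE)
    lo, hi = topo.methylated_range
    rows = []
    m = dmap.matrix
    for a in range(len(pres0)):
        for b in range(a + 1, len(pres0)):
            i, j = int(pres0[a]), int(pres0[b])
            s = j - i
            bg = []
            for k in range(lo - 1, hi - s):
                if k in pres0 and k + s in pres0:
                    continue
                bg.append(m[k, k + s])
            bg_mean = float(np.mean(bg))
            rows.append({"pre_i": i + 1, "pre_j": j + 1, "separation": s,
                         "pre_distance": float(m[i, j]), "background": bg_mean,
                         "gap": float(m[i, j]) - bg_mean})
    return pd.DataFrame(rows)
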