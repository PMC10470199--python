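"""Run configuration, XYZ trajectory serialization and test fixtures.

A ``RunConfig`` groups the force-field, dynamics, topology and experiment
plan blocks; it round-trips losslessly through JSON or YAML, fills defaults
for omitted keys, and rejects unknown keys by name.  Trajectories are
written as plain-text XYZ (one record per bead: type label, x, y, z in
sigma) with a comment line carrying step index, time and box side.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import box_side_for_concentration
from .dynamics import DynamicsParams, Trajectory
from .forcefield import ForceFieldParams
from .loopmodel import standard_configuration
from .mcmd import ExperimentPlan
from .topology import PolymerTopology, build_default


@dataclass(frozen=True)
class TopologyConfig:
    n_beads: int = 360
    methylated_range: tuple[int, int] | None = None   # default: middle third
    pre_indices: tuple[int, ...] | None = None        # default: even-spacing rule

    def build(self) -> PolymerTopology:
        return build_default(self.n_beads,
                             list(self.pre_indices) if self.pre_indices is not None else None)


@dataclass(frozen=True)
class RunConfig:
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    plan: ExperimentPlan = field(default_factory=ExperimentPlan)
    out_dir: str = "polyfold_out"
    seed: int = 0
    scale: float = 0.0024


_BLOCKS = {
    "forcefield": ForceFieldParams,
    "dynamics": DynamicsParams,
    "topology": TopologyConfig,
    "plan": ExperimentPlan,
}
_SCALARS = {"out_dir", "seed", "scale"}


def _build_block(cls, data: dict, block: str):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise KeyError(f"unknown key '{block}.{key}' in configuration")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[f.name] = v
    return cls(**coerced)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for key in list(data):
        if key in _BLOCKS:
            kwargs[key] = _build_block(_BLOCKS[key], data.pop(key) or {}, key)
        elif key in _SCALARS:
            kwargs[key] = data.pop(key)
    if data:
        raise KeyError(f"unknown key '{next(iter(data))}' in configuration")
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    out = {}
    for name, _cls in _BLOCKS.items():
        out[name] = dataclasses.asdict(getattr(cfg, name))
    for name in _SCALARS:
        out[name] = getattr(cfg, name)
    return out


def load_config(path) -> RunConfig:
    """Read a JSON/YAML config; omitted keys fall back to the study defaults."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, topo: PolymerTopology | None = None) -> None:
    labels = topo.labels() if topo is not None else ["BEAD"] * traj.positions.shape[1]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.positions.shape[1]}\n")
            fh.write(f"step={int(traj.step_index[f])} time_tau={traj.time_tau[f]:.10g} "
                     f"box={traj.box_side:.10g}\n")
            for lab, (x, y, z) in zip(labels, traj.positions[f]):
                fh.write(f"{lab} {x:.10g} {y:.10g} {z:.10g}\n")


def read_trajectory(path):
    """Read an XYZ trajectory; returns (Trajectory, per-bead labels)."""
    frames, steps, times = [], [], []
    box = 0.0
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nline = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected bead count, got {lines[i]!r}") from exc
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        steps.append(int(meta.get("step", nline)))
        times.append(float(meta.get("time_tau", 0.0)))
        box = float(meta.get("box", 0.0))
        frame = np.empty((n, 3))
        labs = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{i + 3 + k}: malformed record {lines[i + 2 + k]!r}")
            labs.append(parts[0])
            frame[k] = [float(p) for p in parts[1:]]
        frames.append(frame)
        labels = labs
        i += 2 + n
        nline += 1
    pos = np.array(frames)
    traj = Trajectory(pos, np.zeros_like(pos), np.array(steps),
                      np.array(times), box)
    return traj, labels


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0):
    """Deterministic miniature systems for tests and examples.

    kinds: ``chain60`` (60-mer, methylated core with 2 PREs),
    ``dimer-overlap`` (two beads at 0.5 sigma, for push-off),
    ``calibration-box-small`` (50 binders at 5 uM-equivalent concentration),
    ``loop-configs`` (the three standard loop-model arrangements).
    """
    if kind == "chain60":
        lo, hi = 20, 40
        pres = [lo + round(0.3 * (hi - lo)), lo + round(0.7 * (hi - lo))]
        return build_default(60, pres)
    if kind == "dimer-overlap":
        # 3-bead chain whose two chain ends overlap at ~0.06 sigma (a
        # non-bonded clash), for push-off tests
        from .dynamics import SystemState
        pos = np.array([[0.0, 0.0, 0.0], [0.97, 0.0, 0.0], [0.05, 0.03, 0.0]])
        topo = PolymerTopology(np.zeros(3, np.int64), np.zeros(3, np.bool_), (1, 3))
        state = SystemState(pos, np.zeros((3, 3)), 50.0,
                            seed_seq=np.random.SeedSequence(seed))
        return state, topo
    if kind == "calibration-box-small":
        from .calibration import CalibrationSetup
        n = 50
        return CalibrationSetup(
            n_particles=n,
            box_side=box_side_for_concentration(n, 5e-6),
            frames=120, replicates=2, sample_stride=4000, equil_steps=20_000,
        )
    if kind == "loop-configs":
        return [standard_configuration(i, seed=seed) for i in (1, 2, 3)]
    raise ValueError(f"unknown fixture kind {kind!r}")
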