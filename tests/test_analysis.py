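"""Observables: radius of gyration, distance maps, chain and summary statistics."""

import math

import numpy as np
import pytest

import polyfold as pf
from polyfold import analysis as an
from polyfold.dynamics import Trajectory


def _traj(frames, box=100.0):
    frames = np.asarray(frames, dtype=float)
    z = np.zeros(frames.shape[0])
    return Trajectory(frames, np.zeros_like(frames), z, z, box)


def test_radius_of_gyration_basics():
    assert an.radius_of_gyration(np.zeros((5, 3))) == 0.0
    two = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    assert an.radius_of_gyration(two) == pytest.approx(1.5)   # d/2
    with pytest.raises(ValueError):
        an.radius_of_gyration(two, indices=[])


def test_rg_rigid_motion_invariance():
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(20, 3))
    rg = an.radius_of_gyration(pos)
    # rotate about z by 0.7 rad and translate
    c, s = math.cos(0.7), math.sin(0.7)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    moved = pos @ R.T + np.array([5.0, -2.0, 1.0])
    assert an.radius_of_gyration(moved) == pytest.approx(rg, rel=1e-12)
    assert an.locus_volume(an.radius_of_gyration(moved)) == \
        pytest.approx(an.locus_volume(rg), rel=1e-12)


def test_locus_volume_and_ratio():
    assert an.locus_volume(1.0) == pytest.approx(4 * math.pi / 3)
    assert an.relative_volume(5.0, 5.0) == 1.0
    with pytest.raises(ValueError):
        an.relative_volume(1.0, 0.0)


def test_distance_map_straight_chain():
    n = 10
    b = 0.97
    frame = np.column_stack([b * np.arange(n), np.zeros(n), np.zeros(n)])
    m = an.distance_map(_traj([frame])).matrix
    i, j = np.indices((n, n))
    assert np.allclose(m, np.abs(i - j) * b)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)


def test_distance_map_averaging_is_associative():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(3, 8, 3))
    b = rng.normal(size=(5, 8, 3))
    combined = an.distance_map(_traj(a)).combine(an.distance_map(_traj(b)))
    pooled = an.distance_map(_traj(np.concatenate([a, b])))
    assert np.allclose(combined.matrix, pooled.matrix)
    assert combined.n_frames == pooled.n_frames == 8


def test_pre_proximity_curves_detect_clustered_pres():
    topo = pf.build_default(30, [12, 18])
    # line chain, but bead 18 (PRE, 1-based) folded back next to bead 12
    frame = np.column_stack([np.arange(30, dtype=float), np.zeros(30), np.zeros(30)])
    frame[17] = [11.2, 0.4, 0.0]
    curves, valleys = an.pre_proximity_curves(_traj([frame]), topo)
    assert curves[12][11] == 0.0                    # PRE distance to itself
    assert 18 in valleys[12]                        # valley at the other PRE
    # distances grow with linear separation on an unfolded chain
    assert curves[12][25] > curves[12][14]


def test_chain_stats_rigid_rod():
    n = 12
    frame = np.column_stack([0.97 * np.arange(n), np.zeros(n), np.zeros(n)])
    topo = pf.build_default(n, [])
    cs = an.chain_stats(_traj([frame, frame]), topo)
    assert cs.bond_length == pytest.approx(0.97)
    assert cs.persistence_length == math.inf       # no bending at all
    assert cs.n_bond_samples == 2 * (n - 1)


def test_summarize_interval():
    rng = np.random.default_rng(2)
    mean, (lo, hi) = an.summarize(rng.normal(10.0, 1.0, size=40))
    assert lo < mean < hi
    assert mean == pytest.approx(10.0, abs=0.6)
    m, (l, h) = an.summarize([3.0, 3.0, 3.0])
    assert (m, l, h) == (3.0, 3.0, 3.0)
    with pytest.raises(ValueError):
        an.summarize([1.0])


def test_summarize_coverage():
    """~95% of t-intervals over repeated normal samples cover the true mean."""
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(400):
        _, (lo, hi) = an.summarize(rng.normal(0.0, 1.0, size=10))
        hits += lo <= 0.0 <= hi
    assert 0.90 <= hits / 400 <= 0.99


def test_boxplot_stats_whisker_rule():
    values = [1.0, 2.0, 2.5, 3.0, 3.5, 4.0, 50.0]
    box = an.boxplot_stats(values)
    assert box["median"] == 3.0
    assert box["whisker_high"] == 4.0      # 50 is beyond 1.5 IQR
    assert box["outliers"] == [50.0]
    degenerate = an.boxplot_stats([2.0, 2.0, 2.0])
    assert degenerate["q1"] == degenerate["q3"] == degenerate["median"] == 2.0
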