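"""Polymer layouts, dilution, and the Monte Carlo occupancy assignment."""

import numpy as np
import pytest
from scipy import stats

import polyfold as pf
from polyfold.topology import METH, PRE, UNMETH


def test_default_layout_counts():
    topo = pf.build_default(360)
    assert topo.n_beads == 360
    assert topo.methylated_range == (120, 240)
    assert (topo.types == METH).sum() == 117
    assert (topo.types == PRE).sum() == 4
    assert (topo.types == UNMETH).sum() == 239
    assert topo.pre_indices == [132, 156, 204, 228]
    assert not topo.prc1_bound.any()
    # 360 nucleosomes x 175 bp ~= 63 kb of chromatin
    assert 360 * 175 / 1000 == pytest.approx(63.0)


def test_bonds_and_angles_counts():
    topo = pf.build_default(360)
    assert topo.bonds.shape == (359, 2)
    assert topo.angles.shape == (358, 3)


def test_no_pre_control_layout():
    topo = pf.build_default(360, [])
    assert (topo.types == PRE).sum() == 0
    assert (topo.types == METH).sum() == 121


def test_no_meth_control_layout():
    topo = pf.build_no_meth(360)
    assert (topo.types == METH).sum() == 0
    assert (topo.types == PRE).sum() == 4


def test_pre_outside_locus_rejected():
    with pytest.raises(ValueError, match="outside"):
        pf.build_default(360, [50])


def test_inv_en_placement():
    topo = pf.build_inv_en((0.02, 0.10, 0.90, 0.98))
    assert topo.pre_indices == [122, 132, 228, 238]


def test_inv_en_default_fractions_reproduce_default_layout():
    from polyfold.topology import DEFAULT_PRE_FRACTIONS
    assert pf.build_inv_en(DEFAULT_PRE_FRACTIONS).pre_indices == \
        pf.build_default(360).pre_indices


@pytest.mark.parametrize("fractions", [(0.0, 0.5, 0.6, 0.7), (0.1, 0.05, 0.6, 0.9)])
def test_inv_en_rejects_bad_fractions(fractions):
    with pytest.raises(ValueError):
        pf.build_inv_en(fractions)


def test_demethylate_counts_and_pre_protection():
    topo = pf.build_default(360)
    rng = np.random.default_rng(0)
    assert np.array_equal(pf.demethylate(topo, 0.0, rng).types, topo.types)
    gone = pf.demethylate(topo, 1.0, rng)
    assert (gone.types == METH).sum() == 0
    assert (gone.types == PRE).sum() == 4
    half = pf.demethylate(topo, 0.5, np.random.default_rng(1))
    # round-half-up of 0.5 * 117
    assert (half.types == METH).sum() == 117 - 59
    # deterministic given the seed
    again = pf.demethylate(topo, 0.5, np.random.default_rng(1))
    assert np.array_equal(half.types, again.types)


def test_assign_prc1_extremes():
    topo = pf.build_default(60, [26, 34])
    rng = np.random.default_rng(0)
    assert not pf.assign_prc1(topo, 0.0, rng).prc1_bound.any()
    assert pf.assign_prc1(topo, 1.0, rng).prc1_bound.sum() == 2
    with pytest.raises(ValueError):
        pf.assign_prc1(topo, 1.5, rng)


def test_assign_prc1_binomial_occupancy():
    """Mean bound fraction over many draws lies in the exact binomial 99% CI."""
    topo = pf.build_default(360)
    rng = np.random.default_rng(123)
    pb = 0.3
    n_draws = 10_000
    total = sum(pf.assign_prc1(topo, pb, rng).prc1_bound.sum() for _ in range(n_draws))
    n_trials = 4 * n_draws
    lo, hi = stats.binom.interval(0.99, n_trials, pb)
    assert lo <= total <= hi


def test_occupancy_draws_independent_across_pres():
    """Joint occupancy of two PREs matches independence (chi-square)."""
    topo = pf.build_default(60, [26, 34])
    rng = np.random.default_rng(7)
    counts = np.zeros((2, 2), dtype=int)
    for _ in range(4000):
        b = pf.assign_prc1(topo, 0.5, rng).prc1_bound
        counts[int(b[25]), int(b[33])] += 1
    _, p, _, _ = stats.chi2_contingency(counts)
    assert p > 0.001


def test_only_pre_beads_may_be_bound():
    types = np.array([UNMETH, METH, PRE], dtype=np.int64)
    bad = np.array([True, False, False])
    with pytest.raises(ValueError):
        pf.PolymerTopology(types, bad, (1, 3))


def test_topology_text_round_trip(tmp_path):
    from polyfold.topology import load_topology, save_topology
    topo = pf.assign_prc1(pf.build_default(60, [26, 34]), 1.0,
                          np.random.default_rng(0))
    path = tmp_path / "topo.tsv"
    save_topology(topo, path)
    back = load_topology(path)
    assert np.array_equal(back.types, topo.types)
    assert np.array_equal(back.prc1_bound, topo.prc1_bound)
    assert back.methylated_range == topo.methylated_range
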