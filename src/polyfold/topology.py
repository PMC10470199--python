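"""Polymer layouts and the Monte Carlo PRC1 occupancy assignment.

The default fiber is a 360-bead chain (about 63 kb of chromatin at 175 bp
per nucleosome) divided into three thirds: unmethylated flanks and a central
H3K27me3 block (beads 120..240, 1-based inclusive) containing a few
interspersed PREs.  Bead types:

* ``UNMETH`` -- nucleosome lacking H3K27me3,
* ``METH``   -- H3K27-trimethylated nucleosome,
* ``PRE``    -- Polycomb Response Element; may carry a PRC1-bound flag.

PRE beads are not themselves methylated: they neither attract nor are
attracted except through the (PRC1-bound PRE <-> methylated) term, so the
model provides no direct PRE-PRE interaction.

All public indices (``pre_indices``, ``methylated_range``) are 1-based
inclusive, matching the usual nucleosome-counting convention; internal
arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNMETH, METH, PRE = 0, 1, 2
TYPE_LABELS = {UNMETH: "UNMETH", METH: "METH", PRE: "PRE"}
LABEL_TYPES = {v: k for k, v in TYPE_LABELS.items()}

#: default PRE placement: fractions of the methylated span, measured from its
#: left edge (placement rule: index = lo + round(f * (hi - lo)))
DEFAULT_PRE_FRACTIONS = (0.1, 0.3, 0.7, 0.9)


@dataclass
class PolymerTopology:
    """Bead types, PRE occupancy flags, and the bonded structure of one chain."""

    types: np.ndarray                      # int array of UNMETH/METH/PRE codes
    prc1_bound: np.ndarray                 # bool per bead; True only on PREs
    methylated_range: tuple[int, int]      # 1-based inclusive locus interval
    chain: bool = True                     # False -> unbonded particle gas

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=np.int64)
        self.prc1_bound = np.asarray(self.prc1_bound, dtype=np.bool_)
        if self.n_beads < 3:
            raise ValueError("need at least 3 beads")
        if self.prc1_bound.shape != self.types.shape:
            raise ValueError("prc1_bound and types must have the same length")
        if np.any(self.prc1_bound & (self.types != PRE)):
            raise ValueError("only PRE beads may carry a PRC1-bound flag")

    # -- structure ---------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return int(self.types.shape[0])

    @property
    def bonds(self) -> np.ndarray:
        if not self.chain:
            return np.empty((0, 2), dtype=np.int64)
        n = self.n_beads
        return np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)

    @property
    def angles(self) -> np.ndarray:
        if not self.chain:
            return np.empty((0, 3), dtype=np.int64)
        n = self.n_beads
        return np.column_stack(
            [np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)]
        ).astype(np.int64)

    # -- masks and index views ---------------------------------------------
    @property
    def pre_indices(self) -> list[int]:
        """1-based indices of PRE beads."""
        return [int(i) + 1 for i in np.flatnonzero(self.types == PRE)]

    @property
    def methyl_mask(self) -> np.ndarray:
        return self.types == METH

    @property
    def bound_pre_mask(self) -> np.ndarray:
        return self.prc1_bound.copy()

    @property
    def locus_slice(self) -> slice:
        """0-based slice over the methylated locus interval."""
        lo, hi = self.methylated_range
        return slice(lo - 1, hi)

    def copy(self) -> "PolymerTopology":
        return PolymerTopology(self.types.copy(), self.prc1_bound.copy(),
                               self.methylated_range, self.chain)

    def labels(self) -> list[str]:
        """Per-bead labels; bound PREs are tagged ``PREB``."""
        out = []
        for t, b in zip(self.types, self.prc1_bound):
            out.append("PREB" if b else TYPE_LABELS[int(t)])
        return out


def _place_by_fractions(lo: int, hi: int, fractions) -> list[int]:
    return [lo + int(round(f * (hi - lo))) for f in fractions]


def build_default(n: int = 360, pre_indices=None) -> PolymerTopology:
    """Default three-section layout: UNMETH flanks, central METH block, PREs inside.

    The methylated locus spans the middle third (beads ``n/3 .. 2n/3``,
    1-based; 120..240 for the 360-mer).  ``pre_indices`` (1-based) must lie
    inside the locus; the default places 4 PREs at fractions
    ``DEFAULT_PRE_FRACTIONS`` of the locus span (132, 156, 204, 228 for the
    360-mer).  Pass an empty list for the no-PRE control layout.
    """
    lo = n // 3
    hi = 2 * n // 3
    if pre_indices is None:
        pre_indices = _place_by_fractions(lo, hi, DEFAULT_PRE_FRACTIONS)
    types = np.full(n, UNMETH, dtype=np.int64)
    types[lo - 1:hi] = METH
    for i in pre_indices:
        if not (lo <= i <= hi):
            raise ValueError(f"PRE index {i} outside the methylated region [{lo}, {hi}]")
        types[i - 1] = PRE
    return PolymerTopology(types, np.zeros(n, dtype=np.bool_), (lo, hi))


def build_no_meth(n: int = 360, pre_indices=None) -> PolymerTopology:
    """Control layout: PREs present but no methylated beads (locus unmethylated)."""
    topo = build_default(n, pre_indices)
    types = topo.types.copy()
    types[types == METH] = UNMETH
    return PolymerTopology(types, topo.prc1_bound.copy(), topo.methylated_range)


def build_inv_en(relative_positions=(0.02, 0.10, 0.90, 0.98), n: int = 360) -> PolymerTopology:
    """PRE layout mimicking the *inv-en* locus: PREs near the locus edges.

    ``relative_positions`` are increasing fractions in (0, 1) of the
    methylated-locus span; each maps to bead ``lo + round(f * (hi - lo))``.
    The default fractions are read-from-figure approximations of the
    *inv-en* PRE arrangement (two PREs close to each domain edge).
    """
    fr = list(relative_positions)
    if any(not (0.0 < f < 1.0) for f in fr):
        raise ValueError("relative positions must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("relative positions must be strictly increasing")
    lo = n // 3
    hi = 2 * n // 3
    return build_default(n, _place_by_fractions(lo, hi, fr))


def demethylate(topo: PolymerTopology, fraction_replaced: float, rng) -> PolymerTopology:
    """Replace a random fraction of METH beads with UNMETH (post-replication dilution).

    Exactly ``round(fraction * n_meth)`` uniformly chosen methylated beads
    (round-half-up) are converted; PREs are untouched.  Deterministic given
    the ``rng`` state.
    """
    if not 0.0 <= fraction_replaced <= 1.0:
        raise ValueError("fraction_replaced must be in [0, 1]")
    rng = np.random.default_rng(rng)
    out = topo.copy()
    meth = np.flatnonzero(out.types == METH)
    k = int(np.floor(fraction_replaced * meth.size + 0.5))
    if k:
        chosen = rng.choice(meth, size=k, replace=False)
        out.types[chosen] = UNMETH
    return out


def assign_prc1(topo: PolymerTopology, pb_pre: float, rng) -> PolymerTopology:
    """Monte Carlo PRC1 occupancy: each PRE independently bound with ``pb_pre``.

    Draws are made in ascending bead order (one uniform per PRE, bound if
    ``r < pb_pre``) so a given rng state maps to exactly one occupancy
    pattern.
    """
    if not 0.0 <= pb_pre <= 1.0:
        raise ValueError("pb_pre must be a probability")
    rng = np.random.default_rng(rng)
    out = topo.copy()
    out.prc1_bound[:] = False
    for i in np.flatnonzero(out.types == PRE):
        out.prc1_bound[i] = rng.random() < pb_pre
    return out


def clear_prc1(topo: PolymerTopology) -> PolymerTopology:
    out = topo.copy()
    out.prc1_bound[:] = False
    return out


def save_topology(topo: PolymerTopology, path) -> None:
    """Write the tabular text form: 1-based index, type label, bound flag."""
    with open(path, "w") as fh:
        fh.write(f"# methylated_range {topo.methylated_range[0]} {topo.methylated_range[1]}\n")
        fh.write("index\ttype\tbound\n")
        for i, (t, b) in enumerate(zip(topo.types, topo.prc1_bound), start=1):
            fh.write(f"{i}\t{TYPE_LABELS[int(t)]}\t{int(b)}\n")


def load_topology(path) -> PolymerTopology:
    types, bound = [], []
    mrange = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# methylated_range"):
                _, _, lo, hi = line.split()
                mrange = (int(lo), int(hi))
                continue
            if not line or line.startswith("index"):
                continue
            _, label, b = line.split("\t")
            types.append(LABEL_TYPES[label])
            bound.append(bool(int(b)))
    if mrange is None:
        raise ValueError(f"{path}: missing methylated_range header")
    return PolymerTopology(np.array(types), np.array(bound), mrange)
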