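# polyfold

Monte Carlo–molecular dynamics (MC–MD) simulations of how Polycomb proteins
translate H3K27 trimethylation into chromatin folding.

Polycomb-repressed genes in *Drosophila* are embedded in broad
H3K27me3-methylated chromatin domains and carry Polycomb Response Elements
(PREs) that stably bind Polycomb Repressive Complex 1 (PRC1). `polyfold`
implements a coarse-grained model asking whether *stochastic* PRC1 occupancy
of PREs, combined with the weak affinity of PRE-anchored PRC1 for
H3K27me3 nucleosomes, suffices to fold the methylated locus — and why that
folding makes PREs cluster in space.

## The model

The chromatin fiber is a Kremer–Grest-style bead–spring polymer of N = 360
nucleosome-sized beads (σ = 10 nm ≈ 175 bp; the chain ≈ 63 kb), with

- FENE bonds: V(r) = −½ K_s (R₀/σ)² ln[1 − (r/R₀)²], K_s = 30 k\_BT,
  R₀ = 1.5 σ (mean bond ≈ 0.97 σ),
- bending: V(θ) = K_θ (1 − cos θ), K_θ = 3 k\_BT (persistence length
  l_p = K_θ σ/k\_BT = 3 σ in theory, ≈ 2.7 σ measured),
- WCA excluded volume (truncated-shifted Lennard-Jones, ε_ev = 1 k\_BT),
- a truncated Lennard-Jones **attraction of strength ε acting only between
  PRC1-bound PREs and methylated beads** (range r_int = 2.5 σ),

integrated with velocity-Verlet Langevin dynamics (Γ = 0.5 τ⁻¹,
Δt = 0.012 τ, τ = σ²/D = 20 µs) in a periodic box at the nuclear volume
fraction (360/24³ = 0.026). The MC–MD protocol alternates a Monte Carlo
draw — each PRE independently PRC1-bound with probability p_b^PRE — with a
dynamics round lasting the PRC1 residence time (100 s), then redraws.

The attraction ε is calibrated against dissociation constants two ways:
analytically through K_D = c₀ e^{E_b/k_BT} with E_b ≈ −0.938 ε and the
standard state c₀ = 1/(N_A σ³) ≈ 1.66 mM (giving ε = 6.20 k\_BT at
K_D = 5 µM), and by a many-particle binding simulation whose bound fraction
crosses ½ at ε ≈ 3.94 k\_BT; their mean, ε ≈ 5.1 k\_BT, drives the
chromatin runs. Folding is read out as the locus volume V = 4πR_g³/3
relative to a PRE-free reference (V/V_ref), from mean pairwise-distance
maps, and from per-PRE proximity curves. An analytic anchored-loop model
(Gaussian/half-Gaussian loop lengths) explains the emergent PRE clustering.

## Worked example

`examples/loop_clustering.py` runs the anchored-loop model for the three
standard anchor arrangements:

```
configuration                mean |l1 - l2|   closed form
1: both anchors free          2.007 +/- 0.004    2.000
2: left anchor inward-only    1.766 +/- 0.004    1.761
3: both anchors inward-only   1.523 +/- 0.003    1.521
```

Two anchors (PRC1-bound PREs) sit 2 line-units apart and form Gaussian
loops (σ_l = 0.3); anchors flanked by non-sticky (unmethylated) chromatin
can only loop inward, which pulls the mean anchor distance from 2.00 down
to 1.76 (one restricted anchor) and 1.52 (both restricted) — PREs near the
edges of a methylated domain cluster hardest.

Other examples, one per capability: `examples/calibrate_affinity.py` (the
K_D ↔ ε calibration, both routes — prints the ε ≈ 3.96 simulation crossing
and the 6.20 closed form), `examples/fold_locus.py` (a desk-scale p_b^PRE
folding scan where V/V_ref drops from ≈ 1 at p_b^PRE = 0 to ≈ 0.07 on the
fully-occupied fixture chain), `examples/dilution_after_replication.py`
(folding with 50% of the methylation removed), and
`examples/inv_en_clustering.py` (PRE–PRE distances vs the same-separation
background for an edge-heavy PRE arrangement). A thin CLI exposes the same
drivers (`polyfold scan-pb`, `calibrate-sim`, `loop-model`, ...); run
`polyfold --help`.

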