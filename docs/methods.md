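# Methods

## Model

Chromatin is a semi-flexible, self-avoiding bead–spring chain of
nucleosome-sized beads (σ = 10 nm ≈ 175 bp). Bead types are UNMETH
(unmethylated nucleosome), METH (H3K27me3 nucleosome) and PRE (Polycomb
Response Element); a PRE additionally carries a boolean PRC1-occupancy
flag. The default 360-mer has unmethylated flanks and a central methylated
locus (beads 120–240, 1-based) containing four PREs at fractions
(0.1, 0.3, 0.7, 0.9) of the locus span (beads 132, 156, 204, 228); the
*inv-en*-like variant moves them to (0.02, 0.10, 0.90, 0.98) — fractions
read from the locus map, hence approximate and configurable.

Interactions (reduced units: σ = k_BT = m = τ = 1):

| term | form | default | notes |
|---|---|---|---|
| stretching | FENE, −½K_s(R₀/σ)² ln(1−(r/R₀)²) | K_s = 30, R₀ = 1.5σ | diverges at R₀; mean bond ≈ 0.97σ |
| bending | K_θ(1−cos θ) | K_θ = 3 | θ between successive bonds; l_p = K_θσ in theory |
| excluded volume | WCA (LJ cut at 2^{1/6}σ, shifted) | ε_ev = 1 | applied to **all** pairs, bonded included (Kremer–Grest convention) |
| binding | LJ cut at r_int, shifted to 0 there | ε = 5.1, r_int = 2.5σ | only between PRC1-bound PREs and METH beads |
| push-off | A(1+cos πr/r_c) | A ramps 0→40, r_c = 2.5σ | preparation only; replaces WCA during the ramp |

PREs are not themselves methylated: they neither attract each other nor
unmethylated beads, so the model contains no direct PRE–PRE interaction —
essential for interpreting the clustering result. The WCA term and the
binding term are summed for attracting pairs (their repulsive cores add;
this shifts the contact distance slightly but keeps one uniform excluded
volume for all pairs).

## Dynamics

Langevin equation m r̈ = −mΓṙ + F + W integrated by velocity Verlet with a
Langevin thermostat: per step one Gaussian force of per-component variance
2mΓk_BT/Δt is drawn and applied in both half-kicks together with the
instantaneous friction −mΓv. Drawing the noise once per step makes the
step free of hidden state, so short runs compose exactly like long runs
(important for MC–MD cycling) and Γ = 0 with noise off reduces to plain
velocity Verlet (energy drift < 10⁻³ relative over 10⁴ steps in the tests).
Defaults Γ = 0.5 τ⁻¹, Δt = 0.012 τ.

The physical time unit comes from the bead diffusion constant:
τ = σ²/D = (10 nm)²/(5 µm²/s) = 20 µs, so one step is 0.24 µs and a 100 s
PRC1 residence time is ≈ 4.2 × 10⁸ steps at full scale. Γ and Δt are taken
as primary; the Einstein relation D = k_BT/(mΓ) in reduced units (D = 2)
is *not* forced to agree with the physical D used for the time mapping —
the two published relations are mutually inconsistent, so the code reports
the implied reduced diffusion constant and treats duration as a parameter
(`steps_for_seconds(seconds, scale)`).

Pair forces are evaluated under the minimum-image convention in a cubic
periodic box; coordinates are kept unwrapped (the chain never spans the box
at the simulated density) and all analysis uses unwrapped coordinates.
Forces run either over all pairs or over a Verlet pair list (cutoff
max(2^{1/6}σ, r_int) + 0.3σ skin, rebuilt when any bead has moved half the
skin); both paths produce bitwise-identical forces and the list is the
default above 128 beads. A cell list was not needed at these system sizes
(≤ 450 particles).

## Preparation

1. Random-walk placement (bond 0.97σ) in a box 4× the target side — large
   enough to avoid wrap-around contacts, otherwise arbitrary.
2. Soft push-off: WCA replaced by the bounded cosine potential, amplitude
   ramped 0→40 k_BT over 10³ steps (the exact ramp length is not critical
   and is configurable), followed by a zero-temperature damped descent
   until no **non-bonded** pair is closer than σ. Bonded pairs equilibrate
   near 0.97σ < σ by construction, so the overlap-free criterion applies to
   non-bonded pairs only.
3. Compression: geometric affine rescale of box and coordinates over ~500
   steps to the target side L = (N/0.026)^{1/3} (24σ for the 360-mer),
   matching the nuclear volume fraction (0.026 vs 0.021 estimated for the
   fly nucleus).
4. Equilibration with the attraction off; the full-scale setting is 2 × 10⁶
   steps. Convergence diagnostic: stationarity of the locus R_g over the
   final stretch (warning if violated) — center-of-mass diffusion at these
   lengths is implied by the same time scale.

## MC–MD protocol

One cycle: draw each PRE's occupancy independently (bound if u < p_b^PRE,
ascending bead order for reproducibility), run Langevin dynamics for the
cycle duration with the binding term active for bound PREs, sample frames
at a fixed stride, clear the occupancy, repeat. Averages pool uncorrelated
frames across cycles and replicates at fixed p_b^PRE; the first half of
each cycle's samples is discarded as the post-redraw transient.
Re-inserting the pair potential at a cycle boundary changes the energy
discontinuously; with cycle lengths ≫ the local relaxation time this
transient is negligible (pathologically short cycles would parametrically
heat overlapped pairs — the test suite therefore probes occupancy
statistics with the attraction off).

V_ref is computed from runs of a no-PRE topology (not from p_b^PRE = 0 runs
of the main topology, though both are available and agree within CI).
Confidence intervals are Student-t over replicate means; boxplots report
median/IQR with 1.5·IQR whiskers; the dilution comparison uses a two-sided
Mann–Whitney test at α = 0.05 (the original analysis names no test).

## Binding calibration

Closed form: occupancy of a site at binder concentration c is
p_b = c/(c + K_D) with K_D = c₀ e^{E_b/k_BT}. The well depth
E_b = V_LJ(2^{1/6}σ) − V_LJ(cutoff) is −0.9385 ε at a 2.0σ cutoff and
−0.9837 ε at the dynamics range 2.5σ. The calibration chain that produces
the published numbers (ε = 6.20 k_BT at K_D = 5 µM, consensus 5.07 ≈ 5.1)
uses the 0.938 coefficient and c₀ = 1.67 mM, so `well_coeff = 0.938` and
the printed c₀ are the defaults, with the exact 2.5σ coefficient (0.9837)
and the exact c₀ = 1/(N_Aσ³) = 1.6605 mM selectable. Both discrepancies
(cutoff convention; 1.66 vs 1.67 mM rounding) are deliberate reproductions
of the printed chain, not oversights.

Simulation route: one immobile site, diffusing binders (WCA among
themselves, site attraction only; no occupancy cap, so multiple binders may
crowd the site — one reason this route crosses p_b = ½ near ε ≈ 3.9 while
the single-occupancy closed form gives 6.2). "Bound" means ≥ 1 binder
center within r_int of the site — the only length the interaction defines.
Frames are sampled every 10⁴ steps (site-occupancy decorrelation at the
relevant ε is a few 10³ steps). The full-scale condition is 450 particles
in a (52σ)³ box ≈ 5.3 µM; the desk-scale fixture keeps the 5 µM
concentration with 50 particles in a 25.5σ box, which preserves the
crossing (it depends on concentration and criterion, not box size, up to
small depletion corrections).

## Loop model

Two anchors at 0 and 2 draw loop lengths from N(l₀, σ_l); an anchor whose
outward flank is unmethylated ("non-sticky") draws from the half-Gaussian
toward the methylated side (implemented as |N(0, σ_l)|, distribution-
identical to rejection). The observable is E|l₁ − l₂|, with closed form
L − k σ_l √(2/π) for k inward-restricted anchors when L ≫ σ_l — the
analytic oracle for the sampler. σ_l defaults to 0.3 for the restricted
configurations because the published means (1.76, 1.52) equal the closed
form only at σ_l = 0.3, although σ_l = 0.2 is also printed alongside;
both are selectable and the conflict is documented rather than patched.

## Problem sizes in the tests and acceptance script

The full-scale experiments (360-mer, 150–400 replicates, 100 s ≈ 4 × 10⁸
step cycles) ran for days on HPC. The shipped test suite and
`scripts/acceptance.py` run the same pipeline at desk scale, chosen once:

- chain geometry: 60-mer fixture (20-bead methylated core, 2 PREs at beads
  26 and 34), 1.5 × 10⁵ equilibration + 1.8 × 10⁵ production steps,
  > 10⁵ bond samples;
- folding/clustering: p_b^PRE ∈ {0, 0.5, 1}, 6 replicates, two
  2.5 × 10⁵-step cycles each, no-PRE reference and both controls;
- calibration: 50 binders at 5 µM, ε grid 2–6 k_BT, 2 × 120 frames.

What desk scale does and does not show: orderings and qualitative
signatures are preserved (V/V_ref non-increasing in p_b^PRE, controls at 1,
PRE–PRE distances below the same-separation background, the calibration
crossing near 3.9), but absolute folded ratios are not comparable to the
full-scale 360-mer — the 20-bead locus with 2 PREs condenses almost
completely (V/V_ref ≈ 0.1) where the 121-bead locus with 4 PREs levels off
near 0.5, because a small locus fits entirely within the interaction shells
of its PREs. The synthetic chain also idealizes real chromatin: uniform
bead sizes, a single locus, no transcription/insulators/other binders, and
occupancy that is strictly independent across PREs and cycles.

## Numerical notes

- The truncated binding potential is continuous but its force jumps at
  r_int (inherent to truncation); finite-difference force checks skip the
  measure-zero shell around the cutoff.
- FENE overextension (r ≥ R₀) anywhere aborts the run naming the bond;
  non-finite coordinates abort naming the bead.
- Single global seeds expand to per-replicate/per-stage streams via
  `numpy.random.SeedSequence` spawning, so any replicate can be re-run
  independently and identical (seed, config) pairs give bitwise-identical
  trajectories.
- Persistence length is reported as −⟨b⟩/ln⟨cos θ⟩ (the designated
  estimator; ≈ 2.6–2.7σ at equilibrium), with an exponential fit of
  ⟨u_i·u_{i+s}⟩ over s ≤ 6 reported alongside (≈ 15% higher, picking up
  the excluded-volume-induced slow decay).
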