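# Methods

## Model

Each cell on the rostrocaudal axis carries a five-node regulatory network:
*Hoxa5* mRNA, Hoxa5 protein, *Hoxc8* mRNA, Hoxc8 protein, and a miRNA node
`mir_x`. Every species follows the same relaxation law

    dX_i/dt = γ_i · ( F(u_i) − X_i ),
    F(u)    = 1 / (1 + exp(−σ·u)),
    u_i     = b_i + Σ_j ω_{j→i} X_j + ω_{RA→i}·RA + ω_{FGF→i}·FGF,

with all activities dimensionless in [0, 1] and one time unit ≈ one day.
`F` is the logistic function; `σ` (shared) sets how switch-like responses
are, `b_i` is a basal offset inside the sigmoid argument, and the signed
coefficients `ω_{j→i}` encode activation (+) or repression (−). mRNA and
protein are separated for both Hox genes because the miRNA acts on
translation: candidate `mir_x` outputs target the protein nodes, while
morphogens and transcription-factor inputs target the mRNA nodes.

The basal (miRNA-free) wiring is: RA activates *hoxa5* transcription, FGF
activates *hoxc8* transcription, each mRNA drives its own protein, and
Hoxc8 protein weakly represses *hoxa5* transcription (the repression is
asymmetric; Hoxa5 does not inhibit Hoxc8).

## Morphogen field and noise

RA enters from the rostral boundary and FGF from the caudal boundary of a
unit-length axis discretised into 100 evenly spaced cells. Each profile is
the steady state of linear reaction-diffusion decay,
`M(x) = M0·exp(−d·√(k/D))` with `d` the distance from the source.
Extrinsic temporal noise multiplies each morphogen level by a factor drawn
uniformly from `(1−η, 1+η)`, redrawn every `1/ω` days (ω = 10/day),
independently per morphogen, per interval and per cell. Perturbations are
proportional to the mean level by construction; the uniform form and the
default amplitude η = 0.3 are package choices exposed as configuration.

## Simulation protocols

*Development*: all cells are first relaxed to the morphogen-free steady
state (tolerance 1e−6/day), then the noisy gradients are switched on and
the tissue is integrated for `t_dev` days. Replicates differ only in their
noise realisation; each replicate's generator is spawned from the master
seed so any replicate is reproducible in isolation.

*Differentiation*: a spatially homogeneous group of cells receives an RA
step only (FGF = 0), emulating RA-driven motor-neuron differentiation of an
ES-cell culture; each cell sees an independent noisy RA input. The "day 3"
read-out is taken one day after RA onset (RA is applied on day 2 of the
experimental protocol).

Integration is classical RK4 at a fixed step of 0.01 day. The morphogen
input is held constant within each step; because noise intervals (0.1 day)
are integer multiples of the step, the piecewise-constant forcing is
resolved exactly. Since `F ∈ (0,1)`, the unit box is forward-invariant and
trajectories of well-posed configurations remain in [0, 1].

## Boundary statistics

A cell *expresses* a protein when its level strictly exceeds 0.5 units.
Stacking replicates gives, per position, the occupancy: the fraction of
replicates expressing there. The *transition zone* is the envelope of
positions with occupancy strictly between 15% and 85%; its width Ω
measures roughness, and the expression boundary is the zone midpoint (for
a perfectly sharp profile, the midpoint between the adjacent high/low
cells). A boundary is reported only when the profile has both an
expressing (≥85%) and a non-expressing (≤15%) side; otherwise it is
undefined and any score using it is +∞. This guard matters in the topology
screen: wirings that abolish the Hoxa5 domain altogether would otherwise
obtain finite scores from sub-threshold occupancy blips.

The robustness score of a simulated tissue is the unweighted sum

    score = Ω_a5 + Ω_c8 + |Δ_{a5−c8}|,

where Δ is the distance between the two expression boundaries. Weights are
configurable but default to 1; lower is better. Δ enters in absolute
value, so the score does not depend on the axis orientation convention.

## Topology screen

Six candidate interactions involve `mir_x`: four inputs (RA, FGF, Hoxa5
protein, Hoxc8 protein → mir_x), each in {−1, 0, +1}, and two outputs
(mir_x → Hoxa5 protein, mir_x → Hoxc8 protein), each in {−1, 0} since a
miRNA can only repress translation. The Cartesian product gives
3⁴·2² = 324 topologies, enumerated in a fixed mixed-radix order. Each
topology's edges are added to the basal network at a common strength
(default 1.0), scored as the mean robustness score over 30 noisy
replicates, and ranked ascending with ties broken by canonical id. The
consensus is the set of signed edges identical and non-zero in every
topology of the top 2% (ceiling: 7 of 324). Per-topology seeds derive from
(master seed, topology id), so results are independent of evaluation
order. A strength sweep re-runs the screen at 0.2–1.2.

## Mutants

* `dicer_null` — the mir-x basal offset is set to −100, silencing its
  production; the node decays to ~0 dynamically.
* `mirx_fast` — the mir-x relaxation rate is multiplied by 10.
* `mirx_null` — all edges into and out of mir-x are removed and the node is
  clamped at 0; this is the "no miRNA node" idealisation used for the
  feed-forward delay analysis, distinct from the dynamic Dicer knockout.

## Calibration of the default parameters

The packaged config was calibrated against the qualitative phenotypes the
model is designed to exhibit: overlapping Hoxa5/Hoxc8 expression without the miRNA, a sharp
aligned boundary with the consensus circuit, the delayed Hoxa5 rise under
RA, broader early Hoxa5 distributions in Dicer-null cells, and recovery of
the three consensus interactions by the screen. The structure of the final
calibration matters more than the individual numbers:

* **Saturated direct arm.** At the wild-type boundary (mid-axis) the RA
  input to *hoxa5* transcription is strongly saturating, so the direct arm
  transmits little noise there; boundary placement is delegated to the
  miRNA arm. This is what makes the slow-versus-fast mir-x comparison
  informative: slow mir-x (γ = 0.5/day) time-averages ~20 noise intervals,
  the 10× mutant tracks them.
* **Caudal overshoot.** Without mir-x, Hoxa5's own activation threshold
  lies at ~0.66 of the axis while Hoxc8 switches on at 0.50, giving an
  overlap of ~16% of the axis — the miRNA-free co-expression phenotype,
  and the deterministic penalty (|Δ|) that a correct topology must remove.
* **Weak direct cross-repression.** The Hoxc8⊣*hoxa5* weight is token
  (−0.12). Strong cross-repression creates a band of positions where
  Hoxa5's fate follows Hoxc8, which lets many candidate topologies fake a
  sharp aligned boundary by merely relocating the Hoxc8 domain; with a
  single effective Hoxa5 threshold, only repression of Hoxa5 translation
  in the overlap zone — positioned by RA relief plus the Hoxc8 relay —
  removes the penalty.
* **Stiff Hoxc8 translation.** The c8 protein stage uses a large weight
  (10) and offset (−5), making Hoxc8 output switch-like in its mRNA. A
  unit-strength miRNA repression of Hoxc8 translation then barely moves
  the c8 boundary, so topologies built on mir-x⊣Hoxc8 (including
  latch-like mutual-repression loops) cannot relocate or sharpen it and
  rank poorly, consistent with the non-bistable character of the model.
* **Asymmetric gradients.** RA decays with length 0.4 of the axis, FGF
  with 0.12. Mid-axis FGF is therefore negligible, which makes the FGF
  input to mir-x useless for positioning the miRNA at the boundary — only
  the Hoxc8-protein relay can switch mir-x on exactly where the Hoxc8
  domain begins. The miRNA basal offset (0.6) is
  low enough that this relay is genuinely required, yet high enough that
  mir-x is ON everywhere before gradients appear (its "early" state).
* **Development time.** `t_dev` is 7 days so the slow miRNA transient
  (τ = 2 days) has decayed by the end-time snapshot; with shorter runs the
  leftover transient grants unrelated topologies a spurious Hoxa5
  repression. One corollary: mir-x is high across the whole axis early and
  restricted to the Hoxc8 domain late.

Tunable defaults (units of 1/day unless noted): σ = 5; γ = 5 for mRNAs and
proteins, 0.5 for mir-x; morphogen sources M0 = 5 (dimensionless);
RA k = 6.25, FGF k = 69.44, D = 1 length²/day; noise ω = 10/day, η = 0.3;
tissue 100 cells × 50 replicates. The differentiation protocol uses an RA
step of 1.2 with a 5-day course. All of these live in
`src/hoxmir/configs/default.yaml`, the single source of truth loaded by
`hoxmir.load_defaults()`.

## Analysis problem sizes

The screen scores each of the 324 topologies over 30 replicates of a
100-cell tissue (a few minutes on one core). The paired mutant comparison
uses ten seed batches of 60 replicates on a 200-cell tissue — the finer
grid halves the one-cell quantisation of Ω so that strict width
comparisons are well resolved. The early-dispersion analysis uses ten
batches of 200 cells. The feed-forward delay is deterministic (η = 0); its
analytic cross-check sets the mRNA relaxation to 500/day with a 0.001-day
step, where the Hoxa5 half-rise time approaches ln 2 / γ_protein.

## What the synthetic inputs do and do not capture

The generator reproduces the study conditions: steady exponential opposing
gradients with piecewise-constant multiplicative extrinsic noise. It does
not model intrinsic transcriptional bursting (noise enters only through
the morphogens), cell division or movement, gradient dynamics before
steady state, or 2D/3D geometry. Passing tests therefore demonstrate the
network-level noise-filtering logic under extrinsic input fluctuations,
not a quantitative fit to embryo or ES-cell data; absolute widths and
times depend on the calibrated config.

## Known limitations

* The score surface across topologies is shallow (many wirings are within
  a few cell-widths of each other); consensus extraction is reliable at
  30 replicates per topology but the identity of the single best topology
  fluctuates within the consensus family at smaller budgets, and at weak
  interaction strengths (≤0.4) the screen cannot pin the Hoxc8 input.
* Transition widths are quantised by the cell spacing; comparisons near
  one cell of difference require the finer 200-cell protocol.
* Quantitative outputs (widths, delays, variance ratios) are properties
  of the packaged calibration; a different calibration satisfying the same
  qualitative constraints would shift them.
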