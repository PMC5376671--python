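# hoxmir

Simulation of how a microRNA sharpens the Hoxa5/Hoxc8 expression boundary
in the developing spinal cord.

During rostrocaudal patterning, motor-neuron progenitors transcribe 3′
*Hox* genes noisily under opposing retinoic-acid (RA) and FGF gradients,
yet the Hoxa5/Hoxc8 protein boundary in postmitotic neurons is sharp and
precise. Loss of miRNA biogenesis (Dicer knockout) causes precocious,
fluctuating Hoxa5 protein and a ragged boundary. This package implements
the dynamical model behind that observation: a 1D tissue of cells, each
carrying a small gene network driven by noisy morphogen inputs, in which a
hypothetical miRNA (*mir-x*, experimentally *mir-27*) embeds Hoxa5 in a
pair of coherent feed-forward loops — RA activates *hoxa5* transcription
while repressing mir-x, and Hoxc8 maintains mir-x, which represses Hoxa5
translation. The slow miRNA arm delays Hoxa5 protein onset and filters
morphogen fluctuations, producing a robust boundary.

Every species follows sigmoidal-relaxation dynamics

    dX_i/dt = γ_i (F(u_i) − X_i),   F(u) = 1/(1+e^{−σu}),
    u_i = b_i + Σ_j ω_{j→i} X_j + ω_{RA→i} RA + ω_{FGF→i} FGF,

on a unit axis with steady exponential RA/FGF gradients subject to
piecewise-constant multiplicative noise (frequency 10/day, amplitude 30%).
Boundary quality is scored as Ω_a5 + Ω_c8 + |Δ|: the two transition-zone
widths (positions where 15–85% of replicate simulations express the
protein, at a 0.5-unit call) plus the distance between the two expression
boundaries. The package enumerates all 324 candidate mir-x wiring
diagrams (four signed inputs × two repressive outputs), ranks them by this
score under noise, and extracts the interactions shared by the top 2% —
recovering inhibition of mir-x by RA, activation of mir-x by Hoxc8, and
repression of Hoxa5 translation by mir-x. Mutant transformations
(Dicer-null, 10×-fast mir-x, mir-x deletion) reproduce the precocious
expression, early cell-to-cell dispersion and boundary roughening
phenotypes.

## Layout

- `src/hoxmir/` — the library: `network` (ODE core and mutants),
  `morphogen` (gradients and noise), `tissue` (development and
  differentiation protocols), `metrics` (boundary statistics),
  `screen` (324-topology screen), `runner` (validated experiment
  protocols), `configs/default.yaml` (the calibrated model).
- `analysis/01…05_*.py` — numbered drivers reproducing the in-silico
  analyses; each writes its tables under `results/`.
- `docs/methods.md` — model, assumptions, calibration rationale,
  limitations.

## Worked example

```
$ python analysis/01_develop_patterns.py 1
wild_type: width_a5=0.010 width_c8=0.020 delta=-0.015 score=0.045
dicer_null: width_a5=0.071 width_c8=0.020 delta=+0.106 score=0.197
dicer vs wt: d_width_a5=+0.061 d_score=+0.152
```

Under identical noise, the wild-type Hoxa5 transition zone spans one cell
(1% of the axis) and the two boundaries nearly coincide, while the
Dicer-null tissue's Hoxa5 zone is seven cells wide and its boundary
overshoots ~11% of the axis into the Hoxc8 domain — the rough, overlapping
boundary phenotype. The temporal counterpart:

```
$ python analysis/04_temporal_delay.py 1
wild_type: half_rise=2.45 d  day3 mean=0.050 var=0.0001
dicer_null: half_rise=0.59 d  day3 mean=0.550 var=0.0014
```

mir-x delays the half-rise of Hoxa5 protein by ~1.9 days and keeps the
day-3 across-cell variance an order of magnitude below the Dicer-null
culture, in which Hoxa5 is already high and broadly dispersed.
`analysis/02_topology_screen.py` runs the full screen (a few minutes) and
prints the three consensus interactions.

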