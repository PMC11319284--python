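# sanfib

Two-dimensional simulation of the human sinoatrial node (SAN) driving the
right atrium, with cellular heterogeneity and electrotonically coupled
fibroblasts.

## The problem

The SAN is a small, weakly coupled structure that must nevertheless impose
its rhythm on the large, well-coupled atrium — a severe source–sink
mismatch.  Anatomically the node is insulated from the atrium except at a
few discrete sinoatrial exit pathways (SEPs), and histology shows the node
packed with fibroblasts and strongly heterogeneous myocytes.  This package
reconstructs a tissue-scale model of that system for quantitative
questions: when does the node capture the atrium, with what safety margin,
how fast does it recover from overdrive pacing, and how do heterogeneity
and fibroblasts change the answers.

The model is a 200 × 200 Kirchhoff network of 67 µm cells (desk-scale
presets included): an elliptical SAN of full ionic pacemaker cells
(Fabbri–Wilders–Severi human SAN model) inside an insulating border,
20-cell-long exit pathways into an atrium of Nygren-type human atrial
myocytes, optional MacCannell-type active fibroblasts placed on the
measured density gradient (45.7 % central SAN → 0 ten cells past the
pathway exits), and log-normal conductance heterogeneity (σ = 0.2) on
eleven SAN parameters.  Gap-junctional coupling is ohmic: 1 GΩ between
nodal cells and fibroblasts, 1 MΩ in the atrium, with a sigmoidal
conductivity gradient S(x) = 1/R_RA + (1/R_SAN − 1/R_RA)/(1 + e^(−αx+β))
along each pathway, spread semicircularly into the atrium.  Everything is
integrated cell-by-cell with forward Euler at dt = 5 µs.

Key read-outs (see `docs/methods.md` for definitions): cycle length (CL)
and its dispersion σ_CL, the safety factor for conduction
SF = Q_gap / Q_thr at the leading pathway interface, the sinus-node
recovery time (SNRT) after 2 Hz overdrive pacing, pathway conduction
velocity/time, and activation-time maps.

## Worked example

Spontaneous rate of the single SAN cell and its autonomic/block responses:

```python
from sanfib.cellmodels import CellParams, Phenotype, spontaneous_cycle_length

base = CellParams(Phenotype.SAN)
print(spontaneous_cycle_length(base))                      # 813.5 (ms)
print(spontaneous_cycle_length(
    CellParams(Phenotype.SAN, block_fractions={"If": 0.5})))   # 911.6
print(spontaneous_cycle_length(
    CellParams(Phenotype.SAN, ach_concentration=25.0)))        # 1448.1
```

A desk-scale tissue run — uniform setup, one exit pathway — from the
command line:

```bash
sanfib run --setup U --condition control --scale strip --summary strip.csv
```

which prints a tidy table of the run's metrics (this is the actual output;
the run takes ~10 min on one CPU):

```
setup condition        metric  n        mean  sd      note
    U   control  atrial_cl_ms  1 1361.414786 NaN       NaN
    U   control     san_cl_ms  1  554.812366 NaN       NaN
    U   control safety_factor  1    1.707226 NaN       NaN
    U   control       outcome  1         NaN NaN 2:1-block
```

The node paces and captures every atrial cell, crossing the pathway in
about 0.4 s, but at this reduced scale the rhythm is a 2:1 exit block
(atrial cycle length about twice the nodal interval) rather than the
full-scale study's 1:1 driving — `docs/methods.md` explains the mechanism
and why it is reported rather than tuned away.  The safety factor at the
pathway interface is computed per beat from the interface gap-current
integral against the atrial threshold charge.  The same machinery runs
the full experiment matrix (`U/H/UF/HF` setups × control/ACh/ISO/pacing/
current-block/pathway-width conditions × seeds 1–5) via `sanfib suite`;
`--scale full` selects the study-scale 200 × 200, 50 s configuration
(hours of compute).  `sanfib maps` renders the cell-type and
coupling-conductance maps.

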