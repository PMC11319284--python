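# Methods

`sanfib` simulates a two-dimensional patch of human right-atrial tissue
containing the sinoatrial node (SAN), its insulating border, discrete
sinoatrial exit pathways (SEPs) into the atrium, and optional cellular
heterogeneity and electrotonically coupled fibroblasts.  This note records
the models, the numerical choices, and the places where the design was
genuinely open, in enough detail to reproduce or modify any of them.

## Cell models

Three phenotypes are integrated cell-by-cell; every cell is a full ionic
model, not a phenomenological oscillator.

**SAN myocyte** — the Fabbri–Wilders–Severi human SAN pacemaker model:
membrane currents If, INa, ICaL, ICaT, IKr, IKs, Ito, IKur, IKACh, INaK,
INaCa on a 57 pF membrane, compartmental Ca²⁺ handling (subspace,
myoplasm, junctional/network SR, four-state ryanodine-receptor scheme,
SERCA uptake) and six buffer occupancies; intracellular Na⁺ is clamped at
5 mM.  Our transcription is validated against four published single-cell
behaviours: baseline cycle length (CL) 813.5 ms (published 814), CL 911.6 ms
with 50 % If block (912), CL 1448.1 ms under 25 nM acetylcholine (1448), and
maximum diastolic potential −58.9 mV (−58.9).  Autonomic modulation follows
the model's published formulations: ACh shifts If activation (−6.4 mV at
25 nM), blocks a fraction of ICaL, reduces SERCA uptake and gates IKACh;
isoprenaline (on/off, saturating 1 µM) shifts If by +7.5 mV, raises ICaL by
23 % with a −8 mV activation shift, raises IKs by 20 % with a −14 mV shift,
and raises INaK and SERCA uptake by 20 %/25 %.  One ISO constant could not
be recovered from the published material offline — the factor by which the
ICaL activation slope changes — so it is pinned (0.7291) by requiring the
single-cell 1 µM ISO response to match the published CL of 639 ms.  With
both agonists active the parameter shifts combine additively on each
affected parameter.

**Atrial myocyte** — the Nygren et al. human atrial model (29 states,
50 pF): GHK-form INa with two inactivation gates, ICaL with Ca- and
voltage-dependent inactivation, It, Isus, IKr, IKs, IK1, pumps, exchanger
and background leaks; dynamic intracellular Na⁺/K⁺, a restricted
extracellular cleft, and a two-compartment SR.  This is the parent
formulation of the atrial model used in the study we reproduce (same INa
and the same 50 pF membrane); the descendant's spatial SR-Ca diffusion
scheme is not included.  A consequence we quantify rather than hide: at the
tissue's 1 MΩ atrial coupling this phenotype conducts at ≈37 cm/s with
native gNa and ≈54 cm/s with gNa doubled — exactly the √2 scaling of the
study's printed 70→100 cm/s crista-terminalis calibration, but at about
half the absolute speed.  Raising the Na⁺ permeability to force 70 cm/s is
not an option: beyond ≈2.5× the INa window current sustains a stable
depolarised equilibrium near −20 mV and the cell never repolarises (we
observed entire simulated atria freezing depolarised).  The published
permeability is therefore kept, and conduction velocities are reported as
computed.  The tissue-wide gNa doubling of the crista-terminalis
calibration *is* applied (engine default `atrial_gna_mult = 2.0`), with
atrial cells initialised from a steady state re-equilibrated at the doubled
conductance.

**Fibroblast** — a MacCannell-type active fibroblast (6.3 pF): a time- and
voltage-dependent K⁺ current (activation/inactivation gates), an inward
rectifier, Na⁺/K⁺ pump and background Na⁺ leak, with fixed intracellular
concentrations.  Two reconstruction choices were needed: the inward
rectifier conductance is read as 0.4822 nS *total* (0.0765 nS/pF), and the
background-Na conductance is set by requiring zero net current at the
model's published resting potential of −49.6 mV (giving 0.0105 nS/pF,
consistent with commonly quoted values).  The rest is a true, stable
steady state (verified against ±2–10 mV perturbations); the depolarised
rest is what lets coupled fibroblasts act as current sources for myocytes
hyperpolarised below −49.6 mV.

## Numerics

All integration is forward Euler at dt = 5 µs, matching the study design;
halving dt changes the single-cell CL by <0.5 %.  For speed, each model's
purely voltage-dependent terms (gate steady states/time constants as
`x' = a(V) − b(V)·x` pairs, GHK and exchanger exponentials) are
pre-tabulated on a 0.05 mV grid over [−100, +80] mV (float32) and linearly
interpolated; the closed-form right-hand sides are retained as reference
implementations and the tabulated kernels are pinned to them by tests
(relative agreement ≲2×10⁻³ on randomised states; CL agreement ≲0.02 ms).
Outside the physiological voltage range the tables clamp; stimuli that
would drive a cell far beyond +80 mV are outside the models' domain, so
the threshold-charge search caps its stimulus amplitudes accordingly and
concentration terms in saturating denominators are floored at zero (both
guards are inert in physiological regimes).  Recording follows the study:
full-grid voltages at 200 µs over the analysis window; pathway-interface
gap currents at integration resolution.

## Tissue generation

The SAN is a vertically elongated ellipse (semi-axes 75 × 12 cells at full
scale, 67 µm cells) inside an insulating ring, perforated by up to five
SEPs: 20-cell-long channels of nodal tissue (1.34 mm) of configurable
width (7/11/15/19), evenly spaced along the right border and numbered top
to bottom.  The mosaic option intersperses atrial-phenotype cells in the
channels with probability rising linearly from the nodal to the atrial
end.

**Fibroblast gradient.**  Each eligible cell is independently replaced by
a fibroblast with probability p(x): a plateau of 45.7 % across the SAN up
to two cells left of the ellipse's right edge, then a linear decline to
zero ten cells beyond the pathway exits; atrial cells are eligible only
inside the pathway row bands.  The plateau/zero anchors are the only free
parameters of the gradient and were chosen so the realised regional
fractions reproduce the study's histology-based 45.7 % (central SAN) and
27.7 % (pathways); with the anchors fixed the realised fractions follow
binomial statistics.

**Heterogeneity.**  Each SAN-phenotype cell draws an independent
multiplier for each of the 11 randomised parameters (PCaL, PCaT, gKr,
KNaCa, iNaK_max, gNa, gKs, gf, gto, gKur, Pup_basal) from a log-normal
distribution, `exp(N(0, σ²))` with σ = 0.2 — median 1, so the uniform
setup is the σ→0 limit.  The atrium carries no heterogeneity.  Setups:
U (neither), H (heterogeneity), UF (fibroblasts), HF (both); five named
seeds generate tissues #1–5.

**Coupling map.**  Cells carry a nominal coupling conductivity: 1/R_SAN
for nodal cells and 1/R_fib for fibroblasts (1 GΩ each by default), 1/R_RA
for atrial cells (1 MΩ).  Along each pathway the conductivity follows the
sigmoidal profile S(x) = 1/R_RA + (1/R_SAN − 1/R_RA)/(1 + e^(−αx+β)), with
x counted along the pathway axis pointing into the node; beyond the exit the profile continues as a function of radial
distance from the exit mouth (semicircular iso-contours), which is what
lets an excitation leave the pathway without being absorbed by the atrial
mass.  β (equivalently, the `center_offset` parameter) sets where the
midpoint sits; the per-edge conductance between neighbours is the mean of
the two cells' nominal values (see the design-decisions section).
Insulator faces carry zero conductance and the grid rim is no-flux.

## Protocols and analysis

Runs start from single-cell steady states (500 s at dt = 5 µs; SAN cells
snapshot at the upstroke dV/dt maximum so a uniform tissue starts phase
aligned) and the condition under study — 25 nM ACh, 1 µM ISO, If/ICaL
blocks — is installed on SAN cells only, from t = 0 (continuous
infusion).  Overdrive pacing stimulates a 15 × 15 atrial block in the
top-right corner at 2 Hz, 5 nA, 1 ms pulses (full scale: 32–41.5 s of a
50 s run, last 10 s analysed; scaled presets shift the same schedule
earlier).

Cycle lengths: atrial events are dV/dt maxima of upstrokes gated at
1 mV/ms; SAN events are overshoot peaks above 0 mV; atrial CLs are
averaged in time then across cells, the SAN reports the last CL of each
cell averaged across cells.  The safety factor for conduction is
SF = |∫Igap dt| / Qthr(ta) on the first atrial cells beyond the leading
pathway exit, with the integration window from the instant |Igap| reaches
1 % of its depolarising peak (pre-peak) to the next zero crossing, and
Qthr(ta) the single-cell threshold charge of the tissue's atrial phenotype
(bisection to 10⁻³ on constant-current stimuli), linear in duration and
saturated at its 4 ms value.  SNRT is the delay from the last pacing
stimulus to the first spontaneous atrial upstroke (stimulus-evoked
activity is excluded by a 200 ms window; the corrected SNRT subtracts the
basal CL, with >525 ms flagged as nodal dysfunction).  Conduction velocity
and time are measured along the leading pathway's centreline.  Setup
comparisons use two-sided paired t-tests, or one-sample t-tests against
the single uniform value, at α = 0.05.

## Scaled-down presets and problem sizes

The full-scale study tissue (200 × 200 cells, 50 s, five seeds per setup)
is expressible in configuration but is a multi-hour single-CPU
computation, so the package's default working scale is the `strip` preset:
a reduced elliptical SAN (semi-axes 15 × 11; ≈520 nodal cells, comparable
to the full-scale source mass per pathway), one full-length pathway, and a
≥30-cell-deep atrial field, on a 42 × 80 grid.  Tests and the acceptance
script run strips for 5–6 s and analyse the final seconds (3–5 beats);
single-cell checks use the full 500 s equilibration.  The `half` preset
(100 × 110, five pathways) sits in between.  Sigmoid midpoints are
recomputed per preset so the gradient keeps its position relative to each
pathway.

## What the generator does and does not emulate

The synthetic tissues reproduce the study's randomised inputs — log-normal
conductance heterogeneity of width 0.2, Bernoulli fibroblast placement on
the printed density gradient, the stylised ellipse-and-pathways anatomy —
under exactly the printed coupling resistances and protocols.  They do not
emulate histology-derived geometry, fibre orientation, transitional-cell
gradients, spatially varying autonomic receptor density, atrial
heterogeneity, or 3D structure; passing tests therefore establish the
faithfulness of the *model* reconstruction, not the physiology of any
real node.

## Design decisions taken where the source was open

* **Edge conductance rule.**  The coupling map defines a conductivity per
  cell; a network needs a value per edge.  Combining the two cells' values
  as series half-resistances biases every edge toward the weaker cell; in
  the exponential pathway gradient this starves the exit mouth of charge
  and no parameterisation we tested allowed the node to capture the
  atrium.  Averaging the two values (arithmetic mean) treats the map as a
  conductivity field sampled at cell centres and reproduces pace-and-drive
  behaviour; it is the default (`CouplingConfig.edge_rule`).
* **Sigmoid slope and midpoint.**  β is set per pathway so the profile
  midpoint sits at the channel centre plus `center_offset` cells.  The
  study prints α = 1 and β = 37 without defining the units of its x
  coordinate; in per-cell units we find (by systematic exploration) that a
  wave can only climb the conductance rise for α ≤ 0.5 per cell, and only
  when the rise sits beyond the pathway exit, among excitable atrial
  cells: midpoint placements inside the pathway create a ≥5-cell zone of
  chronically loaded (suppressed) pacemaker cells that no parameterisation
  crosses.  Defaults are α = 0.5, `center_offset` = 21 (midpoint 11 cells
  past the exit) and a 26-cell halo — the configuration at which the strip
  preset shows robust steady-state atrial capture with a pathway
  conduction time (~0.4 s) matching the study's printed table, *and* the
  study's pathway-width threshold: an 11-cell pathway drives the atrium
  while a 7-cell pathway paces without driving.
* **Phase convention.**  SAN steady states are returned at the upstroke
  dV/dt maximum so phase-aligned tissues can be built; any other
  convention washes out within a few beats.
* **Heterogeneous cells start from the baseline steady state** (not
  per-cell re-equilibrated); the tissue run itself provides wash-in.
* **ISO is boolean** (the model is calibrated to a saturating 1 µM
  exposure); intermediate concentrations are rejected.
* **Fibroblast coupling** stays at 1/R_fib everywhere, including inside
  pathways (the gradient applies to myocytes).
* **SF interface** is the first atrial-phenotype column beyond the exit,
  using the atrial threshold charge (a "full upstroke" is an atrial
  criterion); the leading pathway is the one whose interface activates
  earliest, ties broken toward the lowest number.
* **Pacing block at reduced scale** keeps the 15 × 15 block when the grid
  permits, otherwise the largest square that fits.

## Known limitations

* Conduction velocities in the atrium are about half the study's printed
  calibration (see the atrial model section); quantities that depend on
  absolute atrial CV inherit this scale.
* The scaled-down uniform tissue drives the atrium with a 2:1 exit-block
  rhythm (atrial CL ≈ 1.4 s instead of the printed 1:1 at 814 ms).  The
  mechanism is visible in the traces: the ~19 ms/cell crawl through the
  pathway staggers neighbouring APs into each pathway cell's diastole,
  which depolarises diastolic potentials and accelerates the proximal
  pathway into an ectopic focus (~460 ms period); its interposed beats
  reach the exit while the mouth cells are still in their (long, weakly
  coupled) plateau and block.  Every atrial cell is nevertheless captured,
  and a 7-cell pathway paces without driving, as in the study.  We found
  no configuration within the printed resistances that conducts 1:1 at
  the intrinsic rate at this scale; the corresponding acceptance checks
  are deliberately left failing rather than re-tuned.
* The full-scale n = 5 statistics of the study are not reproduced by the
  test suite; the machinery (experiment matrix, seeds, t-tests) is present
  and the full-scale configuration is one flag away, but it is a
  multi-hour run per tissue.
* Simulated electrograms are not implemented.
* Re-entry and exit-block phenomenology at reduced scale is qualitative:
  smaller tissues have fewer pathways and different wavelength-to-size
  ratios than the full-scale model.
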