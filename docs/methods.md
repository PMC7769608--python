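# Methods

## The model

`paracable` simulates saltatory conduction in small-calibre CNS myelinated
axons with a double-cable compartmental model and quantifies paranode
pathology from immunofluorescence line profiles. The axon is a chain of 21
nodes of Ranvier separated by internodes, each internode flanked by a
paranode (the axo-glial junction zone, passive membrane, very thin
peri-axonal space) and a juxtaparanode (fast-Kv1-rich membrane under
compact myelin). Seven fibre calibres are built in, with fibre diameters
d_fibre = 0.5–3.5 um and core diameters d_core = 0.4–2.7 um taken from
primate EM morphometry.

Geometry follows empirical scaling laws: node-to-node spacing
117.52 + 30.47 d_fibre um, juxtaparanode length 19.6 + 2.58 d_fibre um,
node 1 um, paranode 2.3 um (the mean Caspr1 band length in non-neurological
control tissue). The internode is the remainder after subtracting two
paranodes, two juxtaparanodes *and the node* from the node-to-node spacing,
so that compartments tile the spacing exactly (the node subtraction is our
choice; without it the tiling is off by 1 um). Lamella count is the sheath
thickness divided by the 0.0156 um myelin periodicity, rounded half-up
(3 wraps for the smallest calibre, 26 for the largest). The compartment
chain is symmetric — node, paranode, juxtaparanode, internode,
juxtaparanode, paranode, node, … — giving 40 paranodes and 40
juxtaparanodes for 21 nodes.

### Electrical network

Each myelinated segment carries two potentials relative to extracellular
ground: intracellular Vi and peri-axonal Vp; the axolemmal membrane sees
Vi − Vp, the myelin sheath sees Vp. Nodes are bare (their peri-axonal
potential is ground) and carry Vi only. Conductive pathways:

* axial axoplasmic conductance from the core cross-section and the
  axoplasmic resistivity (half-segment resistances in series across each
  interface);
* longitudinal peri-axonal conductance from the annulus cross-section
  pi d_core w (w = peri-axonal width) and the peri-axonal resistivity; the
  peri-axonal pathway opens to grounded extracellular space at each nodal
  gap (a modelling choice — the alternative of a sealed pathway removes
  nearly all sensitivity to peri-axonal widening and cannot reproduce the
  disruption results);
* radial trans-myelin conductance and capacitance: per-lamella values
  divided by the lamella count (series stacking), referenced to the axonal
  surface area. Myelin resistance is 1,000 Ohm cm^2 per lamella.

Baseline peri-axonal widths are 0.002 um (paranode) and 0.02 um
(juxtaparanode, internode); these are back-derived from the disrupted
values quoted for the +500% and +1,000% conditions (0.012/0.12 and
0.022/0.22 um), both of which imply the same baselines.

Compartments longer than 10 um (juxtaparanodes and internodes) are split
into equal sub-segments for spatial accuracy; results are stable to halving
this limit.

### Membrane kinetics

Nodes carry fast Na (m^3 h, 1.5 S/cm^2), persistent Na (p^3, 0.01 S/cm^2)
and slow K (s, 0.088 S/cm^2); juxtaparanodes carry fast K (n^4,
0.02 S/cm^2); paranodes are passive at baseline. Leak conductances are
0.007 (node), 0.0005 (paranode) and 0.005 S/cm^2 (juxtaparanode and
internode). Reversal potentials default to E_Na = +50 mV and E_K = −90 mV
(standard mammalian values; both configurable). All ten alpha/beta rate
functions are implemented in two shapes — the linoid
a x / (1 − exp(−x/k)), whose removable singularity is evaluated by its
analytic limit a k, and the logistic sigmoid — at the coefficients of the
source electrophysiology. Two transcription repairs were needed for
internal consistency: the exponential sign of beta_n (as printed the rate
is negative over part of the physiological range) and the slope sign of
alpha_s (as printed the slow-K activation curve would *decrease* with
depolarisation); both repaired forms are the standard ones in the source
kinetics family. beta_m uses 25.7 mV in both of its half-point positions.

The rate amplitudes are interpreted as already expressed at 37 °C: they
give physiological gating time constants there (nodal Na inactivation
~80 us near 0 mV), whereas scaling them upward by a further q10 factor from
room temperature makes inactivation outrun the internodal charging time and
conduction fails at every calibre. q10 values (2.2 for both Na channels, 3
for fast and slow K) are applied to both rates of each gate for simulations
away from 37 °C.

Each segment's leak reversal is calibrated at assembly so that −80 mV with
steady-state gates is an exact fixed point of its full channel complement;
the network therefore rests at −80 mV to solver precision with the
peri-axonal space at ground.

### Integration

Backward Euler on all potentials: at each step the five gating variables
advance by exact exponential relaxation toward their voltage-dependent
steady state (Rush–Larsen; unconditionally stable and standard for HH-type
kinetics — a deviation in scheme, not in model), the resulting ionic
conductances are frozen, and the pentadiagonal linear system (unknowns
interleaved Vi/Vp along the cable) is solved by banded LU. The default
step is 0.0005 ms with traces sampled at 2,000 points/ms over a 10 ms
window after a 1 ms settling period; the stimulus is a 2 nA, 0.1 ms square
pulse at the midpoint of node 1. Halving dt moves the distal spike time by
well under 1%.

### Measurements

The spike at a node is detected by an upward crossing of −20 mV (the
failure criterion is the absence of such a crossing at node 16 within the
window; the threshold is configurable since "failure" is not defined
numerically in the source). Amplitude is peak minus the deepest
after-potential; width is the full duration at half amplitude with linear
interpolation at the crossings; peak times are refined by parabolic
interpolation. Conduction velocity is the node-4 to node-16 midpoint
distance over the peak-time difference. Velocities from peak times and
from mid-rise crossings agree within a few percent on healthy axons.

### Disruption scenarios

Peri-axonal widening multiplies a baseline width w0 by (1 + f), so f = 5
is "+500%". Scenario kinds: (a) paranodal space only; (b) paranodal and
juxtaparanodal spaces; (c) paranodal space plus Kv dislocation; (d) both
spaces plus Kv dislocation. Disrupting a node widens both of its flanking
paranode/juxtaparanode pairs. Kv dislocation adds fast-K conductance to the
disrupted paranodes at a density that ramps linearly with f up to the full
juxtaparanodal density at f = 10 (the largest increment quoted for the
source experiments); the juxtaparanodal conductance is retained. The cap
and slope are configurable and results reports state the rule used.
Normalised-velocity sweeps fit y = a ln(x) + b with x the percent increase
(f = 0 excluded; ln undefined).

Diameter dependence: small calibres are the most vulnerable in two senses —
their log-fit decay slope is steepest and they reach outright conduction
failure at the smallest fold increase. Pointwise, however, the smallest
calibre can retain slightly *more* normalised velocity than a large one at
mild widening before failing abruptly, so "small axons hit harder" is a
statement about decay slopes and failure thresholds, not about the
normalised velocity at every individual f.

### Calibration

Four passive constants are not printed in the source and serve as the
joint calibration surface, constrained together by the
velocity–diameter slope (4.52 m/s per um of fibre diameter) and the
disruption-failure pattern: axolemmal capacitance 0.3 uF/cm^2, myelin
capacitance 0.2 uF/cm^2 per lamella, axoplasmic resistivity 100 Ohm cm,
peri-axonal resistivity 400 Ohm cm. The peri-axonal value above the
axoplasmic one represents the tortuosity of the sub-myelin pathway. With
these values the model conducts at all seven calibres with a slope within
10% of 4.52, fails at +500% widening for the 0.4 um core under scenario
(b) and by +1,000% for the 0.6 and 0.8 um cores, and slows the 2.7 um
core by ~78% at +1,000% — while the per-lamella myelin *conductance*
stays at its printed value. The myelin-capacitance-per-lamella knob is what separates
small from large calibres here (few lamellae make the sheath capacitance
of small axons disproportionately large), which is the mechanism behind
the model's "small axons hit harder" behaviour.

## Line-profile quantification

Overlap detection works on per-axon two-channel line scans (R = Caspr1,
G = Kv1.2 or pan-Nav, 0–255): position i is overlapping when
|R_i − G_i| < T for a threshold T *and* both channels sit at or above a
background floor B (default 20/255). The floor is our addition: the bare
subtraction rule marks mutual background (0 vs 0) as overlap, which cannot
be the intended biology; B = 0 recovers the literal rule. A single
sub-threshold sample suffices to call an overlap (a minimum-run-length
option exists). The proportion of axons with any overlap is swept over a
threshold grid; the curve is non-decreasing in T by construction.

Paranode length from a single-channel profile is the extent of the
contiguous region around the dominant peak above background plus half the
peak-above-background height (FWHM rule, endpoints linearly interpolated);
the boundary criterion is not stated in the source, so a fixed-level
alternative is provided. Channels sampled on different grids are
interpolated to a common 0.05 um grid.

## Cohort statistics

Summaries per group: n, mean, SD, quartiles, proportions above 3/4/5 um
cutoffs (strict inequality), and the fraction of a test group above a
reference group's percentile (linear interpolation between order
statistics — the 75th-percentile exceedance depends on this rule). Group
comparisons use the two-sided Mann–Whitney test and correlations the
Spearman rank test, both delegated to scipy.stats and labelled "routine";
the bespoke content is the summary definitions.

## Synthetic data

The cohort generator draws paranode lengths from gamma distributions
(strictly positive, right-skewed like the observed histograms,
two-parameter moment match) with group targets control 2.3 ± 0.8 um and
MS-like 2.8 ± 1.1 um, sized like the human study (3,200 paranodes over 16
blocks vs 6,800 over 34). Block effects shift the within-block mean
(SD 0.15 um, chosen as a realistic tissue-block spread and small against
the within-group SD); a block-level microglial-area covariate couples to
the block effect through a Gaussian copula whose latent Pearson
correlation 2 sin(pi rho_s/6) targets a Spearman rho of 0.45.

The profile generator builds plateau bands with error-function shoulders
(saturated immunofluorescence bands are flat-topped, not Gaussian;
shoulder width 0.15 um, configurable) for the paranodal and juxtaparanodal
markers, with a dislocation parameter delta in [0, 1] sliding the Kv band
from one gap-width away (delta = 0, no overlap at T = 50, B = 20) to the
middle of the paranodal zone (delta = 1). Gaussian noise is added and
intensities clipped to 0–255.

What the generators do *not* emulate: optical point-spread blur,
correlated (structured) background, axon-to-axon intensity variation,
partial or asymmetric dislocation geometries, and any 2-D image content.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the *computations*, not the reproduction of the tissue-derived
effect sizes, which require the original microscopy data.

## Problem sizes and runtimes

The calibrated conduction numbers use the full 21-node axon at
dt = 0.0005 ms (seconds per simulation on one CPU; the failure-threshold
and consecutive-node searches are minutes in total). Structural solver
properties (equilibrium, symmetry, monotonicity) use a coarser 0.002 ms
step or a 7-node fixture, which we verified gives the same qualitative
behaviour. Statistical recovery checks use 40–200 seeded replicates.

## Known limitations

* The four passive constants are calibrated, not measured; other
  quadruples may reproduce the same targets (the constraint surface is
  degenerate).
* The d_core 0.6 um axon fails at +900% rather than exactly +1,000%
  (its 0.8 um neighbour fails at +1,000%); the joint failure threshold of
  the pair is what the calibration pins down.
* Localized disruption is more survivable here than in the reference
  behaviour: a fresh spike entering a centered run of disrupted nodes
  persists as a depolarised, persistent-Na-carried wave for two to three
  more nodes than the reference counts suggest, so the minimal failing
  run for the 0.8 um core at widths 0.022/0.22 um is 14 nodes rather than
  11, and the repeating 3-disrupted/2-healthy pattern slows the 0.4 um
  core by ~36% rather than ~73%, while all global (every-node) disruption
  results match. No setting of the calibration constants or of the
  failure-detection threshold was found that reconciles the local and
  global failure patterns simultaneously; the discrepancy most likely
  reflects unprinted structural details of the reference model (nodal
  constriction, per-compartment peri-axonal dimensions). The optional
  `node_diameter_ratio` biophysics parameter exists to explore this
  (default 1.0).
* No extracellular field, ephaptic coupling, ion accumulation,
  demyelination, tapering or branching; single evoked spike only.
* The peri-axonal grounding topology at nodes is a modelling choice
  (flagged above), not an observation.
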