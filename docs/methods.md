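# Methods

## Model structure

The simulator is a hybrid cellular automaton on a cubic lattice with at
most one cell per node. Five cell states exist: fibroblast, mesothelial,
and cancer cells that are proliferating, quiescent or dead. Stromal
states never transition; they consume nutrients and occupy space, and a
migrating cancer cell can displace them into a free neighbouring node.
The lattice mimics an organotypic omentum model: fibroblasts are seeded
uniformly at random in z ∈ [0, Z/2), a mesothelial band (default one
layer) sits immediately above, and cancer cells start in the one or two
layers above the mesothelium. z = 0 is the culture bottom; the region
above the cells represents the peritoneal cavity, so cancer cells never
move upward.

Each iteration corresponds to one hour and runs the environment update
first, then the cell update. Cells are visited in a freshly shuffled
order; each samples exactly one rule (or no action) from its clipped,
jointly renormalised arc probabilities.

### Continuous fields

Glucose, oxygen and drug are dimensionless fields on the same lattice,
normalised to the media/administered concentration. The update is
forward-Euler diffusion with automatic sub-stepping so that
`D·dt_sub ≤ 0.15` (stability bound 1/6 on a unit 3D grid), linear
consumption per living cell, exact exponential drug decay per substep,
and either zero-flux walls everywhere (`closed`) or a Dirichlet top face
(`top_reservoir`): nutrients held at 1, drug at the administered
normalised dose while treatment is active. Values are clamped at 0.

Defaults (per-hour, lattice units; all exposed in `DiffusionParams`):

| parameter | default | rationale |
|---|---|---|
| nutrient/drug diffusivity | 1.0 node²/h | smooth gradients over the ~20-node culture within the 72 h window at a few explicit substeps per hour; with the weak default consumption the nutrient fields stay near 1 regardless, so cell behaviour is dominated by the rule parameters |
| consumption (Glu, O2) | 0.005 /cell/h | depletes a closed node in ~200 h; noticeable but not starving at default densities |
| drug decay | ln2/24 /h | 24 h half-life, motivating re-supply from the top reservoir |

With closed boundaries, zero consumption and zero decay the scheme
conserves total mass to float precision (asserted at 1e−9 per step).

### Behavioural rules

With TLD and AGE the times since last division and since birth, T_c the
current time and T_d the death time (all normalised by the simulation
length), D0 = z/(Z−1) the depth fraction, and S(D) a Hill sigmoid of the
absolute drug concentration with S(IC50) = 0.5 and S(0) = 0:

* divide: `a·TLD + c·(Glu+O2) − f·S(D)`; the daughter occupies a
  uniformly random free Moore neighbour, both cells reset TLD; a division
  with no free neighbour fails silently (the action is consumed).
* migrate: `e·D0`; the node directly below is preferred, otherwise a
  random lower-diagonal neighbour; stromal occupants are displaced to a
  random free Moore neighbour of their node, and an impossible
  displacement cancels the move. Every executed move increments the
  migration tally (the in-silico invasion readout).
* proliferating → quiescent: `b·AGE/(Glu+O2)`.
* quiescent → proliferating: `c·(Glu+O2)`.
* quiescent → dead: `b·AGE/(Glu+O2) − g·S(D)`.
* dead → removed: `d·(T_c − T_d)`.

The division and death rules are the anchor equations of this class of
HGSOC automaton models; the other four arcs are this package's own
modelling choices, built from the same variable set and the intended
parameter roles (b modulates both death and the proliferative/quiescent
transition; c is the nutrient-driven proliferation factor; e drives
depth-directed migration; d the clearance of dead cells). Raw
probabilities are clipped to [0, 1]; when a cell's applicable arcs sum
above 1 they are rescaled to sum to 1 (one rule per cell per iteration),
otherwise the residual is "no action". A nutrient floor of 1e−6 in the
denominators avoids division by zero; the Hill coefficient defaults to 1
and is configurable. Drug effects apply only to division (f) and death
(g).

### Determinism

Each run consumes one seeded RNG stream (lattice seeding from a numpy
`Generator`, the compiled per-cell kernel from numba's RNG seeded off the
same stream), so identical seeds give bitwise-identical trajectories.
Replicate and dose-level seeds are spawned from a master seed via
`SeedSequence`.

## Calibration

The score against a reference dataset is `S = S_p + S_i + S_a` with

* `S_p = |(C_72/C_0 − EG)/EG|`,
* `S_i = |(I_sim − I_vitro)/I_vitro|`,
* `S_a = Σ_{t=2..4} |(C_t/C_4 − A_t/A_4)/(A_t/A_4)|`.

Each component is treated as a deviation magnitude — selecting the
"lowest" score is only meaningful for magnitudes — with a signed mode
retained for auditing. `C_t` counts **every** cancer cell on the lattice including
dead cells not yet degraded: the reference counting/staining assays do
not distinguish freshly dead cells, and this choice also makes the
degradation factor d observable to the search (otherwise d cannot be
identified from the three assays). Dose-response viability, by contrast,
counts live cells only, mirroring metabolic viability assays.

The search enumerates the full regular grid (reference values
`{0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1}` for every parameter, 7⁵ =
16,807 configurations), runs 3 replicates per configuration with a fixed
spawned seed set, averages observables across replicates before scoring,
and breaks ties by the lexicographically smallest parameter tuple. The
same machinery fits (f, g) at a simulated IC50 dose, scored by S_p with
EG = 0.5 on the live count. A separate evaluation pass scores each of
50 simulations independently and reports mean ± sd.

Expected population growth is 2 for 2D references and 0.87 for 3D;
IC50 inputs are cisplatin 10.4 µM and paclitaxel 3.04 nM with the assay
ladder 50, 25, 12.5, 6.2, 3.1, 1.6, 0.8, 0.4, 0 (µM / nM).

## Validation

Dose–response curves are compared by the summed per-dose relative error
`Σ |S([D]) − E([D])| / E([D])` on matching ladders, and by two-sample
Kolmogorov–Smirnov tests (SciPy's implementation; an ECDF brute-force
oracle backs it in the tests) at threshold p < 0.05, applied to
replicate-level distributions. Depth profiles average, over simulations,
the per-state cell count at each (iteration, z), normalised by the total
initial cell number; matrices are exported as CSV so assertions run on
numbers, not rendered images.

## Synthetic reference data

`generate_dataset` draws datasets with the study's structure rather than
fitting the deposited measurements: multiplicative mean-preserving
log-normal replicate noise (readouts are positive and heteroscedastic),
EG means 2.0 (2D) and 0.87 (3D), invasion means 100 (2D) and 190 (3D,
honouring the reported near-doubling), flat adhesion time courses, and
Hill-shaped dose–response with residual-viability floors 0.15 (2D) and
0.35 (3D) and coefficients of variation 0.08 (2D) and 0.20 (3D). These
capture the features the pipeline is sensitive to — relative growth,
invasion contrast, replicate scatter, curve flatness — but not absolute
absorbance scales, plate effects or inter-batch drift; tests passing on
them demonstrate correctness of the machinery, not wet-lab accuracy.
Real measurements can replace them through the documented long-format
CSV schema (`assay, setting, replicate, time_or_dose, value`).

`generate_from_simulator` instead converts simulator output at a known
grid configuration into a dataset (EG = C_end/C_0, invasion = migration
tally, adhesion ∝ early counts), providing exact ground truth for
parameter-recovery experiments. In the noise-free variant (same
replicate seeds for pseudo-data and search) the truth scores exactly
zero; because d only becomes observable once cells die, recovery of d is
the weakest — in practice the four other parameters recover exactly and
d within one grid step.

## Nuclei counting

Segmentation is a global Otsu threshold plus 8-connected component
labelling; components below a 5 px speckle floor are ignored. GFP mode
keeps components with area in [50, 5000] px (inclusive bounds) and mean
intensity above the background level, estimated as the median intensity
outside the segmented mask. Fields whose Otsu separability
(between-class/total variance) falls below 0.75 are reported as empty:
on a noise-only image any global threshold merely splits the noise, and
the guard substitutes for the judgement a human operator would apply.
Touching nuclei merge into one component (no watershed splitting) — a
documented limitation. The synthetic image generator places
Gaussian-blurred disks (radius 6 px, peak 200, background 20, noise sd
5, 8-bit) with optional non-overlap packing and attaches ground truth.

## Problem sizes and numerical choices

Library defaults use a 20³ lattice seeded with 120 fibroblasts, 60
mesothelial and 30 cancer cells (preserving the wet-protocol ordering
fibro > meso > cancer; a 30³/400/200/100 configuration is used for
desk-scale exploration) and 72 iterations. The analysis drivers and the
acceptance script search a reduced grid (3×2×3×1×4 values, denser along
e where the invasion contrast lives) with 3 replicates, and exercise the
full 7⁵ enumeration in dry-run mode; recovery experiments use a 3-value
grid at 3 replicates over 10 (tests) or 5 (acceptance script) master
seeds. The inner loops (diffusion substeps, per-cell updates) are
JIT-compiled with numba; the first call in a fresh environment pays a
one-off compilation cost of a few seconds.

## Known limitations

* The four unprinted behavioural arcs are modelling choices; calibrated
  parameter values are therefore comparable within this package, not
  with the original simulator.
* One cell per node and strictly downward migration coarsen mechanics;
  there is no matrix remodelling, cell geometry or off-lattice motion.
* Dead cells block space until degraded, which couples d to crowding.
* Drug action is purely the S(D) modulation of division and death; no
  pharmacokinetics beyond field decay, no resistance evolution.
* Synthetic defaults are structural stand-ins; quantitative agreement
  with the deposited wet-lab dataset is out of scope without that data.
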