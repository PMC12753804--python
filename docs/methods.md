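# Methods

## The model

Helicase translocation is represented as a continuous-time Markov chain
over metastable conformational states of a helicase–ssDNA complex,
observed through noisy atomic coordinates. The analysis chain —
distance featurization, TICA, k-means discretization, reversible MSM
estimation, PCCA+ coarse-graining, MFPT kinetics, contact persistence and
constriction geometry — assumes that (i) the slow dynamics is Markovian at
the chosen lag, (ii) the system is sampled reversibly enough for a
detailed-balance estimator to be meaningful, and (iii) metastable states
are separable in the space of interatomic distances.

## Synthetic fixtures

Because no raw trajectory data of this kind is publicly deposited, the
package ships a first-class generator whose ground truth is known exactly.

**Geometry.** Each system is a coarse model with one pseudo-atom per
backbone position (named `CA`) plus side-chain/ring pseudo-atoms for
residues with encoded interactions: four rigid domain clusters (RecA1,
RecA2, Arch, Fe–S; 24 bulk positions each) whose centers move along four
collective coordinates (ATPase-cleft closure, Arch opening, Fe–S shift,
Arch twist), dedicated wall residues for the two constrictions, a
12-nucleotide ssDNA (P, C1′ and a 5-atom base-ring centroid per
nucleotide, 6 Å rise), and ATP/ADP/Mg²⁺ ligands that occupy the ATPase
cleft only in the nucleotide-bound states. Widths are exact by
construction: wall atoms sit at ±w/2 so the width metric returns the
configured value on noise-free templates (XPD apo 13.2/6.1 Å, ATP-bound
10.7/11.7 Å; the DinG 3′ constriction is systematically wider). Contact
pseudo-atoms are placed at 2.4 Å (polar), 2.6 Å (ring centroids) or 3.6 Å
(hydrophobic) when an interaction is present and well outside the cutoff
when absent; the distances sit far enough inside the cutoffs that the
default 0.3 Å emission noise does not break persistence. Every template's
detected contact set is verified against its declared pattern at build
time. The two cycle endpoints share identical protein coordinates and
differ by exactly one nucleotide rise of the DNA.

**Kinetics.** The chain topology is linear (S1⋯S7 / SD1⋯SD5) with kinetic
traps attached to the heavily-populated apo endpoint states. A tree
topology satisfies the Kolmogorov cycle criterion trivially, so the chain
is exactly reversible for any rates and the reversible maximum-likelihood
estimator is consistent — embedded MFPTs are recoverable without bias. No
direct endpoint-to-endpoint edge exists: under detailed balance such an
edge would admit an artificial one-step shortcut in the estimated matrix
and corrupt the cycle MFPT. Backward rates are 0.5× the forward rate of
the same edge; weaker back-flow makes backward return times so long that
rare two-step jumps in the discretized kernel dominate first-passage
times. Forward rates are calibrated by Brent root finding so that the
*discrete* kernel P = exp(QΔt) at Δt = 1 µs reproduces the stepwise MFPT
targets to solver precision: S1→S2 = 3.6×10⁻³ s, S3→S4 = 4.1×10⁻⁵ s, and
1×10⁻⁴ s for the steps without a stated value, giving a full-cycle
S1→S7 MFPT of 3.97×10⁻³ s (≈ 4 ms); DinG: SD1→SD2 = 8.6×10⁻³ s, remaining
steps 1.3×10⁻⁴ s, cycle ≈ 9.0×10⁻³ s. Trap exchange dwell times
(0.3–2 ms) were chosen so that traps are metastable, their exchanges are
observed within 5000-frame trajectories, and the implied-timescale
spectrum has no internal gap larger than the slow-process/noise gap that
the macrostate-count selector keys on (verified on the exact kernel at
build design time). Δt = 1 µs makes the fastest embedded MFPT span ≈ 40
frames.

**Emission and sampling.** Frames are templates plus isotropic Gaussian
noise (default σ = 0.3 Å; width-recovery analyses use σ = 0.2 Å).
Trajectory ensembles allocate start states round-robin across all states,
emulating unbiased simulations launched from replicas spanning an
optimized path; the stationary distribution of a driven-downhill chain
concentrates at the cycle end, so equilibrium starts would under-sample
the early states. Transition-count-based estimators do not require
equilibrium sampling, only observed transitions.

**What the generator does not emulate:** continuous intra-state
diffusion (emission noise is i.i.d., so within-state decorrelation is
instantaneous), force-field energetics, solvent, sub-nucleotide DNA
strain, or non-Markovian memory. Passing recovery tests therefore shows
the estimators are correct and well-calibrated on data satisfying the
model assumptions, not that real MD data satisfies them.

## Stage parameters

| Parameter | Default | Notes |
|---|---|---|
| feature stride | 6 | ≈ 29 Cα kept; with Cα–P and P–P pairs, 820 distances |
| TICA lag | 5 frames | any lag shorter than the fastest hidden process works |
| ICs kept | 10 | |
| microstates k | 200 | desk-scale reduction of the full-scale 1500 |
| MSM lag | 3 frames | short lag sharpens the slow/noise timescale gap; the crisp, well-separated discretization keeps the model Markovian at this lag |
| macrostate count | largest implied-timescale ratio gap (cap 12) | m = 1 + argmax tᵢ/tᵢ₊₁ |
| persistence threshold | 0.75 | boundary inclusive (≥) |
| contact subsample | 120 frames per macrostate | persistence fractions are binomial with sd ≤ 0.046 at the encoded extremes |

Ensembles are 60 trajectories × 5000 frames per system (0.3 s aggregate at
Δt = 1 µs). Kinetic re-estimation from state-label sequences uses the plain
conditional MLE (row-normalized counts): the reversible estimator implicitly
assumes equilibrium visitation and acquires a few-percent bias under the
path-spanning start distribution, whereas the conditional MLE is unbiased
for any starts. Sequence lengths span several multiples of the rate-limiting
dwell (10⁷ frames as 500 × 2×10⁴ in the test suite; 1.6×10⁸ as 4000 × 4×10⁴
with source-weighted starts in the reproduction script), putting the re-estimated MFPTs within a few
percent of truth. These sizes keep a full two-system analysis within
minutes on one CPU.

## Numerical choices

* **TICA**: covariances accumulate in both time directions (symmetrized
  estimator, real spectrum, time-reversal invariance); C₀ is
  ridge-regularized with ε = 10⁻¹⁰·tr(C₀)/d because all-pairs distance
  features are collinear by construction; constant columns are dropped
  with a logged notice. Components are scaled to unit variance of the
  training projections with respect to the lag-windowed covariance.
* **Reversible MLE**: counts are restricted to the largest strongly
  connected component (logged); the fixed-point iteration on the symmetric
  flux matrix stops at a 10⁻¹⁰ element-wise change.
* **PCCA+**: inner-simplex vertex guess, negative memberships clipped and
  rows renormalized; no further simplex-rotation optimization (adequate
  for well-separated metastable sets; the membership matrix is exposed for
  refinement). Coarse matrix by π-weighted projection.
* **MFPT aggregation**: first-passage linear solve on the microstate
  chain with the crisp members of the target macrostate absorbing,
  averaged over source members with π weights.
* **Width metric**: symmetrized directed mean-of-minima of heavy-atom
  distances between the two wall residue sets; reduces to the wall
  separation on parallel walls and is robust to single-atom outliers.
  (No standard definition of "channel width" exists; this is the
  package's contract and the fixtures are built against it.)
* **Contacts**: residue-level deduplication (one event per residue pair,
  type and frame); hydrophobic detection restricted to side-chain
  non-polar atoms to avoid backbone-driven false positives; with no
  explicit hydrogens the D–H–A angle test uses an idealized H on the
  donor→acceptor axis and the event is flagged heavy-atom-only. The π–π
  criterion is centroid distance only (no ring-plane angle limit).
  Protonation conventions: Arg/Lys positive, Asp/Glu negative, His
  neutral; the phosphate group (P, OP1, OP2) carries the DNA negative
  charge.
* **NEB**: normalized central-difference tangent (simplest stable choice);
  annealing step counts are dimensionless stand-ins for time-based
  heat/hold/cool phases since analytic potentials have no integrator
  timestep; temperature enters as √T-scaled Gaussian kicks on a damped
  force update. The "partial" restraint scope maps to an optional
  coordinate mask for the springs (default: all coordinates).
* **Tie-breaking**: lowest index everywhere; every stochastic step is
  seeded; DNA register estimation errors out when two offsets tie within
  10⁻⁶ Å.

## Design decisions taken where the design was open

* Seconds are attached to MSM quantities through the explicit frame
  interval Δt; reported times follow the face-value convention of the
  reference kinetics.
* The mutation classifier is strictly rule-based (A: persistent DNA
  contact anywhere in the cycle; B: nucleotide contact or RecA1–RecA2
  interface membership; C: fall-through). Literature class annotations mix
  structural rules with expert judgment (e.g. D681, which positions a
  DNA-binding arginine without touching DNA itself, or G47, which clashes
  sterically with the nucleotide); the report therefore carries both the
  rule-derived and the annotated class and flags disagreements instead of
  hiding them.
* Fixture domain boundaries resolve an inconsistency in the literature
  description of residues 209–223 (attributed to both motor domains in
  different passages) in favor of RecA1, which matches the description of
  the Constriction-2 wall.

## Known limitations

* PCCA+ without simplex-rotation refinement can mis-assign microstates in
  weakly metastable systems.
* The CK test aggregates over user-provided sets and reports a max
  deviation without an automatic bootstrap error band.
* User-input mode (topology + multi-model PDB trajectory) runs the
  feature/TICA/MSM chain; the contact/width stages currently target the
  synthetic systems' constriction definitions and require a config with
  explicit wall residue sets for other proteins.
* Binary trajectory formats (DCD/XTC) and mmCIF are not supported.
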