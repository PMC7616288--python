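# Methods

`cardiotwin` implements a closed functional loop for cardiac digital
twins of myocardial infarction (MI): simulate the QRS complex of
parameterized infarct scenarios on biventricular anatomy, analyze how
the QRS responds to infarct properties, and invert the map — inferring
the scar and border-zone distribution from the QRS and the anatomy.
This note records the models, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Synthetic anatomy and coordinates

Real digital-twin pipelines reconstruct subject-specific meshes from
cine MRI and project them into the consistent biventricular coordinate
system (Cobiveco): transmural `tm` ∈ [0,1] (endo→epi), apicobasal `ab`
∈ [0,1] (apex→base), rotational `rt` ∈ [0,1) (periodic), and
transventricular `tv` ∈ {0 LV, 1 RV}.  Image-based reconstruction is
out of scope here; instead the generator builds idealized anatomies
*parametrically in Cobiveco space*, mapping a structured (tm, ab, rt)
lattice onto truncated-ellipsoid shells.  Coordinates are therefore
exact by construction rather than solved for, which is appropriate
because every downstream component consumes Cobiveco, none re-derives
it.

Key conventions (all code and configs follow these):

* `rt = 0` sits at the anterior LV/RV junction and increases so the LV
  septum occupies rt ∈ [0, 1/3) and the septal side of the RV occupies
  rt ∈ (2/3, 1).  This makes the "LV region" rule — `tv = 0` or
  (`tv = 1` and `rt > 2/3`) — reproducible.
* The two ventricles are separate watertight shells; each activates
  from its own root nodes, so the missing shared septal wall does not
  block physiological propagation.  The mesh generator pinches the
  apex (one node per wall layer) so shells are closed.
* A seeded ±8 % multiplicative perturbation of the shell semi-axes
  emulates inter-subject anatomical variability; Cobiveco stays exact.
* Lengths are mm, times ms; conduction velocities are configured in
  cm/s and converted internally (1 cm/s = 0.01 mm/ms).

Fibers follow a rule-based architecture: the helix angle interpolates
linearly in `tm` from +60° (endo) to −60° (epi), yielding an
orthonormal fiber/sheet/sheet-normal triad per element.  The ±60°
default is the standard rule-based surrogate; the triad, not the exact
angles, is what the anisotropic conduction tensor needs.

The AHA 17-segment map partitions the LV by `ab` bands (apical cap
< 0.20, apical < 0.45, mid < 0.70, basal above) and `rt` sectors (six
for basal/mid, four apical).  The band edges are not fixed by the AHA
convention in Cobiveco units; they are configuration values with the
defaults above, and RV septal points fold onto the LV septal sectors.

## Infarct scenarios

A scar is the set of LV-region points inside an ellipsoid in
(tm, ab, rt) around a center (tm₀, ab₀, rt₀) with radii
(r_tm, r_ab, r_rt); the rotational difference is wrapped on the circle
and the boundary is inclusive.  The border zone (BZ) is the same
ellipsoid with radii scaled by `bz_scale` (default 1.5) minus the scar
core — the BZ extent is not prescribed anywhere authoritative, so the
dilation factor is a package choice matching the notion of "the area
surrounding the scar".

The catalogue enumerates 7 locations × 2 transmural extents, plus a
small lateral scar (r_ab and r_rt halved) at both extents, plus one
slow-conduction variant of the transmural large lateral scar:
17 scenarios, 16 when the slow variant is excluded for inverse
inference.  Transmural scars use r_tm = 3 (all tm₀ = 0, so the
ellipsoid spans the whole wall), subendocardial scars r_tm = 0.5.
Scar/BZ conduction is scaled to 10 %/50 % of healthy (5 %/25 % in the
slow variant).  The seven (ab₀, rt₀) centers and (r_ab, r_rt) radii
are package defaults: each center is validated to land in an AHA
segment of the named wall (asserted in the test suite), and the radii
were chosen once so transmural scars push the QRS duration well into
the pathological range on the default anatomy (baseline ≈ 67 ms;
septal/inferior/lateral transmural ≈ 120–150 ms, the largest apical
and extensive anterior scars ≈ 180–235 ms).  They are not literature
values, and the longest durations exceed typical clinical readings —
a consequence of slowing the fast endocardial layer inside large
scars to 10 %.

## Forward model: orthotropic Eikonal + pseudo-ECG

Activation time t solves ∇tᵀ V² ∇t = 1 with t = pk − min(pk) on the
seven root nodes (four LV: mid-septum, basal-anterior paraseptal, two
mid-posterior; three RV: mid-septum, two free-wall), where pk are
configurable per-root Purkinje delays (default 0) and V² is the
squared-velocity tensor v_f² ffᵀ + v_s² ssᵀ + v_n² nnᵀ with healthy
speeds 65/48/51 cm/s.  A thin endocardial layer (tm ≤ 0.1) conducts
isotropically at 100 cm/s (150 cm/s apically, ab < 0.4) as a surrogate
for the Purkinje-coupled subendocardium; the layer speed is scaled by
the tissue class like the bulk speeds.

Discretization: a shortest-time graph over mesh edges augmented with
2-ring (neighbour-of-neighbour) connections.  Edge traversal time is
length / √(d̂ᵀ V² d̂) with V² averaged over the elements incident to
the edge's endpoints; an element touching scar/BZ nodes is slowed by
the most severe of its nodes' scales.  The solve is multi-source
Dijkstra through a virtual source carrying the normalized delays.
This choice is deterministic, exact on its own graph (verified against
brute-force relaxation), and within 5 % of the analytic solution for
uniform isotropic speed on a box at the mesh densities used; a
PDE-level fast-marching scheme would be more accurate per node but is
not required at desk scale.

The pseudo-ECG approximates the extracellular potential in an infinite
homogeneous medium: φₑ = a²σᵢ/(4σₑ) ∫ −∇Vm·∇(1/r) dV.  Vm is a
normalized-tanh upstroke (1 ms, −85 mV → +15 mV) triggered at the
local activation time; only depolarization is modeled because only the
QRS is analyzed.  ∇Vm uses linear shape functions per tetrahedron and
the kernel is evaluated at the centroid (one-point quadrature,
verified within 5 % of a vertex-quadrature oracle).  Because the
integral is linear in nodal Vm, each electrode reduces to a
precomputed weight vector over nodes and the time loop is one matrix
product; the constant a²σᵢ/(4σₑ) is folded into a gain that cancels
under amplitude normalization.  Electrodes sit on an ellipsoidal
virtual torso (margin 60 mm) at standard 12-lead positions; leads are
I, II and V1–V6 via the Wilson central terminal.  Signals are
normalized to unit peak across leads, trimmed, and zero-padded (never
stretched) to 512 samples at dt = 0.5 ms, recording the pre-padding
duration.  QRS duration is the span where any lead exceeds an
amplitude threshold θ = 0.02; the onset/offset rule is a package
choice.

## QRS analysis

Dissimilarity to baseline is dynamic time warping per lead on the
trimmed signals: |a−b| local cost, accumulated cost normalized by the
warping-path length (ties broken toward shorter paths, which makes the
value well-defined and testable against exhaustive path enumeration),
plus a penalty λ·|Δduration| with λ = 0.005 per ms.  DTW_max and
DTW_avg aggregate the eight leads.

Four local abnormality detectors, with thresholds from standard
clinical practice exposed as configuration: duration prolongation
(> 1.1 × baseline), pathological Q waves (first deflection negative,
width > 40 ms or depth > 25 % of that lead's R amplitude), poor R-wave
progression (R of V1..V4 not strictly increasing, or R(V6) > R(V5)),
and fragmented QRS (≥ 2 more prominence-filtered local extrema inside
the QRS window than the baseline lead, prominence 0.02).

## Inverse model

A dual-branch VAE with an inference head, trained end to end:

* **Point-cloud branch**: farthest-point-sampled clouds (positions +
  Cobiveco, d = 3 and c = 4 features) feed a PointNet-style shared MLP
  with global max-pooling into a Gaussian latent; a fully-connected
  set decoder emits coarse and dense reconstructions per anatomical
  class (LV/RV by `tv`, totals n_coarse/n_dense across classes).
* **QRS branch**: the 8×512 signal is average-pooled 8× in time and
  encoded by a bidirectional Elman recurrent network plus a linear
  skip readout of the pooled signal (the skip eases gradient flow
  through the recursion); decoding runs a latent-conditioned recurrent
  generator whose output is upsampled back to 512 samples.
* The two latent Gaussians are sampled by reparameterization and
  concatenated; the segmentation head conditions per-point features
  (learned + raw) on the tiled latent code and emits
  healthy/scar/BZ logits.

Losses: per-class chamfer reconstruction (coarse + α·dense, α = 5);
QRS reconstruction as MSE plus DTW — exact dynamic programming at
evaluation, and during training a *soft-DTW divergence* (smoothed DP
with γ = 1 on the pooled signals, with the self-alignment terms
subtracted so the term vanishes at a perfect match instead of carrying
the entropic −γ log 3 per-step bias); KL to a standard normal
(weight 0.01); segmentation cross-entropy + Dice; compactness
(mean over predicted infarct points of distances to the predicted and
true infarct centroids, normalized by the true infarct's maximal
centroid distance); size |N_pre − N_gd|/N_gd — the printed signed form
would reward emptying the prediction, so the absolute value is used —
and a spatial penalty N_RV_pre/N_pre excluding a septal boundary band
rt ∈ [2/3 ± 0.02].  During training the counting losses use soft
(probability-mass) counts and probability-weighted centroids, since
hard counts have zero gradient almost everywhere; the evaluation-side
reference implementations use the hard point sets.  The total is
λ_VAE·L_VAE + L_seg + λ_compact·L_compact + λ_size·L_size +
λ_spa·L_spa with all λ = 1 and λ_KL = 0.01.

The network and the training loop (Adam, decoupled weight decay 1e-3,
batch 4, lr schedule ×0.5 every 6800 iterations) run on a compact
reverse-mode autodiff engine written on NumPy inside the package;
gradients of every primitive, of soft-DTW and of chamfer are verified
against finite differences in the test suite.  Posterior log-variance
biases are initialized to −4 so early training is signal- rather than
noise-dominated.  Full-scale defaults follow the reference recipe
(n = 4096 points, 1024/4096 reconstruction sizes, z = 64 + 64,
300 epochs, lr 1e-4); desk-scale runs use `NetworkConfig.desk`
(n = 512, z = 16 + 16, reduced hidden sizes) with a constant lr 3e-3
chosen as this package's calibration for CPU-scale overfit checks.

## Evaluation

Per-class Dice/precision/recall on point clouds with the conventions
empty-vs-empty → 1 and empty-vs-nonempty → 0.  The AHA-loc-score
combines segment-identity match of the infarct centroids (weight 0.5),
IoU of the touched AHA segment sets (0.2), and one minus the centroid
distance normalized by the cloud bounding-box diagonal, clipped to
[0, 1] (0.3).  The normalization constant is a package choice (the
source only calls it a "normalized distance"); the infarct point set
is scar ∪ BZ by default with a scar-only flag.  The reconstruction-
vs-inference correlation reports OLS r² between 0.5·L_PCrec (α = 1) or
L_QRSrec and the scar/BZ Dice.

## Study sizes, runtimes, and what desk-scale results show

Test and acceptance runs use 2–3 synthetic subjects, coarse
(~700-node) or fine (~2100-node) meshes, 512-point clouds, and
150–200-epoch training — sizes chosen so the whole loop runs on one
CPU core in minutes.  At these sizes the pipeline's *orderings* are
stable and are what the acceptance checks assert: transmural scars
perturb the QRS at least as much as subendocardial ones, small lateral
scars less than large ones, slower infarct conduction prolongs the
QRS, training overfits small case sets (mean scar Dice ≥ 0.8), and a
held-out subject shows the extreme Dice ordering (extensive anterior
transmural ≫ small lateral subendocardial).  Absolute magnitudes —
Dice tables, DTW values, millisecond durations — depend on cohort
size, anatomy realism and training scale and are not reproduced at
desk scale.

The generator emulates: two-cavity thick-walled anatomy with exact
coordinates, anisotropic conduction with an endocardial fast layer,
scar/BZ slowing, and far-field ECG genesis.  It does not emulate:
image-derived anatomical detail (papillary muscles, wall-thickness
heterogeneity, true septal fusion of the ventricles), torso
inhomogeneity, measurement noise, or repolarization.  Passing tests
therefore demonstrate internal correctness and the stated orderings on
idealized anatomy, not clinical performance.

## Known limitations

* The two shells interpenetrate slightly near the septum; acceptable
  for a phantom, wrong for volumetric overlap-sensitive analyses.
* Graph-based Eikonal solutions carry a small metrication error
  (bounded by the 2-ring stencil) and inherit mesh anisotropy.
* The QRS branch is a vanilla bidirectional recurrent network, not a
  gated (LSTM/GRU) one; at desk scale this is not the bottleneck.
* Hard-count losses are reported exactly but trained through soft
  surrogates; the two agree only in the confident-prediction limit.
* Scenario radii/centers are package defaults; conclusions that
  depend on absolute infarct size should treat them as free
  parameters.
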