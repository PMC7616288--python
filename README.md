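# cardiotwin

Cardiac digital twins of myocardial infarction (MI), end to end on a
desk: simulate the QRS complex of parameterized infarct scenarios on
synthetic biventricular anatomy, quantify how the QRS responds to
infarct location, size, transmurality and conduction slowing, and
invert the map — inferring the scar and border-zone distribution from
the QRS plus the anatomy with a dual-branch variational autoencoder.

It is written for computational cardiac-electrophysiology researchers
who want a self-contained, reproducible sandbox for the forward and
inverse MI problem without image data, GPU training, or a torso model.

## The model in brief

**Anatomy.** Idealized biventricular meshes are generated
parametrically over the consistent biventricular coordinates
(tm transmural, ab apicobasal, rt rotational, tv transventricular), so
every node carries exact coordinates.  Scars are ellipsoids in
coordinate space,

    (tm−tm₀)²/r²_tm + (ab−ab₀)²/r²_ab + (rt−rt₀)²/r²_rt ≤ 1,

with the border zone the same ellipsoid dilated by 1.5 minus the core.
A catalogue enumerates 17 scenarios (7 AHA locations × 2 transmural
extents, a halved-radius small lateral scar at both extents, and one
slow-conduction variant); 16 are used for inverse inference.

**Forward.** Activation times solve the orthotropic Eikonal equation
∇tᵀV²∇t = 1 from seven endocardial root nodes with configurable
Purkinje delays; V² carries fiber/sheet/normal speeds 65/48/51 cm/s,
an endocardial fast layer (100/150 cm/s), and scar/BZ slowing to
10 %/50 % (5 %/25 % in the slow variant).  The solver is anisotropic
multi-source Dijkstra on a 2-ring edge graph.  The pseudo-ECG
φₑ ∝ ∫ −∇Vm·∇(1/r) dV turns the activation map into 8-lead
(I, II, V1–V6), unit-peak, 512-sample QRS matrices.

**Analysis.** Per-lead dynamic time warping to baseline (path-length
normalized, duration-penalized) plus four clinical QRS abnormality
detectors: duration prolongation, pathological Q waves, poor R-wave
progression, fragmented QRS.

**Inverse.** A PointNet-style point-cloud encoder and a bidirectional
recurrent QRS encoder feed concatenated Gaussian latents; decoders
reconstruct coarse/dense point clouds and the QRS, and a segmentation
head labels each point healthy / scar / border zone.  Training
combines chamfer, MSE + soft-DTW, KL, cross-entropy + Dice,
compactness, size and RV-spatial losses; evaluation reports Dice /
precision / recall and the AHA-loc-score
0.5·δ_segment + 0.2·IoU_segments + 0.3·(1 − normalized centroid
distance).  The network runs on a small NumPy autodiff engine included
in the package — no deep-learning framework required.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

The bundled demo builds two synthetic subjects, simulates four
transmural scenarios, runs the sensitivity study, trains a reduced
inverse model for 80 epochs, and evaluates one training case:

```sh
cardiotwin demo --out runs/demo --seed 0
```

prints (abridged)

```
{"sensitivity_rows": 64,
 "final_loss": 6.41,
 "first_case_metrics": {"dice_scar": 0.21, "precision_scar": 0.33,
                        "recall_scar": 0.15, "aha_loc_score": 0.30}}
```

and writes `sensitivity.csv`, whose per-scenario means (mean DTW to
baseline across leads and subjects; QRS duration vs a 67.0 ms
baseline) show the expected physiology — larger and more anterior
scars perturb the QRS more and prolong it:

```
scenario                       dtw_avg  dtw_max  duration_ms
apical_transmural                0.630    0.661       179.50
extensive_anterior_transmural    0.921    0.960       234.75
inferior_transmural              0.455    0.508       143.25
septal_transmural                0.344    0.382       121.75
```

An 80-epoch, 256-point demo model only begins to localize scar
(Dice 0.21 above); the acceptance checks in the test suite train
200 epochs on 512-point clouds and reach mean training scar
Dice ≥ 0.8.

The same pipeline is scriptable: `cardiotwin simulate | sensitivity |
train | infer | evaluate`, each driven by a YAML run configuration
with explicit seeds.

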