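# pabifurc

Desk-scale pipeline for **main-pulmonary-artery (MPA) bifurcation
morphometry and short-term risk scoring**, exercised entirely on
synthetic geometry and synthetic cohorts:

1. **`pabifurc.synthetic`** — parametric trunk→branch bifurcation surface
   meshes (implicit smooth tube union + marching cubes) with
   independently computed ground truth (closed forms, 2-D implicit
   contouring, voxel counting), and synthetic patient cohorts whose
   group-conditional feature moments reproduce published summary
   statistics via moment-matched zero-truncated normals.
2. **`pabifurc.morphometry`** — centroid-marching centerline extraction,
   placement of the four measurement planes (trunk inlet/outlet, right
   and left branch inlets) by carina detection, per-plane cross-section
   metrics (CSA, perimeter, hydraulic diameter = 4·CSA/perimeter, max
   Feret diameter), bifurcation triangle area/angle, inter-plane lumen
   volume by clip + cap + divergence theorem, and the >29 mm trunk
   dilation dichotomy. Reported units: areas in 100 mm², lengths in
   10 mm, volumes in 1000 mm³.
3. **`pabifurc.risk_model`** — L1-penalised logistic regression solved by
   a glmnet-style coordinate-descent path (numba-accelerated, KKT-checked),
   10-fold cross-validated deviance, minimum / 1-SE penalty selection,
   sparse score formulas. The published three-term formula
   (0.92·bifurcation area + 0.50·outlet hydraulic diameter +
   0.10·outlet CSA) ships as a fixture.
4. **`pabifurc.evaluation`** — ROC-AUC with DeLong variance/CI and the
   paired DeLong test, Youden cutoff, stratified cross-validated
   precision-recall summaries, decision-curve net benefit, two-sample
   t-test and 2×2 chi-square.
5. **`pabifurc.pipeline` / `pabifurc.cli`** — configured, manifest-checked
   end-to-end runs and a `pabifurc` command-line interface.

## CLI

```sh
pabifurc simulate-geometry --out mesh.stl --ground-truth gt.json
pabifurc measure --mesh mesh.stl --out metrics.json --csv metrics.csv
pabifurc simulate-cohort --out cohort.csv
pabifurc fit --cohort cohort.csv --set training --rule 1se --seed 0 --out formula.json
pabifurc score --formula published --in cohort.csv --out scores.csv
pabifurc evaluate --cohort cohort.csv --scores scores.csv --out report.json
pabifurc run --config run.yaml        # multi-stage configured run
pabifurc report --manifest run_output/manifest.json
```

Geometry and cohort specs are YAML files whose keys mirror
`BifurcationSpec` / `CohortSpec` fields; all stochastic stages take
explicit seeds and are deterministic given them.

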