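# morphohead

3D soft-tissue craniofacial geometric morphometrics: thin-plate-spline
multi-point warping with sliding semi-landmarks, generalized Procrustes
analysis, and the downstream statistical battery — Procrustes ANOVA with a
digitization-error stratum, relative-warp PCA with parallel-analysis
retention, EDMA distance tables, allometric regression, MANOVA on allometric
trajectories, CVA and cross-validated discriminant classification.

The package is aimed at morphometricians and forensic/anthropometric
researchers who study craniofacial variation — differences in head and face
shape between population groups, sexes and age classes — from 3D surface
scans.  Manually placed anatomical landmarks capture only a sparse sketch of
a face, so a dense template of surface *semi-landmarks* is warped onto every
specimen and slid into geometric homology before analysis.  Because scan
collections of this kind are license-restricted, a synthetic head-mesh
generator with known, controllable shape structure (group effects,
individual variation, allometry, re-digitization error) stands in for real
data and makes every stage testable end-to-end.

## The method in brief

Dense correspondence uses the 3D thin-plate spline
`h(p) = Psi(p) K + [p, 1] Gamma` with kernel `Psi_w(p) = ||p - P_w||`, fitted
on 20 anatomical anchor landmarks per head; `K` and `Gamma` solve the
bordered system `[[Psi, P], [P^T, 0]] [K; Gamma] = [Q; 0]`.  Warped
semi-landmarks are projected onto the target surface and slid along local
tangent planes to minimize the TPS bending energy
`E = sum_d Y_d^T B Y_d` against the template (B the bending-energy matrix of
the template configuration), in six cycles with a step fraction decaying
geometrically from 100% to 5%, re-projecting after each cycle.  The
homologous 500-point configurations are then superimposed by GPA (translation,
rotation and centroid-size scaling removed; shape dimension `3K - 7`) and
analysed in tangent space.  Details, conventions, and all defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the whole pipeline — simulate a population, build the template, warp and
slide, GPA, then the full statistical battery — from Python:

```python
from morphohead.pipeline import PipelineConfig, run_full_analysis

cfg = PipelineConfig(seed=5,
                     population={"n_total": 60, "n_redigitized": 12, "subdivisions": 3},
                     n_semilandmarks=120, n_permutations=499)
res = run_full_analysis(cfg, "out/")
print(res["anova_all"].table[["variance_pct", "DF", "F", "p"]].round(4))
rep = res["report"]
print("cross-validated accuracy (%):", rep["classification_accuracy_pct"])
print("PCs retained by parallel analysis:", rep["retained_parallel_analysis"])
```

which prints (exact numbers; the run is deterministic per seed):

```
                  variance_pct     DF         F    p
effect
Ethnicity              11.1214    413   11.4569  0.0
Sex                    19.1137    413   19.6902  0.0
Age                    18.2408   1652    4.6977  0.0
Individual             51.4481  21889  153.1652  0.0
Digitizing Error        0.0761   4956       NaN  NaN
Total                 100.0000  29323       NaN  NaN
cross-validated accuracy (%): {'ethnicity': 98.33, 'sex': 100.0, 'age_class': 66.67}
PCs retained by parallel analysis: 8
```

Reading the table: each row is one stratum of the hierarchical Procrustes
ANOVA on the overall landmark partition (here 140 points, so a two-level
factor gets `(2-1) x (3*140 - 7) = 413` degrees of freedom).  Digitization
error — the disagreement between repeat digitizations of the same heads —
accounts for under 0.1% of shape variance, far below every biological
stratum, while individual variation dominates; that ordering is the standard
quality check for a landmarking protocol.  The injected 6 mm sex effect is
recovered at 100% leave-one-out accuracy, and the five age classes, whose
3 mm effect overlaps heavily between neighboring classes, classify at 67%.

The same run writes `anova_*.csv`, `pca_summary.csv`, `edma_distances.csv`,
`allometry.csv`, `manova.csv`, `confusion_matrices.csv`, the aligned-shape
archive `shapes.zip`, per-specimen sliding-energy traces, and a `report.json`
stamped with the config hash — re-running the same config reproduces the
CSVs byte for byte.

The same stages are available as a CLI:

```
morphohead simulate --out data/ --seed 3 --n-total 60
morphohead warp --template-mesh T.ply --template-lm T.csv \
                --target-mesh X.ply --target-anchors X.csv --out X_homologous.csv
morphohead gpa --landmarks-dir data/ --meta data/metadata.csv --out shapes.zip
morphohead analyze anova --shapes shapes.zip --meta data/metadata.csv --out report/
morphohead classify --shapes shapes.zip --meta data/metadata.csv --factor sex --out report/
morphohead run --out full-run/ --seed 1
```

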