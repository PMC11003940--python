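# facedissect

Dissection of 3D facial morphology for population studies.

Anthropometric studies of facial shape start from landmarked 3D surface
scans and ask two questions: *what* can be measured on a face, and *how* do
those measurements differ between population groups. `facedissect`
implements both halves as a tested Python library:

* **Phenotype extraction.** From 26 Farkas-style soft-tissue landmarks and
  the facial surface it derives the full measurement battery used in
  3D facial anthropometry — point coordinates; mean and Gaussian curvature
  (MC = (k₍max₎+k₍min₎)/2, GC = k₍max₎·k₍min₎) from local quadric fits;
  all C(26,2) = 325 Euclidean, Manhattan and on-surface geodesic distances
  (the geodesics solve the Eikonal equation |∇U| = 1 by fast marching on the
  triangulation); 32 proportion indices (smaller/larger × 100); all
  3·C(26,3) = 7800 vertex angles θ = cos⁻¹(⟨u,v⟩/|u||v|); all 2600 Heron
  triangle areas A = √(s(s−a)(s−b)(s−c)); and convex-hull volumes and
  surface areas of 10 facial regions.
* **Global-to-local segmentation.** Template vertices are clustered by the
  RV coefficient of their displacement covariation across the sample and
  recursively bipartitioned by normalized spectral splits; 7 levels give
  2⁷ − 1 = 127 nested facial modules, each contributing shape principal
  components (retained by Horn's parallel analysis), a surface area, and
  Moran's I — I = (n/Σwᵢⱼ) · Σwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)² — of its z
  coordinate and curvatures.
* **Stratification statistics.** Generalized Procrustes alignment without
  scaling; replicate-reliability summaries (per-coordinate SDs and two-way
  mixed-effects consistency ICC); a Spearman/Bonferroni screen labelling
  phenotypes heterogeneous or homogeneous across ordered regions; PLS-DA
  (NIPALS) with VIP variable selection; one-way PERMANOVA (Adonis) with
  permutation p-values; χ² design-balance tests; linear age adjustment.
* **Synthetic populations.** Raw facial scans from such studies are rarely
  deposited, so a procedural face template plus a generative population
  model (regional mean-shape gradients, individual shape noise, duplicate
  landmarking sessions with measurement noise, RBF mesh warps) makes every
  stage reproducible and testable end to end.

## Worked example

`examples/05_population_stratification.py` simulates three regions of 80
faces whose means differ along a north→south gradient on a few nose/cheek/
chin traits, extracts landmark phenotypes, and runs the statistical layer:

```
screened 455 phenotypes at Bonferroni threshold 1.10e-04
heterogeneous (region-dependent): 141
homogeneous: 314
strongest regional gradients:
                                  rho             p
Index:nose_face_width_index  0.790714  1.236621e-52
Point:pronasale.z           -0.753149  3.541214e-45
Euclidean:alare_l|alare_r    0.744531  1.182727e-43

PLS-DA: 1 components, R2X=0.100, R2Y=0.392, Q2=0.376
variables with VIP > 1: 136 (these drive the between-region separation)
PERMANOVA: R2=0.080, pseudo-F=10.4, p=0.001
```

The screen finds the planted gradient traits (nose width and projection) as
the strongest regional signals, labels the untouched majority homogeneous,
and PERMANOVA attributes 8% of the multivariate phenotype variance to
region with the smallest attainable permutation p (1/1000). The other
examples (`examples/01`–`04`) walk through simulation, alignment and
reliability, the full phenotype battery, and the 127-module segmentation.

A thin CLI mirrors the library for shell pipelines:
`facedissect simulate|align|extract|segment|analyze|report --seed N --out DIR …`.

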