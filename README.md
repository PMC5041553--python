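# esalign

Elastic shape analysis of protein 3D structures: pairwise comparison of
backbones as open curves in ℝ^(3+k), with a geodesic shape distance as the
dissimilarity score.

## Who this is for

Structural bioinformaticians who need a fast, alignment-free-in-spirit but
correspondence-aware dissimilarity between two protein chains — for
all-vs-all screening, clustering against SCOP-style class labels, or as a
scoring backend. The method is rigid-motion, translation and scale
invariant and handles unequal chain lengths through optimal
reparameterization.

## The method

Each chain is turned into a composite curve **P** ∈ ℝ^((3+k)×n): three rows
of backbone geometry under one of three criteria —

| criterion | geometry | n |
|---|---|---|
| `ESA-BB` | N, Cα, C atoms interleaved | 3 × residues |
| `ESA-CA` | Cα atoms only | residues |
| `ESA-MC-BB` | centroid of N, Cα, C | residues |

— plus *k* auxiliary rows: backbone dihedrals φ, ψ, ω (always included for
`ESA-CA`/`ESA-MC-BB`) and optional per-residue molecular properties
(hydrophobicity `HP`, polarity `POL`, residue mass `MASS`, functional-group
class `GROUP`, side-chain heavy-atom count `SC-ATOMS`). Glycine contributes
backbone information only (zero side-chain atoms).

The curve is parameterized by normalized spatial arc length T ∈ [0, 1] and
mapped to its square-root velocity function (SRVF)

```
q(t) = (dP/dT) / √‖dP/dT‖ ,
```

under which the elastic metric on curves becomes the ordinary L² metric.
Two SRVFs Q₁, Q₂ on the merged parameter grid are then aligned by

1. **optimal rotation** — the Kabsch/Procrustes solution
   R = U·diag(1, 1, det(UVᵀ))·Vᵀ from the SVD of the weighted spatial
   cross-covariance A = Q₁W Q₂ᵀ, applied as R_A = blockdiag(R, I_k) so the
   property channels never rotate;
2. **optimal matching** — dynamic programming over monotone
   reparameterizations γ of [0, 1], minimizing
   ∫‖q₁(t) − √γ̇(t)·q₂(γ(t))‖² dt;
3. **geodesic distance** — θ = cos⁻¹⟨q₁, q₂*⟩ between the unit-normalized
   SRVFs, i.e. arc length on the unit sphere of the shape space; θ = 0 for
   identical shapes, larger θ for greater shape difference.

For evaluation, all-vs-all θ matrices are converted to similarities by the
sigmoid s(x) = 2/(1 + e^{αx}) and scored against class labels by k-means,
fuzzy c-means and spectral clustering followed by confusion-matrix
statistics (precision, recall, F-measure, Rand index).

## Worked example

Generate two 50-residue synthetic chains (an α-helix-like spiral and an
extended strand) and compare them with Cα geometry, dihedrals, and
hydrophobicity as an auxiliary channel:

```python
from esalign import FixtureSpec, chain_to_pdb, make_chain

with open("helix.pdb", "w") as f:
    f.write(chain_to_pdb(make_chain(FixtureSpec(n_residues=50, family="helix", seed=1))))
with open("strand.pdb", "w") as f:
    f.write(chain_to_pdb(make_chain(FixtureSpec(n_residues=50, family="strand", seed=2))))
```

```
$ esalign compare helix.pdb strand.pdb --criterion ESA-CA --features HP --out report.json
theta = 1.095982 rad (cos = 0.457173)
```

θ ≈ 1.10 rad says the two shapes are far apart on the SRVF sphere (a
structure against a rigidly moved copy of itself gives θ < 1e-5; two
independent noisy copies of the same fold give θ ≈ 0.3–0.7). The JSON
report records the criterion, feature set, residue counts, the merged grid
size (98 here), the 3×3 rotation and the warp γ's change points.

All-vs-all evaluation on a labelled directory:

```
$ esalign matrix demo/ --labels demo/labels.tsv --cluster-method all --seed 0 --out-prefix demo_run
distance matrix (10x10) -> demo_run_distance.tsv
kmeans: RI(accuracy) = 1.0000, RI(pairs) = 1.0000, macro-F = 1.0000
fuzzy-cmeans: RI(accuracy) = 1.0000, RI(pairs) = 1.0000, macro-F = 1.0000
spectral: RI(accuracy) = 1.0000, RI(pairs) = 1.0000, macro-F = 1.0000
metrics -> demo_run_metrics.json
```

Here `demo/` held two families × five noisy replicas (σ = 0.05 Å) from
`esalign.make_dataset`; all three clustering methods recover the families
perfectly.

The same pipeline is available as a library: `esalign.compare_structures`
(paths in, `GeodesicResult` out), `esalign.distance_matrix`,
`esalign.cluster_and_score`.

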