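# Methods

## Model

A protein chain is represented as an open curve in ℝ^(3+k): three spatial
rows from the backbone (criteria `ESA-BB`, `ESA-CA`, `ESA-MC-BB`) and k
auxiliary rows — backbone torsions φ, ψ, ω and optional per-residue
molecular properties. Comparison is elastic shape analysis on the
square-root velocity function (SRVF) q = (dP/dT)/√‖dP/dT‖: after removing
translation (differencing), scale (canonicalization, below), rotation
(Procrustes/Kabsch on the spatial block) and reparameterization (dynamic
programming over monotone warps), the dissimilarity is the spherical
geodesic θ = cos⁻¹⟨q₁, q₂⟩ between unit-normalized SRVFs, θ ∈ [0, π].

The pipeline runs each stage once, in order: build curves → arc-length
parameterization → SRVF → grid merge and resampling → optimal rotation →
optimal matching → distance. An optional alternation of rotation and
matching (`CompareConfig.max_iter` > 1, convergence tolerance 1e-6 rad) is
available but off by default; a single pass matches the method's step
structure and was sufficient in every experiment we ran.

## Parameterization and discretization

* **Arc length** is cumulative Euclidean distance over the *spatial* rows
  only, normalized to [0, 1]. Zero-length segments (duplicate atoms) are
  dropped with a log message; `arc_length_parameterization` therefore
  returns the (possibly reduced) curve together with its grid.
* **Derivatives** are nonuniform finite differences (central in the
  interior, one-sided at the ends), keeping one SRVF column per sample. A
  curve of n points keeps n columns, as the (3+k)×n layout implies.
* **Grid merging** is the sorted union with near-duplicates (< 1e-12)
  collapsed; the merged length n obeys max(n₁, n₂) ≤ n ≤ n₁+n₂−2. SRVFs
  are carried onto new grids by per-row linear interpolation.
* **Inner products** are grid-weighted (trapezoidal cell widths), i.e. a
  discrete L² product; the same weights enter the rotation
  cross-covariance.

## Invariances and the scale canonicalization

Translation invariance is inherited from differencing. Rotation is removed
by the Kabsch solution R = U diag(1,1,det(UVᵀ)) Vᵀ of the weighted spatial
Procrustes problem — the determinant correction guarantees a proper
rotation even for planar (reflection-prone) inputs. Only the spatial block
rotates; auxiliary channels are physically rotation-free and pass through
an identity block.

Scale needs care once auxiliary channels exist: dihedral and property rows
carry no length unit, so scaling the coordinates by c would change the
spatial rows' weight relative to the auxiliary rows and no normalization
of q alone can undo it. The pipeline therefore rescales the spatial rows
of each curve to **unit mean segment spacing** before the SRVF transform
(`canonicalize_scale`). This makes θ(P, cP) = 0 exactly, and it keeps the
natural balance between channels: over a curve of n points, the spatial
derivative magnitude is then ≈ n·(segment/mean-segment) while a
standardized auxiliary row's derivative is also O(n), so neither side
dominates simply because of units.

## Auxiliary channels

Default property scales (all overridable via `PropertyTable.from_files`,
two-column `code value` text files):

| channel | scale | units |
|---|---|---|
| `HP` | Kyte–Doolittle hydropathy | dimensionless |
| `POL` | Grantham (1974) polarity | dimensionless |
| `MASS` | monoisotopic residue mass | Da |
| `GROUP` | functional-group class 1–4 (aliphatic / acyclic polar-charged / hydroxyl-sulphur / aromatic) | code |
| `SC-ATOMS` | side-chain heavy atoms | count |

Property rows are standardized per chain (mean 0, sd 1; constant rows →
zero) and multiplied by a per-channel weight (default 1.0) — raw mixing of
Å, Da and dimensionless scales would let mass dominate. Dihedral rows stay
in raw radians (already O(1)); undefined values (chain termini, collinear
quadruples) become 0 after logging. Torsions follow the field's sign
convention (α-helix φ ≈ −60°); values within 1e-9 of the ±π branch cut are
snapped to +π, because exactly planar trans configurations otherwise flip
sign under rigid motion through rounding noise. The circular discontinuity
at ±π for genuinely near-cis/trans angles is accepted; a circular (sin,
cos) embedding would be the alternative if it ever matters in practice.

Nonstandard residues are mapped to their parent standard residue through a
small editable table (MSE→MET etc.); unmapped codes raise in strict mode
or take a logged neutral value otherwise. Glycine is an ordinary table
entry with `SC-ATOMS` = 0 and no side-chain-derived geometry anywhere.

## Dynamic-programming matching

The matching graph has one vertex per grid-index pair (i, j) and edges
stepping 1..w forward in each index (w = `jump_window`, default 5 — slopes
between 1/5 and 5 per segment). Edge (a, b)→(i, j) costs
∫‖q₁(t) − √γ̇ q₂(γ(t))‖² dt for the linear warp of [T_a, T_i] onto
[T_b, T_j], integrated by trapezoidal quadrature on the grid points inside
the segment. The graph is a DAG, so one topological pass (O(n²w²))
finds the same optimum an all-pairs shortest-path formulation would at
O(n³). The inner loops are numba-compiled; a 300-vs-300-residue `ESA-CA`
comparison (merged grid ≈ 600) runs in under a second after JIT warm-up.
For n ≤ 7 the DP optimum is bit-identical to exhaustive enumeration over
all monotone paths (tested at 100 random instances).

The optimal path yields γ as a piecewise-linear warp through grid vertices
(change points T_g, values G); the second curve is warped as
q₂*(t) = √γ̇(t)·q₂(γ(t)) with γ̇ piecewise constant, then both SRVFs are
re-normalized on the re-merged grid before the final inner product (the
re-merge is a no-op here because the warp's change points are grid
points, but it is executed for fidelity to the step structure). The
cosine is clamped to [−1, 1]; clamping beyond 1e-6 is logged.

**Asymmetry.** The DP is directional, so θ(A,B) ≠ θ(B,A) exactly. Measured
on fixture pairs: ≤ 0.01–0.02 rad for structurally similar chains, up to
≈ 0.16 rad for very dissimilar ones (helix vs random coil), where the
optimal warp is aggressive and interpolation loss differs by direction.
Enriching the final grid with γ-preimages did not reduce this. When a
symmetric matrix matters, `distance_matrix(..., both_directions=True)`
averages the two directions; the default computes each unordered pair once
and mirrors.

## Evaluation harness

`distance_matrix` flags failed pairs as missing (NaN) and aborts if more
than 20 % of pairs fail. Similarity is s(x) = 2/(1+e^{αx}) (s(0)=1,
strictly decreasing; α default 1). `cluster_and_score` feeds spectral
clustering the similarity matrix directly and embeds distances by
classical (Torgerson) MDS into min(N−1, 10) dimensions for k-means and
fuzzy c-means (Bezdek updates, fuzzifier m = 2, tolerance 1e-6). Clusters
are mapped to classes by Hungarian maximum-agreement assignment — without
a fixed mapping the confusion-matrix metrics would be ill-defined.

Two Rand-index readings are reported because the accuracy-style formula
and the pair-counting Rand index are frequently conflated: `ri_accuracy`
= Σᵢ Mᵢᵢ / Σᵢⱼ Mᵢⱼ on the mapped confusion matrix, and `ri_pairs` = the
standard pair-counting index computed from the contingency table. Classes
with an empty row or column get NaN metrics and are excluded from macro
averages, with a log message.

## Synthetic fixtures

`make_chain` builds stylized backbones: helix (Cα radius 2.3 Å, rise
1.5 Å/residue, 100°/residue), strand (3.5 Å spacing, ±1 Å zigzag), and a
persistent random walk (3.8 Å steps). N and C are placed ±0.75 Å along the
local Cα tangent **plus a fixed 0.35 Å off-tangent shift**: with N, Cα, C
exactly collinear every torsion quadruple is degenerate, which turns the
mandatory dihedral channels into pure noise under coordinate perturbation
and masks genuine shape differences. The off-tangent shift keeps all
fixture guarantees (three distinct ordered backbone atoms, constant Cα
spacing, determinism per seed, byte-identical PDB output) while making
φ/ψ/ω well defined and stable.

These fixtures are deliberately not Ramachandran-accurate: bond lengths,
angles and torsion distributions are stylized, and no side-chain atoms are
placed. Passing tests on them demonstrates the algorithm's mathematical
properties (invariances, optimality, separability of distinct geometries),
not biological accuracy on real PDB structures — real chains bring missing
atoms, alternate locations, nonstandard residues and chain breaks, which
`structure_io` handles by dropping/flagging with logs, but the geometric
realism of the fixtures is no evidence about classification accuracy on
real folds.

Problem sizes used by the test suite and the reproduction script were
chosen to exercise every property at interactive scale: 20–60-residue
chains for invariance checks, 2 families × 5 replicas × 40 residues for
clustering (noise σ ∈ {0.05, 0.5, 2.0} Å, 5 seeds for the noise trend),
n ≤ 7 grids for exhaustive-path oracles, and one 300-residue pair for the
large-comparison timing.

## Known limitations

* Global, sequential alignment only — no partial, local or non-sequential
  matching, and no multiple (> 2) alignment.
* θ is not exactly symmetric (see above); use direction averaging when a
  metric-like matrix is required.
* The warp is restricted to grid vertices with slopes in [1/w, w];
  pathological reparameterizations outside that band are not reachable.
* Dihedral channels use raw angles; shapes whose torsions hover near ±π
  can see inflated channel differences from the branch cut.
* PDB input only (wwPDB v3.3 ATOM records); no mmCIF, assemblies or
  symmetry expansion.
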