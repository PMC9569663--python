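# Methods

## Model and procedure

kinogen treats generative molecular design as guided navigation of a
continuous latent space. Given per-family seed sets of known inhibitors, the
pipeline encodes all seeds into R^d (d = 196 by default), fits K-means on
the pooled cloud, and replaces each encoding x by

    x* = (1 − s) x + s c,    s ∈ [0, 1],

where c is the centroid of x's own cluster — never a foreign cluster, so
perturbations stay specific to the structural motif the cluster represents.
The two endpoints are exact by construction: s = 0 returns x and s = 1
returns c (the convex-combination evaluation keeps both floating-point
exact, and gives the contraction identity ‖x*−c‖ = (1−s)‖x−c‖ to ~1e−14).
Zero-mean Gaussian noise is added **after** the contraction.

Each perturbed location is decoded stochastically: 500 attempts, each
validity-checked by canonicalization (multi-fragment SMILES count as
invalid), with acceptance requiring ≥ 100 valid attempts. Retained strings
shorter than 10 raw SMILES characters are dropped, and locations with zero
valid decodes are flagged for exclusion. Accepted decodes become
`GENERATED` records carrying the seed's family as `origin_family`.

Post-processing applies nested filters: deduplication by canonical SMILES
(first-seen survivor, multiplicities summed), novelty against the union of
seed and background sets, a strict likelihood gate (classifier probability
> 0.7), and a high-similarity stage (top 100 by maximum Tanimoto to the
target-family reference among scores strictly > 0.6; ties break by score
descending then lexicographic SMILES). Stage attribution reports each
stage's per-origin-family percentages.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | number of K-means clusters over the pooled seed cloud |
| `s` | 0.8 | contraction fraction towards the own-cluster centroid |
| `noise_level` | 5.0 | noise std as a **percentage of each latent dimension's empirical std** over the encoded input set (the "relative" model); an isotropic absolute-std alternative is selectable |
| `attempts` / `min_valid` / `min_len` | 500 / 100 / 10 | decode-gate budget, acceptance minimum, minimum SMILES length (raw characters) |
| `likelihood_threshold` | 0.7 | strict lower bound for the likelihood gate |
| `seed` | — | master seed; every random stream in a run derives from it |

The defaults (k=3, s=0.8, noise 5) are the configuration found optimal for
yield of valid, novel molecules; sweeps over s ∈ {0.2, 0.8} and noise ∈
{5, 30} are bundled in the test and acceptance harnesses.

Classifier: Random Forest, 500 trees, unlimited depth, √p features per
split, unweighted classes (a `class_weight="balanced"` option exists),
seeded. Predictors are either the 20-descriptor chemical feature vector or
the raw d latent coordinates (d + 1 = 197 table columns); descriptor values
enter unstandardized since tree models are scale-invariant. Train/test
protocol: stratified 80/20 split with a fixed seed; metrics on the held-out
fold. Accuracy, precision, recall and F1 come from the binary confusion
matrix; undefined ratios (empty denominators) are reported as NaN with a
warning, never silently as 0. ROC plots sensitivity against 1 − specificity
with trapezoidal AUC; the test suite cross-checks AUC against an
independent pairwise-comparison (Mann–Whitney) oracle.

Stereochemistry is preserved when present but never enumerated;
stereocenter counts include unassigned centers. The synthetic-accessibility
score uses the published fragment-contribution scheme shipped with RDKit's
contrib tree, behind a swappable interface so unit tests can stub it.

## The surrogate embedder

The encoder the original pipeline assumes is an external pre-trained
network; the method under test here is the navigation and gating layer, so
the bundled surrogate must be exercisable offline and deterministic:

- **Encoding**: Morgan fingerprint (2048 bits, radius 2) × a fixed seeded
  Gaussian projection to d = 196, L2-normalised. Similar structures share
  bits and land close in latent space (tested as an ordering property).
- **Decoding**: per attempt, a validity draw followed by a
  softmax-weighted nearest-neighbour lookup over an encoded candidate
  library (temperature 0.01 on squared distances, sharply peaked so a
  library point decodes to itself almost surely — the round-trip property).
- **Validity model**: p_valid(z) = min(1, (ρ(z)/ρ_ref)^γ) with ρ a
  Gaussian-kernel density over the library cloud (bandwidth = median
  nearest-neighbour distance), ρ_ref the 5% quantile of the library's
  self-densities, γ = 4. On-manifold and centroid-ward locations decode
  almost surely; far-off locations collapse to 0% validity.

### What the surrogate does and does not emulate

The surrogate reproduces: determinism under seed, locality (similar
molecules ↔ nearby encodings), stochastic decoding with multiplicities,
validity collapse far off the data manifold, and the round trip
decode(encode(m)) → m. It does **not** reproduce the noise-level phenomenology
of a trained neural decoder at realistic scale: with a desk-scale candidate
library (~100 molecules) the library's inter-point spacing (~0.5 in
normalized latent units) is larger than the displacement produced by noise
level 30 (~0.23), so valid-molecule yield saturates across the swept noise
range and declines only when displacement reaches the spacing scale
(level ≳ 100). Yield orderings across (s, noise) configurations therefore
hold as ties at saturation rather than strict decreases. The novelty channel
is unaffected — low s decodes back to the seeds while s = 0.8 reaches
neighbouring scaffolds — and the likelihood-gate enrichment and
stage-attribution behaviour of the full pipeline are exercised genuinely.
Passing tests consequently demonstrate the correctness of the perturbation
algebra, gating logic, classifier plumbing and post-processing — not that a
particular noise level is optimal for any real encoder.

## Synthetic data

Scaffold families: each family is one hinge-binder-like heteroaromatic core
(aminopyrimidine, quinazoline, benzimidazole, …) enumerated with small
substituents; within-family mean pairwise Tanimoto similarity is asserted
to exceed the between-family mean at generation time. This mimics the
family structure of curated inhibitor sets without claiming statistical
fidelity to any real compound collection. Latent blobs (axis-aligned
centers at a configurable pairwise separation, isotropic spread) exercise
clustering; labeled tables with designated signal columns and a tunable
effect size exercise the classifiers.

Desk-scale problem sizes used throughout the harnesses: 3 families × 30
library molecules (10 seeds each), 500-attempt gates, 20-seed sweeps,
500–1000 rows per class for classifier tables. These sizes were chosen so
every property is measured with comfortable statistical margins while the
full suite stays fast on one CPU.

## Numerical choices and degenerate inputs

- Population (divide-by-n) convention for per-dimension standard
  deviations in family statistics, so singleton families give 0 (flagged).
- PCA is fit on the union of the sets being co-visualized; rank-0 input
  (all rows identical) yields ratios (0, 0) with a warning rather than an
  error.
- K-means uses k-means++ with 10 restarts and a fixed seed; refitting on
  permuted rows reproduces centroids up to index permutation.
- Decode-gate determinism: the surrogate's vectorised path (binomial +
  multinomial draws) is the statistical equivalent of per-attempt
  simulation; stub decoders without the vectorised hook take the
  per-attempt path, where each distinct output is canonicalized once.
- Strict inequalities throughout the filters ("< 700 Da", "> 0.7", "> 0.6")
  — boundary values are excluded by design.
- A decoder exception during one attempt counts as an invalid attempt and
  never aborts the gate.

## Known limitations

- The surrogate decoder can only emit molecules present in its candidate
  library; novelty is therefore relative to the seed subset, not open-ended.
- Noise-collapse scale differs from a trained decoder (see above).
- The multiclass classifier is provided and tested for table construction
  and training, but the generation pipeline steers with the binary model
  only, mirroring the intended use.
- No 3D, docking or synthesis-route reasoning; similarity is 2D
  fingerprint-based.
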