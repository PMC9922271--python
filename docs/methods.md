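# Methods

## The model

`metaviz` assesses and combines an ensemble of K two-dimensional embeddings
("candidate visualizations") X^(1), …, X^(K) of the same n samples. Each
candidate is summarized by its **normalized pairwise-distance matrix**

    P̄^(k) = D^(k)⁻¹ P^(k),   P^(k)_ij = ‖X_i^(k) − X_j^(k)‖₂,

where D^(k) is the diagonal matrix of row norms of P^(k). Every row of
P̄^(k) is a unit vector, and the summary is invariant to translation,
rotation, reflection and positive rescaling of the embedding — the only
transformations under which a visualization is usually considered equivalent.

For each sample i the rows P̄^(1)_{i·}, …, P̄^(K)_{i·} are K unit vectors in
R^n. Their Gram matrix

    G_i = ( ⟨P̄^(k₁)_{i·}, P̄^(k₂)_{i·}⟩ )_{k₁,k₂}

measures the pairwise local concordance of the candidates around sample i.
The **eigenscores** ŝ_i are the entrywise absolute value of the unit
eigenvector of G_i for its largest eigenvalue — equivalently, the first
principal-component loadings of the stacked n × K matrix
[P̄^(1)_{i·} … P̄^(K)_{i·}]. Under a signal-plus-noise model for the distance
rows, ŝ_i is a consistent estimate (up to normalization) of the **true local
concordance** s_i, whose k-th entry is ⟨P̄^(k)_{i·}, P̄*_{i·}⟩ with P̄* the
normalized distance matrix of the noiseless samples. Candidates that locally
agree with the (unobserved) signal structure therefore receive high
eigenscores without ever looking at the raw data.

The **meta-distance** combines the ensemble row-wise,

    P̄^m_{i·} = Σ_k ŝ_{i,k} P̄^(k)_{i·},

with no renormalization (the eigenscore vector is already unit-norm). A
uniform-weight variant (the *naive* meta-distance, weights 1/K) is provided
as the baseline. The meta-distance is generally asymmetric; for rendering it
is symmetrized as P̄^m + (P̄^m)ᵀ and handed to an embedding method that
accepts precomputed distances.

### Assumptions and limitations

- The theory behind the eigenscores assumes the candidates' distortions from
  the truth are sub-Gaussian, not too strongly correlated across candidates
  (no large block of near-duplicate methods), and that the ensemble carries
  enough signal overall. When every candidate is equally bad, the eigenscores
  degrade gracefully toward uniform weights.
- The absolute-value convention for the leading eigenvector is motivated by
  Perron–Frobenius: with nonnegative distance rows, all entries of G_i are
  nonnegative, and for strictly positive G_i the leading eigenvector has a
  single sign. If a user supplies exotic precomputed rows that produce a
  genuinely mixed-sign leading eigenvector, the absolute value is still taken
  and the event is logged; the scores are then hard to interpret.
- Exact pairwise distances only; no approximate-nearest-neighbour shortcuts.
  Cost is O(K n²) memory and O(n K² + K³) per-sample eigenwork, fine for
  n up to a few tens of thousands.

### Numerical choices

- **Eigenvalue near-ties.** The full symmetric eigendecomposition is
  computed; if the top two eigenvalues of G_i differ by less than 1e−9·K the
  tied eigenvectors are compared by the ℓ1 norm of their absolute values and
  then lexicographically, making degenerate inputs (e.g. two mutually
  orthogonal candidates) deterministic.
- **Degenerate distance rows** (all points of a candidate coincide with
  sample i, row norm 0): the default is a hard error naming the candidate
  and sample; an opt-in policy (`on_degenerate="zero"`) replaces the row with
  zeros, which zeroes that candidate's column of G_i and hence its eigenscore
  at i — the candidate simply stops contributing there.
- **User-supplied matrices** are validated (unit rows to 1e−6 relative, for
  text round-trips; no negative entries; zero diagonal) and never clipped.
- The per-sample loop is embarrassingly parallel and carries no shared
  mutable state; results are identical whatever the execution order.

## Candidate registry

The default registry produces 16 candidates from 12 base methods: PCA,
metric MDS, Kruskal's non-metric MDS, Sammon's mapping, LLE, Hessian LLE,
LTSA, isomap, kernel PCA (Gaussian kernel, median-distance bandwidth),
Laplacian eigenmaps, UMAP and t-SNE. The four most tuning-sensitive methods
are included with two parameter settings each — kPCA (bandwidth = median and
3× median), isomap (10 and 30 neighbours), UMAP (15 and 100 neighbours),
t-SNE (perplexity 30 and 100). These parameter pairs are package defaults
(each library's default plus one perturbed setting), not canonical values.
All adapters delegate to scikit-learn or umap-learn except Sammon's mapping,
which no installed library provides; it is implemented in-package with the
classic diagonal-Newton descent (step factor 0.3, PCA initialization).
Neighbour counts and perplexities are clamped to valid ranges for small n.
Downstream scoring needs only the embeddings, never the raw data matrix.

## Synthetic benchmarks

The generator emulates the signal-plus-noise model Y_i = Y*_i + Z_i with
Z_i ~ N(0, I_p) i.i.d. and signals drawn from a low-dimensional structure,
isometrically embedded into R^p by a Haar-random rotation (QR of a Gaussian
matrix with positive-diagonal sign fix), so the observed coordinates are
dense. A single seed is split (`numpy.random.SeedSequence.spawn`) into
independent streams for rotation, latent sampling and noise, so changing n
leaves the rotation unchanged. Structures:

- **mixture** — r+1 mutually orthogonal centers of norm θ (default r = 5,
  i.e. six clusters, pairwise center distance √2·θ); intrinsic dimension of
  the centered signals is r.
- **smiley** — a fixed unit-diameter 2-D geometry scaled by θ: outline
  circle of radius 0.5, eye discs of radius 0.05 at (±0.18, 0.15), mouth arc
  of radius 0.3 spanning 200°–340° about (0, 0.05). Component weights are
  fixed at 0.55 / 0.25 / 0.10 / 0.10 (outline / mouth / eyes): weighting the
  tiny eye discs by literal area would leave them essentially unsampled at
  n ≈ 500, defeating the purpose of a four-component geometry.
- **mammoth** — a *synthetic*, procedurally generated 3-D mammoth-shaped
  point cloud (ellipsoidal body, spherical head, four leg cylinders, curved
  trunk, two tusk arcs; 4096 points, deterministic), rescaled to unit
  diameter and sampled uniformly with replacement, then scaled by θ. It is a
  stand-in geometry, not the public photogrammetry reconstruction often used
  for this benchmark; any fixed 3-D manifold with mixed component structure
  serves the same role here.

θ is the SNR dial: the norm (mixture) or diameter (smiley/mammoth) of the
latent structure against unit-variance noise. Default equispaced grids are
θ ∈ [2, 8] for the mixture and θ ∈ [10, 40] for the two manifolds (20 points
by default), chosen so per-coordinate SNR spans weak to strong and the
ranges are comparable across structures.

What the generator does **not** emulate: heteroskedastic or heavy-tailed
noise, count sampling, batch effects, or feature correlations typical of
real transcriptomic data. Passing benchmarks here demonstrates the spectral
machinery under its stated model, not performance on any particular real
dataset.

## Evaluation metrics

- **Eigenscore–truth cosine** cos∠(ŝ_i, s_i), averaged over samples: how
  precisely the eigenscores recover the true local concordance.
- **Meta concordance**: per-sample cosine between meta-distance rows and the
  reference rows P̄*_{i·} (meta rows renormalized for the cosine only).
- **Silhouette** on normalized distance matrices (symmetrized by averaging);
  singleton classes score 0.
- **Circular ordering**: samples ranked by angle after mean-centering the
  2-D coordinates (centering makes the statistic translation-invariant;
  radius is discarded). Compared with a true cyclic order by Kendall's tau
  maximized over cyclic shifts of either order and both directions, since a
  cycle has no origin or orientation; the maximized statistic is exactly
  shift-invariant but positively biased under the null.
- **Linear ordering**: ranks along the first principal axis of the 2-D
  coordinates; tau reported as the maximum over the two orientations.
- **Adversarial candidates**: normalized distance matrices of random
  2-D Gaussian embeddings, independent of the data. Note these are
  *approximately* uninformative, not orthogonal to the reference: nonnegative
  unit rows always retain an inner product of roughly 0.6–0.7 with any
  reference row through their shared positive mean component. Consequently
  the naive (uniform-weight) meta-distance degrades only mildly under such
  contamination when measured by cosine concordance — the spectral-vs-naive
  cosine gap with 20% adversaries has a ceiling of a few hundredths even for
  perfect weighting — although the spectral weighting is consistently the
  better of the two at fixed seeds.

## Validation scale

The test suite and `scripts/acceptance.py` exercise the full 16-candidate
pipeline at reduced problem sizes, a deliberate package choice to keep the
benchmark suite desk-scale: the acceptance script uses n = 300, p = 200
(mixture) and n = 250, p = 150 (smiley, mammoth) with 5-point θ grids; the
test suite uses n = 200/150. The grid-averaged eigenscore–truth cosine is
insensitive to this reduction (it stays ≈ 0.99 across scales, as at full
scale), which is what makes the reduction defensible for this statistic.

## Rendering

`render_meta` supports UMAP (`metric="precomputed"`, recommended for cluster
structure), kernel PCA (the symmetrized meta-distance is converted to a
Gaussian kernel exp(−d²/2h²) with h the median off-diagonal distance — a
documented default, as kernelization of a distance matrix has no canonical
choice), and t-SNE (`metric="precomputed"`, random initialization). All are
deterministic given (method, params, seed). When rendering an ensemble that
contains candidates of the same family as the renderer, a practical default
is to copy the hyper-parameters of the family member with the highest median
eigenscore; `MetaVisualizationResults.summary()` exposes the ranking needed
for that choice.
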