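# Methods

This note documents the models, numerical choices and limitations of the
package; the README gives the one-screen overview.

## Source model and inverse operators

The source space is the vertex set of a triangulated cortical surface with
free dipole orientation (3 unknowns per node, ordering `3j + {0,1,2}` for
the x/y/z moments of node j). Two operator forms solve the l2 problem:

* **direct**: `T = W⁻¹Lᵀ [LW⁻¹Lᵀ + αI]⁻¹`, computed by a Cholesky solve of
  the n×n system; α > 0 is an absolute Tikhonov parameter.
* **truncated SVD**: `T = W⁻¹Lᵀ · pinv(LW⁻¹Lᵀ, βμ)` with β ∈ (0,1] relative
  to μ, the largest singular value of `LW⁻¹Lᵀ`. Singular values strictly
  below βμ are zeroed; β = 1 keeps only the leading one.

`W = core ⊗ I₃` is never formed densely: one sparse LU factorization of the
m×m core serves all three orientation coordinates (the 3m-vector is folded
to an m×3 block before the solve). Factorization failure raises an error
carrying a condition estimate; nothing is silently re-regularized, since σ
and α are the method's explicit knobs.

The α for a discrete spectrum is set by the SVD cutoff index (SCI): with
the positive singular values of `LW⁻¹Lᵀ` sorted ascending, SCI = k zeroes
the k smallest; the cutoff value (SCV) is placed *between* s_k and s_{k+1}
as their geometric mean — scale-invariant and guaranteeing α = SCV/s_max ∈
(0,1) — and α (used as β in the truncated-SVD form) is SCV divided by the
largest singular value. With average-referenced data the smallest singular
value is the numerical reference-null, so SCI = 1 removes exactly the
non-physical direction.

## Depth weighting

`depth_weights` implements Ω_jj = Σ_i l_ijᵀ l_ij (the summed squared
channel responses of source j's three columns) by default, with a
`sqrt_variant` switch for Ω_jj = (Σ_i l_ijᵀ l_ij)^{1/2} — the original
LORETA definition. Because Ω enters W twice, the squared form penalizes
sources by the fourth power of their leadfield norm. In the
homogeneous-sphere forward model this over-compensates depth severely: the
baseline minimum-norm estimates land ~3 mm too deep on average and the
LORETA estimates ~10 mm too deep, inverting every qualitative comparison
the protocol is designed to show. The square-root form leaves the baseline
essentially depth-unbiased (mean center-of-mass depth shift ≈ +0.1 mm on
the default benchmark). The *pipeline* therefore uses the square-root
variant as its study condition (`BenchmarkConfig.depth_weight_sqrt`,
default on); the low-level default remains the squared form so both
conventions stay available.

## The smoothness prior and σ

`BᵀB` is singular (constants span the kernel of every scheme), so the prior
core is `BᵀB + σI`. The nominal range σ ∈ (0, η²], η = ‖BᵀB‖₂, is enforced
as a warning, not an error, for a structural reason worth knowing: the
"large σ attenuates the Laplacian" behaviour requires σ to dominate η,
which inside (0, η²] is only possible when η > 1. The graph Laplacians on
typical meshes have η ~ 10²–10⁴ and attenuate as expected; the weighted
schemes built from millimetre distances and mm² areas have η ≪ 1, so the
whole nominal range lies in the strong-smoothing regime and their
σ-deviation curves need not be monotone there. Scale-invariant choices such
as σ = ρ·η behave uniformly across schemes and are used in unit fixtures.

σ selection follows the trade-off scan: for each (σ, α) on a grid, the
cortical solution's goodness of fit against the data and its deviation from
the no-Laplacian solution at the same α are tabulated; σ is *satisfying*
when GOF ≥ 90% and deviation ≥ 10% hold for **all** α in the grid
(requiring all α is the stricter of the two natural quantifications over
the per-α curves), and σ* is the arithmetic mean of
the satisfying set. The scan's α ∈ {0.01, 0.005, 0.0025} are dimensionless;
the scan applies the direct operator at absolute α·μ, whose smoothness in σ
the monotone-attenuation behaviour relies on. When no σ satisfies both
conditions the selection drops the largest α and retries (relaxing the
most demanding fit requirement first), then falls back to the
maximum-deviation σ with GOF ≥ 90%. The scan dataset is standardized: two
bilaterally symmetric lateral sources (the most lateral ±x simulation
candidates, auditory-cortex-like) with identical moments and white noise
at SNR 20 — a fixed configuration, so the selected σ* does not depend on
the benchmark's random dipole draw (it varies by < 15% across seeds,
versus two orders of magnitude when scanned on a random single dipole).

## Synthetic data

* **Cortex surrogate** (`make_cortex_like_surface`): Fibonacci-spiral
  points on the unit sphere with a small seeded tangential jitter,
  triangulated by their convex hull (exact node count, irregular
  triangulation), radially displaced by a smooth sinusoidal fold pattern
  and scaled per axis. Defaults — 65 mm base radius, 12% fold amplitude,
  angular frequency 6, axes (1.0, 0.85, 0.9) — give a closed, folded,
  cortex-scale surface fitting inside an 85 mm scalp sphere with node
  depths spanning roughly 10–45 mm under the covered cap. What it does
  *not* emulate: the sheet-like, two-hemisphere topology of real cortex,
  opposing sulcal banks, or surface cuts; a compact deep blob here always
  surfaces as a single island, whereas on a real cortex it can surface on
  several gyri.
* **Montage**: golden-angle spiral over a 130° polar cap (85 mm radius) —
  quasi-equidistant for any sensor count, deterministic.
* **Leadfield**: closed-form current-dipole potential in a homogeneous
  conducting sphere (insulating exterior; conductivity 0.33 S/m), derived
  by summing the Legendre expansion of the internal monopole exactly.
  Units: positions mm, moments nA·m, potentials µV, average reference.
  This keeps every property the evaluation needs — linearity, rotational
  equivariance, depth attenuation — but decays faster with depth than a
  skull-attenuated multi-shell model, which matters for depth-bias
  comparisons (below).
* **Datasets**: one dipole per dataset at a random triangle barycenter of
  the inverse mesh (guaranteed disjoint from the inverse nodes), random
  uniform orientation, 10 nA·m moment. Noise, when requested, is white
  Gaussian rescaled so the channel-pooled RMS signal-to-noise ratio is met
  exactly; the generator accepts a seed and is fully deterministic.

## Benchmark protocol and what it shows

Defaults: 100 noiseless datasets, 1,000-node cortex, 64 sensors, σ per
scheme from the scan, SCI = 1, truncated-SVD operators built once per
method. On these conditions the Laplacian variants beat the depth-weighted
minimum norm on mean localization error (max-amplitude node: 9.8–11.1 mm
vs 11.7 mm at seed 0) — the headline benefit of surface smoothing.

Two measures do **not** favour the Laplacian variants under these
conditions, for structural reasons visible in the numbers the acceptance
script emits:

* **Local-maxima count** (raw, amplitude-blind): the exact-fit LORETA
  solutions carry sub-1%-amplitude ripple — the final Ω⁻¹ factor of W⁻¹
  modulates the smoothed field with the surface corrugation — which the
  strict neighbour-dominance count registers even though the corresponding
  50%-masked images are single blobs.
* **Depth correlation**: with square-root depth weights the baseline is
  already depth-unbiased in a homogeneous sphere, so the smoothing prior
  has no residual superficial bias to correct; its small extra deepening
  slightly widens the depth scatter instead.

Both are properties of the replication conditions (single-sphere forward
model, convex corrugated surrogate, 64-channel cap), not of the operators.

## Numerical choices

* Obtuseness test: law-of-cosines numerator with 1e-12 relative tolerance;
  right angles take the (limit-equivalent) Voronoi branch.
* Spectra of the mass-normalized stiffness matrix via the similarity
  transform `D^{1/2} B D^{-1/2}` (real symmetric by construction); a zero
  eigenvalue is one below 1e-8 of the largest.
* Negative cotangent weights on obtuse meshes are kept as-is.
* Boundary edges (open meshes) use the single available opposite angle.
* Max-amplitude ties break to the lowest node index; the 50% mask is
  strict ("below"), so exact-half values survive; the center of mass is
  computed on the masked power; the local-maxima count on the raw power.
* Largest singular values: dense SVD below 400 rows, Lanczos (`svds`)
  above, 1e-8 relative accuracy.

## Scale of the shipped experiments

The shipped benchmark and tests run at 100 datasets on a 1,000-node surface
(complete in well under a minute on one core); the protocol itself is
size-agnostic and `BenchmarkConfig` scales every dimension. Summary tables
deliberately stop at per-method means and correlations — formal inference
(ANOVA, post-hoc contrasts) belongs to external statistics tools reading
the per-dataset CSV.
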