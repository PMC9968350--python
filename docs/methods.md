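# Methods

Statistical model, parameter choices, and numerical details of the
`braintx` pipeline. Module references are to `src/braintx/`.

## 1. Coordinate-based effect-size meta-analysis (`meta.py`)

Each study contributes peaks (MNI mm coordinates, t-values) and group sizes
(n₁ patients, n₂ controls). Per peak:

- Cohen's d = t·√(1/n₁ + 1/n₂); Hedges correction J = 1 − 3/(4·df − 1)
  with df = n₁ + n₂ − 2; g = J·d.
- Sampling variance var(g) = (n₁ + n₂)/(n₁·n₂) + g²/(2·df).

**Map reconstruction.** Each study's peaks are smoothed into a whole-brain
effect-size map with an isotropic Gaussian kernel, FWHM 20 mm
(σ = FWHM/2.3548), truncated at 3σ (weight floor e^{−4.5}). The voxel value
is the kernel-weighted mean of peak g values; the voxel variance is
interpolated with the same weights. Voxels with no kernel support get
g = 0 and a default variance of 10 × the median peak variance — weakly
informative rather than spuriously precise. This is a transparent
substitute for full subject-image imputation approaches; it preserves the
effect-size/variance bookkeeping without their complexity.

**Pooling.** DerSimonian–Laird random effects per voxel: fixed-effect
weights wᵢ = 1/varᵢ give Q; τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw));
random-effects weights wᵢ* = 1/(varᵢ + τ²); pooled ĝ = Σwᵢ*gᵢ/Σwᵢ*,
z = ĝ·√Σwᵢ*, one-sided p = 1 − Φ(|z|). I² = max(0, (Q − (k−1))/Q)·100,
labelled low/medium/high at <50 / [50, 75) / ≥75 (with a 1e-9 boundary
tolerance against float fuzz).

**Thresholding.** Uncorrected voxel p ≤ 0.005, cluster extent ≥ 20 voxels,
26-connectivity, positive and negative effects labelled separately.

**Diagnostics.** Egger regression of standardized effect on precision
(intercept t-test, df = k − 2; the intercept p is computed manually because
`scipy.stats.linregress` exposes only the slope p); excess-significance
binomial test (observed vs expected count of significant studies,
one-sided); leave-one-out jackknife with cluster-peak consistency.

## 2. Expression preprocessing (`expression.py`)

Fixed order, mirroring standard atlas practice:

1. **Intensity filter** — keep probes above background in ≥ 50% of samples
   (pooled across donors).
2. **RNA-seq probe selection** — per gene, Spearman-correlate each
   microarray probe with the RNA-seq reference over matched samples
   (≥ 3 required); drop probes with r < 0.2; keep the max-r probe as the
   gene's representative.
3. **Sample filter** — left-hemisphere cortical samples inside the
   analysis mask.
4. **Scaled robust sigmoid (SRS)** — per donor, within sample then within
   gene: s(x) = 1/(1 + exp(−(x − median)/(IQR/1.35))), rescaled to [0, 1]
   (zero-IQR vectors map to 0.5; the sigmoid argument is clipped at ±700
   against overflow).
5. **Differential stability (DS)** — mean pairwise donor Spearman
   correlation of regional expression profiles; keep the top 50% DS genes
   (count = ceil, ties broken by gene id for determinism).

## 3. Spatial association (`association.py`)

The meta-analytic z map is sampled at each tissue coordinate as the mean of
mask voxels whose centres lie within a 3 mm radius (inclusive boundary,
cKDTree; empty spheres are dropped by default, or assigned the nearest
voxel under `empty_policy="nearest"`). Gene-wise Pearson r against the
sampled z vector, p from the t transform with df = n − 2, BH-FDR across
genes via `statsmodels.stats.multitest.multipletests`; significance is
q ≤ 0.05. Constant genes are excluded; ≥ 4 samples required.

## 4. Surrogate permutation null (`surrogates.py`)

Naive label shuffling destroys spatial autocorrelation and understates null
correlations; the surrogate null preserves it:

1. Empirical variogram of the target vector: γ(h) = half mean squared
   difference per distance bin (25 bins, up to 0.25 of the coordinate
   span).
2. Surrogate construction: permute the values, smooth with a k-nearest-
   neighbour exponential kernel (k from a grid, default ≈ {0.05, 0.1, 0.2}
   of n), least-squares match γ_surrogate to γ_source via
   γ ≈ β·γ_smooth + α, form √β·smoothed + √α·noise (negative fitted α, β
   floored at 0), keep the best-SSE k, then rank-match back to the source
   value multiset so marginal distributions are exactly preserved.
3. Per permutation, the association stage is re-run against the surrogate
   (`map_surrogate` mode: one surrogate z vector per permutation — the
   default, cheap and exchangeable in this design; `per_gene_surrogates`
   surrogates each gene instead) and the count of significant genes is
   recorded.
4. p = (#{null ≥ observed} + 1)/(n_perm + 1). With zero exceedances at
   5000 permutations this gives 1/5001 ≈ 2.0 × 10⁻⁴.

## 5. Annotation (`annotation.py`)

- **Enrichment**: two-sided Fisher exact test on the 2×2 overlap table per
  gene set, odds ratio as the sample cross-product ratio ad/bc (∞ when
  bc = 0 with overlap, NaN when degenerate), BH correction across sets.
- **Hubs**: edges with score strictly > 0.9 between significant genes;
  degree via networkx; hubs = top ceil(10%) of connected nodes, ties
  broken by gene id.
- **Behavioural relevance**: each term map is sphere-sampled at the tissue
  coordinates and correlated with every significant gene; terms are ranked
  by mean |r| and selected above 0.2. Constant term maps are skipped with
  a warning.

## 6. Synthetic data (`synthetic.py`)

All inputs are generated with known ground truth on a toy brain: an
ellipsoid (or full-cube) mask on a small isotropic grid centred at the
origin.

- **Effect maps / peaks**: Gaussian-bump pooled effects at chosen cluster
  centres; per-study peaks snap to voxel centres with t-values
  back-converted so the study's g recovers the truth exactly, plus
  controlled noise. Default group sizes cycle through eight published-scale
  (patients, controls) pairs summing to 500/469.
- **Expression**: Gaussian random fields with exponential covariance
  exp(−d/λ), λ = 15 mm default, via Cholesky (1e-8 jitter). Planted genes
  mix the target map with a field orthogonalized against it in-sample, so
  the realized sample correlation equals `target_r` exactly. Donor offset
  and scale effects, multi-probe genes with decoy probes (a pure-noise
  probe and a below-background probe), decoy samples (right hemisphere,
  non-cortex, out-of-mask), and a correlated RNA-seq reference exercise
  every preprocessing rule. KMeans on coordinates provides region labels.
- **Annotation assets**: gene sets with a planted enriched set
  (membership-odds construction at a chosen odds ratio), Erdős–Rényi
  scored edge lists, Gaussian-smoothed term maps.

**Scope and limits.** The generator is a testbed, not a biophysical model:
expression fields are stationary Gaussian, donors differ only by affine
effects, regions are geometric clusters, and the toy grids are far smaller
than a real brain. On small domains the surrogate null of the significant-
gene count has a genuinely heavy upper tail (a surrogate can resemble the
source map by chance), so reduced-scale permutation p-values should be read
as demonstrations of the machinery, not calibrated small-sample inference.

## 7. Determinism and numerics

All randomness flows from a single seed through
`numpy.random.SeedSequence.spawn`, one named substream per stage (all seeds
< 2³¹). Artifacts carry sha256 hashes in a JSON manifest; identical configs
give bit-identical artifacts. Float comparisons in tests use explicit
tolerances; every stochastic test band was measured before being frozen and
is documented in the test docstrings.
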