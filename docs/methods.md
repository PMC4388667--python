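# Methods

## Model and assumptions

`wfgp` models an idealized E&R experiment: a diploid population of fixed
census size *N*, discrete non-overlapping generations, random mating, no
mutation during the experiment, and at most one selected site per fitted
model (homozygote fitnesses 1 and 1+s, heterozygote 1+hs). The founding
haplotypes G₀ are assumed known, as when the experiment is seeded from
sequenced inbred lines. Pooled sequencing draws reads binomially and
independently per site conditional on the population frequency; coverage is
treated as a fixed constant once observed.

The joint distribution of the latent frequency array **X** over the sampled
(time × locus × replicate) grid is approximated as Gaussian with the exact
(to stated order) Wright-Fisher first and second moments. Replicates are
independent and identically distributed, so the covariance is
block-diagonal with identical blocks. The approximation keeps means and all
pairwise covariances — across time and across linked loci — but discards
higher-order dependence.

### Neutral moments (two loci)

One generation applies the recombination map f(z) = z + r·C(z)·ε, with
ε = (−1, 1, 1, −1) and C = z₁z₄ − z₂z₃, followed by multinomial resampling
of 2N gametes. Moments are propagated by a linear recursion that keeps the
full per-generation 1/2N structure and truncates at first order in r:

    m'   = m + ε·B                    B = E(r·C),   B' = (1−1/2N)(1−r)·B
    A'ᵢ  = (1−1/2N)(1−2/2N)·Aᵢ + r·(2N−1)/(2N)²·dᵢ(S)
    S'ᵢⱼ = (1−1/2N)(Sᵢⱼ + εⱼAᵢ + εᵢAⱼ) + δᵢⱼ(mᵢ + εᵢB)/2N

where Aᵢ = E(r·Zᵢ·C) and dᵢ collects the third-order multinomial moments of
Zᵢ·C. Expanding the recursion reproduces the closed-form displays
(e.g. E Z_t⁽ⁱ⁾ = z⁽ⁱ⁾ + εᵢ·t·r·c₀·(1 − (t−1)/4N)) term by term; the
recursion form is preferred because it is unambiguous and exactly conserves
haplotype mass. Accuracy is O(r + 1/2N) and degrades when t·r = O(1); a
warning fires at t·r ≥ 0.1. Correctness is established against exhaustive
Markov-chain enumeration at 2N ∈ {4, 6} and Monte-Carlo simulation at
realistic sizes.

### Selected moments (delta-method engine)

For models with selection the transition f = R ∘ S is no longer linear:
S is marginal-fitness selection Sᵢ(z) = zᵢ(Wz)ᵢ / (zᵀWz) (W depends only on
the selected-locus alleles) and R is random-union recombination, a quadratic
form Rᵢ(y) = yᵀQᵢy with independent crossovers (no interference) in the
L−1 intervals. Writing Z_t = Z̄_t + δZ_t about the deterministic path, the
disturbance moments obey the closed recursion given in the module docstring,
obtained from a second-order Taylor expansion of the multinomial moment
polynomials composed with f. Derivatives of f are evaluated in closed form
by the chain rule on R ∘ S (a finite-difference evaluator cross-validates
them); no symbolic code generation is required. Cross-time covariances are
chained linearly through the Jacobians along the path, consistent with the
second-order closure (the dropped terms involve third moments).

The recursion is exact for L = 1 at s = 0; its truncation error otherwise
shrinks with N (measured: relative variance error ≈ 3–5% at N = 1000,
s = 0.1 over 50 generations, ≈ 10% at N = 200, s = 0.15). A dedicated
scalar fast path implements the L = 1 recursion vectorized over sites and
parameter grids; it is bitwise-checked against the generic engine.

### Covariance assembly

With a selected site in the model: the selected locus uses the one-locus
engine; each neutral locus's mean/variance and its covariance with the
selected locus come from the two-locus selected model (capturing
hitchhiking); covariances between two neutral loci come from the
three-locus model containing both neutrals and the selected locus, ordered
by genomic position. Fully neutral models use the single-locus closed form
on the diagonal and the two-locus neutral recursion off-diagonal. Initial
haplotype frequencies are tabulated directly from the founder matrix.
Recombination fractions integrate the per-basepair map (optionally with a
hotspot interval at α·r) capped at 1/2.

### Likelihood and boundary handling

With effectively infinite coverage the likelihood is the Gaussian density
of the observed frequencies. With finite coverage the binomial emission is
moment-matched: the observed frequency d/c is Gaussian around X with
variance μ̂(1−μ̂)/c added to the diagonal, and a −log c per observation
keeps the value on the count scale; the approximation is within 0.05 nats
of adaptive quadrature of the exact one-dimensional marginal at moderate
coverage. Zero-coverage entries are dropped.

Observations at the boundary of the frequency scale are *censored* rather
than evaluated as densities: entries within half a haplotype copy
(1/4N) of 0/1 under exact frequencies, or with zero/full read counts under
finite coverage, contribute their marginal Gaussian tail mass beyond the
half-step bound, factored out of the joint density (a
conditional-independence approximation). Without this the density diverges
whenever a trajectory is lost or fixes during the experiment and estimates
of s run to the search bounds. Censoring keeps the likelihood bounded while
preserving the directional information in absorption events.

Numerical safeguards: model means clipped to [10⁻⁶, 1−10⁻⁶]; covariance
symmetrized with eigenvalue flooring at 10⁻¹² when a Cholesky factorization
fails; a 10⁻¹⁰ diagonal jitter; invalid fitness regions (1+s ≤ 0 or
1+hs ≤ 0) receive a −10¹² penalty during optimization.

## Inference

- **LR test.** Λ = −2[log L̃(s=0) − sup_u log L̃(s=u)], floored at 0; s is
  maximized by bounded scalar search on [−0.5, 1]. The vectorized scan
  evaluates a fixed 27-point s-grid (denser near 0) with parabolic
  refinement; the exact optimizer path is used for final estimates. The
  null distribution of the region-wide maximum is simulated empirically
  (default 200 neutral replications); a χ² option exists but is not the
  default at small R.
- **Scans consider only observed segregating sites** — a site with no
  remaining variation never appears in a real data set.
- **Joint (h, s)** is estimated by 4-start L-BFGS-B in the box
  s ∈ [−0.45, 1], h ∈ [−5, 25]; under overdominance the product h·s is the
  well-identified combination and is reported alongside the components.
- **Hotspot intensity** maximizes the neutral multi-locus likelihood over
  the hotspot multiplier on a log₁₀ grid with local refinement, using loci
  inside and outside the (known) hotspot boundaries. Among grid points
  within 0.5 nats of the optimum the one closest to the background rate is
  preferred — a parsimony tie-break, because weak hotspots leave the
  likelihood nearly flat in α.
- **Effective size** maximizes the neutral likelihood over N_e on a
  log₁₀ grid [10, 10⁵] with refinement; a near-flat surface (range below
  2 nats) is flagged. Loci are best pre-filtered to intermediate observed
  frequencies ([0.1, 0.9] throughout), which keeps drift-absorbed sites from
  dragging the estimate.
- **Two-pass scan.** Pass 1: MAF filter (closed interval [0.1, 0.9] at
  every generation and replicate; zero-coverage entries do not veto),
  one-locus scan, window averages (half-open fixed-width windows, empty
  windows missing). Regions are nominated where the windowed mean exceeds
  the (1−q) quantile (default q = 0.01, merged when adjacent) — an
  automated, configurable stand-in for what was originally a visual
  inspection step. Pass 2 refits each in-region site as the selected locus
  of 3/5/7-locus models with fixed flanking neutral SNPs nearest to
  multiples of 250 kb from the region midpoint (required within half the
  spacing, else nearest-available with a warning); the final candidate set
  is the intersection of the per-model top-k lists, ordered by the maximum
  Λ across models with ties broken by position.
- **Companion loci** for K-locus fits on simulated regions: K−1 sites with
  founder MAF ≥ 0.1 nearest to targets spaced region_length/(K+1) around
  the focal site, alternating sides.

## Synthetic data

Founder panels draw derived-allele counts k from the neutral frequency
spectrum (P(k) ∝ 1/k, so the minimum MAF is 1/F by construction) and assign
carriers by block copying: the region is cut into blocks of exponential
length (mean 1/(4·N_e·r) with N_e = 10⁶, r = 2×10⁻⁸ per bp — the genealogy
decorrelation scale of a coalescent with recombination, ≈ 12 bp), and sites
within a block assign derived alleles to nested prefixes of one founder
ranking. This yields the neutral SFS, distance-decaying LD, and the
finite-panel background LD (~1/F) the inference exploits; it produces less
short-range LD than a full coalescent (measured r² at <200 bp ≈ 0.02
vs ≈ 0.05 for a coalescent panel at F = 200), which matters little at the
distances the fitted models use. Externally simulated (e.g. msprime) or
real phased matrices can be imported instead.

Forward simulation clones each founder 2N/F times (round-robin remainders,
with a warning) into homozygous diploids — as in a real E&R founding — then
evolves 2N gametes per generation: parents drawn proportional to diploid
fitness at the selected site, crossovers per interval with fraction
min(r·d, 1/2) (hotspot intervals elevated by α), no interference, no
mutation. Pooled sequencing draws Poisson or empirically resampled depths
and binomial read counts. A single master seed spawns independent
substreams per replicate and for sequencing, so runs are bit-reproducible.

Note one deliberate asymmetry: the simulator's generation-0 individuals are
homozygous (founder clones), while the inference model assumes
Hardy-Weinberg parents from the first generation on. The first-generation
selection response of the simulation is therefore slightly stronger than
the model's — a property of real E&R designs that the likelihood, like the
approximation it implements, absorbs as a small upward bias in ŝ.

## Benchmark studies and their scale

The study protocols (`wfgp.studies`) regenerate the simulation benchmark at
reduced scale, chosen once: 20 kb regions (site counts scaled from the
benchmark's segregating-site densities: ~417 sites at F = 200, ~264 at
F = 20), 50 simulations per estimation cell, 100 per ROC arm; default
design N = 1000, R = 3, sampling generations {10, …, 50}, r = 2×10⁻⁸/bp.
Estimation cells condition on the selected site still segregating at the
final sampling generation (sites without remaining variation do not appear
in real data sets) and redraw otherwise; the overdominance study
additionally conditions the initial frequency outside [0.4, 0.6], where
overdominant trajectories are nearly indistinguishable from drift. The
sampling-schedule comparison re-analyses the *same* simulated experiments
under each sequencing schedule (common random numbers), which sharpens the
IQR ordering.

What passing these studies shows — and does not. The synthetic data share
the model's core assumptions (discrete WF generations, random mating,
binomial sequencing), so the studies validate the approximation and the
estimators, not robustness to overlapping generations, non-random mating,
overdispersed coverage, or mis-specified founder haplotypes, all of which
real experiments exhibit to some degree.

## Known limitations

- Moment accuracy degrades for t·r = O(1) (long experiments over large
  distances) and for strong selection in very small populations.
- At most one selected locus per fitted model; no epistasis or population
  structure.
- The Gaussian closure discards third- and higher-order dependence; the
  censored-boundary factorization ignores correlation between censored and
  interior entries.
- The multi-locus precision gain over the one-locus fit at low coverage is
  small at these study scales and can invert on individual replications of
  50 simulations.
- Region nomination in the two-pass scan uses an empirical-quantile
  stand-in threshold; it is configurable and should be tuned to the data
  at hand.
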