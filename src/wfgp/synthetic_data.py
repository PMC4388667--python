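"""Forward simulation of evolve-and-resequence (E&R) experiments.

An E&R experiment starts from ``F`` (nearly) homozygous founder lines whose
haplotypes are known, clones them to a diploid census population of size
``N``, evolves the population for tens of discrete Wright-Fisher generations
under random mating, diploid selection, and recombination, and samples
marginal allele frequencies by pooled sequencing at a set of generations,
independently in ``R`` replicate populations.

This module generates founder panels with a neutral site-frequency spectrum
and distance-decaying linkage disequilibrium, runs the forward simulation,
and emulates pooled sequencing, producing the trajectory data consumed by
the likelihood machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "FounderPanel",
    "ExperimentDesign",
    "SelectionConfig",
    "TrajectoryData",
    "generate_founder_panel",
    "founder_panel_from_matrix",
    "founder_panel_from_msprime",
    "clone_founders",
    "evolve_population",
    "deterministic_trajectory",
    "pooled_sequencing",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderPanel:
    """Haplotype matrix of the founding lines (generation 0).

    Parameters
    ----------
    haplotypes
        ``(F, K)`` matrix with entries in {0, 1}; row = founder line,
        column = segregating site.
    positions
        ``K`` strictly increasing 1-based basepair coordinates.
    region_length
        Length of the simulated region in basepairs.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    region_length: int

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.uint8)
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "haplotypes", hap)
        object.__setattr__(self, "positions", pos)
        if hap.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotypes must be 0/1")
        if pos.shape != (hap.shape[1],):
            raise ValueError("positions must have one entry per site")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if pos.size and (pos[0] < 1 or pos[-1] > self.region_length):
            raise ValueError("positions must lie in [1, region_length]")
        freqs = hap.mean(axis=0)
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("every site must be segregating among founders")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency of each site among the founders."""
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Experimental design: census size, sampling schedule, replication,
    recombination map and sequencing model.

    ``coverage_model`` is ``"infinite"`` (exact population frequencies),
    ``("poisson", C)`` for Poisson-distributed depth with mean ``C``, or
    ``("empirical", depths)`` where ``depths`` is a 1-D array of depths to
    resample from.
    """

    N: int
    sampling_generations: tuple[int, ...]
    R: int = 3
    r_per_bp: float = 2e-8
    coverage_model: object = "infinite"
    seed: int = 0
    hotspot: Optional[tuple[float, float, float]] = None  # (start, end, alpha)

    def __post_init__(self):
        object.__setattr__(
            self, "sampling_generations", tuple(int(t) for t in self.sampling_generations)
        )
        t = self.sampling_generations
        if self.N < 1 or self.R < 1 or len(t) < 1:
            raise ValueError("N >= 1, R >= 1 and at least one sampling generation required")
        if any(a <= 0 for a in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling generations must be strictly increasing positive")
        if self.r_per_bp < 0:
            raise ValueError("r_per_bp must be non-negative")
        if self.hotspot is not None:
            lo, hi, alpha = self.hotspot
            if not (lo < hi and alpha > 0):
                raise ValueError("hotspot must be (start < end, alpha > 0)")
        _validate_coverage_model(self.coverage_model)

    @property
    def T(self) -> int:
        return len(self.sampling_generations)


def _validate_coverage_model(model) -> None:
    if model == "infinite":
        return
    if isinstance(model, tuple) and len(model) == 2:
        kind, arg = model
        if kind == "poisson":
            if not arg > 0:
                raise ValueError("poisson coverage mean must be > 0")
            return
        if kind == "empirical":
            depths = np.asarray(arg)
            if depths.size == 0:
                raise ValueError("empirical coverage model needs a nonempty depth sample")
            if np.any(depths < 0):
                raise ValueError("depths must be non-negative")
            return
    raise ValueError(f"unrecognized coverage model: {model!r}")


@dataclass(frozen=True)
class SelectionConfig:
    """Diploid selection at one site: homozygote fitness ``1+s``,
    heterozygote ``1+h*s``.  ``selected_site_index=None`` means neutrality."""

    selected_site_index: Optional[int] = None
    s: float = 0.0
    h: float = 0.5

    def __post_init__(self):
        if 1 + self.s <= 0 or 1 + self.h * self.s <= 0:
            raise ValueError("fitnesses 1+s and 1+hs must be positive")

    @classmethod
    def neutral(cls) -> "SelectionConfig":
        return cls(None, 0.0, 0.5)


@dataclass
class TrajectoryData:
    """Observed E&R time series over a ``(T, K, R)`` grid.

    ``counts[i, j, k]`` is the number of reads carrying the derived allele at
    sampling time ``i``, site ``j``, replicate ``k`` and ``coverages`` the
    corresponding depth.  Under infinite coverage both are ``None`` and
    ``frequencies`` holds exact population frequencies; otherwise
    ``frequencies = counts / coverages`` (NaN where coverage is zero).
    """

    frequencies: np.ndarray
    counts: Optional[np.ndarray] = None
    coverages: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 3:
            raise ValueError("frequencies must be (T, K, R)")
        finite = np.isfinite(self.frequencies)
        if np.any((self.frequencies[finite] < 0) | (self.frequencies[finite] > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if (self.counts is None) != (self.coverages is None):
            raise ValueError("counts and coverages must be supplied together")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            self.coverages = np.asarray(self.coverages, dtype=np.int64)
            if self.counts.shape != self.frequencies.shape or (
                self.coverages.shape != self.frequencies.shape
            ):
                raise ValueError("counts/coverages must match frequencies' shape")
            if np.any(self.counts < 0) or np.any(self.counts > self.coverages):
                raise ValueError("need 0 <= counts <= coverages")

    @property
    def infinite_coverage(self) -> bool:
        return self.counts is None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frequencies.shape


# ---------------------------------------------------------------------------
# founder panel generation
# ---------------------------------------------------------------------------


def _sample_sfs_counts(F: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts k in {1, .., F-1} with P(k) proportional to 1/k
    (the neutral site-frequency spectrum of a panel of F lines)."""
    k = np.arange(1, F)
    w = 1.0 / k
    return rng.choice(k, size=size, p=w / w.sum())


def generate_founder_panel(
    F: int,
    region_length: int,
    target_site_count: int,
    rng_seed: int | np.random.Generator = 0,
    ld_block_scale: Optional[float] = None,
    founder_ne: float = 1e6,
    founder_r: float = 2e-8,
) -> FounderPanel:
    """Generate a founder panel with a neutral SFS and distance-decaying LD.

    Derived-allele counts are drawn from the neutral frequency spectrum
    (P(k) proportional to 1/k, k = 1..F-1) so the minimum minor allele
    frequency is 1/F by construction.  Linkage disequilibrium is induced by a
    block-copying scheme: the region is partitioned into blocks of
    exponentially distributed length with mean ``ld_block_scale`` (default
    ``1/(4 * founder_ne * founder_r)``, the scale over which genealogies
    decorrelate in a coalescent with recombination); sites within one block
    share a ranking of the founders and derived alleles are assigned to
    nested prefixes of that ranking, giving high positive LD within a block
    and independent assignments across blocks.  Residual long-range LD arises
    from the finite founder count alone, as in a real panel.

    Sites outside blocks are independent; panels are reproducible given the
    seed.
    """
    if F < 2:
        raise ValueError("need at least two founder lines for segregation")
    if target_site_count < 1:
        raise ValueError("target_site_count must be >= 1")
    if target_site_count > region_length:
        raise ValueError("cannot place more sites than basepairs in the region")
    rng = np.random.default_rng(rng_seed)
    if ld_block_scale is None:
        ld_block_scale = 1.0 / (4.0 * founder_ne * founder_r)

    positions = np.sort(
        rng.choice(np.arange(1, region_length + 1), size=target_site_count, replace=False)
    )
    counts = _sample_sfs_counts(F, target_site_count, rng)

    hap = np.zeros((F, target_site_count), dtype=np.uint8)
    block_order = rng.permutation(F)
    block_end = positions[0] + rng.exponential(ld_block_scale)
    for j, pos in enumerate(positions):
        if pos > block_end:
            block_order = rng.permutation(F)
            block_end = pos + rng.exponential(ld_block_scale)
        carriers = block_order[: counts[j]]
        hap[carriers, j] = 1
    return FounderPanel(hap, positions, region_length)


def founder_panel_from_matrix(
    haplotypes: np.ndarray, positions: Sequence[int], region_length: int
) -> FounderPanel:
    """Import an externally simulated or empirically phased haplotype matrix,
    dropping monomorphic columns."""
    hap = np.asarray(haplotypes, dtype=np.uint8)
    pos = np.asarray(positions, dtype=np.int64)
    freq = hap.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    return FounderPanel(hap[:, keep], pos[keep], region_length)


def founder_panel_from_msprime(
    F: int,
    region_length: int,
    Ne: float = 1e6,
    mu: float = 2e-9,
    r: float = 2e-8,
    seed: int = 1,
) -> FounderPanel:
    """Sample a founder panel from the coalescent with recombination using
    msprime (an independent route to standing variation; used mainly for
    cross-checking the built-in generator)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=F,
        ploidy=1,
        population_size=Ne,
        recombination_rate=r,
        sequence_length=region_length,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1, model=msprime.BinaryMutationModel())
    hap = ts.genotype_matrix().T.clip(0, 1)
    pos = np.array([int(v.site.position) + 1 for v in ts.variants()])
    # collapse duplicate integer positions (rare at these mutation rates)
    _, keep = np.unique(pos, return_index=True)
    return founder_panel_from_matrix(hap[:, keep], pos[keep], region_length)


# ---------------------------------------------------------------------------
# cloning and forward evolution
# ---------------------------------------------------------------------------


def clone_founders(panel: FounderPanel, N: int) -> np.ndarray:
    """Clone each founder haplotype 2N/F times, returning a ``(2N, K)``
    haplotype population.  When F does not divide 2N the remainder copies are
    distributed round-robin over the first founders and a warning is emitted.
    Haplotypes 2i and 2i+1 form diploid individual i."""
    F = panel.n_founders
    total = 2 * N
    base, rem = divmod(total, F)
    if base == 0:
        raise ValueError("2N must be at least the number of founder lines")
    if rem:
        warnings.warn(
            f"2N={total} not divisible by F={F}; distributing {rem} extra copies round-robin",
            stacklevel=2,
        )
    copies = np.full(F, base, dtype=int)
    copies[:rem] += 1
    # block layout pairs identical haplotypes: founder lines are homozygous,
    # so generation-0 individuals are homozygous clones, as in a real E&R setup
    return np.repeat(panel.haplotypes, copies, axis=0)


def _diploid_fitness(pop: np.ndarray, sel: SelectionConfig) -> np.ndarray:
    """Fitness of each of the N individuals given haplotype rows (2N, K)."""
    n_ind = pop.shape[0] // 2
    if sel.selected_site_index is None or sel.s == 0.0:
        return np.ones(n_ind)
    j = sel.selected_site_index
    geno = pop[0::2, j].astype(np.int64) + pop[1::2, j].astype(np.int64)
    w = np.ones(n_ind)
    w[geno == 1] = 1 + sel.h * sel.s
    w[geno == 2] = 1 + sel.s
    return w


def _interval_fractions(
    positions: np.ndarray, r_per_bp: float, hotspot=None
) -> np.ndarray:
    """Recombination fraction per interval between adjacent sites; basepairs
    inside a hotspot interval contribute alpha * r each."""
    pos = positions.astype(float)
    total = r_per_bp * np.diff(pos)
    if hotspot is not None:
        lo, hi, alpha = hotspot
        overlap = np.maximum(
            0.0, np.minimum(pos[1:], hi) - np.maximum(pos[:-1], lo)
        )
        total = total + (alpha - 1.0) * r_per_bp * overlap
    return np.minimum(total, 0.5)


def _make_gametes(
    pop: np.ndarray, parents: np.ndarray, frac: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Form one gamete per entry of ``parents`` (individual indices) with
    crossovers between adjacent sites at the given interval fractions.

    Crossover events are sparse under realistic per-basepair rates, so they
    are drawn per interval (Binomial over gametes) and applied only to the
    affected gametes.
    """
    n_gam = parents.size
    K = pop.shape[1]
    start = rng.integers(0, 2, size=n_gam)  # which parental haplotype at site 0
    switch_cols: dict[int, np.ndarray] = {}
    if K > 1 and frac.max() > 0:
        n_events = rng.binomial(n_gam, frac)
        for k in np.nonzero(n_events)[0]:
            switch_cols[k] = rng.choice(n_gam, size=n_events[k], replace=False)

    hapA = pop[2 * parents]
    hapB = pop[2 * parents + 1]
    if not switch_cols:
        choice = np.broadcast_to(start[:, None], (n_gam, K))
    else:
        choice = np.repeat(start[:, None], K, axis=1)
        for k, gams in switch_cols.items():
            # a crossover in interval k flips the source haplotype from site k+1 on
            choice[gams, k + 1 :] ^= 1
    return np.where(choice == 0, hapA, hapB)


def evolve_population(
    population: np.ndarray,
    design: ExperimentDesign,
    selection: SelectionConfig,
    rng: np.random.Generator,
    positions: np.ndarray,
) -> np.ndarray:
    """Evolve a (2N, K) haplotype population forward and return population
    derived-allele frequencies at the sampling generations, shape (T, K).

    Each generation, 2N gametes are formed: for every gamete a parent
    individual is drawn with probability proportional to its diploid fitness
    (1, 1+hs, 1+s by genotype at the selected site) and a recombinant gamete
    is built from the parent's two haplotypes with crossovers between
    adjacent sites at fraction min(r_per_bp * distance, 1/2), no
    interference.  There is no mutation.
    """
    if population.size == 0:
        raise ValueError("empty population")
    if population.shape[0] != 2 * design.N:
        raise ValueError("population inconsistent with design.N")
    K = population.shape[1]
    if selection.selected_site_index is not None and not (
        0 <= selection.selected_site_index < K
    ):
        raise IndexError("selected_site_index out of range")
    frac = _interval_fractions(positions, design.r_per_bp, design.hotspot)

    pop = population
    out = np.empty((design.T, K))
    t_max = design.sampling_generations[-1]
    sample_at = {t: i for i, t in enumerate(design.sampling_generations)}
    n_gam = 2 * design.N
    for t in range(1, t_max + 1):
        w = _diploid_fitness(pop, selection)
        parents = rng.choice(design.N, size=n_gam, p=w / w.sum())
        pop = _make_gametes(pop, parents, frac, rng)
        if t in sample_at:
            out[sample_at[t]] = pop.mean(axis=0)
    return out


def deterministic_trajectory(
    x0: float, s: float, h: float, generations: Sequence[int]
) -> np.ndarray:
    """Infinite-population (N -> infinity) single-locus trajectory under
    diploid selection: x' = (x^2(1+s) + x(1-x)(1+hs)) / wbar.  Oracle for
    tests and a sanity limit of the simulator."""
    t_max = max(generations)
    x = float(x0)
    path = {0: x}
    for t in range(1, t_max + 1):
        wbar = 1 + s * x * (2 * h + (1 - 2 * h) * x)
        x = x + s * x * (1 - x) * (h + (1 - 2 * h) * x) / wbar
        path[t] = x
    return np.array([path[t] for t in generations])


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


def pooled_sequencing(
    frequencies: np.ndarray, coverage_model, rng: np.random.Generator
) -> TrajectoryData:
    """Emulate pooled sequencing of population frequencies (T, K, R).

    Depth is drawn per (time, site, replicate) from the coverage model and
    reads carrying the derived allele are Binomial(depth, frequency),
    independently across sites.  Infinite coverage returns the frequencies
    verbatim.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    _validate_coverage_model(coverage_model)
    if coverage_model == "infinite":
        return TrajectoryData(frequencies=freqs)
    kind, arg = coverage_model
    if kind == "poisson":
        cov = rng.poisson(arg, size=freqs.shape)
    else:
        depths = np.asarray(arg, dtype=np.int64)
        cov = rng.choice(depths, size=freqs.shape)
    counts = rng.binomial(cov, freqs)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(cov > 0, counts / np.maximum(cov, 1), np.nan)
    return TrajectoryData(frequencies=obs, counts=counts, coverages=cov)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    data: TrajectoryData
    true_frequencies: np.ndarray  # (T, K, R) exact population frequencies
    panel: FounderPanel
    selection: SelectionConfig


def run_experiment(
    panel: FounderPanel,
    design: ExperimentDesign,
    selection: SelectionConfig = SelectionConfig.neutral(),
    seed: Optional[int] = None,
) -> ExperimentResult:
    """Clone founders, evolve R replicates independently from identical
    starting conditions, and apply pooled sequencing.

    Replicates (and the sequencing stage) consume independent child streams
    spawned from a master ``numpy.random.SeedSequence``, so runs are
    bit-reproducible given the seed.
    """
    if seed is None:
        seed = design.seed
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(design.R + 1)]
    base_pop = clone_founders(panel, design.N)
    K = panel.n_sites
    true = np.empty((design.T, K, design.R))
    for k in range(design.R):
        true[:, :, k] = evolve_population(
            base_pop.copy(), design, selection, streams[k], panel.positions
        )
    data = pooled_sequencing(true, design.coverage_model, streams[-1])
    return ExperimentResult(data=data, true_frequencies=true, panel=panel, selection=selection)
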