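"""Gaussian-process approximation to E&R allele-frequency likelihoods.

The latent population frequencies ``X`` over the sampled
(time x locus x replicate) grid are approximated as multivariate Gaussian,

    X | G0, theta  ~  N(mu(G0, theta), Sigma(G0, theta)),

with moments assembled from small Wright-Fisher models conditioned on the
founder haplotype configuration ``G0``:

- the selected locus uses the one-locus selected moment recursion;
- a neutral locus linked to the selected one uses the two-locus selected
  model (its marginal mean and variance, plus the neutral-selected
  covariance), which captures hitchhiking;
- covariances between two neutral loci use the three-locus model containing
  both neutrals and the selected locus;
- in a fully neutral model, single-locus closed forms give the diagonal
  blocks and the two-locus neutral recursion the cross-locus covariances.

Replicates are independent and identically distributed, so the covariance
is block-diagonal over replicates with identical blocks.

Sequencing emission: conditional on X, the derived-read count is
``D ~ Binomial(c, X)``.  With deep coverage the likelihood is proportional
to the Gaussian density of X at the observed frequencies; with finite
coverage the binomial emission is moment-matched by a Gaussian on the
count/coverage scale, adding ``mu(1-mu)/c`` to the corresponding diagonal
entry of Sigma.  A 1-D adaptive-quadrature evaluator of the exact
marginal likelihood is provided as a validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.linalg import cho_factor, cho_solve

from . import neutral_moments as nm
from . import selected_moments as sm
from .synthetic_data import ExperimentDesign, FounderPanel, TrajectoryData

__all__ = [
    "ModelTheta",
    "InitialState",
    "GaussianApprox",
    "initial_state_from_founders",
    "recombination_fraction",
    "build_gaussian",
    "log_likelihood",
    "log_likelihood_quadrature_1d",
]

MEAN_CLIP = 1e-6
_EIG_FLOOR = 1e-12
_VAR_JITTER = 1e-10


@dataclass(frozen=True)
class ModelTheta:
    """Population-genetic parameters of the Gaussian model.

    ``hotspot`` is an optional ``(start_bp, end_bp, alpha)`` interval whose
    per-basepair recombination rate is ``alpha * r_per_bp``.
    """

    N_e: int
    s: float = 0.0
    h: float = 0.5
    r_per_bp: float = 2e-8
    hotspot: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        if self.N_e < 1:
            raise ValueError("N_e must be >= 1")
        if 1 + self.s <= 0 or 1 + self.h * self.s <= 0:
            raise ValueError("fitnesses 1+s and 1+hs must be positive")
        if self.hotspot is not None:
            lo, hi, alpha = self.hotspot
            if not (lo < hi and alpha > 0):
                raise ValueError("hotspot must be (start < end, alpha > 0)")


def recombination_fraction(pos_a: float, pos_b: float, theta: ModelTheta) -> float:
    """Recombination fraction between two basepair positions: the per-bp map
    rate integrated over the interval (hotspot basepairs contribute
    ``alpha * r``), capped at 1/2."""
    lo, hi = sorted((float(pos_a), float(pos_b)))
    total = theta.r_per_bp * (hi - lo)
    if theta.hotspot is not None:
        h_lo, h_hi, alpha = theta.hotspot
        overlap = max(0.0, min(hi, h_hi) - max(lo, h_lo))
        total += (alpha - 1.0) * theta.r_per_bp * overlap
    return min(0.5, total)


@dataclass(frozen=True)
class InitialState:
    """Initial haplotype configuration of the model loci, tabulated from the
    founder panel.  Loci are identified by their column index in the panel
    and are kept in ascending genomic order."""

    panel: FounderPanel
    loci: tuple[int, ...]
    selected: Optional[int]  # panel column index, must be in loci

    def __post_init__(self):
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci")
        if any(not 0 <= j < self.panel.n_sites for j in self.loci):
            raise ValueError("locus index outside panel")
        if self.selected is not None and self.selected not in self.loci:
            raise ValueError("selected locus must be among the model loci")
        freqs = self.panel.frequencies[list(self.loci)]
        if np.any((freqs == 0) | (freqs == 1)):
            raise ValueError("monomorphic locus requested")
        object.__setattr__(self, "loci", tuple(sorted(self.loci, key=lambda j: self.panel.positions[j])))

    @property
    def x0(self) -> np.ndarray:
        return self.panel.frequencies[list(self.loci)]

    @property
    def positions(self) -> np.ndarray:
        return self.panel.positions[list(self.loci)]

    def haplotype_freqs(self, cols: Sequence[int]) -> np.ndarray:
        """Empirical joint haplotype frequencies of the given panel columns
        (ascending position order), indexed per
        :func:`selected_moments.haplotype_alleles` (index 0 = all-A1)."""
        cols = sorted(cols, key=lambda j: self.panel.positions[j])
        L = len(cols)
        sub = self.panel.haplotypes[:, cols]
        alleles = sm.haplotype_alleles(L)
        # map each founder haplotype to its index in the table
        bits = ((1 - sub) * (2 ** np.arange(L - 1, -1, -1))).sum(axis=1)
        z = np.bincount(bits, minlength=2 ** L) / self.panel.n_founders
        assert alleles.shape[0] == z.size
        return z

    def pair_c0(self, a: int, b: int) -> float:
        z = self.haplotype_freqs([a, b])
        return float(z[0] * z[3] - z[1] * z[2])


def initial_state_from_founders(
    panel: FounderPanel, loci: Sequence[int], selected: Optional[int] = None
) -> InitialState:
    return InitialState(panel=panel, loci=tuple(loci), selected=selected)


@dataclass
class GaussianApprox:
    """Gaussian approximation over one replicate's (locus, time) grid.

    Flat index convention: entry ``j * T + i`` is locus ``loci[j]`` (panel
    column, ascending position) at sampling generation ``times[i]``.
    Replicate blocks are identical and mutually independent.
    """

    mean: np.ndarray
    cov: np.ndarray
    loci: tuple[int, ...]
    times: tuple[int, ...]
    R: int
    N_e: int = 0  # used to censor boundary observations at half-copy resolution

    def flat_index(self, time_idx: int, locus_idx: int) -> int:
        return locus_idx * len(self.times) + time_idx


def _ensure_psd(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    try:
        np.linalg.cholesky(S + _VAR_JITTER * np.eye(len(S)))
        return S
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(S)
        return (vecs * np.maximum(vals, _EIG_FLOOR)) @ vecs.T


def build_gaussian(
    theta: ModelTheta,
    design: ExperimentDesign,
    init: InitialState,
) -> GaussianApprox:
    """Assemble the mean vector and covariance matrix of the latent
    frequencies over one replicate's sampling grid."""
    loci = init.loci
    if not loci:
        raise ValueError("empty loci list")
    times = design.sampling_generations
    K, T = len(loci), len(times)
    pos = init.positions
    x0 = init.x0
    sel = init.selected if theta.s != 0.0 else None
    sel_local = loci.index(sel) if sel is not None else None

    mu = np.empty(K * T)
    Sigma = np.zeros((K * T, K * T))

    def block(j):
        return slice(j * T, (j + 1) * T)

    # diagonal blocks and means
    for j in range(K):
        if j == sel_local:
            mean_j, cov_j = sm.one_locus_moment_grid(x0[j], theta.s, theta.h, theta.N_e, times)
        elif sel_local is None:
            mean_j, cov_j = sm.one_locus_moment_grid(x0[j], 0.0, 0.5, theta.N_e, times)
        else:
            # neutral locus hitchhiking on the selected one: 2-locus marginal
            grid, p_j, _ = _pair_grid(theta, design, init, j, sel_local)
            mean_j, cov_j = grid.means[p_j], grid.cov[p_j, :, p_j, :]
        mu[block(j)] = mean_j
        Sigma[block(j), block(j)] = cov_j

    # off-diagonal blocks
    for j in range(K):
        for k in range(j + 1, K):
            if sel_local is None:
                blk = _neutral_pair_cross(theta, design, init, j, k)
            elif sel_local in (j, k):
                other = k if sel_local == j else j
                grid, p_o, p_s = _pair_grid(theta, design, init, other, sel_local)
                # rows = locus j, cols = locus k
                if sel_local == j:
                    blk = grid.cov[p_s, :, p_o, :]
                else:
                    blk = grid.cov[p_o, :, p_s, :]
            else:
                blk = _triple_cross(theta, design, init, j, k, sel_local)
            Sigma[block(j), block(k)] = blk
            Sigma[block(k), block(j)] = blk.T

    mu = np.clip(mu, MEAN_CLIP, 1.0 - MEAN_CLIP)
    Sigma = _ensure_psd(Sigma)
    return GaussianApprox(
        mean=mu, cov=Sigma, loci=loci, times=times, R=design.R, N_e=theta.N_e
    )


def _pair_grid(theta, design, init, j_neutral, j_sel):
    """Two-locus selected model for local loci (j_neutral, j_sel); returns
    the marginal grid and the in-model positions of (neutral, selected)."""
    cols = [init.loci[j_neutral], init.loci[j_sel]]
    order = sorted((j_neutral, j_sel))
    z4 = init.haplotype_freqs(cols)
    r = recombination_fraction(
        init.positions[j_neutral], init.positions[j_sel], theta
    )
    sel_pos_in_model = order.index(j_sel)
    spec = sm.SelectedModelSpec(
        L=2, N=theta.N_e, selected_position=sel_pos_in_model,
        s=theta.s, h=theta.h, rec_fractions=(r,),
    )
    grid = sm.marginal_moments(spec, z4, design.sampling_generations)
    return grid, order.index(j_neutral), sel_pos_in_model


def _neutral_pair_cross(theta, design, init, j, k):
    """Cross-time covariance block between two neutral loci (no selection in
    the model), from the two-locus neutral recursion."""
    z4 = init.haplotype_freqs([init.loci[j], init.loci[k]])
    r = recombination_fraction(init.positions[j], init.positions[k], theta)
    two = nm.TwoLocusInit(z=z4, r=r, N=theta.N_e)
    mm = nm.marginal_allele_moments(two, design.sampling_generations)
    # locus j precedes k in genomic order (loci are sorted)
    return mm.cov[0, :, 1, :]


def _triple_cross(theta, design, init, j, k, sel_local):
    """Covariance block between two neutral loci conditioned on the linked
    selected locus, from the three-locus model."""
    local = sorted([j, k, sel_local])
    cols = [init.loci[a] for a in local]
    z8 = init.haplotype_freqs(cols)
    p = init.positions
    r12 = recombination_fraction(p[local[0]], p[local[1]], theta)
    r23 = recombination_fraction(p[local[1]], p[local[2]], theta)
    spec = sm.SelectedModelSpec(
        L=3, N=theta.N_e, selected_position=local.index(sel_local),
        s=theta.s, h=theta.h, rec_fractions=(r12, r23),
    )
    grid = sm.marginal_moments(spec, z8, design.sampling_generations)
    return grid.cov[local.index(j), :, local.index(k), :]


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------


def _mvn_logpdf(y: np.ndarray, mu: np.ndarray, S: np.ndarray) -> float:
    n = y.size
    try:
        c, low = cho_factor(S + _VAR_JITTER * np.eye(n))
    except np.linalg.LinAlgError:
        S = _ensure_psd(S)
        c, low = cho_factor(S + 1e-9 * np.eye(n))
    dev = y - mu
    alpha = cho_solve((c, low), dev)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + dev @ alpha))


def _censored_gauss_ll(y, mu, S, lo_mask, hi_mask, lo_bound, hi_bound):
    """Joint log-likelihood with boundary censoring: interior entries get
    the multivariate Gaussian density; entries at the boundary of the
    frequency scale contribute their marginal Gaussian tail mass beyond the
    half-step bound (a conditional-independence factorization)."""
    interior = ~(lo_mask | hi_mask)
    total = 0.0
    if interior.any():
        idx = np.nonzero(interior)[0]
        total += _mvn_logpdf(y[idx], mu[idx], S[np.ix_(idx, idx)])
    sig = np.sqrt(np.maximum(np.diag(S), _VAR_JITTER))
    if lo_mask.any():
        total += stats.norm.logcdf((lo_bound - mu[lo_mask]) / sig[lo_mask]).sum()
    if hi_mask.any():
        total += stats.norm.logsf((hi_bound - mu[hi_mask]) / sig[hi_mask]).sum()
    return total


def log_likelihood(data: TrajectoryData, gaussian: GaussianApprox) -> float:
    """Marginal log-likelihood of the observed trajectories under the
    Gaussian approximation.

    ``data`` must be restricted to the model's loci (columns ordered as
    ``gaussian.loci``).  With infinite coverage this is the Gaussian
    log-density of the observed frequencies; with finite coverage the
    moment-matched Gaussian emission adds ``mu(1-mu)/c`` to the diagonal and
    scales to the count grid (a ``-log c`` per observation).  Zero-coverage
    entries carry no information and are dropped.

    Observations at the boundary of the frequency scale (within half a
    haplotype copy, 1/(4 N_e), of 0/1 for exact frequencies; zero or full
    read counts for finite coverage) are censored: they contribute the
    Gaussian tail mass rather than a density, which keeps the likelihood
    bounded when a trajectory is lost or fixes during the experiment.
    """
    T, K, R = data.shape
    if K != len(gaussian.loci) or T != len(gaussian.times) or R != gaussian.R:
        raise ValueError("data shape does not match the Gaussian grid")
    mu, S = gaussian.mean, gaussian.cov
    half_copy = 1.0 / (4.0 * gaussian.N_e) if gaussian.N_e else 0.0
    total = 0.0
    if data.infinite_coverage:
        for k in range(R):
            y = data.frequencies[:, :, k].T.reshape(-1)  # locus-major
            lo = y < half_copy
            hi = y > 1.0 - half_copy
            if not (lo.any() or hi.any()):
                total += _mvn_logpdf(y, mu, S)
            else:
                total += _censored_gauss_ll(y, mu, S, lo, hi, half_copy, 1.0 - half_copy)
        return total
    for k in range(R):
        cov_k = data.coverages[:, :, k].T.reshape(-1).astype(float)
        d_k = data.counts[:, :, k].T.reshape(-1)
        keep = cov_k > 0
        if not keep.any():
            continue
        c_sub = cov_k[keep]
        y = d_k[keep] / c_sub
        mu_s = mu[keep]
        emis = mu_s * (1.0 - mu_s) / c_sub
        S_k = S[np.ix_(keep, keep)] + np.diag(emis)
        lo = d_k[keep] == 0
        hi = d_k[keep] == cov_k[keep]
        if not (lo.any() or hi.any()):
            total += _mvn_logpdf(y, mu_s, S_k)
            total -= np.log(c_sub).sum()
        else:
            # per-entry censoring bounds are half a read, 1/(2c)
            interior = ~(lo | hi)
            idx = np.nonzero(interior)[0]
            if idx.size:
                total += _mvn_logpdf(y[idx], mu_s[idx], S_k[np.ix_(idx, idx)])
                total -= np.log(c_sub[idx]).sum()
            sig = np.sqrt(np.maximum(np.diag(S_k), _VAR_JITTER))
            if lo.any():
                total += stats.norm.logcdf(
                    (0.5 / c_sub[lo] - mu_s[lo]) / sig[lo]
                ).sum()
            if hi.any():
                total += stats.norm.logsf(
                    (1.0 - 0.5 / c_sub[hi] - mu_s[hi]) / sig[hi]
                ).sum()
    return total


def log_likelihood_quadrature_1d(
    d: int, c: int, mu: float, var: float
) -> float:
    """Exact marginal log-likelihood for a single observation:
    ``log \\int B(d; c, x) phi(x; mu, var) dx`` by adaptive quadrature.
    A degenerate latent distribution (var -> 0) reduces to the binomial pmf
    at ``mu``.  Validation oracle for the Gaussian emission approximation."""
    if var < 1e-14:
        return float(stats.binom.logpmf(d, c, mu))
    sd = np.sqrt(var)

    def f(x):
        return stats.binom.pmf(d, c, x) * stats.norm.pdf(x, mu, sd)

    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-13, limit=200)
    return float(np.log(val))
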