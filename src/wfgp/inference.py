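"""Likelihood-ratio testing and parameter estimation for E&R time series.

Hypotheses for a region of K segregating sites:

    H0: s_1 = ... = s_K = 0    vs    HA: s_j != 0 for some j,

tested with the likelihood-ratio statistic

    Lambda = -2 [ log L(D | s = 0) - sup_u log L(D | s = u) ],

computed per site under the Gaussian-process likelihood.  Because the
replicate count of a realistic experiment is small, the null distribution of
the region-wide maximum of Lambda is calibrated empirically by simulating
the same experiment under neutrality rather than by the asymptotic
chi-square law (available as an option).

Also provided: maximum-likelihood estimation of the selection coefficient
``s`` (optionally jointly with dominance ``h``; under overdominance the
product h*s is the well-identified combination), recombination-hotspot
intensity, effective population size, and the ``s_fix`` design formula for
the selection strength an allele needs to reach a target frequency within
the experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import gp_likelihood as gp
from . import selected_moments as sm
from . import synthetic_data as sd

__all__ = [
    "LRResult",
    "NullDistribution",
    "scan_1locus",
    "observed_segregating",
    "lr_statistic",
    "empirical_null",
    "localize",
    "companion_loci",
    "mle_s",
    "mle_hs",
    "mle_hotspot",
    "mle_ne",
    "s_fix",
    "roc_curve",
    "tpr_at_fpr",
]

S_BOUNDS = (-0.5, 1.0)
_LAM_TOL = 1e-6

# default one-locus search grid: denser near zero where the likelihood
# surface curves fastest
DEFAULT_S_GRID = np.array(
    [-0.5, -0.3, -0.2, -0.15, -0.1, -0.07, -0.05, -0.03, -0.02, -0.01,
     0.0, 0.01, 0.02, 0.03, 0.05, 0.07, 0.09, 0.11, 0.13, 0.15,
     0.2, 0.25, 0.3, 0.4, 0.5, 0.7, 1.0]
)


@dataclass
class LRResult:
    """Per-site likelihood-ratio scan results (one-locus or multi-locus)."""

    table: pd.DataFrame  # columns: site, position, lam, s_hat

    @property
    def max_lam(self) -> float:
        return float(self.table["lam"].max())

    @property
    def argmax_site(self) -> int:
        t = self.table
        best = t[t.lam == t.lam.max()].sort_values("position")
        return int(best.iloc[0]["site"])


@dataclass
class NullDistribution:
    """Empirical null sample of the region-wide maximum LR statistic."""

    max_lams: np.ndarray
    seed: int

    def __post_init__(self):
        self.max_lams = np.sort(np.asarray(self.max_lams, dtype=float))

    @property
    def n(self) -> int:
        return self.max_lams.size

    def p_value(self, lam: float) -> float:
        """(1 + #{null >= lam}) / (n + 1); always in (0, 1]."""
        return float((1 + np.sum(self.max_lams >= lam)) / (self.n + 1))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.max_lams, q))


# ---------------------------------------------------------------------------
# vectorized one-locus scanning
# ---------------------------------------------------------------------------


def _batched_gauss_ll(y, means, covs):
    """Gaussian log-density of y (..., T) under batched means/covs."""
    n = y.shape[-1]
    covs = covs + gp._VAR_JITTER * np.eye(n)
    try:
        L = np.linalg.cholesky(covs)
    except np.linalg.LinAlgError:
        # boundary trajectories can degenerate the covariance; floor eigenvalues
        vals, vecs = np.linalg.eigh(covs)
        vals = np.maximum(vals, 1e-10)
        covs = np.einsum("...ij,...j,...kj->...ik", vecs, vals, vecs)
        L = np.linalg.cholesky(covs)
    dev = (y - means)[..., None]
    z = np.linalg.solve(L, dev)[..., 0]
    logdet = 2.0 * np.log(np.einsum("...ii->...i", L)).sum(axis=-1)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + (z ** 2).sum(axis=-1))


def _censored_rows(y_row, means_row, covs_row, lo, hi, lob, hib):
    """Censored log-likelihood for one site and one replicate, batched over
    the s-grid axis: interior entries use the joint Gaussian density,
    boundary entries their marginal tail mass."""
    S = means_row.shape[0]
    out = np.zeros(S)
    interior = ~(lo | hi)
    if interior.any():
        idx = np.nonzero(interior)[0]
        sub = covs_row[:, idx][:, :, idx]
        out += _batched_gauss_ll(y_row[idx][None, :], means_row[:, idx], sub)
    sig = np.sqrt(np.maximum(np.einsum("sii->si", covs_row), gp._VAR_JITTER))
    if lo.any():
        out += stats.norm.logcdf((lob - means_row[:, lo]) / sig[:, lo]).sum(axis=1)
    if hi.any():
        out += stats.norm.logsf((hib - means_row[:, hi]) / sig[:, hi]).sum(axis=1)
    return out


def _one_locus_ll_surface(data, design, x0, theta_ne, s_grid, h):
    """Log-likelihood surface (K sites, S grid values) for the one-locus
    model, summed over replicates, with boundary-censored observations."""
    times = design.sampling_generations
    means, covs = sm.one_locus_moment_grid(
        x0[:, None], np.asarray(s_grid)[None, :], h, theta_ne, times
    )
    means = np.clip(means, gp.MEAN_CLIP, 1 - gp.MEAN_CLIP)
    K, S, T = means.shape
    ll = np.zeros((K, S))
    half_copy = 1.0 / (4.0 * theta_ne)
    if data.infinite_coverage:
        freq = data.frequencies  # (T, K, R)
        at_bound = (freq < half_copy) | (freq > 1 - half_copy)
        clean = ~at_bound.any(axis=(0, 2))  # sites fully interior in all reps
        for k in range(data.shape[2]):
            y = freq[:, :, k].T  # (K, T)
            if clean.all():
                ll += _batched_gauss_ll(y[:, None, :], means, covs)
                continue
            ll[clean] += _batched_gauss_ll(y[clean, None, :], means[clean], covs[clean])
            for j in np.nonzero(~clean)[0]:
                lo = y[j] < half_copy
                hi = y[j] > 1 - half_copy
                ll[j] += _censored_rows(y[j], means[j], covs[j], lo, hi,
                                        half_copy, 1 - half_copy)
        return ll
    for k in range(data.shape[2]):
        cov_depth = data.coverages[:, :, k].T.astype(float)  # (K, T)
        d = data.counts[:, :, k].T
        for j in range(K):
            keep = cov_depth[j] > 0
            if not keep.any():
                continue
            c_j = cov_depth[j, keep]
            y_j = d[j, keep] / c_j
            m_j = means[j][:, keep]
            emis = m_j * (1 - m_j) / c_j
            S_j = covs[j][:, keep][:, :, keep] + emis[:, :, None] * np.eye(keep.sum())
            lo = d[j, keep] == 0
            hi = d[j, keep] == c_j
            interior = ~(lo | hi)
            if interior.all():
                ll[j] += _batched_gauss_ll(y_j[None, :], m_j, S_j)
                ll[j] -= np.log(c_j).sum()
                continue
            if interior.any():
                idx = np.nonzero(interior)[0]
                ll[j] += _batched_gauss_ll(
                    y_j[idx][None, :], m_j[:, idx], S_j[:, idx][:, :, idx]
                )
                ll[j] -= np.log(c_j[idx]).sum()
            sig = np.sqrt(np.maximum(np.einsum("sii->si", S_j), gp._VAR_JITTER))
            if lo.any():
                ll[j] += stats.norm.logcdf(
                    (0.5 / c_j[lo] - m_j[:, lo]) / sig[:, lo]
                ).sum(axis=1)
            if hi.any():
                ll[j] += stats.norm.logsf(
                    (1 - 0.5 / c_j[hi] - m_j[:, hi]) / sig[:, hi]
                ).sum(axis=1)
    return ll


def observed_segregating(data: sd.TrajectoryData) -> np.ndarray:
    """Indices of sites segregating in the observed data (some variation
    remains across the sampled grid: not all-lost and not all-fixed).
    Non-segregating sites are absent from a real sequencing data set and are
    excluded from scans and estimation."""
    if data.infinite_coverage:
        f = data.frequencies
        lost = (f <= 0).all(axis=(0, 2))
        fixed = (f >= 1).all(axis=(0, 2))
    else:
        covered = data.coverages > 0
        lost = ((data.counts == 0) | ~covered).all(axis=(0, 2))
        fixed = ((data.counts == data.coverages) | ~covered).all(axis=(0, 2))
    return np.nonzero(~(lost | fixed))[0]


def _parabolic_refine(s_grid, ll_row):
    j = int(np.argmax(ll_row))
    if j == 0 or j == len(s_grid) - 1:
        return float(s_grid[j]), float(ll_row[j])
    x0, x1, x2 = s_grid[j - 1], s_grid[j], s_grid[j + 1]
    y0, y1, y2 = ll_row[j - 1], ll_row[j], ll_row[j + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if abs(denom) < 1e-30:
        return float(x1), float(y1)
    s_hat = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / denom
    s_hat = float(np.clip(s_hat, x0, x2))
    # quadratic interpolation of the peak height
    ll_hat = max(y1, float(np.interp(s_hat, [x0, x1, x2], [y0, y1, y2])))
    return s_hat, ll_hat


def scan_1locus(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    N_e: Optional[int] = None,
    sites: Optional[Sequence[int]] = None,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    h: float = 0.5,
) -> LRResult:
    """One-locus LR scan over sites: per-site statistic Lambda and MLE
    s-hat (grid search with parabolic refinement, vectorized over sites)."""
    if N_e is None:
        N_e = design.N
    if sites is None:
        sites = np.arange(panel.n_sites)
    sites = np.asarray(sites, dtype=int)
    x0 = panel.frequencies[sites]
    sub = sd.TrajectoryData(
        frequencies=data.frequencies[:, sites, :],
        counts=None if data.counts is None else data.counts[:, sites, :],
        coverages=None if data.coverages is None else data.coverages[:, sites, :],
    )
    s_grid = np.asarray(s_grid, dtype=float)
    i0 = int(np.argmin(np.abs(s_grid)))
    if s_grid[i0] != 0.0:
        raise ValueError("s_grid must contain 0 (the null model)")
    ll = _one_locus_ll_surface(sub, design, x0, N_e, s_grid, h)
    lam = np.empty(len(sites))
    s_hat = np.empty(len(sites))
    for j in range(len(sites)):
        sj, llj = _parabolic_refine(s_grid, ll[j])
        s_hat[j] = sj
        lam[j] = max(0.0, 2.0 * (llj - ll[j, i0]))
    table = pd.DataFrame(
        {"site": sites, "position": panel.positions[sites], "lam": lam, "s_hat": s_hat}
    )
    return LRResult(table=table)


# ---------------------------------------------------------------------------
# per-site likelihood maximization (exact optimizer path)
# ---------------------------------------------------------------------------


def companion_loci(
    panel: sd.FounderPanel, focal: int, K: int, maf_min: float = 0.1
) -> list[int]:
    """Choose K-1 neutral companion loci for a K-locus fit: sites with
    founder MAF >= ``maf_min``, nearest to targets evenly spaced around the
    focal site at multiples of region_length / (K + 1), alternating sides."""
    if K <= 1:
        return []
    freqs = panel.frequencies
    maf = np.minimum(freqs, 1 - freqs)
    eligible = [j for j in range(panel.n_sites) if j != focal and maf[j] >= maf_min]
    if len(eligible) < K - 1:
        warnings.warn(
            f"only {len(eligible)} companion candidates with MAF >= {maf_min}; using all",
            stacklevel=2,
        )
        return eligible
    spacing = panel.region_length / (K + 1)
    fpos = panel.positions[focal]
    targets = []
    for m in range(1, K):
        side = 1 if m % 2 else -1
        mult = (m + 1) // 2
        targets.append(fpos + side * mult * spacing)
    chosen: list[int] = []
    pool = set(eligible)
    for tgt in targets:
        best = min(pool, key=lambda j: abs(panel.positions[j] - tgt))
        chosen.append(best)
        pool.remove(best)
    return chosen


def _model_ll_factory(data, design, panel, site, K, N_e, companions=None, theta_kw=None):
    """Return ll(s, h) for a K-locus model with the focal site selected."""
    theta_kw = dict(theta_kw or {})
    theta_kw.setdefault("r_per_bp", design.r_per_bp)
    if companions is None:
        companions = companion_loci(panel, site, K)
    loci = sorted([site] + list(companions), key=lambda j: panel.positions[j])
    cols = np.array(loci)
    sub = sd.TrajectoryData(
        frequencies=data.frequencies[:, cols, :],
        counts=None if data.counts is None else data.counts[:, cols, :],
        coverages=None if data.coverages is None else data.coverages[:, cols, :],
    )
    init = gp.initial_state_from_founders(panel, loci, selected=site)

    def ll(s: float, h: float = 0.5) -> float:
        if 1 + s <= 1e-6 or 1 + h * s <= 1e-6:
            return -1e12  # invalid fitnesses: outside the model's domain
        theta = gp.ModelTheta(N_e=N_e, s=s, h=h, **theta_kw)
        ga = gp.build_gaussian(theta, design, init)
        val = gp.log_likelihood(sub, ga)
        return val if np.isfinite(val) else -1e12

    return ll


def _one_locus_ll_factory(data, design, panel, site, N_e):
    x0 = panel.frequencies[site]
    sub = sd.TrajectoryData(
        frequencies=data.frequencies[:, [site], :],
        counts=None if data.counts is None else data.counts[:, [site], :],
        coverages=None if data.coverages is None else data.coverages[:, [site], :],
    )

    def ll(s: float, h: float = 0.5) -> float:
        if 1 + s <= 1e-6 or 1 + h * s <= 1e-6:
            return -1e12
        surface = _one_locus_ll_surface(sub, design, np.array([x0]), N_e, [s], h)
        val = float(surface[0, 0])
        return val if np.isfinite(val) else -1e12

    return ll


def mle_s(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    site: int,
    K: int = 1,
    N_e: Optional[int] = None,
    h: float = 0.5,
    companions: Optional[Sequence[int]] = None,
) -> tuple[float, float]:
    """Maximum-likelihood estimate of s at a known selected site with a
    K-locus model (h fixed, 1/2 by default).  Returns (s_hat, loglik)."""
    if N_e is None:
        N_e = design.N
    if K == 1:
        ll = _one_locus_ll_factory(data, design, panel, site, N_e)
    else:
        ll = _model_ll_factory(data, design, panel, site, K, N_e, companions)
    res = optimize.minimize_scalar(
        lambda s: -ll(s, h), bounds=S_BOUNDS, method="bounded",
        options={"xatol": 1e-5 if K == 1 else 1e-4},
    )
    return float(res.x), float(-res.fun)


def mle_hs(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    site: int,
    K: int = 1,
    N_e: Optional[int] = None,
    starts: Sequence[tuple[float, float]] = ((0.05, 0.5), (0.02, 5.0), (0.005, 15.0), (0.1, 1.0)),
    bounds: tuple = ((-0.45, 1.0), (-5.0, 25.0)),
) -> tuple[float, float, float]:
    """Joint MLE of (s, h) by multi-start bounded optimization.  Returns
    (s_hat, h_hat, h_hat * s_hat); the product is the identifiable
    combination under overdominance."""
    if N_e is None:
        N_e = design.N
    if K == 1:
        ll = _one_locus_ll_factory(data, design, panel, site, N_e)
    else:
        ll = _model_ll_factory(data, design, panel, site, K, N_e)
    best = None
    for s0, h0 in starts:
        res = optimize.minimize(
            lambda v: -ll(v[0], v[1]), x0=[s0, h0], method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    s_hat, h_hat = float(best.x[0]), float(best.x[1])
    return s_hat, h_hat, s_hat * h_hat


def lr_statistic(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    site: int,
    K: int = 1,
    N_e: Optional[int] = None,
    h: float = 0.5,
    companions: Optional[Sequence[int]] = None,
) -> tuple[float, float]:
    """LR statistic Lambda and s-hat for one focal site under a K-locus
    model (Lambda floored at 0)."""
    if N_e is None:
        N_e = design.N
    if K == 1:
        ll = _one_locus_ll_factory(data, design, panel, site, N_e)
    else:
        ll = _model_ll_factory(data, design, panel, site, K, N_e, companions)
    res = optimize.minimize_scalar(
        lambda s: -ll(s, h), bounds=S_BOUNDS, method="bounded",
        options={"xatol": 1e-5 if K == 1 else 1e-4},
    )
    lam = 2.0 * (-res.fun - ll(0.0, h))
    return max(0.0, float(lam)), float(res.x)


# ---------------------------------------------------------------------------
# empirical null, localization, ROC
# ---------------------------------------------------------------------------


def empirical_null(
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    n_sims: int,
    seed: int,
    N_e: Optional[int] = None,
    s_grid: np.ndarray = DEFAULT_S_GRID,
) -> NullDistribution:
    """Null distribution of the region-wide max LR statistic: simulate
    ``n_sims`` neutral E&R datasets with the same design and panel and scan
    each with the one-locus model."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_sims, dtype=np.uint32)
    out = np.empty(n_sims)
    for i in range(n_sims):
        res = sd.run_experiment(panel, design, sd.SelectionConfig.neutral(), seed=int(child[i]))
        seg = observed_segregating(res.data)
        out[i] = scan_1locus(res.data, design, panel, N_e=N_e, sites=seg, s_grid=s_grid).max_lam
    return NullDistribution(max_lams=out, seed=seed)


def localize(result: LRResult, truth: Optional[int] = None) -> pd.DataFrame:
    """Rank sites by Lambda (descending; ties broken by ascending genomic
    position).  When the true selected site is supplied, adds its rank and
    the basepair distance from the top-ranked site to the truth."""
    t = result.table.sort_values(["lam", "position"], ascending=[False, True]).reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    if truth is not None:
        true_pos = int(t.loc[t.site == truth, "position"].iloc[0])
        t.attrs["rank_of_truth"] = int(t.loc[t.site == truth, "rank"].iloc[0])
        t.attrs["distance_to_truth"] = abs(int(t.iloc[0]["position"]) - true_pos)
    return t


def roc_curve(null_max: np.ndarray, alt_max: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC of the region-wide max-LR test: (FPR, TPR) over all
    thresholds."""
    null_max = np.asarray(null_max, dtype=float)
    alt_max = np.asarray(alt_max, dtype=float)
    if null_max.size == 0 or alt_max.size == 0:
        raise ValueError("both samples must be nonempty")
    thresholds = np.unique(np.concatenate([null_max, alt_max]))[::-1]
    fpr = [(null_max > t).mean() for t in thresholds] + [1.0]
    tpr = [(alt_max > t).mean() for t in thresholds] + [1.0]
    return np.array([0.0] + fpr), np.array([0.0] + tpr)


def tpr_at_fpr(null_max: np.ndarray, alt_max: np.ndarray, fpr: float) -> float:
    """Power of the max-LR test at the threshold whose empirical false
    positive rate is at most ``fpr``."""
    thresh = np.quantile(np.asarray(null_max, float), 1.0 - fpr, method="higher")
    return float((np.asarray(alt_max, float) > thresh).mean())


# ---------------------------------------------------------------------------
# other parameters: hotspot intensity, effective population size
# ---------------------------------------------------------------------------


def _grid_then_refine(neg_ll, grid):
    vals = np.array([neg_ll(g) for g in grid])
    j = int(np.argmin(vals))
    lo = grid[max(0, j - 1)]
    hi = grid[min(len(grid) - 1, j + 1)]
    if lo == hi:
        return float(grid[j]), vals
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": (hi - lo) * 1e-3})
    return float(res.x), vals


def mle_hotspot(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    hotspot_bounds: tuple[float, float],
    N_e: Optional[int] = None,
    n_inside: int = 10,
    n_outside: int = 20,
    rng: Optional[np.random.Generator] = None,
    log10_alpha_grid: Optional[np.ndarray] = None,
) -> float:
    """Estimate the recombination rate inside a hotspot of known boundaries
    by maximizing the neutral multi-locus likelihood over the hotspot
    multiplier alpha (r_H = alpha * r) on a log grid with local refinement,
    using ``n_inside`` loci inside the hotspot and ``n_outside`` outside.
    Returns r_H-hat per basepair."""
    if N_e is None:
        N_e = design.N
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = hotspot_bounds
    pos = panel.positions
    inside = np.nonzero((pos >= lo) & (pos <= hi))[0]
    outside = np.nonzero((pos < lo) | (pos > hi))[0]
    if inside.size < 2:
        raise ValueError("fewer than 2 loci inside the hotspot")
    pick_in = rng.choice(inside, size=min(n_inside, inside.size), replace=False)
    pick_out = rng.choice(outside, size=min(n_outside, outside.size), replace=False)
    loci = sorted(np.concatenate([pick_in, pick_out]).tolist(), key=lambda j: pos[j])
    cols = np.array(loci)
    sub = sd.TrajectoryData(
        frequencies=data.frequencies[:, cols, :],
        counts=None if data.counts is None else data.counts[:, cols, :],
        coverages=None if data.coverages is None else data.coverages[:, cols, :],
    )
    init = gp.initial_state_from_founders(panel, loci)

    def neg_ll(log10_alpha: float) -> float:
        theta = gp.ModelTheta(
            N_e=N_e, r_per_bp=design.r_per_bp,
            hotspot=(lo, hi, 10.0 ** log10_alpha),
        )
        ga = gp.build_gaussian(theta, design, init)
        return -gp.log_likelihood(sub, ga)

    if log10_alpha_grid is None:
        log10_alpha_grid = np.linspace(-1.0, 4.5, 12)
    grid = np.asarray(log10_alpha_grid, dtype=float)
    vals = np.array([neg_ll(g) for g in grid])
    j_best = int(np.argmin(vals))
    # parsimony tie-break: among grid points within 0.5 nats of the optimum,
    # prefer the one closest to the background rate (alpha = 1); the data
    # often carry little information about alpha when the hotspot is weak
    near = np.nonzero(vals <= vals[j_best] + 0.5)[0]
    j = near[np.argmin(np.abs(grid[near]))]
    if j == j_best:
        lo = grid[max(0, j - 1)]
        hi = grid[min(len(grid) - 1, j + 1)]
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": (hi - lo) * 1e-2},
        )
        best = float(res.x) if res.fun <= vals[j] else float(grid[j])
    else:
        best = float(grid[j])
    return float(10.0 ** best * design.r_per_bp)


def mle_ne(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    loci: Optional[Sequence[int]] = None,
    max_loci: int = 20,
    log10_grid: Optional[np.ndarray] = None,
    flat_tol: float = 2.0,
) -> tuple[float, bool]:
    """Estimate the effective population size from drift under the neutral
    model by maximizing the likelihood over N_e on a log grid [10, 1e5] with
    refinement.  Returns (Ne_hat, flat_flag); the flag marks a likelihood
    surface whose total range is below ``flat_tol`` nats (negligible drift
    information)."""
    if loci is None:
        step = max(1, panel.n_sites // max_loci)
        loci = list(range(0, panel.n_sites, step))[:max_loci]
    loci = sorted(loci, key=lambda j: panel.positions[j])
    cols = np.array(loci)
    sub = sd.TrajectoryData(
        frequencies=data.frequencies[:, cols, :],
        counts=None if data.counts is None else data.counts[:, cols, :],
        coverages=None if data.coverages is None else data.coverages[:, cols, :],
    )
    init = gp.initial_state_from_founders(panel, list(loci))

    def neg_ll(log10_ne: float) -> float:
        theta = gp.ModelTheta(N_e=max(1, int(round(10.0 ** log10_ne))), r_per_bp=design.r_per_bp)
        ga = gp.build_gaussian(theta, design, init)
        return -gp.log_likelihood(sub, ga)

    if log10_grid is None:
        log10_grid = np.linspace(1.0, 5.0, 17)
    best, vals = _grid_then_refine(neg_ll, log10_grid)
    flat = bool(vals.max() - vals.min() < flat_tol)
    if flat:
        warnings.warn("likelihood nearly flat in N_e; drift signal negligible", stacklevel=2)
    return float(10.0 ** best), flat


# ---------------------------------------------------------------------------
# design formula
# ---------------------------------------------------------------------------


def s_fix(T: int, F: int, x_f: float) -> float:
    """Expected selection strength for an allele to reach frequency ``x_f``
    in ``T`` generations, averaged over the neutral founder frequency
    spectrum of ``F`` lines:

        s_fix = (1/H_{F-1}) * sum_{k=1}^{F-1} 1/(k T)
                * log[ x_f/(1-x_f) * (F-k)/k ],

    with H_n the n-th harmonic number."""
    if T < 1 or F < 2:
        raise ValueError("need T >= 1 and F >= 2")
    if not 0.0 < x_f < 1.0:
        raise ValueError("x_f must lie strictly in (0, 1)")
    k = np.arange(1, F)
    H = (1.0 / k).sum()
    terms = (1.0 / (k * T)) * np.log(x_f / (1 - x_f) * (F - k) / k)
    return float(terms.sum() / H)


def chi2_p_value(lam: float, df: int = 1) -> float:
    """Asymptotic chi-square p-value for the LR statistic; optional
    alternative to the empirical null (less accurate at small R)."""
    return float(stats.chi2.sf(lam, df))
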