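"""Delta-method moment recursions for Wright-Fisher models with selection.

A population of 2N haplotypes over L linked biallelic loci (L in {1, 2, 3})
evolves by one deterministic round of diploid selection and recombination,

    f = R o S,

followed by multinomial resampling of 2N gametes, i.e.

    2N * Z_{t+1} | Z_t  ~  Multinomial(2N, f(Z_t)).

``S`` is marginal-fitness selection, ``S_i(z) = z_i (W z)_i / (z' W z)``,
where the genotype fitness matrix ``W`` depends only on the alleles carried
at the selected locus (1, 1+hs, 1+s); ``R`` is random-union recombination
with crossover fractions ``r_1, .., r_{L-1}`` between adjacent loci and no
interference, a quadratic map ``R_i(y) = y' Q_i y``.

Moments are propagated by expanding about the deterministic path
``Zbar_t = f(Zbar_{t-1})``: writing ``Z_t = Zbar_t + dZ_t``, the first and
second moments of the disturbance obey a closed recursion obtained from a
second-order Taylor expansion of the multinomial moment polynomials composed
with ``f``.  With ``a = f(Zbar)``, ``J`` and ``H`` the Jacobian and Hessians
of ``f`` at ``Zbar``, and ``m, M`` the current disturbance moments,

    m'_i  = (J m)_i + (1/2) tr(H_i M)
    M'_ij = (1 - 1/2N) (J M J')_ij + delta_ij (a_i + m'_i) / 2N
            - (a_i a_j + a_i m'_j + a_j m'_i) / 2N.

At s = 0 and L = 1 the recursion is exact (f is affine); truncation error is
of the order of the neglected third moments and shrinks with N.  All
derivatives are evaluated in closed form via the chain rule on R o S; a
central finite-difference evaluator is provided for cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "SelectedModelSpec",
    "DeltaMomentPath",
    "selection_step_1locus",
    "multilocus_transition",
    "multinomial_moment_poly",
    "delta_moment_recursion",
    "cross_time_moments",
    "marginal_moments",
    "linked_neutral_moments",
    "one_locus_moment_grid",
    "transition_derivatives",
    "transition_derivatives_fd",
]

_PSD_FLOOR = 1e-12


@dataclass(frozen=True)
class SelectedModelSpec:
    """An L-locus Wright-Fisher model (L in {1,2,3}) with at most one
    selected locus.

    ``rec_fractions`` are the L-1 crossover fractions between adjacent loci,
    ordered by genomic position.  ``selected_position`` indexes the selected
    locus (``None`` for a fully neutral model).
    """

    L: int
    N: int
    selected_position: Optional[int] = None
    s: float = 0.0
    h: float = 0.5
    rec_fractions: tuple[float, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "rec_fractions", tuple(float(r) for r in self.rec_fractions))
        if self.L not in (1, 2, 3):
            raise ValueError("L must be 1, 2 or 3")
        if len(self.rec_fractions) != self.L - 1:
            raise ValueError("need L-1 recombination fractions")
        if any(not (0.0 <= r <= 0.5) for r in self.rec_fractions):
            raise ValueError("recombination fractions must lie in [0, 1/2]")
        if self.selected_position is not None and not (0 <= self.selected_position < self.L):
            raise ValueError("selected_position out of range")
        if 1 + self.s <= 0 or 1 + self.h * self.s <= 0:
            raise ValueError("fitnesses 1+s and 1+hs must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def n_hap(self) -> int:
        return 2 ** self.L

    @property
    def neutral(self) -> bool:
        return self.selected_position is None or self.s == 0.0


def haplotype_alleles(L: int) -> np.ndarray:
    """(2^L, L) allele table; index 0 is the all-A1 haplotype so that for
    L = 2 the order is (A1A1, A1A0, A0A1, A0A0)."""
    n = 2 ** L
    idx = np.arange(n)
    return np.array([1 - ((idx >> (L - 1 - l)) & 1) for l in range(L)]).T


def marginal_matrix(L: int) -> np.ndarray:
    """(L, 2^L) matrix mapping haplotype frequencies to marginal A1
    frequencies."""
    return haplotype_alleles(L).T.astype(float)


def fitness_matrix(spec: SelectedModelSpec) -> np.ndarray:
    """Diploid fitness of the (i, j) haplotype pairing; depends only on the
    alleles at the selected locus."""
    n = spec.n_hap
    if spec.neutral:
        return np.ones((n, n))
    a = haplotype_alleles(spec.L)[:, spec.selected_position]
    geno = a[:, None] + a[None, :]
    W = np.ones((n, n))
    W[geno == 1] = 1 + spec.h * spec.s
    W[geno == 2] = 1 + spec.s
    return W


def recombination_tensor(L: int, rec_fractions: Sequence[float]) -> np.ndarray:
    """Quadratic-form tensor Q with ``R_i(y) = sum_{jk} Q[i,j,k] y_j y_k``.

    A gamete from the parental pair (j, k) copies each locus from one of the
    two parents; the source switches between adjacent loci independently
    with the interval's crossover fraction (no interference).
    """
    n = 2 ** L
    alleles = haplotype_alleles(L)
    Q = np.zeros((n, n, n))
    for sigma in itertools.product((0, 1), repeat=L):
        p = 0.5
        for l in range(1, L):
            r = rec_fractions[l - 1]
            p *= r if sigma[l] != sigma[l - 1] else 1.0 - r
        for j in range(n):
            for k in range(n):
                gam = tuple(
                    alleles[j, l] if sigma[l] == 0 else alleles[k, l] for l in range(L)
                )
                i = int(np.nonzero((alleles == gam).all(axis=1))[0][0])
                Q[i, j, k] += p
    # symmetrize in the parental pair
    return 0.5 * (Q + Q.transpose(0, 2, 1))


# ---------------------------------------------------------------------------
# one-generation transition and its derivatives
# ---------------------------------------------------------------------------


def selection_step_1locus(x: float | np.ndarray, s: float, h: float):
    """One deterministic generation of one-locus diploid selection:
    ``x' = x + s x (1-x) [h + (1-2h) x] / (1 + s x [2h + (1-2h) x])``,
    identical to exact genotype-frequency bookkeeping
    ``(x^2 (1+s) + x (1-x)(1+hs)) / wbar``."""
    if 1 + s <= 0 or 1 + h * s <= 0:
        raise ValueError("fitnesses 1+s and 1+hs must be positive")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    wbar = 1.0 + s * x * (2.0 * h + (1.0 - 2.0 * h) * x)
    out = x + s * x * (1.0 - x) * (h + (1.0 - 2.0 * h) * x) / wbar
    return out if out.ndim else float(out)


def _selection_with_derivs(z: np.ndarray, W: np.ndarray):
    """Marginal-fitness selection map y = S(z) with Jacobian and Hessians.

    ``S_i = A_i / wbar`` with ``A_i = z_i (W z)_i`` and ``wbar = z' W z``;
    all derivatives follow from the quotient rule on these polynomials.
    """
    n = z.size
    Wz = W @ z
    wbar = float(z @ Wz)
    A = z * Wz
    eye = np.eye(n)
    dA = np.diag(Wz) + z[:, None] * W
    d2A = eye[:, :, None] * W[:, None, :] + eye[:, None, :] * W[:, :, None]
    dw = 2.0 * Wz
    d2w = 2.0 * W
    y = A / wbar
    J = dA / wbar - np.outer(A, dw) / wbar ** 2
    H = (
        d2A / wbar
        - (dA[:, :, None] * dw[None, None, :] + dA[:, None, :] * dw[None, :, None]) / wbar ** 2
        - A[:, None, None] * d2w[None, :, :] / wbar ** 2
        + 2.0 * A[:, None, None] * (dw[:, None] * dw[None, :])[None, :, :] / wbar ** 3
    )
    return y, J, H


def _transition_parts(spec: SelectedModelSpec):
    W = None if spec.neutral else fitness_matrix(spec)
    Q = None if spec.L == 1 else recombination_tensor(spec.L, spec.rec_fractions)
    return W, Q


def transition_derivatives(z: np.ndarray, spec: SelectedModelSpec, _parts=None):
    """One-generation map ``f(z)`` with exact Jacobian and Hessian tensor,
    assembled by the chain rule on R o S."""
    z = np.asarray(z, dtype=float)
    n = spec.n_hap
    W, Q = _parts if _parts is not None else _transition_parts(spec)
    if W is None:
        y, J_S, H_S = z, np.eye(n), None
    else:
        y, J_S, H_S = _selection_with_derivs(z, W)
    if Q is None:
        f = y
        J = J_S
        H = H_S if H_S is not None else np.zeros((n, n, n))
        return f, J, H
    Qy = Q @ y                       # (n, n): (Q_i y)_p
    f = np.einsum("ip,p->i", Qy, y)
    J_R = 2.0 * Qy
    if W is None:
        return f, J_R, 2.0 * Q
    J = J_R @ J_S
    H = 2.0 * np.einsum("pl,ipq,qm->ilm", J_S, Q, J_S) + np.einsum(
        "ip,plm->ilm", J_R, H_S
    )
    return f, J, H


def transition_derivatives_fd(z: np.ndarray, spec: SelectedModelSpec, step: float = 1e-6):
    """Central finite-difference Jacobian/Hessian of the transition map;
    independent cross-check of :func:`transition_derivatives`."""
    z = np.asarray(z, dtype=float)
    n = spec.n_hap
    parts = _transition_parts(spec)

    def f(v):
        return transition_derivatives(v, spec, parts)[0]

    f0 = f(z)
    J = np.empty((n, n))
    for l in range(n):
        e = np.zeros(n)
        e[l] = step
        J[:, l] = (f(z + e) - f(z - e)) / (2 * step)
    H = np.empty((n, n, n))
    for l in range(n):
        for m in range(l, n):
            el = np.zeros(n)
            em = np.zeros(n)
            el[l] = step
            em[m] = step
            if l == m:
                val = (f(z + el) - 2 * f0 + f(z - el)) / step ** 2
            else:
                val = (
                    f(z + el + em) - f(z + el - em) - f(z - el + em) + f(z - el - em)
                ) / (4 * step ** 2)
            H[:, l, m] = val
            H[:, m, l] = val
    return f0, J, H


def multilocus_transition(z: np.ndarray, spec: SelectedModelSpec) -> np.ndarray:
    """Apply one deterministic generation (diploid selection, then
    recombination) to haplotype frequencies on the simplex."""
    z = np.asarray(z, dtype=float)
    if z.shape != (spec.n_hap,):
        raise ValueError(f"z must have length {spec.n_hap}")
    if np.any(z < -1e-12) or abs(z.sum() - 1.0) > 1e-9:
        raise ValueError("z must lie on the simplex")
    return transition_derivatives(z, spec)[0]


def multinomial_moment_poly(
    u: int, v: int, i: int, j: int, p: np.ndarray, N: int
) -> float:
    """Moments ``E[(Z_i)^u (Z_j)^v]`` of Z = counts/2N after multinomial
    sampling of 2N gametes with success probabilities p (u + v <= 2)."""
    p = np.asarray(p, dtype=float)
    n2 = 2 * N
    if u + v > 2 or u < 0 or v < 0:
        raise ValueError("only moments of total degree <= 2 are supported")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-12):
        raise ValueError("p must lie on the simplex")
    if u + v == 0:
        return 1.0
    if v == 0 or u == 0:
        k, w = (i, u) if v == 0 else (j, v)
        if w == 1:
            return float(p[k])
        return float(p[k] ** 2 + p[k] * (1 - p[k]) / n2)
    if i == j:
        return float(p[i] ** 2 + p[i] * (1 - p[i]) / n2)
    return float(p[i] * p[j] * (1.0 - 1.0 / n2))


# ---------------------------------------------------------------------------
# the moment recursion
# ---------------------------------------------------------------------------


class DeltaMomentPath(NamedTuple):
    """Deterministic path and disturbance moments, all indexed by generation
    0..t_max.  ``jacobians[t]`` is the Jacobian of f at ``Zbar_t`` (used to
    chain cross-generation covariances)."""

    Zbar: np.ndarray       # (t_max+1, n)
    m: np.ndarray          # (t_max+1, n)   E dZ_t
    M: np.ndarray          # (t_max+1, n, n) E dZ_t dZ_t'
    jacobians: np.ndarray  # (t_max, n, n)


def _psd_repair(M: np.ndarray) -> np.ndarray:
    sym = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= -1e-9:
        return sym
    warnings.warn(
        f"disturbance second-moment matrix lost PSD (min eig {vals.min():.2e}); flooring",
        stacklevel=3,
    )
    return (vecs * np.maximum(vals, _PSD_FLOOR)) @ vecs.T


def delta_moment_recursion(
    spec: SelectedModelSpec, z0: np.ndarray, t_max: int
) -> DeltaMomentPath:
    """Propagate the deterministic path and the disturbance moments
    E(dZ_t), E(dZ_t dZ_t') from t = 0 (where both vanish) to ``t_max``."""
    z0 = np.asarray(z0, dtype=float)
    n = spec.n_hap
    if z0.shape != (n,):
        raise ValueError(f"z0 must have length {n}")
    if np.any(z0 < -1e-12) or abs(z0.sum() - 1.0) > 1e-9:
        raise ValueError("z0 must lie on the simplex")
    n2 = 2.0 * spec.N
    parts = _transition_parts(spec)

    Zbar = np.empty((t_max + 1, n))
    m = np.zeros((t_max + 1, n))
    M = np.zeros((t_max + 1, n, n))
    Js = np.empty((t_max, n, n))
    Zbar[0] = z0
    for t in range(t_max):
        a, J, H = transition_derivatives(Zbar[t], spec, parts)
        Js[t] = J
        b = J @ m[t] + 0.5 * np.einsum("ilm,lm->i", H, M[t])
        JM = J @ M[t] @ J.T
        M_new = (
            (1.0 - 1.0 / n2) * JM
            + np.diag(a + b) / n2
            - (np.outer(a, a) + np.outer(a, b) + np.outer(b, a)) / n2
        )
        M_new = 0.5 * (M_new + M_new.T)
        if np.diag(M_new).min() < 0 or not np.all(np.isfinite(M_new)):
            M_new = _psd_repair(M_new)
        Zbar[t + 1] = a
        m[t + 1] = b
        M[t + 1] = M_new
    return DeltaMomentPath(Zbar=Zbar, m=m, M=M, jacobians=Js)


def cross_time_moments(
    spec: SelectedModelSpec, z0: np.ndarray, t: int, u: int,
    path: Optional[DeltaMomentPath] = None,
) -> np.ndarray:
    """Cross-generation disturbance moments ``E(dZ_{t+u}^(i) dZ_t^(j))``.

    The conditional mean of the disturbance u steps ahead is propagated
    linearly along the deterministic path (the contribution of the quadratic
    terms involves third moments, which the closure drops):
    ``C_u = J_{t+u-1} ... J_t  E(dZ_t dZ_t')``.  Rows index the later time.
    """
    if t < 0 or u < 0:
        raise ValueError("t, u must be >= 0")
    if path is None:
        path = delta_moment_recursion(spec, z0, t + u)
    C = path.M[t]
    for tau in range(t, t + u):
        C = path.jacobians[tau] @ C
    return C


# ---------------------------------------------------------------------------
# sampled-grid marginal moments
# ---------------------------------------------------------------------------


class MarginalGrid(NamedTuple):
    """Marginal allele-frequency moments over a (locus, time) grid.

    ``means[l, ti] = E X_{t_i, l}``;
    ``cov[l, ti, m, tj] = cov(X_{t_i, l}, X_{t_j, m})``.
    """

    times: tuple[int, ...]
    means: np.ndarray
    cov: np.ndarray


def marginal_moments(
    spec: SelectedModelSpec, z0: np.ndarray, times: Sequence[int]
) -> MarginalGrid:
    """Means and within/cross-generation covariances of all L marginal
    allele frequencies at the sampled generations."""
    times = tuple(int(t) for t in times)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    t_max = max(times) if times else 0
    path = delta_moment_recursion(spec, z0, t_max)
    B = marginal_matrix(spec.L)
    L, T = spec.L, len(times)
    means = np.empty((L, T))
    for ti, t in enumerate(times):
        means[:, ti] = B @ (path.Zbar[t] + path.m[t])
    cov = np.empty((L, T, L, T))
    for ti, t in enumerate(times):
        # propagate E[dZ_tt dZ_t'] sequentially to each later sampled time
        C = path.M[t]
        prev = t
        for tj in range(ti, T):
            tt = times[tj]
            for tau in range(prev, tt):
                C = path.jacobians[tau] @ C
            prev = tt
            central = C - np.outer(path.m[tt], path.m[t])
            block = B @ central @ B.T  # rows: later time tj
            cov[:, tj, :, ti] = block
            cov[:, ti, :, tj] = block.T
    return MarginalGrid(times=times, means=means, cov=cov)


def linked_neutral_moments(
    spec: SelectedModelSpec, z0: np.ndarray, times: Sequence[int]
) -> MarginalGrid:
    """Marginal moments of a three-locus model with one selected and two
    neutral loci; captures hitchhiking of the neutral marginals (their mean
    is displaced toward the selected allele when LD with it is positive)."""
    if spec.L != 3 or spec.selected_position is None:
        raise ValueError("expected a 3-locus spec with a selected locus")
    return marginal_moments(spec, z0, times)


# ---------------------------------------------------------------------------
# fast scalar path for one-locus models
# ---------------------------------------------------------------------------


def _one_locus_derivs(x, s, h):
    """f, f', f'' of the diploid selection map, vectorized over x."""
    num = x * ((1 + s) * x + (1 + h * s) * (1 - x))
    dnum = 2 * (1 + s) * x + (1 + h * s) * (1 - 2 * x)
    d2num = 2 * s * (1 - h)
    den = 1 + s * (2 * h * x + (1 - 2 * h) * x ** 2)
    dden = s * (2 * h + 2 * (1 - 2 * h) * x)
    d2den = 2 * s * (1 - 2 * h)
    f = num / den
    f1 = dnum / den - num * dden / den ** 2
    f2 = (
        d2num / den
        - (2 * dnum * dden + num * d2den) / den ** 2
        + 2 * num * dden ** 2 / den ** 3
    )
    return f, f1, f2


def one_locus_moment_grid(
    x0: np.ndarray | float,
    s: np.ndarray | float,
    h: float,
    N: int,
    times: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-locus moment recursion on a sampling grid.

    ``x0`` and ``s`` broadcast to a common batch shape B; returns
    ``means (B, T)`` and ``cov (B, T, T)``.  Identical to the generic engine
    at L = 1 (tested), but runs the scalar recursion directly, which is the
    hot path for single-locus likelihood scans.
    """
    times = tuple(int(t) for t in times)
    t_max = max(times)
    x0_a, s_a = np.broadcast_arrays(np.asarray(x0, float), np.asarray(s, float))
    shape = x0_a.shape
    xb = x0_a.reshape(-1).copy()
    s_f = s_a.reshape(-1)
    B = xb.size
    n2 = 2.0 * N
    m = np.zeros(B)
    v = np.zeros(B)
    T = len(times)
    idx = {t: i for i, t in enumerate(times)}
    means = np.empty((B, T))
    var_at = np.empty((B, T))
    f1_log = np.empty((B, t_max))
    m_at = np.empty((B, T))
    if 0 in idx:
        raise ValueError("times must be positive generations")
    for t in range(1, t_max + 1):
        a, f1, f2 = _one_locus_derivs(xb, s_f, h)
        a = np.clip(a, 0.0, 1.0)
        f1_log[:, t - 1] = f1
        b = f1 * m + 0.5 * f2 * v
        e = np.clip(a + b, 0.0, 1.0)  # mean may graze the boundary at extreme s
        v = np.maximum((1.0 - 1.0 / n2) * f1 ** 2 * v + (e * (1.0 - e) + b ** 2) / n2, 0.0)
        xb, m = a, b
        if t in idx:
            i = idx[t]
            means[:, i] = xb + m
            var_at[:, i] = v - m ** 2
            m_at[:, i] = m
    cov = np.empty((B, T, T))
    for i, t in enumerate(times):
        chain = var_at[:, i] + m_at[:, i] ** 2  # raw E[d_t d_t]
        cov[:, i, i] = var_at[:, i]
        run = chain.copy()
        for j in range(i + 1, T):
            for tau in range(times[j - 1], times[j]):
                run = f1_log[:, tau] * run
            cov[:, j, i] = cov[:, i, j] = run - m_at[:, j] * m_at[:, i]
    return means.reshape(*shape, T), cov.reshape(*shape, T, T)
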