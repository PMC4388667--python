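"""Moments of the neutral two-locus Wright-Fisher haplotype process.

The two-locus haploid process ``Z_t = (z^(1), z^(2), z^(3), z^(4))`` (haplotype
order A1A1, A1A0, A0A1, A0A0) evolves by one round of recombination,

    f(z) = z + r * C(z) * eps,   eps = (-1, 1, 1, -1),
    C(z) = z1*z4 - z2*z3          (linkage disequilibrium),

followed by multinomial resampling of 2N gametes.  All quantities here are
accurate to order O(r + 1/2N): terms of order r^2 are dropped while the full
1/2N dependence per generation is retained, which reproduces the closed-form
first moments

    E Z_t^(i) = z^(i) + eps_i * t * r * c0 * (1 - (t-1)/(4N))

and the matching r-scaled product/LD formulas.  Second moments and
cross-generation products are propagated by the same order-truncated linear
recursion (the closed forms and the recursion agree term by term; the
recursion additionally keeps geometric 1/2N factors exactly).  The
approximation degrades when t*r = O(1); a warning is emitted when
t*r >= 0.1.

Marginal allele frequencies are X^(A) = Z^(1)+Z^(2) and X^(B) = Z^(1)+Z^(3);
their means, variances and cross-time covariances are linear images of the
haplotype moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EPS",
    "TwoLocusInit",
    "HaplotypeMomentSet",
    "first_order_moments",
    "second_moment_matrix",
    "cross_generation_product",
    "marginal_allele_moments",
]

EPS = np.array([-1.0, 1.0, 1.0, -1.0])

_TR_WARN = 0.1


@dataclass(frozen=True)
class TwoLocusInit:
    """Initial condition of the neutral two-locus process."""

    z: np.ndarray
    r: float
    N: int

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.shape != (4,):
            raise ValueError("z must be a 4-vector of haplotype frequencies")
        if np.any(z < -1e-12) or abs(z.sum() - 1.0) > 1e-9:
            raise ValueError("z must lie on the 3-simplex")
        if not (0.0 <= self.r <= 0.5):
            raise ValueError("recombination fraction must lie in [0, 1/2]")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def c0(self) -> float:
        """Initial linkage disequilibrium z1*z4 - z2*z3."""
        z = self.z
        return float(z[0] * z[3] - z[1] * z[2])


class HaplotypeMomentSet(NamedTuple):
    means: np.ndarray          # E Z_t^(i), shape (4,)
    second_moments: np.ndarray  # E Z_t^(i) Z_t^(j), shape (4, 4)
    time: int


class FirstOrderMoments(NamedTuple):
    means: np.ndarray        # E Z_t^(i)
    r_products: np.ndarray   # E(r Z_t^(i) Z_t^(j)), shape (4, 4)
    r_ld_products: np.ndarray  # E(r Z_t^(i) C_t), shape (4,)


def _warn_tr(init: TwoLocusInit, t: int) -> None:
    if t * init.r >= _TR_WARN:
        warnings.warn(
            f"t*r = {t * init.r:.3g} >= {_TR_WARN}; the O(r + 1/2N) moment "
            "approximation degrades in this regime",
            stacklevel=3,
        )


def first_order_moments(init: TwoLocusInit, t: int) -> FirstOrderMoments:
    """First moments and r-scaled second-order quantities at generation t.

    Closed forms, valid to O(r + 1/2N):

    - ``E Z_t^(i) = z^(i) + eps_i t r c0 (1 - (t-1)/(4N))``
    - ``E(r Z_t^(i) Z_t^(j)) = (r/2N) [ z^(i) z^(j) (2N - t) + t z^(i) 1{i=j} ]``
    - ``E(r Z_t^(i) C_t) = (r/2N) { z^(i) c0 (2N - 3t)
        + (t/2) [ (1-eps_i) z1 z4 - (1+eps_i) z2 z3 ] }``
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    _warn_tr(init, t)
    z, r, n2, c0 = init.z, init.r, 2.0 * init.N, init.c0
    means = z + EPS * t * r * c0 * (1.0 - (t - 1) / (2.0 * n2))
    zz = np.outer(z, z)
    r_products = (r / n2) * (zz * (n2 - t) + t * np.diag(z))
    d0 = (1.0 - EPS) * z[0] * z[3] - (1.0 + EPS) * z[1] * z[2]
    r_ld = (r / n2) * (z * c0 * (n2 - 3.0 * t) + 0.5 * t * d0)
    return FirstOrderMoments(means=means, r_products=r_products, r_ld_products=r_ld)


class _NeutralState(NamedTuple):
    """Internal recursion state: mean, raw second moment, r-scaled LD terms."""

    m: np.ndarray   # E Z^(i)
    S: np.ndarray   # E Z^(i) Z^(j)
    A: np.ndarray   # E(r Z^(i) C)
    B: float        # E(r C)


def _recursion_states(init: TwoLocusInit, t_max: int) -> list[_NeutralState]:
    """Propagate the order-(r, 1/2N) moment recursion and return the state at
    each generation 0..t_max.

    One generation combines the deterministic recombination map with the
    exact multinomial resampling moments, dropping O(r^2) terms:

        m'   = m + eps * B
        B'   = (1 - 1/2N) (1 - r) B
        A'_i = (1-1/2N)(1-2/2N) A_i + r ((2N-1)/(2N)^2) d_i(S)
        S'   = (1 - 1/2N) (S + eps_j A_i + eps_i A_j)
               + diag(m_i + eps_i B) / 2N

    where d_i(S) = (1-eps_i)/2 * E[Z1 Z4] - (1+eps_i)/2 * E[Z2 Z3] arises
    from the third-order multinomial moments of Z_i * C.
    """
    z, r, n2 = init.z, init.r, 2.0 * init.N
    m = z.copy()
    S = np.outer(z, z)
    A = r * z * init.c0
    B = r * init.c0
    states = [_NeutralState(m, S, A, B)]
    g3 = (1.0 - 1.0 / n2) * (1.0 - 2.0 / n2)
    for _ in range(t_max):
        d = 0.5 * (1.0 - EPS) * S[0, 3] - 0.5 * (1.0 + EPS) * S[1, 2]
        S_new = (1.0 - 1.0 / n2) * (S + A[:, None] * EPS[None, :]
                                    + EPS[:, None] * A[None, :]) \
            + np.diag(m + EPS * B) / n2
        A_new = g3 * A + r * (n2 - 1.0) / n2 ** 2 * d
        m_new = m + EPS * B
        B_new = (1.0 - 1.0 / n2) * (1.0 - r) * B
        m, S, A, B = m_new, S_new, A_new, B_new
        states.append(_NeutralState(m, S, A, B))
    return states


def second_moment_matrix(init: TwoLocusInit, t: int) -> np.ndarray:
    """Second-moment matrix ``E Z_t^(i) Z_t^(j)`` to order O(r + 1/2N).

    At r = 0 the recursion is the exact multinomial second-moment recursion;
    diagonal entries then equal ``z^2 + z(1-z)(1 - (1-1/2N)^t)`` and
    off-diagonals ``z_i z_j (1-1/2N)^t``, whose first-order expansions are
    the familiar ``z^(i)(1-z^(i)) t/2N`` and ``-z_i z_j t/2N`` drift terms.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    _warn_tr(init, t)
    return _recursion_states(init, t)[t].S


def cross_generation_product(
    init: TwoLocusInit, t: int, u: int, i: int | None = None, j: int | None = None
) -> float | np.ndarray:
    """Cross-generation product ``E(Z_{t+u}^(i) Z_t^(j))``.

    Combines the within-generation second moment with the conditional mean
    displacement:  ``E[Z_t^(i) Z_t^(j)] + eps_i u E(r Z_t^(j) C_t)
    (1 - (u-1)/(4N))``.  With ``i, j = None`` the full 4x4 matrix over (i, j)
    is returned.
    """
    if t < 0 or u < 0:
        raise ValueError("t, u must be >= 0")
    _warn_tr(init, t + u)
    st = _recursion_states(init, t)[t]
    full = st.S + EPS[:, None] * u * st.A[None, :] * (1.0 - (u - 1) / (4.0 * init.N))
    if i is None and j is None:
        return full
    return float(full[i, j])


class MarginalMoments(NamedTuple):
    """Moments of the two marginal allele frequencies on a time grid.

    ``means[a, ti]`` is E X_{t_i}^(locus a); ``cov[a, ti, b, tj]`` is
    cov(X_{t_i}^(a), X_{t_j}^(b)) for loci a, b in {0, 1}.
    """

    times: tuple[int, ...]
    means: np.ndarray  # (2, T)
    cov: np.ndarray    # (2, T, 2, T)


# rows select haplotypes carrying the A1 allele at locus A resp. B
_MARG = np.array([[1.0, 1.0, 0.0, 0.0],   # X^(A) = Z1 + Z2
                  [1.0, 0.0, 1.0, 0.0]])  # X^(B) = Z1 + Z3


def marginal_allele_moments(init: TwoLocusInit, times: Sequence[int]) -> MarginalMoments:
    """Means, variances and cross-time covariances of the marginal allele
    frequencies ``X^(A) = Z^(1)+Z^(2)`` and ``X^(B) = Z^(1)+Z^(3)``."""
    times = tuple(int(t) for t in times)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    t_max = max(times) if times else 0
    _warn_tr(init, t_max)
    states = _recursion_states(init, t_max)
    T = len(times)
    means = np.empty((2, T))
    cov = np.empty((2, T, 2, T))
    for ti, t in enumerate(times):
        means[:, ti] = _MARG @ states[t].m
    for ti, t in enumerate(times):
        st = states[t]
        for tj, tt in enumerate(times):
            if tt < t:
                continue
            u = tt - t
            # raw E[Z_{t+u}^(i) Z_t^(j)]: rows index the later time
            raw = st.S + EPS[:, None] * u * st.A[None, :] * (1.0 - (u - 1) / (4.0 * init.N))
            m_later = _MARG @ states[tt].m
            m_early = _MARG @ states[t].m
            block = _MARG @ raw @ _MARG.T - np.outer(m_later, m_early)
            cov[:, tj, :, ti] = block
            cov[:, ti, :, tj] = block.T
    return MarginalMoments(times=times, means=means, cov=cov)
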