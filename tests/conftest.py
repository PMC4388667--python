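import numpy as np
import pytest

from wfgp import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel():
    """20 founder lines, 5 kb, 40 segregating sites."""
    return sd.generate_founder_panel(20, 5_000, 40, rng_seed=1)


@pytest.fixture(scope="session")
def default_design():
    return sd.ExperimentDesign(
        N=1000, sampling_generations=(10, 20, 30, 40, 50), R=3, r_per_bp=2e-8
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def one_locus_wf_mc(x0, s, h, N, times, n_runs, seed):
    """Vectorized binomial Wright-Fisher Monte Carlo (HWE transition):
    independent oracle for the one-locus moment recursions."""
    from wfgp.selected_moments import selection_step_1locus

    rng = np.random.default_rng(seed)
    x = np.full(n_runs, float(x0))
    out = {}
    for t in range(1, max(times) + 1):
        x = rng.binomial(2 * N, selection_step_1locus(x, s, h)) / (2 * N)
        if t in times:
            out[t] = x.copy()
    return out


def multilocus_wf_mc(z0, spec, times, n_runs, seed):
    """Vectorized multinomial Wright-Fisher Monte Carlo for the L-locus
    haplotype process; oracle for the delta-method engine."""
    from wfgp.selected_moments import _transition_parts

    rng = np.random.default_rng(seed)
    W, Q = _transition_parts(spec)
    n2 = 2 * spec.N
    Z = np.tile(np.asarray(z0, float), (n_runs, 1))
    out = {}
    for t in range(1, max(times) + 1):
        if W is None:
            y = Z
        else:
            Wz = Z @ W.T
            y = Z * Wz / (Z * Wz).sum(axis=1, keepdims=True)
        p = y if Q is None else np.einsum("ijk,nj,nk->ni", Q, y, y)
        p = np.clip(p, 0, None)
        p /= p.sum(axis=1, keepdims=True)
        Z = rng.multinomial(n2, p) / n2
        if t in times:
            out[t] = Z.copy()
    return out
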