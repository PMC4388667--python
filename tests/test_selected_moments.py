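import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import multilocus_wf_mc, one_locus_wf_mc
from wfgp import neutral_moments as nm
from wfgp import selected_moments as sm


def _one_locus_chain_moments(x0, s, h, N, t):
    """Exact mean/variance of the one-locus binomial WF chain by powering
    the (2N+1)-state transition matrix; oracle for the delta recursion."""
    n2 = 2 * N
    grid = np.arange(n2 + 1) / n2
    f = sm.selection_step_1locus(grid, s, h)
    P = stats.binom.pmf(np.arange(n2 + 1)[None, :], n2, f[:, None])
    dist = np.zeros(n2 + 1)
    dist[int(round(x0 * n2))] = 1.0
    for _ in range(t):
        dist = dist @ P
    mean = dist @ grid
    var = dist @ grid ** 2 - mean ** 2
    return mean, var


class TestSelectionStep:
    def test_boundary_fixed_points(self):
        for s, h in [(0.3, 0.5), (-0.2, 2.0), (0.5, -1.0)]:
            assert sm.selection_step_1locus(0.0, s, h) == 0.0
            assert sm.selection_step_1locus(1.0, s, h) == 1.0

    def test_additive_example(self):
        assert sm.selection_step_1locus(0.5, 0.1, 0.5) == pytest.approx(
            0.5375 / 1.05, abs=1e-12
        )

    def test_neutral_identity(self):
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(sm.selection_step_1locus(x, 0.0, 0.7), x)

    def test_matches_genotype_bookkeeping(self):
        # (x^2(1+s) + x(1-x)(1+hs)) / wbar with explicit genotype sums
        x, s, h = 0.3, 0.2, 1.5
        wbar = x ** 2 * (1 + s) + 2 * x * (1 - x) * (1 + h * s) + (1 - x) ** 2
        expected = (x ** 2 * (1 + s) + x * (1 - x) * (1 + h * s)) / wbar
        assert sm.selection_step_1locus(x, s, h) == pytest.approx(expected, rel=1e-12)

    def test_invalid_fitness_rejected(self):
        with pytest.raises(ValueError):
            sm.selection_step_1locus(0.5, -1.5, 0.5)


class TestMultilocusTransition:
    def test_linkage_equilibrium_invariant(self):
        marg = [0.3, 0.6]
        z = np.outer([marg[0], 1 - marg[0]], [marg[1], 1 - marg[1]]).reshape(-1)
        spec = sm.SelectedModelSpec(L=2, N=100, rec_fractions=(0.3,))
        np.testing.assert_allclose(sm.multilocus_transition(z, spec), z, atol=1e-14)

    def test_two_locus_recombination_arithmetic(self):
        z = np.array([0.5, 0.0, 0.0, 0.5])
        spec = sm.SelectedModelSpec(L=2, N=100, rec_fractions=(0.1,))
        out = sm.multilocus_transition(z, spec)
        np.testing.assert_allclose(out, [0.475, 0.025, 0.025, 0.475], atol=1e-14)

    def test_three_locus_marginal_consistency_at_le(self):
        """With the selected locus at linkage equilibrium with its
        neighbours, its post-step marginal equals the one-locus map."""
        margs = np.array([0.4, 0.25, 0.7])
        z = np.einsum(
            "i,j,k->ijk",
            [margs[0], 1 - margs[0]],
            [margs[1], 1 - margs[1]],
            [margs[2], 1 - margs[2]],
        ).reshape(-1)
        spec = sm.SelectedModelSpec(
            L=3, N=100, selected_position=1, s=0.1, h=0.5, rec_fractions=(0.01, 0.02)
        )
        out = sm.multilocus_transition(z, spec)
        B = sm.marginal_matrix(3)
        assert (B @ out)[1] == pytest.approx(
            sm.selection_step_1locus(margs[1], 0.1, 0.5), abs=1e-12
        )

    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        for L in (1, 2, 3):
            spec = sm.SelectedModelSpec(
                L=L, N=50, selected_position=0, s=0.3, h=1.2,
                rec_fractions=(0.05,) * (L - 1),
            )
            z = rng.dirichlet(np.ones(2 ** L))
            assert sm.multilocus_transition(z, spec).sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    weights=st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8),
    s=st.floats(-0.4, 0.9),
    h=st.floats(-1.0, 2.0),
    r1=st.floats(0.0, 0.5),
    r2=st.floats(0.0, 0.5),
)
def test_transition_preserves_simplex(weights, s, h, r1, r2):
    """The selection-recombination map keeps any frequency vector on the
    simplex for all valid parameters."""
    if 1 + s <= 1e-3 or 1 + h * s <= 1e-3:
        return
    z = np.array(weights)
    z /= z.sum()
    spec = sm.SelectedModelSpec(
        L=3, N=100, selected_position=1, s=s, h=h, rec_fractions=(r1, r2)
    )
    out = sm.multilocus_transition(z, spec)
    assert out.sum() == pytest.approx(1.0, abs=1e-9)
    assert (out >= -1e-12).all()


class TestMultinomialMoments:
    def test_first_moment(self):
        assert sm.multinomial_moment_poly(1, 0, 2, 0, np.array([0.2, 0.3, 0.5]), 10) == 0.5

    def test_binomial_second_moment(self):
        assert sm.multinomial_moment_poly(2, 0, 0, 0, np.array([0.5, 0.5]), 2) == pytest.approx(
            0.3125
        )

    def test_cross_moment(self):
        assert sm.multinomial_moment_poly(1, 1, 0, 1, np.array([0.5, 0.5]), 5) == pytest.approx(
            0.225
        )

    def test_degree_cap(self):
        with pytest.raises(ValueError):
            sm.multinomial_moment_poly(2, 1, 0, 1, np.array([0.5, 0.5]), 5)


class TestDerivatives:
    @pytest.mark.parametrize("L,sel", [(1, 0), (2, 1), (3, 0), (3, 2)])
    def test_analytic_matches_finite_differences(self, L, sel):
        spec = sm.SelectedModelSpec(
            L=L, N=100, selected_position=sel, s=0.25, h=0.8,
            rec_fractions=(0.02,) * (L - 1),
        )
        rng = np.random.default_rng(L * 10 + sel)
        z = rng.dirichlet(np.ones(2 ** L))
        f_a, J_a, H_a = sm.transition_derivatives(z, spec)
        f_n, J_n, H_n = sm.transition_derivatives_fd(z, spec, step=1e-5)
        np.testing.assert_allclose(f_a, f_n, atol=1e-12)
        np.testing.assert_allclose(J_a, J_n, atol=1e-6)
        np.testing.assert_allclose(H_a, H_n, atol=1e-3)


class TestDeltaRecursion:
    def test_neutral_one_locus_exact(self):
        spec = sm.SelectedModelSpec(L=1, N=100)
        z0 = np.array([0.3, 0.7])
        path = sm.delta_moment_recursion(spec, z0, 20)
        exact = 0.3 * 0.7 * (1 - (1 - 1 / 200) ** 20)
        assert path.M[20][0, 0] == pytest.approx(exact, rel=1e-12)
        np.testing.assert_allclose(path.m, 0.0, atol=1e-15)

    def test_tiny_population_enumeration_oracle(self):
        """2N = 4, strong selection: engine beats the deterministic path and
        lands within the truncation tolerance of the exact chain."""
        N, s, h, x0, t = 2, 0.5, 0.5, 0.5, 3
        mean_ex, var_ex = _one_locus_chain_moments(x0, s, h, N, t)
        spec = sm.SelectedModelSpec(L=1, N=N, selected_position=0, s=s, h=h)
        path = sm.delta_moment_recursion(spec, np.array([x0, 1 - x0]), t)
        mean_engine = path.Zbar[t][0] + path.m[t][0]
        det_only = path.Zbar[t][0]
        assert abs(mean_engine - mean_ex) < abs(det_only - mean_ex)
        assert abs(mean_engine - mean_ex) < 0.01
        assert path.M[t][0, 0] - path.m[t][0] ** 2 == pytest.approx(var_ex, abs=0.02)

    def test_truncation_error_shrinks_with_n(self):
        errs = []
        for N in (2, 4, 8):
            mean_ex, _ = _one_locus_chain_moments(0.5, 0.5, 0.5, N, 3)
            spec = sm.SelectedModelSpec(L=1, N=N, selected_position=0, s=0.5, h=0.5)
            path = sm.delta_moment_recursion(spec, np.array([0.5, 0.5]), 3)
            errs.append(abs(path.Zbar[3][0] + path.m[3][0] - mean_ex))
        assert errs[0] > errs[-1]

    def test_monte_carlo_oracle_selected(self):
        """L=1, N=1000, s=0.1, x0=0.1, t=50: mean within 3 SE of 1e5 runs."""
        mc = one_locus_wf_mc(0.1, 0.1, 0.5, 1000, (50,), 100_000, seed=21)[50]
        spec = sm.SelectedModelSpec(L=1, N=1000, selected_position=0, s=0.1, h=0.5)
        path = sm.delta_moment_recursion(spec, np.array([0.1, 0.9]), 50)
        se = mc.std() / np.sqrt(mc.size)
        assert abs(path.Zbar[50][0] + path.m[50][0] - mc.mean()) < 3 * se

    def test_mass_conservation(self):
        spec = sm.SelectedModelSpec(
            L=2, N=200, selected_position=0, s=0.2, h=0.5, rec_fractions=(0.01,)
        )
        z0 = np.array([0.2, 0.3, 0.1, 0.4])
        path = sm.delta_moment_recursion(spec, z0, 30)
        totals = path.Zbar.sum(axis=1) + path.m.sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-10)

    def test_monotone_in_s(self):
        means = []
        for s in (0.0, 0.05, 0.1, 0.2):
            spec = sm.SelectedModelSpec(L=1, N=500, selected_position=0, s=s, h=0.5)
            path = sm.delta_moment_recursion(spec, np.array([0.2, 0.8]), 25)
            means.append(path.Zbar[25][0] + path.m[25][0])
        assert np.all(np.diff(means) > 0)


class TestCrossTime:
    def test_u_zero_is_within_generation(self):
        spec = sm.SelectedModelSpec(L=1, N=100, selected_position=0, s=0.1, h=0.5)
        z0 = np.array([0.4, 0.6])
        path = sm.delta_moment_recursion(spec, z0, 10)
        C = sm.cross_time_moments(spec, z0, 10, 0, path=path)
        np.testing.assert_allclose(C, path.M[10])

    def test_neutral_martingale_tower(self):
        spec = sm.SelectedModelSpec(L=1, N=100)
        z0 = np.array([0.3, 0.7])
        path = sm.delta_moment_recursion(spec, z0, 30)
        C = sm.cross_time_moments(spec, z0, 15, 15, path=path)
        np.testing.assert_allclose(C, path.M[15], rtol=1e-12)

    def test_monte_carlo_covariance(self):
        """cov(X_40, X_20) for s=0.05, N=500 within 3 SE of 1e5 runs."""
        mc = one_locus_wf_mc(0.3, 0.05, 0.5, 500, (20, 40), 100_000, seed=31)
        spec = sm.SelectedModelSpec(L=1, N=500, selected_position=0, s=0.05, h=0.5)
        z0 = np.array([0.3, 0.7])
        path = sm.delta_moment_recursion(spec, z0, 40)
        C = sm.cross_time_moments(spec, z0, 20, 20, path=path)
        model = C[0, 0] - path.m[40][0] * path.m[20][0]
        a, b = mc[40], mc[20]
        prods = (a - a.mean()) * (b - b.mean())
        assert abs(model - prods.mean()) < 3 * prods.std() / np.sqrt(a.size)


class TestLinkedNeutralMoments:
    def test_fixed_selected_locus_reduces_to_neutral(self):
        """When the selected locus is fixed there is no segregating
        selection: the neutral pair behaves exactly neutrally."""
        margs = (1.0, 0.3, 0.6)  # selected locus fixed at frequency 1
        z = np.einsum(
            "i,j,k->ijk",
            [margs[0], 1 - margs[0]],
            [0.3, 0.7],
            [0.6, 0.4],
        ).reshape(-1)
        spec = sm.SelectedModelSpec(
            L=3, N=200, selected_position=0, s=0.3, h=0.5, rec_fractions=(0.01, 0.01)
        )
        grid = sm.linked_neutral_moments(spec, z, (5, 15))
        two = nm.TwoLocusInit(np.outer([0.3, 0.7], [0.6, 0.4]).reshape(-1), 0.01, 200)
        mm = nm.marginal_allele_moments(two, (5, 15))
        np.testing.assert_allclose(grid.means[1:], mm.means, atol=2e-3)
        np.testing.assert_allclose(
            grid.cov[1, :, 2, :], mm.cov[0, :, 1, :], atol=2e-3
        )

    def test_hitchhiking_raises_neutral_mean(self):
        # neutral site in positive LD with a selected sweep
        z = np.zeros(8)
        # haplotypes: (sel, n1, n2); index 0 = (1,1,1), index 7 = (0,0,0)
        z[0] = 0.2   # carries selected + both neutral derived
        z[7] = 0.8
        spec = sm.SelectedModelSpec(
            L=3, N=1000, selected_position=0, s=0.2, h=0.5,
            rec_fractions=(1e-3, 1e-3),
        )
        grid = sm.linked_neutral_moments(spec, z, (10, 30))
        assert grid.means[1, 0] > 0.2
        assert grid.means[1, 1] > grid.means[1, 0]

    def test_three_locus_monte_carlo(self):
        """Neutral-site mean under linked selection within 3 SE of 1e4
        three-locus forward simulations."""
        rngz = np.random.default_rng(3)
        z = rngz.dirichlet(np.ones(8) * 2)
        spec = sm.SelectedModelSpec(
            L=3, N=1000, selected_position=1, s=0.1, h=0.5,
            rec_fractions=(1e-3, 1e-3),
        )
        t = 50
        mc = multilocus_wf_mc(z, spec, (t,), 10_000, seed=41)[t]
        B = sm.marginal_matrix(3)
        marg_mc = mc @ B.T
        grid = sm.marginal_moments(spec, z, (t,))
        for locus in range(3):
            se = marg_mc[:, locus].std() / np.sqrt(len(marg_mc))
            assert abs(grid.means[locus, 0] - marg_mc[:, locus].mean()) < 3 * se


class TestScalarFastPath:
    def test_matches_generic_engine(self):
        times = (10, 20, 30, 40, 50)
        for s, h, x0 in [(0.1, 0.5, 0.2), (0.01, 10.0, 0.7), (-0.05, 0.5, 0.5)]:
            spec = sm.SelectedModelSpec(L=1, N=500, selected_position=0, s=s, h=h)
            grid = sm.marginal_moments(spec, np.array([x0, 1 - x0]), times)
            m, c = sm.one_locus_moment_grid(x0, s, h, 500, times)
            np.testing.assert_allclose(grid.means[0], m, atol=1e-12)
            np.testing.assert_allclose(grid.cov[0, :, 0, :], c, atol=1e-12)
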