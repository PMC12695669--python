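"""Unit and property tests for the randomized MoM variance-component core."""

import numpy as np
import pytest
from scipy import stats

from fame.estimator import (ComponentDef, GenotypeColumnSource, ProbeSet,
                            assemble_T, compute_q, cov_sigma, draw_probes,
                            exact_moments_oracle, fit_marginal_epistasis,
                            gwas_h2, gxg_gwas_ratio, heritability_fractions,
                            plugin_cov_q, sketch_component,
                            solve_normal_equations)
from fame.estimator import test_component as component_test
from fame.genotype_io import MatrixSource, StandardizedSource
from fame.interaction import InteractionSource, InteractionSpec
from fame.simulator import SimConfig, simulate_genotypes, simulate_phenotype


def three_components(std_source, target=5):
    xs = std_source.materialize()
    add = GenotypeColumnSource(std_source)
    spec = InteractionSpec(target, frozenset({target}))
    e = InteractionSource(std_source, xs[:, target], spec)
    return [ComponentDef("additive", "genotype_additive", add, add.n_columns),
            ComponentDef("gxg", "interaction", e, e.n_columns),
            ComponentDef("residual", "identity")]


def exact_probes(n):
    """Probe matrix sqrt(N) * I: the streaming trace estimator becomes exact."""
    return ProbeSet(np.eye(n) * np.sqrt(n), seed=-1, B=n)


class TestProbes:
    def test_seeded_determinism(self):
        a = draw_probes(30, 5, seed=3).probe_matrix
        b = draw_probes(30, 5, seed=3).probe_matrix
        np.testing.assert_array_equal(a, b)

    def test_row_covariance_near_identity(self):
        v = draw_probes(50, 10_000, seed=1).probe_matrix
        cov = v @ v.T / v.shape[1]
        tol = 4 / np.sqrt(10_000)
        assert np.abs(cov - np.eye(50)).max() < 4 * tol

    def test_rademacher_probes(self):
        v = draw_probes(20, 100, seed=0, distribution="rademacher").probe_matrix
        assert set(np.unique(v)) == {-1.0, 1.0}


class TestSketches:
    def test_identity_component_passthrough(self, rng):
        probes = draw_probes(25, 4, seed=0)
        y = rng.standard_normal(25)
        sk = sketch_component(ComponentDef("res", "identity"), probes, y)
        np.testing.assert_array_equal(sk.kzv_raw, probes.probe_matrix)
        np.testing.assert_array_equal(sk.kzy_raw, y)
        assert np.isclose(sk.zty_sq, y @ y)

    def test_streamed_equals_dense_product(self, std_panel, rng):
        probes = draw_probes(200, 8, seed=2)
        y = rng.standard_normal(200)
        comp = three_components(std_panel)[0]
        sk = sketch_component(comp, probes, y)
        z = std_panel.materialize()
        np.testing.assert_allclose(sk.kzv_raw, z @ (z.T @ probes.probe_matrix),
                                   atol=1e-8)
        np.testing.assert_allclose(sk.kzy_raw, z @ (z.T @ y), atol=1e-8)

    def test_two_passes_bit_identical(self, std_panel, rng):
        probes = draw_probes(200, 4, seed=2)
        y = rng.standard_normal(200)
        comp = three_components(std_panel)[1]
        a = sketch_component(comp, probes, y)
        b = sketch_component(comp, probes, y)
        np.testing.assert_array_equal(a.kzv_raw, b.kzv_raw)


class TestMomentEquations:
    def test_identity_only_model(self, rng):
        y = rng.standard_normal(40)
        comps = [ComponentDef("res", "identity")]
        probes = draw_probes(40, 3, seed=0)
        sk = [sketch_component(comps[0], probes, y)]
        T = assemble_T(sk, probes)
        q = compute_q(sk)
        np.testing.assert_array_equal(T, [[40.0]])
        assert np.isclose(q[0], y @ y)
        s2 = solve_normal_equations(T, q)
        assert np.isclose(s2[0], (y @ y) / 40)

    def test_identity_entries_exact_under_standardization(self, std_panel, rng):
        comps = three_components(std_panel)
        probes = draw_probes(200, 5, seed=1)
        y = rng.standard_normal(200)
        sk = [sketch_component(c, probes, y) for c in comps]
        T = assemble_T(sk, probes)
        # tr(K1) = N exactly under population scaling
        assert np.isclose(T[0, 2], 200.0, atol=1e-8)
        assert T[2, 2] == 200.0

    def test_stochastic_T_within_mc_error(self, std_panel, rng):
        comps = three_components(std_panel)
        y = rng.standard_normal(200)
        T_ex, _, _ = exact_moments_oracle(comps, y)
        B = 5000
        probes = draw_probes(200, B, seed=4)
        sk = [sketch_component(c, probes, y) for c in comps]
        T = assemble_T(sk, probes)
        # per-probe terms give a Monte-Carlo SE for each stochastic entry
        for (k, l) in [(0, 0), (0, 1), (1, 1)]:
            terms = (sk[k].kzv_raw * sk[l].kzv_raw).sum(axis=0) / (
                sk[k].divisor * sk[l].divisor)
            se = terms.std(ddof=1) / np.sqrt(B)
            assert abs(T[k, l] - T_ex[k, l]) < 3 * se

    def test_unbiased_over_probe_seeds(self, std_panel, rng):
        comps = three_components(std_panel)
        y = rng.standard_normal(200)
        T_ex, _, _ = exact_moments_oracle(comps, y)
        vals = []
        for seed in range(50):
            probes = draw_probes(200, 20, seed=seed)
            sk = [sketch_component(c, probes, y) for c in comps]
            vals.append(assemble_T(sk, probes)[0, 1])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - T_ex[0, 1]) < 3 * se

    def test_q_zero_phenotype(self, std_panel):
        comps = three_components(std_panel)
        probes = draw_probes(200, 2, seed=0)
        sk = [sketch_component(c, probes, np.zeros(200)) for c in comps]
        np.testing.assert_array_equal(compute_q(sk), np.zeros(3))

    def test_q_dense_oracle(self, std_panel, rng):
        comps = three_components(std_panel)
        y = rng.standard_normal(200)
        probes = draw_probes(200, 2, seed=0)
        sk = [sketch_component(c, probes, y) for c in comps]
        _, q_ex, _ = exact_moments_oracle(comps, y)
        np.testing.assert_allclose(compute_q(sk), q_ex, rtol=1e-10)

    def test_singular_T_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            solve_normal_equations(np.array([[1.0, 1.0], [1.0, 1.0]]),
                                   np.array([1.0, 1.0]), ["a", "b"])


class TestCovariance:
    def test_plugin_cov_dense_oracle(self, std_panel, rng):
        comps = three_components(std_panel)
        y = rng.standard_normal(200)
        T_ex, q_ex, covq_ex = exact_moments_oracle(comps, y)
        s2 = solve_normal_equations(T_ex, q_ex)
        probes = draw_probes(200, 2, seed=0)
        sk = [sketch_component(c, probes, y) for c in comps]
        covq = plugin_cov_q(sk, comps, s2)
        np.testing.assert_allclose(covq, covq_ex, atol=1e-8 * np.abs(covq_ex).max())

    def test_zero_sigma_gives_zero_cov(self, std_panel, rng):
        comps = three_components(std_panel)
        y = rng.standard_normal(200)
        probes = draw_probes(200, 2, seed=0)
        sk = [sketch_component(c, probes, y) for c in comps]
        np.testing.assert_array_equal(plugin_cov_q(sk, comps, np.zeros(3)),
                                      np.zeros((3, 3)))

    def test_identity_model_matches_analytic_variance(self, rng):
        # Var(sigma2_e~) -> 2 sigma^4 / N for Gaussian y
        n = 20_000
        y = rng.standard_normal(n) * 1.3
        comp = [ComponentDef("res", "identity")]
        probes = draw_probes(n, 1, seed=0)
        sk = [sketch_component(comp[0], probes, y)]
        T = assemble_T(sk, probes)
        s2 = solve_normal_equations(T, compute_q(sk))
        cs = cov_sigma(T, plugin_cov_q(sk, comp, s2))
        analytic = 2 * 1.3 ** 4 / n
        assert np.isclose(cs[0, 0], analytic, rtol=0.1)

    def test_cov_q_zero_gives_zero(self):
        out = cov_sigma(np.eye(2) * 5, np.zeros((2, 2)))
        np.testing.assert_array_equal(out, np.zeros((2, 2)))


class TestTestsAndFractions:
    def test_zero_estimate(self):
        z, p, neg = component_test(np.array([0.0]), np.array([[4.0]]), 0)
        assert z == 0 and p == 1 and not neg

    def test_z_quantile(self):
        z, p, _ = component_test(np.array([1.959964]), np.array([[1.0]]), 0)
        assert np.isclose(p, 0.05, atol=1e-6)

    def test_negative_flagged_but_reported(self):
        z, p, neg = component_test(np.array([-0.2]), np.array([[0.01]]), 0)
        assert neg and np.isclose(z, -2.0)

    def test_zero_se_errors(self):
        with pytest.raises(ZeroDivisionError):
            component_test(np.array([1.0]), np.array([[0.0]]), 0)

    def test_fraction_unit_total(self):
        h2_gxg, h2_add = heritability_fractions(
            np.array([0.3, 0.01, 0.69]), ["additive", "gxg_genome", "residual"])
        assert np.isclose(h2_gxg, 0.01) and np.isclose(h2_add, 0.3)

    def test_negative_component_floored(self):
        h2_gxg, _ = heritability_fractions(
            np.array([0.5, -0.1, 0.5]), ["additive", "gxg_genome", "residual"])
        assert h2_gxg == 0.0

    def test_gwas_h2_square(self):
        assert gwas_h2(0.1) == pytest.approx(0.01)
        assert gwas_h2(0.0) == 0.0

    def test_ratio(self):
        assert gxg_gwas_ratio(2e-3, 1e-3) == pytest.approx(2.0)
        assert np.isnan(gxg_gwas_ratio(1e-3, 0.0))


class TestOracle:
    def test_identity_pair_trace(self, rng):
        T, _, _ = exact_moments_oracle([ComponentDef("res", "identity")],
                                       rng.standard_normal(30))
        assert T[0, 0] == 30

    def test_frobenius_trace_identity(self, rng):
        x = rng.standard_normal((40, 12))
        x -= x.mean(0)
        x /= np.sqrt((x ** 2).sum(0) / 40)
        from tests.conftest import make_snps
        src = MatrixSource(x, make_snps(12), standardized=True)
        comp = ComponentDef("add", "genotype_additive",
                            GenotypeColumnSource(src), 12)
        T, _, _ = exact_moments_oracle([comp], rng.standard_normal(40))
        k1 = x @ x.T / 12
        assert np.isclose(T[0, 0], np.linalg.norm(x.T @ x / 12, "fro") ** 2)
        assert np.isclose(T[0, 0], np.trace(k1 @ k1), atol=1e-10)

    def test_memory_guard(self, rng):
        with pytest.raises(MemoryError):
            exact_moments_oracle([ComponentDef("res", "identity")],
                                 np.zeros(2001))


class TestFullFit:
    def test_recovers_additive_variance(self):
        src = simulate_genotypes(2000, 300, seed=3)
        ests = []
        for rep in range(8):
            cfg = SimConfig(N=2000, M=300, sigma2_g=0.25, sigma2_gxg=0.0,
                            seed=100 + rep)
            y, truth = simulate_phenotype(src, cfg)
            fit = fit_marginal_epistasis(src, y, None, truth.target_index,
                                         B=100, seed=rep)
            ests.append(fit["additive"])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 0.25) < max(3 * se, 0.03)

    def test_deterministic_given_seed(self):
        src = simulate_genotypes(500, 100, seed=3)
        cfg = SimConfig(N=500, M=100, sigma2_g=0.3, sigma2_gxg=0.05, seed=9)
        y, truth = simulate_phenotype(src, cfg)
        f1 = fit_marginal_epistasis(src, y, None, truth.target_index, B=50, seed=4)
        f2 = fit_marginal_epistasis(src, y, None, truth.target_index, B=50, seed=4)
        np.testing.assert_array_equal(f1.sigma2, f2.sigma2)
        np.testing.assert_array_equal(f1.p, f2.p)

    def test_se_shrinks_with_sample_size(self):
        # log SE vs log N slope near -1 (kernel-averaging CLT rate)
        ses = []
        sizes = [500, 2000, 8000]
        for n in sizes:
            src = simulate_genotypes(n, 100, seed=5)
            reps = []
            for rep in range(3):
                cfg = SimConfig(N=n, M=100, sigma2_g=0.3, seed=50 + rep)
                y, truth = simulate_phenotype(src, cfg)
                fit = fit_marginal_epistasis(src, y, None, truth.target_index,
                                             B=50, seed=rep)
                reps.append(fit.se()[fit.labels.index("gxg_genome")])
            ses.append(np.mean(reps))
        slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
        assert -1.35 < slope < -0.65

    def test_local_distal_scopes_run(self):
        src = simulate_genotypes(800, 200, seed=8, n_chromosomes=2)
        cfg = SimConfig(N=800, M=200, sigma2_g=0.3, sigma2_gxg=0.05, seed=2,
                        n_chromosomes=2)
        y, truth = simulate_phenotype(src, cfg)
        for scope in ("local", "distal"):
            fit = fit_marginal_epistasis(src, y, None, truth.target_index,
                                         B=50, seed=1, scope=scope)
            assert np.isfinite(fit.p).all()
            assert fit.labels[1] == f"gxg_{scope}"


class _SyntheticStream:
    """Column source that regenerates blocks from seeds, never storing the
    full matrix — stands in for a large on-disk panel."""

    def __init__(self, n, m, block=2000):
        self.n_samples, self.n_columns, self.block = n, m, block

    def iter_blocks(self):
        for start in range(0, self.n_columns, self.block):
            b = min(self.block, self.n_columns - start)
            yield np.random.default_rng(start).standard_normal((self.n_samples, b))


def test_streaming_memory_independent_of_panel_size():
    """Sketching a 500 x 100k component peaks far below the ~400 MB a dense
    matrix would need: memory is O(N*B + N*block), not O(N*M)."""
    import tracemalloc
    n, m, B = 500, 100_000, 20
    comp = ComponentDef("big", "genotype_additive", _SyntheticStream(n, m), m)
    probes = draw_probes(n, B, seed=0)
    y = np.zeros(n)
    tracemalloc.start()
    sketch_component(comp, probes, y)
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    dense_bytes = n * m * 8
    assert peak < dense_bytes / 5
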