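"""REML correctness, t/PI inference, I² decomposition, marginal means, AIC."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
import scipy.optimize as opt
import scipy.stats as st

from darrmeta.model import (
    FitResult,
    aic_compare,
    contrast,
    design_matrix,
    fit_reml,
    i2_decomposition,
    marginal_means,
    prediction_interval,
    restricted_loglik,
    t_inference,
    typical_sampling_variance,
)
from darrmeta.phylo import grafen_lengths, phylo_correlation
from darrmeta.simulate import simulate_tree


def _instance(seed, k=20, s=6, p=2, het=False):
    """A random multilevel instance with known structure."""
    rng = np.random.default_rng(seed)
    A = phylo_correlation(grafen_lengths(simulate_tree(s, seed + 100)))
    uniq = A.species
    species = [uniq[i % s] for i in range(k)]
    Z = np.zeros((k, s))
    for i, sp in enumerate(species):
        Z[i, uniq.index(sp)] = 1.0
    v = rng.uniform(0.005, 0.05, k)
    X = np.column_stack([np.ones(k)] + [rng.standard_normal(k) for _ in range(p - 1)])
    Sig = 0.05 * Z @ A.matrix @ Z.T + 0.03 * Z @ Z.T + 0.1 * np.eye(k) + np.diag(v)
    y = np.linalg.cholesky(Sig) @ rng.standard_normal(k) + X @ ([0.2] + [0.1] * (p - 1))
    levels = ["a" if i % 2 else "b" for i in range(k)] if het else None
    return y, X, v, species, A, Z, levels


def _contrast_oracle_nll(y, X, V, mats):
    """Independent REML oracle: density of orthonormal error contrasts."""
    k, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    K = Q[:, p:].T
    Ky = K @ y

    def nll(log_s2):
        s2 = np.exp(log_s2)
        S = V + sum(a * M for a, M in zip(s2, mats))
        KSK = K @ S @ K.T
        _, ld = np.linalg.slogdet(KSK)
        return 0.5 * ((k - p) * np.log(2 * np.pi) + ld
                      + Ky @ np.linalg.solve(KSK, Ky))

    return nll


class TestREMLCore:
    def test_closed_form_equal_variance_case(self):
        """Intercept-only, equal known variances: REML total variance is
        the sample variance, so sigma2_obs = 1 - 0.1 = 0.9."""
        fit = fit_reml(np.array([0.0, 1.0, 2.0]), V=np.full(3, 0.1),
                       random=("observation",))
        assert fit.variance_components["obs"] == pytest.approx(0.9, rel=1e-5)
        assert fit.beta[0] == pytest.approx(1.0, rel=1e-8)
        assert fit.se_beta[0] == pytest.approx(np.sqrt(1.0 / 3), rel=1e-5)

    @pytest.mark.parametrize("seed,k,p,het", [(1, 20, 1, False), (2, 30, 2, False),
                                              (3, 24, 1, True)])
    def test_matches_dense_contrast_oracle(self, seed, k, p, het):
        """Structured REML optimum equals a generic Nelder-Mead
        maximization of the error-contrast density (loglik to 1e-6,
        beta to 1e-6)."""
        y, X, v, species, A, Z, levels = _instance(seed, k=k, p=p, het=het)
        fit = fit_reml(y, X=X, V=v, species=species, A=A, obs_levels=levels)
        mats = [Z @ A.matrix @ Z.T, Z @ Z.T]
        if levels is None:
            mats.append(np.eye(k))
        else:
            for lev in sorted(set(levels)):
                mats.append(np.diag([1.0 if x == lev else 0.0 for x in levels]))
        nll = _contrast_oracle_nll(y, X, np.diag(v), mats)
        best = None
        for scale in (0.05, 0.2, 0.01):
            r = opt.minimize(nll, np.log([scale] * len(mats)), method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-14,
                                      "maxiter": 20000, "maxfev": 20000})
            if best is None or r.fun < best.fun:
                best = r
        assert fit.restricted_loglik == pytest.approx(-best.fun, abs=1e-6)
        s2 = np.exp(best.x)
        S = np.diag(v) + sum(a * M for a, M in zip(s2, mats))
        Si = np.linalg.inv(S)
        beta_o = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        assert np.abs(fit.beta - beta_o).max() < 1e-6

    def test_zero_components_reduce_to_gls(self):
        y, X, v, species, A, _, _ = _instance(4, k=15, p=2)
        fit = fit_reml(y, X=X, V=v, species=species, A=A, random=())
        W = np.diag(1.0 / v)
        beta_gls = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert np.allclose(fit.beta, beta_gls, atol=1e-10)

    def test_matches_metafor_rma_mv(self, tmp_path):
        """Independent cross-check against the reference multilevel
        meta-analysis implementation on a small instance."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the metafor cross-check")
        y, X, v, species, A, _, _ = _instance(5, k=60, s=12, p=1)
        fit = fit_reml(y, X=X, V=v, species=species, A=A)
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "v.csv", v, delimiter=",")
        np.savetxt(tmp_path / "A.csv", A.matrix, delimiter=",")
        (tmp_path / "sp.txt").write_text("\n".join(species) + "\n")
        (tmp_path / "Aord.txt").write_text("\n".join(A.species) + "\n")
        rcode = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            y <- scan("{tmp_path}/y.csv"); v <- scan("{tmp_path}/v.csv")
            sp <- readLines("{tmp_path}/sp.txt")
            A <- as.matrix(read.csv("{tmp_path}/A.csv", header=FALSE))
            rownames(A) <- colnames(A) <- readLines("{tmp_path}/Aord.txt")
            d <- data.frame(y=y, sp=sp, phylo=sp, id=seq_along(y))
            m <- rma.mv(y, V=v, random=list(~1|phylo, ~1|sp, ~1|id),
                        R=list(phylo=A), data=d, test="t", method="REML")
            cat(coef(m), m$se, m$sigma2, logLik(m), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        assert fit.beta[0] == pytest.approx(vals[0], abs=1e-4)
        assert fit.se_beta[0] == pytest.approx(vals[1], abs=1e-4)
        assert fit.restricted_loglik == pytest.approx(vals[5], abs=1e-3)
        # our multistart+polish should never find a worse optimum
        assert fit.restricted_loglik >= vals[5] - 1e-4

    def test_rank_deficient_design_rejected(self):
        y, X, v, species, A, _, _ = _instance(6, k=15, p=1)
        X2 = np.column_stack([X, X])
        with pytest.raises(ValueError, match="rank"):
            fit_reml(y, X=X2, V=v, species=species, A=A)

    def test_deterministic_given_inputs(self):
        y, X, v, species, A, _, _ = _instance(7, k=18, p=1)
        f1 = fit_reml(y, X=X, V=v, species=species, A=A)
        f2 = fit_reml(y, X=X, V=v, species=species, A=A)
        assert f1.restricted_loglik == f2.restricted_loglik
        assert np.array_equal(f1.beta, f2.beta)


class TestInference:
    def _toy_fit(self, beta, cov, k=10):
        beta = np.asarray(beta, float)
        cov = np.asarray(cov, float)
        return FitResult(
            beta=beta, se_beta=np.sqrt(np.diag(cov)), cov_beta=cov,
            coef_names=[f"lvl{i}" for i in range(len(beta))],
            variance_components={"obs": 0.0}, restricted_loglik=0.0,
            k=k, p=len(beta), converged=True, vi=np.full(k, 0.1),
        )

    def test_t_statistic_arithmetic(self):
        fit = fit_reml(np.array([0.0, 1.0, 2.0]), V=np.full(3, 0.1),
                       random=("observation",))
        inf = t_inference(fit)
        assert inf["df"] == 2
        assert inf["t"][0] == pytest.approx(1.0 / 0.57735, rel=1e-4)

    def test_ci_quantiles_match_independent_t_quantile(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df = int(rng.integers(2, 60))
            se = float(rng.uniform(0.01, 2))
            fit = self._toy_fit([0.3], [[se**2]], k=df + 1)
            inf = t_inference(fit)
            # Cornish-Fisher-free oracle: invert the t CDF by bisection
            lo, hi = 0.0, 200.0
            for _ in range(200):
                mid = (lo + hi) / 2
                if st.t.cdf(mid, df) < 0.975:
                    lo = mid
                else:
                    hi = mid
            assert inf["ci_upper"][0] == pytest.approx(0.3 + lo * se, abs=1e-8)

    def test_zero_se_collapses_ci(self):
        fit = self._toy_fit([0.5], [[0.0]])
        inf = t_inference(fit)
        assert inf["ci_lower"][0] == inf["ci_upper"][0] == 0.5
        assert inf["p"][0] == 0.0

    def test_df_error_when_saturated(self):
        fit = self._toy_fit([0.1, 0.2], np.eye(2) * 0.01, k=2)
        with pytest.raises(ValueError):
            t_inference(fit)


class TestPredictionInterval:
    def test_half_width_adds_heterogeneity(self):
        fit = fit_reml(np.array([0.0, 1.0, 2.0]), V=np.full(3, 0.1),
                       random=("observation",))
        pi = prediction_interval(fit)
        half = st.t.ppf(0.975, 2) * np.sqrt(fit.se_beta[0] ** 2 + 0.9)
        assert (pi["pi_upper"][0] - pi["pi_lower"][0]) / 2 == pytest.approx(half, rel=1e-4)
        assert half == pytest.approx(4.779, abs=0.01)

    def test_zero_heterogeneity_pi_equals_ci(self):
        fit = FitResult(
            beta=np.array([0.2]), se_beta=np.array([0.1]),
            cov_beta=np.array([[0.01]]), coef_names=["intercept"],
            variance_components={"obs": 0.0}, restricted_loglik=0.0,
            k=10, p=1, converged=True, vi=np.full(10, 0.1),
        )
        inf = t_inference(fit)
        pi = prediction_interval(fit)
        assert pi["pi_lower"][0] == pytest.approx(inf["ci_lower"][0])
        assert pi["pi_upper"][0] == pytest.approx(inf["ci_upper"][0])

    def test_pi_always_contains_ci(self, small_system):
        from darrmeta.pipeline import analyze_groups
        _, groups, _, A = small_system
        fit = analyze_groups(groups, A=A).fit
        inf = t_inference(fit)
        pi = prediction_interval(fit)
        assert np.all(pi["pi_lower"] <= inf["ci_lower"])
        assert np.all(pi["pi_upper"] >= inf["ci_upper"])


class TestI2:
    def test_equal_variance_toy_case(self):
        fit = fit_reml(np.array([0.0, 1.0, 2.0]), V=np.full(3, 0.1),
                       random=("observation",))
        i2 = i2_decomposition(fit)
        assert typical_sampling_variance(np.full(3, 0.1)) == pytest.approx(0.1)
        assert i2["i2_total"] == pytest.approx(90.0, abs=0.01)

    def test_components_sum_to_total(self, small_system):
        from darrmeta.pipeline import analyze_groups
        _, groups, _, A = small_system
        fit = analyze_groups(groups, A=A).fit
        i2 = i2_decomposition(fit)
        parts = sum(v for k, v in i2.items() if k != "i2_total")
        assert parts == pytest.approx(i2["i2_total"], abs=1e-10)

    def test_invariant_to_common_rescaling(self):
        y, X, v, species, A, _, _ = _instance(8, k=20, p=1)
        f1 = fit_reml(y, X=X, V=v, species=species, A=A)
        c = 3.7
        f2 = fit_reml(y * np.sqrt(c), X=X, V=v * c, species=species, A=A)
        i1, i2_ = i2_decomposition(f1), i2_decomposition(f2)
        for key in i1:
            assert i1[key] == pytest.approx(i2_[key], abs=0.2)

    def test_vanishing_sampling_variance_drives_i2_to_100(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.2, 0.5, 30)
        fit = fit_reml(y, V=np.full(30, 1e-8), random=("observation",))
        assert i2_decomposition(fit)["i2_total"] > 99.99


class TestMarginalMeansContrast:
    def _habitat_fit(self):
        cov = np.diag([0.01, 0.04])
        return FitResult(
            beta=np.array([0.209, 0.060]), se_beta=np.sqrt(np.diag(cov)),
            cov_beta=cov, coef_names=["habitat[aquatic]", "habitat[terrestrial]"],
            variance_components={"obs": 0.0}, restricted_loglik=0.0,
            k=50, p=2, converged=True, vi=np.full(50, 0.1),
        )

    def test_equal_weight_marginal_mean(self):
        mm = marginal_means(self._habitat_fit())
        assert mm["estimate"] == pytest.approx(0.1345)
        assert mm["se"] == pytest.approx(np.sqrt(0.0125), rel=1e-6)

    def test_single_level_returns_that_level(self):
        mm = marginal_means(self._habitat_fit(), levels=["habitat[aquatic]"])
        assert mm["estimate"] == pytest.approx(0.209)

    def test_equal_level_estimates_give_common_value(self):
        fit = self._habitat_fit()
        fit.beta = np.array([0.15, 0.15])
        assert marginal_means(fit)["estimate"] == pytest.approx(0.15)

    def test_missing_level_errors(self):
        with pytest.raises(KeyError):
            marginal_means(self._habitat_fit(), levels=["habitat[arboreal]"])

    def test_pairwise_contrast_arithmetic(self):
        con = contrast(self._habitat_fit(), [1, -1])
        assert con["estimate"] == pytest.approx(0.149)
        assert con["se"] == pytest.approx(np.sqrt(0.05), rel=1e-6)

    def test_unit_vector_contrast_reproduces_coefficient(self):
        fit = self._habitat_fit()
        con = contrast(fit, [0, 1])
        inf = t_inference(fit)
        assert con["estimate"] == pytest.approx(fit.beta[1])
        assert con["ci_lower"] == pytest.approx(inf["ci_lower"][1])

    def test_self_contrast_is_exactly_zero(self):
        con = contrast(self._habitat_fit(), [0, 0])
        assert con["estimate"] == 0.0 and con["se"] == 0.0

    def test_nonconformable_contrast_rejected(self):
        with pytest.raises(ValueError):
            contrast(self._habitat_fit(), [1, -1, 0])


class TestAIC:
    def test_identical_models_have_zero_delta(self):
        y, X, v, species, A, _, _ = _instance(9, k=20, p=1)
        f = fit_reml(y, X=X, V=v, species=species, A=A)
        tab = aic_compare({"a": f, "b": f})
        assert np.allclose(tab["delta_aic"], 0.0)

    def test_extra_variance_parameter_never_lowers_loglik(self):
        y, X, v, species, A, _, levels = _instance(10, k=24, p=1, het=True)
        levels = ["a" if i % 2 else "b" for i in range(24)]
        homo = fit_reml(y, X=X, V=v, species=species, A=A)
        het = fit_reml(y, X=X, V=v, species=species, A=A, obs_levels=levels)
        assert het.restricted_loglik >= homo.restricted_loglik - 1e-6
        assert het.n_var_params == homo.n_var_params + 1

    def test_differing_designs_rejected(self):
        y, X, v, species, A, _, _ = _instance(11, k=20, p=2)
        f1 = fit_reml(y, X=X, V=v, species=species, A=A)
        f2 = fit_reml(y, X=X[:, :1], V=v, species=species, A=A)
        with pytest.raises(ValueError, match="design"):
            aic_compare({"full": f1, "intercept": f2})

    def test_heteroscedastic_truth_prefers_heteroscedastic_model(self):
        """Simulate strongly unequal level variances; the per-level model
        should win the AIC comparison in most replicates."""
        wins = 0
        reps = 12
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            k = 120
            levels = ["a"] * (k // 2) + ["b"] * (k - k // 2)
            s2 = np.where(np.array(levels) == "a", 0.02, 0.6)
            v = np.full(k, 0.01)
            y = 0.2 + rng.normal(0, np.sqrt(s2 + v))
            homo = fit_reml(y, V=v, random=("observation",))
            het = fit_reml(y, V=v, random=("observation",), obs_levels=levels)
            wins += het.aic < homo.aic
        assert wins >= reps - 1


class TestHeteroscedastic:
    def test_equal_true_level_variances_recovered_near_equal(self):
        """With equal true observation-level variances, the per-level fit
        should estimate near-equal components (max ratio < 2) in most
        replicates."""
        from darrmeta.effects import build_effects
        from darrmeta.pipeline import fit_effects
        from darrmeta.simulate import SimTruth, simulate_dataset

        ok = 0
        reps = 8
        for seed in range(reps):
            truth = SimTruth(n_species=60, studies_per_species=(3, 5),
                             frac_tdt=0.0, frac_missing_sd=0.0,
                             frac_persistent=0.4, seed=700 + seed)
            groups, _, A = simulate_dataset(truth)
            effects, _ = build_effects(groups)
            fit, _ = fit_effects(effects, A=A, obs_level_moderator="timing")
            s2 = [v for k, v in fit.variance_components.items()
                  if k.startswith("obs:")]
            assert len(s2) == 2
            ratio = max(s2) / max(min(s2), 1e-12)
            ok += ratio < 2
        assert ok >= reps - 1


class TestDesignMatrix:
    def test_cell_means_coding_single_categorical(self):
        data = {"habitat": ["aquatic", "terrestrial", "aquatic"]}
        X, names = design_matrix(data, ["habitat"])
        assert names == ["habitat[aquatic]", "habitat[terrestrial]"]
        assert np.array_equal(X, [[1, 0], [0, 1], [1, 0]])

    def test_continuous_moderator_centered_with_intercept(self):
        data = {"year": [2000.0, 2010.0, 2020.0]}
        X, names = design_matrix(data, ["year"])
        assert names == ["intercept", "year"]
        assert np.allclose(X[:, 1], [-10, 0, 10])
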