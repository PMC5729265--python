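"""RDA fit, pseudo-F, permutation test and biplot coordinates."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methrda import (
    DesignMatrix,
    biplot_coordinates,
    encode_design,
    fit_rda,
    permutation_test,
    pseudo_f,
)
from methrda.exceptions import (
    InsufficientSamplesError,
    ParameterError,
    RankError,
)
from methrda.rda import RDAFit

from conftest import binary_design


def _random_case(rng, k=5, n=12, m=2, q=0):
    y = rng.normal(size=(k, n))
    x = rng.normal(size=(n, m))
    x -= x.mean(axis=0)
    z = None
    if q:
        z = rng.normal(size=(n, q))
        z -= z.mean(axis=0)
    design = DesignMatrix(values=x, column_names=[f"x{i}" for i in range(m)],
                          conditioning=z,
                          conditioning_names=[f"z{i}" for i in range(q)])
    return y, design


class TestFitAgainstPerCpGLeastSquares:
    def test_single_cpg_r2_is_squared_correlation(self):
        rng = np.random.default_rng(7)
        n = 20
        design = binary_design(n)
        y = rng.normal(size=(1, n))
        fit = fit_rda(y, design)
        r, _ = stats.pearsonr(design.values[:, 0], y[0])
        assert fit.r2 == pytest.approx(r**2, rel=1e-10)

    def test_intercept_only_gives_zero_r2(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(4, 10))
        design = DesignMatrix(values=np.empty((10, 0)), column_names=[])
        fit = fit_rda(y, design)
        assert fit.r2 == 0.0 and fit.ss_fitted == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_fitted_ss_matches_ols_oracle(self, seed):
        """ss_fitted equals the summed per-CpG OLS explained SS (q = 0)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        k, n, m = rng.integers(2, 7), rng.integers(8, 13), rng.integers(1, 3)
        y, design = _random_case(rng, k=k, n=n, m=m)
        fit = fit_rda(y, design)
        explained = 0.0
        for j in range(k):
            ols = sm.OLS(y[j], sm.add_constant(design.values)).fit()
            explained += ols.ess
        assert fit.ss_fitted == pytest.approx(explained, rel=1e-8)
        # r2 is the variance-weighted mean of per-CpG R2
        total = sum(np.var(y[j], ddof=0) * n for j in range(k))
        assert fit.r2 == pytest.approx(explained / fit.ss_total, rel=1e-8)


class TestFitContracts:
    @pytest.mark.parametrize("q,scale", [(0, False), (2, False), (0, True)])
    def test_variance_decomposition_and_components(self, q, scale):
        rng = np.random.default_rng(q + 10 * scale)
        for _ in range(20):
            k = int(rng.integers(1, 8))
            n = int(rng.integers(q + 5, 15))
            m = int(rng.integers(1, 3))
            y, design = _random_case(rng, k=k, n=n, m=m, q=q)
            fit = fit_rda(y, design, scale=scale)
            total = fit.ss_conditioned + fit.ss_fitted + fit.ss_residual
            assert total == pytest.approx(fit.ss_total, rel=1e-8)
            assert 0.0 <= fit.r2 <= 1.0
            assert fit.n_components <= min(m, k, n - 1)
            eig = fit.eigenvalues
            assert (np.diff(eig) <= 1e-12).all() and (eig >= -1e-12).all()
            assert eig.sum() == pytest.approx(fit.ss_fitted / (n - 1), rel=1e-8)

    def test_r2_invariant_to_cpg_order_and_offsets(self):
        rng = np.random.default_rng(3)
        y, design = _random_case(rng, k=6, n=14, m=1)
        base = fit_rda(y, design).r2
        perm = rng.permutation(6)
        assert fit_rda(y[perm], design).r2 == pytest.approx(base, rel=1e-12)
        shifted = y.copy()
        shifted[2] += 17.5
        assert fit_rda(shifted, design).r2 == pytest.approx(base, rel=1e-10)

    def test_conditioning_shrinks_total_denominator_r2(self):
        """With a total-variance denominator, partialling out a correlated
        covariate can only reduce R2 (the reported drop 0.063 -> 0.027
        pattern for adjusted models)."""
        rng = np.random.default_rng(12)
        n = 30
        z = rng.normal(size=(n, 1))
        x = 0.8 * z + 0.6 * rng.normal(size=(n, 1))
        y = (2.0 * x + rng.normal(size=(n, 4))).T
        crude = fit_rda(y, DesignMatrix(values=x - x.mean(0), column_names=["x"]))
        adjusted = fit_rda(
            y,
            DesignMatrix(values=x - x.mean(0), column_names=["x"],
                         conditioning=z - z.mean(0), conditioning_names=["z"]),
        )
        assert adjusted.r2 < crude.r2
        post = fit_rda(
            y,
            DesignMatrix(values=x - x.mean(0), column_names=["x"],
                         conditioning=z - z.mean(0), conditioning_names=["z"]),
            r2_denominator="conditioned",
        )
        assert post.r2 > adjusted.r2

    def test_null_r2_expectation_matches_analytic(self):
        """E[R2] = 1/(n-1) for one centered binary predictor on iid data."""
        rng = np.random.default_rng(99)
        for n in (10, 40, 100):
            design = binary_design(n)
            r2s = [fit_rda(rng.normal(size=(5, n)), design).r2 for _ in range(400)]
            mean, se = np.mean(r2s), np.std(r2s, ddof=1) / np.sqrt(len(r2s))
            assert abs(mean - 1 / (n - 1)) < 3 * se

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(3, 10))
        x = rng.normal(size=(10, 1))
        design = DesignMatrix(values=np.hstack([x, 2 * x]), column_names=["a", "b"])
        with pytest.raises(RankError):
            fit_rda(y, design)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(4)
        y, design = _random_case(rng, k=3, n=3, m=2)
        with pytest.raises(InsufficientSamplesError):
            fit_rda(y, design)


class TestPseudoF:
    def _fit_with_r2(self, r2, m=1, q=0, n=42):
        return RDAFit(r2=r2, ss_total=1.0, ss_fitted=r2, ss_residual=1.0 - r2,
                      ss_conditioned=0.0, sample_scores=np.empty((n, 0)),
                      cpg_loadings=np.empty((3, 0)), eigenvalues=np.empty(0),
                      m=m, n=n, k=3, q=q)

    def test_algebra(self):
        assert pseudo_f(self._fit_with_r2(0.5)) == pytest.approx(40.0)
        assert pseudo_f(self._fit_with_r2(0.0)) == 0.0

    def test_monotone_in_r2(self):
        assert pseudo_f(self._fit_with_r2(0.3)) < pseudo_f(self._fit_with_r2(0.6))

    def test_zero_residual_warns_and_returns_inf(self):
        with pytest.warns(UserWarning):
            f = pseudo_f(self._fit_with_r2(1.0))
        assert np.isinf(f)


class TestPermutationTest:
    def test_p_value_bounds_and_formula(self):
        rng = np.random.default_rng(21)
        y, design = _random_case(rng, k=4, n=16, m=1)
        res = permutation_test(y, design, b=99, seed=5)
        assert 1 / 100 <= res.p_value <= 1.0
        expected = (1 + int((res.f_null >= res.f_obs).sum())) / (res.b + 1)
        assert res.p_value == expected

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(22)
        y, design = _random_case(rng, k=4, n=16, m=2)
        a = permutation_test(y, design, b=50, seed=9)
        c = permutation_test(y, design, b=50, seed=9)
        np.testing.assert_array_equal(a.f_null, c.f_null)
        assert a.p_value == c.p_value

    def test_strong_signal_reaches_minimum_p(self):
        rng = np.random.default_rng(23)
        n = 20
        x = np.linspace(-1, 1, n)[:, None]
        y = (10 * x + 0.01 * rng.normal(size=(n, 4))).T
        design = DesignMatrix(values=x - x.mean(0), column_names=["x"])
        res = permutation_test(y, design, b=199, seed=1)
        assert res.p_value == 1 / 200

    def test_slow_and_fast_paths_agree_without_conditioning(self):
        """The conditioned (refit) path with q=0-like dummy covariate must
        match the vectorized path on the same permutations' statistic set."""
        rng = np.random.default_rng(24)
        y, design = _random_case(rng, k=3, n=12, m=1)
        fast = permutation_test(y, design, b=30, seed=7)
        # brute-force recomputation with per-permutation refits
        perm_rng = np.random.default_rng(7)
        perms = np.array([perm_rng.permutation(12) for _ in range(30)])
        f_brute = []
        for order in perms:
            d2 = DesignMatrix(values=design.values[order], column_names=["x"])
            fit = fit_rda(y, d2)
            f_brute.append(pseudo_f(fit))
        np.testing.assert_allclose(fast.f_null, f_brute, rtol=1e-9)

    def test_invalid_permutation_count(self):
        rng = np.random.default_rng(25)
        y, design = _random_case(rng)
        with pytest.raises(ParameterError):
            permutation_test(y, design, b=0)


class TestBiplot:
    def test_centroids_separate_groups_on_first_axis(self):
        rng = np.random.default_rng(31)
        n = 20
        design = binary_design(n)
        shift = np.repeat([0.0, 3.0], n // 2)
        y = (shift[:, None] + rng.normal(scale=0.3, size=(n, 6))).T
        fit = fit_rda(y, design)
        groups = ["A"] * (n // 2) + ["B"] * (n // 2)
        coords = biplot_coordinates(fit, n_components=1, groups=groups)
        a, b = coords.group_centroids["RDA1"]
        assert a * b < 0  # opposite signs around the origin

    def test_zero_labeled_cpgs(self):
        rng = np.random.default_rng(32)
        y, design = _random_case(rng, k=5, n=14, m=1)
        fit = fit_rda(y, design)
        coords = biplot_coordinates(fit, n_components=1, n_labeled_cpgs=0)
        assert coords.cpg_coordinates.empty

    def test_top_loading_cpg_matches_per_cpg_r2(self):
        """In a single-factor simulation the strongest-loading CpG is the
        CpG with maximal univariate R2."""
        rng = np.random.default_rng(33)
        n, k = 40, 8
        design = binary_design(n)
        x = design.values[:, 0]
        effects = np.array([0.1, 0.2, 3.0, 0.15, 0.05, 0.4, 0.1, 0.2])
        y = (np.outer(x, effects) + rng.normal(scale=0.5, size=(n, k))).T
        fit = fit_rda(pd.DataFrame(y, index=[f"cg{j}" for j in range(k)]), design)
        coords = biplot_coordinates(fit, n_components=1, n_labeled_cpgs=1)
        per_cpg_r2 = [stats.pearsonr(x, y[j])[0] ** 2 for j in range(k)]
        assert coords.cpg_coordinates.index[0] == f"cg{int(np.argmax(per_cpg_r2))}"

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(34)
        y, design = _random_case(rng, k=5, n=14, m=1)
        fit = fit_rda(y, design)
        with pytest.raises(ParameterError):
            biplot_coordinates(fit, n_components=fit.n_components + 1)


class TestAgainstReferenceOrdination:
    """Cross-check against the independent constrained-ordination
    implementation in R's vegan package (rda), including a partial model."""

    def test_matches_vegan(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript not on PATH"
        rng = np.random.default_rng(41)
        n, k = 14, 5
        y = rng.normal(size=(n, k))
        g = np.tile([0.0, 1.0], n // 2)
        age = rng.normal(size=n)
        z = rng.normal(size=n)
        pd.DataFrame(y, columns=[f"cg{j}" for j in range(k)]).to_csv(
            tmp_path / "y.csv", index_label="s"
        )
        pd.DataFrame({"g": g, "age": age, "z": z}).to_csv(
            tmp_path / "x.csv", index_label="s"
        )
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly = TRUE)
            Y <- as.matrix(read.csv(args[1], row.names = 1))
            X <- read.csv(args[2], row.names = 1)
            fit <- rda(Y ~ g + age, data = X)
            n <- nrow(Y); m <- 2
            r2 <- fit$CCA$tot.chi / fit$tot.chi
            f <- (fit$CCA$tot.chi / m) / (fit$CA$tot.chi / (n - m - 1))
            pfit <- rda(Y ~ g + Condition(z), data = X)
            pr2 <- pfit$CCA$tot.chi / pfit$tot.chi
            pf <- (pfit$CCA$tot.chi / 1) / (pfit$CA$tot.chi / (n - 1 - 1 - 1))
            fmt <- function(v) sprintf("%.15g", v)
            cat(fmt(r2), fmt(f), paste(fmt(fit$CCA$eig), collapse=","),
                fmt(pr2), fmt(pf), sep="\\n")
            """
        )
        (tmp_path / "ref.R").write_text(script)
        out = subprocess.run(
            [rscript, str(tmp_path / "ref.R"), str(tmp_path / "y.csv"),
             str(tmp_path / "x.csv")],
            capture_output=True, text=True, timeout=300, check=True,
        ).stdout.split()
        ref_r2, ref_f = float(out[0]), float(out[1])
        ref_eig = np.array([float(v) for v in out[2].split(",")])
        ref_pr2, ref_pf = float(out[3]), float(out[4])

        pheno = pd.DataFrame({"g": g, "age": age, "z": z},
                             index=[f"s{i}" for i in range(n)])
        design = encode_design(pheno, ["g", "age"])
        fit = fit_rda(y.T, design)
        assert fit.r2 == pytest.approx(ref_r2, rel=1e-8)
        assert pseudo_f(fit) == pytest.approx(ref_f, rel=1e-8)
        np.testing.assert_allclose(fit.eigenvalues, ref_eig, rtol=1e-8)

        partial = fit_rda(y.T, encode_design(pheno, ["g"], ["z"]))
        assert partial.r2 == pytest.approx(ref_pr2, rel=1e-8)
        assert pseudo_f(partial) == pytest.approx(ref_pf, rel=1e-8)
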