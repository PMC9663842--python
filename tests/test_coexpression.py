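"""Signed networks, TOM, module detection/refinement, DcoExp, trait links."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from perifat import coexpression as cx

from .conftest import make_counts  # noqa: F401  (fixture helpers)


def planted_expression(rng, blocks, n_noise, n_samples, rho=0.85):
    """Latent-factor blocks plus iid noise genes; returns (frame, labels)."""
    rows, labels = [], []
    for bi, size in enumerate(blocks):
        f = rng.normal(size=n_samples)
        x = np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * rng.normal(
            size=(size, n_samples)
        )
        rows.append(x)
        labels += [bi] * size
    if n_noise:
        rows.append(rng.normal(size=(n_noise, n_samples)))
        labels += [-1] * n_noise
    X = np.vstack(rows)
    frame = pd.DataFrame(
        X,
        index=[f"g{i}" for i in range(len(X))],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return frame, np.array(labels)


class TestGoodSamplesGenes:
    def test_constant_gene_dropped(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 6)))
        mat.iloc[0] = 3.0
        out = cx.good_samples_genes(mat)
        assert 0 not in out.index

    def test_clean_input_identity(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 6)))
        pd.testing.assert_frame_equal(cx.good_samples_genes(mat), mat)

    def test_mostly_missing_gene_dropped(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 12)))
        mat.iloc[1, :7] = np.nan
        out = cx.good_samples_genes(mat)
        assert 1 not in out.index


class TestSoftThreshold:
    def test_deterministic_and_bounded(self, rng):
        expr, _ = planted_expression(rng, [50, 50], 50, 20)
        beta1 = cx.pick_soft_threshold(expr)
        beta2 = cx.pick_soft_threshold(expr)
        assert beta1 == beta2
        assert 1 <= beta1 <= 20

    def test_pure_noise_falls_back(self, rng):
        noise = pd.DataFrame(rng.normal(size=(150, 12)))
        assert cx.pick_soft_threshold(noise) == 12


class TestSignedAdjacency:
    def test_extreme_correlations(self):
        up = np.linspace(0, 1, 10)
        expr = pd.DataFrame([up, up * 2, -up])
        a = cx.signed_adjacency(expr, 6)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self, rng):
        # cor = 0 -> ((1+0)/2)^6
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        a = cx.signed_adjacency(pd.DataFrame([x, y]), 6)
        assert a[0, 1] == pytest.approx(0.5**6)


class TestTom:
    def test_two_gene_network(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        tom = cx.tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.3)

    def test_three_gene_hand_arithmetic(self):
        # a12=0.5, a13=0.4, a23=0.2:
        # TOM12 = (a13 a23 + a12) / (min(k1,k2) + 1 - a12)
        #       = (0.4*0.2 + 0.5) / (0.7 + 1 - 0.5) = 0.58/1.2
        a = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.2], [0.4, 0.2, 1.0]])
        tom = cx.tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.58 / 1.2)

    def test_complete_graph_saturates(self):
        a = np.ones((4, 4))
        assert np.allclose(cx.tom_similarity(a), 1.0)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr, truth = planted_expression(rng, [50, 50], 0, 20, rho=0.9)
        tom = cx.tom_similarity(cx.signed_adjacency(expr, 12))
        assign = cx.detect_modules(tom, list(expr.index))
        labels = assign.to_numpy()
        non_grey = [m for m in np.unique(labels) if m != cx.GREY]
        assert len(non_grey) == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_noise_mostly_grey(self, rng):
        noise = pd.DataFrame(
            rng.normal(size=(200, 12)), index=[f"g{i}" for i in range(200)]
        )
        tom = cx.tom_similarity(cx.signed_adjacency(noise, 12))
        assign = cx.detect_modules(
            tom, list(noise.index), corr=cx.gene_correlation(noise)
        )
        assert (assign == cx.GREY).mean() >= 0.95

    def test_oversized_min_module_all_grey(self, rng):
        expr, _ = planted_expression(rng, [10], 0, 8)
        tom = cx.tom_similarity(cx.signed_adjacency(expr, 6))
        assign = cx.detect_modules(tom, list(expr.index), min_module_size=50)
        assert (assign == cx.GREY).all()


class TestEigengene:
    def test_identical_profiles(self, rng):
        base = rng.normal(size=10)
        expr = pd.DataFrame([base, base * 2 + 1, base - 3]).astype(float)
        eig = cx.module_eigengene(expr, [0, 1, 2])
        z = (base - base.mean()) / base.std(ddof=1)
        assert np.allclose(np.abs(np.corrcoef(eig, z)[0, 1]), 1.0)

    def test_maximises_explained_variance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 10)))
        eig = cx.module_eigengene(expr, list(range(15)))
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        cov = z.T @ z
        w, v = np.linalg.eigh(cov)
        lead = v[:, -1]
        cos = abs(eig.to_numpy() @ lead) / (
            np.linalg.norm(eig) * np.linalg.norm(lead)
        )
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, rng):
        for _ in range(10):
            expr = pd.DataFrame(rng.normal(size=(8, 10)))
            eig = cx.module_eigengene(expr, list(range(8)))
            rowmean = expr.mean(axis=0)
            assert np.corrcoef(eig, rowmean)[0, 1] >= 0


class TestKmeansRefine:
    def test_converged_assignment_unchanged(self, rng):
        expr, truth = planted_expression(rng, [40, 40], 0, 20, rho=0.95)
        assign = pd.Series(
            np.where(truth == 0, "turquoise", "blue"), index=expr.index
        )
        ms = cx.kmeans_refine(expr, assign)
        assert ms.assignment.equals(assign)

    def test_misassigned_gene_moves_home(self, rng):
        expr, truth = planted_expression(rng, [40, 40], 0, 20, rho=0.95)
        assign = pd.Series(
            np.where(truth == 0, "turquoise", "blue"), index=expr.index
        )
        assign.iloc[0] = "blue"  # gene from block 0 mislabelled
        ms = cx.kmeans_refine(expr, assign)
        assert ms.assignment.iloc[0] == "turquoise"

    def test_deterministic(self, rng):
        expr, truth = planted_expression(rng, [40, 40], 20, 20)
        assign = pd.Series(
            np.where(truth == 0, "turquoise", np.where(truth == 1, "blue", cx.GREY)),
            index=expr.index,
        )
        a = cx.kmeans_refine(expr, assign).assignment
        b = cx.kmeans_refine(expr, assign).assignment
        assert a.equals(b)


def fisher_enumeration(k, a_only, b_only, rest):
    """One-sided (greater) Fisher p by direct hypergeometric enumeration."""
    n1 = k + a_only
    n2 = b_only + rest
    K = k + b_only
    N = n1 + n2
    total = comb(N, K, exact=True)
    p = 0.0
    for kk in range(k, min(n1, K) + 1):
        p += comb(n1, kk, exact=True) * comb(n2, K - kk, exact=True) / total
    return p


class TestDcoExp:
    def _module_set(self, sex, assignment):
        return cx.ModuleSet(sex=sex, assignment=assignment)

    def test_identical_modules_no_specific(self):
        genes = [f"g{i}" for i in range(120)]
        assign = pd.Series(
            ["turquoise"] * 60 + ["blue"] * 60, index=genes
        )
        res = cx.dcoexp_fisher(
            self._module_set("M", assign), self._module_set("F", assign.copy()), genes
        )
        assert all(not r.specific for r in res)

    def test_planted_male_only_module_specific(self, rng):
        genes = [f"g{i}" for i in range(300)]
        male = pd.Series(cx.GREY, index=genes)
        male.iloc[:40] = "turquoise"
        female = pd.Series(cx.GREY, index=genes)
        female.iloc[rng.choice(np.arange(100, 300), 40, replace=False)] = "blue"
        res = cx.dcoexp_fisher(
            self._module_set("M", male), self._module_set("F", female), genes
        )
        male_res = [r for r in res if r.sex == "M"][0]
        assert male_res.specific

    def test_fisher_p_matches_enumeration(self):
        genes = [f"g{i}" for i in range(60)]
        male = pd.Series(cx.GREY, index=genes)
        male.iloc[:20] = "turquoise"
        female = pd.Series(cx.GREY, index=genes)
        female.iloc[10:40] = "blue"
        res = cx.dcoexp_fisher(
            self._module_set("M", male), self._module_set("F", female), genes
        )
        male_res = [r for r in res if r.sex == "M"][0]
        expected = fisher_enumeration(10, 10, 20, 20)
        assert male_res.fisher_p == pytest.approx(expected, rel=1e-9)

    def test_symmetric_under_sex_swap(self, rng):
        genes = [f"g{i}" for i in range(200)]
        a = pd.Series(rng.choice(["turquoise", "blue", cx.GREY], 200), index=genes)
        b = pd.Series(rng.choice(["brown", cx.GREY], 200), index=genes)
        r1 = cx.dcoexp_fisher(self._module_set("M", a), self._module_set("F", b), genes)
        r2 = cx.dcoexp_fisher(self._module_set("M", b), self._module_set("F", a), genes)
        key1 = {(r.sex, r.module): (r.fisher_p, r.specific) for r in r1}
        key2 = {(r.sex, r.module): (r.fisher_p, r.specific) for r in r2}
        # swapping the inputs swaps which sex each module is reported under
        assert {(("M", "F")[s == "M"], m): v for (s, m), v in key1.items()} == key2

    def test_background_violation_errors(self):
        genes = [f"g{i}" for i in range(10)]
        assign = pd.Series("turquoise", index=genes + ["extra"])
        with pytest.raises(ValueError, match="background"):
            cx.dcoexp_fisher(
                self._module_set("M", assign), self._module_set("F", assign), genes
            )


class TestModuleTrait:
    def _ms_with_eigengene(self, metadata, sex, eig):
        samples = metadata.samples_of_sex(sex)
        return cx.ModuleSet(
            sex=sex,
            assignment=pd.Series("turquoise", index=["g1", "g2"]),
            eigengenes=pd.DataFrame({"turquoise": eig}, index=samples),
        )

    def test_trait_equal_eigengene(self, metadata12, rng):
        eig = rng.normal(size=6)
        ms = self._ms_with_eigengene(metadata12, "M", eig)
        meta = metadata12
        meta.frame.loc[meta.samples_of_sex("M"), "renal"] = (
            10 + 2 * (eig - eig.min())
        )
        res = cx.module_trait_correlation(ms, meta, traits=["renal"])
        assert res[0].pearson_r == pytest.approx(1.0)
        assert res[0].significant

    def test_anticorrelated_trait(self, metadata12, rng):
        eig = rng.normal(size=6)
        ms = self._ms_with_eigengene(metadata12, "F", eig)
        metadata12.frame.loc[metadata12.samples_of_sex("F"), "pelvic"] = (
            50 - 3 * (eig - eig.min())
        )
        res = cx.module_trait_correlation(ms, metadata12, traits=["pelvic"])
        assert res[0].pearson_r == pytest.approx(-1.0)

    def test_independent_trait_rarely_significant(self, metadata12, rng):
        """|r| over 6 samples stays below the p=0.05 critical value (~0.81)
        for >=95% of independent replicates."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            eig = rng.normal(size=6)
            ms = self._ms_with_eigengene(metadata12, "M", eig)
            metadata12.frame.loc[
                metadata12.samples_of_sex("M"), "renal"
            ] = rng.uniform(5, 30, 6)
            res = cx.module_trait_correlation(ms, metadata12, traits=["renal"])
            hits += abs(res[0].pearson_r) >= 0.811
        assert hits / n_rep <= 0.10

    def test_zero_variance_trait_reported_missing(self, metadata12, rng):
        eig = rng.normal(size=6)
        ms = self._ms_with_eigengene(metadata12, "M", eig)
        metadata12.frame.loc[metadata12.samples_of_sex("M"), "renal"] = 10.0
        res = cx.module_trait_correlation(ms, metadata12, traits=["renal"])
        assert np.isnan(res[0].pearson_r)
        assert not res[0].significant
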