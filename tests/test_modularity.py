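from itertools import combinations

import numpy as np
import pytest

from morphomod.hypotheses import ModulePartition, ParameterizationScheme, enumerate_schemes
from morphomod.modularity import (
    CRResult,
    LandmarkCorrelationMatrix,
    aicc,
    compare_cr,
    covariance_ratio,
    cr_permutation_test,
    emmli_fit,
    integration_report,
    landmark_correlations,
)
from morphomod.procrustes import AlignedShapes


def brute_force_cr(cov, idx1, idx2):
    """Independent oracle: CR for two landmark index sets by explicit block
    slicing of the 3P x 3P covariance."""
    cols1 = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in idx1])
    cols2 = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in idx2])
    s12 = cov[np.ix_(cols1, cols2)]
    s11 = cov[np.ix_(cols1, cols1)].copy()
    s22 = cov[np.ix_(cols2, cols2)].copy()
    np.fill_diagonal(s11, 0.0)
    np.fill_diagonal(s22, 0.0)
    return np.sqrt((s12 ** 2).sum() / np.sqrt((s11 ** 2).sum() * (s22 ** 2).sum()))


def make_aligned(dev, seed=0):
    """Wrap (S, P, 3) deviations as aligned shapes (centered per specimen)."""
    s, p, _ = dev.shape
    base = np.zeros((p, 3))
    base[:, 0] = np.linspace(-1, 1, p)
    base[:, 1] = np.linspace(-0.5, 0.5, p) ** 2
    coords = base[None] + dev
    coords = coords - coords.mean(axis=1, keepdims=True)
    return AlignedShapes(
        specimen_labels=[f"s{i}" for i in range(s)],
        landmark_labels=[f"L{j}" for j in range(p)],
        symmetric=coords,
        asymmetric=np.zeros_like(coords),
        mean_shape=coords.mean(axis=0),
        centroid_sizes=np.ones(s),
    )


def block_deviations(s, p, rho_w, rho_b, seed, scale=1e-2):
    """Deviations with two equal landmark blocks at the given correlations."""
    rho = np.full((p, p), rho_b)
    h = p // 2
    rho[:h, :h] = rho_w
    rho[h:, h:] = rho_w
    np.fill_diagonal(rho, 1.0)
    l = np.linalg.cholesky(rho)
    rng = np.random.default_rng(seed)
    dev = np.empty((s, p, 3))
    for axis in range(3):
        dev[:, :, axis] = rng.standard_normal((s, p)) @ l.T * scale
    return dev


def independent_block_deviations(s, p, seed, n_factors=2, noise=0.3, scale=1e-2):
    """Two strictly independent landmark blocks built from shared within-block
    factors whose landmark patterns are centered, so per-specimen centering
    leaves the block independence intact."""
    rng = np.random.default_rng(seed)
    h = p // 2
    dev = np.empty((s, p, 3))
    for lo, hi in ((0, h), (h, p)):
        block = np.zeros((s, hi - lo, 3))
        for _ in range(n_factors):
            pattern = rng.normal(size=(hi - lo, 3))
            pattern -= pattern.mean(axis=0)
            block += rng.standard_normal(s)[:, None, None] * pattern[None]
        eps = rng.normal(0, noise, size=(s, hi - lo, 3))
        eps -= eps.mean(axis=1, keepdims=True)
        dev[:, lo:hi, :] = (block + eps) * scale
    return dev


def two_block_partition(p):
    h = p // 2
    labels = [f"L{j}" for j in range(p)]
    return ModulePartition("blocks", "development",
                           {"A": labels[:h], "B": labels[h:]})


class TestCovarianceRatio:
    def test_zero_between_covariance_gives_zero(self):
        p = 6
        cov = np.zeros((3 * p, 3 * p))
        h = 3 * (p // 2)
        rng = np.random.default_rng(0)
        a = rng.normal(size=(h, h))
        b = rng.normal(size=(h, h))
        cov[:h, :h] = a @ a.T
        cov[h:, h:] = b @ b.T
        part = two_block_partition(p)
        assert covariance_ratio(cov, part, [f"L{j}" for j in range(p)]) == pytest.approx(0.0)

    def test_toy_covariance_matches_block_oracle(self):
        p = 4
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3 * p, 3 * p))
        cov = a @ a.T
        part = two_block_partition(p)
        got = covariance_ratio(cov, part, [f"L{j}" for j in range(p)])
        assert got == pytest.approx(brute_force_cr(cov, [0, 1], [2, 3]), abs=1e-12)

    def test_multi_module_cr_is_mean_of_pairwise(self):
        p = 6
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3 * p, 3 * p))
        cov = a @ a.T
        labels = [f"L{j}" for j in range(p)]
        part = ModulePartition("three", "development",
                               {"A": labels[:2], "B": labels[2:4], "C": labels[4:]})
        got = covariance_ratio(cov, part, labels)
        pairs = [([0, 1], [2, 3]), ([0, 1], [4, 5]), ([2, 3], [4, 5])]
        expected = np.mean([brute_force_cr(cov, i, j) for i, j in pairs])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_equicorrelated_data_give_cr_near_one(self):
        p = 10
        rho = np.full((3 * p, 3 * p), 0.4)
        np.fill_diagonal(rho, 1.0)
        l = np.linalg.cholesky(rho)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 3 * p)) @ l.T
        cov = np.cov(x, rowvar=False)
        part = two_block_partition(p)
        assert covariance_ratio(cov, part, [f"L{j}" for j in range(p)]) == pytest.approx(1.0, abs=0.05)


class TestCRPermutationTest:
    def test_strong_modularity_attains_floor_p(self):
        # enough landmarks that no random reassignment reproduces the blocks
        dev = independent_block_deviations(38, 20, seed=4, noise=0.01)
        shapes = make_aligned(dev)
        res = cr_permutation_test(shapes, two_block_partition(20), n_perm=999, seed=1)
        # the observed CR sits below every null draw, so p hits the floor
        assert res.cr < res.null_distribution[1:].min()
        assert res.p_value == pytest.approx(0.001)
        assert res.z_cr < 0

    def test_power_on_independent_blocks(self):
        hits = 0
        for rep in range(20):
            dev = independent_block_deviations(38, 12, seed=100 + rep)
            shapes = make_aligned(dev)
            res = cr_permutation_test(shapes, two_block_partition(12), n_perm=199, seed=rep)
            hits += res.p_value <= 0.05
        assert hits >= 16  # >= 80% of replicates significant

    def test_exchangeable_data_calibrated(self):
        ps, zs = [], []
        for rep in range(20):
            dev = block_deviations(20, 12, rho_w=0.3, rho_b=0.3, seed=200 + rep)
            shapes = make_aligned(dev)
            res = cr_permutation_test(shapes, two_block_partition(12), n_perm=199, seed=rep)
            ps.append(res.p_value)
            zs.append(res.z_cr)
        assert 0.25 <= np.mean(ps) <= 0.75
        assert sum(p <= 0.05 for p in ps) <= 4
        assert np.mean(np.abs(zs)) < 2.0

    def test_phylo_corrected_uses_evolutionary_covariance(self, study_sim):
        from morphomod.procrustes import symmetry_decompose

        shapes = symmetry_decompose(study_sim["dataset"], study_sim["template"].pairing)
        raw = cr_permutation_test(shapes, study_sim["generating"], n_perm=99, seed=0)
        cor = cr_permutation_test(shapes, study_sim["generating"], n_perm=99, seed=0,
                                  tree=study_sim["tree"])
        assert not raw.corrected and cor.corrected
        assert raw.cr != pytest.approx(cor.cr)


class TestCompareCR:
    def _result(self, name, z, corrected=False):
        return CRResult(hypothesis=name, cr=0.5, p_value=0.01, z_cr=z,
                        null_distribution=np.linspace(0.4, 1.2, 100),
                        corrected=corrected, n_perm=99, warnings=[])

    def test_identical_results_have_zero_difference(self):
        df = compare_cr([self._result("A", -3.0), self._result("B", -3.0)])
        assert df["z_diff"].abs().max() == 0.0
        assert (df["p_value"] == 1.0).all()

    def test_ranking_invariant_to_input_order(self):
        rs = [self._result(n, z) for n, z in [("A", -1.0), ("B", -5.0), ("C", -3.0)]]
        df1 = compare_cr(rs)
        df2 = compare_cr(rs[::-1])
        assert df1["hypothesis_1"].tolist() == df2["hypothesis_1"].tolist()
        assert df1["hypothesis_1"].iloc[0] == "B"  # most negative first

    def test_mixed_corrected_flags_rejected(self):
        with pytest.raises(ValueError, match="corrected"):
            compare_cr([self._result("A", -1.0), self._result("B", -2.0, corrected=True)])


class TestLandmarkCorrelations:
    def test_identical_displacements_give_one(self):
        rng = np.random.default_rng(5)
        common = rng.normal(size=(10, 1, 3))
        # landmarks 0 and 1 displace identically; centering subtracts the same
        # per-specimen offset from both, so their deviations stay identical
        dev = np.concatenate([common, common, rng.normal(size=(10, 2, 3))], axis=1)
        shapes = make_aligned(dev * 1e-2)
        corr = landmark_correlations(shapes)
        assert corr.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_displacements_give_zero(self):
        s = 8
        dev = np.zeros((s, 4, 3))
        t = np.arange(s, dtype=float)
        pat1 = np.cos(2 * np.pi * t / s)
        pat2 = np.sin(2 * np.pi * t / s)
        dev[:, 0, 0] = pat1
        dev[:, 1, 1] = pat2
        # landmarks 2, 3 absorb the centering so 0 and 1 keep their patterns
        dev[:, 2, 0] = -pat1
        dev[:, 3, 1] = -pat2
        shapes = AlignedShapes(
            specimen_labels=[f"s{i}" for i in range(s)],
            landmark_labels=["L0", "L1", "L2", "L3"],
            symmetric=dev - dev.mean(axis=1, keepdims=True),
            asymmetric=np.zeros_like(dev),
            mean_shape=dev.mean(axis=0),
            centroid_sizes=np.ones(s),
        )
        corr = landmark_correlations(shapes)
        assert corr.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_congruence_oracle(self):
        rng = np.random.default_rng(6)
        dev = rng.normal(size=(5, 3, 3)) * 1e-2
        shapes = make_aligned(dev)
        corr = landmark_correlations(shapes).matrix
        centered = shapes.symmetric - shapes.symmetric.mean(axis=0, keepdims=True)
        for l, m in combinations(range(3), 2):
            num = sum(centered[s, l] @ centered[s, m] for s in range(5))
            den = np.sqrt(sum(centered[s, l] @ centered[s, l] for s in range(5))) * \
                np.sqrt(sum(centered[s, m] @ centered[s, m] for s in range(5)))
            assert corr[l, m] == pytest.approx(abs(num) / den, abs=1e-12)

    def test_zero_deviation_landmark_named_in_error(self):
        # per-specimen landmark means are zero by construction, so the frozen
        # landmark "Lfix" keeps exactly zero deviation across specimens
        rng = np.random.default_rng(7)
        dev = np.zeros((6, 4, 3))
        dev[:, 0, :] = rng.normal(size=(6, 3))
        dev[:, 1, :] = rng.normal(size=(6, 3))
        dev[:, 3, :] = -(dev[:, 0, :] + dev[:, 1, :])
        shapes = AlignedShapes(
            specimen_labels=[f"s{i}" for i in range(6)],
            landmark_labels=["L0", "L1", "Lfix", "L3"],
            symmetric=dev,
            asymmetric=np.zeros_like(dev),
            mean_shape=dev.mean(axis=0),
            centroid_sizes=np.ones(6),
        )
        with pytest.raises(ValueError, match="Lfix"):
            landmark_correlations(shapes)

    def test_corrected_uses_contrasts(self, study_sim):
        from morphomod.procrustes import symmetry_decompose

        shapes = symmetry_decompose(study_sim["dataset"], study_sim["template"].pairing)
        corr = landmark_correlations(shapes, tree=study_sim["tree"])
        assert corr.corrected
        assert corr.n_rows_used == shapes.n_specimens - 1


class TestEmmli:
    def test_aicc_reproduces_printed_best_model_row(self):
        assert aicc(1128.777, 11, 1326) == pytest.approx(-2235.353, abs=5e-4)

    def test_aicc_reproduces_printed_null_row(self):
        assert aicc(778.313, 2, 1326) == pytest.approx(-1552.617, abs=5e-4)

    def test_nested_schemes_have_monotone_likelihood(self, ledger, template, study_sim):
        from morphomod.procrustes import symmetry_decompose

        shapes = symmetry_decompose(study_sim["dataset"], study_sim["template"].pairing)
        corr = landmark_correlations(shapes)
        schemes = enumerate_schemes(study_sim["ledger"], study_sim["dataset"].landmark_labels)
        fits = {f.scheme_id: f for f in emmli_fit(corr, schemes)}
        for hyp in ("H2", "H2*", "H5", "H5*", "H6", "H6*"):
            a, b = fits[f"{hyp}-a"].max_l, fits[f"{hyp}-b"].max_l
            c, d = fits[f"{hyp}-c"].max_l, fits[f"{hyp}-d"].max_l
            assert d >= b - 1e-9 >= a - 1e-9
            assert d >= c - 1e-9 >= a - 1e-9

    def test_weights_sum_to_one(self, study_sim):
        from morphomod.procrustes import symmetry_decompose

        shapes = symmetry_decompose(study_sim["dataset"], study_sim["template"].pairing)
        corr = landmark_correlations(shapes)
        schemes = enumerate_schemes(study_sim["ledger"], study_sim["dataset"].landmark_labels)
        fits = emmli_fit(corr, schemes)
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-9)
        assert min(f.delta_aicc for f in fits) == 0.0

    def test_k_counts_rho_sets_plus_one(self, study_sim):
        schemes = enumerate_schemes(study_sim["ledger"], study_sim["dataset"].landmark_labels)
        for s in schemes:
            assert s.k == len(s.rho_sets) + 1


class TestIntegrationReport:
    def _fit_on_block_correlations(self, rho_w, rho_b, n_eff, seed):
        """Recover rho from congruence correlations of block-correlated
        landmark displacement samples (estimator-level recovery)."""
        p = 16
        labels = [f"L{j}" for j in range(p)]
        part = ModulePartition("gen", "development", {
            "A": labels[:4], "B": labels[4:8], "C": labels[8:12], "D": labels[12:],
        })
        rho = np.full((p, p), rho_b)
        assign = part.assignment(labels)
        for i in range(p):
            for j in range(p):
                if assign[i] == assign[j]:
                    rho[i, j] = rho_w
            rho[i, i] = 1.0
        l = np.linalg.cholesky(rho)
        rng = np.random.default_rng(seed)
        dev = np.stack([rng.standard_normal((n_eff, p)) @ l.T for _ in range(3)], axis=2)
        g = np.einsum("slk,smk->lm", dev, dev)
        r = np.abs(g) / np.sqrt(np.outer(np.diag(g), np.diag(g)))
        np.fill_diagonal(r, 1.0)
        corr = LandmarkCorrelationMatrix(np.clip(r, 0, 1), labels, n_eff, False)
        schemes = enumerate_schemes([part], labels, include_null=False)
        d = next(s for s in schemes if s.scheme == "d")
        return emmli_fit(corr, [d])[0]

    def test_rho_recovery_within_bands(self):
        fit = self._fit_on_block_correlations(0.5, 0.15, n_eff=200, seed=8)
        report = integration_report(fit)
        within = report.loc[report["type"] == "within", "rho"]
        between = report.loc[report["type"] == "between", "rho"]
        assert len(within) == 4 and len(between) == 6
        assert ((within >= 0.4) & (within <= 0.6)).all()
        assert ((between >= 0.05) & (between <= 0.25)).all()

    def test_within_exceeds_between_in_most_replicates(self):
        ok = 0
        for rep in range(20):
            fit = self._fit_on_block_correlations(0.5, 0.15, n_eff=38, seed=300 + rep)
            report = integration_report(fit)
            w_min = report.loc[report["type"] == "within", "rho"].min()
            b_max = report.loc[report["type"] == "between", "rho"].max()
            ok += w_min >= b_max
        assert ok >= 11  # majority of replicates

    def test_corrected_column_present_when_given(self):
        fit = self._fit_on_block_correlations(0.5, 0.15, n_eff=200, seed=9)
        fit2 = self._fit_on_block_correlations(0.5, 0.15, n_eff=200, seed=10)
        report = integration_report(fit, fit2)
        assert "rho_corrected" in report.columns
        assert report["rho_corrected"].notna().all()
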