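import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import recipcross as rc
from recipcross import ValidationError
from recipcross.diffexpr import estimate_dispersion, fit_nb_glm


def brute_force_median_of_ratios(mat):
    """Independent oracle: literal median-of-ratios with per-gene loops."""
    mat = np.asarray(mat, dtype=float)
    keep = [g for g in range(mat.shape[0]) if (mat[g] > 0).all()]
    gm = [np.prod(mat[g]) ** (1.0 / mat.shape[1]) for g in keep]
    s = np.array(
        [np.median([mat[g, j] / gm[i] for i, g in enumerate(keep)])
         for j in range(mat.shape[1])]
    )
    return s / np.prod(s) ** (1.0 / len(s))


def brute_force_bh(p):
    """Literal BH step-up: find the largest k with p_(k) <= k q / m by
    scanning, then report step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_from_top in range(m):
        i = m - 1 - rank_from_top
        val = p[order[i]] * m / (i + 1)
        if rank_from_top == 0:
            adj[order[i]] = min(val, 1.0)
        else:
            adj[order[i]] = min(val, adj[order[i + 1]], 1.0)
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = np.tile([[10], [20], [5]], (1, 4))
        np.testing.assert_allclose(rc.size_factors(mat), np.ones(4))

    def test_doubled_column_scales_factor(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, size=100) + 1
        mat = np.tile(col[:, None], (1, 4))
        mat[:, 0] *= 2
        s = rc.size_factors(mat)
        np.testing.assert_allclose(s[0] / s[1], 2.0, rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(30, size=(50, 6)) + 1
        np.testing.assert_allclose(
            rc.size_factors(mat), brute_force_median_of_ratios(mat), rtol=1e-10
        )

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError, match="nonzero"):
            rc.size_factors(np.zeros((5, 3), dtype=int))


class TestDispersion:
    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(3)
        mat = rng.poisson(200, size=(200, 120))
        alpha = estimate_dispersion(mat, np.ones(120))
        assert np.median(alpha) < 0.01

    def test_constant_gene_hits_floor(self):
        mat = np.full((1, 10), 7)
        alpha = estimate_dispersion(mat, np.ones(10))
        assert alpha[0] == pytest.approx(1e-8)

    def test_nb_gene_recovered(self):
        rng = np.random.default_rng(4)
        mu, a = 100.0, 0.5
        mat = rng.negative_binomial(1 / a, 1 / (1 + a * mu), size=(300, 120))
        alpha = estimate_dispersion(mat, np.ones(120))
        assert 0.3 < np.median(alpha) < 0.8


class TestNBGLM:
    def test_matches_poisson_glm_oracle_in_limit(self, design15):
        """With dispersion ~0 and large counts, the NB Wald test must
        agree with an independent Poisson GLM fit (statsmodels)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        meta = design15[design15.cross.isin(["HH", "NN"])].reset_index(drop=True)
        n = len(meta)
        group = (meta.cross == "HH").to_numpy(dtype=float)
        mu = 500.0 * np.exp(0.15 * group)
        counts = rc.CountMatrix(
            [f"g{i}" for i in range(20)],
            meta.sample_id.tolist(),
            rng.poisson(mu, size=(20, n)),
        )
        meta = meta.copy()
        meta["group"] = pd.Categorical(
            np.where(group == 1, "A", "B"), categories=["B", "A"]
        )
        table = fit_nb_glm(
            counts, meta, (), "group",
            factors=np.ones(n), alpha=np.full(20, 1e-10),
        )
        x = sm.add_constant(group)
        # the pipeline reports df-corrected SEs; undo the documented
        # sqrt(n/(n-p)) factor to compare raw information-matrix SEs
        from scipy import stats
        correction = np.sqrt(n / (n - 2))
        for i in range(20):
            fit = sm.GLM(counts.counts[i], x, family=sm.families.Poisson()).fit()
            z_raw = table.wald_stat.iloc[i] * correction
            p_raw = 2 * stats.norm.sf(abs(z_raw))
            assert p_raw == pytest.approx(fit.pvalues[1], abs=1e-6)
            assert table.log2_fold_change.iloc[i] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-6
            )

    def test_planted_effect_recovered(self, design15, planted_data):
        counts, truth = planted_data
        res = rc.run_de(counts, design15, "HH", "NN")
        anc = truth[truth.gene_class == "ancestry"].set_index("gene_id")
        est = res.table.loc[anc.index]
        cover = (
            (est.log2_fold_change - anc.log2_effect).abs() < 3 * est.lfc_se
        ).mean()
        assert cover > 0.9
        sign_ok = (np.sign(est.log2_fold_change) == np.sign(anc.log2_effect)).mean()
        assert sign_ok > 0.95

    def test_all_zero_gene_flagged_not_tested(self, design15):
        rng = np.random.default_rng(6)
        counts = rc.CountMatrix(
            ["dead", "alive"],
            design15.sample_id.tolist(),
            np.vstack([np.zeros(120, dtype=int), rng.poisson(50, 120)]),
        )
        res = rc.run_de(counts, design15, "HH", "NN", design_terms=())
        assert np.isnan(res.table.loc["dead", "p_value"])
        assert not res.table.loc["dead", "converged"]
        assert np.isfinite(res.table.loc["alive", "p_value"])

    def test_rank_deficient_design_rejected(self, design15):
        meta = design15.copy()
        meta["dup"] = meta["sex"]
        with pytest.raises(ValidationError, match="rank deficient"):
            rc.build_design(meta, ("sex", "dup"))


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            rc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(rc.bh_adjust([0.4]), [0.4])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(rc.bh_adjust(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(500)
        np.testing.assert_allclose(
            rc.bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rc.bh_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_properties(self, p):
        adj = rc.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        adj = rc.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.02])


class TestRunDE:
    def test_group_contracts(self, design15, null_data):
        counts, _ = null_data
        with pytest.raises(ValidationError, match="disjoint"):
            rc.run_de(counts, design15, "HH", "HH")
        with pytest.raises(ValidationError, match="at least 2"):
            rc.run_de(counts, design15, design15.sample_id[:1].tolist(), "NN")

    def test_power_monotone_in_effect_size(self, design15):
        """Detection power must not decrease as the planted effect grows."""
        powers = []
        for eff in (0.5, 1.0, 2.0):
            cfg = rc.SimulationConfig(
                seed=31, n_genes=300, n_ancestry_genes=60,
                ancestry_effect=eff, ancestry_effect_sd=0.0,
                n_maternal_genes=0, n_paternal_genes=0,
            )
            counts, truth = rc.simulate_counts(
                cfg, design15, np.random.default_rng(31)
            )
            res = rc.run_de(counts, design15, "HH", "NN")
            anc = (truth.gene_class == "ancestry").values
            powers.append((res.table.p_adj.values[anc] < 0.05).mean())
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.9


class TestSiblingCorrelation:
    def test_no_family_effect_gives_near_zero(self, design15, null_data):
        counts, _ = null_data
        assert abs(rc.sibling_correlation(counts, design15)) < 0.05

    def test_duplicated_columns_give_near_one(self, design15):
        rng = np.random.default_rng(9)
        half = rng.poisson(40, size=(300, 60))
        meta = design15.sort_values(["family_code", "sex"]).reset_index(drop=True)
        # make the two sibs of every family identical copies
        counts = np.empty((300, 120), dtype=int)
        counts[:, 0::2] = half
        counts[:, 1::2] = half
        cm = rc.CountMatrix(
            [f"g{i}" for i in range(300)], meta.sample_id.tolist(), counts
        )
        assert rc.sibling_correlation(cm, meta) > 0.95

    def test_too_few_families_rejected(self, design15):
        tiny = design15[design15.family_code.isin(["1A", "1B"])].reset_index(drop=True)
        cm = rc.CountMatrix(
            ["g1"], tiny.sample_id.tolist(), np.ones((1, len(tiny)), dtype=int)
        )
        with pytest.raises(ValidationError, match="famil"):
            rc.sibling_correlation(cm, tiny)
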