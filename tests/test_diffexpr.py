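"""Differential expression: contrast enumeration, NB-GLM engine, FDR,
consensus rule."""

import numpy as np
import pandas as pd
import pytest

from venomgland import diffexpr as de
from venomgland.metadata import sidewinder_factor_table


def nb_counts(rng, mu, alpha, size):
    """NB draws parameterized by mean and dispersion."""
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size=size)


def custom_table(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "sex": ["M"] * n,
        "svl_cm": np.linspace(30, 50, n),
        "subspecies": ["x"] * n,
        "mtdna_lineage": ["x"] * n,
        "nontoxin_lineage": ["x"] * n,
    }
    base.update(cols)
    return pd.DataFrame(base, index=[f"I{i}" for i in range(n)])


class TestEnumerateContrasts:
    def test_published_metadata_yields_seventeen(self):
        contrasts = de.enumerate_contrasts(sidewinder_factor_table())
        assert len(contrasts) == 17
        kinds = pd.Series([c.kind for c in contrasts]).value_counts()
        assert kinds["continuous"] == 1 and kinds["pairwise"] == 16
        by_factor = pd.Series([c.factor for c in contrasts]).value_counts()
        assert by_factor["sex"] == 1
        assert by_factor["subspecies"] == 3
        assert by_factor["mtdna_lineage"] == 6
        assert by_factor["nontoxin_lineage"] == 6

    def test_single_two_level_factor_gives_one_pairwise(self):
        with pytest.warns(UserWarning):
            contrasts = de.enumerate_contrasts(
                custom_table(sex=["M", "M", "F", "F"])
            )
        pairwise = [c for c in contrasts if c.kind == "pairwise"]
        assert len(pairwise) == 1

    def test_four_level_factor_gives_six_pairs(self):
        with pytest.warns(UserWarning):
            contrasts = de.enumerate_contrasts(
                custom_table(mtdna_lineage=list("aabbccdd"))
            )
        pairwise = [c for c in contrasts if c.kind == "pairwise"]
        assert len(pairwise) == 6  # C(4, 2)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            de.enumerate_contrasts(sidewinder_factor_table().iloc[:0])


class TestEngine:
    def test_equal_counts_give_zero_lfc(self):
        table = custom_table(sex=["M"] * 4 + ["F"] * 4)
        counts = pd.DataFrame({"g1": [50] * 8}, index=table.index).T
        res = de.run_de(counts, table,
                        [de.Contrast("sex", "pairwise", "F", "M")])
        assert res.log2fc.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res.p_wald.iloc[0] > 0.9

    def test_dispersion_shrinks_toward_zero_for_poisson_data(self):
        rng = np.random.default_rng(80)
        for n, bound in ((8, 0.2), (60, 0.02)):
            counts = pd.DataFrame(
                rng.poisson(100, size=(300, n)),
                columns=[f"I{i}" for i in range(n)],
            )
            sf = de.size_factors(counts)
            disp = de.estimate_dispersions(counts, sf)
            assert np.median(disp) < bound

    def test_fit_matches_brute_force_likelihood_grid(self):
        # 2-group, 4-sample toy: the GLM optimum must dominate a coarse
        # grid over (intercept, effect) at fixed dispersion
        from scipy.special import gammaln

        y = np.array([12.0, 18.0, 40.0, 55.0])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        alpha = 0.1

        def nb_loglik(b0, b1):
            mu = np.exp(b0 + b1 * X[:, 1])
            r = 1.0 / alpha
            p = r / (r + mu)
            return float(
                np.sum(
                    gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                    + r * np.log(p) + y * np.log1p(-p)
                )
            )

        fit = de.fit_nb_glm(y, X, alpha)
        ll_fit = nb_loglik(fit.params[0], fit.params[1])
        grid_best = max(
            nb_loglik(b0, b1)
            for b0 in np.arange(1.5, 4.0, 0.02)
            for b1 in np.arange(-1.0, 2.5, 0.02)
        )
        assert ll_fit >= grid_best - 1e-3

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(81)
        table = custom_table(sex=["M"] * 4 + ["F"] * 4)
        mu = np.exp(rng.normal(np.log(100), 1.0, 300))
        counts = pd.DataFrame(
            nb_counts(rng, mu[:, None], 0.1, (300, 8)),
            index=[f"g{i}" for i in range(300)], columns=table.index,
        )
        res = de.run_de(counts, table,
                        [de.Contrast("sex", "pairwise", "F", "M")])
        assert 0.015 <= (res.p_wald <= 0.05).mean() <= 0.09
        assert 0.015 <= (res.p_lrt <= 0.05).mean() <= 0.09

    def test_label_permutation_destroys_planted_detection(self):
        rng = np.random.default_rng(82)
        table = custom_table(mtdna_lineage=list("aaaabbbb"))
        eff = np.array([1.0] * 4 + [4.0] * 4)
        planted = nb_counts(rng, 200.0 * eff[None, :], 0.05, (10, 8))
        null = nb_counts(rng, np.full((90, 8), 200.0), 0.05, (90, 8))
        counts = pd.DataFrame(
            np.vstack([planted, null]),
            index=[f"g{i}" for i in range(100)], columns=table.index,
        )
        contrast = [de.Contrast("mtdna_lineage", "pairwise", "a", "b")]
        res = de.run_de(counts, table, contrast)
        planted_q = res[res.transcript_id.isin([f"g{i}" for i in range(10)])]
        assert planted_q.consensus_significant.all()
        # permute individuals: effect should vanish
        qs = []
        for rep in range(3):
            perm = rng.permutation(8)
            shuffled = table.copy()
            shuffled["mtdna_lineage"] = np.asarray(
                table["mtdna_lineage"], dtype=object
            )[perm]
            res_p = de.run_de(counts, shuffled, contrast)
            qs.append(
                res_p[res_p.transcript_id.isin([f"g{i}" for i in range(10)])]
                .q_wald.median()
            )
        assert np.median(qs) > 0.05

    def test_lfc_sign_matches_planted_direction(self):
        rng = np.random.default_rng(83)
        table = custom_table(sex=["M"] * 4 + ["F"] * 4)
        up = nb_counts(rng, np.array([100.0] * 4 + [400.0] * 4)[None, :],
                       0.05, (5, 8))
        null = nb_counts(rng, np.full((45, 8), 150.0), 0.05, (45, 8))
        counts = pd.DataFrame(np.vstack([up, null]),
                              index=[f"g{i}" for i in range(50)],
                              columns=table.index)
        res = de.run_de(counts, table,
                        [de.Contrast("sex", "pairwise", "F", "M")])
        planted = res[res.transcript_id.isin([f"g{i}" for i in range(5)])]
        # level_b == M is the indicator: M lower than F -> negative lfc
        assert (planted.log2fc < 0).all()


class TestFdr:
    def test_bh_arithmetic(self):
        q = de.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.adjust_fdr([0.42])[0] == pytest.approx(0.42)

    def test_q_at_least_p_and_nan_passthrough(self):
        p = np.array([0.001, 0.5, np.nan, 0.2])
        q = de.adjust_fdr(p)
        ok = ~np.isnan(p)
        assert (q[ok] >= p[ok] - 1e-12).all()
        assert np.isnan(q[2])


class TestConsensusRule:
    def test_wald_only_significance_is_not_consensus(self):
        res = pd.DataFrame({
            "transcript_id": ["t1"], "contrast": ["c"],
            "log2fc": [2.0], "p_wald": [1e-5], "p_lrt": [0.5],
            "q_wald": [1e-4], "q_lrt": [0.6],
        })
        res["consensus_significant"] = (res.q_wald <= 0.05) & (res.q_lrt <= 0.05)
        assert not res.consensus_significant.iloc[0]

    def test_comparison_bookkeeping(self):
        rows = [
            {"transcript_id": f"t{i}", "contrast": f"c{j}",
             "log2fc": 0.0, "p_wald": 1.0, "p_lrt": 1.0,
             "q_wald": 1.0, "q_lrt": 1.0, "consensus_significant": False}
            for i in range(62) for j in range(17)
        ]
        s = de.consensus_summary(pd.DataFrame(rows))
        assert s["n_comparisons"] == 1054
        assert s["n_transcripts"] == 62 and s["n_contrasts"] == 17
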