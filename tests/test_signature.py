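"""Gene ranking, Bonferroni filtering, signature selection, pairwise correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import raddose as rd
from raddose.signature import spearman_dose_correlations


def _expr(signal: np.ndarray, dose, genes=None, time=None) -> rd.ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(signal.shape[0])]
    samples = [f"s{i}" for i in range(signal.shape[1])]
    meta = pd.DataFrame(
        {
            "dose_gy": dose,
            "time_days": time if time is not None else np.ones(len(samples)),
            "study": "toy",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    mat = pd.DataFrame(signal, index=pd.Index(genes, name="gene_id"), columns=samples)
    return rd.ExpressionMatrix(signal=mat, metadata=meta)


def brute_force_spearman(x, y) -> float:
    """Closed form 1 - 6*sum(d^2)/(n(n^2-1)) on hand-computed ranks (no ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d2 = float(np.sum((rx - ry) ** 2))
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


class TestRanking:
    def test_perfect_monotone_gene(self):
        expr = _expr(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]), dose=[0, 1, 2, 3, 4])
        out = rd.rank_genes_by_dose_correlation(expr)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "direction"] == "up"

    def test_matches_closed_form_rank_formula(self):
        signal = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        dose = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expected = brute_force_spearman(signal, dose)  # = 0.5 by hand ranking
        assert expected == pytest.approx(0.5)
        out = rd.rank_genes_by_dose_correlation(_expr(signal[None, :], dose))
        assert out.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_small_n_pvalue_is_exact_permutation(self):
        """For n < 10 the two-sided p equals the enumerated permutation null."""
        signal = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        dose = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        out = spearman_dose_correlations(signal[:, None], dose, ["g"])
        rho_obs = out.loc[0, "rho"]
        count = 0
        perms = list(itertools.permutations(signal))
        for perm in perms:
            if abs(brute_force_spearman(np.array(perm), dose)) >= abs(rho_obs) - 1e-12:
                count += 1
        assert out.loc[0, "p_value"] == pytest.approx(count / len(perms), abs=1e-12)

    def test_constant_gene_flagged_and_excluded(self):
        signal = np.vstack([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7]]).astype(float)
        out = rd.rank_genes_by_dose_correlation(_expr(signal, [0, 1, 2, 3, 4]))
        const = out[out["gene_id"] == "g1"].iloc[0]
        assert const["constant"]
        assert np.isnan(const["rho"])
        # Bonferroni multiplier counts only tested (non-constant) genes
        tested = out[~out["constant"]]
        assert np.allclose(
            tested["p_bonferroni"], np.minimum(1.0, tested["p_value"] * 1)
        )

    def test_requires_three_dose_levels(self):
        with pytest.raises(rd.ValidationError):
            rd.rank_genes_by_dose_correlation(
                _expr(np.random.default_rng(0).normal(size=(3, 6)), [0, 0, 0, 1, 1, 1])
            )

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 2 * v + 7])
    def test_invariant_under_increasing_transforms(self, transform):
        rng = np.random.default_rng(1)
        signal = rng.normal(size=(4, 20))
        dose = rng.permutation(np.repeat([0.0, 1.0, 2.0, 4.0], 5))
        base = spearman_dose_correlations(signal.T, dose, list("abcd"))
        warped = spearman_dose_correlations(transform(signal).T, dose, list("abcd"))
        pd.testing.assert_series_equal(base["rho"], warped["rho"], atol=1e-12)

    def test_simulated_up_genes_outrank_background(self):
        cfg = rd.ArraySimConfig(noise_sd=0.05, n_background_genes=100, seed=8,
                                samples_per_condition=3)
        out = rd.rank_genes_by_dose_correlation(rd.generate_array_study(cfg))
        top = out.head(cfg.n_up_genes)["gene_id"]
        assert all(g.startswith("UP") for g in top)


class TestBonferroniFilter:
    def test_threshold_arithmetic(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "rho": [0.5, 0.4],
                "p_value": [0.0004, 0.001],
                "p_bonferroni": [0.04, 0.1],  # 100 genes tested
                "direction": ["up", "up"],
                "constant": [False, False],
            }
        )
        kept = rd.bonferroni_filter(df, alpha=0.05)
        assert kept["gene_id"].tolist() == ["a"]

    def test_empty_survivor_set_is_valid(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "rho": [0.1], "p_value": [0.9],
             "p_bonferroni": [1.0], "direction": ["up"], "constant": [False]}
        )
        assert rd.bonferroni_filter(df).empty

    def test_null_background_false_positive_rate(self):
        """Background genes have no dose term; the expected number of
        Bonferroni survivors among them is <= alpha per dataset."""
        total_fp = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = rd.ArraySimConfig(seed=seed, n_background_genes=300,
                                    samples_per_condition=2, times=(1.0,))
            out = rd.rank_genes_by_dose_correlation(rd.generate_array_study(cfg))
            kept = rd.bonferroni_filter(out)
            total_fp += int(kept["gene_id"].str.startswith("BG").sum())
        # E[FP] <= 0.05/dataset -> P(total > 5 over 15 datasets) is negligible
        assert total_fp <= 5


class TestSelectSignature:
    def _corr(self, genes, rhos, ps):
        return pd.DataFrame(
            {"gene_id": genes, "rho": rhos, "p_value": ps,
             "p_bonferroni": ps, "direction": ["up" if r > 0 else "down" for r in rhos],
             "constant": False}
        )

    def test_three_gene_toy(self):
        sig = rd.select_signature(
            self._corr(["a", "b", "c"], [0.9, -0.9, 0.1], [0.01] * 3), n_up=1, n_down=1
        )
        assert sig.up_genes == ["a"] and sig.down_genes == ["b"]

    def test_tie_break_by_p_then_gene_id(self):
        df = self._corr(["b", "a", "c", "d"], [0.8, 0.8, 0.8, -0.5],
                        [0.02, 0.01, 0.01, 0.01])
        sig = rd.select_signature(df, n_up=2, n_down=1)
        # rho tied: smaller p first (a, c), then lexicographic among equal p
        assert sig.up_genes == ["a", "c"]
        # exhaustive oracle over the same ordering rule
        rows = sorted(df[df.rho > 0].itertuples(),
                      key=lambda r: (-r.rho, r.p_value, r.gene_id))
        assert sig.up_genes == [r.gene_id for r in rows[:2]]

    def test_insufficient_survivors_names_shortfall(self):
        with pytest.raises(rd.ValidationError, match="insufficient"):
            rd.select_signature(self._corr(["a"], [0.9], [0.001]), n_up=1, n_down=1)


class TestPairwiseMatrix:
    def test_identity_negation_and_symmetry(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        signal = np.vstack([base, base, -base, np.random.default_rng(0).normal(size=5)])
        expr = _expr(signal, [0, 1, 2, 3, 4])
        m = rd.pairwise_correlation_matrix(expr, ["g0", "g1", "g2", "g3"])
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)
        assert m.loc["g0", "g1"] == pytest.approx(1.0)
        assert m.loc["g0", "g2"] == pytest.approx(-1.0)
        assert m.to_numpy()[np.isfinite(m.to_numpy())].max() <= 1.0 + 1e-12

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(2)
        signal = rng.normal(size=(4, 12))
        expr = _expr(signal, rng.integers(0, 5, 12).astype(float))
        genes = ["g0", "g1", "g2", "g3"]
        m = rd.pairwise_correlation_matrix(expr, genes)
        for i, j in itertools.combinations(range(4), 2):
            rho, _ = stats.spearmanr(signal[i], signal[j])
            assert m.iloc[i, j] == pytest.approx(rho, abs=1e-12)

    def test_constant_gene_flagged_nan(self):
        signal = np.vstack([[1, 2, 3, 4], [5, 5, 5, 5.0]])
        m = rd.pairwise_correlation_matrix(
            _expr(signal, [0, 1, 2, 3]), ["g0", "g1"]
        )
        assert np.isnan(m.loc["g0", "g1"])
        assert m.loc["g1", "g1"] == 1.0

    def test_requires_two_genes(self):
        with pytest.raises(rd.ValidationError):
            rd.pairwise_correlation_matrix(
                _expr(np.ones((2, 4)), [0, 1, 2, 3]), ["g0"]
            )


class TestSelectorEstimator:
    def test_fit_transform_matches_functional_path(self, noisy_array):
        X = noisy_array.signal.T  # samples x genes DataFrame
        sel = rd.SpearmanSignatureSelector(n_up=20, n_down=10).fit(X, noisy_array.dose)
        assert set(sel.signature_.up_genes) == set(f"UP{i:03d}" for i in range(1, 21))
        n_est = sel.transform(X)[:, 0]
        ns = rd.net_signal_array(noisy_array, sel.signature_)
        np.testing.assert_allclose(n_est, ns.values)

    def test_sklearn_params_round_trip(self):
        sel = rd.SpearmanSignatureSelector(n_up=5)
        assert sel.get_params()["n_up"] == 5
        sel.set_params(n_down=3)
        assert sel.n_down == 3
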