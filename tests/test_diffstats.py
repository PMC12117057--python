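"""GLM oracles, BH correction, Spearman screen, Fisher co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddabpp.diffstats import (
    GlmSpec,
    adjust_bh,
    fisher_cooccurrence,
    fit_glm,
    fit_glm_many,
    spearman_screen,
)
from ddabpp.io import CohortDesign
from ddabpp.simulate import simulate_mutation_table
from tests.conftest import make_design


def two_group_design(n_per_group: int = 6) -> CohortDesign:
    """Two conditions only (T_long vs N_long)."""
    rows = []
    for i in range(n_per_group):
        pat = f"P{i + 1:02d}"
        for tissue in ("T", "N"):
            rows.append({"sample_id": f"{pat}_{tissue}", "patient_id": pat,
                         "tissue": tissue, "survival": "long",
                         "age": 60 + i, "sex": i % 2, "smoking": i % 2})
    return CohortDesign(pd.DataFrame(rows))


class TestGlm:
    def test_gaussian_reproduces_two_sample_t(self):
        d = two_group_design(8)
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(0, 1, 16), index=d.samples)
        res = fit_glm(y, d, GlmSpec("gaussian"))
        cond = d.data.set_index("sample_id")["condition"]
        a = y[cond[y.index] == "N_long"]
        b = y[cond[y.index] == "T_long"]
        t, p = stats.ttest_ind(a, b)
        assert res["statistic"].iloc[0] == pytest.approx(t, rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p, rel=1e-10)
        assert res["estimate"].iloc[0] == pytest.approx(a.mean() - b.mean())

    def test_identical_groups_null_result(self):
        d = two_group_design(4)
        cond = d.data.set_index("sample_id")["condition"]
        y = pd.Series(index=d.samples, dtype=float)
        for c in ("T_long", "N_long"):  # identical response in both groups
            y[cond[y.index] == c] = [1.0, 2.0, 3.0, 4.0]
        res = fit_glm(y, d, GlmSpec("gaussian"))
        assert res["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] > 0.99

    def test_collinear_covariate_raises(self):
        d = two_group_design(4)
        df = d.data.copy()
        df["sex"] = (df["condition"] == "T_long").astype(int)  # == group
        d2 = CohortDesign(df.drop(columns=["condition"]))
        y = pd.Series(np.arange(8.0), index=d2.samples)
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_glm(y, d2, GlmSpec("gaussian", covariates=("sex",)))

    def test_quasibinomial_power_on_planted_activity(self):
        """alpha 0.6 vs 0.1 (sd 0.05, n=6/6) is detected in >=90% of seeds."""
        d = two_group_design(6)
        cond = d.data.set_index("sample_id")["condition"]
        spec = GlmSpec("quasibinomial_probit")
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = pd.Series(index=d.samples, dtype=float)
            y[cond[y.index] == "T_long"] = np.clip(rng.normal(0.6, 0.05, 6), 0, 1)
            y[cond[y.index] == "N_long"] = np.clip(rng.normal(0.1, 0.05, 6), 0, 1)
            res = fit_glm(y, d, spec)
            hits += res["p"].iloc[0] < 0.05
        assert hits / n_seeds >= 0.90

    def test_quasibinomial_fitted_means_match_groups(self):
        d = two_group_design(5)
        cond = d.data.set_index("sample_id")["condition"]
        y = pd.Series(np.where(cond[d.samples] == "T_long", 0.8, 0.3),
                      index=d.samples)
        res = fit_glm(y, d, GlmSpec("quasibinomial_probit"))
        # estimate on probit scale: qnorm(0.3) - qnorm(0.8)
        expected = stats.norm.ppf(0.3) - stats.norm.ppf(0.8)
        assert res["estimate"].iloc[0] == pytest.approx(expected, abs=1e-4)

    def test_degenerate_all_zero_raddi_flagged(self):
        d = two_group_design(4)
        y = pd.Series(0.0, index=d.samples)
        res = fit_glm(y, d, GlmSpec("quasibinomial_probit"))
        assert res["degenerate"].iloc[0]
        assert np.isnan(res["p"].iloc[0])

    def test_poisson_rejects_non_integer(self):
        d = two_group_design(4)
        y = pd.Series(np.linspace(0.1, 1.0, 8), index=d.samples)
        with pytest.raises(ValueError, match="integer"):
            fit_glm(y, d, GlmSpec("poisson"))

    def test_multi_contrast_adjustment_present(self, design24):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=24), index=design24.samples)
        res = fit_glm(y, design24, GlmSpec("gaussian", seed=1))
        assert len(res) == 6  # all pairs of 4 conditions
        assert (res["p_adj_contrasts"].dropna()
                >= res["p"].dropna() - 1e-12).all()

    def test_many_features_bh_within_contrast(self, design24):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(5, 24)),
                           index=[f"F{i}" for i in range(5)],
                           columns=design24.samples)
        out = fit_glm_many(mat, design24, GlmSpec("gaussian"))
        assert {"feature_id", "q"} <= set(out.columns)
        assert (out["q"].dropna() >= out["p"].dropna() - 1e-12).all()


class TestBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert adjust_bh([0.04]) == pytest.approx([0.04])

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_missing_propagates(self):
        q = adjust_bh([0.01, np.nan, 0.03])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_oracle = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):  # classic step-up, from the top
            i = order[rank_from_top - 1]
            prev = min(prev, p[i] * m / rank_from_top)
            q_oracle[i] = prev
        assert adjust_bh(p) == pytest.approx(q_oracle, abs=1e-12)


class TestSpearman:
    def test_monotone_pair_flagged(self):
        act = pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]],
                           index=["E1"], columns=[f"S{i}" for i in range(12)])
        cov = pd.DataFrame({"metal": np.arange(12.0) ** 2},
                           index=[f"S{i}" for i in range(12)])
        out = spearman_screen(act, cov)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["flagged"].iloc[0]

    def test_below_threshold_not_flagged(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rho = stats.spearmanr(x, y)[0]
            if 0.3 < abs(rho) < 0.55:
                break
        act = pd.DataFrame([x], index=["E1"],
                           columns=[f"S{i}" for i in range(12)])
        cov = pd.DataFrame({"m": y}, index=[f"S{i}" for i in range(12)])
        assert not spearman_screen(act, cov)["flagged"].iloc[0]

    def test_constant_vector_skipped_with_note(self):
        act = pd.DataFrame([[1.0] * 8], index=["E1"],
                           columns=[f"S{i}" for i in range(8)])
        cov = pd.DataFrame({"m": np.arange(8.0)},
                           index=[f"S{i}" for i in range(8)])
        out = spearman_screen(act, cov)
        assert out["note"].iloc[0] == "constant vector"

    def test_null_flag_rate_calibrated(self):
        rng = np.random.default_rng(7)
        flags = 0
        reps = 1000
        cols = [f"S{i}" for i in range(12)]
        for _ in range(reps):
            act = pd.DataFrame([rng.normal(size=12)], index=["E"], columns=cols)
            cov = pd.DataFrame({"m": rng.normal(size=12)}, index=cols)
            flags += spearman_screen(act, cov)["flagged"].iloc[0]
        # |rho| > 0.6 at n = 12 is rarer than p < 0.05 alone
        assert 0.005 <= flags / reps <= 0.06


class TestFisher:
    def test_hypergeometric_tail_enumeration(self):
        """One-sided p equals the brute-force hypergeometric tail."""
        n_patients, anchor_pos, gene_mut, both = 100, 30, 20, 15
        anchor = np.zeros(n_patients, dtype=bool)
        anchor[:anchor_pos] = True
        gene = np.zeros(n_patients, dtype=bool)
        gene[:both] = True
        gene[anchor_pos:anchor_pos + (gene_mut - both)] = True
        mut = pd.DataFrame({"ANCHOR": anchor, "G": gene})
        p = fisher_cooccurrence(mut, "ANCHOR")["p"].iloc[0]
        # brute force: sum hypergeometric pmf over the upper tail
        oracle = sum(stats.hypergeom.pmf(k, n_patients, anchor_pos, gene_mut)
                     for k in range(both, gene_mut + 1))
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_exclusive_cooccurrence_minimal_p(self):
        mut = simulate_mutation_table(300, 0.3, {"G1": 0.2},
                                      {"G1": np.inf}, seed=2)
        res = fisher_cooccurrence(mut, "ANCHOR")
        assert res["p"].iloc[0] < 1e-10
        assert res["co_fraction"].iloc[0] == 1.0

    def test_never_mutated_gene_excluded(self):
        mut = pd.DataFrame({"ANCHOR": [True, False], "G": [False, False]})
        assert fisher_cooccurrence(mut, "ANCHOR").empty

    def test_length_scaling_reported(self):
        mut = simulate_mutation_table(100, 0.3, {"G1": 0.5}, seed=3)
        res = fisher_cooccurrence(mut, "ANCHOR", {"G1": 250})
        assert res["rate_per_residue"].iloc[0] == pytest.approx(
            res["n_mutated"].iloc[0] / 250)
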