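"""ISP selection filters, normalization, imputation, median polish."""

import numpy as np
import pandas as pd
import pytest

from ddabpp.io import PairedQuantTable
from ddabpp.preprocess import (
    IspCriteria,
    IspSet,
    NoIspError,
    impute_missing,
    median_polish,
    normalize_by_isp,
    select_isp,
    summarize_protein,
)
from tests.conftest import make_quant, paired_rows


def _stable_candidate_rows(protein="HK1", peptide="STABLEPEPK", n_samples=8,
                           rho_noise=0.0, seed=0, missing=0):
    """Paired rows for a candidate peptide with correlated dep/tot values."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        base = 2 ** (14 + rng.normal(0, 1))
        tot = base * 2 ** rng.normal(0, rho_noise)
        dep = base * 2 ** rng.normal(0, rho_noise)
        rows += paired_rows(protein, f"S{i}", tot, dep, peptide=peptide)
    for k in range(missing):
        rows[k]["intensity"] = np.nan
    return rows


class TestIspSelection:
    def test_all_filters_pass(self):
        q = make_quant(_stable_candidate_rows(rho_noise=0.05))
        isp = select_isp(q, IspCriteria(candidate_ids={"HK1"}))
        assert isp.keys() == {("HK1", "STABLEPEPK")}

    def test_short_peptide_rejected(self):
        rows = (_stable_candidate_rows(peptide="SHORTPK", rho_noise=0.05)
                + _stable_candidate_rows(peptide="LONGPEPTIDEK", rho_noise=0.05,
                                         seed=1))
        isp = select_isp(make_quant(rows), IspCriteria(candidate_ids={"HK1"}))
        assert ("HK1", "SHORTPK") not in isp.keys()  # 7 residues < 8
        assert ("HK1", "LONGPEPTIDEK") in isp.keys()

    def test_missingness_rejected(self):
        rows = (_stable_candidate_rows(peptide="GAPPYPEPTIDE", rho_noise=0.05,
                                       missing=2)
                + _stable_candidate_rows(peptide="FULLPEPTIDEK", rho_noise=0.05,
                                         seed=1))
        isp = select_isp(make_quant(rows), IspCriteria(candidate_ids={"HK1"}))
        assert ("HK1", "GAPPYPEPTIDE") not in isp.keys()  # 12.5% missing >= 5%
        assert ("HK1", "FULLPEPTIDEK") in isp.keys()

    def test_non_candidate_rejected(self):
        rows = _stable_candidate_rows(protein="XX1", rho_noise=0.05)
        with pytest.raises(NoIspError):
            select_isp(make_quant(rows), IspCriteria(candidate_ids={"HK1"}))

    def test_uncorrelated_peptide_rejected(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(10):  # dep and tot vary independently: low Pearson
            rows += paired_rows("HK1", f"S{i}", 2 ** rng.normal(14, 1),
                                2 ** rng.normal(14, 1), peptide="RANDOMPEPK")
        rows += _stable_candidate_rows(peptide="OKPEPTIDEK", rho_noise=0.05,
                                       seed=2, n_samples=10)
        # filler peptides give the internal quantile normalization resolution
        for j in range(30):
            for i in range(10):
                rows += paired_rows("XX1", f"S{i}", 2 ** rng.normal(14, 2),
                                    2 ** rng.normal(14, 2),
                                    peptide=f"FILLERPEP{j:02d}K")
        isp = select_isp(make_quant(rows), IspCriteria(candidate_ids={"HK1"}))
        assert ("HK1", "RANDOMPEPK") not in isp.keys()

    def test_order_independent(self, noisy_cohort):
        params, quant, _, _ = noisy_cohort
        crit = IspCriteria(candidate_ids=set(params.isp_ids))
        shuffled = PairedQuantTable(
            quant.data.sample(frac=1.0, random_state=9).reset_index(drop=True))
        assert select_isp(quant, crit).keys() == select_isp(shuffled, crit).keys()


class TestNormalization:
    @staticmethod
    def _two_run_table():
        # ISP medians differ by 2 between samples: {10, 12} -> both 11
        rows = []
        for sample, shift in (("S1", 0.0), ("S2", 2.0)):
            for pep, off in (("AAAAPEPK", -1.0), ("BBBBPEPK", 0.0),
                             ("CCCCPEPK", 1.0)):
                for extract in ("total", "depleted"):
                    rows.append({
                        "protein_id": "HK1", "peptide_seq": pep,
                        "transition_id": "t1", "sample_id": sample,
                        "extract": extract, "intensity": 2 ** (10 + off + shift)})
        return make_quant(rows), IspSet(pd.DataFrame({
            "protein_id": ["HK1"] * 3,
            "peptide_seq": ["AAAAPEPK", "BBBBPEPK", "CCCCPEPK"]}))

    def test_two_run_medians_meet_at_grand_median(self):
        q, isp = self._two_run_table()
        out = normalize_by_isp(q, isp)
        log2 = np.log2(out.data.set_index(["sample_id", "peptide_seq"])
                       .query("extract == 'total'")["intensity"])
        assert np.median(log2.loc["S1"]) == pytest.approx(11.0, abs=1e-12)
        assert np.median(log2.loc["S2"]) == pytest.approx(11.0, abs=1e-12)

    def test_idempotent(self):
        q, isp = self._two_run_table()
        once = normalize_by_isp(q, isp)
        twice = normalize_by_isp(once, isp)
        assert np.allclose(once.data["intensity"], twice.data["intensity"])

    def test_rank_preserving_within_run(self, noisy_cohort):
        params, quant, _, _ = noisy_cohort
        from ddabpp.preprocess import select_isp
        isp = select_isp(quant, IspCriteria(candidate_ids=set(params.isp_ids)))
        out = normalize_by_isp(quant, isp)
        sub_in = quant.data.query("sample_id == 'P01_T' and extract == 'total'")
        sub_out = out.data.query("sample_id == 'P01_T' and extract == 'total'")
        assert (sub_in["intensity"].rank() == sub_out["intensity"].rank()).all()

    def test_run_without_isp_named(self):
        q, isp = self._two_run_table()
        df = q.data[~((q.data["sample_id"] == "S2")
                      & (q.data["extract"] == "depleted"))]
        extra = pd.DataFrame([{  # S2-depleted now has only a non-ISP protein
            "protein_id": "ZZ1", "peptide_seq": "ZZZZPEPK", "transition_id": "t1",
            "sample_id": "S2", "extract": "depleted", "intensity": 100.0,
            "decoy": False}])
        broken = PairedQuantTable(pd.concat([df, extra], ignore_index=True))
        with pytest.raises(ValueError, match="S2"):
            normalize_by_isp(broken, isp)


class TestImputation:
    def test_draws_follow_low_value_distribution(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, v in enumerate(rng.normal(2000, 100, 200)):
            rows.append({"protein_id": "P1", "peptide_seq": "PEPTIDEK",
                         "transition_id": f"t{i}", "sample_id": "S1",
                         "extract": "total", "intensity": v})
        rows[0]["intensity"] = 1000.0  # the observed minimum
        sd = pd.DataFrame(rows)["intensity"].std(ddof=1)
        for i in range(300):
            rows.append({"protein_id": "P1", "peptide_seq": "PEPTIDEK",
                         "transition_id": f"m{i}", "sample_id": "S1",
                         "extract": "total", "intensity": np.nan})
        out = impute_missing(make_quant(rows), seed=1)
        imputed = out.data["intensity"].iloc[-300:]
        assert imputed.mean() == pytest.approx(0.9 * 1000, rel=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.5 * sd, rel=0.15)

    def test_identity_without_missing(self):
        q = make_quant(paired_rows("P1", "S1", 100.0, 50.0))
        out = impute_missing(q, seed=0)
        assert np.allclose(out.data["intensity"], q.data["intensity"])

    def test_observed_untouched_and_seed_reproducible(self):
        rows = (paired_rows("P1", "S1", 100.0, 50.0)
                + paired_rows("P1", "S2", 120.0, 60.0)
                + paired_rows("P1", "S3", 130.0, np.nan))
        a = impute_missing(make_quant(rows), seed=3)
        b = impute_missing(make_quant(rows), seed=3)
        c = impute_missing(make_quant(rows), seed=4)
        assert a.data["intensity"].equals(b.data["intensity"])
        assert not a.data["intensity"].equals(c.data["intensity"])
        assert a.data["intensity"].iloc[0] == 100

    def test_fully_missing_protein_falls_back_to_global_min(self):
        rows = paired_rows("P1", "S1", 100, 50)
        rows += [{"protein_id": "P2", "peptide_seq": "OTHERPEPK",
                  "transition_id": "t1", "sample_id": "S1",
                  "extract": "total", "intensity": np.nan}]
        with pytest.warns(UserWarning, match="global minimum"):
            out = impute_missing(make_quant(rows), seed=0)
        assert out.data["intensity"].notna().all()


class TestSummarization:
    def test_additive_block_recovered_exactly(self):
        rows = []
        for t, t_eff in (("t1", 0.0), ("t2", 1.0)):
            for s, s_eff in (("S1", 0.0), ("S2", 2.0)):
                rows.append({"protein_id": "P1", "peptide_seq": "PEPTIDEK",
                             "transition_id": t, "sample_id": s,
                             "extract": "total",
                             "intensity": 2 ** (10 + t_eff + s_eff)})
        mat = summarize_protein(make_quant(rows), "total")
        diff = mat.loc["P1", "S2"] - mat.loc["P1", "S1"]
        assert diff == pytest.approx(2.0, abs=1e-9)

    def test_single_transition_passthrough(self):
        rows = [{"protein_id": "P1", "peptide_seq": "PEPTIDEK",
                 "transition_id": "t1", "sample_id": "S1", "extract": "total",
                 "intensity": 1024.0}]
        mat = summarize_protein(make_quant(rows), "total")
        assert mat.loc["P1", "S1"] == pytest.approx(10.0)

    def test_outlier_transition_is_damped(self):
        rng = np.random.default_rng(2)
        rows = []
        clean = 12.0
        for ti in range(5):
            for s in range(6):
                val = clean + rng.normal(0, 0.01)
                if ti == 4:
                    val += 5.0  # one contaminated transition
                rows.append({"protein_id": "P1", "peptide_seq": "PEPTIDEK",
                             "transition_id": f"t{ti}", "sample_id": f"S{s}",
                             "extract": "total", "intensity": 2 ** val})
        mat = summarize_protein(make_quant(rows), "total")
        assert np.abs(mat.loc["P1"] - clean).max() < 0.1

    def test_median_polish_fixed_point_on_additive_data(self):
        x = np.add.outer([0.0, 1.0, 3.0], [10.0, 12.0])
        overall, row, col, resid = median_polish(x)
        assert np.abs(resid).max() < 1e-9
        assert (overall + row[:, None] + col[None, :]) == pytest.approx(x)
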