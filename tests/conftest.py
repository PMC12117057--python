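"""Shared fixtures: tiny hand-built tables and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from ddabpp.io import CohortDesign, PairedQuantTable


def make_design(n_patients: int = 12) -> CohortDesign:
    """Balanced paired design: n_patients, each with one T and one N sample."""
    rows = []
    half = n_patients // 2
    for i in range(n_patients):
        pat = f"P{i + 1:02d}"
        surv = "long" if i < half else "short"
        for tissue in ("T", "N"):
            rows.append({
                "sample_id": f"{pat}_{tissue}", "patient_id": pat,
                "tissue": tissue, "survival": surv,
                "age": 55 + i, "sex": i % 2, "smoking": (i // 2) % 2,
                "tumor_cell_pct": 60.0 if tissue == "T" else np.nan,
            })
    return CohortDesign(pd.DataFrame(rows))


def make_quant(records: list[dict]) -> PairedQuantTable:
    """Quant table from a list of row dicts (defaults filled in)."""
    df = pd.DataFrame(records)
    for col, default in [("peptide_seq", "PEPTIDEK"), ("transition_id", "t1"),
                         ("decoy", False)]:
        if col not in df.columns:
            df[col] = default
    return PairedQuantTable(df)


def paired_rows(protein, sample, total, depleted, peptide="PEPTIDEK",
                transition="t1"):
    """One matched transition: a (total, depleted) row pair."""
    return [
        {"protein_id": protein, "peptide_seq": peptide, "transition_id": transition,
         "sample_id": sample, "extract": "total", "intensity": total},
        {"protein_id": protein, "peptide_seq": peptide, "transition_id": transition,
         "sample_id": sample, "extract": "depleted", "intensity": depleted},
    ]


@pytest.fixture(scope="session")
def design24() -> CohortDesign:
    return make_design(12)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless small cohort with one active enzyme (alpha=0.7 in tumors)."""
    from ddabpp.simulate import SimulationParams, simulate_cohort
    params = SimulationParams(
        n_enzymes=5, n_background_proteins=10, n_isp_proteins=8,
        alpha={"T_long": {"SH001": 0.7}, "T_short": {"SH001": 0.7}},
        noise_sd_log2=0.0, seed=11,
    )
    return params, *simulate_cohort(params)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort with realistic noise, one active enzyme and a coupling."""
    from ddabpp.simulate import SimulationParams, simulate_cohort
    alpha = {c: {"SH001": 0.8, "SH002": 0.5} for c in
             ("T_long", "T_short", "N_long", "N_short")}
    params = SimulationParams(
        n_enzymes=8, n_background_proteins=30, n_isp_proteins=12,
        alpha=alpha, codepletion_couplings=[("SH001", "BG001", 0.7)],
        noise_sd_log2=0.15, seed=7,
    )
    return params, *simulate_cohort(params)
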