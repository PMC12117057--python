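"""ISP selection, ISP-anchored normalization, imputation and summarization.

Internal standard peptides (ISPs) are endogenous housekeeping/cytoskeletal
peptides that are stable between the paired total and depleted extracts.
They serve two roles downstream: a run-level normalization anchor, and the
technical-noise reference distribution the activity gate tests against.
Selection applies five filters jointly, on quantile-normalized log2 data:

1. candidate membership (housekeeping/cytoskeletal id list),
2. missing fraction < 5% across runs,
3. variance equality between depleted- and total-run log2 values
   (two-sided F-test, p > 0.2),
4. Pearson correlation between paired depleted/total log2 values
   (r > 0.6, p < 0.05),
5. peptide length >= 8 residues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ddabpp.io import PairedQuantTable

logger = logging.getLogger(__name__)


class NoIspError(RuntimeError):
    """No peptide survived ISP selection: no noise reference, KS gating impossible."""


@dataclass
class IspCriteria:
    """Thresholds of the five ISP filters (defaults: the published cutoffs)."""

    candidate_ids: set = field(default_factory=set)
    max_missing_frac: float = 0.05
    f_test_min_p: float = 0.2
    pearson_min_r: float = 0.6
    pearson_max_p: float = 0.05
    min_peptide_len: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_frac <= 1.0):
            raise ValueError("max_missing_frac outside [0, 1]")
        for name in ("f_test_min_p", "pearson_max_p"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if not (-1.0 <= self.pearson_min_r <= 1.0):
            raise ValueError("pearson_min_r outside [-1, 1]")


@dataclass
class IspSet:
    """Selected internal-standard peptides, keyed by (protein, peptide)."""

    peptides: pd.DataFrame  # protein_id, peptide_seq

    def __post_init__(self) -> None:
        self.peptides = (
            self.peptides[["protein_id", "peptide_seq"]]
            .drop_duplicates()
            .sort_values(["protein_id", "peptide_seq"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.peptides["protein_id"].unique())

    def keys(self) -> set:
        return set(map(tuple, self.peptides.values))

    def write(self, path) -> None:
        self.peptides.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "IspSet":
        return cls(pd.read_csv(path, sep="\t"))


def _peptide_run_matrix(quant: PairedQuantTable) -> pd.DataFrame:
    """log2 peptide-level (summed transitions) matrix: (protein, peptide) x run.

    A run is one (sample, extract) injection.  A peptide value is the sum of
    its observed transition intensities in the run; it is missing only if no
    transition was observed.
    """
    df = quant.targets()
    grouped = df.groupby(
        ["protein_id", "peptide_seq", "sample_id", "extract"], sort=True
    )["intensity"].sum(min_count=1)
    mat = grouped.unstack(["sample_id", "extract"])
    with np.errstate(divide="ignore"):
        return np.log2(mat.where(mat > 0))


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Column-wise quantile normalization, tolerant of missing cells.

    Each column's observed values are mapped, by rank quantile, onto the mean
    quantile curve of all columns (computed on a common grid by linear
    interpolation).
    """
    grid = np.linspace(0.0, 1.0, 101)
    curves = []
    for col in mat.columns:
        v = np.sort(mat[col].dropna().to_numpy())
        if v.size == 0:
            continue
        q = np.linspace(0.0, 1.0, v.size) if v.size > 1 else np.array([0.5])
        curves.append(np.interp(grid, q, v))
    if not curves:
        return mat.copy()
    ref = np.mean(curves, axis=0)
    out = mat.copy()
    for col in mat.columns:
        v = mat[col]
        obs = v.dropna()
        if obs.size == 0:
            continue
        ranks = obs.rank(method="average").to_numpy()
        q = (ranks - 1) / max(obs.size - 1, 1) if obs.size > 1 else np.array([0.5])
        out.loc[obs.index, col] = np.interp(q, grid, ref)
    return out


def select_isp(quant: PairedQuantTable, criteria: IspCriteria) -> IspSet:
    """Apply the five ISP filters and return the surviving peptide set."""
    if not criteria.candidate_ids:
        raise ValueError("candidate_ids is empty: provide housekeeping/cytoskeletal ids")
    df = quant.targets()
    cells = df.assign(missing=df["intensity"].isna())
    missing_frac = cells.groupby(["protein_id", "peptide_seq"], sort=True)["missing"].mean()

    mat = _peptide_run_matrix(quant)
    mat = quantile_normalize(mat)
    dep = mat.xs("depleted", axis=1, level="extract")
    tot = mat.xs("total", axis=1, level="extract")
    common = dep.columns.intersection(tot.columns)
    dep, tot = dep[common], tot[common]

    rows = []
    for key in mat.index:
        protein, peptide = key
        if protein not in criteria.candidate_ids:
            continue
        if len(peptide) < criteria.min_peptide_len:
            continue
        if missing_frac.get(key, 1.0) >= criteria.max_missing_frac:
            continue
        d = dep.loc[key].dropna() if key in dep.index else pd.Series(dtype=float)
        t = tot.loc[key].dropna() if key in tot.index else pd.Series(dtype=float)
        if len(d) < 3 or len(t) < 3:
            continue
        v1, v2 = d.var(ddof=1), t.var(ddof=1)
        if v1 <= 0 or v2 <= 0:
            f_p = 1.0  # degenerate: no variability difference detectable
        else:
            big, small = (v1, v2) if v1 >= v2 else (v2, v1)
            dfn = (len(d) - 1) if v1 >= v2 else (len(t) - 1)
            dfd = (len(t) - 1) if v1 >= v2 else (len(d) - 1)
            f_p = min(1.0, 2.0 * stats.f.sf(big / small, dfn, dfd))
        if f_p <= criteria.f_test_min_p:
            continue
        paired = pd.concat([d, t], axis=1, join="inner").dropna()
        if len(paired) < 3:
            continue
        dv, tv = paired.iloc[:, 0], paired.iloc[:, 1]
        if dv.std() == 0 or tv.std() == 0:
            # perfectly stable peptide (identical paired values): ideal ISP
            if np.allclose(dv, tv):
                r, r_p = 1.0, 0.0
            else:
                continue
        else:
            r, r_p = stats.pearsonr(dv, tv)
        if r <= criteria.pearson_min_r or r_p >= criteria.pearson_max_p:
            continue
        rows.append({"protein_id": protein, "peptide_seq": peptide})
    if not rows:
        raise NoIspError("no peptide passed ISP selection; KS gating impossible")
    return IspSet(pd.DataFrame(rows))


def normalize_by_isp(quant: PairedQuantTable, isp: IspSet) -> PairedQuantTable:
    """Equalize per-run ISP medians (global-standard normalization).

    Per run (sample x extract), the median log2 intensity of ISP features is
    shifted to the grand median (median of per-run ISP medians); all of the
    run's intensities receive the same log2 shift, so within-run differences
    and ranks are untouched.  Idempotent.
    """
    df = quant.data.copy()
    keyed = pd.MultiIndex.from_frame(df[["protein_id", "peptide_seq"]])
    is_isp = keyed.isin(isp.keys()) & ~df["decoy"] & df["intensity"].notna()
    with np.errstate(divide="ignore"):
        log2_int = np.log2(df["intensity"].where(df["intensity"] > 0))
    isp_rows = df[is_isp].assign(_log2=log2_int[is_isp])
    run_medians = isp_rows.groupby(["sample_id", "extract"])["_log2"].median()
    all_runs = set(map(tuple, df[["sample_id", "extract"]].drop_duplicates().values))
    missing_runs = sorted(all_runs - set(run_medians.index))
    if missing_runs:
        raise ValueError(f"run(s) without ISP features: {missing_runs}")
    grand = run_medians.median()
    shift = run_medians - grand  # log2 shift per run
    run_index = pd.MultiIndex.from_frame(df[["sample_id", "extract"]])
    factor = np.exp2(-shift.reindex(run_index).to_numpy())
    df["intensity"] = df["intensity"] * factor
    return PairedQuantTable(df, peptide_fdr_threshold=quant.peptide_fdr_threshold)


def impute_missing(quant: PairedQuantTable, seed: int,
                   scale: str = "linear") -> PairedQuantTable:
    """Replace missing intensities with low-value draws.

    Per (protein, extract), each missing cell is drawn from
    ``Normal(0.9 * min(observed), 0.5 * SD(observed))``, floored at 0; a
    protein with no observed values in an extract falls back to the global
    minimum/SD (logged, not fatal).  Observed cells are never touched, and
    the same seed reproduces the same draws.

    ``scale`` chooses the scale the moments are taken on: ``"linear"``
    (default, matching the stored intensities) or ``"log2"`` (draw in log2
    space, then exponentiate).
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    rng = np.random.default_rng(seed)
    df = quant.data.copy()
    values = df["intensity"].to_numpy(dtype=float)
    if scale == "log2":
        with np.errstate(divide="ignore"):
            values = np.where(np.isnan(values), np.nan, np.log2(np.maximum(values, 1e-300)))
    obs = ~np.isnan(values)
    if obs.sum() == 0:
        raise ValueError("table has no observed intensities to impute from")
    global_min = np.nanmin(values)
    global_sd = float(np.nanstd(values, ddof=1)) if obs.sum() > 1 else 0.0

    group = df.groupby(["protein_id", "extract"], sort=False)
    out = values.copy()
    for _, idx in group.indices.items():
        vals = values[idx]
        miss = np.isnan(vals)
        if not miss.any():
            continue
        seen = vals[~miss]
        if seen.size == 0:
            mu, sd = 0.9 * global_min, 0.5 * global_sd
            logger.info("protein group with no observed values; global-min fallback")
            warnings.warn("fully missing protein group imputed from global minimum",
                          stacklevel=2)
        else:
            mu = 0.9 * float(seen.min())
            sd = 0.5 * (float(seen.std(ddof=1)) if seen.size > 1 else 0.0)
        draws = rng.normal(mu, sd, size=int(miss.sum())) if sd > 0 else np.full(
            int(miss.sum()), mu)
        out[idx[miss]] = draws
    if scale == "log2":
        imputed = np.exp2(out)
        imputed[obs] = df["intensity"].to_numpy(dtype=float)[obs]
        df["intensity"] = imputed
    else:
        df["intensity"] = np.maximum(out, 0.0)
    return PairedQuantTable(df, peptide_fdr_threshold=quant.peptide_fdr_threshold)


def median_polish(x: np.ndarray, max_iter: int = 20, tol: float = 1e-9):
    """Tukey median polish of a 2-D array (NaN-tolerant).

    Returns (overall, row_effects, col_effects, residuals) with the additive
    decomposition ``x ≈ overall + row + col + residual``.
    """
    x = np.asarray(x, dtype=float)
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.nanmedian(row) if row.size else 0.0
        row -= cmed_of_row
        overall += cmed_of_row
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cmed = np.nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.nanmedian(col) if col.size else 0.0
        col -= rmed_of_col
        overall += rmed_of_col
        if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def summarize_protein(quant: PairedQuantTable, extract: str) -> pd.DataFrame:
    """Protein x sample log2 abundance matrix via Tukey median polish.

    Each protein's transition x sample log2 submatrix is polished; the
    per-sample abundance is ``overall + column effect``.  Single-transition
    proteins pass through as their log2 intensity.
    """
    if extract not in ("total", "depleted"):
        raise ValueError(f"unknown extract {extract!r}")
    df = quant.targets()
    df = df[(df["extract"] == extract) & df["intensity"].notna() & (df["intensity"] > 0)]
    samples = sorted(quant.data["sample_id"].unique())
    out = {}
    for protein, sub in df.groupby("protein_id", sort=True):
        mat = sub.pivot_table(
            index=["peptide_seq", "transition_id"], columns="sample_id",
            values="intensity", aggfunc="first",
        ).reindex(columns=samples)
        if mat.empty:
            warnings.warn(f"protein {protein!r} has no usable {extract} data; excluded",
                          stacklevel=2)
            continue
        log2 = np.log2(mat.to_numpy(dtype=float))
        if log2.shape[0] == 1:
            out[protein] = log2[0]
            continue
        overall, _, col, _ = median_polish(log2)
        abundance = overall + col
        abundance[np.isnan(log2).all(axis=0)] = np.nan
        out[protein] = abundance
    return pd.DataFrame.from_dict(out, orient="index", columns=samples)
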