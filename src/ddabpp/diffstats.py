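"""Differential and association statistics over the dd-ABPP data layers.

Family-to-layer mapping follows the study design: Gaussian GLM (identity
link) for log2 protein abundances, quasibinomial GLM with probit link for
RADDi active fractions (proportion data inflated with zeros), and Poisson
GLM (log link) for on-bead spectral counts.  Age, sex and smoking status
enter as confounders (sex/smoking coded 0/1).  When more than one condition
contrast is tested per feature, a post-hoc single-step max-|z| adjustment
(seeded multivariate-normal resampling of the contrast correlation, the
multcomp-style default) or Bonferroni is applied within the feature;
Benjamini–Hochberg FDR is applied across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ddabpp.io import CohortDesign

FAMILIES = ("gaussian", "quasibinomial_probit", "poisson")


@dataclass
class GlmSpec:
    """Family, confounders and contrasts of one differential fit."""

    family: str = "gaussian"
    covariates: tuple = ()
    contrasts: list | None = None  # [(cond_a, cond_b)]; None = all pairs
    adjust: str = "max_t"          # "max_t", "bonferroni" or "none"
    raddi_nudge: float = 1e-6      # pull exact 0/1 proportions off the boundary
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.adjust not in ("max_t", "bonferroni", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        bad = set(self.covariates) - {"age", "sex", "smoking", "tumor_cell_pct"}
        if bad:
            raise ValueError(f"unknown covariate(s) {sorted(bad)}")


def _design_matrix(df: pd.DataFrame, conditions: list[str], covariates: tuple):
    """Intercept + condition indicators (first condition reference) + covariates."""
    cols = {"const": np.ones(len(df))}
    for cond in conditions[1:]:
        cols[f"cond[{cond}]"] = (df["condition"] == cond).astype(float).to_numpy()
    for cov in covariates:
        cols[cov] = df[cov].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=df.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design: a covariate is collinear "
                         "with the condition factor")
    return X


def _contrast_vector(pair, conditions, n_params):
    a, b = pair
    v = np.zeros(n_params)
    for sign, cond in ((1.0, a), (-1.0, b)):
        if cond != conditions[0]:
            v[conditions.index(cond)] = sign  # positions 1.. hold cond coefs
    return v


def fit_glm(y: pd.Series, design: CohortDesign, spec: GlmSpec) -> pd.DataFrame:
    """Fit one feature's response against condition + confounders.

    ``y`` is indexed by sample_id.  Returns one row per contrast with the
    estimate (difference a − b on the linear-predictor scale), its SE, the
    Wald statistic, the raw two-sided p and — when more than one contrast is
    tested — a within-feature adjusted p (``p_adj_contrasts``).

    Degenerate responses (zero variance within both contrasted groups, e.g.
    all-zero RADDi) yield ``p = NaN`` with ``degenerate = True``.
    """
    df = design.data.set_index("sample_id").copy()
    df["y"] = y.reindex(df.index)
    needed = ["y", "condition", *spec.covariates]
    df = df.dropna(subset=needed)
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions with data")
    counts = df.groupby("condition").size()
    if (counts < 2).any():
        raise ValueError("need >=2 samples in every contrasted group")
    contrasts = spec.contrasts or list(combinations(conditions, 2))

    yv = df["y"].astype(float)
    if spec.family == "poisson":
        if not np.allclose(yv, np.round(yv)) or (yv < 0).any():
            raise ValueError("poisson family requires nonnegative integer counts")
    if spec.family == "quasibinomial_probit":
        if ((yv < 0) | (yv > 1)).any():
            raise ValueError("proportion response must lie in [0, 1]")
        yv = yv.clip(spec.raddi_nudge, 1.0 - spec.raddi_nudge)

    X = _design_matrix(df, conditions, spec.covariates)
    if spec.family == "gaussian":
        res = sm.OLS(yv, X).fit()  # t-based inference: two-group fit == t-test
        scale_kind = "t"
        dfree = res.df_resid
    elif spec.family == "quasibinomial_probit":
        model = sm.GLM(yv, X, family=sm.families.Binomial(
            link=sm.families.links.Probit()))
        import warnings as _warnings
        with _warnings.catch_warnings():
            # zero-inflated RADDi can separate perfectly; flagged downstream
            _warnings.simplefilter("ignore")
            res = model.fit(scale="X2")  # Pearson chi2/df dispersion
        scale_kind = "z"
        dfree = None
    else:
        res = sm.GLM(yv, X, family=sm.families.Poisson()).fit()
        scale_kind = "z"
        dfree = None

    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    rows, vecs = [], []
    for pair in contrasts:
        a, b = pair
        degenerate = False
        if spec.family == "quasibinomial_probit":
            g = df[df["condition"].isin(pair)].groupby("condition")["y"]
            if (g.nunique() == 1).all() and g.first().nunique() == 1:
                degenerate = True  # e.g. all-zero RADDi in both groups
        v = _contrast_vector(pair, conditions, len(params))
        est = float(v @ params)
        se = float(np.sqrt(v @ cov @ v))
        if degenerate or se == 0 or not np.isfinite(se):
            stat, p = np.nan, np.nan
            degenerate = True
        else:
            stat = est / se
            p = (2 * stats.t.sf(abs(stat), dfree) if scale_kind == "t"
                 else 2 * stats.norm.sf(abs(stat)))
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "statistic": stat, "p": p, "degenerate": degenerate})
        vecs.append(v)
    out = pd.DataFrame(rows)

    if len(contrasts) > 1 and spec.adjust != "none":
        p_adj = np.full(len(out), np.nan)
        stats_abs = out["statistic"].abs().to_numpy()
        ok = np.isfinite(stats_abs)
        if spec.adjust == "bonferroni":
            p_adj[ok] = np.minimum(1.0, out.loc[ok, "p"] * ok.sum())
        else:
            V = np.asarray(vecs)[ok]
            C = V @ cov @ V.T
            d = np.sqrt(np.diag(C))
            R = C / np.outer(d, d)
            rng = np.random.default_rng(spec.seed)
            draws = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=20000,
                                            method="svd")
            maxabs = np.abs(draws).max(axis=1)
            p_adj[ok] = [(maxabs >= t).mean() for t in stats_abs[ok]]
        out["p_adj_contrasts"] = p_adj
    else:
        out["p_adj_contrasts"] = out["p"]
    return out


def fit_glm_many(matrix: pd.DataFrame, design: CohortDesign,
                 spec: GlmSpec) -> pd.DataFrame:
    """Fit every row (feature) of a feature x sample matrix; BH across features.

    Features whose fit fails structurally (too few groups, degenerate) are
    kept with missing p.  Returns long results with raw and BH-adjusted
    columns (the study reports unadjusted activity p-values as primary, so
    both are always emitted).
    """
    frames = []
    for feature, row in matrix.iterrows():
        try:
            res = fit_glm(row, design, spec)
        except ValueError:
            continue
        res.insert(0, "feature_id", feature)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["feature_id", "contrast", "estimate", "se",
                                     "statistic", "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    out["q"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    return out


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; missing p propagates to missing q."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def spearman_screen(activity: pd.DataFrame, covariates: pd.DataFrame,
                    rho_min: float = 0.6, p_max: float = 0.05,
                    min_n: int = 4) -> pd.DataFrame:
    """Spearman screen of per-sample activity against sample covariates.

    ``activity`` is feature x sample, ``covariates`` is sample x variable
    (e.g. tissue metal concentrations).  Rows with ``|rho| > rho_min`` and
    two-sided ``p < p_max`` (t approximation) are flagged.  Constant vectors
    and pairs with fewer than ``min_n`` complete observations are skipped
    with a note.
    """
    rows = []
    for feature, act in activity.iterrows():
        for var in covariates.columns:
            pair = pd.concat([act, covariates[var]], axis=1, join="inner").dropna()
            note = ""
            if len(pair) < min_n:
                note = "too few paired observations"
                rho, p, flagged = np.nan, np.nan, False
            elif pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
                note = "constant vector"
                rho, p, flagged = np.nan, np.nan, False
            else:
                rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                flagged = bool(abs(rho) > rho_min and p < p_max)
            rows.append({"feature_id": feature, "covariate": var, "n": len(pair),
                         "rho": rho, "p": p, "flagged": flagged, "note": note})
    return pd.DataFrame(rows)


def fisher_cooccurrence(mutations: pd.DataFrame, anchor_gene: str,
                        protein_lengths: dict | pd.Series | None = None
                        ) -> pd.DataFrame:
    """Per-gene Fisher exact test of co-mutation with an anchor oncogene.

    ``mutations`` is a binary patient x gene matrix.  For each non-anchor
    gene with at least one mutated patient, the 2x2 table (gene x anchor)
    is tested one-sided for enrichment of anchor co-mutation over the cohort
    anchor background; p-values are BH-corrected across genes.  When protein
    lengths are supplied, a descriptive mutation rate per residue is added.
    """
    if anchor_gene not in mutations.columns:
        raise ValueError(f"anchor gene {anchor_gene!r} not in mutation table")
    anchor = mutations[anchor_gene].astype(bool)
    lengths = pd.Series(protein_lengths) if protein_lengths is not None else None
    rows = []
    for gene in mutations.columns:
        if gene == anchor_gene:
            continue
        g = mutations[gene].astype(bool)
        n_mut = int(g.sum())
        if n_mut == 0:
            continue  # never mutated: excluded
        both = int((g & anchor).sum())
        table = [[both, n_mut - both],
                 [int((~g & anchor).sum()), int((~g & ~anchor).sum())]]
        p = stats.fisher_exact(table, alternative="greater")[1]
        row = {"gene": gene, "n_mutated": n_mut, "n_co_mutated": both,
               "co_fraction": both / n_mut, "p": p}
        if lengths is not None and gene in lengths.index:
            row["rate_per_residue"] = n_mut / float(lengths[gene])
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = adjust_bh(out["p"].to_numpy())
    return out
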