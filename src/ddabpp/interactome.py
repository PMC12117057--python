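"""Co-depletion calls, interactor-degree annotation and permutation nulls.

A background (non-enzyme) protein that loses signal in the depleted extract
together with the captured active enzymes is a candidate physical interactor.
Co-depletion is called per protein by a TWO-SIDED two-sample KS test of its
depletion ratios against the ISP noise reference, at two strata (p < 0.05 and
the stricter p < 0.01, the latter nested in the former by construction).

Enrichment of called proteins among known enzyme interactors is assessed
against two permutation nulls, each summarized by a one-tailed normal
(pnorm-style) z-test: random pseudo-target interactomes of the same size, and
random protein subsets for the physical-evidence overlap of correlation-
selected enzyme–protein pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ddabpp.activity import depletion_ratio_matrix, isp_reference_distribution
from ddabpp.io import CohortDesign, InteractionSet, PairedQuantTable
from ddabpp.preprocess import IspSet


def call_codepleted(quant: PairedQuantTable, isp: IspSet, design: CohortDesign,
                    proteins: list[str] | None = None, min_samples: int = 3,
                    strata: tuple = (0.05, 0.01)) -> pd.DataFrame:
    """Two-sided KS co-depletion calls per protein, per condition and pooled.

    Returns one row per (protein, condition) — condition ``"pooled"`` uses
    all samples — with the two-sided KS p against the condition's ISP
    reference and boolean calls at both strata.  Undersized proteins stay
    uncalled (p missing).
    """
    loose, strict = max(strata), min(strata)
    if proteins is None:
        proteins = sorted(set(quant.proteins) - set(isp.proteins))
    ratios = depletion_ratio_matrix(quant, proteins=proteins)
    groups = {c: design.samples_in(c) for c in design.conditions}
    groups["pooled"] = design.samples
    rows = []
    for cond, samples in groups.items():
        ref = isp_reference_distribution(quant, isp, samples)
        cols = [s for s in samples if s in ratios.columns]
        for protein in proteins:
            vals = (ratios.loc[protein, cols].dropna().to_numpy()
                    if protein in ratios.index else np.array([]))
            if vals.size < min_samples or ref.size == 0:
                p = np.nan
            else:
                p = float(stats.ks_2samp(vals, ref).pvalue)
            rows.append({
                "protein_id": protein, "condition": cond, "n": int(vals.size),
                "ks_p_two_sided": p,
                f"depleted_{loose:g}".replace("0.", ""): bool(p <= loose)
                if np.isfinite(p) else False,
                f"depleted_{strict:g}".replace("0.", ""): bool(p <= strict)
                if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows)


def codepleted_set(calls: pd.DataFrame, condition: str = "pooled",
                   stratum: float = 0.05) -> set[str]:
    """Proteins called co-depleted in one condition at one stratum."""
    col = f"depleted_{stratum:g}".replace("0.", "")
    sub = calls[calls["condition"] == condition]
    return set(sub.loc[sub[col], "protein_id"])


def annotate_degree(called: set[str], graph: InteractionSet,
                    sh_set: set[str]) -> dict[str, str]:
    """Label each called protein 1st degree, 2nd degree or unannotated.

    1st degree = direct neighbor of an enzyme; 2nd degree = neighbor of a
    1st-degree interactor that is not itself 1st degree.  A protein reachable
    both ways is labeled 1st (precedence).  Invariant to edge ordering and
    duplication (the edge set is canonicalized at load).
    """
    g = graph.graph()
    first = set()
    for sh in sh_set:
        if sh in g:
            first |= set(g.neighbors(sh))
    first -= sh_set
    second = set()
    for p in first:
        second |= set(g.neighbors(p))
    second -= first | sh_set
    out = {}
    for protein in called:
        if protein in first:
            out[protein] = "1st"
        elif protein in second:
            out[protein] = "2nd"
        else:
            out[protein] = "unannotated"
    return out


def _pnorm_tail(observed: float, null: np.ndarray):
    mean, sd = float(np.mean(null)), float(np.std(null, ddof=1))
    if sd == 0:
        warnings.warn("degenerate permutation null (sd = 0); boundary p reported",
                      stacklevel=3)
        return np.inf if observed > mean else -np.inf, \
            0.0 if observed > mean else 1.0
    z = (observed - mean) / sd
    return z, float(stats.norm.sf(z))


def random_interactome_null(observed_overlap: int, graph: InteractionSet,
                            universe: list[str], n_sh: int, depleted: set[str],
                            n_iter: int = 200, seed: int = 0):
    """Null for depleted-set overlap with the enzyme interactome.

    ``n_iter`` times, ``n_sh`` pseudo-targets are drawn without replacement
    from the quantified-protein universe; the overlap of their pooled
    1st-degree neighborhoods with the depleted set forms the null.  Returns
    ``(z, p)`` with a one-tailed (enrichment) normal p.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 to form a null distribution")
    if not set(depleted) <= set(universe):
        raise ValueError("depleted set must be contained in the universe")
    rng = np.random.default_rng(seed)
    g = graph.graph()
    universe = np.asarray(sorted(universe))
    null = np.empty(n_iter)
    for it in range(n_iter):
        targets = rng.choice(universe, size=n_sh, replace=False)
        neigh = set()
        for t in targets:
            if t in g:
                neigh |= set(g.neighbors(t))
        neigh -= set(targets)
        null[it] = len(neigh & depleted)
    return _pnorm_tail(float(observed_overlap), null)


def correlation_pairs(activity: pd.DataFrame, depletion: pd.DataFrame,
                      r_min: float = 0.4, p_max: float = 0.05,
                      evidence: InteractionSet | None = None) -> pd.DataFrame:
    """Pearson enzyme–protein pairing across samples with the t significance.

    ``activity`` (enzymes x samples) and ``depletion`` (proteins x samples)
    must share the sample axis (n >= 4).  Two-sided p from
    ``t = r sqrt(n−2) / sqrt(1−r²)``; a pair is retained when ``|r| > r_min``
    and ``p < p_max``.  Constant features are skipped.  When an evidence
    graph is supplied, a ``physical_evidence`` column marks experimentally
    supported edges.
    """
    samples = activity.columns.intersection(depletion.columns)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 shared samples")
    A = activity[samples].to_numpy(dtype=float)
    D = depletion[samples].to_numpy(dtype=float)
    a_ok = np.nanstd(A, axis=1) > 0
    d_ok = np.nanstd(D, axis=1) > 0
    A = A - A.mean(axis=1, keepdims=True)
    D = D - D.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(np.sqrt((A**2).sum(axis=1)), np.sqrt((D**2).sum(axis=1)))
        R = (A @ D.T) / denom
        R = np.clip(R, -1.0, 1.0)
        T = R * np.sqrt(n - 2) / np.sqrt(1.0 - R**2)
    P = 2 * stats.t.sf(np.abs(T), n - 2)
    rows = []
    for i, enz in enumerate(activity.index):
        if not a_ok[i]:
            continue
        for j, prot in enumerate(depletion.index):
            if not d_ok[j] or enz == prot:
                continue
            r, p = float(R[i, j]), float(P[i, j])
            if not np.isfinite(r):
                continue
            rows.append({"enzyme_id": enz, "protein_id": prot, "correlation": r,
                         "p": p, "retained": bool(abs(r) > r_min and p < p_max)})
    out = pd.DataFrame(rows)
    if evidence is not None and not out.empty:
        out["physical_evidence"] = [
            evidence.has_edge(e, q, "experimental")
            for e, q in out[["enzyme_id", "protein_id"]].itertuples(index=False)]
    return out


def physical_overlap_null(pairs: pd.DataFrame, evidence_graph: InteractionSet,
                          universe: list[str], n_iter: int = 100, seed: int = 0):
    """Null for the physical-evidence content of retained enzyme–protein pairs.

    The observed count is the number of retained pairs with an experimental
    edge.  Each of ``n_iter`` null replicates re-pairs the same enzymes with
    a random protein subset of the same size sampled from the quantified
    universe, and counts evidence edges.  Returns ``(z, p)`` one-tailed.
    """
    if pairs.empty:
        raise ValueError("empty pair set")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    retained = pairs[pairs["retained"]] if "retained" in pairs.columns else pairs
    if retained.empty:
        raise ValueError("no retained pairs")
    rng = np.random.default_rng(seed)
    observed = sum(evidence_graph.has_edge(e, p, "experimental")
                   for e, p in retained[["enzyme_id", "protein_id"]]
                   .itertuples(index=False))
    prots = retained["protein_id"].to_numpy()
    unique_prots = pd.unique(prots)
    universe = np.asarray(sorted(set(universe)))
    null = np.empty(n_iter)
    for it in range(n_iter):
        subset = rng.choice(universe, size=len(unique_prots), replace=False)
        mapping = dict(zip(unique_prots, subset))
        null[it] = sum(evidence_graph.has_edge(e, mapping[p], "experimental")
                       for e, p in retained[["enzyme_id", "protein_id"]]
                       .itertuples(index=False))
    return _pnorm_tail(float(observed), null)
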