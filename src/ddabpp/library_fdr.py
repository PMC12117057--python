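"""Targeted spectral-library assembly and permutation-based FDR estimation.

A targeted sub-library is assembled for a query protein set from two source
assay libraries (a project-specific library and a large pan-human one): the
project-specific entry wins on peptide overlap, non-proteotypic peptides are
excluded, and each peptide keeps its top six most intense transitions.

Because the sub-library is filtered out of sources that themselves carry a
known false-positive content, its error rate is estimated by permutation:
virtual source libraries of the printed sizes are seeded with 1% false
targets, random sub-libraries of the target size are drawn repeatedly, and
the empirical FDR distribution over draws bounds the sub-library's FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LIBRARY_COLUMNS = ["peptide_seq", "protein_id", "precursor_mz", "fragment",
                   "product_mz", "rel_intensity"]

# printed source-library sizes: pan-human library peptide count, and the
# project library (unprinted; fixed default), with the filtered sub-library
PHL_SIZE = 139_449
PROJECT_LIB_SIZE = 30_000
SUB_LIBRARY_SIZE = 3_593


@dataclass
class AssemblyResult:
    """Assembled targeted library plus exclusion bookkeeping."""

    library: pd.DataFrame
    n_nonproteotypic: int

    @property
    def n_peptides(self) -> int:
        return self.library["peptide_seq"].nunique()


def assemble_targeted_library(lib_a: pd.DataFrame, lib_b: pd.DataFrame,
                              targets: set[str], top_n: int = 6) -> AssemblyResult:
    """Assemble a target-protein sub-library from two source libraries.

    ``lib_a`` (project-specific) takes precedence over ``lib_b`` on peptide
    overlap.  Peptides mapping to more than one target protein are excluded
    as non-proteotypic (counted).  Transitions are truncated to the ``top_n``
    most intense, ties broken by product m/z ascending.  Idempotent: running
    the assembly on its own output changes nothing.
    """
    frames = []
    for source, lib in (("lib_a", lib_a), ("lib_b", lib_b)):
        sub = lib[lib["protein_id"].isin(targets)].copy()
        sub["source"] = source
        frames.append(sub)
    pool = pd.concat(frames, ignore_index=True)
    if pool.empty:
        return AssemblyResult(pool.assign(), 0)

    prot_per_pep = pool.groupby("peptide_seq")["protein_id"].nunique()
    shared = set(prot_per_pep[prot_per_pep > 1].index)
    pool = pool[~pool["peptide_seq"].isin(shared)]

    # project-specific entries win on overlap
    order = {"lib_a": 0, "lib_b": 1}
    pool = pool.sort_values("source", key=lambda s: s.map(order), kind="stable")
    winner = pool.groupby("peptide_seq")["source"].first()
    pool = pool[pool["source"] == pool["peptide_seq"].map(winner)]

    pool = pool.sort_values(
        ["peptide_seq", "rel_intensity", "product_mz"],
        ascending=[True, False, True], kind="stable")
    pool = pool.groupby("peptide_seq", group_keys=False).head(top_n)
    pool = pool.sort_values(["protein_id", "peptide_seq", "product_mz"]).reset_index(drop=True)
    return AssemblyResult(pool, len(shared))


@dataclass
class FdrSummary:
    """Empirical FDR distribution of random sub-library draws."""

    fdrs: np.ndarray
    bound: float

    @property
    def mean(self) -> float:
        return float(self.fdrs.mean())

    @property
    def sd(self) -> float:
        return float(self.fdrs.std(ddof=1))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.fdrs, q))

    @property
    def q95(self) -> float:
        return self.quantile(0.95)

    @property
    def p_exceed(self) -> float:
        """One-sided probability that a draw's FDR exceeds the stated bound."""
        return float((self.fdrs > self.bound).mean())

    def summary(self) -> str:
        return (f"empirical FDR over {self.fdrs.size} draws: "
                f"mean {self.mean:.4f}, sd {self.sd:.4f}, "
                f"95th pct {self.q95:.4f}; "
                f"P(FDR > {self.bound:g}) = {self.p_exceed:.3f}")


def estimate_fdr_permutation(size_a: int = PHL_SIZE, size_b: int = PROJECT_LIB_SIZE,
                             sub_size: int = SUB_LIBRARY_SIZE, fp_rate: float = 0.01,
                             n_perm: int = 100, seed: int = 0,
                             bound: float = 0.02) -> FdrSummary:
    """Permutation FDR of a filtered sub-library from false-target-seeded sources.

    Two virtual library matrices of ``size_a`` and ``size_b`` entries are
    each seeded with ``floor(fp_rate * size)`` false targets; ``n_perm``
    random sub-libraries of ``sub_size`` entries are drawn uniformly without
    replacement from the pooled matrices, and each draw's empirical FDR is
    the fraction of false targets it contains.
    """
    if not (0.0 <= fp_rate < 1.0):
        raise ValueError("fp_rate must be in [0, 1)")
    if sub_size > size_a + size_b:
        raise ValueError("sub_size exceeds the pooled library size")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.zeros(size_a + size_b, dtype=bool)
    pool[:int(np.floor(fp_rate * size_a))] = True
    pool[size_a:size_a + int(np.floor(fp_rate * size_b))] = True
    fdrs = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(pool.size, size=sub_size, replace=False)
        fdrs[i] = pool[draw].mean()
    return FdrSummary(fdrs, bound)
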