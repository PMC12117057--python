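"""Data model, readers/writers and structural validation for dd-ABPP tables.

The canonical on-disk format for quantitative data is a UTF-8, tab-separated
long table with one row per (protein, peptide, transition, sample, extract)
and a raw linear-scale ``intensity`` column.  Missing intensities are empty
fields or ``NA`` on disk — never 0, which is a legal measured floor after
imputation.  Column names in foreign exports (OpenSWATH / SWATH2stats
variants) are mapped onto the canonical names through a dialect dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

EXTRACTS = ("total", "depleted")

QUANT_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "transition_id",
    "sample_id",
    "extract",
    "intensity",
    "decoy",
]

QUANT_KEY = ["protein_id", "peptide_seq", "transition_id", "sample_id", "extract"]

DESIGN_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "survival",
    "age",
    "sex",
    "smoking",
    "tumor_cell_pct",
]

ENZYME_CLASSES = ("serine_protease", "metabolic_SH", "non_annotated", "inactive")

EVIDENCE_TIERS = ("experimental", "predicted", "any")


class FormatError(ValueError):
    """Input file violates the expected format or a controlled vocabulary."""


class IntegrityError(ValueError):
    """Input is well-formed but internally inconsistent (duplicates, pairing)."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


@dataclass
class PairedQuantTable:
    """Long-format transition intensities for paired total/depleted extracts.

    ``data`` holds the canonical columns of :data:`QUANT_COLUMNS`.  Intensities
    are linear scale; any log2 transform is an explicit downstream operation.
    Decoy rows are carried on input but excluded from all statistics unless
    ``include_decoys`` is requested explicitly.
    """

    data: pd.DataFrame
    peptide_fdr_threshold: float | None = None  # upstream ID filter, metadata only

    def __post_init__(self) -> None:
        _require_columns(self.data, QUANT_COLUMNS[:6], "quant table")
        if "decoy" not in self.data.columns:
            self.data = self.data.assign(decoy=False)
        self.data = self.data[QUANT_COLUMNS].reset_index(drop=True)
        bad = set(self.data["extract"].unique()) - set(EXTRACTS)
        if bad:
            raise FormatError(f"unknown extract label(s): {sorted(bad)}")
        dup = self.data.duplicated(QUANT_KEY)
        if dup.any():
            key = tuple(self.data.loc[dup.idxmax(), QUANT_KEY])
            raise IntegrityError(f"duplicate quant key {key}")
        neg = self.data["intensity"].dropna() < 0
        if neg.any():
            raise FormatError("negative intensity encountered; intensities are linear scale")

    def targets(self) -> pd.DataFrame:
        """Non-decoy rows (the default statistical universe)."""
        return self.data[~self.data["decoy"]]

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.targets()["protein_id"].unique())

    def log2_intensity(self) -> pd.Series:
        """log2 of the intensity column; missing and zero stay missing/-inf-free."""
        with np.errstate(divide="ignore"):
            out = np.log2(self.data["intensity"].astype(float))
        return out.replace(-np.inf, np.nan)

    def write(self, path) -> None:
        out = self.data.copy()
        out["decoy"] = out["decoy"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class CohortDesign:
    """Sample annotation: patient pairing, tissue, survival class, confounders.

    The condition label is the tissue × survival-class cross (for example
    ``T_long``); it is derived once at construction and used everywhere a
    per-condition quantity is computed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, DESIGN_COLUMNS[:4], "design table")
        df = self.data.copy()
        for col, vocab in [("tissue", {"T", "N"}), ("survival", {"long", "short"})]:
            vals = df[col].astype(str)
            bad = df.loc[~vals.isin(vocab) | df[col].isna(), "sample_id"].tolist()
            if bad:
                raise FormatError(f"invalid {col} value for sample(s) {bad}")
        dup = df.duplicated(["patient_id", "tissue"])
        if dup.any():
            pat = df.loc[dup.idxmax(), ["patient_id", "tissue"]]
            raise IntegrityError(
                f"patient {pat['patient_id']!r} has more than one {pat['tissue']} sample"
            )
        if df["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample_id in design")
        df["condition"] = df["tissue"].astype(str) + "_" + df["survival"].astype(str)
        for col in ("age", "sex", "smoking", "tumor_cell_pct"):
            if col not in df.columns:
                df[col] = np.nan
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def condition_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id, "condition"]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in design")
        return row.iloc[0]

    def samples_in(self, condition: str) -> list[str]:
        return self.data.loc[self.data["condition"] == condition, "sample_id"].tolist()

    def write(self, path) -> None:
        self.data.drop(columns=["condition"]).to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class EnzymeCatalog:
    """Query list of serine-hydrolase identifiers with class labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, ["protein_id", "enzyme_class"], "enzyme catalog")
        bad = set(self.data["enzyme_class"]) - set(ENZYME_CLASSES)
        if bad:
            raise FormatError(f"unknown enzyme class(es): {sorted(bad)}")
        if self.data["protein_id"].duplicated().any():
            raise IntegrityError("duplicate protein_id in enzyme catalog")
        if "catalytic_ok" not in self.data.columns:
            self.data = self.data.assign(
                catalytic_ok=self.data["enzyme_class"] != "inactive"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def ids(self) -> set[str]:
        return set(self.data["protein_id"])

    def __len__(self) -> int:
        return len(self.data)

    def class_counts(self) -> pd.Series:
        return self.data["enzyme_class"].value_counts()


@dataclass
class InteractionSet:
    """Undirected protein–protein edges with an evidence tier per edge.

    Self-edges are dropped (with a warning at read time); duplicate edges in
    either orientation collapse to one.  Neighborhood queries are backed by a
    :class:`networkx.Graph` and are deterministic (sorted output).
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["protein_a", "protein_b", "evidence"]))

    def __post_init__(self) -> None:
        _require_columns(self.edges, ["protein_a", "protein_b"], "interaction set")
        df = self.edges.copy()
        if "evidence" not in df.columns:
            df["evidence"] = "any"
        bad = set(df["evidence"]) - set(EVIDENCE_TIERS)
        if bad:
            raise FormatError(f"unknown evidence tier(s): {sorted(bad)}")
        df = df[df["protein_a"] != df["protein_b"]]
        a = df[["protein_a", "protein_b"]].min(axis=1)
        b = df[["protein_a", "protein_b"]].max(axis=1)
        df = pd.DataFrame({"protein_a": a, "protein_b": b, "evidence": df["evidence"].values})
        # experimental evidence wins over predicted/any when duplicated
        order = {"experimental": 0, "predicted": 1, "any": 2}
        df = df.sort_values("evidence", key=lambda s: s.map(order), kind="stable")
        df = df.drop_duplicates(["protein_a", "protein_b"], keep="first")
        self.edges = df.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def subset(self, evidence: str) -> "InteractionSet":
        """Edges at or above an evidence tier; ``any`` keeps everything."""
        if evidence == "any":
            return self
        return InteractionSet(self.edges[self.edges["evidence"] == evidence].copy())

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges[["protein_a", "protein_b"]].itertuples(index=False))
        return g

    def neighbors(self, node: str, degree: int = 1) -> set[str]:
        """All nodes within graph distance ``degree`` of ``node`` (excl. itself)."""
        g = self.graph()
        if node not in g:
            return set()
        reached = nx.single_source_shortest_path_length(g, node, cutoff=degree)
        return {n for n, d in reached.items() if d >= 1}

    def has_edge(self, a: str, b: str, evidence: str = "any") -> bool:
        lo, hi = min(a, b), max(a, b)
        rows = self.edges[(self.edges["protein_a"] == lo) & (self.edges["protein_b"] == hi)]
        if rows.empty:
            return False
        return evidence == "any" or (rows["evidence"] == evidence).any()

    def write(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


DEFAULT_DIALECT = {c: c for c in QUANT_COLUMNS}


def read_quant_table(
    path,
    dialect: dict | None = None,
    casefold_extract: bool = False,
    peptide_fdr_threshold: float | None = None,
) -> PairedQuantTable:
    """Read a long-format paired quant TSV into a :class:`PairedQuantTable`.

    Parameters
    ----------
    dialect
        Mapping from canonical column name to the column name in the file,
        for foreign exports.  Unlisted columns use their canonical name.
    casefold_extract
        Lower-case the extract labels before validation (``"Depleted"`` →
        ``"depleted"``).
    peptide_fdr_threshold
        The upstream peptide-identification FDR the table was filtered at;
        recorded as metadata only (the reader accepts pre-filtered tables).
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=False)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    df = df.rename(columns=rename)
    _require_columns(df, QUANT_COLUMNS[:6], "quant table")
    if casefold_extract:
        df["extract"] = df["extract"].astype(str).str.lower()
    if "decoy" in df.columns:
        df["decoy"] = df["decoy"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    return PairedQuantTable(df, peptide_fdr_threshold=peptide_fdr_threshold)


def read_design(path) -> CohortDesign:
    """Read the sample-annotation TSV into a :class:`CohortDesign`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=False)
    _require_columns(df, DESIGN_COLUMNS[:4], "design table")
    missing_surv = df["survival"].isna() | (df["survival"].astype(str).str.strip() == "")
    if missing_surv.any():
        raise FormatError(
            f"empty survival for sample(s) {df.loc[missing_surv, 'sample_id'].tolist()}"
        )
    for col in ("age", "sex", "smoking", "tumor_cell_pct"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return CohortDesign(df)


def read_catalog(path) -> EnzymeCatalog:
    """Read the enzyme query-list TSV (protein_id, enzyme_class[, catalytic_ok])."""
    df = pd.read_csv(path, sep="\t")
    if "catalytic_ok" in df.columns:
        df["catalytic_ok"] = df["catalytic_ok"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )
    return EnzymeCatalog(df)


def read_interactions(path) -> InteractionSet:
    """Read an edge-list TSV (protein_a, protein_b[, evidence]); dedup, drop self-edges."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein_a", "protein_b"], "interaction set")
    n_self = int((df["protein_a"] == df["protein_b"]).sum())
    if n_self:
        warnings.warn(f"dropped {n_self} self-edge(s)", stacklevel=2)
    return InteractionSet(df)


@dataclass
class PairingReport:
    """Per-sample pairing between the total and depleted extracts.

    ``matched`` counts transitions observed (non-missing) in both extracts of
    the sample — the set eligible for depletion-ratio sums; ``orphans`` counts
    transitions present in exactly one extract.  A sample with zero matched
    transitions is flagged unusable, not fatal.
    """

    per_sample: pd.DataFrame  # sample_id, matched, orphans, usable

    @property
    def unusable(self) -> list[str]:
        return self.per_sample.loc[~self.per_sample["usable"], "sample_id"].tolist()


def validate_pairing(quant: PairedQuantTable, design: CohortDesign) -> PairingReport:
    """Check every design sample for transitions present in both extracts."""
    df = quant.targets()
    df = df[df["intensity"].notna()]
    rows = []
    for sample in design.samples:
        sub = df[df["sample_id"] == sample]
        key = ["protein_id", "peptide_seq", "transition_id"]
        tot = set(map(tuple, sub.loc[sub["extract"] == "total", key].values))
        dep = set(map(tuple, sub.loc[sub["extract"] == "depleted", key].values))
        matched = len(tot & dep)
        orphans = len(tot ^ dep)
        rows.append({"sample_id": sample, "matched": matched,
                     "orphans": orphans, "usable": matched > 0})
    extra = set(df["sample_id"].unique()) - set(design.samples)
    if extra:
        raise IntegrityError(f"quant table contains undeclared sample(s) {sorted(extra)}")
    return PairingReport(pd.DataFrame(rows))
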