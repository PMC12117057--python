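"""Synthetic paired-extract cohorts, interactomes and mutation tables.

The generator emulates the dd-ABPP measurement model: one tissue lysate is
split into two aliquots; the "total" aliquot is measured as is, the
"depleted" aliquot loses the active fraction ``alpha`` of each probe-reactive
enzyme on the capture beads, so on the linear intensity scale

    depleted = total * (1 - alpha) * 2**eps,    eps ~ Normal(0, noise_sd_log2)

with independent multiplicative noise on both extracts.  Housekeeping-like
internal-standard proteins (``HK`` id namespace) always have ``alpha = 0``;
interactor proteins coupled to an enzyme are co-depleted proportionally to
that enzyme's active fraction.  Every emitted table is reproducible from the
seed, and the planted truth is returned alongside the data for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ddabpp.io import CohortDesign, InteractionSet, PairedQuantTable

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ParameterError(ValueError):
    """Simulation parameter outside its legal range."""


@dataclass
class SimulationParams:
    """Knobs of the paired-cohort generator.

    The default cohort mirrors the discovery layout: 12 patients each
    contributing one tumor (T) and one adjacent nontumor (N) sample, split
    into long/short survival halves — 4 conditions x 6 samples.  Baseline
    transition abundances are log-normal (log2 mean 14, sd 2), spanning a
    DIA-like dynamic range; per-sample run shifts (log2 sd 0.3) emulate LC-MS
    drift and are shared by the two extracts of a sample, while
    ``extract_effect_sd`` optionally adds per-run (sample x extract) drift
    that only ISP normalization can remove.
    """

    n_patients: int = 12
    n_enzymes: int = 50
    n_background_proteins: int = 100
    n_isp_proteins: int = 20
    peptides_per_protein: int = 2
    transitions_per_peptide: int = 3
    alpha: dict = field(default_factory=dict)  # condition -> {enzyme_id: fraction}
    noise_sd_log2: float = 0.2
    missing_rate: float = 0.0
    missing_mechanism: str = "mcar"  # or "censored" (left-censored, low-intensity)
    codepletion_couplings: list = field(default_factory=list)  # (enzyme, partner, strength)
    class_effects: dict = field(default_factory=dict)  # (protein, condition) -> log2 offset
    baseline_log2_mean: float = 14.0
    baseline_log2_sd: float = 2.0
    biological_sd_log2: float = 0.5
    run_effect_sd: float = 0.3
    extract_effect_sd: float = 0.0
    isp_noise_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, entry in self.alpha.items():
            for enz, a in entry.items():
                if not (0.0 <= a <= 1.0):
                    raise ParameterError(f"alpha[{cond}][{enz}]={a} outside [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.noise_sd_log2 < 0:
            raise ParameterError("noise_sd_log2 must be >= 0")
        if self.missing_mechanism not in ("mcar", "censored"):
            raise ParameterError(f"unknown missing mechanism {self.missing_mechanism!r}")

    @property
    def enzyme_ids(self) -> list[str]:
        return [f"SH{i:03d}" for i in range(1, self.n_enzymes + 1)]

    @property
    def background_ids(self) -> list[str]:
        return [f"BG{i:03d}" for i in range(1, self.n_background_proteins + 1)]

    @property
    def isp_ids(self) -> list[str]:
        return [f"HK{i:03d}" for i in range(1, self.n_isp_proteins + 1)]


@dataclass
class GroundTruth:
    """Planted parameters returned with every simulated cohort."""

    alpha: pd.DataFrame  # condition x protein effective active fractions
    coupled_pairs: list  # (enzyme, partner, strength)
    class_effects: dict  # (protein, condition) -> log2 abundance offset

    def write(self, path) -> None:
        long = self.alpha.stack().rename("alpha").reset_index()
        long.columns = ["condition", "protein_id", "alpha"]
        long.to_csv(path, sep="\t", index=False)


def _make_design(params: SimulationParams, rng: np.random.Generator) -> CohortDesign:
    rows = []
    half = params.n_patients // 2
    for i in range(params.n_patients):
        patient = f"P{i + 1:02d}"
        survival = "long" if i < half else "short"
        age = int(rng.integers(50, 76))
        sex = int(rng.integers(0, 2))
        smoking = int(rng.integers(0, 2))
        for tissue in ("T", "N"):
            rows.append({
                "sample_id": f"{patient}_{tissue}",
                "patient_id": patient,
                "tissue": tissue,
                "survival": survival,
                "age": age,
                "sex": sex,
                "smoking": smoking,
                "tumor_cell_pct": float(rng.integers(30, 91)) if tissue == "T" else np.nan,
            })
    return CohortDesign(pd.DataFrame(rows))


def _peptide_seqs(n: int, rng: np.random.Generator, min_len: int = 8,
                  max_len: int = 18) -> list[str]:
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return ["".join(rng.choice(_AA, size=L)) for L in lengths]


def simulate_cohort(params: SimulationParams):
    """Generate a paired total/depleted cohort with known ground truth.

    Returns
    -------
    (PairedQuantTable, CohortDesign, GroundTruth)
    """
    rng = np.random.default_rng(params.seed)
    design = _make_design(params, rng)
    samples = design.samples
    conditions = design.conditions
    n_samples = len(samples)

    proteins = params.enzyme_ids + params.background_ids + params.isp_ids
    ppp, tpp = params.peptides_per_protein, params.transitions_per_peptide
    n_prot = len(proteins)
    n_feat = n_prot * ppp * tpp

    # effective per-condition active fraction for every protein
    alpha_eff = pd.DataFrame(0.0, index=conditions, columns=proteins)
    for cond, entry in params.alpha.items():
        if cond not in alpha_eff.index:
            raise ParameterError(f"alpha refers to unknown condition {cond!r}")
        for enz, a in entry.items():
            if enz not in alpha_eff.columns:
                raise ParameterError(f"alpha refers to unknown protein {enz!r}")
            alpha_eff.loc[cond, enz] = a
    for enz, partner, strength in params.codepletion_couplings:
        if partner not in alpha_eff.columns or enz not in alpha_eff.columns:
            raise ParameterError(f"coupling refers to unknown protein ({enz}, {partner})")
        coupled = (strength * alpha_eff[enz]).clip(0.0, 1.0)
        alpha_eff[partner] = np.maximum(alpha_eff[partner], coupled)

    prot_of_feat = np.repeat(np.arange(n_prot), ppp * tpp)
    pep_seqs = _peptide_seqs(n_prot * ppp, rng)
    pep_of_feat = np.repeat(np.arange(n_prot * ppp), tpp)

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n_feat)
    # per-(protein, sample) biological abundance variation, shared by the two
    # aliquots of a sample (the split happens after lysis) — cancels in ratios
    bio = (rng.normal(0.0, params.biological_sd_log2, size=(n_prot, n_samples))
           if params.biological_sd_log2 > 0 else np.zeros((n_prot, n_samples)))
    run_shift = rng.normal(0.0, params.run_effect_sd, size=n_samples)
    extract_shift = (
        rng.normal(0.0, params.extract_effect_sd, size=(n_samples, 2))
        if params.extract_effect_sd > 0 else np.zeros((n_samples, 2))
    )

    noise_scale = np.where(
        np.isin(prot_of_feat, np.arange(n_prot - params.n_isp_proteins, n_prot)),
        params.isp_noise_factor * params.noise_sd_log2,
        params.noise_sd_log2,
    )
    eps = (
        rng.normal(0.0, 1.0, size=(n_feat, n_samples, 2)) * noise_scale[:, None, None]
        if params.noise_sd_log2 > 0 else np.zeros((n_feat, n_samples, 2))
    )

    cond_of_sample = np.array([design.condition_of(s) for s in samples])
    alpha_mat = alpha_eff.loc[cond_of_sample, :].to_numpy().T  # protein x sample
    with np.errstate(divide="ignore"):
        log2_keep = np.where(alpha_mat >= 1.0, -np.inf, np.log2(1.0 - alpha_mat))

    offset = np.zeros((n_prot, n_samples))
    for (prot, cond), shift in params.class_effects.items():
        if prot not in proteins:
            raise ParameterError(f"class effect refers to unknown protein {prot!r}")
        offset[proteins.index(prot), :] += np.where(cond_of_sample == cond, shift, 0.0)

    common = (baseline[:, None] + run_shift[None, :]
              + (bio + offset)[prot_of_feat])
    log2_total = common + extract_shift[None, :, 0] + eps[:, :, 0]
    log2_dep = (common + extract_shift[None, :, 1]
                + log2_keep[prot_of_feat] + eps[:, :, 1])
    total = np.exp2(log2_total)
    depleted = np.exp2(log2_dep)
    # fully removed signal (alpha == 1) is absent, i.e. missing, not zero
    depleted[~np.isfinite(depleted)] = np.nan

    intensity = np.stack([total, depleted], axis=2).ravel()  # feat x sample x extract
    if params.missing_rate > 0:
        if params.missing_mechanism == "mcar":
            drop = rng.random(intensity.shape) < params.missing_rate
        else:  # left-censored: low-intensity cells are more likely to drop
            order = np.argsort(np.argsort(np.where(np.isnan(intensity), np.inf, intensity)))
            pct = order / max(len(intensity) - 1, 1)
            drop = rng.random(intensity.shape) < np.clip(
                2.0 * params.missing_rate * (1.0 - pct), 0.0, 1.0)
        intensity = np.where(drop, np.nan, intensity)

    prot_arr = np.asarray(proteins)[prot_of_feat]
    pep_arr = np.asarray(pep_seqs)[pep_of_feat]
    trans_arr = np.array([f"t{i % tpp + 1}" for i in range(n_feat)])
    table = pd.DataFrame({
        "protein_id": np.repeat(prot_arr, n_samples * 2),
        "peptide_seq": np.repeat(pep_arr, n_samples * 2),
        "transition_id": np.repeat(trans_arr, n_samples * 2),
        "sample_id": np.tile(np.repeat(samples, 2), n_feat),
        "extract": np.tile(["total", "depleted"], n_feat * n_samples),
        "intensity": intensity,
        "decoy": False,
    })
    truth = GroundTruth(
        alpha=alpha_eff,
        coupled_pairs=list(params.codepletion_couplings),
        class_effects=dict(params.class_effects),
    )
    return PairedQuantTable(table), design, truth


def simulate_interactome(
    n_nodes: int,
    n_edges: int,
    planted: set | None = None,
    seed: int = 0,
    nodes: list[str] | None = None,
    evidence_tiers: tuple = ("experimental", "predicted"),
) -> InteractionSet:
    """Erdős–Rényi-style random edge set plus always-present planted edges."""
    rng = np.random.default_rng(seed)
    if nodes is None:
        nodes = [f"N{i:04d}" for i in range(1, n_nodes + 1)]
    if len(nodes) != n_nodes:
        raise ParameterError("len(nodes) must equal n_nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ParameterError(f"n_edges={n_edges} exceeds {max_edges} possible edges")
    node_set = set(nodes)
    planted = planted or set()
    planted_norm = []
    for a, b in planted:
        if a not in node_set or b not in node_set:
            raise ParameterError(f"planted edge ({a}, {b}) references unknown node")
        planted_norm.append((min(a, b), max(a, b)))

    idx = rng.choice(max_edges, size=n_edges, replace=False)
    # map flat index -> (i, j) over the upper triangle
    i = (n_nodes - 2 - np.floor(
        np.sqrt(-8 * idx + 4 * n_nodes * (n_nodes - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (idx + i + 1 - n_nodes * (n_nodes - 1) // 2
         + (n_nodes - i) * (n_nodes - i - 1) // 2).astype(int)
    arr = np.asarray(nodes)
    tiers = rng.choice(evidence_tiers, size=n_edges)
    edges = pd.DataFrame({"protein_a": arr[i], "protein_b": arr[j], "evidence": tiers})
    if planted_norm:
        extra = pd.DataFrame(planted_norm, columns=["protein_a", "protein_b"])
        extra["evidence"] = "experimental"
        edges = pd.concat([extra, edges], ignore_index=True)
    return InteractionSet(edges)


def simulate_mutation_table(
    n_patients: int,
    anchor_rate: float,
    gene_rates: dict,
    cooccurrence_boost: dict | None = None,
    anchor_gene: str = "ANCHOR",
    seed: int = 0,
) -> pd.DataFrame:
    """Binary patient x gene mutation matrix with an anchor oncogene.

    A gene with boost ``b > 1`` mutates at rate ``min(1, rate * b)`` among
    anchor-mutated patients and ``rate / b`` otherwise, so ``b = 1`` is the
    independence null and ``b -> inf`` makes the gene co-occur exclusively
    with the anchor.
    """
    if not (0.0 <= anchor_rate <= 1.0):
        raise ParameterError("anchor_rate must be in [0, 1]")
    for g, r in gene_rates.items():
        if not (0.0 <= r <= 1.0):
            raise ParameterError(f"gene rate for {g} outside [0, 1]")
    boosts = dict(cooccurrence_boost or {})
    rng = np.random.default_rng(seed)
    patients = [f"PT{i:04d}" for i in range(1, n_patients + 1)]
    anchor = rng.random(n_patients) < anchor_rate
    data = {anchor_gene: anchor}
    for gene, rate in gene_rates.items():
        b = boosts.get(gene, 1.0)
        if np.isinf(b):
            p_pos, p_neg = 1.0, 0.0
        else:
            p_pos = min(1.0, rate * b)
            p_neg = rate / b if b >= 1 else rate
        p = np.where(anchor, p_pos, p_neg)
        data[gene] = rng.random(n_patients) < p
    return pd.DataFrame(data, index=pd.Index(patients, name="patient_id"))
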