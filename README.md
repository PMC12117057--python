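# ddabpp — depletion-dependent activity-based protein profiling

`ddabpp` analyses paired DIA/SWATH proteomics experiments in which one
aliquot of a tissue extract is measured untouched (**total**) while the
second is reacted with an activity-based probe and depleted of the
captured, catalytically **active** enzymes on beads (**depleted**).
Comparing the two extracts turns an ordinary abundance measurement into an
activity measurement: whatever fraction of an enzyme was active is exactly
the fraction of its signal that disappears from the depleted extract.

The package is aimed at proteomics groups running serine-hydrolase (or any
probe-addressable enzyme family) profiling on clinical cohorts: it takes
long-format transition intensity tables, a sample annotation table, an
enzyme query list and a protein–protein interaction edge list, and produces
per-enzyme active fractions, differential activity statistics, co-depletion
interactome enrichment and cross-validated discriminant signatures.

## The model

For an enzyme *E* with active fraction α, the depleted aliquot retains
(1 − α) of *E*'s molecules, so over the *k* confident peptides whose
transitions are observed in **both** extracts of a sample:

```
log2ΔInt = log2( Σᵢ dep.intensityᵢ[E] ) − log2( Σᵢ tot.intensityᵢ[E] )
RADDi(E) = 1 − 2^log2ΔInt                  (clamped to [0, 1])
```

RADDi (relative activity-dependent depletion index) recovers α exactly in
the noiseless limit, since log2ΔInt → log2(1 − α).

Because technical noise also moves ratios, an enzyme's per-sample ratios in
each condition are gated against a technical-noise reference: the pooled
depletion ratios of **internal standard peptides** (ISPs), endogenous
housekeeping/cytoskeletal peptides selected by five stability filters
(candidate membership, <5 % missingness, variance equality F-test p > 0.2,
paired Pearson r > 0.6 with p < 0.05, length ≥ 8 residues).  The gate is a
one-sided two-sample Kolmogorov–Smirnov test (R `ks.test` convention,
`alternative = "greater"`: enzyme ratios stochastically smaller, i.e. more
depleted), p = exp(−2·m·n·D⁺²/(m+n)).  Where the gate fails, RADDi is set
to 0.

Downstream layers follow the same paired logic: non-enzyme proteins whose
ratios shift (two-sided KS) are **co-depleted** candidate interactors of the
captured enzymes, tested for enrichment among known 1st/2nd-degree
interactors with permutation nulls and one-tailed normal (pnorm-style)
z-tests; activity and co-depletion matrices feed sparse PLS-DA and
DIABLO-style multi-block integration with 5-fold cross-validated,
centroid-distance consensus-model tuning; differential testing uses the
family matched to each layer (Gaussian for log2 abundance, quasibinomial
probit for zero-inflated RADDi proportions, Poisson for spectral counts)
with age/sex/smoking confounders and BH FDR.

## Worked example

Simulate a 24-sample cohort (4 conditions × 6 samples) with two active
enzymes planted (SH001: α = 0.60 in long-survival tumors and 0.85 in
short-survival tumors; SH002: α = 0.25 in both tumor conditions), select
ISPs, normalize and fit the activity model:

```python
import pandas as pd
from ddabpp import (SimulationParams, simulate_cohort, select_isp,
                    IspCriteria, normalize_by_isp, ActivityModel, EnzymeCatalog)

alpha = {"T_long": {"SH001": 0.60, "SH002": 0.25},
         "T_short": {"SH001": 0.85, "SH002": 0.25}}
params = SimulationParams(n_enzymes=3, n_background_proteins=20,
                          n_isp_proteins=10, alpha=alpha,
                          noise_sd_log2=0.1, seed=42)
quant, design, truth = simulate_cohort(params)
isp = select_isp(quant, IspCriteria(candidate_ids=set(params.isp_ids)))
quant = normalize_by_isp(quant, isp)
catalog = EnzymeCatalog(pd.DataFrame({"protein_id": params.enzyme_ids,
                                      "enzyme_class": "metabolic_SH"}))
results = ActivityModel(quant, design, isp, catalog).fit()
print(results)
print(results.condition_means().round(3))
```

Output:

```
Activity profile summary (RADDi, KS-gated)
  enzymes: 3, samples: 24
  gate level alpha = 0.05
           enzymes_tested  enzymes_gated  mean_raddi_gated
condition
N_long                3.0            0.0               NaN
N_short               3.0            0.0               NaN
T_long                3.0            2.0           0.40345
T_short               3.0            2.0           0.55663

condition  N_long  N_short  T_long  T_short
enzyme_id
SH001         0.0      0.0   0.596    0.852
SH002         0.0      0.0   0.211    0.261
SH003         0.0      0.0   0.000    0.000
```

The planted active fractions are recovered (0.60 → 0.596, 0.85 → 0.852,
0.25 → 0.211/0.261 under noise), the inactive enzyme SH003 and all
nontumor conditions are gated to 0, and the per-condition means are the
quantities a cohort-level activity map reports.

The same stages are available as a CLI (`ddabpp simulate | select-isp |
normalize | impute | raddi | differential | interactome | classify |
libfdr | pipeline`); `ddabpp pipeline --config run.yaml --out dir/` chains
them end to end and writes a manifest with every stage's seed and output
checksums.

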