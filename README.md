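# denovostruct

Structural-evolution analysis of **de novo proteins** (genes born from
ancestrally noncoding sequence) versus **gene duplicates**, on the *Oryza*
branch ladder br1–br9 (~15 My of divergence). The package computes every
per-protein descriptor the comparison needs — intrinsic structural disorder
(ISD), secondary-structure element proportions, amino-acid composition,
molecular weight, net charge and isoelectric point, hydrophobicity, molecular
recognition features (MoRFs), pLDDT folding-confidence and TM-score
fold-similarity classes — plus complex-interface contact statistics,
ΔG↔Kd binding thermodynamics, Pearson coexpression partner selection, and
synteny-based gene age dating. A synthetic-data generator plants known ground
truth for every stage, so the whole pipeline is testable without downloads.

## The statistical core

Each gene is assigned an origination branch *b* with divergence time *t_b*
(Mya). For a per-protein metric *m* (e.g. the ISD ratio — the fraction of
residues in disordered regions — or the element proportion
*P_i = l_i / l_total* for *i* ∈ {coil, α helix, 3₁₀ helix, β strand}), the
per-branch **medians** are regressed on time by ordinary least squares:

```
median_b(m) = β₀ + β₁ · t_b + ε
```

with the two-sided t-test on β₁ and adjusted R². The evolutionary rate is
read off as |β₁|×100 "% per protein per million years"; extrapolation
`t* = (benchmark − β₀)/β₁` answers how long the trend needs to reach a
reference level. Supporting statistics: Wilcoxon rank-sum comparisons (exact
for small tie-free samples, normal approximation with tie and continuity
corrections otherwise), per-amino-acid Pearson age correlations, and risk or
odds ratios with Wald intervals for 2×2 count comparisons. Interface contacts
follow the 5.5 Å heavy-atom convention, affinity uses ΔG = R·T·ln(Kd) with
the −10 kcal/mol (Kd 10⁻⁸ M) high-affinity cutoff.

Because the observational cohort is not shipped, rate claims are validated by
**parameter recovery**: cohorts are simulated under a planted median-trend
law (per-protein noise on the logit scale, which leaves branch medians
exactly on the law), pushed through the real descriptor + median + OLS
pipeline, and the recovered slope is compared with the planted one.

## Worked example

```bash
python analysis/02_isd_trends.py
```

prints

```
denovo: ISD median trend slope -0.1421/My (14.2% per protein per My), p = 6.17e-06, adj R^2 = 0.995
  -> at this rate, de novo proteins reach the duplicate median disorder (0.31) in ~4.6 My
duplicate: ISD median trend slope -0.1005/My (10.1% per protein per My), p = 0.000258, adj R^2 = 0.967
```

i.e. for one simulated cohort (six branches, 200 proteins each) the de novo
disorder decay is recovered at ≈14% per My versus ≈10% per My for
duplicates, and linear extrapolation puts the de novo cohort at the
duplicates' median disorder level in under five million years. The numbered
scripts under `analysis/` run the remaining stages (secondary structure,
composition and physicochemistry, age dating, coexpression, complex
interfaces) and write their tables under `results/`; large regenerable
simulation artifacts go to `scratch/`.

The same pipeline is scriptable via the CLI:

```bash
denovostruct simulate --preset denovo-isd --seed 1 --out sim
denovostruct describe --fasta sim/proteins.fasta --meta sim/meta.tsv \
    --disorder sim/disorder.tsv --out descriptors.tsv
denovostruct trends --descriptors descriptors.tsv --metric isd_ratio --out trends.tsv
```

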