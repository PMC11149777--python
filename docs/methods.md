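# Methods

## Model and procedure

The package treats structural evolution as a median-trend problem on a
phylostratigraphic ladder. Genes carry an origination branch br1..br9, each
mapped to a divergence time in Mya by a `BranchTable`. For any per-protein
metric, the per-branch median is the unit of analysis; medians are regressed
on branch time (or log₁₀ time) by ordinary least squares, and the slope is
the evolutionary rate. Medians rather than means are used throughout because
the per-protein distributions of disorder and element proportions are skewed
and bounded; the median is also what the generator's noise model preserves
exactly (below).

Assumptions: branch assignments are exchangeable within a branch (no
phylogenetic autocorrelation between proteins), branch times are known
constants, and the trend over the ~0.1–2.4 My window analysed is adequately
linear. Mixed models, PGLS, and bootstrap intervals on medians are
deliberately out of scope.

## Descriptors

* **ISD ratio** — fraction of residues called disordered. Probability tracks
  (Metapredict/AUCpreD-style) are binarized at 0.5 (≥ threshold =
  disordered; configurable, since upstream tools only publish the consensus
  track). A protein is *fully disordered* iff its ratio is exactly 1.0.
* **Secondary structure** — STRIDE one-letter strings; the default partition
  maps H,I→helix, G→3₁₀ helix, E→strand, B→bridge, C,T→coil. Counting turns
  as coil is what yields unstructured medians in the observed 40–47% range;
  the partition is a config knob and every row records which one was used.
  Proportions always sum to 1 under any total partition.
* **Molecular weight** — average residue masses plus one water, via
  Biopython; 'X'-masked residues are excluded.
* **Net charge / pI** — Henderson–Hasselbalch sums over the termini and the
  D,E,C,Y,H,K,R side chains. Default pKa set: EMBOSS (the ipc2 constants the
  original pI values came from are not published as a plain table); the set
  name travels with every output row. Net charge is monotonically
  non-increasing in pH, so the pI is found by bisection on [0, 14] to
  |charge| < 1e-4 and is unique.
* **Hydrophobicity** — mean per-residue Kyte–Doolittle value by default
  (the upstream method's exact formula is not specified; the scale name is
  recorded, and alternatives can be registered).
* **Folding confidence** — "an element over ten amino acids" is read
  strictly: a contiguous run of ≥ 11 residues each individually ≥ 0.9
  (high) or ≥ 0.7 (medium) pLDDT; anything else is low. The run reading
  (rather than SS-segment-mean) is the unambiguous, stricter choice.
* **Fold similarity** — median pairwise TM score: > 0.5 similar, < 0.17
  near-random, else intermediate.

pLDDT lives on [0,1] internally; the only division by 100 happens at PDB
ingestion, where the B-factor column carries 0–100 values.

## Interfaces and thermodynamics

Residue–residue contacts use the 5.5 Å any-heavy-atom cutoff (inclusive).
Raw RR counts are distinct residue pairs; the nonredundant ratio divides by
the total complex length (len_a + len_b). A second reading — distinct
interface residues over total length — is available because the phrasing
"adjusted with total protein length" is ambiguous. ΔG = R·T·ln(Kd) with
R = 1.987×10⁻³ kcal/(mol·K); the default temperature is 273.15 K because it
is the unique choice making the printed −10 kcal/mol ↔ Kd 10⁻⁸ M cutoff
pairing exact (298.15 K gives −10.9). Both the temperature and the cutoff
are configurable and recorded. Note the boundary subtlety: ΔG(10⁻⁸, 273.15)
= −9.998, which rounds to −10 but is not ≤ −10, so Kd exactly 10⁻⁸ M does
not itself classify as high-affinity under the inclusive cutoff.

## Age dating

Reciprocal best hits require a *unique* top score in both directions; a tied
top score drops the query (conservative; the alternative of keeping all tied
pairs inflates RBH counts). Synteny blocks chain anchors on the same
chromosome pair while at most five genes intervene on *both* genomes
(both-genome is the stricter reading of the published "no more than five
genes" criterion). A gene is present in an outgroup when it anchors a block
with ≥ 2 anchors. Branch assignment is oldest-presence-wins with no
contiguity requirement across intermediate branches — standard
phylostratigraphy, tolerant of lineage-specific loss; absence everywhere is
focal-specific (br1). The shipped branch times carry published anchors
(br4 ≈ 0.94, br5 ≈ 1.0, br6 = 2.41, depth ≈ 15 Mya) with interpolated
placeholders elsewhere; real analyses must supply timetree values.

The homology-detection-failure null is the linear scaling
n_source × (μ_focal/μ_source) × (t_focal/t_source); with the published
inputs (85 genes, 1.7×10⁻⁷ vs 6.5×10⁻⁹ subst/site/generation, 20 vs 2.4 My)
it gives 0.39 expected spurious young genes. Generation-time or unit
conversions that would shrink this further are not asserted; all four
factors are exposed.

## Coexpression

Pearson r on untransformed TPM with the two-sided t-transform p-value
(log-transform available but off by default, matching the upstream choice of
plain TPM). Partners are the top 30 by r among genes with raw p < 10⁻⁵
(adjusted-p reading not assumed); zero-variance genes are excluded with a
count, and ties break by gene id so output is deterministic.

## Synthetic cohorts: what they emulate and what they don't

The generator's defaults are the study conditions: six branches at
(0.1, 0.3, 0.5, 0.94, 1.0, 2.41) Mya, 200 proteins per branch, and planted
median-trend laws matching the fitted rates — ISD 0.97 − 0.14·t for the de
novo class and 0.55 − 0.099·t for duplicates (the duplicate intercept is
calibrated so the br6 median sits at the duplicates' overall median of 0.31,
the one anchor the class has); coil/helix/strand at −0.084/+0.041/+0.065
per My from intercepts 0.47/0.23/0.13 with the 3₁₀ helix flat at 2.8% and
the isolated bridge absorbing the residual; MoRF 0.05 + 0.023·t over
br2–br6; normalized hydrophobicity 0.35 + 0.048·t.

Per-protein spread is Gaussian on the logit scale (σ = 0.4–0.5), mapped back
through the logistic. Because the logistic is monotone and the noise has
zero median, the *median* of each branch lands exactly on the law — the
property that makes slope recovery unbiased — while values stay in (0, 1)
without clipping artifacts. Binary tracks realize the planted fraction by
rounding to the protein length (100–300 residues), adding only O(1/L)
discretization. SS strings are multinomial draws of length 300 at the branch
target proportions. The 181-protein bookkeeping cohort plants exactly 68
fully disordered proteins for the count-arithmetic check.

What the generator does **not** emulate: real sequence evolution
(substitution processes, indels, selection), correlations between
descriptors within a protein (disorder and composition are drawn
independently), phylogenetic non-independence, branch-specific sample-size
imbalance, or biophysically meaningful geometry in toy complexes (residues
are single pseudo-atoms placed to make the planted contact set exact, with a
> 1 Å margin around the cutoff). Passing recovery tests therefore shows the
*estimator pipeline* is correct and unbiased under the stated law + noise
model — not that real rice data would yield these rates.

Synteny fixtures interleave planted genes with an always-present old-gene
backbone so that removing any subset of young genes leaves anchor gaps ≤ 1;
a gene planted at branch b appears (with its conserved neighborhood) in the
outgroups that diverged after its origin (br2..b) and in none deeper.
Expression fixtures add Gaussian noise with sd σ_x·√(1/r² − 1) to the target
row, giving expected correlation r to the planted partners; clipping at 0 is
rare at the TPM-like scale used (mean 50, sd 20).

## Numerical choices

Bisection tolerance 1e-4 on charge (≈ 2e-4 pH); OLS via scipy's linregress
with adjusted R² = 1 − (1−R²)(n−1)/(n−2); flat-data fits (zero slope, zero
residual) report p = 1. Wilcoxon uses exact enumeration for tie-free samples
with n ≤ 12 and the tie/continuity-corrected normal approximation otherwise.
2×2 ratios use Wald intervals on the log scale, with a 0.5 continuity
addition on zero cells (error if disabled) and a saturated-margin fast path;
Fisher's exact p is available behind a flag. Contact boundary is inclusive
(≤ cutoff). Track positions are 1-based in files, 0-based in memory.
Multi-seed summaries derive child seeds from `SeedSequence([base, i])`, so
results depend only on (base seed, seed count).

## Problem sizes

Recovery runs use 50 seeds × 6 branches × 200 proteins (60,000 proteins per
metric; 50,000 for the five-branch MoRF preset) — enough that the mean
recovered slope has a standard error well under 2% of the planted value for
every preset, so the 10% acceptance band tests bias, not luck.

## Known limitations

* The placeholder branch times (br1–br3, br7–br8) are not literature values;
  conclusions sensitive to them require user-supplied times.
* The EMBOSS pKa set approximates, but does not reproduce, ipc2 pI values.
* The Kyte–Doolittle mean is a stand-in for the unspecified upstream
  hydrophobicity formula.
* `partner_filter` trusts its input table; it does not recompute disorder or
  coexpression from raw data.
* The toy-complex geometry cannot plant more contacts than
  min(len_a, len_b); dense interfaces need real structures.
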