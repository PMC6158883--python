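# Methods

This note documents the models and procedures implemented in `moonpipe`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not emulate.

## Interactor calling

**Model.** A protein observed in controlled IP-MS evidence is called a
high-confidence interactor of the bait iff

* for *each* of the two bait antibodies, the fraction of wild-type samples
  with ≥ `min_unique_peptides` (default 2) unique peptides is
  ≥ `min_fraction_per_bait_antibody` (default 0.5), and
* it has **no** record (≥ 1 peptide) in any *forbidden-group* sample — by
  default every knockout pull-down and the isotype control.

Absence of a record is treated exactly as a zero count throughout.

**Interpretation choices.** "Detected in 50 % of samples" is read per
antibody over wild-type samples only, with the ≥ 2-peptide threshold applied
per sample *before* the fraction, and the fraction compared with ≥ (so 3/4,
2/4 and 1/2 all pass at 0.5 — the only reading under which the canonical
reference table's `1/2` rows are callable). On the control side, *any* record
disqualifies — deliberately stricter than the wild-type threshold, since
"not detected in any" carries no count qualifier. The alternative reading
(wild-type detection at ≥ 1 peptide) remains available via
`min_unique_peptides=1`.

Reports are sorted by descending total wild-type peptide count, then protein
id, for deterministic output. Empty forbidden groups pass vacuously with a
warning rather than failing, so partial designs remain analysable.

**Limitations.** No spectral-level FDR model and no probabilistic scoring of
background binders (SAINT/CRAPome-style); counts are taken as given, and
isoform ambiguity upstream of the unique-peptide counts is out of scope.

## Co-expression scoring

Each compendium dataset is analysed *as deposited* — no cross-dataset
normalisation — matching the meta-analytic design this stage emulates.
Multi-probe features are collapsed to the probe with the highest mean signal
(missing values ignored; ties go to the lexicographically smallest feature
id, an arbitrary but deterministic rule).

The indicator x<sub>gd</sub> ∈ {0, 1} is, by default, 1 iff the
pairwise-complete Pearson correlation between gene *g* and the query is
≥ τ = 0.7. The threshold is one-sided: the indicator is meant to capture
co-induction, not anti-correlation. Construction of the indicator from a
per-dataset clustering is genuinely open design space; an alternative
co-cluster rule (average-linkage agglomeration on 1 − r, cut at 1 − τ, with
x = 1 for the query's cluster) is provided behind
`CoexpressionParams(indicator_rule="co_cluster")`. Every downstream formula
consumes only x<sub>gd</sub>, so the two rules are interchangeable.

Missingness is first-class: a gene with fewer than `min_samples` (default 6)
paired observations in a dataset, or any gene in a dataset whose query row
is absent/constant/under-measured, gets a *missing* indicator — distinct
from 0 — contributing nothing to either the overall score
w<sub>g</sub> = Σ<sub>d</sub> x<sub>gd</sub> or the dataset score
s<sub>d</sub> = Σ<sub>g∈S</sub> w<sub>g</sub> x<sub>gd</sub>, while reducing
the gene's recorded *coverage*. Genes with zero coverage are excluded from
ranked universes (low array representation must not masquerade as absence of
co-expression).

## Running-sum enrichment

The statistic is the weighted Kolmogorov–Smirnov running sum: along the
ranking (descending score, ties by gene id), hits add
|score|<sup>p</sup> / Σ<sub>hits</sub>|score|<sup>p</sup>, misses subtract
1/(N − |S|), and ES is the signed extremum (the positive extremum wins exact
ties). The weight exponent defaults to p = 1, the convention of the
statistic's standard implementation; p = 0 gives a rank-only variant (exactly
invariant under monotone score transforms, and antisymmetric under ranking
reversal). If all hit weights are zero the hit increments fall back to the
unweighted 1/|S|.

The null permutes gene labels — equivalently draws uniform same-size gene
sets — so no sample-level data are required. p-values use the add-one
estimator (1 + #extreme)/(n\_perm + 1): never zero, and super-uniform under
the null by construction. The default is two-sided on |ES|, because both
enrichment and depletion of the same set are scientifically relevant;
one-sided modes exist. Comparisons against the observed ES carry a 10⁻¹²
tolerance so that exact ES ties (common in small universes) cannot be
dropped by floating-point summation-order noise.

The permutation engine samples hit positions with replacement and rejects
rows containing duplicates (exact uniform sampling, far cheaper than partial
shuffles for |S| ≪ N), and evaluates ES per draw from the 2|S| candidate
extrema (just after each hit, just before each hit) rather than the full
walk.

**Percentile membership.** The count of set members "within" the
q-quantile (default 0.95) of all genes' overall scores uses an *inclusive*
comparison (score ≥ threshold). Overall scores are small-integer sums with
massive ties; when the quantile lands inside a tied block, a strict
comparison would arbitrarily drop the whole block, making the count unstable
at desk scale. Inclusive membership is stable and matches the everyday
meaning of "within the 95th percentile".

## Knockdown signatures and connectivity

Hairpins are ranked by the mean z-score of the target gene over each
hairpin's experiments (most negative = strongest knockdown) and the top k
(default 3) retained. The consensus signature is the *flat* gene-wise mean
over all surviving experiments — not a mean of per-cell-line means — after
excluding listed cell lines (those with too few replicates to trust).

The connectivity score between consensus signatures is this package's own
formulation of the CMap idea, since the online service's normalisation is
not public: raw similarity of *a* to *b* averages the enrichment score of
*a*'s top-n genes in *b*'s ranking with the negated enrichment of *a*'s
bottom-n genes (n = 150, rank-only weights); raw values are then
percentile-mapped against the batch pooled with its own negation — an odd
map, so sign survives, zero maps to zero, and the extremes hit exactly
±100 — and symmetrised by averaging, diagonal fixed at 100. Numerical
identity with any external service is *not* claimed; the conventional
|score| > 90 significance threshold is kept as a default constant.

Clustering of connectivity rows uses average linkage on correlation distance
1 − r (SciPy); constant rows get the maximal distance 2 to everything, with
a warning, rather than poisoning the matrix with NaNs.

## Network and screen corroboration

**Edge-count enrichment.** The null resamples uniform same-size node sets
from the background network — no degree preservation, matching the plain
"expected by chance" reading — with p = (1 + #{null ≥ obs})/(n\_draws + 1).
Hub-rich sets inflate this null, so a degree-stratified variant (quantile
bins, per-bin sampling) is provided. Background edges are kept only above a
confidence threshold (default 0.400 exclusive, the conventional
medium-confidence cut for STRING-style scores).

**Dependency screens.** Pearson correlation of every gene's dependency
profile against the query's, pairwise-complete over shared non-missing cell
lines (Achilles-style matrices are gappy and the per-gene n is recorded);
two-sided p from the exact t transform t = r√((n−2)/(1−r²)); Bonferroni over
the genes actually tested (n ≥ 3, non-degenerate variance).

**Half-life percentiles.** The query's percentile among the metabolic
enzymes *quantified in that cell line* (not the full enzyme list), computed
as the mean ascending rank (ties averaged) over the count, per cell line —
hence invariant under monotone transforms of the half-life scale. The
cumulative-frequency curve points are returned alongside.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seed through named substreams (one per input
class), so adding a generator never perturbs another's draws and identical
configs give bit-identical outputs. Defaults are the desk-scale study
conditions the pipeline is tested under:

* **IP-MS** — 200 proteins × the canonical 12-sample design (WT 4+2 bait,
  2 isotype; KO 2+2). 29 true interactors detected only in WT bait samples
  (per-sample probability 0.9, counts 1 + Poisson(3)); background binders
  stick to *every* sample with probability 0.3 (counts 1 + Poisson(1)); the
  bait detected in all WT bait samples. Under these conditions the filter is
  deliberately imperfect: a true interactor occasionally misses a detection
  and roughly one background binder in a hundred evades all six control
  samples, so measured precision/recall hover near, not at, 1.
* **Compendium** — 200 datasets × 500 genes × 20 samples, 20 datasets
  carrying a latent-factor module (the query + its 29 partners) at pairwise
  population correlation 0.9; optional second, attenuated, lower-mean probes
  exercise collapsing.
* **Signatures** — 12,000 genes × (5 hairpins × 9 cell lines) plus two
  sparse cell lines meant to be excluded; per-hairpin on-target depths
  (4.0, 3.5, 3.0, 1.0, 0.5 SD) make the strongest three identifiable; the
  planted depleted set loses 1.5 SD in every experiment.
* **Dependency** — 1,000 genes × 300 cell lines, a 10-gene block (query
  included) at pairwise correlation 0.6, 5 % missing entries.
* **Half-life** — 600 log-normal enzyme half-lives (median ≈ 40 h,
  log-sd 0.8) per cell line; the query is planted *between order statistics*
  so its rank percentile equals the requested quantile (default 0.05) to
  within 0.5/(m+1) by construction.
* **Network** — 500-node Erdős–Rényi background (edge probability 0.02) with
  the interactor set planted as a clique.

The generators emulate the *statistical structure* the pipeline keys on —
contamination, planted correlation, planted depletion, planted cliques —
not the marginal distributions of real platforms: no platform-specific
intensity distributions, no L1000 peak deconvolution, no batch effects, no
cross-species probe mapping. Passing the planted-truth tests therefore
demonstrates that each stage recovers the signal it is designed for under
its stated noise model; it does not certify performance on any particular
public dataset.

## Reference interactor table

`moonpipe.reference` curates the published 29-interactor table for MTHFD2
in HCT-116 cells: per protein, the fraction of wild-type samples per bait
antibody with ≥ 2 unique peptides, plus the MTHFD1 counter-example
(wild-type detections but knockout detections too). `reference_evidence()`
expands these fractions into a *synthetic* evidence table — which replicates
carry the detections and the exact counts are arbitrary deterministic
choices the calling rule is invariant to. Running the default filter over it
recovers exactly the 29 curated interactors with their fractions; it cannot
test rejection of the full unpublished background, since only the called
rows are public.

## Problem sizes and budgets

The test suite and acceptance script run entirely on the desk-scale sizes
above (chosen as the package's own test conditions): 1,000-table
filter-oracle equivalence, 100-replicate planted-dataset ranking and
depletion-power studies, 1,000-replicate type-I and family-wise-error
calibrations, and 10,000-permutation / 100,000-draw nulls in the acceptance
script, all completing in minutes on a single CPU.
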