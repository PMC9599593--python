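# Methods

This note documents the statistical procedures implemented in `painnets`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## GWAS processing

A study enters as a marker table (chrom, pos, id, ref, alt, maf, info,
pvalue). Three operations are applied in order:

* **QC filter** — keep markers with MAF strictly above 0.05 and imputation
  quality strictly above 0.3. Both inequalities are strict.
* **Top-fraction selection** — rank by −log10 p and keep the top
  ⌈fraction·n⌉ (default fraction 0.5). Boundary ties are broken by
  (chrom, pos) ascending so the selection is deterministic.
* **Iterative LD pruning** — "adjacent" is read as consecutive surviving
  markers in position order per chromosome. Each sweep scans adjacent
  pairs; when r² > 0.5 the member with the larger p-value is dropped (tie:
  the downstream marker). Sweeps repeat until one removes nothing. The
  procedure is idempotent and never removes a chromosome's most
  significant marker. Marker pairs absent from the LD table count as
  r² = 0.

Selection order is filter → rank/top-50% → LD prune. Study-level cohort
gates (sample size > 10,000, cases > 500) act on a study manifest, not on
markers.

## Marker-to-gene mapping

Two evidence paths, merged as a set union with provenance:

* **eQTL** — keep associations with qval ≤ 0.05 (inclusive) whose variant
  survived GWAS processing.
* **Proximity + regulatory evidence** — distance is measured to the
  nearest gene-body edge (0 inside the gene), boundary inclusive at 50 kb.
  Public regulatory-evidence resources score variants on an ordinal scale
  whose numeric recoding varies between analyses; scores are therefore
  consumed as an opaque integer where higher = stronger, thresholded
  strictly > 4. The recoding is an input-preparation concern, not
  pipeline logic.
  Markers without a score are excluded from this path only.

Shrinking either threshold can only shrink the map (monotonicity), which
the tests assert.

## Co-expression modules

Unsigned WGCNA-style network: adjacency a_ij = |cor(x_i, x_j)|^β with
Pearson correlation; constant genes correlate 0 (logged). The soft power β
is the smallest integer in 1..20 whose scale-free topology fit reaches
R² ≥ 0.85, computed as the R² of the log10 p(k) vs log10 k regression over
10 degree bins with a negative-slope requirement. Two guards matter:

* Powers that leave the network with mean connectivity < 1 are skipped.
  On pure noise the raw R² criterion turns spuriously high at large β
  because the adjacency is almost empty; requiring residual connectivity
  restores the intended behavior (noise falls through to the fallback).
* When no power qualifies, β = 6 is used with a logged warning — the
  conventional default for unsigned networks. The planted-factor synthetic
  data takes this path by design: latent-factor expression is not
  scale-free, exactly like the criterion intends.

Topological overlap is TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
(min(k_i, k_j) + 1 − a_ij) with k_i = Σ_{u≠i} a_iu, unit diagonal, clipped
to [0, 1]. Modules are flat clusters of average-linkage hierarchical
clustering on 1 − TOM cut at a fixed height (default 0.9); clusters under
10 genes go to the unassigned pool. A fixed-height cut was chosen over
dynamic tree cut deliberately: it is compact, fully deterministic, and
sufficient for planted-structure recovery; parity with the reference R
implementation is a non-goal. Module annotation uses one-sided Fisher
exact tests against the pathway collection with Bonferroni correction over
all pairs tested in the call; the annotation universe is the tissue's
expression gene set.

## MSEA and meta-analysis

Each mapped gene carries the maximum −log10 p over its markers
(equivalently the minimum p), plus its marker count. For a module, the
statistic is

    χ = Σ_i (O_i − E_i) / √(E_i + κ),   κ = 1,

over cutoffs at the top 50/25/10/5/1% quantiles of the scored universe;
O_i counts member genes above cutoff i and E_i = |module| × (universe
fraction above cutoff i). The null resamples same-size gene sets within
marker-count quartile strata, preserving gene-to-marker multiplicity (the
gene-length bias offset). The p-value is the one-sided Gaussian tail of
the studentized observed χ against the permutation moments rather than an
empirical rank — so p can fall below 1/n_perm, which the downstream
Stouffer combination requires. Default n_perm is 10,000 (2,000 in the
end-to-end pipeline); below 100 the null moments are unstable and the call
errors. BH FDR is applied across modules per study.

Meta-analysis: Z_i = Φ⁻¹(1 − p_i) with p clamped to [1e−300, 1 − 1e−16],
meta-Z = Σ Z_i / √k over the k (study × tissue) results containing the
module — the grid is flattened with equal weights since no weighting is
specified — meta-p = 1 − Φ(meta-Z), BH across modules, significance at
meta-FDR < 0.05.

Calibration is verified empirically: on null synthetic data the fraction
of random modules with p < 0.05 lies within [0.03, 0.07] (acceptance
suite, 300 modules).

## Overlap test and supernets

The overlap permutation test redraws BOTH lists uniformly without
replacement from the universe each permutation (this two-sided resampling
is equal in law to a hypergeometric draw, which provides the independent
oracle for testing). A success is a permuted overlap ≥ observed; p is
stored as (s + 1)/(n_perm + 1) and displayed as "< 1/n_perm" when s = 0.
The enrichment fold divides the observation by the permutation median,
falling back to the mean — flagged in the result — when the median is 0,
as happens for sparse overlaps like the pain-gene test. The implementation
selects subsets via per-row random keys (membership = key ≤ k-th smallest),
chunked to cap memory at ~0.3 GB for large universes.

At the published scale (799 modules, 105/106 significant, 34 shared) the
permutation fold is ≈ 2.4; the published value 2.62 would follow from a
null that preserves additional structure (e.g. per-tissue module counts),
which is not reconstructible from printed numbers alone — the pooled null
is implemented and this discrepancy is documented rather than tuned away.

Supernets: for each pathway significantly annotated to ≥ 1 significant
module in both conditions, the per-condition gene sets are the unions of
those modules' genes; a supernet (the union of both sides) is created only
when the intersection strictly exceeds 15% of each side.

## Weighted key-driver analysis

Candidate hubs are nodes with degree ≥ max(5, the 75th degree percentile);
both knobs are exposed because the original tool does not quantify
"sufficient" connectivity. The statistic W sums the weights of edges from
the hub to neighbors in the member set. The null permutes member labels
within degree-quartile strata — hub degree is the classic confounder of
neighborhood enrichment, and stratification removes it — giving one-sided
empirical p-values, BH FDR per (tissue, supernet) by default with a
Bonferroni option, significance at 0.05. Calibration on uniformly random
member sets is checked empirically ([0.03, 0.07] at nominal 0.05).

Consolidation counts, per gene, the tissues where it is significant for
BOTH conditions; genes with Ntissue ≥ 2 are conservative key drivers,
sorted by Ntissue descending then gene id. The KD subnetwork keeps the KDs
plus one-edge neighbors whose minimum mapped GWAS p is below 5×10⁻⁸ in at
least one condition; KDs without qualifying neighbors remain as isolated
nodes. Subnetwork pathway/GO annotation reuses the Fisher/Bonferroni
machinery with fold = observed/expected overlap.

## Mouse-model enrichment factor

EF = [E(model, tissue)/E(model, blood)] / [E(CTR, tissue)/E(CTR, blood)],
with a pseudocount (default 1.0) added to every expression value before
any ratio — the formula's source is silent on zeros, and an additive guard
keeps EF defined and scale-invariant in the limit of no zeros. Replicate
rows for a cell are averaged before the ratio; log2 EF is reported. A gene
is `up_both`/`down_both` when log2 EF clears the threshold (default 0)
with one sign across all tested tissues in both models, `discordant` when
the models carry opposite signs in some tissue, `mixed` otherwise
(including "did not change", |log2 EF| ≤ threshold).

## Synthetic study generator

The generator emulates the *statistical structure* the pipeline consumes,
at desk scale. Defaults: 600 genes on 6 chromosomes, 6 planted modules of
50 genes, 3 tissues × 120 samples, 2 studies per condition, ~3 markers per
gene (Poisson, min 1), LD blocks of 10 markers with r² = 0.8^distance,
signal shift 2.0 on z for the genes of 2 signal modules, 300-node
preferential-attachment networks (m = 3) with one planted hub, 20 random
pathways of 40 genes plus one high-overlap pathway per planted module.
These sizes make every recovery target (module ARI, MSEA separation, hub
rank) attainable but not trivial while keeping full runs in seconds.

Design points:

* Expression is a one-factor model per module, x_g = λ_g f + ε with
  positive loadings λ_g ~ U(0.6, 1) and noise σ = 0.4, giving
  within-module correlations ≈ 0.7–0.9, typical of tight co-expression
  modules.
* The −log10 p inflation is planted on z (z ~ N(shift, 1) for signal
  genes), not on p, so the null stays exactly calibrated; two-sided p from
  z. MAF ~ U(0.01, 0.5) and info ~ U(0.1, 1.0) leave the QC filters real
  work.
* eQTL qvals ~ U(0, 0.1) so the 0.05 filter removes about half of the true
  links; decoy links (default 30%) exercise specificity.
* One hub gene is planted in *every* tissue network, rewired so ≥ 70% of
  its neighbors lie in the first signal module's genes — the member set
  the downstream key-driver test probes — so cross-tissue consolidation
  has a recoverable conservative KD.
* Every generator draws from its own named random stream derived from the
  single config seed (seed + CRC32 of the stream name), so adding a
  generator never perturbs another and identical configs produce
  byte-identical files.

What the generator does **not** emulate: realistic allele-frequency
spectra, genome-scale marker counts, recombination maps, correlated
samples across tissues, overlapping or hierarchical modules, and
inter-study heterogeneity beyond independent draws. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated model, not performance on real cohort data.

## Numerical conventions

* p-values clamped to [1e−300, 1 − 1e−16] before normal quantiles.
* Permutation p-values reported as (s + 1)/(n_perm + 1), never zero.
* All ranking ties broken by genomic coordinate or lexicographic id;
  module names assigned by decreasing size.
* The pipeline derives every internal seed deterministically from the
  config seed and a stage tag, so a rerun writes byte-identical tables.
* Degenerate inputs: empty marker tables error on ranking; constant
  expression rows correlate 0; modules without scored genes are skipped
  with a warning; networks without eligible hubs return an empty result
  with a warning.
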