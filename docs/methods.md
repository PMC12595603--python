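# Methods

## Study frame

The package models a repeated hyperosmotic stress experiment: samples at
0, 24, 48, 96, 120 and 144 h with replicate counts 6, 4, 6, 4, 4 and 3
(control; first stress S1 at 24–48 h; recovery R at 96 h; second stress S2
at 120–144 h). All contrasts compare each later time point against 0 h; the
methylation analysis additionally contrasts the recovery point (96 h)
against each second-stress point (120, 144 h). The analysis frame is a
user-supplied list of functional genes (osmotic pathways: water transport,
ion transport, free amino acid metabolism/biogenesis).

## Coordinates and compartments

Internal coordinates are 0-based half-open; GFF3 and CpG site tables at the
boundary are 1-based (GFF3 closed). One representative transcript per gene
is used — the mRNA with the largest spliced length. The promoter is the
`upstream_bp` (default 2000) bases 5′ of the TSS in transcription
orientation; because the source convention is not fully determined, a
`promoter_strand_aware: false` switch makes the window genomically left of
the span instead. The gene body is the genomic span TSS→TES including
introns; promoter and body are disjoint by construction, and a site landing
in the promoter of one gene and the body of an overlapping neighbour is
assigned to both genes independently. miRNA binding intervals live in
transcript coordinates and take the compartment (5′UTR/CDS/3′UTR) of
maximal overlap; exact ties resolve 3′UTR > CDS > 5′UTR, the canonical
priority of miRNA target biology, which also makes outputs deterministic.

## Statistical primitives

- **Pearson correlation** by the product-moment formula; two-sided p from
  t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom; n ≥ 3 and nonzero
  variance required, |r| = 1 reports p = 0. The sign (positive / negative /
  zero) drives all correlation labels; r exactly 0 is "zero" and excluded
  from sign tallies.
- **Wilcoxon rank-sum**, two-sided. For pooled sizes ≤ 16 without ties the
  exact permutation null of the U statistic is enumerated (a
  restricted-partition recurrence); otherwise the normal approximation with
  tie correction and a 0.5 continuity correction. Replicate groups here are
  3–6 samples, where the exact null matters.
- **Benjamini–Hochberg** step-up adjustment with monotonicity enforcement,
  capped at 1. The adjusted-p thresholds below always refer to BH.
- **Fisher exact test** for 2×2 pooled count tables: two-sided conditional
  test summing hypergeometric probabilities ≤ (1+1e−7)× the observed
  table's.

All four are validated in the test suite against independent reference
implementations (scipy, statsmodels) to ≤ 1e−9.

## Differential expression

External per-contrast statistics tables are first-class inputs; the
thresholds — |log₂FC| > 1 and BH-adjusted p < 0.05, both strict — are the
package's calling rule. The built-in `simple_de_test` (for synthetic runs)
normalizes by median-of-ratios size factors, computes log₂FC on group means
with pseudocount 0.5, and takes p from Welch's t on log₂(normalized+0.5).
It is deliberately simple and documented as such: no dispersion shrinkage
or outlier handling, and no claim of equivalence with negative-binomial DE
callers. Its type-I error under a negative-binomial null is calibrated
(~5%) in the test suite.

## Target pairs

A (miRNA, gene) relation is a consensus target pair when both prediction
sources report it and the duplex energy passes ≤ −20 kcal/mol. "Overlap" is
at the (miRNA, gene) level, not binding coordinates, since different
prediction tools report different coordinate systems. The energy filter
applies per source by default (the stricter reading); `per_source=False`
requires only the best source to pass. The retained binding interval and
energy come from the lower-energy source; `n_sites` counts distinct
passing binding sites so both pair-level and site-level granularities are
reportable. Expression correlation uses per-time replicate means (6 time
points including 0 h) — well-defined with unequal replicate counts. A pair
is *active* at time t when its miRNA and its target are both differential
at t.

## Differential methylation and DMSGs

CpG sites require coverage ≥ 10 in every sample of both contrast groups
(configurable); symmetric-CpG strand merging is off by default, with a flag
that collapses a − strand call at p+1 into the + strand call at p. Counts
are pooled within groups; a site is differential at |Δ| ≥ 25 percentage
points and q < 0.01 (Fisher + BH). These cutoffs are this package's
defaults — they mirror the common defaults of WGBS differential-methylation
practice rather than reproduce any specific tool. Genes carrying ≥ 1
differential site in promoter or gene body are DMSGs; all sites are kept
(one record per gene × site), with a `top_site_only` report mode collapsing
to the largest-|Δ| site per gene for one-row-per-gene tables. Gene-level
methylation is the unweighted mean over covered promoter ∪ body sites of
the pooled rate meth/(meth+unmeth); a coverage-weighted variant is a flag.
Genes with no covered site return NaN and are excluded (and counted) in
group comparisons.

## Integration

For each time point the cohort is the functional genes differentially
expressed at t (genes without an expression change have no regulated
response to classify; `cohort='all'` widens to every functional gene).
miRNA evidence = target of an active pair; methylation evidence = DMSG for
the 0 h-vs-t contrast; the 2×2 evidence table yields miRNA-only /
methylation-only / dual / none. Mode proportions are reported over genes
with ≥ 1 evidence.

The dual-regulation permutation test redraws **both** gene sets uniformly
without replacement from the universe each iteration (equivalent in
distribution to fixing one set), records the overlap, and reports the
add-one empirical p = (1 + #{null ≥ observed})/(iterations + 1) — never
zero, by construction. The universe defaults to the functional gene list
(the analysis frame), configurable to all annotated genes. The overlap of
two independent uniform draws is hypergeometric; the test suite checks the
empirical null against that analytic oracle (total-variation < 0.05 at
10,000 iterations on small universes).

Structural complementarity compares targeted vs non-targeted genes per time
point on gene-level methylation (rank-sum, group means ± sd, significance
stars at 0.05/0.01/0.001/0.0001) plus one across-gene CpG site-count
comparison. |log₂FC| contrasts compare miRNA-only vs dual and
methylation-only vs dual; empty groups are reported as not computable
rather than erroring. A watchlist report surfaces cross-layer machinery
hits (MBD2, DGCR8, DNMT, Dicer, Drosha) appearing as miRNA targets or as
DMSGs. Term enrichment of dual genes is only a hook: a one-sided
hypergeometric test over a user-supplied gene→term map (no bundled
databases).

## Synthetic data

The generator emits a complete bundle — GFF3, count tables, sample sheet,
two prediction TSVs with decoys, per-sample CpG tables, functional list and
truth tables — deterministically from one seed.

- Genes are laid out non-overlapping with UTR/CDS/UTR structure and
  optional introns on 4 chromosomes; emitted GFF3 reloads and round-trips
  exactly.
- Counts are negative-binomial (gamma–Poisson, dispersion 0.1) around
  lognormal baselines with per-sample scale factors; planted effects give
  responsive entities |log₂FC| ≈ 2 (≥ 1.2) at a random subset of stress
  times. Each target pair is negatively correlated with probability set per
  region (5′UTR 0.70, CDS 0.42, 3′UTR 0.73 — the reported scale of
  region-wise negative regulation); the miRNA profile mirrors (or tracks)
  its targets' planted effects so the correlation is clean.
- Binding regions are drawn with weights (0.1, 0.7, 0.2) for
  5′UTR/CDS/3′UTR — CDS-dominant, as observed. Decoy predictions of three
  kinds (single-tool, weak-energy, shuffled-gene) are always emitted and
  must all be rejected by the intersection filter.
- Methylation counts are beta-binomial: per-site latent levels from
  Beta(mean 0.20, concentration 25; per-gene sd ≈ 0.08, the scale of the
  reported 0.19–0.23 group levels), per-sample replicate noise
  (concentration 60), coverage 10 + Poisson(30). Targeted genes have their
  baseline mean depressed by `delta_targeted` = 0.035 and their CpG count
  multiplied by `site_count_deficit` = 0.88 — scale-matching of the
  reported structural-complementarity effects, not a fidelity claim.
  Differential sites in methylation-regulated genes shift by
  `dm_shift` = 30 points at the gene's responsive times, with the shift
  direction coupled positively or negatively (50/50) to the expression
  response; the baseline is clamped so the planted direction is never
  silently flipped.
- `rho_dual` is the enrichment factor of dual regulation **relative to
  independence**: each methylation-regulated slot is dual with probability
  ρ·nA/N, so E[overlap] = ρ·nA·nB/N and ρ = 1 reproduces independent
  draws (hypergeometric overlap, verified). Configurations whose expected
  dual count exceeds the marginals (or ρ·nA/N > 1) are rejected as
  infeasible.

What the generator does **not** emulate: nucleotide sequences and seed
matching, read-level noise, isoform structure, genomic correlation of
methylation, batch effects. Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery under the declared
statistical structure, not performance on real sequencing data.

## Problem sizes

Defaults were chosen so a full synthetic pipeline run takes seconds:
500 genes (150 functional), 60 miRNAs, 27 samples, ~3 CpG sites per gene.
The planted-enrichment permutation analysis uses a universe of 1000
functional genes with 200 miRNA-regulated and 60 methylation-regulated
genes and 1000 iterations — large enough that the null overlap (12.0 ± 3.0)
cleanly separates from the planted threefold enrichment (~36).

## Known limitations

- The built-in DE and differential-methylation tests are intentionally
  plain (Welch t; pooled Fisher) — use external callers for real data and
  feed their statistics tables in.
- Site-to-gene assignment uses one representative transcript; alternative
  promoters and isoform-resolved targeting are out of scope.
- The Wilcoxon exact null is limited to pooled n ≤ 16 without ties; beyond
  that the corrected normal approximation is used.
- Empirical permutation p-values are floored at 1/(iterations+1); claims
  below that resolution require more iterations.
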