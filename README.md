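# mirmeth

Joint analysis of **miRNA targeting** and **DNA methylation** as regulators
of stress-responsive genes over a repeated-stress time course.

Marine invertebrates facing recurrent environmental stress (the motivating
system is an invasive ascidian under repeated hyperosmotic challenge:
control at 0 h, a first stress phase sampled at 24/48 h, recovery at 96 h,
and a second stress phase at 120/144 h) adjust the expression of osmotic
pathway genes — water transport, ion transport, and free amino acid (FAA)
metabolism — through at least two epigenetic layers. `mirmeth` implements
the integrative analysis of those layers as a tested, reusable library:

- **annotation** — strand-aware gene models from GFF3; the promoter is the
  2000 bp upstream of the TSS (in transcription orientation), the gene body
  runs TSS→TES; miRNA binding sites in transcript coordinates are assigned
  to 5′UTR/CDS/3′UTR by maximal overlap.
- **differential** — the study thresholds |log₂FC| > 1 and adjusted
  *p* < 0.05 applied to per-contrast statistics tables (every later time
  point vs 0 h, plus 96 h vs 120/144 h), with a built-in
  median-of-ratios + Welch-*t* caller for synthetic runs.
- **targeting** — consensus miRNA→gene pairs: present in **both** prediction
  sources with duplex energy ≤ −20 kcal/mol, annotated with binding region
  and the Pearson correlation of the two expression profiles.
- **methylome** — per-CpG differential methylation (pooled Fisher exact,
  BH-adjusted, |Δ| ≥ 25 points, q < 0.01, coverage ≥ 10) and DMSGs: genes
  carrying a differential site in promoter or gene body.
- **integration** — per-time regulation modes (miRNA-only /
  methylation-only / dual / none), the 1000-iteration permutation test for
  non-random dual regulation with empirical
  p = (1 + #{null ≥ observed}) / (iterations + 1), structural-complementarity
  comparisons (methylation level and CpG site counts of targeted vs
  non-targeted genes, Wilcoxon), and |log₂FC| contrasts between regulation
  groups.
- **synthetic** — a fully parameterized generator of multi-omics bundles
  (negative-binomial counts, beta-binomial CpG calls, decoy-laden prediction
  tables, planted effects and truth tables) so the entire pipeline is
  testable without any download.

A packaged 22-row DMSG reference table (ion transport and FAA genes with
site location, methylation direction and correlation sign) serves as a
fixed ground truth for the reporting layer.

## Worked example

```bash
python examples/03_permutation_test.py
```

prints

```
universe N = 1000, |miRNA set| = 200, |methylation set| = 60
observed dual-regulated genes: 32
null overlap: mean 12.03, sd 2.95 (analytic expectation 12.0)
empirical p = 0.000999
```

Under the null, two independent gene sets of sizes 200 and 60 drawn from
1000 genes overlap in 12 genes on average; the generator planted a
threefold enrichment of dual regulation, the observed overlap (32) exceeds
every one of the 1000 null draws, and the add-one empirical p sits at its
floor 1/1001 — dual regulation is non-random. The other examples cover the
reference-table summary (`01`), a full synthetic pipeline run with
per-time regulation-mode proportions (`02`), and the
structural-complementarity comparison showing the planted ~0.035 depression
of methylation levels in miRNA-targeted genes (`04`).

A thin CLI wraps the same functions
(`mirmeth simulate|report|annotate|de|targets|dmr|permtest|table1`).

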