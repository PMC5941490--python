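# phylosel

Comparative molecular evolution for a pair of closely related genomes:
codon-model selection tests with FDR control, ortholog quality control,
alignment-uncertainty robustness screening, GO-category enrichment, and
genome heterozygosity / PSMC-input statistics — with seeded synthetic
generators providing known truth for every stage.

The motivating system is the Chinese bamboo partridge
(*Bambusicola thoracicus*) and the Red Junglefowl (*Gallus gallus*)
inside the five-taxon galliform phylogeny
`((Colinus,(Coturnix,(Meleagris,(Bambusicola,Gallus)))))`.  The package
is for researchers who want to ask, with a draft genome and a handful of
relatives: do the focal lineages differ in gene-wide dN/dS?  Which genes
show episodic positive selection on a chosen branch, and does that
signal survive alignment uncertainty?  Which functional categories are
over- or under-represented among the hits?  And how heterozygous is each
genome, prepared for PSMC demographic inference?

## The models and tests

The core is a Goldman–Yang-style codon model over the 61 sense codons:
single-nucleotide changes occur at rate `pi_j`, multiplied by `kappa`
for transitions and `omega = dN/dS` for nonsynonymous changes, scaled to
one expected substitution per codon at stationarity, with F3x4 codon
frequencies and Felsenstein-pruning likelihoods.

* **Branch test** — H0: one gene-wide omega; H1: a separate omega on the
  foreground branch.  LRT ~ chi-square(1).
* **Branch-site test** — model A: site classes with `omega0 <= 1` and
  `omega1 = 1`, plus foreground classes whose omega2 is fixed at 1 (H0)
  or free `>= 1` (H1).  LRT ~ chi-square(1); the boundary mixture
  ½·chi²₀+½·chi²₁ is available as an option.
* **FDR** — Benjamini–Hochberg at 0.05, applied independently per
  foreground branch and test family; both the canonical step-up rule
  and a literal rank-threshold variant are implemented.
* **Ortholog QC** — single-copy filter, species-tree topology match,
  and removal of contaminant/paralogous sequences whose minimum
  patristic dS exceeds the 0.99 quantile of a moment-fitted Beta.
* **Genome layer** — heterozygous-site filters (bi-allelic, depth >= 20,
  quality >= 20, minor-allele fraction >= 0.1, autosomes only), het/kb
  summaries, false-positive-rate estimation against a truth set, 100-bp
  K/T/N binning with <= 10,000-bin segments for PSMC, and rescaling of
  PSMC output to years and Ne with `mu = 1.91e-9`/year, generation time
  1 year.

See `docs/methods.md` for assumptions, numerical choices, and what the
synthetic generators do and do not emulate.

## Worked example

Run the full pipeline on a small simulated dataset (12 single-copy
orthogroups of 120 codons with a 10% contamination rate, plus a
simulated diploid genome):

```bash
phylosel run-all --outdir results/demo --seed 1
```

`results/demo/tests.tsv` then contains one row per gene × foreground
branch test (output from an actual run):

```
gene_id  foreground        p        q  significant  foreground_omega  background_omega
 og0004 Bambusicola 0.000065 0.004545         True         50.000000          0.184035
 og0005 Bambusicola 0.135090 0.009091        False          0.000100          0.329229
```

`og0004` is a (simulated) false positive whose foreground omega ran to
the optimizer bound — with 120-codon genes a handful of nonsynonymous
changes on a short branch can do that; the q column shows the BH
threshold each p-value was compared against.  `het.tsv` summarizes the
simulated diploid genome, here planted at 3.8 het/kb:

```
chrom   callable_bases  het_bases  het_per_kb
chr1            433914       1688      3.8902
chr2            259903       987       3.7976
genome          693817       2675      3.8555
```

and `psmc.psmcfa` holds the 100-bp K/T/N binning ready for PSMC.  The
same stages are available as library functions
(`phylosel.selection_tests.branch_test`,
`phylosel.ortholog_qc.beta_outlier_filter`,
`phylosel.genome_stats.make_psmcfa`, ...) and as individual subcommands
(`simulate`, `qc`, `test`, `robust`, `enrich`, `hetstats`, `psmcfa`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main computation from scratch — simulating a
dataset from the given seed, running ortholog QC, the three-foreground
branch tests with BH correction, enrichment, and the heterozygosity /
PSMC-input layer — leaving the pipeline outputs under
`results/pipeline/` and writing the results JSON to the requested path.
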