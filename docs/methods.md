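# Methods

`phylosel` reimplements, as a tested library, a comparative
molecular-evolution workflow for a pair of closely related genomes
embedded in a five-taxon phylogeny — the motivating system is the
Chinese bamboo partridge (*Bambusicola thoracicus*) and the Red
Junglefowl (*Gallus gallus*) inside the galliform tree
`((Colinus,(Coturnix,(Meleagris,(Bambusicola,Gallus)))))`.  The
pipeline asks whether the two focal lineages differ in gene-wide dN/dS,
whether individual genes show episodic positive selection on either
terminal branch or their ancestral stem, whether those signals survive
alignment uncertainty, which functional categories they concentrate in,
and how genome-wide heterozygosity (the raw material for PSMC demographic
inference) compares between the lineages.

## Codon model

The substitution model is the standard Goldman–Yang-style Markov process
on the 61 sense codons.  For codons *i ≠ j*:

    q_ij = 0                      more than one nucleotide change
    q_ij = pi_j                   synonymous transversion
    q_ij = kappa * pi_j           synonymous transition
    q_ij = omega * pi_j           nonsynonymous transversion
    q_ij = omega * kappa * pi_j   nonsynonymous transition

with the matrix scaled so the expected substitution rate at stationarity
is one per codon per unit branch length.  Codon frequencies `pi` are the
F3x4 estimates (position-specific nucleotide frequencies multiplied
across codon positions, stops zeroed, renormalized) and are held fixed
during optimization — the default of the ML software this emulates.
Transition probabilities come from a symmetric eigendecomposition of the
reversible rate matrix; likelihoods from Felsenstein pruning over
site-pattern-compressed columns with per-node rescaling.  Ambiguous or
gapped codons are treated as fully missing (partial likelihood one for
all states).

Five hypotheses are fitted by bounded L-BFGS-B on log/logit-transformed
parameters: `one_ratio` (a single gene-wide omega), `two_ratio` (one
extra omega on a designated foreground branch), `free_ratio` (an omega
per branch, used only to obtain per-branch dS for quality control), and
the branch-site "model A" pair — the null with site classes
`{omega0 <= 1, omega1 = 1}` plus foreground classes capped at
`omega2 = 1`, and the alternative freeing `omega2 >= 1`.  Site-class
proportions are parameterized through two logits (total mass of classes
0+1, and the 0:1 split, which also divides class 2 into 2a:2b), so the
simplex constraint is built in.

Two numerical choices matter enough to state explicitly:

* **Mixture rate scaling.**  In mixture models each branch length is the
  expected number of substitutions per codon *averaged over site
  classes*; each class then advances by `t * r(omega_c) / mean_c r(omega_c)`
  where `r(omega) = rs + omega * rn` is the unscaled flux.  Normalizing
  each class's matrix separately (a tempting simplification) silently
  removes the rate elevation of the positive-selection class and
  destroys most of the branch-site test's power; we verified this
  empirically before adopting the averaged convention, which is also
  what the standard ML implementation does.
* **Alternative-model starts.**  The model-A alternative has a saddle at
  `(p2 ~ 0, omega2 ~ 1)` — exactly where a warm start from the null
  lands.  Fits therefore start with the foreground class mass capped at
  0.9 and `omega2 = 2.5`, and multi-start fitting adds a structured
  "strong selection" start (`p0+p1 = 0.7, omega2 = 8`) before random
  jitters.  Defaults: 3 seeded starts; convergence when L-BFGS-B's
  relative improvement falls below 1e-8; bounds
  `omega ∈ [1e-4, 50]`, `kappa ∈ [0.1, 50]`, `t ∈ [1e-6, 20]`.

Rooted binary input trees are derooted before fitting because the two
root-adjacent branch lengths are only jointly identifiable under a
reversible model; fitted lengths are reported on the derooted topology.

## Selection tests and FDR

Branch tests compare `one_ratio` vs `two_ratio`; branch-site tests
compare the model-A pair.  Both statistics are referred to chi-square
with 1 df, as in the study being reproduced; the statistically stricter
½·chi²₀ + ½·chi²₁ boundary mixture for the branch-site test is available
as an option (`boundary_mixture=True`) but is not the default, because
fidelity to the original procedure comes first.  Three foregrounds are
tested per gene: each focal terminal branch and the branch to their most
recent common ancestor, and Benjamini–Hochberg control at FDR 0.05 is
applied independently per foreground and per test family.  Two BH modes
exist: the canonical step-up rule (default) and a literal
"reject iff p_i < (rank_i/m)·fdr" reading (`rank_threshold`), which can only
be more conservative.  Summaries render the share of significant tests
with one decimal and direction splits as whole percentages, matching the
source tables.

## Ortholog quality control

Orthogroups are consumed, not computed: the filter keeps groups with
exactly one sequence per species whose gene-tree topology matches the
species tree (bipartition equality, lengths ignored).  Codon alignments
are rebuilt by mapping each CDS codon onto its protein alignment row.
Contaminant and paralogous sequences are flagged via the minimum
patristic distance on the dS-scaled gene tree (dS per branch from a
free-ratio fit, converted as `dS = t * rho_S / (3 f_S)` with synonymous
site content measured at omega = 1): a Beta distribution is
moment-fitted to the pooled minimum-dS values and any sequence above its
0.99 quantile is removed, excluding its gene.  Because dS can exceed the
Beta's (0,1) support, values >= 1 — exactly the gross contamination the
filter targets — are removed up front and excluded from moment
estimation.  The Beta is fitted globally across genes by default (the
singular "a Beta distribution" reading); per-gene fitting is a caller
choice by passing per-gene value maps.

## Alignment-uncertainty robustness

The original study integrated over alignment posteriors from a Bayesian
joint sampler; that sampler is out of scope here.  Ensembles instead
come either from externally supplied FASTA samples
(`<gene>.<k>.fasta`) or from an internal perturbation operator that
slides each gap block left or right by 0–2 codons while provably
preserving every row's ungapped sequence.  Each significant test is
re-run across the ensemble and judged by two criteria: p < 0.05 on at
least 95% of alignments, and the LRT exceeding the chi-square threshold
implied by the test's original q-value on every alignment.
Non-converged re-fits shrink the denominator (and are reported); a
strict variant counting them as non-significant is also returned.
Kendall's tau-b compares estimators of the positively selected site
proportion across genes.

## Enrichment

For each foreground, genes are cross-classified as (significant,
non-significant) × (in category, not in category), with branch-test
significants split by direction (higher vs lower foreground dN/dS
scanned separately, the other direction counting as non-significant).
Each 2×2 table gets a two-sided Fisher exact test (minimum-likelihood
rule, as in R's `fisher.test`); over/under-representation is read off
the odds-ratio side; BH at FDR 0.05 is applied across the whole scan
(per class as an option).  GO-slim mapping and graph propagation are
out of scope; slimmed annotations are inputs.

## Genome statistics

Heterozygous sites must be bi-allelic with total depth >= 20, base
quality >= 20 and minor-allele read fraction >= 0.1 (computed from
allele depths, not genotype likelihoods), restricted to autosomes via a
scaffold-to-chromosome map; the PSMC input variant instead bounds depth
in [10, 50] (or [15, 70] for a deeper genome).  Heterozygosity is
reported per chromosome and pooled as het bases per kb of callable
sequence.  The false-positive rate is the percentage of truth-homozygous
positions (e.g. Sanger-sequenced introns) called heterozygous.  PSMC
input bins 100 bp to K (>= 1 het), N (> 90% of positions masked; a het
call wins over the mask and is logged) or T, drops trailing partial
bins, and splits chromosomes into <= 10,000-bin records serialized as
60-column FASTA-like text.  PSMC-scaled output is converted with
`N0 = theta0 / (4 mu g binsize)`, `Ne = N0 * lambda`,
`years = 2 N0 t g`, defaulting to mu = 1.91e-9 per year and a one-year
generation time.  Pairwise 100-kb window statistics count fraction
aligned, mismatches per aligned base (gaps excluded), and GC over
aligned bases only — how uncallable bases inside a window affect GC is
unstated in the source, so GC here is over called bases by decision.
SiteCall positions are 1-based (pileup convention); windows and BED-like
masks are 0-based half-open.

## Synthetic data: what it emulates and what it does not

The study's raw sequencing data are unavailable, so every stage is
exercised on generators that are pure functions of (configuration,
seed):

* **Codon alignments** evolve forward from root draws of `pi` under the
  exact model above, including model-A site-class mixtures with classes
  fixed across the tree.  Default species-tree branch lengths place the
  focal terminals at ~0.06 substitutions/codon — the few-percent
  divergence scale of the real pair.
* **Orthogroup sets** draw per-branch dS around the species-tree scale
  with gamma jitter and plant contaminants by inflating one terminal
  branch's dS by +0.8.
* **Variant sites** use Poisson depth (mean 25, the assembly's
  coverage), Binomial(depth, ½) allele depths at true hets at rate
  0.0038/bp (the observed ~3.8 het/kb scale), planted miscalls at a
  configurable error rate, and report callable length as the count of
  depth >= 20 positions so recovery comparisons are unbiased.
* **Annotation maps** assign categories independently (p = 0.15) and
  draw significance labels from a logistic model with a log-odds boost
  for one planted category.

What a green test therefore establishes: internal consistency of the
estimators and procedures at realistic parameter scales with known
truth.  What it does not: anything about real read-level artifacts
(mapping error, reference bias, indel misalignment structure beyond
gap-block shifts), real GO topologies, or the study's genome-scale
counts, which depend on data that were never released.

## Power at the study scale

With the foreground terminal at ~0.06 substitutions/codon, the
branch-site test's power against omega2 = 4 on 15% of sites at 1000
codons is only ~25% — low power with five taxa is a known property of
this design and is remarked on in the source study itself.  The power
unit test therefore uses a scenario tree with a 0.2-long foreground
branch (measured power ~0.8); calibration tests, which do not need
power, stay at the study scale.

## Scaled-down replicate counts

To keep the default suite inside a CI budget: branch-test calibration
uses the stated 200 null replicates, branch-site calibration 100 (band
widened accordingly); the robustness-pruning contrast uses 60 null and
10 selection genes with 8-member ensembles rather than 50/100-member
ones.  The contrasts and tolerances tested are otherwise as stated.

## Known limitations

* No Bayes empirical Bayes site identification, clade models, or
  RELAX-style tests; no amino-acid or nucleotide models.
* The optimizer reports non-convergence rather than failing, but a
  multimodal model-A surface can still under-estimate the alternative's
  likelihood on rare fits; this biases the branch-site test conservative.
* The internal alignment-perturbation ensemble is a stand-in for a
  posterior sampler: it preserves the inferential logic (integration
  over alignment uncertainty) but not the posterior's actual shape.
* PSMC's EM inference itself is out of scope — the package prepares its
  input and rescales its output.
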