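# Methods

## Ka/Ks estimation (NG86)

The estimator implements the Nei–Gojobori (1986) counting method on
pre-aligned, in-frame coding-sequence pairs. For each sense codon the
nine single-nucleotide neighbours are enumerated against the standard
nuclear genetic code: a neighbour coding the same amino acid
contributes 1/3 to the codon's synonymous site count s, any other
neighbour — including one creating a stop codon — contributes 1/3 to
the nonsynonymous count n, so s + n = 3 exactly. Differences between
two codons at k positions are decomposed over all k! single-step
mutational pathways; each pathway's synonymous/nonsynonymous step
counts are averaged. Pathways passing through a stop codon are
excluded from the average; in the (rare) situation that every pathway
is blocked, all pathways are used with any stop-involving step counted
as nonsynonymous. S and N are averaged over the two sequences, Sd and
Nd summed over codon columns, and pS = Sd/S, pN = Nd/N are corrected
for multiple hits by Jukes–Cantor, d = −(3/4) ln(1 − 4p/3).

Choices the counting method leaves open, and how this implementation
resolves them (recorded in every run's metadata so results are
auditable):

* **Genetic code** — standard code only; the study system is nuclear
  plant genes. The code table is a visible module constant, but
  alternative codes are rejected rather than silently mis-handled.
* **Stop-codon neighbours in site counting** — nonsynonymous.
* **Gapped or ambiguous codon columns** — the whole column is dropped
  in both sequences (complete deletion at codon granularity) and
  counted in `excluded_codons`. This keeps S + N = 3L exact.
* **Saturation** — pS or pN at or above 3/4 yields NaN (flagged), never
  a clamped value; downstream stages propagate NaN. Large but finite
  Ks values (the oldest ortholog pairs reach Ks ≈ 1.8) must survive,
  so nothing is truncated below the saturation point.
* **Short alignments** — below 30 retained codons the result carries a
  `too_short` flag (warning, not error); the threshold is a visible
  constant.

The optimized path (cached per-codon tables) is cross-checked in the
test suite against a deliberately naive enumerator written
independently (no caching, code table rebuilt inline) to 1e-9 on
hundreds of random pairs.

## Divergence dating and event assignment

Times follow T = Ks/(2r) with r in substitutions·site⁻¹·year⁻¹,
reported in Mya (full precision internally, 2 decimals in outputs).
Two rates ship as defaults: 5.2 × 10⁻⁹ for comparisons within Apiaceae
(celery, coriander, carrot) and 1.5 × 10⁻⁸ (general dicot rate) for
cross-clade comparisons such as celery vs. Arabidopsis; `select_rate`
applies the within-clade rate only when both species are in the
configured clade. No rate is asserted for other specific comparisons
(e.g. celery vs. grape); callers must choose one explicitly, and the
CLI applies a single named rate per run.

Event anchors — the modal Ks of the paralog cohort created by each
polyploidization event — are configuration, not computation: the
shipped sets (γ 1.2560, α 0.3659; ω at 0.7154/0.7194/0.7470 in
celery/coriander/carrot; L1 0.6415 in lettuce; G1 0.2884 and G2 0.0297
in ginseng) are consumed as given constants. Fitting mixture models to
Ks distributions to *discover* anchors is out of scope.

Binning uses (lower, upper] intervals: a Ks exactly at an anchor is
attributed to that anchor's event, because a pair born at the event
has exactly its Ks; attribution is always to the interval's upper
anchor, and a Ks above the largest anchor predates the oldest known
event and receives no attribution. For three-anchor sets the four
intervals also carry the conventional colour classes red/green/
orange/blue from youngest to oldest. NaN Ks is reported as
"unassigned" with a warning rather than an error.

## Duplicate-type classification

Five labels with strict precedence: a gene in any collinear pair is
`wgd_segmental`; otherwise a homolog at the adjacent gene-order rank on
the same chromosome makes it `tandem`; otherwise a homolog within the
proximal window (default 10 ranks, configurable, logged into output)
makes it `proximal`; any other homolog means `dispersed`; none means
`singleton`. Ranks are genome-order indices computed over **all**
supplied loci, not just family genes — family-only ranks would inflate
tandem calls — sorted by start coordinate per chromosome, strand
ignored. The precedence order follows the established MCScanX
classifier convention. Collinear-block detection itself is out of
scope; collinear pairs are an input.

## Reconciliation

Standard parsimony LCA reconciliation of a rooted binary gene tree
against a rooted binary species tree with unit duplication and loss
costs: each gene node maps to the LCA of its descendants' species; a
node is a duplication iff it maps to the same species node as one of
its children; for each gene edge whose endpoint maps skip d
species-tree edges, d − 1 losses are counted (d at a duplication
parent), each attributed to the off-path sibling branch. Polytomies
are rejected rather than resolved — any resolution policy would
silently change the counts — and no rearrangement of weakly supported
edges is performed; this is a deliberate simplification relative to
rearrangement-mode reconcilers, which require branch-support
thresholds this package does not model.

## Synthetic data

* **Codon pairs.** A uniform-random ancestor over the 61 sense codons
  evolves down two independent lineages by single-nucleotide
  proposals, uniform over sites and alternative bases; stop-creating
  proposals are rejected, nonsynonymous proposals accepted with
  probability ω, synonymous always. Each lineage stops when its count
  of accepted synonymous events per ancestral NG86 synonymous site
  reaches Ks/2 — divergence is controlled by counting realized events,
  giving exact ground truth without solving for expected substitution
  counts under rejection. Uniform codon usage is a simplification
  (real genomes have codon bias, site-rate heterogeneity and indels),
  so recovery tests validate the estimator's counting and correction,
  not its robustness to those features.
* **Genomes.** Planted features occupy disjoint gene slots: collinear
  blocks (rank-preserving homolog runs across two chromosomes), tandem
  arrays (adjacent runs), proximal pairs (2..window ranks apart),
  dispersed pairs (across chromosomes); everything else is a
  singleton. Since homology exists only where planted, the classifier
  must recover labels exactly; capacity overflows raise rather than
  silently truncate.
* **Gene trees.** Grown top-down from the species tree by explicit
  (branch, duplication|loss) events applied to a random live lineage
  in event order; truth counts come from planted-event bookkeeping.
  Parsimony cannot see every possible history: a duplication both of
  whose copies die, copies surviving only in disjoint sub-clades, or
  losses that empty a whole sub-clade are invisible or collapsed. The
  guaranteed-observable case builder therefore restricts losses to
  terminal branches and applies a structural visibility predicate
  (both duplication copies survive and at least one still spans the
  duplication branch; dead speciation sides are single direct terminal
  losses; no losses above the gene tree's first branching point),
  redrawing deterministically from the seed until it holds. The
  predicate is structural — it never runs the reconciler — so the
  recovery test remains a genuine two-route check.

## Problem sizes and numerical notes

Default validation sizes: 200 simulated pairs of 300 codons for Ks
recovery (mean recovered Ks ≈ 0.30 at true 0.3), 50 genomes of 5 × 40
genes for classifier recovery, 50 gene trees on a 7-species tree (0–3
duplications and losses) for reconciliation recovery; all complete in
seconds. Floating-point output is fixed at 4 decimals (matching the
precision of the anchor constants), NaN prints as `NA`, and all
generators and the pipeline are pure functions of their inputs plus
seed, so reruns are byte-identical.

## Known limitations

* NG86 ignores transition/transversion bias and codon-frequency
  effects; maximum-likelihood codon models would give different (often
  larger) Ks at high divergence. For event binning against anchors
  *estimated the same way*, the consistency matters more than the
  absolute scale.
* Anchor values are genome-wide constants; lineage rate variation or
  anchor uncertainty is not propagated into assignments.
* The classifier labels only the supplied family set, assuming the
  supplied pair lists are complete for those genes.
* Reconciliation reports parsimony counts; histories hidden from
  parsimony (see above) are under-counted by construction, as with any
  LCA reconciler.
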