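# Methods

## Gene retention rates

The unit of analysis is the hierarchical orthologous group (HOG): an
orthogroup defined at a fixed node of the species tree and nested inside a
parent orthogroup (OG). For one species panel a HOG is *present* in a line
when at least one of its member genes for that species is present. The gene
retention rate is GRR = 100·n_present/n_lines, kept at full rational
precision internally and rounded to one decimal only in rendered reports.

Presence calls can come from an explicit presence/absence matrix or be
inferred from SNP genotype missingness: a gene is called absent in a line
when the missing fraction of its genotyped markers exceeds a threshold
(default 0.8; no published value exists for this cutoff, so it is exposed in
configuration). Gene/line combinations with zero genotyped markers carry no
evidence and are flagged *no-data*. By default no-data counts as absent —
the convention of published pangenome presence/absence tables, where an
unassembled gene is reported missing — and `exclude_nodata` removes such
lines from the GRR denominator instead.

HOGs enter the retention table when they carry at least one gene in at
least one panel. Requiring genes in *all* species would discard exactly the
interesting case of a family absent from one species' reference assembly,
so membership in a single panel suffices and missing species yield an
undefined (NaN) GRR.

## Dosage-pattern filter and R_bw categories

The pattern filter keeps HOGs whose GRR decreases strictly along a
ploidy-ordered species list (barley > emmer > wheat in the reference
configuration). Strict inequalities are the default; a relaxed mode (≥ with
at least one strict drop) is available. Reference gene ids are collected
from the first species in the order.

Species preference is categorised by R_bw = GRR_barley/GRR_wheat with
cutoffs ≥ 1.2 (barley preferential), 0.9 < R_bw < 1.1 (neutral) and ≤ 0.8
(wheat preferential). The cutoffs deliberately leave the gaps (0.8, 0.9]
and [1.1, 1.2); ratios falling there are labeled *unassigned* and excluded
from enrichment rather than silently merged into a neighbouring class.
GRR_wheat = 0 with GRR_barley > 0 yields R_bw = +∞ and is classed barley
preferential — full loss in one species with retention in the other is the
extreme preferential case; both rates zero is undefined and excluded.

Family size is the number of HOGs under a parent OG (taken from the OG
column of the HOG table), and the dosage-constraint diagnostic is the
Pearson correlation between family size and the unweighted mean GRR of the
OG's member HOGs, with the least-squares slope reported alongside.

## Duplication typing

Homology hits (tabular BLAST dialect) are filtered to non-self hits at
e ≤ 1e−5, keeping the five best per query (ties broken by bit score, then
subject id). Classification precedence is WGD/segmental > tandem > proximal
> dispersed, applied over a gene's retained hits; genes without hits are
singletons. Tandem means a hit partner at adjacent gene rank on the same
chromosome; proximal within 2–10 ranks (window configurable; the cited
classifier's window for the published analysis is not stated); any other
hit is dispersed. A gene that anchors a collinear block is WGD/segmental.

Blocks are chained per chromosome pair by an O(n²) longest-chain dynamic
program over anchor rank pairs: monotone in both genomes (same or inverted
orientation), consecutive anchors within 25 ranks in both, minimum 5
anchors. Chains are extracted greedily best-first, each anchor joining at
most one block. Chain length is the score; the e-value-based block scoring
of the cited synteny tool is deliberately not reproduced.

## Pairwise Ka/Ks (NG86)

Synonymous sites per codon are the sum over the three positions of the
fraction of single-nucleotide changes that are synonymous, computed among
changes that do not create a stop codon, with s + n normalised to 3 per
codon (so S + N = 3·codons exactly). Differences between codons diverged at
k positions are averaged over the k! single-step pathways, discarding
pathways through stop codons; in the pathological case where every pathway
is blocked, all pathways are used with each step classified by its actual
synonymy. Proportions pS = Sd/S and pN = Nd/N receive the Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as saturation
(NaN). ω = Ka/Ks is NaN when Ks = 0 (optionally +∞ when Ka > 0 and the
`inf_omega` flag is set).

NG86 is the concrete estimator because the wrapper tool used for the
published pairwise values does not state its model; the estimator is
isolated behind a single function so an ML pairwise method could be
substituted. Published NG86 variants differ in their stop-codon handling;
the conventions above are asserted against an independent enumeration
oracle in the tests.

## Codon selection models

The substitution model is GY94-style over the 61 sense codons:
q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for single-nucleotide
changes, zero otherwise. Equilibrium frequencies are F1X4 (pooled
nucleotide frequencies multiplied across the three positions, stops
removed, renormalised, zero entries floored at 1e−10 to keep the chain
irreducible). For branch models each branch class's matrix is scaled to
unit expected rate, so branch lengths are expected substitutions per codon.

Branch-site Model A uses four site classes — conserved (ω0 ≤ 1 everywhere),
neutral (ω1 = 1), and two classes with foreground ω2 ≥ 1 over background ω0
or ω1 — parameterised by (θ1, θ2) with p0 = θ1θ2, p1 = θ1(1−θ2),
p2a = (1−θ1)θ2, p2b = (1−θ1)(1−θ2), which enforces p2a/p2b = p0/p1. Within
each branch type (background/foreground) the four class matrices share one
scale factor, the mixture-weighted expected rate, so branch lengths are
substitutions per codon averaged over classes and positively selected
classes genuinely evolve faster. The simulator uses the same scaled
matrices, keeping generation and inference exactly consistent.

Likelihoods are computed by Felsenstein pruning with per-node rescaling;
gap or ambiguous codons are missing data (flat tip partials). Branch
lengths are held fixed from the input tree by default — the published
analysis used software that optimises them jointly, which is available via
`optimize_branch_lengths` at a documented runtime cost. Optimisation is
bounded L-BFGS-B on transformed parameters (ω ∈ [1e−4, 50], κ ∈ [0.1, 20])
with five seeded restarts by default; alignments with no variation have a
flat likelihood in ω and return `converged=False`. When Model A and its
null are fitted together, the null solution warm-starts the alternative,
guaranteeing the nesting inequality numerically.

Positively selected sites are reported by naive empirical Bayes posteriors
of the foreground classes (threshold 0.6). The full hierarchical
Bayes-empirical-Bayes treatment is out of scope, so posteriors here condition
on the point estimates and understate uncertainty at small sample sizes.

The LRT statistic 2Δℓ is referred to χ² with the difference in free
parameters. For Model A vs its null the ω2 = 1 value lies on the boundary
of the alternative space, which makes the nominal χ²(1) test conservative;
the calibration test therefore checks that the empirical type-I rate does
not exceed the nominal 5% (plus three binomial sigmas) rather than that it
equals 5%. Slightly negative statistics from optimizer noise are clamped to
zero with a warning; substantially negative ones raise.

## GO enrichment

Over-representation p-values are exact upper hypergeometric tails
P[X ≥ k] for overlap k between a query of n genes and a term with K genes
in a universe of N (default universe: all genes in the annotation table).
Multiple testing is controlled per namespace by Benjamini–Hochberg FDR at
0.05 — a well-defined, reimplementable substitute for the service-specific
correction used in the published workflow. The enrichment score is −log10
of the raw p. Term-overlap counts |A ∩ B| over significant terms provide
edges for enrichment-network views. GO-graph ancestor propagation is not
performed; annotations are taken as given.

## Synthetic data and what passing tests show

The generators are pure functions of (configuration, seed), via a single
`numpy.random.default_rng` generator each.

**Pangenome.** The default panel mirrors the study conditions — barley
(diploid, 20 lines), emmer (tetraploid, 20), wheat (hexaploid, 15). Parent
OGs hold a geometric(1/2) number of HOGs (mean 2, truncated at 12); each
HOG carries one gene per species; each line carries each gene independently
with retention probability

p = logistic(β0 − [β_f + β_i·(ploidy/2 − 1)]·(f − 1) − β_p·(ploidy/2 − 1)),

the minimal monotone form of the dosage-constraint hypothesis (larger
families and higher ploidy can only lower retention; the interaction β_i
makes the family-size effect steeper at higher ploidy). Defaults
β0 = 4.0, β_f = 0.4, β_p = 0.5, β_i = 0.2 give a realistic regime:
single-copy diploid genes are near-core (p ≈ 0.98), hexaploid members of
large families are heavily lost (p ≈ 0.07 at f = 8), and preferential
retention is a minority phenomenon rather than genome-wide. What the model
does **not** emulate: linkage between neighbouring genes' loss events,
line relatedness/population structure, reference-assembly artefacts, and
environment-correlated retention — so passing tests demonstrate the
statistical machinery, not robustness to those real-data effects.

**Genome layout.** Duplication events are planted non-overlapping with a
one-gene margin, hits are emitted at e = 1e−30, and segmental events pair
`min_block_size` consecutive genes on two chromosomes. Classifier tests on
this layout show exact recovery under clean, separated evidence; real
genomes overlay multiple duplication histories on the same genes, where the
precedence rule (not ground truth) decides.

**Codon alignments.** Root codons are drawn from π and evolved by the
transition matrices of the scaled rate matrices over each branch; stop
codons never occur because the state space is the 61 sense codons. The
Model A simulation draws a class per site and reuses the inference-side
matrices verbatim.

**GO annotations.** Unplanted terms sample genes uniformly; the planted
term is over-represented in the designated query (or, in the
pangenome-linked variant, drawn mostly from genes whose true retention
ratio is dosage-biased), so enrichment can be checked against a known
answer.

## Numerical choices and problem sizes

- GRR is exact rational arithmetic in floating point (no rounding before
  reports); Pearson correlations use scipy.
- Rate-matrix exponentials use the symmetric eigendecomposition of the
  reversible generator; transition probabilities are clipped at 0.
- Pruning rescales partials per node by their per-site maximum.
- Tie-breaks are deterministic everywhere: gene-id order for equal gene
  starts and hit ranks, lexicographic anchor order in block chaining.
- Test and acceptance problem sizes are chosen to characterise the
  estimators at desk scale: 400-OG panels (~800 HOGs), 500-codon
  alignments on 6–8 taxa for recovery checks, 200 codons × 200 replicates
  on a 4-taxon tree for the type-I calibration, 500 random 30-codon pairs
  for the NG86 oracle.

## Known limitations

- Absolute log-likelihood values of published real-data fits are not
  reproducible without the original alignment and exact software parity;
  the selection machinery is validated by enumeration oracles and
  simulation recovery instead.
- The Model A split between the two positively selected classes is rarely
  identifiable at small alignment sizes; only constrained mixture totals
  should be interpreted.
- Branch lengths fixed at input values bias ω estimates when the input
  tree is poor; use `optimize_branch_lengths` in that case.
- The block detector scores chains by length only and does not merge
  blocks across chromosome-pair boundaries.
- BH-FDR and the published service-specific multiple-testing correction
  can disagree near the significance threshold.
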