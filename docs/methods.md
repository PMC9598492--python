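# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulators do and do not emulate, and the numerical
conventions that make runs deterministic.

## Coordinate and gene-model conventions

GFF3 and VCF are 1-based inclusive on disk; internally every interval is
0-based half-open, converted only in readers/writers. Each gene is
represented by one transcript — the one with the longest summed CDS, ties
broken by lexicographically smallest transcript id — because downstream
statistics need exactly one protein per gene and the longest CDS is the
most information-rich deterministic choice. CDS parts are stored in
transcription order so a minus-strand gene splices by plain concatenation
of reverse-complemented parts. Genes whose CDS length is not a multiple of
3 stay in the catalog (they still occupy a rank, which matters for
synteny) but are excluded from codon analyses. Codons containing N are
dropped from alignments column-wise; the gene is retained.

## Colinear block detection

Anchors are homologous gene pairs (hits filtered at e-value ≤ 1e-10,
inclusive) with each gene's dense rank along its chromosome. A block is a
chain of anchors strictly monotone in rank on both sides (increasing on
side b for "same" orientation, decreasing for "inverted") with at most
`max_intervening = 5` non-anchor genes between consecutive anchors *on
each side* (i.e. rank gap ≤ 6), and at least `min_block_genes = 10`
anchors. The per-side reading of the gap rule follows common collinearity-
tool behaviour; "nearly colinear" is absorbed into the gap allowance while
crossing anchors are never allowed within a chain.

Chains are found per chromosome pair and orientation by O(n²) longest-
chain dynamic programming scored lexicographically by (anchor count,
summed bit score); overlapping chains are resolved greedily best-first
(count, then score sum, then smallest start rank, then "same" orientation
first), removing used anchors after each extraction. This is deterministic
and, on instances small enough to enumerate, provably optimal for the
first chain (the test suite checks equivalence with brute-force
enumeration on random instances of ≤ 15 anchors).

Intra-genomic mode first collapses tandem arrays: mutually-hitting genes
on one chromosome within `max_tandem_rank_gap = 1` ranks form an array and
only the member with the highest total bit score keeps its hits. Without
this, a tandem array paired with a single partner gene can masquerade as a
short block. Reciprocal intra-genomic hits are deduplicated to unordered
pairs. Inter-genomic mode uses the identical machinery with neither step.

## 4DTv

A column of the protein-guided codon alignment is a comparable fourfold-
degenerate (4D) site iff both codons belong to a 4D family of the standard
code (prefixes CT, GT, TC, CC, AC, GC, CG, GG) *and* the first two bases
are identical across the pair. This is the strictest common convention; it
guarantees both observed third bases are synonymous and the site's
degeneracy class is unambiguous. The statistic is p = transversions / 4D
sites, with the saturation correction

    d = -(1/2) ln(1 - 2 p),

the standard correction for a quantity that saturates at 1/2 under
symmetric substitution models. Pairs with p ≥ 0.5 are undefined
(saturated) and are excluded from distributions but counted. Pairs with
fewer than `min_4d = 10` comparable sites are excluded as too short — at
10 sites the binomial noise on p already spans most of the unit interval,
so smaller counts carry no signal.

Protein alignment uses BLOSUM62 with gap open 10 / extend 1. These
parameters only decide which codon columns exist, not the statistic's
definition; any optimal-score alignment gives the same statistic up to
boundary columns, and the aligner's traceback is deterministic.

## Peak detection

The mode of a 4DTv distribution is the argmax of a Gaussian KDE with
Silverman's rule-of-thumb bandwidth (0.9 · min(sd, IQR/1.34) · n^(−1/5)),
evaluated on a fixed 512-point grid over [0, max + bandwidth] and reported
to 3 decimals. A KDE rather than a histogram because peak locations are
reported at finer resolution than any reasonable bin width; the fixed grid
and bandwidth rule make the report deterministic. Secondary local maxima
are reported when their density exceeds half the global maximum.
Degenerate distributions (all values equal, bandwidth 0) report the common
value. Distributions with fewer than 30 values refuse KDE mode detection
and direct the caller to a histogram.

## SNP filter cascade

Order: per-genotype depth mask → per-locus missingness → per-locus MAF.

* Depth: genotypes with depth outside [20, 200], or with no recorded
  depth, are set missing. The bound is applied per genotype, not per site:
  a site-level mean can hide individual genotypes supported by 3 reads,
  and per-genotype masking composes cleanly with the missingness filter.
* Missingness: loci with missing fraction ≥ 0.10 are dropped ("less than
  10 % missing" kept).
* MAF: computed on the calls that survive masking; loci kept only with
  MAF strictly > 0.05.

Attrition is reported per stage so alternative orders can be compared.
The cascade is idempotent. The optional fourfold-degenerate restriction
keeps loci whose position is the third base of a 4D reference codon of the
representative transcript, strand-aware; positions inside the CDS of more
than one gene are excluded as ambiguous.

## Diversity statistics

With alt-allele frequency p over non-missing calls, q = 1 − p:
GD = 1 − p² − q² (expected heterozygosity), PIC = GD − 2p²q², Ho = fraction
of heterozygotes among non-missing genotypes, MAF = min(p, q). Loci with
zero surviving calls are flagged and excluded from summaries.

## PCA

Covariance method: genotypes are centered per locus (missing imputed to
the locus mean — the simplest defensible choice, equivalent to projecting
missing entries onto the panel average), the sample × sample covariance
matrix is eigendecomposed, eigenvalues are sorted descending, and scores
are eigenvectors scaled by the square root of their eigenvalue. Variance
proportions are eigenvalues over their sum. Sign convention: each
component's largest-magnitude loading is positive.

## Admixture model and EM

The likelihood is the binomial admixture model: individual i's genotype at
locus l is Binomial(2, Σ_k q_ik p_kl). The EM updates compute per-allele-
copy cluster responsibilities (E) and renormalize Q rows and set P to
responsibility-weighted allele fractions (M); missing genotypes contribute
nothing. The log-likelihood trace is retained and is non-decreasing (EM
guarantee; asserted in tests). Stopping: |Δ log L| < 1e-6 or 2000
iterations. P is clamped to [1e-6, 1 − 1e-6] to keep the likelihood
finite; after MAF filtering the clamp is never active at convergence.
Initialization is seed-deterministic: P as the observed frequencies plus
uniform ±0.1 noise, Q from a flat Dirichlet. K = 1 converges in one step
to the observed allele frequencies (a closed-form check in the tests).

This is a deliberate reimplementation choice: the classical Bayesian MCMC
clustering approach estimates the same underlying frequency model, but a
maximum-likelihood EM is deterministic given a seed, orders of magnitude
faster, and sufficient for Evanno-style model selection, with replicate
log-likelihoods standing in for replicate posterior estimates. ΔK(K) =
|L̄(K+1) − 2 L̄(K) + L̄(K−1)| / sd(L(K)) over ≥ 3 replicates per K; ΔK is
defined only at interior K and where sd > 0 (K = 1 has a deterministic
optimum, so its sd is 0, but boundary K never needs one). Selection is
flagged unreliable when mean log-likelihood is essentially flat across K.
Because ΔK needs both neighbours, fits are run at K = 1..4 so that the
study's K ∈ {2, 3} interior range is selectable.

## Synthetic data

**Duplicated genome.** Genes are random codon sequences (ATG start, stops
excluded) with a configurable fraction (default 0.6) drawn from 4D
families so 4D site counts are large and binomial error bounds tight.
Every chromosome is duplicated; in the duplicate, each 4D third position
mutates to a transversion with probability p* (default 0.12) and to a
transition with probability p*·(ts/tv) (default ratio 2), leaving protein
sequences identical — this isolates the 4DTv statistic from alignment
error by construction. A fraction of duplicated genes is deleted (default
0.1) and adjacent-swap shuffling (default rate 0.02) perturbs gene order.
The hits table lists true homeolog pairs; the truth table records each
pair's realized transversion count, so every downstream estimate is a
parameter-recovery test. Default scale: 20 chromosomes × 60 genes × 200
codons. Not emulated: intergenic/repeat content, protein-level
divergence (mutations are confined to third positions by design, which
keeps protein alignment exact and isolates the statistic — real homeologs
also accumulate nonsynonymous change and alignment error), segmental
(non-whole-genome) duplications, and fractionation bias.

**Admixed panel.** Balding–Nichols: ancestral frequencies ~ U(0.1, 0.9);
population frequencies Beta-distributed around them with variance
p(1−p)·Fst. Defaults: two populations of 40 + 45 individuals (85 total),
2500 loci, Fst 0.1 — the scale of a RAD-seq germplasm panel. Individual
ancestry Q ~ Dirichlet(9, 1) favouring the home population: mostly-
assigned individuals with minor admixture, matching how structured
germplasm panels typically look. Depths ~ NegativeBinomial(mean 60,
dispersion 10) — realistic RAD-seq coverage with a few percent of
genotypes outside [20, 200], so the depth filter does real work — and 5 %
random missingness. Not emulated: linkage disequilibrium between loci
(loci are independent draws), genotyping error conditional on depth,
allele dropout, or related individuals. Passing tests therefore
demonstrate correct inference under the model's assumptions, not
robustness to LD or call-error artifacts in real panels.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; replicate fits derive
seeds deterministically from a base seed. All writers emit fixed column
orders and float formats, so identical configs and seeds give byte-
identical artifacts (asserted end to end). The test suite exercises the
full default scales for the two recovery checks (20 × 60 × 200 genome;
85 × 2500 panel) and reduced scales elsewhere — e.g. the byte-determinism
check runs at 5 chromosomes × 30 genes and 40 samples × 600 loci, since
determinism is scale-independent.

## Known limitations

* The saturation correction assumes symmetric substitution; strongly
  asymmetric base composition biases d slightly. An HKY-style correction
  is not currently implemented.
* Overlap resolution between candidate chains is greedy; a globally
  optimal block partition (weighted interval scheduling over chains) could
  differ on pathological anchor sets.
* ΔK cannot select K = 1 (the statistic is undefined at the boundary);
  flat-likelihood detection is the guard for unstructured data.
* The admixture EM finds local optima; replicates with different seeds
  mitigate but do not eliminate this.
* PCA imputes missing genotypes to locus means, which shrinks scores of
  high-missingness samples toward the origin.
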