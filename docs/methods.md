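# Methods

This note documents the models, estimators, numerical choices and study
designs behind each stage of the pipeline, and what the synthetic-data
validation does and does not demonstrate about real data.

## Likelihood engine

Site likelihoods are computed with Felsenstein's pruning algorithm over
compressed site patterns.  Substitution models are time-reversible with
the generator normalized to one expected substitution per site per unit
branch length: JC69, HKY and GTR for nucleotides and WAG (published
exchangeabilities and frequencies; empirical frequencies may be
substituted) for proteins.  Rate heterogeneity uses the discrete-gamma
approximation with equal-probability categories and category means
(default 4 categories); this is a deterministic, standard alternative to
per-site rate-category approximations used by some ML programs, and
because the topology test depends only on log-likelihood *differences*
between hypotheses scored under the same model, the choice of
heterogeneity approximation is not load-bearing.  Gaps and ambiguity
codes are treated as fully missing (all-ones conditional likelihoods).
Underflow is controlled by per-node log-scaling factors shared across
rate categories.

Transition matrices come from a cached symmetric eigendecomposition of
the generator, so P(t) is exact and cheap for repeated evaluations.

**Branch-length optimization.**  Topology fixed, branch lengths are
optimized coordinate-wise.  For one branch the site likelihood
factorizes into an inside partial below the branch and an outside
partial above it; projecting both onto the model's eigenbasis makes the
1-D profile likelihood a linear combination Σ_k A_k e^{λ_k t}, evaluated
with a single matrix–vector product.  A sweep walks the tree depth-first
with Brent's bounded method per branch (bounds [1e-8, 10] expected
substitutions/site, xatol 1e-7), updating inside/outside partials
incrementally so every 1-D step sees the exact profile likelihood given
all current lengths — a Gauss–Seidel scheme whose total log-likelihood
never decreases.  Sweeps repeat until the gain drops below `tol`
(default 1e-6, cap 20 sweeps; hitting the cap sets a warning flag, not
an exception).  New branches start at 0.1 substitutions/site.

## Topology-conflict stage (ΔGLS)

The three competing species-level arrangements place the magnoliids
sister to eudicots (1), sister to monocots (2), or sister to the
eudicot+monocot clade (3); the basal angiosperm subtends the three focal
clades and the gymnosperm is the outgroup in all three.  Within-clade
topology comes from one fixed guide arrangement (a ladder over the
configured species order), identical across hypotheses, so the trees
differ only in the arrangement of the focal clades.

* **Low-copy filter** — an orthogroup is kept iff no species carries
  more than one copy and per-clade presence meets the minima
  4 eudicots / 4 monocots / 3 magnoliids / 1 basal angiosperm /
  1 gymnosperm (all configurable).
* **Gene-tree screen** — a neighbour-joining gene tree on
  Jukes–Cantor-type corrected distances, rooted at the gymnosperm; the
  orthogroup is kept iff every focal clade present with ≥ 2 members is
  monophyletic.  This removes genes whose history visibly contradicts
  any species-level arrangement (hidden paralogy, contamination).
* **Scoring** — each hypothesis tree is pruned to the gene's taxon set
  (degree-2 nodes suppressed, lengths summed) and branch lengths are
  optimized; if the hypotheses prune to a single topology the three
  scores are equal by construction and the gene is uninformative.
* **ΔGLS** — Δij = lnL_i − lnL_j; the supported topology is the argmax
  when it beats the runner-up by more than the tie tolerance (1e-3 lnL
  units; ties are labelled uninformative and excluded from counts).
* **Outlier removal** — Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
  computed per pairwise-ΔGLS distribution; a gene is removed if any of
  its three ΔGLS values falls outside its fences (k configurable).
  The rule is deliberately parameter-light and idempotent.
* **Uniformity test** — Pearson goodness-of-fit against equal expected
  counts, df = k − 1, no continuity correction, p from the χ² survival
  function (for df = 2, p = e^{−χ²/2} exactly).  The lineage-specific
  gene-family bias test is the Pearson 2×2 statistic
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, also uncorrected.

## Ks, 4DTv and WGD dating

**NG86.**  Synonymous site fractions per codon (each of the three
positions contributes the fraction of its three possible mutations that
are synonymous), averaged over the two sequences; mutations to stop
codons count as nonsynonymous.  Codons differing at more than one
position are handled by equal-weight pathway averaging; pathways passing
through a stop codon are excluded (if every ordering is blocked, all
orderings are used).  Both pS and pN receive the Jukes–Cantor correction
K = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 sets the saturated flag (such pairs
are excluded from density estimation).  Codons containing gaps or
ambiguity codes are skipped; fewer than 30 comparable codons triggers a
warning.  The implementation is cross-checked in the tests against
Biopython's independent NG86 routine (small systematic differences
remain because stop-codon-neighbourhood conventions differ).

**4DTv** is the raw transversion fraction at third positions of codons
whose first two bases are identical in both sequences and form a
fourfold-degenerate prefix.  No multiple-hit correction is applied —
the statistic is the uncorrected fraction by definition.

**Node weighting.**  Large families would otherwise contribute
quadratically many redundant pairs to the paranome distribution.  Each
family's pairwise Ks matrix is clustered (average linkage) and each of
the m−1 join heights contributes one value with weight 1, so a 10-gene
family contributes total weight 9 regardless of its 45 raw pairs.

**Peak detection.**  Weighted Gaussian KDE over the range filter
(default [0.01, 3.0]); bandwidth is Silverman's rule on the weighted
sample unless given explicitly.  The sample is reflected at both range
edges before density estimation — without this, range truncation of a
decaying background manufactures a spurious interior mode.  Peaks are
interior local maxima with prominence ≥ 10% of the maximum density,
sorted by height; at least 50 in-range values are required.

**Age conversion.**  T = Ks/(2r) exactly, reported in years and Ma.
With the genic synonymous rate 3.02 × 10⁻⁹ substitutions·site⁻¹·yr⁻¹ a
Ks peak near 0.70 converts to ≈ 116 Ma; with the intergenic rate
1.51 × 10⁻⁹ an LTR divergence peak of 0.05 converts to ≈ 16.6 Ma.  The
module applies the conversion to any divergence estimate supplied.

## Syntenic depth

Gene positions are ordinal ranks per chromosome (BED input is converted
to ranks by start coordinate).  Within each chromosome pair, anchors are
chained by dynamic programming into strictly collinear runs — unit score
per anchor, no gap penalty, but a hard cap (default 25 intervening gene
ranks on either genome); inverted blocks are found by rerunning the DP
on negated B-coordinates.  Chains are extracted greedily in score order
with deterministic tie-breaks; blocks need ≥ 5 anchor pairs and never
share an anchor.  Depth of a target gene is the number of blocks whose
target-side span covers its rank; the depth ratio is the reduced ratio
of the two reciprocal modal depths (genes at depth 0 are excluded from
the mode).

## Population-genetic statistics

All statistics are per callable base pair; the callable length L is a
required input because a genome-wide π cannot be derived from a SNP
count alone.  π is the unbiased per-site heterozygosity
2p̂(1−p̂)·n/(n−1) summed over sites; θw = S/(a_n·L) with
a_n = Σ_{i<n} 1/i computed from the group's full allele count (per-site
missingness affects S only).  FST is Hudson's ratio-of-sums:
numerator Σ(π_between − mean within-group heterozygosity), denominator
Σπ_between, sites with < 2 called alleles in either group skipped;
negative estimates are reported raw with a clamped convenience field.
(A Weir–Cockerham variant is deliberately not provided; Hudson's
estimator was chosen for its low sample-size bias.)  Distances are
allele-sharing p-distances with pairwise deletion.  Neighbour joining
delegates to scikit-bio's Saitou–Nei implementation (exact on additive
matrices); taxa are presented in sorted order so ties resolve
deterministically.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) — no global RNG
state — and are exercised by the same code paths as real inputs.

* **Gene sets** — alignments evolved by drawing root states from the
  stationary distribution and propagating along each branch; each
  gene's generating topology is a draw from the configured mixture.
  The species tree carries no published branch lengths, so the defaults
  (internal 0.05, terminal 0.2 substitutions/site, 300 bp, JC69) are
  synthetic and labelled as such; they produce strong but not saturated
  signal (~98% of genes recover their generating topology).
* **Coalescent SNPs** — genealogy and infinite-sites mutations from
  msprime (Hudson's algorithm) with diploid population sizes, optional
  sequential splits and migration; θ is the per-locus 4N₀μL of the
  focal deme; samples are haploid sequences.  Monomorphic columns are
  dropped; positions are floored to strictly increasing integers.
* **Paranome** — background Ks ~ Exponential(decay), WGD peak
  ~ Normal(μ, σ) truncated at 0 by redraw.  Optional codon pairs are
  built from fourfold-degenerate codon families and evolved at third
  positions only under JC69 at branch length Ks; in these families each
  codon carries exactly one synonymous site, so the expected NG86
  estimate equals the target.  This is an approximation that leaves
  first/second positions invariant.
* **Post-WGD gene order** — n copies of the ancestral order; the first
  subgenome retains every gene, each additional copy retains each gene
  independently with the retention probability (retention 0 therefore
  collapses to a single copy and retention 1 keeps every duplicate);
  local order is perturbed by random adjacent-segment inversions of
  ≤ 5 genes.

Passing the simulation-recovery tests shows the estimators are correct
and well calibrated under their own generating assumptions.  It does not
demonstrate robustness to indels and alignment error, selection,
recombination within loci, sequencing/genotyping error, paralogy
misassignment, or model misspecification — none of which the generators
model.

## Validation study designs

Chosen once, sized to run on a single CPU in minutes; all seeds fixed.

* Likelihood oracle: brute-force enumeration over internal-node states,
  all trees ≤ 5 leaves, ≤ 20 sites, random GTR(±Γ), tolerance 1e-8.
* Mixture recovery: 300 genes, 13 taxa, mixture (0.6, 0.2, 0.2);
  support fractions within 3 binomial SEs; uniformity p < 0.01.
* Null calibration: 200 replicates of 30 genes on the minimal 5-taxon
  design at uniform mixture (length 120, optimization tol 1e-2);
  rejection rate at α = 0.05 within 5% ± 3% (measured 3.5%).
* Ks recovery: 200 pairs × 300 codons at Ks ∈ {0.05, 0.2, 0.5, 1.0},
  mean within 10%; planted peak at 0.7 (σ 0.08, 500 WGD over 1000
  background pairs) detected within ±0.05.
* Depth ratios: 2000-gene genomes; 2:1 across retention 0.3–0.9; 3:2
  for a triplicated vs duplicated descendant pair (retention 0.9).
* Neutral calibration: 200 single-population replicates, n = 10,
  θ = 5/locus: mean π and θw within 3 SEs of θ.  Island model: two
  demes, 4Nm = 1, 20 haplotypes/deme, 10⁴ sites, 50 replicates: mean
  Hudson FST within ±0.1 of the coalescent expectation
  1/(1 + 4Nm·d/(d−1)) = 1/3.
* NJ grouping: three demes (N = 10⁴) splitting 100k and 200k
  generations ago, θ = 40 over 50 kb, 6 haplotypes/deme; all three
  groups monophyletic in ≥ 90/100 seeds.

## Known limitations

* The likelihood engine optimizes branch lengths only; topology search,
  bootstrap support and Bayesian dating are out of scope.
* NG86 is a counting method; ML codon models would differ slightly at
  high divergence, and the saturation cutoff (pS ≥ 0.75) is a hard rule.
* The anchor chainer assumes precomputed homology pairs; all-vs-all
  similarity search is out of scope.
* Coordinate-wise branch optimization can in principle stop at a
  non-stationary point of the joint surface on pathological flat
  likelihoods (e.g. signal-free alignments near saturation); with
  informative data the Gauss–Seidel sweeps converge in a handful of
  rounds.
* Hudson FST on very few segregating sites is noisy; windowed estimates
  are left to the caller.
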