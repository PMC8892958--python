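# Methods

## Model and objectives

A read is represented in variant space as a sparse map from SNP index to
allele code in {0,1,2,3}; absence of an index is the gap symbol '−'. For
two reads, d and s count the shared positions with differing and equal
alleles. The consensus H(R) of a read cluster takes the per-site majority
allele (ties to the smallest code; no coverage → '−'); the cluster's
error counts are D = Σ_r d(H,r) and S = Σ_r s(H,r), and the MEC score of
a partition is Σᵢ Dᵢ. Up to three alternate alleles per site are
supported throughout, even though the simulator emits bi-allelic sites.

**Edge weight.** Two error-free reads from the same haplotype disagree at
a shared SNP with probability p = 2δ(1−δ), where δ is the per-allele
miscall rate. For an observed disagreement fraction E = d/(d+s), the edge
weight is (d+s)·KL(E‖p) with the sign flipped when E < p, making the
weight strictly increasing in E. For E > p the Chernoff bound
Pr[Binom(n,p) ≥ En] ≤ exp(−n·KL(E‖p)) identifies the weight with the
negative log p-value of a one-sided binomial test of "same haplotype";
this bound is verified exactly over a grid in the test suite. Natural
logarithms are used everywhere (no base is required for the arg-optima
to be well defined).

**SMTP.** A partition is *valid* when every cluster induces a connected
subgraph of the read-graph; its score is the sum over clusters of the
maximum-spanning-tree weight. Minimizing this over valid partitions is
NP-hard (reduction from graph coloring), so the pipeline uses a greedy
heuristic and treats the score as a diagnostic. With the raw weight
w = d, the per-cluster tree weight plus min_r d(r, H(R)) upper-bounds the
cluster's MEC on read sets that all cover one common interval (star-graph
argument); on local blocks the two scores are strongly linearly related
(Pearson r ≈ 0.97–0.99 in the shipped experiment).

**UPEM.** The refinement objective is
Σᵢ log Pr[Xᵢ > Dᵢ/σ] + log χ²(|R₁|,…,|R_k|) with
Xᵢ ~ Binom((Dᵢ+Sᵢ)/σ, δ). Conventions:

* (D+S)/σ and D/σ are rounded half-up to integers before the exact
  binomial tail (the tail is computed in log space via the survival
  function); the strict inequality Pr[X > t] is used as printed, and an
  empty tail (t ≥ n) contributes the finite floor −700 rather than −∞.
* The uniformity term is Pearson's chi-square of the cluster sizes
  against the uniform expectation, df = k−1, log survival probability;
  equal sizes give exactly 0.
* An empty cluster contributes no binomial term, but its zero size enters
  the chi-square term and penalizes imbalance.

σ keeps the binomial term from drowning out the chi-square term when
clusters carry many observations; it is set to the median read length
(last minus first covered index) divided by 25, floored at 0.01.

## Algorithms

**Block extraction.** Block i spans SNP indices [b·(i−1), b·i] (inclusive,
so consecutive blocks share the boundary site) and contains every read
covering at least one site of the interval. b defaults to the lower-third
quantile of read lengths — long enough that most reads span a whole
block — computed by linear interpolation at rank (n−1)·q. Blocks with
fewer than k reads are folded into their predecessor before phasing.

**Local clustering.** Each block's clusters are seeded by a greedy
k-clique on the block's read-graph: start from the heaviest edge (the two
most divergent reads), then repeatedly add the vertex maximizing its
minimum weight to the current members, preferring vertices adjacent to
all members (the graph need not contain a true k-clique; when no vertex
is fully adjacent the minimum is taken over the edges it does have).
Remaining vertices are assigned over n = 10 sweeps: per sweep, unassigned
vertices are sorted descending by min-over-clusters of max-overlap
(s+d), the top ⌈|V|/n⌉ are placed, each into the cluster minimizing the
maximum edge weight from the vertex (keeping heavy edges out of every
cluster's spanning tree), and clusters are updated between sweeps.
Vertices with no edge to any cluster are deferred to the end of the sweep
and then put in the smallest cluster. All tie-breaks are smallest cluster
index, then lexicographic fragment id, so runs are deterministic.

**Refinement.** Kernighan–Lin-style: each round scores every single-read
move between clusters (incrementally, via per-cluster per-site allele
tallies; the incremental delta is verified against full recomputation to
1e-9 relative), applies the best ⌈|S|/n⌉ positive-gain moves in gain
order — a read moves at most once per round, and deltas are evaluated
against the round-start partition as later moves are applied — then
recomputes UPEM and reverts the round if it dropped. At most n = 10
rounds; the returned partition never scores below the input.

**Outlier fill-in.** Per-block UPEM scores are screened with a one-sided
3.0×IQR rule (score < Q1 − 3·IQR); an outlier block is re-phased by
seeding from the nearest preceding non-outlier partition and assigning
only the block's new reads by the min-max rule (clique seeding skipped).
A leading outlier with no predecessor is kept as-is. The step can be
disabled for data with strong coverage variation, which distorts the
UPEM distribution.

**Merging.** Partitions are chained left to right: at each step the
cluster permutation maximizing the total read intersection with the
accumulated partition is found by exhaustive search over S_k (exact;
ploidy is capped at 8 so k! ≤ 40320), ties to the lexicographically
smallest permutation, no shared reads → identity with a warning. The
printed union rule can place a read appearing in two blocks into two
clusters when the blocks disagree; here a read keeps its first
(leftmost-block) assignment, so the final partition is a true partition.

**Parameter estimation.** δ starts from the initial guess 0.03; ten
randomly chosen blocks (seeded; all blocks when fewer exist) are
clustered and refined at that guess, and δ is set to the 1/10-quantile of
the resulting per-cluster error rates D/(D+S), clamped to [1e-4, 0.49].
The bottom quantile deliberately underestimates, since part of the
observed error is the clustering's own. On deep synthetic data
(20× per haplotype, true δ = 0.03) the estimate lands within ±0.01.

**Output.** Without genotypes, rows are cluster consensuses (possibly
with '−'). With a VCF, every site's (cluster, allele) pairs are ranked by
the confidence c(i,j,a) = |{r∈P[j]: r[i]=a}| / (|{r∈P[j]: r[i]≠a}|+1)
(the denominator counts covering, disagreeing reads only) and alleles are
assigned greedily subject to the dosage; because all 4k pairs enter the
ranking, every haplotype receives a call at every site and the phased
column dosages equal the VCF's exactly. Ranking ties break by (cluster
index, allele code).

## Accuracy metrics

Hamming error rate: min over row permutations of the mismatch fraction,
where a coordinate with differing alleles or exactly one '−' counts as an
error. Switch error rate: per column i, Π_i is the set of
truth-to-candidate row permutations preserving that column's alleles; the
minimum number of permutation changes along the chromosome is found by
dynamic programming over (column, permutation) states and divided by m.
When allele errors empty some Π_i, the set relaxes to the
minimum-mismatch permutations and the residual mismatches are reported
separately — an extension needed for imperfect candidates. The q-block
error rate cuts the matrices into consecutive q-SNP windows and averages
the per-window best-permutation Hamming rate; at q = m it equals the
Hamming rate exactly, and at small q it behaves like a local switch
measure. The q-block windowing here (min-permutation Hamming per window,
unweighted mean over windows, trailing partial window included) is this
package's own reconstruction satisfying both stated limits.

## Synthetic data generator

The simulator works purely in variant space: k haplotypes over m
bi-allelic SNPs, every site heterozygous with an alternate dosage drawn
from a configurable distribution (default uniform over 1..k−1, which for
triploids automatically excludes the impossible three-alternate case; an
option forces two haplotypes identical to exercise collapsing). Reads
pick a haplotype uniformly, a length from a clipped normal (measured in
variants, matching the pipeline's length convention), and a start uniform
over all lattice placements with truncation at the contig edges — so the
expected depth is uniform at every site, including the ends, as the UPEM
model assumes; the read count is chosen so per-haplotype depth equals the
configured coverage. Each covered allele is independently miscalled with
probability δ to a uniformly chosen different code. Default study
conditions for the shipped experiments: k = 4, m = 200, 10× per
haplotype, mean read length 40 variants (sd 10), δ ∈ {0, 0.03}.

What the generator does not emulate: nucleotide-level errors and
alignment (no indels, no soft-clips, no mapping bias), non-uniform
coverage, chimeric or supplementary reads, and linkage structure in the
dosage process. Passing tests therefore demonstrate correctness of the
method under its own model assumptions, not performance on real
sequencing data.

## Numerical and design choices

* Binomial and chi-square log p-values come from scipy's survival
  functions; repeated evaluations are memoized.
* Maximum spanning trees use Kruskal on negated weights with a
  deterministic (weight, edge-id) tie-break; an independent graph library
  serves as the oracle in tests, never the implementation.
* In diagnostics (per-block SMTP reporting) a disconnected cluster falls
  back to the maximum spanning forest; the strict scoring API raises.
* The quantile convention (linear interpolation at rank (n−1)·q) is fixed
  for both the block length (q = 1/3) and the δ estimate (q = 1/10) so
  results are exactly reproducible.
* Problem sizes in the shipped experiments (m = 200–400, 10–20×, 5
  replicates; 1000 random sets for the tree bound; a 3 × 60 × 19 grid for
  the Chernoff bound) were chosen as the smallest instances at which the
  measured quantities are stable across seeds.

## Known limitations

* Local UPEM optima can misplace reads that barely overlap a block (tail
  reads whose evidence lies mostly in the next block); occasionally this
  flips one merge permutation and produces a single global switch, which
  the Hamming rate then amplifies. This is an objective-level ambiguity:
  the affected partitions score at or above the truth partition under
  both UPEM and MEC.
* Haplotype collapsing under strong coverage distortion is only
  mitigated, not prevented, by the uniformity term; no coverage-aware
  post-processing is attempted.
* The merge search is exhaustive over k!, capping supported ploidy at 8.
* Fragment extraction from alignments is SNP-only; indels and >4-allelic
  sites are skipped.
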