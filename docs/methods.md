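# Methods

`cladepred` benchmarks statistical prediction of binary microbial traits
(growth/no-growth on single carbon sources, and any other binary phenotype)
from gene presence/absence, with explicit control for phylogenetic
confounding. This note documents the models and procedures, the choices
made where several designs were defensible, and what the synthetic data do
and do not establish.

## Data model

A study consists of a binary strain × gene matrix `X` (gene-family
presence/absence, e.g. KO annotations), a binary strain × trait table `Y`
that may contain missing entries, and a rooted phylogeny with branch
lengths whose leaves are the strains. Missing trait entries are dropped
strain-wise per trait at analysis time; there is no imputation. Raw growth
assays with two technical replicates are binarized by thresholding the
final optical density (default threshold 0.2 OD units); entries whose
replicates disagree *after* binarization are recorded as missing. The raw
replicate-inconsistency rule is applied on the binarized values rather
than on raw OD differences — a deliberate, documented choice; any
reasonable alternative would only change which borderline wells are
dropped. Traits with fewer than 10 non-missing strains in either class are
excluded from evaluation (configurable), since accuracy distributions on
nearly constant traits are uninformative.

Distances: *patristic* (sum of branch lengths between leaves), *Hamming*
on aligned marker-gene sequences (raw count of mismatching columns, not
length-normalized — only the ordering matters for 1-NN, but the convention
is fixed and documented; gap characters count as ordinary symbols), and
*L1* on gene-content vectors (number of differing genes, identical to
Hamming on binary vectors).

## Partitioning regimes

*Random*: hold out `round(0.2 n)` strains uniformly.

*Out-of-clade*: hold out one clade, or the union of two leaf-disjoint
clades, whose combined leaf count lies in `[ceil(0.1 n), floor(0.3 n)]`
where `n` counts the strains usable for the trait (strains with missing
labels are pruned from the tree before any size accounting). Candidate
test sets are enumerated exhaustively — every subtree in the window, plus
every leaf-disjoint pair of in-window subtrees whose union is still in the
window — and one candidate is drawn uniformly from the pooled list.
"Size" means leaf count: test sets are strains. Single leaves count as
1-leaf clades and enter only when the window's lower bound is 1. The
disjointness requirement exists because nested clades would double-count
leaves. This hold-out forces models to predict for strains that are
phylogenetically far from all training data, which is the regime where
phylogeny-driven shortcuts stop working.

## Models

* **1-nearest-neighbour** on any of the three distances; ties resolve to
  the lexicographically smallest training ID so runs are reproducible.
* **Random forest** (scikit-learn), 100 trees, `max_features=None` so every
  tree may consider every gene at every split — with thousands of mostly
  irrelevant genes, per-tree feature subsampling routinely hides the few
  informative ones. Importances are normalized mean impurity decrease
  (configurable in spirit: the hyperparameter sweep over `max_depth` and
  `max_features` is exposed through the model config). Exact 50/50 votes
  resolve to class 0.
* **Logistic regression with L1 penalty** (liblinear, C = 1), probability
  threshold 0.5.

## Evaluation protocol

Accuracy is the fraction of correct test predictions; balanced accuracy is
the mean of sensitivity and specificity, and is flagged undefined (plain
accuracy is reported in its place) when a test set contains one class —
the trait filter avoids this on real data but synthetic clade hold-outs
can produce it. A model's accuracy distribution over partitions is
compared with two baselines evaluated on *identical* partitions:

* **Bernoulli null** — predicts 1 with the training-set frequency of 1s;
* **identity null** — always predicts the training majority (ties → 1).

Comparisons use a two-sided permutation test on the pooled t statistic
(default 10^5 permutations; exhaustive enumeration whenever the number of
assignments fits the budget, so tiny samples get exact p-values; zero
within-group variance maps to |t| = 0 or ∞ according to the mean
difference). P-values are Holm–Šidák-corrected across all traits evaluated
in one run, separately per null family. "Significantly better" requires
both corrected p < 0.05 *and* a higher mean than both nulls, because the
test itself is two-sided. For a single fixed external prediction vector
(e.g. from a genome-scale metabolic model) the p-value is the fraction of
null accuracies strictly greater than the observed accuracy over random
partitions; a `plus_one` guard is available but off by default, matching
the strict counting definition.

## Phylogenetic signal

The *correlation length* of a trait: for each grid distance `d`, strain
pairs with distance in `[d − w, d)` (default window `w = 0.1`) form a 2×2
contingency table against all remaining pairs, split by same/different
trait; each window gets a Pearson chi-square (with Yates continuity
correction by default, configurable). The correlation length is the
largest `d` whose window is significant at α = 0.05 *with an excess of
same-trait pairs inside the window* (the directionality guard keeps
anti-correlated windows from setting the length); it is defined as 0 when
the smallest non-degenerate window is not significant — no short-range
correlation means no correlation at all. Windows with an empty table row
or column are skipped. The default grid runs from `w` to the maximum
pairwise distance in steps of `w/2`.

The *mimicry statistic* μ asks whether a trained classifier `f` behaves
like 1-NN on gene-content distance: per partition, μ is the mean over test
strains of |f(test) − f(L1-nearest training strain)|; the reference value
μ_rand replaces the neighbour with a uniformly random training strain. The
neighbour lookup always uses the L1 gene-content metric regardless of the
model under test — the statistic is defined against that specific
shortcut. An exact 1-NN classifier gives μ ≡ 0. The μ vs μ_rand comparison
uses the same permutation test.

## Feature selection

*Conditional entropy*: H(y|X_S) computed over empirical row-groups of the
selected gene set S, in bits (base 2; the base rescales scores and never
reorders candidates). Beam search with width 5 and k ≤ 5 by default: round
r keeps the 5 best r-gene sets and expands each with every other gene,
deduplicating sets; the search stops early at zero entropy, where no
addition can help. Ties break on the sorted gene-ID tuple. With beam width
1 the search is purely greedy and can miss XOR-coupled pairs — a test
documents this failure mode; a beam as wide as the gene panel makes pair
recovery deterministic.

*Meta-learning*: identical beam search, but a candidate set is scored by
mean accuracy of a decision tree over 20 out-of-clade meta-partitions
drawn from the training set only (domain generalization within the
training clades). Single-gene sets use a depth-1 stump — the natural
one-feature classifier. The final model is a decision tree on the winning
set, fit on the full training data. Cost grows as
`beam × genes × meta-partitions` tree fits per round; it is intended for
panels of at most a few hundred genes.

*Reaction-graph selection* operates on a user-supplied curated graph
(metabolites as nodes, reactions as edges with gene-ortholog sets,
pathway membership, and a destination list naming central-metabolism
compounds). Three scopes: all genes of pathways containing the carbon; all
genes of reactions incident to it; or the genes along the top-3 shortest
loopless paths (by reaction count; ties broken by lexicographic compound
sequence) from the carbon to any destination, with directed or undirected
traversal. A path's hop may be realized by several parallel reactions, in
which case all their gene sets are unioned. A small hand-built fixture
graph (16 compounds, 19 reactions, 3 pathways) ships with the package,
together with hand-derived expected selections used as test oracles. Live
database retrieval is out of scope.

## Synthetic data generator

The generator emulates the statistical structure the benchmark needs,
not any particular taxon:

* *Tree*: random bifurcating topology by sequential random leaf
  attachment; i.i.d. exponential branch lengths, default mean 0.05, giving
  root-to-leaf depths of ~0.3–0.5 for 64–1000 leaves, so the 0.1 distance
  window used by the correlation-length statistic is meaningful.
* *Gene content*: each gene is an independent two-state Markov chain along
  the tree (gain rate 0.67, loss rate 1.56 by default → stationary
  presence frequency 0.30, sibling-leaf state correlation ≈ 0.8 at the
  default branch scale), with the root drawn from the stationary
  distribution. Leaf-pair agreement follows the closed form
  π₀² + π₁² + 2π₀π₁ e^(−(a+b)t), which the tests verify by simulation.
* *Traits*: random AND/OR expression trees over trait-defining genes drawn
  from the retained gene panel. The modularity parameter
  m ∈ [0, 0.5] requires min(|L|,|R|)/(|L|+|R|) ≥ m at every internal node
  (the symmetric normalization keeps the parameter on a fixed scale and
  makes m = 0.3 feasible for small gene counts); feasibility is checked
  recursively and infeasible (m, gene-count) combinations are rejected
  with a diagnostic. Benchmark cells rejection-sample traits until each
  has ≥ 10% of both classes, with 1000 retries per trait before a cell is
  reported infeasible.

What the generator does *not* emulate: real gene co-occurrence beyond
shared phylogeny (operons, HGT, genome streamlining), annotation noise,
measurement error in growth calls, or uneven taxon sampling. Passing the
synthetic benchmarks therefore shows the machinery is correct and that the
qualitative sample-size/complexity trends hold under idealized phylogenetic
structure — not that any particular real trait is predictable.

## Scaled simulation study

`cladepred.experiments.scaled_sample_size_study` runs the sample-size
experiment at desk scale: a 1000-leaf master collection, 300 genes, traits
over 3 genes with modularity 0, 10 traits per cell, 20 partitions per
regime, sample sizes 100 and 1000. These sizes keep a full run in the
minutes range on a single core while preserving the qualitative claims:
out-of-clade accuracy rises with sample size, random partitions are never
harder than out-of-clade ones, at the large size the forest beats both
nulls on nearly all traits, and the trait-defining genes surface among the
top mean importances.

## Numerical and degenerate-case conventions

* Monte-Carlo permutation p-values use (count+1)/(B+1); exhaustive ones
  use count/total with the identity assignment included, so the smallest
  attainable exhaustive p is 1/total.
* 0·log 0 ≡ 0 throughout entropy computations.
* Empty-table chi-square windows are skipped, not imputed.
* All stochastic procedures accept an integer seed and are reproducible;
  derived seeds stay below 2³¹.

## Known limitations

* Loopless-path enumeration in the reaction graph is exponential in the
  worst case; it is meant for curated graphs of modest size (a `cutoff`
  is exposed for larger ones).
* The meta-learning selector refits one decision tree per candidate set
  per meta-partition; it does not cache across rounds.
* `correlation_length` tests many windows without multiplicity control,
  exactly as the sliding-window definition prescribes; its type-I
  behaviour is governed by the smallest-window rule, which the tests
  verify empirically.
* Out-of-clade candidate enumeration requires that the (pruned) tree has
  a subtree in the target window; extremely unbalanced trees with narrow
  windows are rejected with a diagnostic rather than silently degraded.
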