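# Methods

## Model

`hybcoal` estimates the contribution of hybridization to a putative hybrid
species' genome while accounting for incomplete lineage sorting (ILS), using
only multi-locus *rooted gene-tree topologies* — gene-tree branch lengths are
deliberately ignored, which makes the method robust to poorly estimated
branch lengths in recently diverged groups.

The data model is a four-taxon **hybrid species tree**: a hybrid species H,
its two parents P1 and P2, and an outgroup O, with one hybrid edge between
sister lineages.  Under the mosaic-genome assumption, each locus in H derives
its ancestry from exactly one parental lineage, so the hybrid species tree
decomposes into two ordinary **parental trees**

    tau1 = (((H,P1),P2),O)        tau2 = (((H,P2),P1),O)

that share node heights h1 = t1, h2 = t1 + t2, h3 = t1 + t2 + t3, where the
intervals t = (t1, t2, t3) are measured in coalescent units (2Ne
generations).  t1 is both the hybridization time and the most recent
speciation time: tying the hybrid divergence to the (H, parent) node height
in *both* parental trees is the only reading consistent with a single shared
three-interval parameterization, and we adopt it as a convention (only the
empirical behavior of the deepest interval supports it indirectly; see
Limitations).

With probability gamma a locus traces its history through tau1, with
probability 1 − gamma through tau2, independently across loci; within a
parental tree, gene-tree topologies follow the multispecies coalescent.  For
a sample D = (g_1, ..., g_N) of rooted gene-tree topologies,

    L(gamma, t | D) = prod_i [ gamma P(g_i | t, tau1) + (1-gamma) P(g_i | t, tau2) ].

`gamma` has a direct interpretation as the proportion of the hybrid genome
derived from the P1 lineage.

## Gene-tree topology probabilities

P(g | t, tau) is the classic multispecies-coalescent topology probability
with arbitrarily many sampled individuals per species.  Each species-tree
branch is an independent population in which k lineages coalesce at rate
C(k,2) per coalescent unit; the root population is unbounded.  The
probability is a sum over *coalescent histories* (assignments of gene-tree
coalescences to species-tree branches):

    P(g | tau) = sum_h prod_b g_{i_b j_b}(T_b) * w_b(h) / d_b(h)

where g_ij(T) is Tavare's transition probability for the block-counting
death chain, d_b = prod_{k=j+1..i} C(k,2) counts all ordered coalescence
sequences in branch b, and w_b counts those consistent with g.

The implementation (`coalprob`) evaluates this sum by dynamic programming
over **ancestral configurations** — the sets of partially coalesced lineages
entering each branch — with ordered-merge-sequence counting, and aggregates
histories into per-branch lineage-count *signatures* (i_b, j_b).  The
signature table depends only on the three topologies (gene tree, species
tree, taxon map), not on branch lengths, so it is built once and re-used for
every likelihood evaluation during optimization; individuals of the same
species are exchangeable under the coalescent, so gene trees are first
canonicalized at the species level, which also shares tables across
relabeled datasets.

Two numerical points:

* g_ij(T) is computed from the standard alternating-sign spectral expansion
  with precomputed coefficients, clipped to [0,1]; at the sample sizes used
  here (i <= 14) the worst-case cancellation error is well below 1e-8
  (cross-checked in the tests against the matrix exponential of the
  pure-death generator).
* Probabilities within one gene tree are sums of positive, well-scaled
  terms and are accumulated in linear space; only the product across loci
  is taken in log space.

**Multifurcating gene trees.**  A polytomy in an input gene tree is treated
as *uncertainty*, not as a hard polytomy: the DP leaves the relative order
of a polytomy's children unconstrained, which is exactly the summed
probability of all binary resolutions (verified in the tests against
explicit resolution enumeration).  This defines how consensus trees from
tied ML searches enter the likelihood: P(consensus) is the probability that
the true gene tree is compatible with it.

## Estimation and testing

MLEs of (gamma, t1, t2, t3) are obtained by cyclic coordinate ascent — one
bounded Brent-type (parabolic interpolation + golden section)
one-dimensional search per parameter, in the fixed order gamma, t1, t2, t3,
repeated until both the relative log-likelihood change falls below 1e-6 and
no parameter moves by more than 1e-4 in a full cycle (defaults; at most 100
cycles).  Starting point: gamma = 0.5, t = (1,1,1).  gamma is bounded to
[0,1]; intervals to [1e-6, t_upper].  The lower bound avoids degenerate
zero-length populations; the upper bound (default 5.0 coalescent units) is
*required*: when every observed topology is concordant with one parental
tree, the likelihood increases monotonically as intervals grow (ILS is not
needed to explain the data) and asymptotes, so interval MLEs can land
exactly on the bound.  Such estimates are flagged (`boundary_flags`,
tolerance 1e-3) and are a diagnostic, not an error.  Endpoints of each 1-D
search are evaluated explicitly so boundary maxima are returned exactly.

The no-hybridization test is a likelihood-ratio test of H0: gamma = 0
against the two-sided alternative, Delta = 2(ln L1 − ln L0) with t
re-optimized under both hypotheses.  Because the null pins gamma to the
boundary of its range, Delta is referred to a 50:50 mixture of a point mass
at 0 and chi-square with 1 df: p = 1 if Delta = 0, else 0.5 P(chi2_1 >=
Delta).  Negative Delta beyond −1e-8 raises an optimizer-failure error;
values in (−1e-8, 0] are clamped to 0.

**ITERATE mode** (`iterate_hybrid_assignments`) re-runs fit + test with each
of the three ingroup species cast as the hybrid of the remaining pair,
keeping the outgroup fixed — for data sets where the hybrid cannot be named
a priori.  Parent roles are interchangeable (gamma vs 1 − gamma), so parents
are listed alphabetically.

## Synthetic-data generator

`simulate` reproduces the study design the model was built for:

| parameter | default | meaning |
|---|---|---|
| samples | 4, 4, 4 ingroup; 2 outgroup (14 tips) | individuals per species |
| t | (1.0, 1.0, 1.0) coalescent units | moderate ILS |
| n_loci | 10 | loci per data set |
| gamma | {0, 0.1, 0.3, 0.5} | levels studied |
| theta | 5.0 per locus | mutation parameter 4 Ne mu |
| seq_length | 500 bp | JC69 sites per locus |
| branch_scale | 0.005 | coalescent units -> substitutions/site (theta / sites / 2) |
| t_upper | 5.0 | optimizer bound |
| alpha | 0.05 | LRT level |

Per replicate: the number of tau1 loci is Binomial(n_loci, gamma); gene
trees are simulated with msprime (populations of relative size 1, ploidy 1,
population splits at the parental-tree node heights — an island model with
no migration, which is the standard multispecies coalescent); sequences
evolve site-i.i.d. under JC69 from a uniform root base; and each locus's
gene tree is *re-estimated* from its alignment before fitting, so estimation
error is part of the study, as in the original design.  theta enters only
through branch_scale (5.0 / 500 / 2 = 0.005); no other use is consistent
with both stated values.  Per-replicate RNG streams are derived from the
master seed and the replicate index, so any replicate is reproducible in
isolation.

**Gene-tree estimation.**  ML under JC69 *with a molecular clock* — the
generating process is ultrametric in time, so the clock is the correct
model and also fixes the root without an outgroup heuristic.  The
estimator uses site-pattern-compressed Felsenstein pruning on rooted
ultrametric trees parameterized by node heights (substitutions/site): a
UPGMA starting tree on JC-corrected distances, coordinate ascent on node
heights (vectorized grid refinement of each bounded 1-D problem, endpoints
included so zero-length branches are exact), and rooted-NNI hill climbing
in which each rearrangement is scored with the affected node and parent
heights re-optimized and the best candidates are verified by a full height
sweep (reverted if not a real improvement).  On matched simulated loci
this search lands within about one log-unit of an independent
clock-constrained ML implementation, and the residual search difference
does not move the study-level statistics (verified during development
against phangorn's rooted-NNI ML in R).  Classic analyses of this design
used stepwise-addition + TBR searches; NNI from a UPGMA start is this
package's surrogate, chosen because at 500 bp/14 tips the alignment's
information content, not the search strategy, dominates the error.  Score ties within
1e-6 log-units — assessed over the rooted-NNI neighborhood, which captures
the zero-length-branch ties that dominate at these divergences — are
resolved by semi-strict (combinable-component) consensus of the tied
topologies, so estimated gene trees may contain polytomies.  The 1e-6 tie
window is a package choice; the original program's tie tolerance is not
published.  A clock-free unrooted searcher (`ml_search`) is also provided
as a utility.

What the generator does *not* emulate: recombination within loci,
migration/gene flow after divergence, rate heterogeneity across sites or
loci, non-JC substitution processes, and model misspecification in
gene-tree estimation (data are analyzed under their generating model).
Passing the study-level tests therefore demonstrates correct recovery of
the generating process under idealized sequence evolution, not robustness
to real-data violations.

## Study problem sizes

The shipped study driver (`scripts/acceptance.py`, and the corresponding
tests) runs 60 replicates per gamma level (100 at gamma = 0.1, where the
test's rejection rate is most variable) — a scaled-down version of the
original 100-replicate design chosen as a sensible accuracy/runtime balance
for a desk-scale reproduction; summary statistics carry binomial/Monte
Carlo error of roughly +/- 0.05-0.07 at these sizes.

## Empirical reanalysis recipe (external validation)

The motivating *Sistrurus* rattlesnake analysis (four S. c. catenatus, four
S. c. tergeminus, four putative-hybrid individuals, two *Agkistrodon*
outgroups; twelve nuclear loci) is not shipped as a test because it
requires third-party data and tools: sequences from GenBank (accessions
JN241640–JN241676 plus the remainder cited therein) and per-locus Bayesian
consensus gene trees (e.g. MrBayes under GTR, majority-rule consensus after
burn-in).  To reproduce it: (1) download and align the loci; (2) estimate a
rooted consensus gene tree per locus; (3) write them as newick plus a
two-column taxon map; (4) run

    hybcoal test --genetrees trees.nwk --map map.tsv --species species.json --t-upper 2.0

with the hybrid species tree designating the putative-hybrid population as
H, the two subspecies as parents, and *Agkistrodon* as outgroup.  The
published result for comparison: gamma-hat identically 0, t-hat = (0.1114,
0.0945, 2.0) with the deepest interval at the 2.0 bound used in that
analysis — i.e., ILS alone explains the gene-tree discordance and the
putative hybrids are pure S. c. tergeminus.

## Design choices and limitations

* **Interval-label convention.**  t1 is the most recent interval (tip to
  first speciation/hybridization), t2 the middle, t3 the deepest.  The
  labeling is a convention of this package; swapping conventions relabels
  columns in study summaries but changes nothing else.
* **Missing data.**  All gene trees in a sample must contain the identical
  individual set; there is no missing-data treatment.  Tip matching is
  exact, case-sensitive string equality.
* **Scope.**  One hybridization event between sister lineages; three
  ingroup species plus an outgroup.  Multiple simultaneous hybrid edges,
  hybridization between non-sister taxa (beyond what ITERATE's relabeling
  provides), and likelihoods using gene-tree branch lengths are out of
  scope.
* **Zero-probability loci.**  Every binary rooted topology has positive
  probability under the coalescent, so a locus with zero probability under
  both parental trees signals a data or taxon-map error; the log-likelihood
  is −inf and fitting raises an error rather than applying pseudo-counts.
* **Bias.**  With only 10 loci the likelihood carries little information
  about the intervals: estimates are noisy, mildly upward-biased, and can
  be driven to the upper search bound when the observed topologies require
  no deep coalescence on a branch.  This is a property of the estimator at
  this design, reported — not corrected — by this package.
* **Near-star gene trees.**  Exact polytomy marginalization grows with the
  unresolvedness of the input; a configurable state cap (500k) raises an
  error for pathologically unresolved trees, with the advice to re-estimate
  the locus.
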