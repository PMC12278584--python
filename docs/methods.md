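# Methods

This note documents the models, algorithms, default parameters and design
choices behind gtdiscord, and what its tests do and do not establish.

## The question the pipeline operationalizes

For each protein-coding locus there are three candidate topologies: a
reference species-tree topology trimmed to the locus's taxa (the
"no-discordance" hypothesis), and two estimated gene trees, one per model
family (a nucleotide GTR family and a codon family). Robinson–Foulds and
Steel–Penny path distances rank the two estimated trees by discordance
with the reference; a locus enters the experiment only when both metrics
agree on the ranking without ties. Branch lengths for all three topologies
are then re-optimized under each scoring model (GTR, FMutSel0, SelAC-style),
and the model "prefers less discordance" at a locus when its best-lnL
topology is the least-discordant estimated gene tree. The per-model success
counts are tested against the coin-flip null.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, not a reanalysis of any particular empirical collection.

* **Species tree.** Pure-birth (Yule) with birth rate 1, branch lengths
  multiplied by `coal_scale` (default 2.0) into coalescent units (units of
  2N generations). Internal branches are floored at 0.1 coalescent units so
  that "short" is well defined, then `short_branch_fraction` (default 0.2)
  of them are forced to Uniform(0.01, 0.09) — anomaly-zone candidates.
* **Gene trees.** Multispecies coalescent with one haploid sample per
  species: within each species-tree branch of duration x, the k entering
  lineages merge pairwise at total rate k(k−1)/2; survivors pass rootward
  and coalescence is forced above the root. No migration, hybridization or
  gene flow: all discordance is ILS. The closed-form concordance
  probability 1 − (2/3)e^(−x) for a rooted triple is the calibration
  oracle.
* **Sequences.** Codon states over the 61 sense codons of the standard
  code, root states from the model's stationary distribution, branch
  transitions by eigendecomposition of the rate matrix. Branch lengths are
  coalescent lengths times `subst_scale` (default 0.1 expected
  substitutions per codon site per coalescent unit — noticeable but not
  saturating divergence at typical depths). Nucleotide GTR parameters are
  lifted to a sense-codon mutation-layer matrix for simulation, so stop
  codons are never emitted by construction; empirical nucleotide
  frequencies therefore converge to the sense-codon-conditioned marginals
  of the mutation layer, which is what the stationarity tests check. The
  default generating model for whole datasets is FMutSel0 with amino-acid
  fitnesses drawn once per dataset from N(0, 1) and ω = 0.3: protein-coding
  loci under purifying selection, which is also what makes the two
  inference families (nucleotide vs codon) disagree realistically on weak
  loci.
* **Occupancy.** Default study-style window of 34–50 species per locus,
  clamped to the taxon count at desk scale; a designated outgroup is always
  retained so every locus stays rootable. Defaults for scale are 56 taxa,
  100 loci and locus lengths of 100–1600 codons; tests and the acceptance
  script run smaller configurations of the same generator (stated with each
  run) purely as a problem-size choice.
* What the generator does **not** emulate: alignment error, indels,
  recombination within loci, rate heterotachy across lineages, gene flow.
  Passing tests therefore show the machinery is correct and calibrated
  under ILS-only discordance; they do not show robustness to misalignment
  or introgression.

## Substitution models and likelihood

* **GTR+Γ.** Six exchangeabilities, stationary frequencies, gamma rate
  heterogeneity with k equal-probability categories, either bin conditional
  means (mean discretization; mean exactly 1) or bin medians rescaled to
  mean 1 (median discretization). The nucleotide family defaults to median
  discretization and the codon families to mean, and both are available
  everywhere.
* **FMutSel0.** q_ij = μ_ij · h(S_ij) · ω^[nonsyn] for single-nucleotide
  codon changes, with μ the GTR mutation layer, S_ij = F_aa(j) − F_aa(i)
  scaled amino-acid fitness differences, and h(S) = S/(1 − e^(−S))
  (h(0) = 1; evaluated piecewise for numerical stability). The stationary
  distribution is π_mut · e^F renormalized — an analytic identity the tests
  verify to 1e−8 — and the matrix is scaled to unit expected rate at
  stationarity. Both ω and the 19 free fitnesses are representable; the
  packaged default optimizes ω with fitnesses held fixed, treating ω as
  the model's single selection parameter, with fitnesses available for
  simulation and for nested-model comparisons.
* **SelAC-style.** Same construction with F_j = −ψ·G(aa(j), a*), where G
  is the weighted Grantham distance (composition, polarity, volume weights
  1.833, 0.1018, 0.000399, global scale 50.723 so G(Ser, Leu) ≈ 145) and
  a* is the site's optimal amino acid — majority rule by default,
  maximum-likelihood over the 20 candidates available. ψ (default 0.02,
  so ψ·G spans roughly 0–4 across amino-acid pairs) absorbs gene
  expression/selection strength; ψ = 0 collapses to the mutation layer.
  The likelihood partitions sites by optimal amino acid, one rate-matrix
  family per group.
* **Empirical codon exchangeabilities** are supported only through a
  user-supplied 61×61 file; nothing is bundled. When absent, the
  ω-only FMutSel0 parameterization plays the role of the second (codon)
  inference family.
* **Pruning.** Felsenstein pruning over 4 or 61 states with per-pattern
  scaling, gap/ambiguous codons as fully missing, gamma categories averaged
  with equal weights. Reversible matrices are eigendecomposed through the
  π-symmetrized similarity transform, so P(t) costs two dense
  multiplications. Likelihoods are computed on the derooted tree and are
  invariant to rooting and taxon order (tested).
* **Branch-length optimization.** Coordinate ascent: per sweep, conditional
  likelihoods above and below every edge are cached and each edge is
  optimized by bounded Brent in log-length space (short branches need
  relative, not absolute, resolution; bounds 1e−8 to 20). The edge
  objective uses the spectral form sum_k e^(λ_k r_c t) H_k(pattern), making
  each evaluation one exponential and a matvec. Within-sweep cache
  staleness is guarded: if a sweep fails to improve the exact lnL, it is
  redone edge-by-edge with fresh caches. Sweeps stop when the improvement
  falls below 1e−4 lnL (coarse settings: fewer sweeps, looser Brent — used
  for tree search and screening; final refits use the strict settings).
  Multi-start protocol: start 0 from the topology's own lengths, further
  starts jittered log-normally; "converged" means at least two starts
  within one lnL unit of the best, and a 4-then-8 extension schedule is
  provided for fits that fail the rule.
* **ω/ψ optimization** is an outer bounded Brent on log10 of the parameter
  (ω ∈ [0.01, 10], ψ ∈ [1e−4, 3.16]) with warm-started inner branch-length
  sweeps.

## Gene-tree search

NNI-only hill climbing: from a neighbor-joining start (JC-corrected
nucleotide distances for the nucleotide family; Poisson-corrected
amino-acid distances for the codon families, which see the alignment
through its protein), all nearest-neighbor interchanges are scored with
branch lengths re-optimized per candidate, moving while any neighbor
improves the lnL. Topologies are cached by their split sets. SPR is
deliberately omitted: at the locus sizes this package targets, the NNI
neighborhood around an NJ start is where the signal is, and exhaustive
scoring of 4-taxon cases doubles as the search oracle in tests.

## The statistical battery

* **Proportion z-test** on the binary outcomes with the *sample* standard
  deviation (denominator n − 1) in the standard error, two-sided — the
  convention that reproduces the worked 38-locus examples (22/38 → 0.33,
  25/38 → 0.04). lnL ties within 1e−6 score 0 (conservative toward the
  null) and are logged; preferring the reference topology also scores 0,
  since the reference is not an estimated gene tree.
* **Sign test** (exact binomial, two-sided) and a **randomization test**
  (10,000 independent sign flips of the centered outcomes, p = fraction of
  |mean| at least the observed).
* **KS vs resampled null.** The observed per-locus Δ-lnLs are compared to
  4000 differences of pairs drawn independently with replacement from the
  pooled per-topology lnLs of all models. The pairing rule for the null is
  a package choice (independent minuend and subtrahend draws); its
  calibration under the null is itself tested.
* **Regressions** of Δ-lnL on topological distinctness (OLS; slope, R²,
  two-sided p), with a variant excluding the j most extreme x-values.
* No multiple-testing correction is applied across the battery; α is fixed
  at 0.05 up front.

## Calibration of the whole experiment — and a finding

The type-I error of the preference experiment is checked by simulating the
entire pipeline under a null. Designing that null was not cosmetic:

* Making the two candidate gene trees *independent random single-NNI
  perturbations* of the true gene tree, ranked against the generating
  species tree, rejects at ~33% instead of 5%. This is not a bug in the
  test: under ILS, a rearrangement that moves a gene tree *toward* the
  species tree preferentially crosses one of the gene tree's weakly
  supported (short) edges, so the less-discordant candidate really does fit
  the data better on average. Equal RF error is not equal likelihood error.
* Same-edge symmetric rearrangements still reject at ~10% through the same
  coupling, weakened.
* The shipped null therefore draws both candidates as independent
  three-move NNI random walks from the true gene tree (equally wrong by
  construction) and ranks discordance against an *independently simulated*
  reference topology, redrawn per locus so that locus outcomes are
  independent (a shared reference correlates outcomes within a replicate
  and inflates the z-test's rejection rate). The residual coupling (via
  tree-shape centrality) is negligible at the tested size.

This matters for interpreting the experiment on real data: part of any
observed preference for less-discordant topologies is expected purely from
the geometry of likelihood surfaces under ILS, even when models have no
special affinity for the species tree.

Calibration runs use 10 taxa, 20 retained loci per replicate, 60-codon
alignments and single-start coarse fits — the two candidates are treated
identically, which is all a symmetry-based null requires — with at least
300 replicate experiments for the type-I error and a strong-signal variant
(the least-discordant candidate *is* the true topology, 100 codons) for
power.

## Species trees and evaluation

* **Estimation** maximizes the number of induced gene-tree quartets that
  agree with the candidate topology (the quartet-agreement criterion of
  coalescent quartet methods). Exhaustive enumeration to 8 taxa; otherwise
  NNI hill climbing from a greedy bipartition consensus (all gene trees on
  one taxon set) or an NJ tree on the across-tree average topological
  distance matrix (varying taxon sets, where greedy consensus over partial
  bipartitions is ill-defined). Gene trees with missing taxa contribute the
  quartets they resolve; a pair of taxa never co-occurring is an error.
* **Branch metrics.** q₁/q₂/q₃ count induced quartet resolutions around
  each internal branch (one taxon per neighbor subtree, all combinations,
  all gene trees); support defaults to q₁ rather than a local posterior —
  transparent and monotone in it — and externally computed support
  annotations can be supplied. Gene concordance factor is the fraction of
  decisive gene trees (≥ 2 taxa on each side after restriction) containing
  the branch's restricted bipartition; split frequency is the same over all
  gene trees. Coalescent lengths invert q₁ via x = −ln(3/2(1 − q₁)),
  clamped to 0 at q₁ ≤ 1/3 and +inf at q₁ = 1.
* **Tree-level scores.** The distance score of a test tree against
  (reference, minimum-discordance, maximum-discordance) references averages
  scaled RF and path distances, c = (RF/RF_max + path/path_max)/2 with
  maxima over all pairwise comparisons in the evaluated set, and returns
  ((1 − c_ref) + (1 − c_min) + c_max)/3 ∈ [0, 1]. The
  selected-relationships score tallies +1 for clades shared with the
  low-discordance references and −1 for clades shared with the
  maximum-discordance tree. Predictive power is the mean (with a 95%
  bootstrap percentile interval over 100 resampling trials) of the fraction
  of the tree's restricted bipartitions found in held-out gene trees.
* **Anomaly scan.** Contiguous internal ancestor–descendant pairs (x, y)
  are anomalous when y < a(x); a node is "in the anomaly zone" when it is
  the junction of a flagged pair. When the species tree lacks coalescent
  lengths they are taken from the quartet inversion, and the source is
  recorded. Difficult nodes apply the four thresholds (0.1 coalescent
  units, 10% gCF, 10% split frequency, 0.5 support) as strict inequalities,
  configurable; an undefined metric fails its criterion. Note that with few
  taxa a random gene tree still matches a short branch's bipartition about
  a third of the time, so the 10% gCF default is a large-tree criterion;
  the tests demonstrate discrimination on desk-scale trees with uniformly
  widened thresholds.

## Numerical and engineering choices

* Branch-length bounds 1e−8 to 20 expected substitutions per site;
  per-pattern likelihood scaling throughout; site log-likelihoods
  retrievable per pattern.
* RF distance is the symmetric difference of canonical split sets computed
  directly on the tree (dendropy's bipartition machinery is the independent
  oracle in the tests); the path distance is the Euclidean (Steel–Penny)
  form on edge-count tip distances, with the absolute-sum variant behind a
  flag. Both ignore branch lengths, and both treat trees as unrooted.
* Normalized RF uses the binary-tree maximum 2(n − 3).
* All randomness flows through numpy Generators seeded from explicit
  integers; pipeline stages derive their seeds from the master seed by
  fixed offsets, and every artifact needed to replay a single locus is
  logged.

## Limitations

* The quartet species-tree search is exact only to 8 taxa; above that the
  NNI climb inherits the usual local-optimum caveats (its agreement with
  the exhaustive oracle is asserted on 6-taxon fixtures).
* SelAC here is a single-gene, single-ψ variant with majority-rule optimal
  amino acids; it does not share parameters across genes.
* The FMutSel0 default treats ω as the only free selection parameter;
  fitness estimation is possible but not routine.
* Desk-scale runs use few taxa and short loci; absolute values of
  concordance factors, support and retention rates scale with problem size
  and should not be read as study-scale predictions.
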