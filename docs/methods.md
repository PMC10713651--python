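# Methods

## The model

The package treats a brain as an undirected structural graph G = {V, W}:
N parcellated regions, a symmetric binary adjacency, and edge weights equal
to the Euclidean distance between region centroids in millimeters. Distance
weighting deliberately ignores streamline counts or tract integrity — it is
the one weighting computable identically across species and datasets, and
it encodes the assumption that signaling over physically shorter axons is
metabolically cheaper.

For each region pair the k = 5 minimum-length loopless paths are
enumerated. The choice k = 5 reflects the saturation of edge participation:
the fraction of structural edges used by at least one multi-step path grows
with k and plateaus around k ≈ 5, so larger ensembles add length without
adding coverage. The direct 1-hop edge, when present, is enumerated as a
candidate (it is usually rank 1 under distance weights) but excluded from
relay assessment — an inequality over a chain cannot be evaluated on a
single step. `multi_step_only=True` instead enumerates k multi-hop paths.

Each region carries a time series X^i, z-scored per region (population
standard deviation, i.e. divide by T). Pairwise dependence is measured by
plug-in histogram mutual information in bits on a shared square grid whose
bin edges are anchored at 0 (…, −w, 0, w, …) with default width w = 0.5.
Marginals are obtained by summing the joint histogram, and the estimate is
averaged over both orientations of the joint table, which makes
I(x, y) = I(y, x) hold bitwise. No bias correction is applied; the plug-in
bias under independence and under correlated Gaussians is characterized
empirically by Monte-Carlo oracles in the test suite (at T = 10⁴ and
w = 0.5 the estimator sits ≈0.12 bits below the analytic value
−½log₂(1−ρ²) at ρ = 0.9, from quantization, and ≈0.01 bits above 0 under
independence, from sampling bias).

A structural path is labeled a **relay information-related pathway** when
the MI profile along it is consistent with a Markov chain (data processing
inequality): information about the source cannot grow with distance along
the chain. Three inequality sets are exposed because the source ambiguity
is real:

- `source`: the source-anchored sequence Φ is non-increasing;
- `bidirectional` (default): Φ non-increasing for both anchors — an
  undirected chain read backwards is also a Markov chain;
- `all_triplets`: I(u,w) ≤ min(I(u,v), I(v,w)) for every ordered triplet
  along the path (the strictest reading; relay sets are nested
  all_triplets ⊆ bidirectional ⊆ source).

Inequalities are non-strict with zero tolerance on the computed doubles:
exact ties (possible with identical series) count as satisfying. Note that
`source` mode depends on path orientation; ensembles store paths anchored
at the lower-index endpoint, so only the two direction-symmetric modes are
exactly equivariant under region relabeling.

The **parallel communication score** PCS_ij counts DPI-respecting
multi-step paths among the pair's ensemble (0 = no Markovian transmission,
1 = selective, >1 = parallel). Pairs with no enumerated multi-step path
carry PCS 0 plus a missing-mask bit, so summaries can include them as
"no transmission" (the default) or exclude them. **Communication density**
is the percentage of assessable paths labeled relay, reported per path
rank (a path's rank is its 1-based position in the pair's k-shortest
list).

## Group-level connectome construction

Two routes produce the group binary adjacency:

- **Consensus binarization**: keep an edge iff it appears in ≥ a threshold
  fraction of individual connectomes; the default threshold 1.0 ("all
  subjects") minimizes false positives, and ≥ makes 1.0 exact.
- **Tracer tables** (directed injection records with ipsilateral /
  contralateral laterality): keep right-hemisphere records, drop
  connections with strength < 10^−3.5, OR-symmetrize ipsilateral edges,
  mirror them to the left hemisphere, and transpose contralateral edges.
  The strength threshold is applied before presence-symmetrization by
  default — the stricter order, since thresholding after symmetrization
  can rescue an edge through its weak reverse record; both orders are
  supported because the original step ordering is ambiguous. Homologues
  are matched by name stem (`VISp_R` ↔ `VISp_L`).

## Null models

1. **Region shuffle** (default 3000 replicates/subject): permute which
   region carries which time series. This preserves the connectome exactly
   and the multivariate statistics of the panel exactly (same column
   multiset) — the MI matrix of a shuffled panel is the
   permutation-conjugated original, bitwise. Replicate group-average PCS
   matrices give a per-pair null distribution.
2. **iid Gaussian** (default 100 simulations): N(0, 1) noise panels of
   matched size; the absent-communication scenario.
3. **Variogram-matched surrogate** (default 100 runs/subject): MI values
   are treated as a 1-D field over inter-centroid distance; their
   variogram (semivariance vs |d_a − d_b| lag, 25 equal-width bins, bins
   with <2 entry pairs dropped) quantifies spatial autocorrelation. Per
   run, the upper-triangle values are permuted, smoothed with a Gaussian
   kernel over lag (bandwidth drawn log-uniformly between the 5th and 95th
   lag percentiles), rescaled by the OLS regression of the original
   variogram on the surrogate variogram (applied as v′ = βv + α, clipped
   at 0 since MI is nonnegative), and scored by the SSE of that fit; the
   minimum-SSE run is returned. The lag metric and kernel schedule are
   package choices — the construction of a variogram for matrix-valued
   fields is genuinely open — and are isolated behind the `variogram`
   interface so alternatives can be swapped.

Screening: z = (real − null mean)/null sd thresholded at 1.96, and
empirical p-values with the add-one rule p = (#{null ≥ real}+1)/(R+1)
(avoids p = 0 at finite R; a deliberate deviation from literal counting),
Benjamini–Hochberg FDR at 0.05 over the upper triangle.

## Fingerprinting

Time series are split into first/last ⌊T/2⌋ samples (odd middle sample
dropped), z-scoring reapplied per half, and PCS recomputed per half.
Similarity between two PCS matrices defaults to **match fraction**: the
fraction of region pairs with exactly the same integer score. The
operational definition is agreement over all pairs; a `nonzero_jaccard`
variant (agreement restricted to pairs where either matrix is nonzero,
over the size of that union) is provided because the score's set-style
name suggests it, and neither is silently preferred in reports. A subject
is identified when its diagonal entry is the *strict* row maximum — ties
count as misses, which avoids inflating success rates on discrete
similarities. Stratified success rates split pairs at group-average
PCS ≤ 1.3 vs > 1.3.

Nodal SNR is the ratio of low- to high-frequency periodogram power with
the cut at half the Nyquist frequency (boundary bin in the high band, no
tapering); white noise gives ratios near 1, hemodynamics-like slow signals
well above 1. Its association with nodal PCS uses Spearman rank
correlation per subject.

The bin-width diagnostic evaluates candidate widths 0.05–2.00 (step 0.05)
against two criteria: median real MI must exceed a size-matched iid
Gaussian null, and split-half MI-matrix identifiability (Pearson
similarity of upper triangles) must lie within 1% of its maximum over the
remaining widths (plateau rule). The recommended width is the smallest
satisfying both; an iid cohort yields no recommendation.

## Synthetic data generator

`synth_connectome` places centroids uniformly in a 100 mm cube, guarantees
connectivity with the Euclidean minimum spanning tree, and fills the edge
budget (default density 0.15) by sampling pairs without replacement with
probability ∝ exp(−d/(box/4)), giving the short-edge preference of real
connectomes and exact density up to rounding.

`synth_relay_panel` plants Markov relay chains: the chain source is iid
N(0, 1); each next chain node is the previous node's series plus
independent Gaussian noise (default sd 0.5 per hop); other regions are
independent noise; everything is z-scored. Additive-Gaussian propagation
is the simplest process that is exactly Markov, so the DPI holds along
chains in expectation while MI decays with hop count, and the estimator's
behavior stays analytically checkable. Temporal autocorrelation is
deliberately absent from the default generator. Overlapping chains are
rejected unless explicitly allowed (a shared node then sums its parents'
signals); acceptance fixtures use disjoint chains only, for unambiguous
ground truth.

Two chain-placement strategies serve different purposes:

- `plant_chains`: chains are weighted shortest paths of 2–3 hops, so each
  planted chain appears at rank 1 among its pair's multi-step k-shortest
  paths — used for relay-recovery experiments. A pilot sweep at the
  default conditions (N = 40, T = 800, hop noise 0.5) put recovery
  sensitivity near 1.0; the acceptance operating point is frozen at 0.9.
- `plant_walk_chains`: long node-disjoint self-avoiding walks (default 9
  hops) — used for subject-specific structure in cohorts. The reason is
  statistical: match-fraction similarity has a noise floor of
  √(q(1−q)/n_pairs) over the n_pairs region pairs, and a chain of L nodes
  makes all L(L−1)/2 within-chain pairs carry stable, subject-specific MI
  ordering. Short chains (3 informative pairs each) cannot lift
  self-similarity above that floor at any noise level; long chains mirror
  how real functional connectomes distribute subject identity across the
  whole matrix. Construction restarts from scratch when greedy placement
  strands nodes.

`synth_cohort` gives all subjects shared base chains plus
round(subject_effect × n_individual_chains) private walk chains per
subject. At subject_effect = 0 subjects are exchangeable and
identification can only succeed at chance (1/S); at subject_effect = 1
with moderate noise, split-half identification approaches 100%.

What the generator does **not** emulate: hemodynamic convolution and
temporal autocorrelation, scanner noise, global signal, spatially
autocorrelated "background" functional connectivity, or inter-subject
variation in the structural graph. Passing tests on synthetic cohorts
therefore demonstrate the correctness and statistical behavior of the
pipeline under its own model assumptions, not performance on real fMRI.

## Numerical choices

- Path-length comparisons use exact ordering of computed doubles (weights
  are sums of a few norms); equal-length path ties are broken by
  lexicographic node-name order, making enumeration deterministic across
  platforms and prefix-stable in k.
- Histograms anchor bin edges at 0; grid extent is data-driven (empty bins
  contribute nothing).
- 0·log 0 = 0 throughout; MI is clamped only by construction (sums of
  nonnegative terms), never post-hoc.
- Degenerate inputs fail loudly: constant series (z-score), coincident
  centroids on an edge, zero-variance variograms, empty strata,
  zero-high-band power. Disconnected connectomes are permitted with a
  warning; disconnected pairs yield empty ensembles and masked PCS 0.
- All stochastic steps take a seed or `numpy` Generator;
  `spawn_seeds` derives independent child streams below 2³¹.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in a few minutes on one CPU: connectomes of 8–40
regions, T = 100–800 time points (T = 10⁴ for the Gaussian-limit check),
cohorts of up to 10 subjects, and null ensembles of 2–100 replicates in
tests (the library defaults remain 3000/100/100). Chance-level
fingerprinting simulations use 500 repetitions for the 100-subject cohort
and 2000 for the 9- and 10-subject cohorts, drawing PCS matrices from the
empirical no-communication score distribution computed by one full
pipeline run — the chance level depends only on subject exchangeability,
not on how individual matrices are produced.

## Known limitations

- The MI estimator is biased at finite T and coarse bins; cross-subject
  comparisons are valid because T and binning are matched, absolute MI
  values are not calibrated.
- The variogram construction for matrix-valued fields (lag metric, bin
  count, bandwidth schedule) is one defensible choice among several.
- `source`-mode relay labels depend on which endpoint is called the
  source; prefer `bidirectional` (default) or `all_triplets` for
  orientation-free results.
- Yen's algorithm over all pairs scales roughly as O(N² · k · Dijkstra);
  beyond ~500 regions, enumeration dominates runtime and caching the
  ensemble (HDF5) across subjects is essential.
- Directed or conditional information measures (transfer entropy) and
  non-Markovian communication models are out of scope.
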