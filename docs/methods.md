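# Methods

This note documents the models, conventions and design choices behind
`strucnet`, in the order the pipeline applies them.

## Streamline filtering (anatomical exclusion criteria)

A connection's candidate streamlines are abstract records: track weight,
mean FA along the trajectory, and the set of gray-matter regions visited
(endpoints included). No 3D geometry is processed; mapping tractogram files
onto this table is delegated to an external adapter
(`strucnet.aec.TRACTOGRAM_ADAPTER_CONTRACT` names the contract).

Two rules are applied, in a fixed order:

1. **Weight threshold.** Keep records with weight ≥ `fraction` × the
   maximum weight *within that connection* (default fraction 0.01). The
   per-connection, relative-to-maximum reading makes the rule scale-free
   within a connection and degenerate-safe for single-streamline bundles.
   Alternatives (relative to total weight, or a weight quantile) would also
   be defensible; only the relative-to-maximum form is implemented.
2. **Anatomical exclusion.** Keep records whose visited-region set equals
   exactly the two endpoints. Streamlines touching any extra region, or
   truncated before reaching both endpoints, are removed.

The steps do not commute: an off-path record carrying the maximum weight
sets the threshold in step 1 before being removed in step 2. The
threshold-then-exclusion order is fixed and tested
(`test_order_threshold_then_exclusion`). The composition is idempotent and
monotone in `fraction`.

## Connectivity matrices

Edge FA is the **unweighted** arithmetic mean of the surviving streamlines'
mean-FA values (a track-weight-weighted mean is available behind
`weight_by_track=True`; averaging FA per streamline first, rather than
pooling FA samples across all streamline points, is the implemented
convention). An edge exists iff at least one streamline survives; absent
edges are 0 and participate in group statistics. Matrices are validated
against: symmetry (tolerance 1e−12), zero diagonal, entries in [0, 1],
label/shape consistency. TSV I/O round-trips at full float64 precision
(shortest-repr writing, `round_trip` parsing).

The packaged node table is the Desikan-Killiany cortical parcellation (34
regions per hemisphere) plus 8 subcortical structures per hemisphere
(thalamus, caudate, putamen, pallidum, hippocampus, amygdala, accumbens,
cerebellar cortex): 84 nodes, 3486 unordered pairs.

## Graph metrics

All metrics are computed on the weighted undirected matrix, following the
Brain Connectivity Toolbox's weighted conventions:

- **Lengths.** Connection length is 1/w; this is the single supported map.
- **Path length** averages shortest distances over *connected* pairs only;
  a fully disconnected graph is a degenerate input (error), an isolated
  node simply drops its pairs from the mean.
- **Global efficiency** is the mean of 1/d over all pairs with 1/∞ = 0, so
  disconnection lowers efficiency rather than erroring.
- **Transitivity / clustering** use the cube-root geometric-mean triangle
  intensity t_i = ½ Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3} with weights normalised by the
  network maximum, over binary degrees: T = Σ 2t_i / Σ k_i(k_i−1),
  c_i = 2t_i / (k_i(k_i−1)). Nodes of degree < 2 have c_i = 0.
- **Assortativity** is the Pearson correlation of endpoint *strengths* over
  the directed edge list (both orientations per undirected edge). On
  regular graphs the variance is zero and the result is an explicit NaN
  marker (`assortativity_defined=False`), never a silent 0.
- **Betweenness** is Brandes' single-source accumulation with
  multiplicity-aware path counting on Dijkstra orderings, reported as raw
  unordered-pair counts (not normalised fractions — the magnitudes of
  whole-brain summaries in this literature, ≈ 32 on 84 nodes, correspond to
  raw counts). Equal-length path ties are detected with relative tolerance
  1e−12; with continuous weights exact ties are measure-zero, and the test
  oracles use the same tolerance.
- **Hubs.** A node is a hub iff its strength, averaged across the group's
  subjects, strictly exceeds the across-node mean + 1 sample SD (n−1
  denominator). Ties at the threshold are not hubs. The rule is
  translation-invariant and is applied per group.
- The per-subject whole-brain record reports the across-node means of
  strength and betweenness (the mean-strength reading of group summary
  tables, rather than a network sum).

Every metric is verified against independent brute-force oracles
(Floyd-Warshall distances, explicit triple-loop triangle sums, exhaustive
simple-path enumeration for betweenness, the raw correlation formula for
assortativity) on random graphs of ≤ 6 nodes, to 1e−9.

## Statistics

- **Two-sample tests** are Student's pooled-variance t (not Welch), two
  sided. Zero pooled variance with equal means returns (t = 0, p = 1); with
  unequal means the vectorized screens return ±∞ and p = 0.
- **Families.** Bonferroni is reserved for the six whole-brain metrics
  (0.05/6 = 0.00833, reported as 0.008 at three decimals). The node screen
  (84 strengths) and the edge screen (all 3486 pairs, absent edges as 0)
  each get Benjamini-Hochberg FDR within their own family; cognition
  screens get FDR separately per score and per family. A minimum-presence
  filter for edges exists behind `min_presence` but defaults to off, since
  reported edge fractions in this literature refer to the full connection
  count.
- **BH-FDR** adjusted p-values are computed by statsmodels' step-up
  implementation and tested against the literal min-over-tail definition;
  rejection is adjusted-p ≤ q (default q = 0.05).
- **Correlations** are Pearson r with two-sided p from the t transform,
  computed over patients only (healthy volunteers carry no cognitive
  scores). Zero-variance edges yield r = NaN and are never significant; a
  constant score vector is a degenerate-input error.
- **ICC** is the two-way random-effects, absolute-agreement, single-measure
  form: ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2
  sessions and n = items. Items are the upper-triangle edges nonzero in at
  least one session — all-zero edges carry no agreement information; this
  dialect choice (vs all 3486 edges) raises n_items-sensitivity slightly
  but does not change the estimate materially at realistic densities. The
  implementation is a direct two-way ANOVA decomposition, cross-checked in
  tests against pingouin's ICC(A,1).
- **zAttention** is the arithmetic mean of zPASAT and zSDMT.

## Synthetic cohort generator

The generator replaces unavailable patient MRI data with cohorts whose
statistical structure matches the study design the pipeline targets.

**Base network.** A modular random graph (two hemisphere-like modules,
within:between edge-probability ratio 1.5) with preferential extra
attachment (factor 1.6) to `n_hub_nodes` designated hub nodes; pair
probabilities are rescaled by fixed-point iteration so the expected edge
count equals `edge_density` × 3486 exactly, hub boost notwithstanding. Edge
FA is Normal(fa_mean, fa_sd) clipped to [0.01, 1].

**Defaults** (chosen once as a realistic desk-scale study; uncalibrated to
any particular dataset): 84 nodes; 38 HV / 72 MS; edge density 0.6 and FA
0.45 ± 0.04, which yield whole-brain strengths ≈ 22–24 and path lengths ≈
2.9–3.1, the magnitudes typical of FA-weighted 84-node connectomes; 9 hub
nodes; FA reduced by 0.08 on 793 edges and increased by 0.08 on 24
(mirroring the scale of reported MS edge effects); subject noise SD 0.03;
retest noise SD 0.02 (giving ICC ≈ 0.8, the test-retest range reported for
FA-weighted matrices); cognition coupling 0.8 with noise SD 0.8 (z-scores
with SD ≈ 1.1); a 73-edge cognition circuit drawn from the decreased mask.

**Group effects** are applied to the shared base matrix *before*
per-subject noise, so all patients share effect loci (as lesion topography
partially does); per-subject variability enters only through additive
Gaussian edge noise truncated to [0, 1], applied to nonzero edges (support
is preserved, except that an effect large enough to drive an edge to 0
removes it for all patients).

**Cognition.** Patient z-scores are `coupling × (standardized circuit-mean
FA) + Normal(0, cognition_noise_sd)`, independently for zPASAT and zSDMT;
zAttention is their mean. A consequence of this generative form: because
all patients share the group-level effects, between-subject circuit-mean
variation is pure noise averaged over the circuit, so the correlation
between any *single* circuit edge and the score scales like
coupling-attenuated 1/√(circuit size). At the default 73-edge circuit,
per-edge correlations (≈ 0.1) sit below FDR detectability at n = 72 — the
default full-pipeline run therefore reports essentially no significant
cognition edges, and the recovery tests use small circuits (2–3 edges)
where per-edge correlations are strong. Recovering per-edge correlations
of ≈ 0.4–0.55 at a 73-edge circuit would require a per-subject severity
factor modulating the effect edges jointly, which this generator
deliberately does not include.

**What passing tests show.** The synthetic data share the analysis' own
assumptions (Gaussian edge noise, homoscedastic groups, linear coupling,
independent edges given the base). Passing null-calibration and recovery
tests therefore demonstrates the correctness and calibration of the
implementation under its stated model — not robustness to the realistic
violations (spatially correlated lesions, heteroscedastic FA, registration
error, non-Gaussian tails) present in real diffusion-MRI cohorts.

**Streamline bundles** for the AEC stage contain `n_true` direct-link
records (weights 0.6–1.0), `n_offpath` records visiting 1–2 extra regions,
and `n_lowweight` direct-link records with weights below 1% of the
true/off-path maximum. If a bundle contains only low-weight records the 1%
rule is relative to themselves and the heaviest survives; this edge case is
documented rather than special-cased.

## Pipeline and problem sizes

`run_full_analysis` executes: cohort simulation (or manifest loading), an
AEC→build demonstration on a subset of connections (default 30 pairs of the
first subject, 28 streamlines each — generating bundles for all 3486 pairs
× 110 subjects would add nothing scientifically), whole-brain/node/edge
comparisons, per-group hub detection, cognition screens, and same-day
retest ICC on the first `n_retest_subjects` (default 5) subjects. Runs are
deterministic given the seed and echo their resolved configuration;
re-running from the echoed configuration reproduces every table exactly.

The acceptance script scales its Monte-Carlo loops to desk size: 100 random
graphs for the metric oracles, 60 null replicates at the full 38/72 × 84
design for FDR calibration, 3 replicates for effect recovery, 20 seeds per
retest-noise level. The statistical acceptance tests use 100 null
replicates and 3 recovery replicates; a module-level null-exchangeability
test checks the nominal 5% rejection rate within its 99.9% binomial band
plus Kolmogorov-Smirnov uniformity of the p-values, the statistically
stable form of "never significant under the null".

## Known limitations

- No 3D streamline geometry, parcellation, registration, or MRI ingestion;
  the adapter from tractogram formats is a named contract, not code.
- Graph metrics beyond the implemented set (modularity, rich club,
  small-worldness, null-model normalisation) are out of scope.
- Betweenness tie handling assumes continuous weights; heavily quantised
  weight matrices could split ties inconsistently at the 1e−12 tolerance.
- The edge screen tests absent edges as structural zeros; if absence itself
  is informative missingness, the resulting t-tests mix presence and
  intensity effects.
- ICC is reported for the nonzero-union edge set; studies defining items as
  all possible edges will report slightly different values.
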