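# Methods

## Differential expression

Each contrast is a two-group comparison on sample-group labels. Per gene we
fit group means and a pooled residual variance s² on d = n₁ + n₂ − 2
degrees of freedom, then shrink toward a common prior by empirical Bayes:
the marginal distribution of s² across genes is treated as scaled F, and
(d₀, s₀²) are estimated by matching the mean and variance of log s² using
digamma/trigamma identities (the trigamma inverse is solved by Newton
iteration). The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) gives the
moderated t on d + d₀ df. When the log-variances are underdispersed
relative to trigamma(d/2), d₀ = ∞ and every gene uses s₀². The test suite
cross-checks the whole machinery against the reference R implementation
(limma, via Rscript) to 1e-10 on a heteroscedastic fixture; the estimator
is deterministic — no iterative model fitting beyond the scalar Newton
solve. Genes whose moderated variance is exactly zero are excluded with a
warning. Multiple testing is Benjamini–Hochberg everywhere, implemented
once in `diffexpr.bh_adjust` (validated against a brute-force step-up
enumeration and statsmodels) and reused by every stage. Selection
thresholds are strict (`fdr < threshold`).

The two contrast schemes of the pipeline are per-time (each post-injury
group vs control, default FDR < 0.001) and injured vs healthier (4 hpi–14
dpi vs controls + 90 dpi, default FDR < 0.005). Only the second feeds the
network; assigning fully regenerated 90 dpi hearts to the healthier side is
the biological statement that regeneration has returned expression to
baseline.

Probe collapsing keeps, per gene, the probe with the largest sample
variance by default ("max-variance"); "max-mean" and "mean" are selectable.
Max-variance favours probes that actually respond, which is the common
convention when no platform-specific rule is published.

## Network construction

Unsigned soft-threshold adjacency a_ij = |r_ij|^β with β = 6 over all
samples of all groups. β is deliberately fixed: `beta_sweep` reports
scale-free R², slope, median connectivity, density, heterogeneity and a
greedy-modularity Q across β = 1..12 for diagnostics, but nothing
auto-selects, so runs are comparable.

Edge filtering removes weights below τ; the boundary weight is kept. The
default τ = 0.26 corresponds to |r| ≈ 0.7996 at β = 6, marginally more
permissive than |r| ≥ 0.8 (0.8⁶ = 0.262144); an exact |r|-based filter is
available (`edge_filter: correlation`). Zero-variance genes are dropped
with a warning before correlation. The scale-free fit bins connectivities
into 10 equal-width bins and regresses log10(frequency) on log10(mean k);
degenerate inputs (constant k, fewer than 3 usable bins) are reported as
invalid fits with R² = 0 rather than an exception, because they occur
legitimately on thresholded near-regular networks.

## Module detection

**Hierarchical route.** Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) is computed on
the thresholded network; 1 − TOM feeds average-linkage clustering. The cut
is static and deterministic: among candidate heights (midpoints of gaps
between consecutive merge heights) we pick the one that maximises the
number of clusters of at least `min_size` (30) members, preferring wider
gaps and then lower cuts. Cutting too low merely fragments a module, which
the next step repairs: modules whose eigengenes (first principal component
of the standardised submatrix, sign-aligned with the mean profile)
correlate above `merge_threshold` (0.75) are merged iteratively, most
correlated pair first. A quantile-based cut is available via
`cut_quantile`; it is not the default because a fixed high quantile sits
above the module-join heights whenever weak between-module edges populate
the upper dendrogram, collapsing everything into one cluster. Modules are
labelled 1A..nA by decreasing size (ties broken by smallest gene id);
everything in clusters below `min_size` is reported unassigned.

**Cohesiveness route.** Greedy growth on the thresholded edge list: seeds
are unvisited nodes in decreasing weighted-connectivity order (ties by gene
id); each step applies the best single add/remove of a node by the
cohesiveness f(V) = w_in/(w_in + w_out + p·|V|) with penalty p = 2, until
no step improves f. The seed is never removed, which guarantees
termination; the accepted step log is retained so the monotone-growth
invariant is assertable. Candidate clusters with overlap
ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8 are merged to a fixed point; clusters below
`min_size` (5) or density 0.5 are dropped; survivors must pass a one-sided
Mann–Whitney comparison of member in-cluster vs out-of-cluster weight sums
(BH across clusters, adjusted p < 0.05). Labels 1B..nB by decreasing size.
Defaults are the conventional ones for this algorithm family;
`min_size` 5 keeps single-digit-size clusters — which this method is
expected to find — detectable.

Catalogues are compared by the full pairwise Jaccard matrix with the
arg-max pair reported.

## Hub detection

Weighted connectivity k_i = Σ_j a_ij over retained edges. The null
reassigns the multiset of retained edge weights at random to the fixed
edge set; per permutation all connectivities are recomputed, and
p_i = (1 + #{k_i^perm ≥ k_i})/(B + 1) with B = 1000 by default (p-values
floored at 1/(B+1); equality is counted with a small relative tolerance so
that exactly invariant configurations give p = 1). BH across genes, hubs
at adjusted p < 0.05, one-sided by construction — hubs are excesses, not
deficits. This null conditions on each node's degree, so a hub is a node
whose incident weights are systematically stronger than a random draw of
equally many weights: "many strong connections" rather than raw degree.
An alternative degree-preserving rewiring null (double edge swaps with
weights travelling with edges, 3 sweeps per permutation) is selectable;
finite swap budgets leave residual correlation with the observed topology,
which can only make that null conservative, and the suite asserts exactly
that.

A practical consequence, visible on the synthetic fixture: when a network
mixes strong within-module edges with weaker peripheral ones, the entire
tightly co-expressed module cores sit above the pooled-weight null and are
flagged alongside planted hubs. Planted-hub recall is therefore the
recovery target; the hub count itself depends on how heterogeneous the
edge-weight pool is.

## Enrichment, conservation, miR targets

Module–term enrichment is the one-sided hypergeometric upper tail on the
network's gene set as universe (modules are drawn from the network, so
testing against the whole array would inflate significance); annotations
are restricted to the universe first, only overlapping pairs are tested,
and BH runs across all tested pairs. Conservation is a 2×2 Pearson
chi-square without continuity correction (selectable), one species at a
time; a gene is conserved if it has at least one orthology record for that
species regardless of source, and network genes missing from the table
count as non-conserved with a logged warning. Zero margins are reported as
undefined rather than raised. miR mapping joins hub orthologs against the
target table per species, optionally restricted to a miR whitelist, and
collapses duplicate (miR, hub, species) triples keeping validated over
predicted evidence.

## Synthetic data

The generator emulates the statistical structure the analysis assumes — it
is a model of the analysis problem, not of microarray physics. Expression
is baseline + factor model + injury response + Gaussian noise:

- **Design:** 7 groups (control, 4 hpi, 1/3/7/14/90 dpi) × 3 replicates;
  2,000 genes, five 60-gene modules, 20 planted hubs by default — large
  enough to exercise all stages, seconds-scale to run.
- **Modules:** per-sample latent factors with loadings set so two ordinary
  members correlate at `within_module_correlation` (0.85). Latents are
  standardised and orthogonalised against the intercept, the
  injured-vs-healthier contrast, every module's response profile and each
  other. With only 21 samples, chance alignments of order 1/√21 ≈ 0.22
  would otherwise couple whole module pairs or make a module coherently
  stronger than its peers; orthogonalisation makes the latents what they
  represent — distinct co-expression programmes beyond the shared injury
  response.
- **Injury response:** per-gene group-mean shift
  sign·d·sd_g·decay(group)^γ, where d is a standardised effect size
  (default 2.6 within-group standard deviations), decay is
  (1, 1, 0.95, 0.85, 0.75, 0) from 4 hpi to 90 dpi (monotone, zero in
  regenerated hearts, largest early), and γ is a response-speed exponent
  drawn log-uniformly in (0.8, 1.25), shared within a module. Members of a
  module respond with a common sign and speed — a coherent programme —
  while background responsive genes draw their own sign and speed.
  Standardising the effect keeps the shared decay shape from turning the
  background responsive genes into one spurious co-expression blob, which
  would otherwise dominate the thresholded network. When
  `de_fraction > 0`, all module members are responsive (the network stage
  only sees injury-selected genes, so planted modules must survive
  selection); `de_fraction = 0` is the fully null configuration used for
  calibration, with no responsive genes at all.
- **Hubs:** planted hubs are module members with strongly reduced private
  noise (scale 0.1) and a small secondary loading (0.1) on a second
  module's latent. Their correlations to co-members — hence their incident
  edge weights — exceed ordinary members', which is precisely the excess
  the weight-shuffle test detects; hubness here is shared signal, not
  amplitude.
- **Companion tables:** annotation terms draw genes with configurable odds
  in favour of a designated module (odds 1 = enrichment null, ∞ = pure
  module terms); orthology assigns per-species orthologs with separate
  Bernoulli rates for hubs (default 0.78–0.79) and other genes (0.50);
  the miR table connects named regeneration-driver miRs to hub orthologs
  with validated/predicted labels, plus decoy rows targeting non-hubs so
  joins must filter.

Everything is deterministic given the config seed; a single generator
drives all draws in a fixed order.

**What passing tests do and do not show.** The generator produces
block-structured correlation, coherent group-mean responses and
conserved-enriched hubs, so recovery tests demonstrate that each algorithm
detects the structure it is designed for at realistic sizes and noise. It
does not emulate probe-level artefacts, batch effects, heavy-tailed noise,
correlated backgrounds, nested or overlapping true modules, or
array-specific normalisation — results on real arrays depend on those
upstream steps, which are out of scope (input is an already-normalised
matrix).

## Numerical and degenerate-input choices

- Correlations are clipped to [−1, 1]; adjacencies symmetrised and the
  diagonal zeroed exactly; TOM averaged with its transpose and clipped to
  [0, 1] against float drift.
- Thresholding is idempotent and keeps isolated nodes in the node list.
- Eigengenes drop constant genes with a warning and refuse all-constant
  submatrices; orientation follows the mean standardised profile.
- Sorting uses stable keys with explicit gene-id tie-breaks, so module ids
  and seeds are reproducible across platforms.
- The permutation test floors p at 1/(B+1) and requires B ≥ 100 and a
  thresholded network; an empty edge set yields all-ones p-values with a
  warning.
- results.json carries the config snapshot, package version and all stage
  summaries, sorted and timestamp-free; timestamps live in run.log, so
  repeated seeded runs are byte-identical.

## Problem sizes used by tests and the acceptance script

Unit tests run on hand-built instances and 120–800-gene simulations; the
recovery and acceptance checks use the full default 2,000-gene fixture
(≈380-node network after selection, B = 1000 permutations); calibration
uses one 2,000-gene null time course for the moderated t and ten
150-node/1,200-edge exchangeable networks at B = 199 for the hub test.
These sizes keep the whole suite around two minutes on one CPU while
leaving every stage at the scale the defaults target.

## Known limitations

- The moderated-t hyperparameter estimator assumes a common residual df
  across genes (no missing values within a contrast).
- The static dendrogram cut, though deterministic and robust on
  block-structured TOM, is not dynamic tree cut; deeply nested module
  hierarchies will be cut at a single height.
- The cohesiveness significance test treats member weight sums as
  exchangeable between clusters; it is a screening filter, not a
  calibrated p-value for overlapping clusters.
- The weight-shuffle hub null flags any node whose incident weights beat
  the pooled edge-weight distribution, including entire strong module
  cores (see Hub detection); interpret hub calls together with module
  membership.
- Orthology and miR tables are taken at face value: one record suffices
  for conservation, and evidence labels are not weighted.
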