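# Methods

This note documents the models and conventions behind `agonet`: what
each statistic is, the choices made where several definitions exist,
what the synthetic generator does and does not emulate, and the known
limitations.

## Aggression networks

The observational unit is one agonistic event: an initiator directs one
of four ethogram actions (head-knock, bite, fight, chase) at a receiver
in the same pen. Events accumulate over all observation sessions into a
weighted directed graph per pen with edge weight w(i→j) = number of
actions i initiated toward j, all four action types pooled ("total
aggression"). Conventions:

* **Fights count once**, attributed to the listed initiator. A fight is
  reciprocal by definition, but every logged event names an initiator
  and no symmetrization rule is defensible from the event record alone;
  attributing to the initiator keeps the edge semantics uniform across
  action types.
* **Rows with a "non-identified" initiator are dropped by default**
  (policy flag `non_identified_policy`): an event without a known
  initiator cannot contribute a directed edge. Dropped rows are counted
  in the ingest report so the information loss is visible.
* **The full roster is the node set.** Animals never observed
  interacting remain as zero-degree nodes — they are exactly the
  animals the rank classifier must label Isolated, so removing them
  would bias every population-level proportion.

## Individual centrality

* **Degrees are unweighted distinct-partner counts** (number of edges,
  not summed weights): out-degree = number of pen-mates attacked at
  least once, in-degree = number of distinct aggressors, all-degree =
  their sum. In pens of 10–15 animals these are small integers, which
  is what makes the Social Rank Index a simple fraction.
* **Closeness and betweenness use directed, unweighted shortest
  paths.** Attack counts are interaction tallies, not distances, so
  they carry no path-length meaning. Betweenness is raw (unnormalized)
  Freeman betweenness with fractional counting of tied shortest paths.
* **Unreachable pairs are charged distance n** in closeness:
  c(i) = 1 / Σ_{j≠i} d(i,j) with d(i,j) := n when j is unreachable
  from i. Sparse aggression graphs are mostly disconnected, so a
  finite-penalty convention is required for closeness to be defined at
  all; with it, an isolated animal in a pen of n scores 1/(n(n−1)),
  about 0.01 for n = 11 — the natural floor of the measure.
* **Eigenvector centrality is computed on the symmetrized weighted
  graph** A = W + Wᵀ: the measure describes connectivity to
  well-connected animals regardless of direction, and a directed
  variant is ill-defined on graphs that are not strongly connected
  (virtually every sparse pen). The principal eigenvector is found by
  power iteration to 1e-10 on A + I — the diagonal shift leaves the
  Perron vector unchanged while making the dominant eigenvalue strictly
  largest in magnitude, so the iteration also converges on bipartite
  components — and is rescaled so the maximum score is 1. An edgeless
  pen has all scores defined as 0.

## Social rank

SI = out-degree / all-degree for animals with all-degree > 0; SI ≥ 0.70
is Dominant (boundary inclusive), SI < 0.70 Subordinate; all-degree 0
is Isolated with SI undefined. Because degrees are unweighted, SI is
invariant to how often a given dyad repeated its interactions, and
reversing every edge maps SI → 1 − SI (Dominant and Subordinate can
swap; Isolated never changes).

## Group measures

* **Density** |E|/n(n−1) and **reciprocity** (fraction of directed
  edges whose reverse exists) are computed on the binarized graph;
  reciprocity of an edgeless pen is defined as 0 with a warning.
* **Freeman centralization** of a measure is Σᵢ(c\* − cᵢ) divided by
  the value of that sum on the star configuration of the same size —
  the classical normalizing graph — and clamped to [0, 1]. The star
  denominators are evaluated numerically once per (measure, n) by
  building the bidirectional star and scoring it with the package's own
  centrality functions, which keeps numerator and denominator on
  exactly the same convention (this matters for closeness, where the
  unreachable-penalty affects both). The clamp is needed because, under
  directed conventions, extreme configurations other than the star can
  slightly exceed the star sum for closeness.
* **Modularity** is weighted Newman Q on the symmetrized graph:
  Q = Σ_c [w_c/2m − (s_c/2m)²], with w_c the intra-community
  symmetrized weight, s_c the community strength and 2m the total
  symmetrized weight. Q of an edgeless network is defined as 0.
* **Community detection** is deterministic greedy agglomeration
  (Clauset–Newman–Moore style): start from singletons, repeatedly merge
  the connected community pair with the largest ΔQ (ties broken by the
  lexicographically smallest pair of representatives), continue to the
  top of the dendrogram, and return the best partition encountered.
  Merges across disconnected components are never made (they strictly
  lower Q and cannot enable a better later merge). If nothing beats the
  trivial single community, that is returned, so detected Q ≥ 0.
  Zero-degree animals are always reported as singleton communities
  (their modularity contribution is identically zero). Greedy
  agglomeration is not globally optimal — adversarial small graphs
  exist where the best cut requires declining the locally best merge —
  but it is deterministic and exact on clearly separated structure.

## Between-pen comparison

The Hamming distance between two equal-size pens is |E_A Δ E_B| over
binarized directed edge sets with **animals matched by roster slot
index**. Different pens house different animals, so no biological
correspondence exists; slot matching measures dissimilarity of labelled
structure (the convention of standard network Hamming routines) and is
documented prominently for that reason. The distance matrix per
equal-size pen group is projected by classical (Torgerson) MDS:
B = −½ J D² J, top-k eigenpairs, coordinates V√Λ. Classical MDS is
deterministic and exactly recovers Euclidean-embeddable inputs; graph
distances are generally not Euclidean, so negative eigenvalues are
truncated at zero with a warning. Pen groups are auto-detected by
roster size; singleton size classes are skipped with a warning.

## Traits

ADG is the within-animal OLS slope of body weight (kg) on age (days);
BW and BF are the fitted lines evaluated at 180 days. FCR = ADC/ADG,
flagged undefined when ADG ≤ 0. Feeding-behaviour traits are computed
per day, then averaged over days with visits: FR = daily intake / daily
trough time (g/min) — the "average of daily rates", which differs from
total intake / total time under day-to-day variation; OT = daily trough
minutes; FF = daily visit count; FInt = mean gap between consecutive
visit start times in minutes, averaged over days with ≥ 2 visits; ADC =
mean daily intake in kg. FInt units are a genuinely open convention in
the field's reporting (min/day and hours both appear, mutually
inconsistently at typical visit frequencies); minutes between
consecutive starts is used here and stated in every output header.

## Association

Spearman ρ is the Pearson correlation of mid-ranks, with two-sided
p-values from t = ρ√((n−2)/(1−ρ²)) on n−2 df. The t approximation is
accurate at the ~300-animal scale of a multi-pen study; a seeded
permutation option exists for small samples. Animals are pooled across
pens (pen structure ignored), matching how individual-score association
tables are conventionally reported; a stratified per-pen analysis can
be built from the per-pen tables if needed. No multiple-testing
correction is applied; stars mark per-cell p < 0.05 / p < 0.01.

## Synthetic study generator

The generator emulates a fattening-unit study: 29 pens totalling 326
animals (11 pens of 11 and 8 of 12 — the two equal-size comparison
groups — plus 7 of 10 and 3 of 13), six observation sessions, behaviour
mix 74/19/5/2% head-knock/bite/fight/chase, and a few hundred events
concentrated in few dyads.

Model: each animal has latent dominance d_i ~ N(0,1) and is isolated
with probability p_iso = 0.21 (isolated animals neither initiate nor
receive — total non-participation, matching the all-degree-zero
definition of Isolated). Attack counts per ordered non-isolated pair
are Poisson with mean λ·exp(α(d_i − d_j)); the exponential form sends
attacks down the hierarchy and produces the strong dyad concentration
seen in sparse pen aggression. Optional planted community blocks
multiply within-block rates by a configurable factor.

Calibration (all frozen defaults):

* λ is derived from a target expected event total of 551 via
  E[exp(α(d_i − d_j))] = exp(α²), i.e. λ = T / (Σ_pens n(n−1) ·
  (1−p_iso)² · exp(α²)). Realized totals vary substantially between
  seeds because the rate distribution is heavy-tailed.
* α = 0.5 was chosen by a one-time sweep so that the pooled rank
  composition lands near 21/58/21% Dominant/Subordinate/Isolated; the
  realized Isolated share exceeds p_iso slightly because non-isolated
  animals can also end up with zero interactions by chance.
* Trait marginals use realistic fattening-pig scales (FR 40.6 ± 8.0
  g/min, OT 59.5 ± 9.7 min/day, FF 10.7 ± 2.9 visits/day, ADG 0.81 ±
  0.10 kg/day, BF 18.5 ± 4.2 mm; FInt 80 ± 18 min between starts).

Trait coupling is a Gaussian copula on pooled out-degree mid-ranks: for
each configured trait, a latent normal score with Pearson correlation
2·sin(πρ_s/6) to the rank-normal out-degree score is drawn, so the
targeted *Spearman* correlation is ρ_s (default effects: FR −0.18, OT
+0.15, FF +0.10, FInt −0.11, ADG −0.01, BF −0.01). Feeder visit logs
and measurement series are then synthesized around the per-animal
targets with small day-level noise (gamma-distributed visit durations
and gaps, ~1 kg weighing noise), so the traits the pipeline derives
from raw logs inherit the planted correlations with mild attenuation
(ties in out-degree and day-level noise shrink recovered |ρ| by roughly
0.01–0.03 at 326 animals).

Randomness: one seed drives everything; per-pen substreams are keyed by
(seed, pen index) so each pen's data is independent of how many other
pens exist or in what order they are generated. Identical (config,
seed) pairs reproduce every table byte for byte.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: temporal dynamics of hierarchy formation
across sessions (events are exchangeable over sessions); sex-group
differences; observation-window censoring (real studies watch 40
min/day, the generator draws study-total counts directly); growth
nonlinearity (weights are linear in age by construction, so the OLS
growth model is exactly specified rather than an approximation); and
any dependence of feeding behaviour on pen-mates' behaviour beyond the
planted rank correlations.

## Problem sizes and tolerances

Graph-measure implementations are validated exhaustively against
brute-force references on all digraphs with n ≤ 4 and on batches of
random digraphs up to n = 8; Spearman against an explicit
rank-then-Pearson computation to 1e-12; MDS against Euclidean inputs to
1e-8; eigenvector centrality against dense eigendecomposition to 1e-8.
Synthetic-recovery checks use 50-seed batches at the default 29-pen
scale. Degenerate inputs (edgeless pens, constant vectors, single-visit
days, unequal pen sizes) are either defined explicitly (see above) or
rejected with named errors; these choices are covered by dedicated
tests.

## Limitations

* Greedy modularity is a heuristic (see above); reported Q values are
  lower bounds on the optimum.
* Slot-index Hamming comparison is structural, not biological; distances
  between pens say nothing about individual animals.
* The closeness unreachable-penalty and the star-denominator details of
  centralization are conventions; scores are comparable within this
  package but not necessarily with other software using different
  conventions.
* Pooled correlations ignore pen-level dependence, so p-values are
  anti-conservative to the extent that pen effects exist.
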