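# Methods

## Scope

fconnet analyzes the topology of resting-state functional connectomes:
per-subject correlation matrices are proportionally thresholded into
binary graphs, a standard measure set is computed per node and whole-brain
across a sparsity grid, groups are compared on cross-sparsity integrated
values with multiple-comparison control, and a diagonal NCA ranks which
whole-brain measure best separates the groups. Everything upstream of the
ROI time series (image preprocessing, parcellation of volumes, nuisance
regression) is out of scope: the input contract is one T×N delimited-text
matrix per subject plus a node table (label, MNI coordinate, functional
network).

## Synthetic cohort generator

Each subject's time series is drawn from a zero-mean multivariate normal
whose correlation matrix is block-structured: within-network off-diagonal
entries take a per-group, per-network target `w`, all other off-diagonals
a common `b < w`, unit diagonal. Independent Gaussian observation noise of
standard deviation `noise_sd` is added.

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| groups | HC / ODN / ODP, 15 subjects each | three-group case-control design |
| T | 150 volumes | a conventional ~6 min run at TR 2.5 s |
| within `w` | HC: 0.60 all networks; ODN: DMN 0.58, cingulo-opercular 0.46, others 0.52; ODP: DMN 0.62, cingulo-opercular 0.36, others 0.42 | segregation ordered HC > ODN > ODP with a DMN-specific increase and cingulo-opercular decrease in the patient groups |
| between `b` | 0.10 | weak background coupling |
| noise_sd | 0.3 | attenuates correlations by 1/(1+0.3²) ≈ 0.92, leaving empirical within-network r ≈ 0.55 for HC |
| atlas | 160 ROIs in six networks (cerebellum 18, cingulo-opercular 32, default 34, fronto-parietal 21, occipital 22, sensorimotor 33) | the six names and the 160 total follow the Dosenbach-style scheme; the per-network counts are a plausible partition and are configurable; other sizes are scaled proportionally |

Two facts worth knowing. First, observation noise attenuates *every*
correlation by `1/(1 + noise_sd²)`, so empirical matrices converge to the
attenuated block structure, not the raw targets; convergence to the
targets themselves holds at `noise_sd = 0` (checked at T = 5000 within
±0.02). Second, a `match_mean_connectivity` variant solves per-group `b`
so the weighted mean off-diagonal correlation is identical across groups —
group effects are then carried purely by the within/between contrast
(segregation) rather than overall connectivity strength.

The generator does **not** emulate hemodynamics, temporal autocorrelation,
motion or physiological artifacts, negative correlations, spatial
autocorrelation, or heavy-tailed noise. Passing recovery tests therefore
demonstrates that the analysis chain detects the designed covariance
effects at realistic sample sizes — not that it is robust to real fMRI
artifact structure. Positive-definiteness of every target matrix is
verified by Cholesky factorization at generation time (with the
within > between ≥ 0 design constraints it is provably positive definite;
the check guards externally supplied matrices).

## Connectivity and thresholding

Pearson r between all ROI pairs, clipped to ±(1 − 1e−7) before the Fisher
transform so z stays finite, diagonal fixed at 0. Binarization keeps the
`round(S · N(N−1)/2)` strongest edges (signed Fisher z by default —
strongest positive first, the common proportional-thresholding practice;
an `absolute` mode ranks by |z|). Ties break by lexicographic (i, j)
order, which makes edge sets exactly nested across the grid and the edge
count bit-reproducible. Because ranking is invariant to strictly monotone
transforms, thresholding on raw r or Fisher z yields identical graphs.
The default grid is 0.10–0.50 in steps of 0.05 (nine levels); the 10%
floor limits fragmentation at the sparse end.

## Graph measures: conventions

- Clustering `C_i = 2E_i/(k_i(k_i−1))`; nodes with degree < 2 get `C_i = 0`
  and are included in the whole-brain mean.
- Path length averages over reachable ordered pairs only; a node with no
  reachable partner gets NaN, is excluded from the global mean, and a
  warning is emitted. Efficiency uses 1/∞ = 0, so it is always defined.
- Local efficiency of node i = global efficiency of the subgraph induced
  by its neighbors (i excluded); 0 for degree < 2.
- Betweenness uses the ordered-pair normalization
  `b_i = (1/((n−1)(n−2))) Σ_{h≠j≠i} ρ_hj(i)/ρ_hj ∈ [0, 1]` (Brandes
  accumulation via networkx; for undirected graphs the networkx normalized
  value equals this exactly).
- Modularity uses the degree-sum convention `l = Σ_i k_i = 2E`, validated
  by the fixed case "two disconnected equal cliques, natural partition →
  Q = 0.5". Louvain runs at resolution 1 with 10 restarts (seeded), keeping
  the max-Q partition; community structure is estimated per subject and
  per sparsity level.
- Participation `y_i = 1 − Σ_m (k_i(m)/k_i)²`, 0 for isolated nodes.
- Assortativity is the Pearson correlation of end-point degrees over the
  edge list (both orientations); NaN (undefined) when the end-point degree
  variance is zero, e.g. regular graphs. Undefined values are excluded
  pairwise from group contrasts.
- Null model: Maslov–Sneppen double-edge swaps, preserving the degree
  sequence exactly; defaults 100 nulls, 10 swaps per edge. With 0 swaps
  the nulls equal the graph itself, giving γ = λ = σ = 1 exactly — a
  useful identity check. A triangle-free null ensemble (C_Rand = 0) leaves
  γ undefined (NaN) rather than infinite.
- Small-world flag: γ > 1, |λ − 1| ≤ 0.15 (configurable) and σ > 1.
- Cross-sparsity integration: trapezoidal area under the
  metric-versus-sparsity curve over the grid; per-level values are also
  retained, and per-level statistics are available.

## Group statistics

Two-sample two-tailed t-tests, equal-variance by default (Welch via flag).
Reported t carries the sign of (second − first) group mean, so a negative
t means the second group in the contrast is lower — the usual
patient-versus-control table convention; swapping the contrast order flips
every sign exactly. Nodal comparisons run on integrated values with one
BH-FDR family per contrast per metric (the N nodes); the uncorrected
p < 0.005 mode mirrors exploratory nodal mapping practice. The
network-level "normalized clustering coefficient" is defined here as the
subject's mean nodal clustering over a network's ROIs divided by the
subject's whole-brain mean nodal clustering — an interpretation choice,
flagged as such; it expresses each network relative to the subject's
overall segregation level and cancels global shifts.

## NCA feature ranking

Ten whole-brain features per subject (CC, SW, LE, PL, GE, Ass, PC, FC,
Mod, BC; FC = mean upper-triangle Fisher z), z-scored. The diagonal NCA
objective is the expected leave-one-out soft-nearest-neighbor
misclassification loss with reference probabilities
`p_ij ∝ exp(−d_w(x_i,x_j)/σ_kernel)` and weighted L1 distance
`d_w = Σ_r w_r²|x_ir − x_jr|`, plus ridge penalty `β Σ_r w_r²` — the form
used by the standard MATLAB implementation of this method. Defaults:
σ_kernel = 1 (natural after z-scoring), β = 1/n. Optimization is
deterministic L-BFGS-B with analytic gradient from the fixed start
w_r = 1; leave-one-out is implicit in the j ≠ i sum (no outer CV loop).
The objective trace over accepted iterates is monotone non-increasing;
non-convergence flags the result rather than raising. Importance = w²;
the report normalizes importances to sum to 1 (uniform if all are zero,
e.g. the single-class degenerate case).

## Validation experiments and problem sizes

The `experiments` module packages the standard validation studies; the
test suite and `scripts/acceptance.py` run them at these sizes, chosen so
a full multi-seed study completes in minutes on one core:

- **Oracle agreement**: 200 random graphs, n ≤ 15, every measure vs an
  independent brute-force implementation (triangle enumeration,
  Floyd–Warshall, exhaustive geodesic counting), tolerance 1e−10.
- **Small-world benchmarks**: Watts–Strogatz ring (n=100, k=4, p=0.1)
  against 100 nulls (σ ≫ 1); Erdős–Rényi control at matched density
  reported as the mean σ over 10 instances — at mean degree 4 a single
  instance holds only a handful of triangles, so per-instance σ is a ratio
  of two small counts and fluctuates ~0.5–1.4 while the instance mean sits
  at ≈ 1.
- **Type-I control**: 100 cohorts of three identically-generated groups
  (n = 15, 40 ROIs); fraction of cohorts where the nodal FDR < 0.05
  clustering comparison rejects ≥ 1 node.
- **Effect recovery**: 20 seeds of the default design at 40 ROIs:
  whole-brain clustering lower in ODP vs HC (p < 0.05), DMN normalized
  clustering ordered ODP > ODN > HC, cingulo-opercular ordered
  HC > ODN > ODP.
- **NCA recovery**: 20 seeds of the mean-connectivity-matched design at
  40 ROIs with reduced ensembles (6 nulls, 3 swaps/edge, 3 Louvain
  restarts) for the per-subject, per-level small-world features; a
  label-permutation control.

## Known limitations

- **Collinear features and NCA selection.** Under a block-correlation
  generator, whole-brain clustering and local efficiency are near-collinear
  readouts of the same injected effect (r ≈ 0.98 across subjects), and at
  fixed edge count a drop in within-network correlation randomizes
  topology, moving integration measures (path length, global efficiency,
  betweenness) together with segregation. The sparse NCA therefore
  reliably ranks small-worldness first (~90% of seeds) but splits the
  remaining weight essentially arbitrarily within the
  clustering/efficiency family — the exact pair {CC, SW} tops the ranking
  in only ~25–35% of seeds. This is a property of the generator class and
  of sparse selection among collinear features, not of the optimizer:
  empirical cohorts in which integration genuinely does not differ between
  groups are outside what a block-correlation design can produce.
- Path-length integration over the grid is NaN for subjects with a node
  unreachable at every level; nodal statistics on path length at very
  sparse thresholds should be interpreted accordingly (clustering, the
  default statistics metric, is always defined).
- Louvain is a stochastic heuristic; restarts with a fixed seed make runs
  reproducible, not globally optimal.
- The per-subject, per-level community structure means participation
  coefficients are not directly comparable node-by-node across subjects;
  only their summaries are compared.
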