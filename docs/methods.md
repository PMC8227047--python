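# Methods

This note records the model assumptions, parameter choices, and numerical
decisions behind `strucnet`, in the spirit of a methods appendix.

## Network construction

A weighted connectome `W` (symmetric, nonnegative, zero diagonal; entries
are streamline counts) is binarized by an absolute threshold
`t = f · max(W)` with `f = 0.001` by default (0.1% of the maximum count,
the convention of common deterministic-tractography software). The
comparison is `w_ij ≥ t`: an edge exactly at threshold survives, which
keeps the rule stable when counts are integers. Isolated nodes are
retained, so `N` is fixed by the parcellation scale and disconnection is
handled explicitly by the metrics.

The group backbone keeps edge (i, j) when the fraction of subjects whose
binary network contains it is ≥ the consensus level (default 0.75, so 3 of
4 subjects qualifies). The threshold is applied per subject before
consensus, matching the order subject-network → backbone. Per-edge
consensus fractions are stored alongside the backbone adjacency.

## Topological metrics

- **Clustering** `C_i = 2·T_i / (k_i(k_i−1))` with `T_i` triangles at node
  i; degree-<2 nodes contribute 0 and are included in the average over all
  N nodes (toolbox convention).
- **Characteristic path length** averages BFS distances over connected
  ordered pairs only; the disconnected-pair fraction is reported as a
  separate field rather than folded into the mean.
- **Global efficiency** uses `1/∞ = 0`, so it is defined for disconnected
  networks and increases weakly when edges are added.
- **Small-world reference**: `C_R = d/N`, `I_R = log N / log d` are the
  closed-form Erdős–Rényi expectations for matched size and mean degree;
  the log base cancels in the ratio (natural log used). `I_R` requires
  `d > 1`. The analytic reference is fast and deterministic but is an
  asymptotic approximation: in dense graphs it understates the true ER
  path length, so `σ` for a dense ER graph sits slightly *below* 1
  (measured ≈ 0.79–0.81 at N=200, p=0.2) rather than exactly at 1. `σ > 1`
  is the single small-world criterion.
- **Modularity** is maximized by Newman's spectral method: recursive
  bisection along the sign of the leading eigenvector of the generalized
  modularity matrix, each bisection refined by a Kernighan–Lin
  single-node-swap pass, followed by greedy single-node moves (including
  into fresh singleton communities) and community merges until Q is
  stable. Eigenvector sign and all ties are resolved toward the lower node
  index, so the optimizer is deterministic without any seed. Because
  recursive bisection cannot represent every optimum on very small graphs,
  communities of ≤ 12 nodes are bisected by exact sign-vector enumeration
  and whole networks of ≤ 10 nodes are solved by exhaustive partition
  search; at those sizes enumeration costs milliseconds and removes the
  heuristic gap entirely (verified against brute force over all set
  partitions in the test suite).

## Rich-club analysis

`Φ(k)` retains nodes with degree **strictly greater** than k (the `E_>k`,
`N_>k` convention); the result is NaN when fewer than two nodes remain,
and the k grid runs from 1 to max-degree − 1. `Φ(k)` is computed in O(E)
per network from the histogram of per-edge minimum endpoint degrees, which
matters because it is evaluated on every null network. Note `Φ(k)` is not
guaranteed monotone in k — small graphs show genuine dips — although it
typically trends upward.

Null networks are Maslov–Sneppen double-edge swaps: `10·|E|` successful
swaps per null, rejecting proposals that would create self-loops or
multi-edges, which preserves every node degree exactly. Proposals are
pre-drawn in blocks from a seeded PCG64 generator and consumed by a
compiled (numba) kernel, so each null is bit-reproducible given its seed;
the m nulls use independent `SeedSequence` substreams spawned from the
master seed. Inputs admitting no legal swap (e.g. complete graphs,
triangles) are returned unchanged after a bounded number of rejected
attempts, with a warning. Connectedness is not enforced — only the degree
sequence is.

Significance is assessed two ways, both reported:

- per k: `p(k) = #{Φ_random,i(k) ≥ Φ(k)}/m`, the plain null proportion,
  with ≥ so ties make p conservative; p = 0 is printed as `< 1/m`. The
  `significant_k_range` is the longest contiguous run with `Φ_norm > 1`
  and `p < α` (first run on ties).
- range level: Φ and each null's Φ_random are averaged over the rich-club
  zone (the k with `Φ_norm > 1`) and compared as a single permutation test.

Neither test alone is calibrated as a detector: the per-k run inherits a
multiplicity over the ~k_max degree levels (on Erdős–Rényi graphs a
spurious one-k "run" appears in roughly a fifth of draws), while the range
test conditions on the `Φ_norm > 1` zone, biasing the observed average
upward. The package therefore calls a network *rich-club organized*
(`RichClubResult.has_rich_club_regime`) only when **both** tests reject at
α. Measured on 20 ER draws (N=200, d=10, m=200) this declares no regime in
19/20, while planted-hub networks are detected in 20/20 with perfect hub
recovery.

The reported k level is the k minimizing `|#{i: k_i > k} − 0.2·N|`
(20% of nodes ranked rich by default), ties toward the smaller k (the more
inclusive club). On degenerate degree distributions (e.g. regular graphs)
the nearest achievable club can be empty or the whole node set; the result
carries a `degenerate_club` flag. Edges are then classified RC (both
endpoints rich), FC (exactly one), LC (neither); the three percentages
partition the edge set and sum to 100.

## Friedman test

Within-subject ranks (average ranks on ties), tie-corrected chi-square
statistic with df = c − 1 and the upper-tail asymptotic p. For panels with
n·c ≤ 12 cells an exact p is computed by enumerating all `(c!)^n`
within-subject orderings (the identity included, so p ≥ (c!)^-n and the
exact test is level-α). The chi-square approximation is coarse at these
sizes — against the exhaustive oracle the asymptotic p deviates by up to
≈ 0.27 for c = 2 panels — which is why the exact p is attached whenever
feasible; at n = 30 the asymptotic p tracks a Monte-Carlo permutation p
within ≈ 0.03. No multiple-testing correction is applied across
metric/scale panels by default (per-comparison α = 0.05); a Bonferroni
option exists.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the imaging physics. Defaults mirror a 35-subject cohort, eight sampling
schemes (four single-shell, four multishell tags) and six scales (68, 200,
400, 600, 800, 1000 nodes).

- **Base networks**: Erdős–Rényi; Watts–Strogatz; planted rich-club (the
  first ⌈0.2·N⌉ nodes are hubs, block densities p_rr = 0.9, p_rf = 0.3,
  p_ll = 0.1); planted modular (equal blocks, p_in, p_out). Hub/module
  *proportions* are held fixed across scales; the base network is redrawn
  per scale (no geometric atlas downsampling).
- **Subject noise**: each dyad flips with probability 0.05 — small enough
  that a 75% consensus backbone recovers the base edge set almost exactly
  (binomial tail: ≥ 6/20 flips is ~3·10⁻⁴ per edge), large enough that
  subjects differ visibly.
- **Scheme effects**: schemes add long-range edges (ring distance > N/4 in
  an index embedding) with a bonus probability growing from 0 to 0.01 with
  the highest b-value in the tag — a minimal, qualitative emulation of
  high-b acquisitions recovering longer streamlines. It is not a diffusion
  model.
- **Weights**: present edges draw counts `1 + NegBin(mean 49, size 0.5)`
  (mean 50, overdispersed, strictly positive), a stand-in for heavy-tailed
  streamline counts.
- Every (subject, scheme, scale) cell has its own keyed `SeedSequence`
  substream, so any subset of the design reproduces the full design's
  matrices bit-for-bit.

What passing tests on these cohorts shows: the pipeline recovers planted
topology (hubs, modules, backbone edge sets) under subject noise and
controls false positives on structureless graphs. What it does not show:
robustness to tractography biases (distance-dependent false negatives,
gyral bias, spatially correlated noise), which real streamline data have
and this generator deliberately does not model.

## Problem sizes and defaults

The number of rewired nulls defaults to m = 1000 (standard analysis
value); the packaged demo config uses m = 200 with 8 subjects, 2 schemes
and scales 68/120, which completes in well under a minute on one CPU while
leaving the permutation resolution at 1/200 = 0.005. Stochastic
validation suites (ER control, planted recovery) use 20 seeds at N = 200,
m = 200. Pipeline group seeds are SHA-256 hashes of
(master seed, scheme, scale), so adding a group never perturbs another
group's nulls, and `results.json` is byte-identical across reruns of the
same config.

## Known limitations

- Weighted-network metric variants (weighted rich club, weighted
  efficiency) are out of scope; all analysis is on binarized networks.
- The analytic small-world reference is biased in dense or very sparse
  regimes (see above); it is the method's stated reference, not a
  limitation of the implementation, but σ values should not be compared
  across very different densities.
- The range-level permutation test inherits the zone-selection bias of its
  definition; use `has_rich_club_regime` (the conjunction) for detection
  decisions.
- The spectral modularity optimizer is a heuristic for networks larger
  than 10 nodes; Q is a lower bound on the true maximum there (the planted
  4-module recovery suite measures ARI ≥ 0.9 in practice).
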