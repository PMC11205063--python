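# Methods

## The estimation problem

Verbal fluency data — ordered lists of category exemplars produced under
time pressure — are a standard behavioral window onto the organization of
semantic memory. A group-based semantic network treats each distinct
response type as a node and infers edges from how responses co-occur across
participants. Because a single group yields a single network, and therefore
a single value of any global structure metric, group comparisons require a
resampling scheme; this package implements the full chain from raw response
lists to bootstrap-based inference.

## Pipeline

1. **Cleaning.** Tokens are whitespace-trimmed and case-folded, passed
   through a user-supplied normalization dictionary (variant → canonical;
   required to be idempotent), checked against an exclusion list of
   non-category intrusions, and de-duplicated within each participant's
   list keeping the earliest position. Cleaning is deterministic and fully
   logged; it replaces interactive expert spell-checking so that every
   exclusion is reproducible from the logs alone.
2. **Participant exclusion and grouping.** Participants producing fewer
   than 3 responses on any task are removed from all tasks. Knowledge
   groups are formed by a median split on the knowledge-test score computed
   over the retained participants; participants scoring exactly the median
   belong to neither group, so the groups are strictly separated. When the
   sample median falls between two observed values nobody is removed.
3. **Binarization and filtering.** A binary participant × response-type
   incidence matrix is built per task and timepoint over the analyzed
   sample; response types produced by fewer than 2 participants are
   dropped. Compared cells (group × timepoint) are then restricted to the
   intersection of their produced-token sets, in identical column order, so
   structural comparisons are not confounded by vocabulary differences.
4. **Association and filtering to a network.** Pairwise association is the
   cosine of the binary production vectors, in [0, 1]. The dense cosine
   matrix is filtered with the triangulated maximally filtered graph
   (TMFG): seed the 4-clique over the vertices with the largest similarity
   row sums, then repeatedly insert the (vertex, triangular face) pair with
   the largest summed similarity to the face's corners, splitting that face
   into three. The output is planar and connected with exactly 3n − 6
   edges. Edges whose cosine is exactly zero carry no co-occurrence
   evidence — they are forced in only by the triangulation — and are
   dropped from the final binary network, which is analyzed unweighted
   (cosine values are kept as edge annotations only).
5. **Global metrics.** Clustering coefficient CC (average local clustering,
   with degree < 2 nodes contributing 0; global transitivity available as a
   variant), average shortest path length ASPL (breadth-first distances
   averaged over unordered pairs; on a disconnected graph, computed on the
   largest component with a logged warning), modularity Q (Newman–Girvan
   value of the best partition found by multilevel Louvain detection),
   plus density, average degree, and global efficiency as descriptives.
6. **Inference.** Each observed network is benchmarked against M uniform
   random simple graphs with matched node and edge counts (empirical
   two-sided p with the +1 correction, so the smallest attainable p is
   1/(M+1)). Group and timepoint contrasts use a case-wise bootstrap:
   participants are resampled with replacement at the original n, the
   network re-estimated per replicate (node universe and frequency filter
   fixed from the full sample; zero-production columns dropped per
   replicate), and the B replicate metric values compared with
   pooled-variance Student t-tests — independent between groups
   (df = 2B − 2), paired by iteration index across timepoints (df = B − 1)
   — a 2×2 fixed-effects ANOVA with interaction on the 4B replicate values
   (denominator df = 4B − 4, η² = SS_effect/SS_total), and BIC-approximated
   Bayes factors, BF₁₀ = exp((BIC₀ − BIC₁)/2), from the nested Gaussian
   mean models on the replicate values; BF₁₀ ≥ 3 is the conventional
   evidence threshold. Self-reported course grades are natural-log
   transformed (they are strongly right-skewed) before Pearson correlation
   with test scores and fluency counts, pairwise complete.

Degrees of freedom in this scheme scale with B, an analysis choice, not
with the number of participants; p-values from bootstrap comparisons are
therefore resolution-dependent and the effect size d is the primary
output. Every comparison logs this caveat.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_responses` | 3 | lists shorter than this exclude the participant everywhere |
| `min_producers` | 2 | minimum producers for a response type to enter the matrix |
| `B` | 1000 | bootstrap iterations per cell |
| `M` | 1000 | matched random graphs per baseline test |
| `cc_variant` | `local_average` | Watts–Strogatz average local clustering |
| `louvain_runs` | 10 (3 inside the bootstrap) | seeded detection restarts; best-Q partition kept |
| `master_seed` | 0 | all stage seeds derive from it by hashing the stage name |

The analysis drivers under `analysis/` run with B = M = 300 to keep a desk
run in the low minutes; the inferential conventions are unchanged, only the
resolution of the bootstrap distributions.

## Numerical and algorithmic choices

- **TMFG tie-breaks.** Seed clique: largest similarity row sums, ties to
  the lowest label; insertion: largest gain, ties to the lowest vertex
  label then the lowest face creation index. This makes the filter
  deterministic and label-permutation equivariant, verified against a
  brute-force full-rescan implementation in the tests.
- **Community detection.** Louvain's outcome depends on traversal order, so
  restarts present the vertices in fresh seeded random orders and the
  highest-Q partition is kept; detection uses igraph's C multilevel
  implementation with its RNG pinned per restart, so results are
  bit-reproducible given the seed. Because Louvain is a greedy heuristic,
  the detected partition can miss the exhaustive-search maximum on a small
  fraction of graphs (about 0.5% of random ≤8-node graphs in our battery);
  the tests therefore verify the Q *value* against the hand formula
  Σ(e_ii − a_i²) on the detected partition and bound it by the exhaustive
  maximum, rather than asserting heuristic optimality.
- **Gaussian BIC for Bayes factors.** BIC = n·ln(RSS/n) + k·ln(n) with k
  counting mean parameters; the shared variance parameter contributes
  identically to both models and cancels in the difference.
- **Rounding.** Printed descriptives are rounded half-up at 2 decimals.
- **Degenerate inputs.** Zero-variance comparisons, edgeless graphs for
  path metrics, empty filtered matrices, and infeasible (n, m) requests
  raise typed errors rather than returning placeholders; bootstrap
  replicates with fewer than 4 produced response types are redrawn (logged)
  and 100 consecutive failures abort.

## The synthetic-data generator

Each group × timepoint cell gets a planted connected network —
Watts–Strogatz small-world (`n_words`, even `k_neighbors`, `rewire_prob`)
or planted-partition (`n_blocks`, `p_in > p_out`) — whose true CC/ASPL/Q
are recorded. A simulated participant produces a fluency list by a censored
random walk: uniform start, uniform steps to neighbors, a uniform restart
with probability 0.05 per step (a stand-in for strategic patch switching),
reporting each node on first visit only, until the target list length or a
step cap of 1000 × length. List lengths are truncated-normal integers
(floor 3), defaulting to the magnitudes typical of these tasks:
domain-specific lists ≈ 10 (SD ≈ 4) and domain-general lists ≈ 16–17
(SD ≈ 5) per group. Knowledge scores are integer normals per group (low
14 ± 3, high 26 ± 3 out of 37), separated enough that a median split
recovers the planted groups; the 1–9 grade ordinal loosely tracks the
score. Planted networks default to `k_neighbors = 6` — matching the
average degree a 3n − 6 planar filter can actually represent — with the
high-knowledge group barely rewired (0.05) and the low group heavily
rewired (0.3) by default.

What the generator does **not** emulate: word-frequency and typicality
effects, semantic-distance-weighted transitions, retrieval fatigue over
the list, within-participant retention across timepoints (each cell gets a
fresh planted network), or item-level realism for any specific domain.
Passing recovery tests on this generator show the estimation chain is
internally consistent, not that real fluency data satisfy the random-walk
model.

## A negative result worth knowing about

With planted small-world contrasts (rewire 0.05 vs 0.5 at 60 words, 60
participants per group, lists ≈ 15), the pipeline recovers the planted
ASPL and Q orderings in 20/20 replications — but systematically *inverts*
the CC ordering (0/20). The inversion is not a sampling artifact: it
persists with more participants and longer lists, at every latent density
we probed (k = 6 to 20), and even when the estimator is handed a
near-perfect similarity matrix (the latent adjacency plus negligible
noise). The cause is the filter itself: TMFG always returns a planar
triangulation with ~3n − 6 edges, and its average local clustering is
dominated by the triangulation geometry. Unstructured similarity yields a
compact, quasi-random maximal planar graph with high local clustering
(≈ 0.72), while strongly locally-structured similarity forces an elongated,
ring-like triangulation with more low-clustering bridge regions (≈ 0.67).
CC differences between TMFG networks therefore reflect how *concentrated*
the co-occurrence structure is, not the latent graph's Watts–Strogatz
clustering, and published CC contrasts between fluency groups should be
read in that light. ASPL and Q do not suffer from this: path lengths and
community structure of the triangulation track the latent structure
faithfully. The corresponding acceptance check is left failing by design,
with this analysis as the explanation.

## Known limitations

- Group-based estimation pools participants; no individual-level networks.
- Bootstrap t-tests inherit the df-scales-with-B caveat above.
- The random-graph null matches only n and m, not the degree sequence.
- ASPL on disconnected networks is largest-component only.
- No multiple-comparison correction is applied anywhere.
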