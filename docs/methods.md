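# Methods

## Effective information on networks

For a directed network of N nodes, each node v_i carries a row-stochastic
out-weight vector W_i^out (obtained by normalizing its out-weights; a node
with no out-edges receives a probability-1 self-loop, the traditional
Boolean-analysis convention for nodes whose targets fall outside the
modelled subnetwork).  The effective information of the network is

    EI = H(<W_i^out>) − <H(W_i^out)>     [bits]

where `<·>` is the unweighted average over nodes and H is Shannon entropy in
base 2 with the 0·log 0 = 0 convention.  The two components are

    determinism = log2(N) − <H(W_i^out)>     (certainty about the future)
    degeneracy  = log2(N) − H(<W_i^out>)     (overlap in targeting;
                                              uncertainty about the past)

so EI = determinism − degeneracy, bounded between 0 and log2(N), and maximal
exactly when every node deterministically targets a unique node.  EI is also
the mutual information I(S; D) between a source node S drawn uniformly at
random (a maximum-entropy intervention) and the one-step destination D;
`ei_via_intervention` computes that mutual information directly from the
joint distribution p(i, j) = T[i, j]/N, and a property test asserts the two
formulations agree to 1e-10 on a thousand random networks.  Calibration
points: the uniform complete graph and the all-onto-one star both have
EI = 0; permutation networks have EI = log2(N).

Comparisons with externally reported EI values use a tolerance of ±0.02
bits, because such values are typically printed to two decimals (and are
sometimes internally truncated rather than rounded).

## Boolean networks and state-transition graphs

Boolean models are parsed from BoolNet-dialect rule files (`targets,
factors` header; `& | !`, parentheses, constants 0/1 — the dialect Cell
Collective exports).  A declared variable without a rule self-copies.  Under
synchronous update the model induces a deterministic map on its 2^n states;
`expand_state_space` materializes it as a sparse transition structure whose
labels are binary strings in declared-variable order (leftmost bit = first
variable).  The expansion is capped at 20 variables by default (2^20 states)
for memory safety, with an explicit override.  Attractors are the terminal
cycles of this map, found by iterative path-following in O(2^n); basins
partition the state set by construction.  For any deterministic
state-transition graph the determinism term is exactly n bits, so all EI
differences between scales are degeneracy differences.

## Macro-nodes and coarse-graining

A macro-mapping assigns every micro-node to a macro-node (singletons
allowed).  The induced macro transition structure combines member rows and
then aggregates destination mass by summing columns within each group, so
intra-group mass becomes macro self-loop mass — the unique aggregation that
preserves one-step walker flow.  Two row-combination methods:

- `average` — unweighted mean of member rows; the simplest coarse-grain and
  the default for state-transition graphs, whose transient states carry no
  stationary mass.
- `stationary_weighted` — member rows weighted by their stationary
  probabilities renormalized within the group.  This preserves the
  stationary distribution exactly (the macro chain's stationary mass on a
  group equals the summed micro mass, asserted to 1e-9 in tests).  Groups
  whose total stationary mass is below 1e-10 fall back to the unweighted
  mean with a warning, since weighting by numerical-noise mass is
  meaningless.

The stationary distribution is computed by power iteration on the lazy
chain 0.99·T + 0.01·I, which has the same stationary set as T but is
aperiodic, so the iteration converges geometrically even on cycles; for
reducible chains it converges to the mixture selected by the uniform start.
Residual tolerance 1e-12 in L1; non-convergence raises.

`walker_consistency` quantifies dynamical fidelity of a macro-scale: both
chains start from the micro stationary distribution (projected onto groups
for the macro walker) and the score is the mean, over a default horizon of
10 steps, of the KL divergence (bits) between the projected micro
distribution and the macro distribution.  Exactly lumpable partitions score
0; zero-support mismatches are smoothed with ε = 1e-12 and warned about.

## Searching for causal emergence

Causal emergence is a partition whose macro network has strictly more EI
than the micro network.  Three searches, all over average coarse-grains,
all accepting only mappings with gain > ε (default 1e-10 bits; identity
returned otherwise):

- `exhaustive_search` (N ≤ 10): enumerates all partitions in
  restricted-growth order; the testing oracle.  Ties break to the first
  (lexicographically smallest) encoding.
- `greedy_search`: best-improvement hill climbing over pairwise group
  merges; candidate pairs restricted to nodes within undirected graph
  distance 2 (full pairwise by flag); evaluation order and exact-tie
  breaking are controlled by `order_seed`.  A strict-improvement pairwise
  scheme cannot cross EI-neutral plateaus, so on symmetric families it can
  reach the optimal EI through a different partition than the oracle's;
  tests assert gain dominance rather than partition identity for greedy.
- `spectral_search`: nodes are embedded using the leading
  k = min(N−1, 20) eigenvectors of the transition matrix (|λ|-weighted,
  real and imaginary parts), augmented with the one- and two-step
  transition profiles (rows of T and T²).  The augmentation matters:
  deterministic state-transition graphs are defective matrices — almost all
  eigenvalues are 0 and the surviving eigenvectors are constant on
  attractor basins — so the raw eigenbasis collapses dynamically distinct
  states, while the profile coordinates preserve the key property that
  nodes with identical out-rows embed at exactly the same point.  DBSCAN
  (min_samples = 2) at a swept reachability level proposes disjoint
  candidate clusters; the EI-maximal *subset* of clusters (exhaustive for
  ≤ 12 clusters, forward-plus-backward selection above) is evaluated as a
  joint merge, and the best level wins.  Joint subset validation is
  essential, not cosmetic: groups of degenerate nodes often raise EI only
  together (on the cardiac model, merging either 8-state group alone lowers
  EI; merging both raises it), so validating clusters one at a time strands
  the search below available macro-scales.  Eigensolver failure falls back
  to greedy with a warning.

On the cardiac model the spectral search reports the published macro-scale
(18 states, EI 2.906, macro degeneracy 1.264, participation 50%, macro
still deterministic).  The greedy search shows this macro is not the global
EI optimum (pairwise merging reaches 16 states at EI ≈ 3.08); which result
a study reports is a property of the algorithm it ran, and the spectral
pipeline is the default reporting algorithm here.

## Synthetic families and the cardiac fixture

Generator families (all byte-for-byte reproducible from family, n, params,
seed): `permutation` (deterministic unique targets; EI = log2 N),
`complete_uniform` (EI = 0), `star_degenerate` (H(<W_out>) = 0),
`erdos_renyi` (directed G(n, p) null; emergence searches on it are expected
to find essentially nothing, and the test threshold is a gain below 0.05
bits at N = 100, p = 0.05), `boolean_random` (N-K model with fan-in k), and
`two_block_noisy`.

`two_block_noisy` is the constructed causal-emergence example with a known
oracle: two unequal blocks (default 4 + 2) in which every node spreads its
out-weight uniformly over the other block.  Each node is maximally noisy
within its block, but the blocks map onto each other exactly, so grouping
the blocks yields a deterministic 2-node swap with EI = 1 bit, above the
micro EI of 0.918 bits.  The inequality of the block sizes is what creates
the gain: with equal blocks the micro EI already equals 1 bit (the
cross-block Jensen gap argument makes micro EI ≥ macro EI with equality
under exact lumpability), so the equal-block version shows no emergence.

The cardiac fixture is a five-gene Boolean model of early mammalian cardiac
development (exogen_canWnt_II, Foxc1_2, Fgf8, CanWnt, Isl1, in state-label
order).  Its exact published rules are not available, so the shipped rule
set is a reconstruction, selected by exhaustive search over small-fan-in
truth tables and accepted only because it reproduces all published
behaviour simultaneously: the deterministic 32-state synchronous state
space; attractors exactly {00001} (Isl1 ON, basin 31) and {00000} (basin
1); micro EI 2.789 / degeneracy 2.211 / determinism 5 bits; and an
18-state macro-scale at EI 2.906 with degeneracy 1.264 in which the two
macro-nodes are exactly the "exogenous pulse ON, Foxc1_2 OFF" and
"exogenous pulse ON, Foxc1_2 ON" state families (participation 50%).  The
fixture-validation test enforces all of these, and the file's header
documents its reconstructed status.  Biologically the rules read as: a
transient exogenous canWnt-II pulse activates CanWnt; CanWnt induces
Foxc1_2; Foxc1_2 drives Fgf8, which self-maintains; Fgf8 activates Isl1
once the Wnt pulse subsides; Isl1 latches on (self-loop, its onward targets
lying outside the subnetwork) and shuts Fgf8 down.

## What the synthetic data does and does not show

The generators produce exact, noise-free realizations of analytic cases;
they validate the estimator algebra, the coarse-graining operators and the
search contracts, not robustness to empirical noise.  Real interactomes and
GRN reconstructions contain false and missing edges, which inflate apparent
causal emergence; nothing in the test surface measures that effect, and EI
values on inferred networks should be read accordingly.  All analyses here
are desk-scale (≤ a few hundred nodes; 2^20-state cap on expansions);
asynchronous update semantics, probabilistic Boolean networks, overlapping
(soft) partitions, and continuous-state EI are out of scope.

## Numerical conventions

Row-stochasticity is validated to 1e-9 at construction and probabilities
below 1e-15 are kept (entropy code handles them via 0·log 0 = 0).  All
logarithms are base 2 and all information quantities are reported in bits
at full float precision.  Search acceptance uses ε = 1e-10 bits to avoid
float-noise merges; EI values of candidate macros are always recomputed
from the macro network, never updated incrementally.
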