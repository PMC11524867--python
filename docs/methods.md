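# Methods

## The operation

`apply_pcro` acts on a simple undirected graph in two stages.

**Cutting.**  The constraints `k1`, `k2` are resolved against the pre-cut
graph (literal values pass through; `avg_pre` resolves to the realized
average degree `2L/N`, unrounded, and `max_pre` to the realized maximum
degree).  Nodes with degree in the closed band `[k1, k2]` are candidates;
each is independently selected with probability `p_pcro`, and every edge
incident to a selected candidate is removed.  Unselected candidates keep
all their links.

**Classification.**  After the cut, isolated nodes fall into three
mutually exclusive classes: NIN (degree 0 already before the cut), ADIN
(selected candidates), PDIN (pre-degree ≥ 1, not selected, isolated
because every neighbor was selected).  These three classes together are
the common leaves; their union is exactly the set of post-cut isolated
nodes, an identity asserted on every simulated realization.

**Rewiring.**  `k3` is resolved against the post-cut graph (`max_post` by
default).  The `n_hubs` (default 2) non-isolated nodes whose post-cut
degree is closest to `k3` become hubs, ties broken by ascending node id so
the choice is deterministic and seed-free.  Every common leaf is attached
to every hub, so each leaf ends with degree `n_hubs` and the edge count
grows by exactly `n_hubs · N_CL`.  If fewer than `n_hubs` non-isolated
nodes exist the realization is *degenerate* and raises a typed error; the
Monte Carlo layer records counts before rewiring, so degeneracy is tallied
but never biases count statistics.

Leaves attach to *all* hubs rather than being split among them; this is
what makes them "common" leaves and is the reading of the operation's
schematic this package follows.  A hub may be a candidate that survived
the cut — nothing in the operation forbids it.

## The closed-form count laws

All distributions are mixtures over the edge count
`L ~ Binomial(N(N−1)/2, P_ER)`.  Each `L` is mapped to an equivalent
connection probability `P_ECP = 2L/(N(N−1))`, under which a node's degree
is modeled as `Binomial(N−1, P_ECP)`.  Symbolic band edges are resolved
per mixture term (`avg_pre → 2L/N`; `max_pre → N−1`, since no realized
degree can exceed the realized maximum, making the band unbounded above).
The degree sum runs over the integers in `[⌈k1⌉, ⌊k2⌋]`; an empty band
contributes probability 0.

* **Candidates**: `Binomial(N, q_L)` mixed over `L`, with `q_L` the band
  mass of `Binomial(N−1, P_ECP)`.
* **ADIN**: the candidate law thinned by `p_pcro` (computed by the
  explicit thinning sum; equals the mixture of `Binomial(N, q_L · p_pcro)`
  by the binomial thinning identity, and its mean is exactly
  `p_pcro · E[N_NSPCCP]`).
* **PDIN**: `Binomial(N, p_PDIN)` with

  `p_PDIN = Σ_L p_L Σ_{k_i ≥ 1} PCP1(k_i) · B_L^{k_i} · p_pcro^{k_i} · p_{k_i}`

  where `PCP1 = 1 − p_pcro` inside the band and 1 outside (the node itself
  must survive), and `B_L` is the probability that one neighbor's degree
  lies in the band under the size-biased neighbor law
  `Binomial(N−2, P_ECP)` on (degree − 1).  The derivation's intermediate
  average over the candidate count multiplies a quantity that does not
  depend on it, so it collapses analytically; the test suite checks the
  collapsed implementation against a literal triple summation that keeps
  the average explicit, to ten significant digits.
* **NIN**: `Binomial(N, (1−P_ER)^{N−1})`; the per-node probability is
  exact and is verified against the rational-arithmetic enumeration.
* **CL**: convolution of the NIN, ADIN and PDIN laws (the counts are
  treated as independent).  The convolution may place negligible mass
  above `N`; it is preserved rather than clipped so the component means
  add exactly.

**The focal node's degree law in `p_PDIN` (`pki_form`).**  For the node at
risk of passive deletion, the correct degree law is the plain
`Binomial(N−1, P_ECP)` — the node is an arbitrary node, not one reached by
following an edge — and that is the default (`pki_form="plain"`).
Applying the size-biased neighbor law to the focal node itself
(`pki_form="edge_biased"`, kept as an option) understates `p_PDIN`
severalfold: at `N=100, P_ER=0.05, p_pcro=0.5` the simulated per-node
probability is 4.4·10⁻³, the plain form gives 4.7·10⁻³, the edge-biased
form 1.5·10⁻³.  The validation suite reports the comparison.

**Truncation.**  The `L`-mixture is truncated to the smallest contiguous
support carrying mass ≥ 1 − `truncation_tol` (default 10⁻¹⁰) and
renormalized; results are insensitive to the tolerance across
10⁻⁸…10⁻¹² within 10⁻⁶ TV (tested).  Powers `(B_L · p_pcro)^{k_i}` may
underflow to zero for large `k_i`; those terms are genuinely negligible
and float underflow is harmless here.

## Where the approximations bend

The Monte Carlo engine redraws the network for every sample (the theory
averages over `L`, which requires redrawing; a fixed-graph comparison
would test a different quantity).  It is validated against an exhaustive
enumeration of all labeled four-node graphs and all cut subsets: joint-law
TV ≈ 0.003 at 10⁵ samples, so remaining analytic–empirical gaps are
attributable to the theory, not the sampler.  Three approximation effects
are measurable (TV figures below are at 4·10⁵ samples, i.e. essentially
noise-free):

1. **Candidate-count overdispersion.**  Given `L` the degrees are
   negatively correlated (they sum to `2L`), so the true candidate count
   is narrower than `Binomial(N, q_L)`: at `N=100, P_ER=0.05,
   p_pcro=0.75` the analytic candidate variance is 57.0 against 42.9
   empirically, pushing the ADIN and CL TVs to ≈ 0.050–0.054.  At
   `p_pcro ≤ 0.5` the TVs stay at or below ≈ 0.04.
2. **Wide cut bands.**  With `k1=avg_pre, k2=max_pre` the band covers the
   upper degree tail and `p_PDIN` varies strongly with `L`, so the single
   marginal binomial for PDIN misses the mixture spread (PDIN TV ≈ 0.10,
   CL TV ≈ 0.066 at the canonical size).
3. **Isolation correlation.**  Isolation events are positively
   correlated (a missing edge helps both endpoints be isolated), so the
   NIN count is overdispersed relative to its binomial: negligible at
   `N=100, P_ER=0.05` (TV 0.007) but visible at `N=50` (variance 4.56 vs
   3.72, TV 0.053).

The mean CL curve is unaffected by all three effects (means are exact
under thinning and additivity given the per-node probabilities); analytic
and empirical means agree to ≈ 0.1–0.3 leaves at the canonical setting.

## Structural metrics

Clustering is the mean local coefficient with degree-<2 nodes contributing
0 (the common convention).  Operated networks can be disconnected, so mean
shortest path length is averaged over connected ordered pairs only and the
excluded-pair fraction is always reported, letting a largest-component
convention be reconstructed if desired.  Both metrics are cross-checked
against brute-force triangle counts and Floyd–Warshall.

Measured on operated networks at `N=90, P_ER=0.032` (100 realizations per
grid point), clustering **rises** with the operation probability
(0.037 → 0.11–0.14 at `p_pcro=0.97`) and mean path length **falls**
(4.1 → 2.96–2.99): common leaves tied to both hubs create triangles
whenever the hubs are adjacent (frequency ≈ 0.23 at `p_pcro=0.97`) and put
every leaf within two steps of every other.  The endpoints are close to
the clustering/path-length balance (≈ 0.25, ≈ 3.0) associated in the
seizure-modeling literature with networks that support self-initiating
and self-terminating synchronization episodes — the operated network
reaches that balance from the random side, by gaining clustering and
losing path length rather than the reverse.  Claims that the trend runs
the other way are not reproduced by the operation as defined.

## FitzHugh–Nagumo dynamics

Each node follows

    ε du_i/dt = u_i − u_i³/3 − v_i + σ Σ_j A_ij [ cos φ (u_j−u_i) + sin φ (v_j−v_i) ]
      dv_i/dt = u_i + α         + σ Σ_j A_ij [ −sin φ (u_j−u_i) + cos φ (v_j−v_i) ]

with defaults `α = 0.5` (oscillatory units), `ε = 0.05`, `φ = π/2 − 0.1`
(nearly cross-variable coupling), `σ = 0.07`.  The coupling uses the raw
adjacency matrix; a degree-normalized variant sits behind a flag.  The
right-hand side is the standard rotational-coupling form of this model
family; the phase is the four-quadrant angle of `(u, v)` about the origin
and `r(t)` is the modulus of the mean unit phasor (origin states are
excluded with a warning).

Integration is fixed-step RK4.  The default step `dt = 0.005` model units
was set by a step-halving study: the activator's relaxation jumps at
`ε = 0.05` make `dt = 0.01` too coarse (sup-norm change 5.8·10⁻³ on
halving over a 100-unit window), while convergence is cleanly fourth
order (3.5·10⁻⁴ at 0.005, 2.2·10⁻⁵ at 0.0025), so 0.005 keeps the
halving error well under 10⁻³.  `seconds_per_unit` (default 1.0) maps
model time to seconds for the episode rule — the mapping is a free
calibration, not a model fact — and episodes are maximal runs with
`r > 0.8` lasting strictly more than 8 s.

## Problem sizes and reproducibility

Validation and the acceptance script use 10⁴ Monte Carlo samples per cell
(10⁵ for the four-node enumeration comparison) and 100 realizations per
metric grid point; at these sizes the sampling contribution to a TV
distance at the canonical setting is ≈ 0.02–0.04, which is why the
coincidence checks quote TV at 10⁴ samples while the approximation
analysis above uses 4·10⁵.  Larger sample counts are a parameter, not a
code change.  Every stochastic routine takes an explicit seed or
generator; one generator per top-level call, no global state.  Batch size
is part of the sampler's determinism contract (fixed by default).

## Scope and limitations

The substrate is the Erdős–Rényi model only; the closed forms lean on its
degree exchangeability and would need re-derivation for small-world or
scale-free substrates.  The generator emulates idealized random graphs —
it reproduces none of the degree heterogeneity, modularity, or spatial
structure of empirical brain networks, so agreement here validates the
statistical method, not any claim about real physiological data.  The
operation is single-shot (no iterated application), unweighted, and
undirected.  The joint law of the three isolated-node counts is only
computed by enumeration/simulation; the closed forms are marginals plus an
independence assumption.  Dynamics initial conditions are uniform on
`[−2, 2]²` unless supplied; empirical seizure statistics over parameter
sweeps are out of scope.
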