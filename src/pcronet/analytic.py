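"""Closed-form count distributions for the node classes created by the PCRO.

For an Erdős–Rényi network G(N, P_ER) subjected to the cutting–rewiring
operation, the counts of the four node classes admit compound-binomial
expressions built on one approximation: a realized edge count L is treated as
if it came from an "equivalent connection probability" P_ECP = 2L/(N(N-1)),
so that degree statistics conditional on L are Binomial(N-1, P_ECP).

* Candidates (degree in [k1, k2]): a binomial mixture over the edge-count
  distribution p_L = Binomial(N(N-1)/2, P_ER).
* Actively deleted isolated nodes: the candidate count thinned by the
  operation probability p_pcro.
* Passively deleted isolated nodes: a per-node probability combining three
  simultaneous conditions — the node itself survives the cut, every neighbor
  lies in the cut band, and every neighbor is actually selected.
* Naturally isolated nodes: Binomial(N, (1-P_ER)^(N-1)), exact.

The common-leaf count is the sum of the three isolated-node counts; under the
independence (superposition) assumption its distribution is the discrete
convolution of the three component distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .pcro import ConstraintKind, ConstraintSpec

__all__ = [
    "CountDistribution",
    "AnalyticModel",
    "edge_count_pmf",
    "equivalent_connection_prob",
    "nspccp_prob_given_L",
    "nspccp_count_dist",
    "adin_count_dist",
    "pdin_node_prob",
    "pdin_count_dist",
    "nin_count_dist",
    "cl_count_dist",
    "mean_cl_curve",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class CountDistribution:
    """A probability mass function on a contiguous integer support.

    ``support[0]`` need not be 0; ``pmf`` entries are non-negative and sum to
    one within 1e-9 (renormalization after truncation is the caller's job).
    """

    support: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        pmf = np.asarray(self.pmf, dtype=np.float64)
        if support.shape != pmf.shape or support.ndim != 1:
            raise ValueError("support and pmf must be 1-d arrays of equal length")
        if np.any(np.diff(support) != 1):
            raise ValueError("support must be contiguous integers")
        if np.any(pmf < -1e-15):
            raise ValueError("pmf entries must be non-negative")
        total = pmf.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"pmf sums to {total}, outside 1 +/- {_NORM_TOL}")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pmf", np.clip(pmf, 0.0, None))

    @classmethod
    def delta(cls, value: int) -> "CountDistribution":
        return cls(np.array([value]), np.array([1.0]))

    @classmethod
    def binomial(cls, n: int, p: float) -> "CountDistribution":
        support = np.arange(n + 1)
        return cls(support, stats.binom.pmf(support, n, p))

    @classmethod
    def from_dense(cls, pmf: np.ndarray, start: int = 0) -> "CountDistribution":
        pmf = np.asarray(pmf, dtype=np.float64)
        return cls(np.arange(start, start + pmf.size), pmf)

    def prob(self, k: int) -> float:
        lo = int(self.support[0])
        if lo <= k <= int(self.support[-1]):
            return float(self.pmf[k - lo])
        return 0.0

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.support - m) ** 2, self.pmf))

    def truncate(self, tol: float) -> "CountDistribution":
        """Smallest contiguous central support carrying >= 1-tol mass,
        renormalized."""
        order = np.argsort(self.pmf)[::-1]
        cum = np.cumsum(self.pmf[order])
        k = int(np.searchsorted(cum, 1.0 - tol)) + 1
        kept = np.sort(order[:k])
        lo, hi = kept[0], kept[-1]
        pmf = self.pmf[lo : hi + 1]
        return CountDistribution(self.support[lo : hi + 1], pmf / pmf.sum())

    def convolve(self, other: "CountDistribution") -> "CountDistribution":
        pmf = np.convolve(self.pmf, other.pmf)
        start = int(self.support[0] + other.support[0])
        return CountDistribution(np.arange(start, start + pmf.size), pmf / pmf.sum())

    def total_variation(self, other: "CountDistribution") -> float:
        lo = int(min(self.support[0], other.support[0]))
        hi = int(max(self.support[-1], other.support[-1]))
        p = np.zeros(hi - lo + 1)
        q = np.zeros(hi - lo + 1)
        p[self.support - lo] = self.pmf
        q[other.support - lo] = other.pmf
        return 0.5 * float(np.abs(p - q).sum())


@dataclass(frozen=True)
class AnalyticModel:
    """Parameters of the closed-form theory.

    ``k1``/``k2`` accept literals, ``avg_pre`` (resolved to 2L/N inside each
    edge-count mixture term) or ``max_pre`` (resolved to N-1: no realized
    degree can exceed it, so the band is unbounded above).  ``pki_form``
    selects the degree law used for the focal node in the passively-deleted
    derivation: ``"plain"`` (default) uses the ordinary Binomial(N-1, P_ECP)
    degree law, which is the correct law for an arbitrary node and matches
    Monte Carlo; ``"edge_biased"`` applies the size-biased conditional form
    that governs a neighbor reached along an edge — appropriate for the
    neighbors in the derivation but, applied to the focal node itself,
    it understates the isolation probability severalfold.
    """

    n_nodes: int
    connection_prob: float
    k1: ConstraintSpec = ConstraintSpec(ConstraintKind.LITERAL, 1.0)
    k2: ConstraintSpec = ConstraintSpec(ConstraintKind.AVG_PRE)
    p_pcro: float = 0.5
    truncation_tol: float = 1e-10
    pki_form: str = "plain"

    def __post_init__(self) -> None:
        object.__setattr__(self, "k1", ConstraintSpec.parse(self.k1))
        object.__setattr__(self, "k2", ConstraintSpec.parse(self.k2))
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValueError("connection_prob must lie in [0, 1]")
        if not 0.0 <= self.p_pcro <= 1.0:
            raise ValueError("p_pcro must lie in [0, 1]")
        if not 0.0 < self.truncation_tol <= 1e-6:
            raise ValueError("truncation_tol must lie in (0, 1e-6]")
        if self.pki_form not in ("edge_biased", "plain"):
            raise ValueError("pki_form must be 'edge_biased' or 'plain'")
        for name in ("k1", "k2"):
            kind = getattr(self, name).kind
            if kind in (ConstraintKind.AVG_POST, ConstraintKind.MAX_POST):
                raise ValueError(f"{name} must refer to the pre-cut graph")

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def resolve_band(self, L: int) -> tuple[float, float]:
        """The cut band [k1, k2] for a network with realized edge count L."""
        return self._resolve(self.k1, L), self._resolve(self.k2, L)

    def _resolve(self, spec: ConstraintSpec, L: int) -> float:
        if spec.kind is ConstraintKind.LITERAL:
            return float(spec.value)
        if spec.kind is ConstraintKind.AVG_PRE:
            return 2.0 * L / self.n_nodes
        return float(self.n_nodes - 1)  # max_pre: band is unbounded above


def edge_count_pmf(model: AnalyticModel) -> CountDistribution:
    """Edge-count law p_L = Binomial(N(N-1)/2, P_ER), truncated to the central
    >= 1 - truncation_tol mass and renormalized."""
    full = CountDistribution.binomial(model.n_pairs, model.connection_prob)
    return full.truncate(model.truncation_tol)


def equivalent_connection_prob(L: int, N: int) -> float:
    """P_ECP = 2L/(N(N-1)): the pair probability whose expected average degree
    matches a realized edge count L."""
    n_pairs = N * (N - 1) / 2
    if not 0 <= L <= n_pairs:
        raise ValueError(f"L={L} outside [0, {n_pairs}]")
    return L / n_pairs


def _band_indices(k1: float, k2: float, kmax: int, kmin: int = 0) -> np.ndarray:
    """Integer degrees in [k1, k2] clipped to [kmin, kmax]; empty if none."""
    lo = max(math.ceil(k1), kmin)
    hi = min(math.floor(k2), kmax)
    if hi < lo:
        return np.arange(0)
    return np.arange(lo, hi + 1)


def nspccp_prob_given_L(model: AnalyticModel, L: int) -> float:
    """Conditional probability that an arbitrary node is a cut candidate,
    given a realized edge count L: Binomial(N-1, P_ECP) mass on [k1, k2]."""
    k1, k2 = model.resolve_band(L)
    ks = _band_indices(k1, k2, model.n_nodes - 1)
    if ks.size == 0:
        return 0.0
    pecp = equivalent_connection_prob(L, model.n_nodes)
    return float(stats.binom.pmf(ks, model.n_nodes - 1, pecp).sum())


def nspccp_count_dist(model: AnalyticModel) -> CountDistribution:
    """Candidate-count distribution: a Binomial(N, q_L) mixture over p_L."""
    pL = edge_count_pmf(model)
    n = np.arange(model.n_nodes + 1)
    pmf = np.zeros(model.n_nodes + 1)
    for L, w in zip(pL.support, pL.pmf):
        q = nspccp_prob_given_L(model, int(L))
        pmf += w * stats.binom.pmf(n, model.n_nodes, q)
    return CountDistribution(n, pmf / pmf.sum())


def adin_count_dist(
    model: AnalyticModel, nspccp: CountDistribution | None = None
) -> CountDistribution:
    """Actively-deleted count: the candidate count thinned by p_pcro.

    P(n) = sum_m P_NSPCCP(m) Binomial(m, p_pcro)(n); the mean is exactly
    p_pcro times the candidate mean.
    """
    if nspccp is None:
        nspccp = nspccp_count_dist(model)
    n = np.arange(int(nspccp.support[-1]) + 1)
    pmf = np.zeros(n.size)
    for m, w in zip(nspccp.support, nspccp.pmf):
        pmf += w * stats.binom.pmf(n, int(m), model.p_pcro)
    return CountDistribution(n, pmf / pmf.sum())


def _neighbor_band_mass(model: AnalyticModel, L: int, k1: float, k2: float) -> float:
    """Probability that a neighbor's degree lies in [k1, k2], using the
    size-biased conditional law Binomial(N-2, P_ECP) on (degree - 1)."""
    kjs = _band_indices(k1, k2, model.n_nodes - 1, kmin=1)
    if kjs.size == 0:
        return 0.0
    pecp = equivalent_connection_prob(L, model.n_nodes)
    return float(stats.binom.pmf(kjs - 1, model.n_nodes - 2, pecp).sum())


def pdin_node_prob(model: AnalyticModel) -> float:
    """Probability that an arbitrary node ends up passively deleted.

    Mixes over the edge-count law; for each L, sums over the node's own
    degree ki >= 1 the product of three factors: survival of the node itself
    (1 - p_pcro inside the cut band, 1 outside), the probability that all ki
    neighbors lie in the band (the single-neighbor band mass to the power
    ki), and the probability that all ki neighbors are selected (p_pcro^ki).

    The intermediate average over the candidate count is a weighted sum of a
    quantity that does not depend on it, so it collapses analytically and is
    not enumerated here.
    """
    pL = edge_count_pmf(model)
    N = model.n_nodes
    ki = np.arange(1, N)
    p = model.p_pcro
    total = 0.0
    for L, w in zip(pL.support, pL.pmf):
        L = int(L)
        if L == 0:
            continue  # no edges: every node has degree 0, none can be a PDIN
        k1, k2 = model.resolve_band(L)
        band = _neighbor_band_mass(model, L, k1, k2)
        pecp = equivalent_connection_prob(L, N)
        if model.pki_form == "edge_biased":
            pki = stats.binom.pmf(ki - 1, N - 2, pecp)
        else:
            pki = stats.binom.pmf(ki, N - 1, pecp)
        pcp1 = np.where((ki >= k1) & (ki <= k2), 1.0 - p, 1.0)
        total += w * float(np.sum(pcp1 * np.power(band * p, ki) * pki))
    return total


def pdin_count_dist(model: AnalyticModel, p_pdin: float | None = None) -> CountDistribution:
    """Passively-deleted count distribution: Binomial(N, p_PDIN)."""
    if p_pdin is None:
        p_pdin = pdin_node_prob(model)
    if not 0.0 <= p_pdin <= 1.0:
        raise ValueError(f"p_PDIN={p_pdin} outside [0, 1]")
    return CountDistribution.binomial(model.n_nodes, p_pdin)


def nin_node_prob(model: AnalyticModel) -> float:
    """Exact probability that a node is isolated in G(N, P_ER):
    (1 - P_ER)^(N-1)."""
    return (1.0 - model.connection_prob) ** (model.n_nodes - 1)


def nin_count_dist(model: AnalyticModel) -> CountDistribution:
    """Naturally-isolated count distribution: Binomial(N, (1-P_ER)^(N-1))."""
    return CountDistribution.binomial(model.n_nodes, nin_node_prob(model))


def cl_count_dist(
    model: AnalyticModel,
    components: tuple[CountDistribution, CountDistribution, CountDistribution] | None = None,
) -> CountDistribution:
    """Common-leaf count: convolution of the NIN, ADIN, and PDIN laws.

    The three counts are treated as independent (the superposition
    assumption); their independence is approximate, and the convolution may
    place negligible mass above N, which is kept rather than clipped.
    """
    if components is None:
        components = (nin_count_dist(model), adin_count_dist(model), pdin_count_dist(model))
    nin, adin, pdin = components
    return nin.convolve(adin).convolve(pdin)


def mean_cl_curve(model: AnalyticModel, p_pcro_grid) -> list[tuple[float, float]]:
    """Analytic mean common-leaf count as a function of the operation
    probability; non-decreasing on [0, 1]."""
    out = []
    for p in p_pcro_grid:
        m = replace(model, p_pcro=float(p))
        out.append((float(p), cl_count_dist(m).mean()))
    return out
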