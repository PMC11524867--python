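"""The preferential cutting–rewiring operation (PCRO).

The operation runs in two stages on a simple undirected graph:

1. *Cutting.*  Nodes whose degree lies in a preferential band [k1, k2] are
   candidates.  Each candidate is independently selected with probability
   ``p_pcro``; every edge incident to a selected candidate is discarded.
2. *Rewiring.*  Every node isolated after the cut — whether naturally
   isolated (NIN, degree 0 before the cut), actively deleted (ADIN, a cut
   candidate), or passively deleted (PDIN, a non-candidate whose neighbors
   were all cut) — becomes a *common leaf* (CL) and is attached to each of
   the ``n_hubs`` target nodes whose post-cut degree best matches the
   rewiring constraint k3.

Constraints may be literal numbers or symbolic quantities of the pre- or
post-cut graph (realized average degree 2L/N, or maximum degree).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph

__all__ = [
    "ConstraintKind",
    "ConstraintSpec",
    "PCROConfig",
    "NodeLabel",
    "NodeClassification",
    "PCROResult",
    "DegenerateNetworkError",
    "resolve_constraint",
    "identify_candidates",
    "cut",
    "classify_isolated",
    "select_hubs",
    "rewire",
    "apply_pcro",
]


class DegenerateNetworkError(RuntimeError):
    """Post-cut graph has fewer non-isolated nodes than requested hubs."""


class InternalConsistencyError(RuntimeError):
    """Inputs violate an invariant the pipeline guarantees by construction."""


class ConstraintKind(str, enum.Enum):
    LITERAL = "literal"
    AVG_PRE = "avg_pre"    # realized average degree 2L/N of the pre-cut graph
    MAX_PRE = "max_pre"    # maximum degree of the pre-cut graph
    AVG_POST = "avg_post"  # realized average degree of the post-cut graph
    MAX_POST = "max_post"  # maximum degree of the post-cut graph


_PRE_KINDS = {ConstraintKind.AVG_PRE, ConstraintKind.MAX_PRE}
_POST_KINDS = {ConstraintKind.AVG_POST, ConstraintKind.MAX_POST}


@dataclass(frozen=True)
class ConstraintSpec:
    """A preferential constraint: a literal degree value or a symbolic one."""

    kind: ConstraintKind
    value: float | None = None

    def __post_init__(self) -> None:
        kind = ConstraintKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is ConstraintKind.LITERAL:
            if self.value is None or self.value < 0:
                raise ValueError("literal constraint needs a value >= 0")
        elif self.value is not None:
            raise ValueError(f"symbolic constraint {kind.value!r} carries no value")

    @classmethod
    def parse(cls, spec: "ConstraintSpec | str | float | int") -> "ConstraintSpec":
        """Accept a ConstraintSpec, a kind name like ``"avg_pre"``, or a number."""
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, str):
            return cls(ConstraintKind(spec))
        return cls(ConstraintKind.LITERAL, float(spec))


@dataclass(frozen=True)
class PCROConfig:
    """Full parameterization of one PCRO application.

    Defaults follow the canonical setting k1=1, k2=⟨k⟩AV (pre-cut average
    degree), k3=k'Max (post-cut maximum degree), with two hubs.
    """

    k1: ConstraintSpec = ConstraintSpec(ConstraintKind.LITERAL, 1.0)
    k2: ConstraintSpec = ConstraintSpec(ConstraintKind.AVG_PRE)
    k3: ConstraintSpec = ConstraintSpec(ConstraintKind.MAX_POST)
    p_pcro: float = 0.5
    n_hubs: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "k1", ConstraintSpec.parse(self.k1))
        object.__setattr__(self, "k2", ConstraintSpec.parse(self.k2))
        object.__setattr__(self, "k3", ConstraintSpec.parse(self.k3))
        if not 0.0 <= self.p_pcro <= 1.0:
            raise ValueError("p_pcro must lie in [0, 1]")
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")


class NodeLabel(str, enum.Enum):
    ORDINARY = "ORDINARY"
    NIN = "NIN"      # naturally isolated: degree 0 before the cut
    ADIN = "ADIN"    # actively deleted: a candidate whose links were cut
    PDIN = "PDIN"    # passively deleted: isolated because all neighbors were cut
    HUB = "HUB"


@dataclass(frozen=True)
class NodeClassification:
    """Per-node labels plus the candidate (NSPCCP) set, recorded separately.

    A node is a common leaf (CL) iff its label is NIN, ADIN, or PDIN.
    """

    labels: tuple[NodeLabel, ...]
    candidates: frozenset[int] = field(default_factory=frozenset)

    def nodes_with(self, label: NodeLabel) -> frozenset[int]:
        return frozenset(i for i, lab in enumerate(self.labels) if lab is label)

    @property
    def nin(self) -> frozenset[int]:
        return self.nodes_with(NodeLabel.NIN)

    @property
    def adin(self) -> frozenset[int]:
        return self.nodes_with(NodeLabel.ADIN)

    @property
    def pdin(self) -> frozenset[int]:
        return self.nodes_with(NodeLabel.PDIN)

    @property
    def hubs(self) -> frozenset[int]:
        return self.nodes_with(NodeLabel.HUB)

    @property
    def common_leaves(self) -> frozenset[int]:
        return self.nin | self.adin | self.pdin

    def is_cl(self, node: int) -> bool:
        return self.labels[node] in (NodeLabel.NIN, NodeLabel.ADIN, NodeLabel.PDIN)

    def with_hubs(self, hub_ids) -> "NodeClassification":
        labels = list(self.labels)
        for h in hub_ids:
            if labels[h] is not NodeLabel.ORDINARY:
                raise InternalConsistencyError(f"hub {h} already labeled {labels[h]}")
            labels[h] = NodeLabel.HUB
        return NodeClassification(tuple(labels), self.candidates)


@dataclass(frozen=True)
class PCROResult:
    """Everything one PCRO application produced."""

    pre_graph: Graph
    post_cut_graph: Graph
    final_graph: Graph
    classification: NodeClassification
    resolved_k1: float
    resolved_k2: float
    resolved_k3: float
    hub_ids: tuple[int, ...]

    @property
    def n_cl(self) -> int:
        return len(self.classification.common_leaves)

    def counts(self) -> dict[str, int]:
        c = self.classification
        return {
            "NSPCCP": len(c.candidates),
            "NIN": len(c.nin),
            "ADIN": len(c.adin),
            "PDIN": len(c.pdin),
            "CL": self.n_cl,
        }


def resolve_constraint(spec: ConstraintSpec, g: Graph) -> float:
    """Resolve a constraint against a graph (caller supplies pre or post cut).

    ``avg_*`` kinds resolve to the unrounded realized average degree 2L/N;
    ``max_*`` to the maximum degree; literals pass through.
    """
    spec = ConstraintSpec.parse(spec)
    if spec.kind is ConstraintKind.LITERAL:
        return float(spec.value)
    if spec.kind in (ConstraintKind.AVG_PRE, ConstraintKind.AVG_POST):
        return g.average_degree()
    return float(g.degrees().max()) if g.n_edges else 0.0


def identify_candidates(g: Graph, k1: float, k2: float) -> frozenset[int]:
    """Nodes with degree in the inclusive band [k1, k2] (the NSPCCPs)."""
    if k1 > k2:
        raise ValueError(f"k1={k1} must not exceed k2={k2}")
    deg = g.degrees()
    return frozenset(np.flatnonzero((deg >= k1) & (deg <= k2)).tolist())


def cut(
    g: Graph,
    candidates: frozenset[int] | set[int],
    p_pcro: float,
    rng: np.random.Generator,
) -> tuple[Graph, frozenset[int]]:
    """Cutting stage: select each candidate with probability ``p_pcro`` and
    discard every edge incident to a selected candidate.

    Returns the post-cut graph and the set of selected candidates (the ADINs).
    Unselected candidates keep all their links.
    """
    if not set(candidates) <= set(range(g.n_nodes)):
        raise ValueError("candidates must be node ids of g")
    cand = sorted(candidates)
    selected = rng.random(len(cand)) < p_pcro
    adin = frozenset(c for c, s in zip(cand, selected) if s)
    surviving = frozenset(e for e in g.edges if e[0] not in adin and e[1] not in adin)
    return Graph(g.n_nodes, surviving), adin


def classify_isolated(
    pre: Graph, post_cut: Graph, adin_set: frozenset[int] | set[int]
) -> NodeClassification:
    """Label every node NIN / ADIN / PDIN / ORDINARY from the two graphs.

    NIN: degree 0 already before the cut.  ADIN: a selected candidate.
    PDIN: a non-candidate node with pre-cut degree >= 1 isolated by the cut
    (all its neighbors were ADINs).  Hubs are assigned later.
    """
    if pre.n_nodes != post_cut.n_nodes:
        raise InternalConsistencyError("pre and post-cut graphs differ in node count")
    pre_deg = pre.degrees()
    post_deg = post_cut.degrees()
    adin = frozenset(adin_set)
    if any(post_deg[a] != 0 for a in adin):
        raise InternalConsistencyError("an ADIN retains surviving edges")

    labels = []
    for i in range(pre.n_nodes):
        if pre_deg[i] == 0:
            labels.append(NodeLabel.NIN)
        elif i in adin:
            labels.append(NodeLabel.ADIN)
        elif post_deg[i] == 0:
            labels.append(NodeLabel.PDIN)
        else:
            labels.append(NodeLabel.ORDINARY)
    return NodeClassification(tuple(labels))


def select_hubs(
    post_cut: Graph,
    k3: float,
    n_hubs: int,
    eligible: frozenset[int] | set[int] | None = None,
) -> tuple[int, ...]:
    """Pick the ``n_hubs`` non-isolated nodes whose post-cut degree is closest
    to k3, breaking ties by ascending node id (deterministic, seed-free).

    For k3 = post-cut maximum degree this selects maximum-degree nodes.
    """
    deg = post_cut.degrees()
    if eligible is None:
        eligible = frozenset(np.flatnonzero(deg >= 1).tolist())
    eligible = sorted(eligible)
    if len(eligible) < n_hubs:
        raise DegenerateNetworkError(
            f"only {len(eligible)} non-isolated nodes, need {n_hubs} hubs"
        )
    ranked = sorted(eligible, key=lambda i: (abs(float(deg[i]) - k3), i))
    return tuple(ranked[:n_hubs])


def rewire(
    post_cut: Graph,
    cl_set: frozenset[int] | set[int],
    hub_ids: tuple[int, ...] | list[int],
) -> Graph:
    """Rewiring stage: attach every common leaf to every hub."""
    cl = frozenset(cl_set)
    hubs = tuple(hub_ids)
    if cl & set(hubs):
        raise InternalConsistencyError("a node cannot be both a common leaf and a hub")
    deg = post_cut.degrees()
    if any(deg[c] != 0 for c in cl):
        raise InternalConsistencyError("a common leaf must be isolated post-cut")
    new_edges = set(post_cut.edges)
    for c in cl:
        for h in hubs:
            new_edges.add((c, h) if c < h else (h, c))
    return Graph(post_cut.n_nodes, frozenset(new_edges))


def apply_pcro(
    g: Graph, config: PCROConfig, rng: np.random.Generator | int
) -> PCROResult:
    """Run the full two-stage operation on a graph.

    Pipeline: resolve k1, k2 on the pre-cut graph -> candidates -> cut ->
    classify isolated nodes -> resolve k3 on the post-cut graph -> hubs ->
    rewire all common leaves to all hubs.

    Raises :class:`DegenerateNetworkError` when the post-cut graph has fewer
    non-isolated nodes than ``n_hubs``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if ConstraintSpec.parse(config.k1).kind in _POST_KINDS or ConstraintSpec.parse(
        config.k2
    ).kind in _POST_KINDS:
        raise ValueError("cutting constraints k1, k2 must refer to the pre-cut graph")

    k1 = resolve_constraint(config.k1, g)
    k2 = resolve_constraint(config.k2, g)
    if k1 > k2:
        raise ValueError(f"resolved k1={k1} exceeds resolved k2={k2}")
    candidates = identify_candidates(g, k1, k2)
    post_cut, adin = cut(g, candidates, config.p_pcro, rng)
    classification = NodeClassification(
        classify_isolated(g, post_cut, adin).labels, candidates
    )

    k3_graph = g if ConstraintSpec.parse(config.k3).kind in _PRE_KINDS else post_cut
    k3 = resolve_constraint(config.k3, k3_graph)
    hub_ids = select_hubs(post_cut, k3, config.n_hubs)
    classification = classification.with_hubs(hub_ids)
    final = rewire(post_cut, classification.common_leaves, hub_ids)

    return PCROResult(
        pre_graph=g,
        post_cut_graph=post_cut,
        final_graph=final,
        classification=classification,
        resolved_k1=k1,
        resolved_k2=k2,
        resolved_k3=k3,
        hub_ids=hub_ids,
    )
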