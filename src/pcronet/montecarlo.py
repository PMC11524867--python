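"""Empirical validation of the analytic theory.

Three layers:

* a vectorized sampler that redraws an Erdős–Rényi network and applies the
  cutting stage S times, recording the per-realization counts of the four
  node classes (classification needs no rewiring topology, so degenerate
  hub selection never biases the counts — it is only tallied);
* an exhaustive-enumeration oracle for tiny networks (N <= 5) that iterates
  every labeled graph and every cut subset, giving the exact joint law of
  the three isolated-node counts with no equivalent-probability
  approximation;
* a validation grid that compares analytic and empirical distributions by
  total variation distance across operation probabilities, constraint
  variants, and network sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .analytic import (
    AnalyticModel,
    CountDistribution,
    adin_count_dist,
    cl_count_dist,
    nin_count_dist,
    pdin_count_dist,
)
from .graph import ERRNParams, pair_index_arrays
from .pcro import ConstraintKind, ConstraintSpec, PCROConfig

__all__ = [
    "SimulationReport",
    "simulate_counts",
    "total_variation",
    "enumerate_exact",
    "joint_marginal",
    "validation_suite",
    "default_validation_cells",
]

_BATCH = 1000


@dataclass(frozen=True)
class SimulationReport:
    """Per-realization node-class counts from repeated (ERRN draw -> cut)."""

    n_samples: int
    n_rejected: int
    seed: int
    nspccp: np.ndarray
    nin: np.ndarray
    adin: np.ndarray
    pdin: np.ndarray
    cl: np.ndarray

    def empirical_pmf(self, which: str) -> CountDistribution:
        """Raw-frequency pmf of one count ('nin', 'adin', 'pdin', 'cl',
        'nspccp') over the observed support 0..max."""
        counts = getattr(self, which)
        freq = np.bincount(counts) / counts.size
        return CountDistribution.from_dense(freq)

    def mean(self, which: str) -> float:
        return float(getattr(self, which).mean())

    def sem(self, which: str) -> float:
        x = getattr(self, which)
        return float(x.std(ddof=1) / math.sqrt(x.size))

    def summary(self) -> pd.DataFrame:
        rows = []
        for which in ("nspccp", "nin", "adin", "pdin", "cl"):
            rows.append(
                {"count": which, "mean": self.mean(which), "sem": self.sem(which)}
            )
        return pd.DataFrame(rows)


def _resolve_band_arrays(
    config: PCROConfig, n_nodes: int, L: np.ndarray, max_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    def resolve(spec: ConstraintSpec) -> np.ndarray:
        if spec.kind is ConstraintKind.LITERAL:
            return np.full(L.shape, float(spec.value))
        if spec.kind is ConstraintKind.AVG_PRE:
            return 2.0 * L / n_nodes
        if spec.kind is ConstraintKind.MAX_PRE:
            return max_deg.astype(np.float64)
        raise ValueError(f"cutting constraint cannot be {spec.kind.value}")

    return resolve(ConstraintSpec.parse(config.k1)), resolve(
        ConstraintSpec.parse(config.k2)
    )


def simulate_counts(
    errn: ERRNParams,
    config: PCROConfig,
    n_samples: int,
    seed: int,
    batch_size: int = _BATCH,
) -> SimulationReport:
    """Draw ``n_samples`` independent (network, cut) realizations and record
    the class counts of each.

    Every sample redraws the Erdős–Rényi network (the theory averages over
    the edge count, which requires redrawing).  Reproducible from ``seed``
    for a fixed ``batch_size``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    N = errn.n_nodes
    iu, ju = pair_index_arrays(N)

    out = {k: [] for k in ("nspccp", "nin", "adin", "pdin", "cl")}
    n_rejected = 0
    remaining = n_samples
    while remaining > 0:
        B = min(batch_size, remaining)
        remaining -= B
        present = rng.random((B, iu.size)) < errn.connection_prob
        rows, pairs = np.nonzero(present)
        ends = np.concatenate([rows * N + iu[pairs], rows * N + ju[pairs]])
        deg = np.bincount(ends, minlength=B * N).reshape(B, N)

        L = deg.sum(axis=1) // 2
        k1, k2 = _resolve_band_arrays(config, N, L, deg.max(axis=1))
        cand = (deg >= k1[:, None]) & (deg <= k2[:, None])
        adin = cand & (rng.random((B, N)) < config.p_pcro)

        cut_edge = adin[rows, iu[pairs]] | adin[rows, ju[pairs]]
        keep_rows, keep_pairs = rows[~cut_edge], pairs[~cut_edge]
        kept = np.concatenate(
            [keep_rows * N + iu[keep_pairs], keep_rows * N + ju[keep_pairs]]
        )
        post_deg = np.bincount(kept, minlength=B * N).reshape(B, N)

        nin = deg == 0
        pdin = (deg > 0) & ~adin & (post_deg == 0)
        out["nspccp"].append(cand.sum(axis=1))
        out["nin"].append(nin.sum(axis=1))
        out["adin"].append(adin.sum(axis=1))
        out["pdin"].append(pdin.sum(axis=1))
        out["cl"].append((nin | adin | pdin).sum(axis=1))
        n_rejected += int(((post_deg >= 1).sum(axis=1) < config.n_hubs).sum())

    arrays = {k: np.concatenate(v).astype(np.int64) for k, v in out.items()}
    assert np.array_equal(
        arrays["cl"], arrays["nin"] + arrays["adin"] + arrays["pdin"]
    ), "per-realization identity N_CL = N_NIN + N_ADIN + N_PDIN violated"
    return SimulationReport(
        n_samples=n_samples, n_rejected=n_rejected, seed=seed, **arrays
    )


def total_variation(p: CountDistribution, q: CountDistribution) -> float:
    """Total variation distance (1/2) sum |p - q| over the union support."""
    return p.total_variation(q)


def enumerate_exact(
    n_nodes: int,
    p_er: float | Fraction,
    config: PCROConfig,
    exact: bool = False,
) -> dict[tuple[int, int, int], float | Fraction]:
    """Exact joint law of (N_NIN, N_ADIN, N_PDIN) by brute force.

    Iterates every labeled graph on ``n_nodes`` nodes (weight
    P_ER^L (1-P_ER)^(pairs-L)) and every subset of its cut candidates
    (weight p^|A| (1-p)^(|cand|-|A|)), applying the deterministic
    classification rules.  With ``exact=True`` all weights are Fractions and
    the joint pmf sums to 1 exactly.  Refuses n_nodes > 5.
    """
    if n_nodes > 5:
        raise ValueError("exhaustive enumeration is limited to n_nodes <= 5")
    pairs = list(itertools.combinations(range(n_nodes), 2))
    one = Fraction(1) if exact else 1.0
    p_er = Fraction(p_er) if exact else float(p_er)
    p = Fraction(config.p_pcro) if exact else float(config.p_pcro)
    k1s, k2s = ConstraintSpec.parse(config.k1), ConstraintSpec.parse(config.k2)

    joint: dict[tuple[int, int, int], float | Fraction] = {}
    for edge_mask in range(1 << len(pairs)):
        deg = [0] * n_nodes
        present = []
        for idx, (u, v) in enumerate(pairs):
            if edge_mask >> idx & 1:
                deg[u] += 1
                deg[v] += 1
                present.append((u, v))
        L = len(present)
        w_graph = p_er**L * (1 - p_er) ** (len(pairs) - L)

        def resolve(spec: ConstraintSpec) -> float:
            if spec.kind is ConstraintKind.LITERAL:
                return float(spec.value)
            if spec.kind is ConstraintKind.AVG_PRE:
                return 2.0 * L / n_nodes
            if spec.kind is ConstraintKind.MAX_PRE:
                return float(max(deg))
            raise ValueError(f"cutting constraint cannot be {spec.kind.value}")

        k1, k2 = resolve(k1s), resolve(k2s)
        cand = [i for i in range(n_nodes) if k1 <= deg[i] <= k2]
        nin = sum(1 for i in range(n_nodes) if deg[i] == 0)

        if w_graph == 0:
            continue
        for cut_mask in range(1 << len(cand)):
            adin = {c for idx, c in enumerate(cand) if cut_mask >> idx & 1}
            w = w_graph * p ** len(adin) * (1 - p) ** (len(cand) - len(adin))
            if w == 0:
                continue
            post_deg = [0] * n_nodes
            for u, v in present:
                if u not in adin and v not in adin:
                    post_deg[u] += 1
                    post_deg[v] += 1
            pdin = sum(
                1
                for i in range(n_nodes)
                if deg[i] > 0 and i not in adin and post_deg[i] == 0
            )
            key = (nin, len(adin), pdin)
            joint[key] = joint.get(key, 0 * one) + w
    return joint


def joint_marginal(
    joint: dict[tuple[int, int, int], float | Fraction], axis: int
) -> CountDistribution:
    """Marginal pmf of one coordinate of the exact joint law (0 = NIN,
    1 = ADIN, 2 = PDIN)."""
    hi = max(k[axis] for k in joint)
    pmf = np.zeros(hi + 1)
    for key, w in joint.items():
        pmf[key[axis]] += float(w)
    return CountDistribution.from_dense(pmf / pmf.sum())


def joint_from_counts(
    nin: np.ndarray, adin: np.ndarray, pdin: np.ndarray
) -> dict[tuple[int, int, int], float]:
    """Empirical joint frequency of (N_NIN, N_ADIN, N_PDIN)."""
    joint: dict[tuple[int, int, int], float] = {}
    keys, counts = np.unique(
        np.stack([nin, adin, pdin], axis=1), axis=0, return_counts=True
    )
    total = nin.size
    for key, c in zip(keys, counts):
        joint[tuple(int(x) for x in key)] = c / total
    return joint


def joint_total_variation(
    p: dict[tuple[int, int, int], float], q: dict[tuple[int, int, int], float]
) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(float(p.get(k, 0.0)) - float(q.get(k, 0.0))) for k in keys)


def default_validation_cells() -> list[dict]:
    """The canonical comparison grid: operation-probability sweep at the
    default setting, the three constraint variants, and size/density
    variants."""
    base = dict(n_nodes=100, p_er=0.05, k1=1.0, k2="avg_pre", k3="max_post")
    cells: list[dict] = []
    for p in (0.25, 0.50, 0.75):
        cells.append({**base, "p_pcro": p, "cell": f"default p={p}"})
    variants = [
        ("avg_pre", "max_pre", "max_post"),
        (1.0, "avg_pre", "avg_post"),
        ("avg_pre", "max_pre", "avg_post"),
    ]
    for k1, k2, k3 in variants:
        cells.append(
            {
                **base,
                "k1": k1,
                "k2": k2,
                "k3": k3,
                "p_pcro": 0.50,
                "cell": f"constraints k1={k1},k2={k2},k3={k3}",
            }
        )
    for p_er, n in ((0.03, 100), (0.08, 100), (0.05, 50), (0.05, 200)):
        cells.append(
            {
                **base,
                "n_nodes": n,
                "p_er": p_er,
                "p_pcro": 0.50,
                "cell": f"P_ER={p_er}, N={n}",
            }
        )
    return cells


def compare_cell(
    cell: dict, n_samples: int, seed: int, tv_threshold: float = 0.05
) -> dict:
    """Analytic-vs-empirical comparison for one parameter cell."""
    errn = ERRNParams(cell["n_nodes"], cell["p_er"])
    config = PCROConfig(
        k1=cell["k1"], k2=cell["k2"], k3=cell.get("k3", "max_post"),
        p_pcro=cell["p_pcro"],
    )
    model = AnalyticModel(
        n_nodes=cell["n_nodes"],
        connection_prob=cell["p_er"],
        k1=config.k1,
        k2=config.k2,
        p_pcro=cell["p_pcro"],
    )
    report = simulate_counts(errn, config, n_samples, seed)
    nin_d = nin_count_dist(model)
    adin_d = adin_count_dist(model)
    cl_d = cl_count_dist(model, (nin_d, adin_d, pdin_count_dist(model)))
    tv = {
        "tv_adin": total_variation(adin_d, report.empirical_pmf("adin")),
        "tv_nin": total_variation(nin_d, report.empirical_pmf("nin")),
        "tv_cl": total_variation(cl_d, report.empirical_pmf("cl")),
    }
    row = {
        "cell": cell.get("cell", str(cell)),
        **{k: cell[k] for k in ("n_nodes", "p_er", "k1", "k2", "p_pcro")},
        **tv,
        "mean_cl_analytic": cl_d.mean(),
        "mean_cl_empirical": report.mean("cl"),
        "mean_cl_sem": report.sem("cl"),
        "n_samples": n_samples,
        "n_rejected": report.n_rejected,
    }
    row["mean_cl_discrepancy"] = abs(row["mean_cl_analytic"] - row["mean_cl_empirical"])
    row["pass"] = all(v <= tv_threshold for v in tv.values())
    return row


def validation_suite(
    cells: list[dict] | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    tv_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the full comparison grid; one row per cell, flagging cells whose
    total variation distance exceeds the threshold."""
    if cells is None:
        cells = default_validation_cells()
    rows = [
        compare_cell(cell, n_samples, seed + i, tv_threshold)
        for i, cell in enumerate(cells)
    ]
    return pd.DataFrame(rows)
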