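"""Structural metrics of operated networks: clustering and path length.

Operated networks can be disconnected (hubs plus leaves may split off), so
the mean shortest path length is averaged over *connected* pairs only, and
the fraction of excluded (disconnected) pairs is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ERRNParams, Graph, generate_errn
from .pcro import DegenerateNetworkError, PCROConfig, apply_pcro

__all__ = [
    "avg_clustering",
    "mean_shortest_path",
    "shortest_path_stats",
    "metric_curve",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no value (e.g. no connected pair exists)."""


def avg_clustering(g: Graph) -> float:
    """Mean local clustering coefficient over all nodes; nodes of degree < 2
    contribute 0."""
    return float(nx.average_clustering(g.to_networkx(), count_zeros=True))


@dataclass(frozen=True)
class PathStats:
    mean: float
    excluded_fraction: float  # fraction of ordered node pairs with no path


def shortest_path_stats(g: Graph) -> PathStats:
    """Mean shortest-path distance over connected ordered pairs, plus the
    fraction of pairs excluded for being disconnected."""
    nxg = g.to_networkx()
    total = 0
    n_connected = 0
    for _, dists in nx.all_pairs_shortest_path_length(nxg):
        for target, d in dists.items():
            if d > 0:
                total += d
                n_connected += 1
    n_pairs = g.n_nodes * (g.n_nodes - 1)
    if n_connected == 0:
        raise UndefinedMetricError("graph has no connected pair of nodes")
    return PathStats(
        mean=total / n_connected,
        excluded_fraction=1.0 - n_connected / n_pairs,
    )


def mean_shortest_path(g: Graph) -> float:
    return shortest_path_stats(g).mean


def metric_curve(
    errn: ERRNParams,
    p_pcro_grid,
    n_realizations: int,
    seed: int,
    config: PCROConfig | None = None,
) -> pd.DataFrame:
    """Clustering and path length of the post-rewire network versus the
    operation probability, averaged over fresh realizations.

    Degenerate realizations (too few non-isolated nodes to host the hubs)
    are skipped and counted.  Columns: p_pcro, c_mean, c_se, l_mean, l_se,
    excluded_fraction, n_ok, n_rejected.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    base = config or PCROConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for p in p_pcro_grid:
        cfg = PCROConfig(k1=base.k1, k2=base.k2, k3=base.k3,
                         p_pcro=float(p), n_hubs=base.n_hubs)
        cs, ls, excl = [], [], []
        n_rejected = 0
        for _ in range(n_realizations):
            g = generate_errn(errn, rng)
            try:
                result = apply_pcro(g, cfg, rng)
            except DegenerateNetworkError:
                n_rejected += 1
                continue
            final = result.final_graph
            cs.append(avg_clustering(final))
            stats = shortest_path_stats(final)
            ls.append(stats.mean)
            excl.append(stats.excluded_fraction)
        cs_a, ls_a = np.array(cs), np.array(ls)
        rows.append(
            {
                "p_pcro": float(p),
                "c_mean": cs_a.mean() if cs else np.nan,
                "c_se": cs_a.std(ddof=1) / np.sqrt(len(cs)) if len(cs) > 1 else np.nan,
                "l_mean": ls_a.mean() if ls else np.nan,
                "l_se": ls_a.std(ddof=1) / np.sqrt(len(ls)) if len(ls) > 1 else np.nan,
                "excluded_fraction": float(np.mean(excl)) if excl else np.nan,
                "n_ok": len(cs),
                "n_rejected": n_rejected,
            }
        )
    return pd.DataFrame(rows)
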