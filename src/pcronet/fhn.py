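"""FitzHugh–Nagumo network dynamics with rotational coupling.

Each node carries a fast activator u and a slow inhibitor v:

    eps * du_i/dt = u_i - u_i^3/3 - v_i
                    + sigma * sum_j A_ij [ cos(phi) (u_j - u_i) + sin(phi) (v_j - v_i) ]
    dv_i/dt       = u_i + alpha
                    + sigma * sum_j A_ij [ -sin(phi) (u_j - u_i) + cos(phi) (v_j - v_i) ]

The coupling matrix is the rotation by angle phi acting on the (u, v)
difference vector; with phi near pi/2 the coupling is mostly cross-variable,
which is what makes transient synchronization episodes possible on suitable
topologies.  For alpha < 1 each uncoupled unit is oscillatory.

Synchrony is measured by the global Kuramoto order parameter
r(t) = |mean_i exp(i theta_i(t))| with theta_i the geometric phase of
(u_i, v_i) about the origin; seizure-like episodes are maximal intervals
with r above a threshold sustained longer than a minimum duration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph

__all__ = [
    "FHNParams",
    "FHNTrajectory",
    "SeizureEpisode",
    "IntegrationBlowupError",
    "simulate_fhn",
    "kuramoto_order",
    "detect_seizures",
]


class IntegrationBlowupError(RuntimeError):
    """State became non-finite during integration."""

    def __init__(self, t: float):
        super().__init__(f"non-finite state at t={t:.6g}")
        self.t = t


@dataclass(frozen=True)
class FHNParams:
    """Model and integration parameters.

    alpha: excitability (alpha < 1: oscillatory units).  epsilon: timescale
    separation of the activator.  phi: coupling rotation angle.  sigma:
    coupling strength.  dt: fixed RK4 step in model time units.  t_total:
    integration span.  seconds_per_unit maps model time to seconds for the
    episode rule (1.0 unless the user supplies a calibration).
    degree_normalized divides the coupling of each node by its degree.
    """

    alpha: float = 0.5
    epsilon: float = 0.05
    phi: float = math.pi / 2 - 0.1
    sigma: float = 0.07
    dt: float = 0.005
    t_total: float = 100.0
    seconds_per_unit: float = 1.0
    degree_normalized: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.seconds_per_unit <= 0:
            raise ValueError("seconds_per_unit must be > 0")


@dataclass(frozen=True)
class FHNTrajectory:
    """Integrated time series: t (T,), u and v (T, N)."""

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    params: FHNParams

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape or self.u.shape[0] != self.t.shape[0]:
            raise ValueError("inconsistent trajectory array shapes")


@dataclass(frozen=True)
class SeizureEpisode:
    """One detected synchronization episode, in seconds."""

    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _rhs(
    u: np.ndarray, v: np.ndarray, adj, deg: np.ndarray, p: FHNParams
) -> tuple[np.ndarray, np.ndarray]:
    cu = adj @ u - deg * u  # sum_j A_ij (u_j - u_i)
    cv = adj @ v - deg * v
    if p.degree_normalized:
        safe = np.maximum(deg, 1.0)
        cu, cv = cu / safe, cv / safe
    cosp, sinp = math.cos(p.phi), math.sin(p.phi)
    du = (u - u**3 / 3.0 - v + p.sigma * (cosp * cu + sinp * cv)) / p.epsilon
    dv = u + p.alpha + p.sigma * (-sinp * cu + cosp * cv)
    return du, dv


def simulate_fhn(
    g: Graph,
    params: FHNParams,
    initial_state: tuple[np.ndarray, np.ndarray] | str = "random",
    seed: int | np.random.Generator = 0,
) -> FHNTrajectory:
    """Integrate the coupled system with fixed-step RK4.

    ``initial_state`` is either explicit per-node ``(u0, v0)`` arrays or
    ``"random"``, which draws u and v uniformly from [-2, 2] x [-2, 2]
    (covering the uncoupled limit cycle) with the given seed.  Deterministic
    given (graph, params, initial_state, seed).
    """
    n = g.n_nodes
    if initial_state == "random":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        u = rng.uniform(-2.0, 2.0, size=n)
        v = rng.uniform(-2.0, 2.0, size=n)
    else:
        u0, v0 = initial_state
        u = np.array(u0, dtype=np.float64)
        v = np.array(v0, dtype=np.float64)
        if u.shape != (n,) or v.shape != (n,):
            raise ValueError(f"initial state must have shape ({n},)")

    import scipy.sparse as sp

    iu = [e[0] for e in g.edges]
    ju = [e[1] for e in g.edges]
    adj = sp.coo_matrix(
        (np.ones(2 * len(iu)), (iu + ju, ju + iu)), shape=(n, n)
    ).tocsr()
    deg = g.degrees().astype(np.float64)

    n_steps = int(round(params.t_total / params.dt))
    t = np.arange(n_steps + 1) * params.dt
    us = np.empty((n_steps + 1, n))
    vs = np.empty((n_steps + 1, n))
    us[0], vs[0] = u, v
    h = params.dt
    for step in range(1, n_steps + 1):
        k1u, k1v = _rhs(u, v, adj, deg, params)
        k2u, k2v = _rhs(u + 0.5 * h * k1u, v + 0.5 * h * k1v, adj, deg, params)
        k3u, k3v = _rhs(u + 0.5 * h * k2u, v + 0.5 * h * k2v, adj, deg, params)
        k4u, k4v = _rhs(u + h * k3u, v + h * k3v, adj, deg, params)
        u = u + h / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        v = v + h / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise IntegrationBlowupError(step * h)
        us[step], vs[step] = u, v
    return FHNTrajectory(t=t, u=us, v=vs, params=params)


def kuramoto_order(traj: FHNTrajectory) -> np.ndarray:
    """Global Kuramoto order parameter r(t) in [0, 1].

    The phase of each node is the four-quadrant angle of (u, v) about the
    origin; nodes sitting exactly at the origin have no phase and are
    excluded from the average with a warning.
    """
    theta = np.arctan2(traj.v, traj.u)
    at_origin = (traj.u == 0.0) & (traj.v == 0.0)
    if np.any(at_origin):
        warnings.warn(
            "state exactly at the origin: phase undefined for "
            f"{int(at_origin.sum())} node-time samples; excluded from r",
            stacklevel=2,
        )
        phasor = np.where(at_origin, 0.0, np.exp(1j * theta))
        counts = np.maximum((~at_origin).sum(axis=1), 1)
        return np.abs(phasor.sum(axis=1)) / counts
    return np.abs(np.exp(1j * theta).mean(axis=1))


def detect_seizures(
    r: np.ndarray,
    t: np.ndarray,
    threshold: float = 0.8,
    min_duration_s: float = 8.0,
    seconds_per_unit: float = 1.0,
) -> list[SeizureEpisode]:
    """Maximal runs with r > threshold lasting more than ``min_duration_s``
    seconds (model time mapped through ``seconds_per_unit``).

    Returns non-overlapping, time-ordered episodes with start/end instants
    in seconds.
    """
    r = np.asarray(r, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if r.shape != t.shape:
        raise ValueError("r and t must have the same shape")
    above = r > threshold
    episodes: list[SeizureEpisode] = []
    idx = 0
    n = above.size
    while idx < n:
        if not above[idx]:
            idx += 1
            continue
        start = idx
        while idx < n and above[idx]:
            idx += 1
        t_start = t[start] * seconds_per_unit
        t_end = t[idx - 1] * seconds_per_unit
        if t_end - t_start > min_duration_s:
            episodes.append(SeizureEpisode(t_start, t_end))
    return episodes
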