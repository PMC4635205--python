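"""Behavior contagion on contact networks.

Covers four layers of the network story:

* graph generators — Poisson (Erdős–Rényi-style) random graphs,
  Barabási–Albert preferential-attachment trees, and the configuration
  model with a prescribed degree sequence;
* percolation analytics with immune-node removal — a fraction ``alpha`` of
  individuals is immune to behavioral influence and is deleted uniformly at
  random; a giant component of the residual network emerges at
  ``p (1 - alpha) n = 1``, the expected outbreak fraction solves
  ``r = 1 - exp(-c r)`` with ``c = (1 - alpha) n p``, and for the
  configuration model the threshold is ``<d^2> = 2 <d>`` on the residual
  degree sequence;
* mean-field spreading — the homogeneous logistic equation
  ``di/dt = lambda <k> i (1 - i)`` and the degree-based (heterogeneous)
  density equations ``di_k/dt = lambda k theta(t) (1 - i_k)`` with their
  early-time exponential closed form;
* a networked agent-based simulator with per-agent ``behavioral_degree``
  (diffusion strength in [0, 1]), synchronous discrete-time updates, and no
  recovery.

Graphs are plain :class:`networkx.Graph` objects with nodes 0..n-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.sparse import csr_array

__all__ = [
    "ImmunityConfig",
    "DegreeMoments",
    "MeanFieldSISParams",
    "OutbreakEstimate",
    "PercolationSweep",
    "generate_poisson_graph",
    "generate_ba_graph",
    "generate_configuration_graph",
    "remove_immune",
    "giant_component_fraction",
    "solve_outbreak_fraction",
    "outbreak_coupling",
    "estimate_percolation_threshold",
    "connectivity_regime",
    "config_supercritical_margin",
    "degree_moments",
    "meanfield_homogeneous",
    "meanfield_degree_based",
    "simulate_network_contagion",
]


@dataclass(frozen=True)
class ImmunityConfig:
    """Probability that any individual is immune to others' behavior."""

    alpha_immune: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_immune <= 1.0:
            raise ValueError("alpha_immune must be in [0, 1]")


@dataclass(frozen=True)
class DegreeMoments:
    """First and second moments of a degree distribution."""

    mean_deg: float
    second_moment: float

    def __post_init__(self) -> None:
        if self.mean_deg < 0 or self.second_moment < 0:
            raise ValueError("moments must be non-negative")
        if self.second_moment < self.mean_deg**2 - 1e-12:
            raise ValueError("second_moment must be >= mean_deg^2 (Jensen)")


@dataclass(frozen=True)
class OutbreakEstimate:
    """Dimensionless coupling c = (1-alpha) n p and outbreak fraction r."""

    c: float
    r: float


def generate_poisson_graph(n: int, p: float, seed: Optional[int] = None) -> nx.Graph:
    """Poisson random network: each unordered pair linked with probability p."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return nx.fast_gnp_random_graph(n, p, seed=seed)


def generate_ba_graph(n: int, seed: Optional[int] = None) -> nx.Graph:
    """Preferential-attachment graph grown one edge per arriving node.

    Each new node attaches to an existing node i with probability
    proportional to its degree k_i; the result is a tree on n nodes whose
    degree distribution follows a power law P(k) ~ k^-gamma, 2 <= gamma <= 3.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return nx.barabasi_albert_graph(n, 1, seed=seed)


def generate_configuration_graph(
    degree_sequence: Sequence[int], seed: Optional[int] = None
) -> nx.Graph:
    """Stub-matching configuration model, simplified to a plain graph.

    Self-loops and parallel edges produced by the matching are removed
    (standard simplification; the degree distortion is O(1) edges).
    """
    degs = [int(d) for d in degree_sequence]
    if any(d < 0 for d in degs):
        raise ValueError("degrees must be non-negative")
    if sum(degs) % 2 != 0:
        raise ValueError("degree sum must be even")
    multi = nx.configuration_model(degs, seed=seed)
    g = nx.Graph(multi)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def remove_immune(graph: nx.Graph, cfg: ImmunityConfig) -> tuple[nx.Graph, np.ndarray]:
    """Delete immune nodes (each node immune independently with prob alpha).

    Returns the induced subgraph relabeled 0..m-1 plus the array of original
    node ids that survived (position j holds the original id of new node j).
    """
    rng = np.random.default_rng(cfg.seed)
    nodes = np.array(sorted(graph.nodes()))
    keep = nodes[rng.random(nodes.size) >= cfg.alpha_immune]
    sub = graph.subgraph(keep).copy()
    relabeled = nx.relabel_nodes(sub, {old: new for new, old in enumerate(keep)})
    return relabeled, keep


def giant_component_fraction(graph: nx.Graph) -> float:
    """Size of the largest connected component divided by n (0 if empty)."""
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    return max(len(c) for c in nx.connected_components(graph)) / n


def solve_outbreak_fraction(c: float) -> float:
    """Largest root in [0, 1] of the outbreak equation r = 1 - exp(-c r).

    c is the dimensionless coupling (1 - alpha) n p. Below and at the
    percolation threshold (c <= 1) the only root is r = 0.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    if c <= 1.0:
        return 0.0
    f = lambda r: 1.0 - math.exp(-c * r) - r
    # f(eps) > 0 for c > 1, f(1) = -exp(-c) < 0: bracketed root.
    return float(brentq(f, 1e-12, 1.0, xtol=1e-14, rtol=8.9e-16))


def outbreak_coupling(r: float) -> float:
    """Coupling (1-alpha) n p implied by an outbreak fraction r in (0, 1).

    Algebraic rearrangement of r = 1 - exp(-c r): c = -ln(1 - r) / r.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    return -math.log1p(-r) / r


@dataclass(frozen=True)
class PercolationSweep:
    """Result of a giant-component emergence sweep over link probabilities."""

    p_critical: float
    coupling_at_crossing: float  # p (1 - alpha) n at the crossing
    curve: pd.DataFrame  # columns: p, coupling, mean_giant_fraction
    crossed_at_first_point: bool


def estimate_percolation_threshold(
    n: int,
    alpha_immune: float,
    p_grid: Sequence[float],
    reps: int,
    seed: Optional[int] = None,
    emergence_cutoff: float = 0.05,
) -> PercolationSweep:
    """Monte-Carlo estimate of the giant-component emergence threshold.

    For each p: generate a Poisson graph on n nodes, remove immune nodes
    (probability ``alpha_immune`` each), and average the largest-component
    fraction of the residual graph over ``reps`` replicates. The critical p
    is the first grid point where the average crosses ``emergence_cutoff``.
    """
    p_arr = np.asarray(p_grid, dtype=float)
    if p_arr.size == 0 or np.any(np.diff(p_arr) <= 0):
        raise ValueError("p_grid must be non-empty and sorted increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * p_arr.size * reps)
    means = np.empty(p_arr.size)
    idx = 0
    for j, p in enumerate(p_arr):
        fractions = np.empty(reps)
        for r in range(reps):
            g = generate_poisson_graph(n, float(p), seed=int(child_seeds[idx]))
            residual, _ = remove_immune(
                g, ImmunityConfig(alpha_immune, seed=int(child_seeds[idx + 1]))
            )
            fractions[r] = giant_component_fraction(residual)
            idx += 2
        means[j] = fractions.mean()
    curve = pd.DataFrame(
        {"p": p_arr, "coupling": p_arr * (1.0 - alpha_immune) * n, "mean_giant_fraction": means}
    )
    crossed = np.nonzero(means >= emergence_cutoff)[0]
    if crossed.size == 0:
        raise RuntimeError("no threshold in range: emergence cutoff never crossed")
    k = int(crossed[0])
    first = k == 0
    if first:
        warnings.warn(
            "emergence cutoff already exceeded at the first grid point; "
            "the reported threshold is an upper bound",
            RuntimeWarning,
            stacklevel=2,
        )
    return PercolationSweep(
        p_critical=float(p_arr[k]),
        coupling_at_crossing=float(p_arr[k] * (1.0 - alpha_immune) * n),
        curve=curve,
        crossed_at_first_point=first,
    )


def connectivity_regime(n: int, alpha_immune: float, p: float) -> str:
    """Classify the residual network regime for link probability p.

    Returns "subcritical" (p below 1/((1-alpha)n), only small components),
    "supercritical" (a giant component but not full connectivity), or
    "connected-regime" (p above log((1-alpha)n)/((1-alpha)n), the whole
    susceptible network is connected asymptotically).
    """
    m = (1.0 - alpha_immune) * n
    if m < 2:
        raise ValueError("(1 - alpha) n must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p * m < 1.0:
        return "subcritical"
    if p > math.log(m) / m:
        return "connected-regime"
    return "supercritical"


def degree_moments(graph: nx.Graph) -> DegreeMoments:
    """Empirical <d> and <d^2> of a graph's degree sequence."""
    degs = np.array([d for _, d in graph.degree()], dtype=float)
    if degs.size == 0:
        return DegreeMoments(0.0, 0.0)
    return DegreeMoments(float(degs.mean()), float((degs**2).mean()))


def config_supercritical_margin(moments: DegreeMoments) -> float:
    """Signed distance <d^2> - 2<d> from the configuration-model threshold.

    Positive: a giant component is expected; zero: critical; negative:
    subcritical. When immune removal applies, compute the moments on the
    residual (post-removal) graph.
    """
    return moments.second_moment - 2.0 * moments.mean_deg


def meanfield_homogeneous(lam: float, k_mean: float, i0: float, times) -> np.ndarray:
    """Informed density i(t) in a homogeneous network of mean degree <k>.

    Logistic solution of di/dt = lambda <k> i (1 - i):
    i(t) = i0 e^{lambda <k> t} / (1 - i0 + i0 e^{lambda <k> t}).
    """
    if lam < 0 or k_mean < 0:
        raise ValueError("lam and k_mean must be non-negative")
    if not 0.0 <= i0 <= 1.0:
        raise ValueError("i0 must be in [0, 1]")
    t = np.asarray(times, dtype=float)
    g = np.exp(lam * k_mean * t)
    return i0 * g / (1.0 - i0 + i0 * g)


@dataclass(frozen=True)
class MeanFieldSISParams:
    """Degree-based mean-field parameters.

    lam         : diffusion probability per unit time, in (0, 1]
    i0          : initial informed density, in (0, 1]
    degrees     : integer degree classes k
    pk          : degree distribution P(k) over those classes (sums to 1)
    """

    lam: float
    i0: float
    degrees: np.ndarray
    pk: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.degrees, dtype=float)
        p = np.asarray(self.pk, dtype=float)
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must be in (0, 1]")
        if not 0.0 < self.i0 <= 1.0:
            raise ValueError("i0 must be in (0, 1]")
        if k.shape != p.shape or k.ndim != 1:
            raise ValueError("degrees and pk must be 1-D arrays of equal length")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pk must be a probability distribution")
        object.__setattr__(self, "degrees", k)
        object.__setattr__(self, "pk", p)
        if self.k2_mean <= self.k_mean:
            raise ValueError("<k^2> must exceed <k> for the spreading time scale")

    @property
    def k_mean(self) -> float:
        return float(np.sum(self.degrees * self.pk))

    @property
    def k2_mean(self) -> float:
        return float(np.sum(self.degrees**2 * self.pk))

    @property
    def tau(self) -> float:
        """Spreading time scale <k^2> / (lambda (<k^2> - <k>)), as printed
        in the source model description (see also :attr:`tau_consistent`)."""
        return self.k2_mean / (self.lam * (self.k2_mean - self.k_mean))

    @property
    def tau_consistent(self) -> float:
        """Time scale <k> / (lambda (<k^2> - <k>)) that makes the early-time
        closed form consistent with the density equations (the form in the
        mean-field literature this model descends from)."""
        return self.k_mean / (self.lam * (self.k2_mean - self.k_mean))


@dataclass(frozen=True)
class MeanFieldResult:
    times: np.ndarray
    i_k_closed: np.ndarray  # shape (n_degrees, n_times), capped at 1
    i_k_ode: np.ndarray  # numerically integrated densities
    aggregate_closed: np.ndarray
    aggregate_ode: np.ndarray
    tau: float


def meanfield_degree_based(
    params: MeanFieldSISParams, times, tau: Optional[float] = None
) -> MeanFieldResult:
    """Per-degree informed densities i_k(t): closed form and ODE integration.

    Closed form (early-time, uniform initial condition i_k(0) = i0):
    ``i_k(t) = i0 [1 + k <k> / (<k^2> - <k>) (e^{t/tau} - 1)]`` capped at 1,
    with ``tau`` defaulting to :attr:`MeanFieldSISParams.tau`. The ODE route
    integrates ``di_k/dt = lambda k theta(t) (1 - i_k)`` with the
    uncorrelated-network neighbor field
    ``theta(t) = sum_k k P(k) i_k(t) / <k>``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be non-negative and sorted")
    k = params.degrees
    if tau is None:
        tau = params.tau
    amp = k * params.k_mean / (params.k2_mean - params.k_mean)
    closed = params.i0 * (1.0 + amp[:, None] * (np.exp(t[None, :] / tau) - 1.0))
    closed = np.minimum(closed, 1.0)

    km = params.k_mean

    def rhs(_t, y):
        theta = float(np.sum(k * params.pk * y)) / km
        return params.lam * k * theta * (1.0 - y)

    if float(t.max()) == 0.0:
        ode = np.full((k.size, t.size), params.i0)
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(t.max())),
            np.full(k.size, params.i0),
            t_eval=t,
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed: {sol.message}")
        ode = sol.y
    return MeanFieldResult(
        times=t,
        i_k_closed=closed,
        i_k_ode=ode,
        aggregate_closed=np.sum(params.pk[:, None] * closed, axis=0),
        aggregate_ode=np.sum(params.pk[:, None] * ode, axis=0),
        tau=float(tau),
    )


def simulate_network_contagion(
    graph: nx.Graph,
    transmit_prob: float,
    spontaneous_prob: float,
    initial_adopters: Iterable[int],
    t_steps: int,
    seed: Optional[int] = None,
    reps: int = 1,
    immune_set: Iterable[int] = (),
    behavioral_degree: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Synchronous agent-based contagion without recovery.

    Each step, every adopter with positive ``behavioral_degree`` tries to
    spread the behavior: a non-immune, non-adopted neighbor of adopter i
    adopts with probability ``transmit_prob * behavioral_degree[i]``,
    independently per adopter neighbor. Non-adopters additionally adopt
    spontaneously with ``spontaneous_prob``. Immune agents never adopt.

    Returns an array of shape (reps, t_steps + 1) of adopted counts per
    step; column 0 is the initial state. Runs are bit-reproducible for a
    given seed.
    """
    if not 0.0 <= transmit_prob <= 1.0 or not 0.0 <= spontaneous_prob <= 1.0:
        raise ValueError("probabilities must be in [0, 1]")
    if t_steps < 0 or reps < 1:
        raise ValueError("t_steps must be >= 0 and reps >= 1")
    n = graph.number_of_nodes()
    bd = np.ones(n) if behavioral_degree is None else np.asarray(behavioral_degree, float)
    if bd.shape != (n,) or np.any(bd < 0) or np.any(bd > 1):
        raise ValueError("behavioral_degree must be per-node values in [0, 1]")
    immune = np.zeros(n, dtype=bool)
    immune[list(immune_set)] = True
    seeds = np.fromiter(initial_adopters, dtype=int)
    if np.any(immune[seeds]):
        raise ValueError("initial adopters must not be immune")

    adj = nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr", dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty((reps, t_steps + 1), dtype=int)
    # Per-adopter "missed transmission" log-probability; A @ x sums it over
    # adopter neighbors, so exp of the sum is P(no neighbor transmits).
    with np.errstate(divide="ignore"):
        log_miss = np.log1p(-np.clip(transmit_prob * bd, 0.0, 1.0))
    for rep in range(reps):
        adopted = np.zeros(n, dtype=bool)
        adopted[seeds] = True
        out[rep, 0] = int(adopted.sum())
        for step in range(1, t_steps + 1):
            source = np.where(adopted, log_miss, 0.0)
            total_log_miss = adj @ source
            p_contact = -np.expm1(total_log_miss)
            p_adopt = p_contact + (1.0 - p_contact) * spontaneous_prob
            can_adopt = ~adopted & ~immune
            new = can_adopt & (rng.random(n) < p_adopt)
            adopted |= new
            out[rep, step] = int(adopted.sum())
            if not new.any() and spontaneous_prob == 0.0:
                out[rep, step:] = out[rep, step]
                break
    return out
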