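"""Integrated network-contagion + discrete-event policy model.

Networked agents adopt a behavior by contagion (as in
:func:`behaviordyn.networks.simulate_network_contagion`). Each agent keeps
an internal adoption output — its adoption state smoothed exponentially
into an exposure score — and when that output exceeds a threshold the
agent emits a behavior-change request. Requests enter a FIFO queue served
by a capacity-limited policy layer (the "public policy" block): each
processed request reverts the agent to the non-adopted state with a given
success probability. The model explores how policy capacity shapes the
long-run adopted fraction.

This layer is a deliberately simplified reconstruction: the source
describes the coupling between agent-level outputs and a top-level
discrete-event policy but gives no block equations, so the smoothing and
the single FIFO service discipline here are this package's own choices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["PolicyConfig", "run_integrated_model"]


@dataclass(frozen=True)
class PolicyConfig:
    """Discrete-event policy layer parameters.

    output_threshold : internal-output level above which an agent requests
                       a behavior change (internal output lies in [0, 1])
    service_capacity : requests processed per time step (>= 0)
    success_prob     : probability a processed request reverts the agent
    smoothing        : exponential smoothing constant of the exposure score
                       (1.0 means the output equals the raw adoption state)
    """

    output_threshold: float
    service_capacity: int
    success_prob: float
    smoothing: float = 1.0

    def __post_init__(self) -> None:
        if self.service_capacity < 0:
            raise ValueError("service_capacity must be >= 0")
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must be in [0, 1]")
        if not 0.0 < self.smoothing <= 1.0:
            raise ValueError("smoothing must be in (0, 1]")


def run_integrated_model(
    graph: nx.Graph,
    transmit_prob: float,
    spontaneous_prob: float,
    initial_adopters: Iterable[int],
    policy: PolicyConfig,
    t_steps: int,
    seed: Optional[int] = None,
    immune_set: Iterable[int] = (),
) -> pd.DataFrame:
    """Run the integrated contagion + policy model for ``t_steps`` steps.

    Per step: (1) synchronous contagion update (adopters transmit to each
    susceptible neighbor with ``transmit_prob``; susceptibles also adopt
    spontaneously with ``spontaneous_prob``; immune agents never adopt);
    (2) agents whose smoothed output exceeds ``output_threshold`` enqueue
    one request (no duplicates while queued); (3) the policy serves up to
    ``service_capacity`` queued requests FIFO, each reverting the agent to
    susceptible with ``success_prob``.

    Returns a per-step trajectory: adopted count, queue length, requests
    emitted, requests served, successful reversions.
    """
    if not 0.0 <= transmit_prob <= 1.0 or not 0.0 <= spontaneous_prob <= 1.0:
        raise ValueError("probabilities must be in [0, 1]")
    if t_steps < 0:
        raise ValueError("t_steps must be >= 0")
    n = graph.number_of_nodes()
    immune = np.zeros(n, dtype=bool)
    immune[list(immune_set)] = True
    seeds = np.fromiter(initial_adopters, dtype=int)
    if np.any(immune[seeds]):
        raise ValueError("initial adopters must not be immune")

    adj = nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr", dtype=float)
    rng = np.random.default_rng(seed)
    adopted = np.zeros(n, dtype=bool)
    adopted[seeds] = True
    output = adopted.astype(float)  # smoothed exposure score, in [0, 1]
    queued = np.zeros(n, dtype=bool)
    queue: deque[int] = deque()
    gamma = policy.smoothing

    rows = [
        {
            "step": 0,
            "adopted": int(adopted.sum()),
            "queue_length": 0,
            "requests": 0,
            "served": 0,
            "reversions": 0,
        }
    ]
    with np.errstate(divide="ignore"):
        log_miss = float(np.log1p(-transmit_prob)) if transmit_prob < 1 else -np.inf
    for step in range(1, t_steps + 1):
        # (1) contagion update
        source = np.where(adopted, log_miss, 0.0)
        p_contact = -np.expm1(adj @ source)
        p_adopt = p_contact + (1.0 - p_contact) * spontaneous_prob
        new = ~adopted & ~immune & (rng.random(n) < p_adopt)
        adopted |= new
        output = (1.0 - gamma) * output + gamma * adopted.astype(float)

        # (2) emit requests
        want = (output > policy.output_threshold) & ~queued & ~immune
        requests = int(want.sum())
        for agent in np.nonzero(want)[0]:
            queue.append(int(agent))
        queued |= want

        # (3) serve
        served = 0
        reversions = 0
        while queue and served < policy.service_capacity:
            agent = queue.popleft()
            queued[agent] = False
            served += 1
            if adopted[agent] and rng.random() < policy.success_prob:
                adopted[agent] = False
                output[agent] = 0.0
                reversions += 1
        rows.append(
            {
                "step": step,
                "adopted": int(adopted.sum()),
                "queue_length": len(queue),
                "requests": requests,
                "served": served,
                "reversions": reversions,
            }
        )
    return pd.DataFrame(rows)
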