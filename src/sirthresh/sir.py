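"""Discrete-time synchronous-update SIR simulation on a network.

One randomly chosen seed node starts infected, all others susceptible.  Each
step, every infected node independently transmits to each susceptible
neighbor with probability β and then recovers with probability γ (the
transmit-then-recover micro-order: a node may transmit and recover in the
same step, and nodes infected at step t first transmit at step t+1).  The
process absorbs when no infected nodes remain; the observable is the final
recovered fraction r = R_∞/N ∈ [1/N, 1].

``run_sir`` is a transparent single-realization implementation with an
optional trajectory output (used for conservation checks); ``run_ensemble``
drives the compiled frontier kernel for the 10³–10⁵-realization ensembles the
threshold pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _kernel
from .network import Network

__all__ = ["SIRParams", "OutbreakEnsemble", "run_sir", "run_ensemble"]


@dataclass(frozen=True)
class SIRParams:
    beta: float
    gamma: float
    seed_node: Union[int, str] = "random"
    rng_seed: int = 0
    transmit_first: bool = True

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")

    @property
    def lam(self) -> float:
        """Effective spreading rate λ = β/γ."""
        return self.beta / self.gamma


@dataclass(frozen=True)
class OutbreakEnsemble:
    """Final epidemic sizes of independent realizations at one (λ, γ)."""

    network_id: str
    n_nodes: int
    lam: float
    gamma: float
    final_sizes: np.ndarray  # recovered fractions, each in [1/N, 1]
    rng_seed: int

    @property
    def n_realizations(self) -> int:
        return int(self.final_sizes.size)

    @property
    def beta(self) -> float:
        return self.lam * self.gamma

    def moments(self) -> tuple[float, float]:
        r = self.final_sizes
        return float(r.mean()), float((r**2).mean())


def run_sir(
    net: Network,
    params: SIRParams,
    return_trajectory: bool = False,
):
    """One SIR realization; returns the final recovered fraction.

    With ``return_trajectory=True`` also returns the per-step (S, I, R)
    counts, including the initial condition — a debugging/validation hook.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = net.n_nodes
    if params.seed_node == "random":
        seed = int(rng.integers(n))
    else:
        seed = int(params.seed_node)
        if not 0 <= seed < n:
            raise ValueError("seed node out of range")
    adj = net.adjacency
    indptr, indices = adj.indptr, adj.indices
    state = np.zeros(n, dtype=np.int8)  # 0 S, 1 I, 2 R
    state[seed] = 1
    infected = [seed]
    traj = [(n - 1, 1, 0)]
    while infected:
        if not params.transmit_first:
            recov = rng.random(len(infected)) < params.gamma
            for i, rec in zip(infected, recov):
                if rec:
                    state[i] = 2
            infected = [i for i, rec in zip(infected, recov) if not rec]
        newly = []
        for i in infected:
            for j in indices[indptr[i]:indptr[i + 1]]:
                if state[j] == 0 and rng.random() < params.beta:
                    state[j] = 3  # infected this step; active next step
                    newly.append(int(j))
        if params.transmit_first:
            recov = rng.random(len(infected)) < params.gamma
            for i, rec in zip(infected, recov):
                if rec:
                    state[i] = 2
            infected = [i for i, rec in zip(infected, recov) if not rec]
        for j in newly:
            state[j] = 1
        infected.extend(newly)
        s = int(np.sum(state == 0))
        i_ct = int(np.sum(state == 1))
        r_ct = int(np.sum(state == 2))
        traj.append((s, i_ct, r_ct))
    r_final = float(np.sum(state == 2)) / n
    if return_trajectory:
        return r_final, traj
    return r_final


def run_ensemble(
    net: Network,
    lam: float,
    gamma: float,
    n_realizations: int,
    rng_seed: int,
    transmit_first: bool = True,
    network_id: str = "",
) -> OutbreakEnsemble:
    """Independent final-size ensemble at effective rate λ (β = λ·γ).

    Each realization gets its own seed node, drawn uniformly, and its own RNG
    stream derived from ``rng_seed``; the ensemble is bit-reproducible.
    """
    beta = lam * gamma
    if beta > 1.0 + 1e-12:
        raise ValueError(f"beta = lambda*gamma = {beta:.4g} exceeds 1")
    beta = min(beta, 1.0)
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    ss = np.random.SeedSequence(rng_seed)
    seeds = (ss.generate_state(n_realizations, dtype=np.uint32)
             & np.uint32(0x7FFFFFFF)).astype(np.int64)
    rng = np.random.default_rng(ss.spawn(1)[0])
    seed_nodes = rng.integers(net.n_nodes, size=n_realizations)
    adj = net.adjacency
    counts = _kernel.final_sizes(
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        float(beta),
        float(gamma),
        seeds,
        seed_nodes.astype(np.int64),
        transmit_first,
    )
    return OutbreakEnsemble(
        network_id=network_id,
        n_nodes=net.n_nodes,
        lam=float(lam),
        gamma=float(gamma),
        final_sizes=counts / net.n_nodes,
        rng_seed=rng_seed,
    )
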