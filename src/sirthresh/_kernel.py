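"""Numba inner loop for SIR final-size ensembles.

A realization only ever touches the out-neighborhoods of infected nodes, so
the kernel walks the CSR adjacency frontier-by-frontier instead of doing
whole-network sweeps; sub- and near-critical outbreaks then cost O(outbreak
size × ⟨k⟩) regardless of N.  State resets between realizations also touch
only the previously infected nodes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_S, _I, _R, _NEW = np.uint8(0), np.uint8(1), np.uint8(2), np.uint8(3)


@njit(cache=True)
def final_sizes(indptr, indices, beta, gamma, seeds, seed_nodes,
                transmit_first):
    """Run one SIR realization per (seed, seed_node) pair; return recovered
    counts at absorption.

    Synchronous updating: each step the current infected set attempts
    transmission to susceptible neighbors (prob beta per contact) and then
    each infected node recovers with prob gamma (``transmit_first=True``,
    the standard order — a node can transmit and recover in the same step).
    With ``transmit_first=False`` recoveries are applied first and recovered
    nodes do not transmit that step.  Newly infected nodes become infectious
    the following step in both orders.
    """
    n_real = seeds.shape[0]
    n_nodes = indptr.shape[0] - 1
    out = np.empty(n_real, dtype=np.int64)
    state = np.zeros(n_nodes, dtype=np.uint8)
    frontier = np.empty(n_nodes, dtype=np.int64)
    nxt = np.empty(n_nodes, dtype=np.int64)
    touched = np.empty(n_nodes, dtype=np.int64)

    for t in range(n_real):
        np.random.seed(seeds[t])
        seed_node = seed_nodes[t]
        state[seed_node] = _I
        frontier[0] = seed_node
        n_front = 1
        touched[0] = seed_node
        n_touch = 1

        while n_front > 0:
            n_nxt = 0
            if not transmit_first:
                # recover-first order: survivors of recovery transmit below
                n_keep = 0
                for fi in range(n_front):
                    i = frontier[fi]
                    if np.random.random() < gamma:
                        state[i] = _R
                    else:
                        frontier[n_keep] = i
                        n_keep += 1
                n_front = n_keep
            # transmission from the current infectious set
            for fi in range(n_front):
                i = frontier[fi]
                for p in range(indptr[i], indptr[i + 1]):
                    j = indices[p]
                    if state[j] == _S and np.random.random() < beta:
                        state[j] = _NEW
                        nxt[n_nxt] = j
                        n_nxt += 1
                        touched[n_touch] = j
                        n_touch += 1
            if transmit_first:
                n_keep = 0
                for fi in range(n_front):
                    i = frontier[fi]
                    if np.random.random() < gamma:
                        state[i] = _R
                    else:
                        frontier[n_keep] = i
                        n_keep += 1
                n_front = n_keep
            # promote this step's infections; they transmit from next step
            for q in range(n_nxt):
                j = nxt[q]
                state[j] = _I
                frontier[n_front] = j
                n_front += 1

        out[t] = n_touch  # every ever-infected node has recovered
        for q in range(n_touch):
            state[touched[q]] = _S
    return out
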