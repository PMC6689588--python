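"""Compiled inner loop for memory writes and best-patch cache maintenance."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def update_memory_kernel(
    mem_keys: np.ndarray,
    mem_vals: np.ndarray,
    mem_count: np.ndarray,
    best_patch: np.ndarray,
    best_val: np.ndarray,
    agents: np.ndarray,
    patches: np.ndarray,
    values: np.ndarray,
    coins: np.ndarray,
) -> None:
    """Apply one observation per listed agent, in place.

    A repeat observation overwrites the patch's existing slot; a new patch is
    appended. The best-entry cache is updated incrementally: a strictly
    better value (or an equal value for a different patch winning its coin
    flip in ``coins``) moves the cache; a downward revision of the current
    best entry triggers a rescan over that agent's known entries.
    """
    for i in range(agents.shape[0]):
        a = agents[i]
        p = patches[i]
        v = values[i]
        cnt = mem_count[a]
        slot = -1
        for j in range(cnt):
            if mem_keys[a, j] == p:
                slot = j
                break
        if slot == -1:
            slot = cnt
            if slot >= mem_keys.shape[1]:
                raise RuntimeError(
                    "memory capacity exceeded: population stepped for more "
                    "rounds than it was sized for")
            mem_keys[a, slot] = p
            mem_count[a] = cnt + 1
        mem_vals[a, slot] = v

        bv = best_val[a]
        bp = best_patch[a]
        if v > bv or (v == bv and p != bp and coins[i] < 0.5):
            best_val[a] = v
            best_patch[a] = p
        elif p == bp and v < bv:
            m = mem_count[a]
            bj = 0
            nbv = mem_vals[a, 0]
            for j in range(1, m):
                if mem_vals[a, j] > nbv:
                    nbv = mem_vals[a, j]
                    bj = j
            best_val[a] = nbv
            best_patch[a] = mem_keys[a, bj]
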