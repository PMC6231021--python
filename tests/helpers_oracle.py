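"""Brute-force oracles for the path-pair tallies, kept deliberately naive:
every matched terminal is materialised as an (row, column) item and all
unordered pairs are classified one by one."""

from __future__ import annotations

import math

import numpy as np


def materialise_terminals(counts: np.ndarray) -> list[tuple[int, int]]:
    items: list[tuple[int, int]] = []
    n_rows, n_cols = counts.shape
    for i in range(n_rows):
        for j in range(n_cols):
            items.extend([(i, j)] * int(counts[i, j]))
    return items


def path_tallies_oracle(counts: np.ndarray) -> tuple[int, int, int]:
    """(TP, FN, FP) by exhaustive pair classification.

    Interior pairs sharing both labels are true positives; pairs sharing the
    ground-truth neuron but not the fragment (deleted terminals included)
    are false negatives; pairs sharing the fragment but not the neuron
    (inserted terminals included) are false positives.
    """
    items = materialise_terminals(np.asarray(counts))
    tp = fn = fp = 0
    n = len(items)
    for a in range(n):
        i1, j1 = items[a]
        for b in range(a + 1, n):
            i2, j2 = items[b]
            if i1 >= 1 and i2 >= 1 and j1 >= 1 and j2 >= 1:
                if i1 == i2 and j1 == j2:
                    tp += 1
                elif i1 == i2:
                    fn += 1
                elif j1 == j2:
                    fp += 1
            elif (j1 == 0 or j2 == 0) and i1 == i2:
                fn += 1  # a deleted terminal paired within its neuron
            elif (i1 == 0 or i2 == 0) and j1 == j2:
                fp += 1  # an inserted terminal paired within its fragment
    return tp, fn, fp


def rand_index_oracle(counts: np.ndarray) -> float:
    """Rand index over the two terminal partitions, reserved row/column
    treated as ordinary clusters."""
    items = materialise_terminals(np.asarray(counts))
    agree = 0
    total = 0
    n = len(items)
    for a in range(n):
        i1, j1 = items[a]
        for b in range(a + 1, n):
            i2, j2 = items[b]
            total += 1
            if (i1 == i2) == (j1 == j2):
                agree += 1
    return agree / total


def nvi_oracle(counts: np.ndarray) -> float:
    """Normalized variation of information by direct entropy sums."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    h_joint = h_g = h_s = 0.0
    for p in (c / total).ravel():
        if p > 0:
            h_joint -= p * math.log(p)
    for p in (c.sum(axis=1) / total):
        if p > 0:
            h_g -= p * math.log(p)
    for p in (c.sum(axis=0) / total):
        if p > 0:
            h_s -= p * math.log(p)
    vi = 2 * h_joint - h_g - h_s  # H(G|S) + H(S|G)
    return vi / h_joint if h_joint > 0 else 0.0
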