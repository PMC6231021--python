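"""Synapse correspondence by centroid proximity.

Reconstruction synapse ids carry no relation to ground-truth ids, so the two
tables are reconciled by a minimum-cost one-to-one assignment on Euclidean
centroid distance (Hungarian algorithm), with a distance cap beyond which a
synapse is better left unassigned.  Unassigned ground-truth synapses are
deletions; unassigned reconstruction synapses are insertions.

The cap is implemented exactly with the standard augmented formulation: every
synapse gets a private "unassigned" slot at cost equal to the cap, and pairs
farther apart than the cap are forbidden.  The optimum therefore minimises

    sum(paired distances) + cap * (number of unassigned synapses)

which never pairs two synapses farther apart than the cap, and pairs
everything it can otherwise.  Because a pair costs at most ``cap`` while two
unassigned slots cost ``2*cap``, unassignment is chosen only when no partner
within the cap is available (or when freeing a partner lowers total cost).

For large tables the problem is solved sparsely: only pairs within the cap
are candidates, and each connected component of the candidate graph is solved
independently — the augmented objective is separable over components, so this
is exact, not an approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .graph_model import SynapseTable

__all__ = ["Matching", "match_synapses", "assignment_oracle", "DEFAULT_MAX_DISTANCE"]

DEFAULT_MAX_DISTANCE = 300.0  # nm


@dataclass
class Matching:
    """A one-to-one pairing of reconstruction synapses to ground-truth synapses.

    ``pairs`` holds (gt synapse_id, recon synapse_id); every id appears in at
    most one pair and every paired distance is <= ``max_distance``.  Ids not
    in any pair land in ``unmatched_gt`` (deletions) or ``unmatched_recon``
    (insertions).
    """

    pairs: list[tuple[str, str]]
    unmatched_gt: set[str]
    unmatched_recon: set[str]
    max_distance: float
    distances: list[float] = field(default_factory=list)

    @property
    def total_distance(self) -> float:
        return float(sum(self.distances))

    def to_csv(self, path) -> None:
        """Audit export: one row per correspondence, with unmatched synapses
        listed against an empty partner field."""
        import pandas as pd

        rows = [
            {"gt_synapse": g, "recon_synapse": r, "distance_nm": d}
            for (g, r), d in zip(self.pairs, self.distances)
        ]
        rows += [{"gt_synapse": g, "recon_synapse": "", "distance_nm": ""}
                 for g in sorted(self.unmatched_gt)]
        rows += [{"gt_synapse": "", "recon_synapse": r, "distance_nm": ""}
                 for r in sorted(self.unmatched_recon)]
        pd.DataFrame(rows, columns=["gt_synapse", "recon_synapse", "distance_nm"]).to_csv(
            path, index=False, lineterminator="\n"
        )

    @property
    def objective(self) -> float:
        """Augmented assignment objective: paired distance plus cap per
        unassigned synapse."""
        return self.total_distance + self.max_distance * (
            len(self.unmatched_gt) + len(self.unmatched_recon)
        )


def match_synapses(
    gt: SynapseTable,
    recon: SynapseTable,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> Matching:
    """Optimally assign reconstruction synapses to ground-truth synapses.

    Returns the minimum of ``sum(paired distance) + max_distance * unassigned``
    over all one-to-one pairings that respect the cap.  Deterministic: inputs
    are processed in synapse-id order; among equal-cost optima the solver's
    deterministic choice is returned.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    gt_records = sorted(gt.records, key=lambda r: r.synapse_id)
    recon_records = sorted(recon.records, key=lambda r: r.synapse_id)
    gt_ids = [r.synapse_id for r in gt_records]
    recon_ids = [r.synapse_id for r in recon_records]
    if not gt_records or not recon_records:
        return Matching([], set(gt_ids), set(recon_ids), max_distance)

    gt_xyz = np.array([r.centroid for r in gt_records], dtype=float)
    recon_xyz = np.array([r.centroid for r in recon_records], dtype=float)

    tree_g = cKDTree(gt_xyz)
    tree_r = cKDTree(recon_xyz)
    # candidate gt->recon edges within the cap, as a sparse adjacency
    neighbor_lists = tree_g.query_ball_tree(tree_r, r=max_distance)

    # union-find over the bipartite candidate graph
    n_g, n_r = len(gt_ids), len(recon_ids)
    parent = list(range(n_g + n_r))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for gi, neigh in enumerate(neighbor_lists):
        for rj in neigh:
            union(gi, n_g + rj)

    comps: dict[int, tuple[list[int], list[int]]] = {}
    for gi in range(n_g):
        comps.setdefault(find(gi), ([], []))[0].append(gi)
    for rj in range(n_r):
        comps.setdefault(find(n_g + rj), ([], []))[1].append(rj)

    pairs: list[tuple[str, str]] = []
    distances: list[float] = []
    unmatched_gt: set[str] = set()
    unmatched_recon: set[str] = set()

    for root in sorted(comps):
        g_idx, r_idx = comps[root]
        if not g_idx or not r_idx:
            unmatched_gt.update(gt_ids[i] for i in g_idx)
            unmatched_recon.update(recon_ids[j] for j in r_idx)
            continue
        sub = np.linalg.norm(
            gt_xyz[g_idx][:, None, :] - recon_xyz[r_idx][None, :, :], axis=-1
        )
        rows, cols = _solve_capped(sub, max_distance)
        assigned_r = set()
        assigned_g = set()
        for a, b in zip(rows, cols):
            pairs.append((gt_ids[g_idx[a]], recon_ids[r_idx[b]]))
            distances.append(float(sub[a, b]))
            assigned_g.add(a)
            assigned_r.add(b)
        unmatched_gt.update(gt_ids[g_idx[a]] for a in range(len(g_idx)) if a not in assigned_g)
        unmatched_recon.update(
            recon_ids[r_idx[b]] for b in range(len(r_idx)) if b not in assigned_r
        )

    order = np.argsort([p[0] for p in pairs], kind="stable")
    pairs = [pairs[i] for i in order]
    distances = [distances[i] for i in order]
    return Matching(pairs, unmatched_gt, unmatched_recon, max_distance, distances)


def _solve_capped(cost: np.ndarray, cap: float) -> tuple[list[int], list[int]]:
    """Solve one capped assignment block exactly.

    Builds the (n+m) x (m+n) augmented square matrix: real costs top-left
    (forbidden beyond the cap), a private dummy column per row and dummy row
    per column at cost ``cap``, zeros for dummy-dummy.  Returns the indices of
    real row-column pairs in the optimum.
    """
    n, m = cost.shape
    big = cap * (n + m) + 1.0
    full = np.full((n + m, m + n), big)
    real = np.where(cost <= cap, cost, big)
    full[:n, :m] = real
    for i in range(n):
        full[i, m + i] = cap
    for j in range(m):
        full[n + j, j] = cap
    full[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(full)
    out_r: list[int] = []
    out_c: list[int] = []
    for a, b in zip(rows, cols):
        if a < n and b < m and cost[a, b] <= cap:
            out_r.append(int(a))
            out_c.append(int(b))
    return out_r, out_c


def assignment_oracle(cost: np.ndarray, max_distance: float) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive-search optimum of the capped assignment objective.

    Test oracle only: enumerates every partial one-to-one pairing whose pair
    costs are within the cap and minimises
    ``sum(pair costs) + max_distance * unassigned``.  Refuses matrices larger
    than 8 x 8.  Returns (pairs, objective value).
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n > 8 or m > 8:
        raise ValueError("assignment_oracle only accepts matrices up to 8 x 8")
    best_obj = float("inf")
    best_pairs: list[tuple[int, int]] = []
    cols = list(range(m))
    for k in range(0, min(n, m) + 1):
        for row_subset in itertools.combinations(range(n), k):
            for col_subset in itertools.permutations(cols, k):
                total = 0.0
                ok = True
                for i, j in zip(row_subset, col_subset):
                    c = cost[i, j]
                    if c > max_distance:
                        ok = False
                        break
                    total += c
                if not ok:
                    continue
                obj = total + max_distance * ((n - k) + (m - k))
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_pairs = list(zip(row_subset, col_subset))
    return best_pairs, best_obj
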