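"""Connectivity metrics computed from a count table.

The unit of account is the *intracellular path*: an unordered pair of
synaptic terminals residing on the same cell.  A reconstruction scores well
when the terminal pairs co-located on a ground-truth neuron are also
co-located on a single reconstructed fragment (true positives), without
co-locating pairs that belong to different ground-truth neurons (false
positives) or separating pairs that belong together (false negatives).

From the count table ``c_ij`` (rows: ground-truth neurons, columns:
reconstructed fragments, reserved index 0 for insertions/deletions):

* ``TP = sum_{i>=1, j>=1} C(c_ij, 2)``
* ``FN = sum_{i>=1} [ C(c_i0, 2) + sum_{0<=j<j'} c_ij c_ij' ]``
* ``FP``: the same formula on the transpose (insertion row in place of the
  deletion column).

The NRI score is the f-beta (default f1, the harmonic mean) of the precision
and recall built from those tallies, per neuron or globally.  The adapted
Rand index and the normalized variation of information (NVI) are computed
from the same table, treating the reserved row/column as extra "neurons".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .count_table import INS, CountTable
from .graph_model import SynapseTable, ValidationError
from .matching import Matching

__all__ = [
    "MetricCounts",
    "MetricResult",
    "NviTerms",
    "count_tp",
    "count_fn",
    "count_fp",
    "path_counts",
    "nri_from_counts",
    "neuron_nri",
    "global_nri",
    "adapted_rand",
    "normalized_vi",
    "undirected_tallies",
    "global_nri_undirected",
]


def _comb2(a: np.ndarray | int) -> np.ndarray | int:
    return a * (a - 1) // 2


@dataclass
class MetricCounts:
    """TP / FN / FP path-pair tallies (TN only for the adapted Rand index).

    ``fp_by_neuron`` carries the fractional false-positive attribution FP(i):
    merge-induced pairs are split half-and-half between the two neurons,
    insertion-vs-neuron pairs go fully to the neuron, and pure insertion
    pairs are booked under the reserved key ``"ins"``.  The attribution sums
    to the global FP exactly.
    """

    tp: int
    fn: int
    fp: int
    tn: int | None = None
    fp_by_neuron: dict[str, float] = field(default_factory=dict)


@dataclass
class MetricResult:
    precision: float
    recall: float
    score: float
    beta: float = 1.0
    variant: str = "directed"
    attribution: str = "attributed"
    tp: float = 0.0
    fp: float = 0.0
    fn: float = 0.0


def count_tp(table: CountTable) -> tuple[int, dict[str, int]]:
    """True positives: ``sum C(c_ij, 2)`` over the interior, with the
    per-neuron decomposition (the inner sum of the defining double sum)."""
    interior = table.interior
    per_row = _comb2(interior).sum(axis=1)
    per_neuron = {n: int(per_row[i]) for i, n in enumerate(table.row_labels)}
    return int(per_row.sum()), per_neuron


def count_fn(table: CountTable) -> tuple[int, dict[str, int]]:
    """False negatives per ground-truth neuron, deletion column included.

    A deleted terminal is paired once with every matched terminal of its
    neuron and once with every other deleted terminal of that neuron, so
    TP + FN for a neuron always equals C(row total, 2).
    """
    rows = table.counts[1:, :]  # include deletion column 0
    row_tot = rows.sum(axis=1)
    cross = (row_tot * row_tot - (rows * rows).sum(axis=1)) // 2
    per_row = _comb2(rows[:, 0]) + cross
    per_neuron = {n: int(per_row[i]) for i, n in enumerate(table.row_labels)}
    return int(per_row.sum()), per_neuron


def count_fp(table: CountTable) -> tuple[int, dict[str, float]]:
    """Global false positives (transpose form) and the attribution FP(i).

    FP(i) = sum_j c_ij c_0j + (1/2) sum_j sum_{i' != i} c_ij c_i'j, with the
    pure-insertion pairs sum_j C(c_0j, 2) booked under ``"ins"``; the terms
    sum to the global FP exactly.
    """
    cols = table.counts[:, 1:]  # include insertion row 0
    col_tot = cols.sum(axis=0)
    cross = (col_tot * col_tot - (cols * cols).sum(axis=0)) // 2
    global_fp = int((_comb2(cols[0, :]) + cross).sum())

    interior = table.interior
    ins_row = cols[0, :]
    interior_col_tot = interior.sum(axis=0)
    attribution: dict[str, float] = {INS: float(_comb2(ins_row).sum())}
    for i, neuron in enumerate(table.row_labels):
        c_i = interior[i, :]
        ins_pairs = float((c_i * ins_row).sum())
        merge_pairs = 0.5 * float((c_i * (interior_col_tot - c_i)).sum())
        attribution[neuron] = ins_pairs + merge_pairs
    return global_fp, attribution


def path_counts(table: CountTable) -> MetricCounts:
    """All global tallies plus the FP attribution, in one pass."""
    tp, _ = count_tp(table)
    fn, _ = count_fn(table)
    fp, attribution = count_fp(table)
    return MetricCounts(tp=tp, fn=fn, fp=fp, fp_by_neuron=attribution)


def nri_from_counts(
    tp: float,
    fp: float,
    fn: float,
    beta: float = 1.0,
    variant: str = "directed",
    attribution: str = "attributed",
) -> MetricResult:
    """f-beta of precision and recall over path pairs.

    Conventions at the boundary of the defining ratios:

    * no paths at all (TP = FP = FN = 0): nothing to get wrong, score 1;
    * TP = 0 with any error present: score 0;
    * an undefined precision (TP + FP = 0) or recall is reported as 1.0 when
      the other error count is also zero, else as NaN (the score is still 0).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        return MetricResult(1.0, 1.0, 1.0, beta, variant, attribution, tp, fp, fn)
    precision = tp / (tp + fp) if tp + fp > 0 else (1.0 if fn == 0 else math.nan)
    recall = tp / (tp + fn) if tp + fn > 0 else (1.0 if fp == 0 else math.nan)
    if tp == 0:
        score = 0.0
    else:
        b2 = beta * beta
        score = (1 + b2) * tp / ((1 + b2) * tp + b2 * fn + fp)
    return MetricResult(precision, recall, score, beta, variant, attribution, tp, fp, fn)


def neuron_nri(
    table: CountTable,
    neuron: str,
    attribution: str = "attributed",
    beta: float = 1.0,
) -> MetricResult:
    """Single-neuron NRI.

    ``attribution`` controls the false-positive share of the neuron:

    * ``"attributed"``: FP(i) with merge pairs halved between the two neurons
      involved — sums to the global FP over the network;
    * ``"incident"``: every false-positive pair containing at least one of
      the neuron's matched terminals, at full weight (double-counts across
      neurons, matches the single-neuron worked-example convention).
    """
    i = table.row_index(neuron)
    row = table.counts[i, :]
    tp = int(_comb2(row[1:]).sum())
    row_tot = int(row.sum())
    fn = int(_comb2(row[0]) + (row_tot * row_tot - int((row * row).sum())) // 2)
    if attribution == "attributed":
        _, attr = count_fp(table)
        fp: float = attr[neuron]
    elif attribution == "incident":
        col_tot = table.counts[:, 1:].sum(axis=0)
        c_i = table.counts[i, 1:]
        fp = float((c_i * (col_tot - c_i)).sum())
    else:
        raise ValueError(f"unknown attribution {attribution!r}")
    return nri_from_counts(tp, fp, fn, beta=beta, attribution=attribution)


def global_nri(table: CountTable, beta: float = 1.0) -> MetricResult:
    """Network-level NRI: f-beta of the total TP/FP/FN tallies."""
    tp, _ = count_tp(table)
    fn, _ = count_fn(table)
    fp, _ = count_fp(table)
    return nri_from_counts(tp, fp, fn, beta=beta)


def adapted_rand(table: CountTable, tn_mode: str = "pair_consistent") -> float:
    """Terminal-based Rand index, insertions/deletions as extra neurons.

    TP / FN / FP run over all indices including the reserved ones.  True
    negatives are, by default, the unordered terminal pairs lying in a
    different row *and* a different column (``pair_consistent``), the only
    definition under which TP+TN+FP+FN exhausts C(total, 2); the
    ``as_printed`` mode restricts the column pair to j < j' for literal
    reproduction of the published double sum.
    """
    c = table.counts
    total = int(c.sum())
    if total == 0:
        raise ValidationError("adapted Rand index undefined on an all-zero table")
    tp = int(_comb2(c).sum())
    row_tot = c.sum(axis=1)
    col_tot = c.sum(axis=0)
    fn = int(((row_tot * row_tot - (c * c).sum(axis=1)) // 2).sum())
    fp = int(((col_tot * col_tot - (c * c).sum(axis=0)) // 2).sum())
    if tn_mode == "pair_consistent":
        cross_row = (total * total - int((row_tot * row_tot).sum())) // 2
        same_col_cross_row = fp
        tn = cross_row - same_col_cross_row
    elif tn_mode == "as_printed":
        # suffix[i, j] = sum of c over i' > i and j' > j
        suffix = np.flip(np.cumsum(np.cumsum(np.flip(c), axis=0), axis=1))
        pad = np.zeros_like(c)
        pad[:-1, :-1] = suffix[1:, 1:]
        tn = int((c * pad).sum())
    else:
        raise ValueError(f"unknown tn_mode {tn_mode!r}")
    denom = tp + tn + fp + fn
    if denom == 0:
        # under pair_consistent this means < 2 terminals; under as_printed it
        # can also happen when every pair sits on the dropped anti-diagonal
        raise ValidationError("Rand index undefined: no classified terminal pairs")
    return (tp + tn) / denom


@dataclass
class NviTerms:
    """Joint/marginal matched-terminal distributions and the entropy terms of
    the normalized variation of information."""

    joint: np.ndarray
    p_gt: np.ndarray
    p_recon: np.ndarray
    h_gt_given_recon: float
    h_recon_given_gt: float
    h_joint: float
    nvi: float


def normalized_vi(table: CountTable) -> NviTerms:
    """Variation of information between the two terminal partitions,
    normalized by the joint entropy to [0, 1].

    The insertion row and deletion column count as additional neurons.
    Natural logarithms are used; the ratio is base-invariant.  A table whose
    mass sits in a single cell (one neuron matched to one fragment) has zero
    joint entropy and scores 0 — the two one-block partitions are identical.
    """
    c = table.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValidationError("NVI undefined on an all-zero table")
    joint = c / total
    p_gt = joint.sum(axis=1)
    p_recon = joint.sum(axis=0)
    nz = joint > 0
    h_joint = float(-(joint[nz] * np.log(joint[nz])).sum())
    cond_s = joint / np.where(p_recon > 0, p_recon, 1.0)[None, :]
    h_g_s = float(-(joint[nz] * np.log(cond_s[nz])).sum())
    cond_g = joint / np.where(p_gt > 0, p_gt, 1.0)[:, None]
    h_s_g = float(-(joint[nz] * np.log(cond_g[nz])).sum())
    nvi = (h_g_s + h_s_g) / h_joint if h_joint > 0 else 0.0
    return NviTerms(joint, p_gt, p_recon, h_g_s, h_s_g, h_joint, min(max(nvi, 0.0), 1.0))


def undirected_tallies(
    gt: SynapseTable, recon: SynapseTable, matching: Matching
) -> MetricCounts:
    """Polarity-free path tallies, by direct pair enumeration.

    Without trusted synapse direction the count table's oriented terminal
    pairing is unavailable, so the undirected variant enumerates unordered
    pairs of terminals directly: a ground-truth pair is a true positive when
    both synapses are matched and their reconstruction partners share a
    fragment (either end), a false negative otherwise; reconstruction-side
    pairs whose partners share no ground-truth neuron are false positives.
    On reversal-free inputs this equals the directed tallies.
    """
    gt_by_id = gt.by_id()
    recon_by_id = recon.by_id()
    g2r = dict(matching.pairs)
    r2g = {r: g for g, r in matching.pairs}

    def endpoint_sets(records, partner_map, partner_table):
        # per synapse id: the set of cell ids at its partner's two ends
        out = {}
        for rec in records:
            p_id = partner_map.get(rec.synapse_id)
            if p_id is None:
                out[rec.synapse_id] = None
            else:
                p = partner_table[p_id]
                out[rec.synapse_id] = frozenset((p.pre_neuron, p.post_neuron))
        return out

    gt_partner = endpoint_sets(gt.records, g2r, recon_by_id)
    recon_partner = endpoint_sets(recon.records, r2g, gt_by_id)

    def incident(records) -> dict[str, list[str]]:
        inc: dict[str, list[str]] = {}
        for rec in records:
            inc.setdefault(rec.pre_neuron, []).append(rec.synapse_id)
            inc.setdefault(rec.post_neuron, []).append(rec.synapse_id)
        return inc

    tp = fn = fp = 0
    for neuron, syn_ids in sorted(incident(gt.records).items()):
        sets = [gt_partner[s] for s in syn_ids]
        n = len(sets)
        for a in range(n):
            for b in range(a + 1, n):
                sa, sb = sets[a], sets[b]
                if sa is not None and sb is not None and sa & sb:
                    tp += 1
                else:
                    fn += 1
    for fragment, syn_ids in sorted(incident(recon.records).items()):
        sets = [recon_partner[s] for s in syn_ids]
        n = len(sets)
        for a in range(n):
            for b in range(a + 1, n):
                sa, sb = sets[a], sets[b]
                if sa is None or sb is None or not (sa & sb):
                    fp += 1
    return MetricCounts(tp=tp, fn=fn, fp=fp)


def global_nri_undirected(
    gt: SynapseTable, recon: SynapseTable, matching: Matching, beta: float = 1.0
) -> MetricResult:
    """Network NRI on undirected paths (see :func:`undirected_tallies`)."""
    counts = undirected_tallies(gt, recon, matching)
    return nri_from_counts(
        counts.tp, counts.fp, counts.fn, beta=beta, variant="undirected"
    )
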