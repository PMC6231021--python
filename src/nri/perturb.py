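"""Reconstruction-error models and perturbation diagnostics.

Four error models turn a ground-truth network into an imperfect
"reconstruction":

* **delete** — a fixed fraction of synapses, sampled uniformly, is removed;
* **insert** — every cross-neuron segment pair may gain a spurious synapse,
  with probability maximal below an inner surface distance ``d1`` and
  falling linearly to zero at ``d2``;
* **split** — every process segment may become a split site, with
  probability maximal below diameter ``d1`` and zero above ``d2``; the
  segment's subtree detaches as a new fragment (thin processes such as spine
  necks are the most likely split sites);
* **merge** — close cross-neuron segment pairs may trigger a merge event;
  neurons are unified by connected components of merge events, so each
  ground-truth neuron is wholly contained in one reconstructed neuron.

Split and merge relabel cells without touching synapse centroids, and
deletions remove whole synapses, so centroid matching between ground truth
and perturbed network stays exact; inserted synapses get a jittered centroid
at the contact midpoint.  Per-neuron perturbation magnitudes (deleted
fraction, foreign-synapse fraction, split entropy) are computed from the
count table, and a crop-and-relabel preprocessing step reproduces what a
reconstruction restricted to an annotated box would look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import clip_segment_to_box, linear_kernel
from .count_table import CountTable
from .graph_model import (
    RECONSTRUCTION,
    NetworkMorphology,
    Segment,
    SynapseRecord,
    SynapseTable,
)
from .synth_network import candidate_segment_pairs

__all__ = [
    "Kernel",
    "PerturbConfig",
    "PerturbationScore",
    "delete_synapses",
    "insert_synapses",
    "split_neurons",
    "merge_neurons",
    "apply_perturbation",
    "perturbation_scores",
    "crop_relabel",
    "DELETED_FRACTION",
    "FOREIGN_FRACTION",
    "SPLIT_ENTROPY",
]

DELETED_FRACTION = "deleted_fraction"
FOREIGN_FRACTION = "foreign_fraction"
SPLIT_ENTROPY = "split_entropy"

MODELS = ("delete", "insert", "split", "merge")


@dataclass(frozen=True)
class Kernel:
    """Linear probability kernel of the geometric error models.

    For insert/merge the argument is the surface-to-surface distance between
    two segments (nm); for split it is the process diameter (nm)."""

    p_max: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        if not 0.0 < self.d1 < self.d2:
            raise ValueError("need 0 < d1 < d2")

    def __call__(self, x) -> np.ndarray:
        return linear_kernel(x, self.p_max, self.d1, self.d2)


@dataclass(frozen=True)
class PerturbConfig:
    """One error model application: exactly one of the four models, with a
    deletion fraction or a geometric kernel as appropriate."""

    model: str
    fraction: float | None = None
    kernel: Kernel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.model == "delete":
            if self.fraction is None or not 0.0 <= self.fraction <= 1.0:
                raise ValueError("delete model requires fraction in [0, 1]")
        else:
            if self.kernel is None:
                raise ValueError(f"{self.model} model requires a kernel")


@dataclass(frozen=True)
class PerturbationScore:
    neuron: str
    kind: str
    value: float


def delete_synapses(graph: SynapseTable, fraction: float, seed: int = 0) -> SynapseTable:
    """Remove exactly ``round(fraction * N)`` synapses, chosen uniformly
    without replacement (half-up rounding)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(graph.records)
    n_delete = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = sorted(range(n), key=lambda i: graph.records[i].synapse_id)
    doomed = set(rng.choice(np.asarray(order), size=n_delete, replace=False).tolist()) if n_delete else set()
    kept = [r for i, r in enumerate(graph.records) if i not in doomed]
    return SynapseTable(kept, role=RECONSTRUCTION)


def insert_synapses(
    morph: NetworkMorphology, kernel: Kernel, seed: int = 0
) -> NetworkMorphology:
    """Add spurious synapses on close cross-neuron segment pairs.

    Inserted synapses are flagged by the ``ins:`` id prefix; their centroid
    is the contact midpoint jittered by at most 10 nm so it never collides
    exactly with a real synapse.  When the pair mixes an axonal and a
    dendritic segment the axon takes the presynaptic side; otherwise the
    orientation is drawn at random.
    """
    rng = np.random.default_rng(seed)
    procs = sorted(
        (s for s in morph.segments if s.kind in ("axon", "dendrite")),
        key=lambda s: s.segment_id,
    )
    pairs, surface, contacts = candidate_segment_pairs(morph, kernel.d2, cross_kind_only=False)
    new_syn: list[SynapseRecord] = []
    new_anchors: dict[str, tuple[str, str]] = {}
    if pairs:
        p = kernel(surface)
        accepted = np.nonzero(rng.random(len(pairs)) < p)[0]
        for k, idx in enumerate(accepted):
            a, b = pairs[idx]
            sa, sb = procs[a], procs[b]
            if sa.kind == sb.kind and rng.random() < 0.5:
                sa, sb = sb, sa
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
            jitter = (direction / norm) * rng.uniform(0.0, 10.0) if norm > 0 else 0.0
            syn_id = f"ins:{k:06d}"
            new_syn.append(
                SynapseRecord(
                    synapse_id=syn_id,
                    pre_neuron=sa.neuron,
                    post_neuron=sb.neuron,
                    centroid=tuple(contacts[idx] + jitter),
                )
            )
            new_anchors[syn_id] = (sa.segment_id, sb.segment_id)
    return NetworkMorphology(
        list(morph.segments),
        list(morph.synapses) + new_syn,
        {**morph.anchors, **new_anchors},
    )


def split_neurons(
    morph: NetworkMorphology, kernel: Kernel, seed: int = 0
) -> NetworkMorphology:
    """Split neurons at thin process segments.

    Each selected segment detaches together with all its descendants as a
    new fragment (fresh id ``<neuron>#s<k>``); the parent side keeps the
    original id.  Multiple splits compose: a split inside an already-detached
    subtree yields a fragment of a fragment.  Synapses anchored on moved
    segments follow their segment's fragment.
    """
    rng = np.random.default_rng(seed)
    procs = sorted(
        (s for s in morph.segments if s.kind in ("axon", "dendrite")),
        key=lambda s: s.segment_id,
    )
    diam = np.array([s.diameter for s in procs])
    selected_ids = {
        procs[i].segment_id
        for i in np.nonzero(rng.random(len(procs)) < kernel(diam))[0]
    }

    by_id = morph.segments_by_id()
    order = _topological_order(morph.segments)
    frag: dict[str, str] = {}
    counters: dict[str, int] = {}
    new_segments: list[Segment] = []
    for seg in order:
        if seg.parent is None:
            frag[seg.segment_id] = seg.neuron
            new_segments.append(seg)
            continue
        if seg.segment_id in selected_ids:
            k = counters.get(seg.neuron, 0)
            counters[seg.neuron] = k + 1
            label = f"{seg.neuron}#s{k}"
            frag[seg.segment_id] = label
            new_segments.append(replace(seg, neuron=label, parent=None))
        else:
            label = frag[seg.parent]
            frag[seg.segment_id] = label
            new_segments.append(replace(seg, neuron=label))

    new_synapses = [
        replace(
            r,
            pre_neuron=frag[morph.anchors[r.synapse_id][0]],
            post_neuron=frag[morph.anchors[r.synapse_id][1]],
        )
        for r in morph.synapses
    ]
    return NetworkMorphology(new_segments, new_synapses, dict(morph.anchors))


def merge_neurons(
    morph: NetworkMorphology, kernel: Kernel, seed: int = 0
) -> NetworkMorphology:
    """Merge whole neurons wherever a merge event fires between close
    cross-neuron segments; events compose transitively (union-find), and all
    neurons of a merge component share the component's smallest id."""
    rng = np.random.default_rng(seed)
    procs = sorted(
        (s for s in morph.segments if s.kind in ("axon", "dendrite")),
        key=lambda s: s.segment_id,
    )
    pairs, surface, _ = candidate_segment_pairs(morph, kernel.d2, cross_kind_only=False)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    if pairs:
        p = kernel(surface)
        for idx in np.nonzero(rng.random(len(pairs)) < p)[0]:
            a, b = pairs[idx]
            union(procs[a].neuron, procs[b].neuron)
    mapping = {n: find(n) for n in morph.neuron_ids()}
    return morph.relabel_neurons(mapping)


def apply_perturbation(morph: NetworkMorphology, config: PerturbConfig) -> NetworkMorphology:
    """Dispatch one error model, returning the perturbed morphology."""
    if config.model == "delete":
        from .synth_network import derive_graph

        kept = delete_synapses(derive_graph(morph), config.fraction, seed=config.seed)
        kept_ids = {r.synapse_id for r in kept.records}
        return NetworkMorphology(
            list(morph.segments),
            [r for r in morph.synapses if r.synapse_id in kept_ids],
            {k: v for k, v in morph.anchors.items() if k in kept_ids},
        )
    if config.model == "insert":
        return insert_synapses(morph, config.kernel, seed=config.seed)
    if config.model == "split":
        return split_neurons(morph, config.kernel, seed=config.seed)
    return merge_neurons(morph, config.kernel, seed=config.seed)


def _topological_order(segments):
    by_parent: dict[str | None, list] = {}
    for s in segments:
        by_parent.setdefault(s.parent, []).append(s)
    for children in by_parent.values():
        children.sort(key=lambda s: s.segment_id)
    out = []
    stack = list(reversed(by_parent.get(None, [])))
    while stack:
        seg = stack.pop()
        out.append(seg)
        stack.extend(reversed(by_parent.get(seg.segment_id, [])))
    return out


def perturbation_scores(table: CountTable, kind: str) -> list[PerturbationScore]:
    """Per-neuron perturbation magnitude, from the count table.

    * ``deleted_fraction``: share of the neuron's terminals in the deletion
      column;
    * ``foreign_fraction``: for the reconstructed neuron hosting most of the
      neuron's terminals, the share of that fragment's terminals that do not
      come from the neuron (``(n_B + n_C) / (n_A + n_B + n_C)`` when A was
      merged with B and C);
    * ``split_entropy``: Shannon entropy of the neuron's matched terminals
      across fragments, normalized by the log of the neuron's matched
      terminal count (0 for an unsplit neuron, bounded by 1).
    """
    if kind not in (DELETED_FRACTION, FOREIGN_FRACTION, SPLIT_ENTROPY):
        raise ValueError(f"unknown perturbation score kind {kind!r}")
    scores: list[PerturbationScore] = []
    counts = table.counts
    for i, neuron in enumerate(table.row_labels, start=1):
        row = counts[i, :]
        row_total = int(row.sum())
        matched = row[1:]
        matched_total = int(matched.sum())
        if kind == DELETED_FRACTION:
            value = row[0] / row_total if row_total else 0.0
        elif kind == FOREIGN_FRACTION:
            if matched_total == 0:
                value = 0.0
            else:
                j = int(np.argmax(matched)) + 1
                col_total = int(counts[:, j].sum())
                value = (col_total - int(counts[i, j])) / col_total
        else:
            if matched_total <= 1:
                value = 0.0
            else:
                q = matched[matched > 0] / matched_total
                h = float(-(q * np.log(q)).sum())
                value = h / np.log(matched_total)
        scores.append(PerturbationScore(neuron, kind, float(value)))
    return scores


def crop_relabel(
    morph: NetworkMorphology,
    lo: tuple[float, float, float],
    hi: tuple[float, float, float],
) -> NetworkMorphology:
    """Crop a morphology to an axis-aligned box and relabel fragments by
    connected components.

    Segments intersecting the box are kept (clipped at the boundary); each
    neuron's survivors are relabeled one fragment per connected component of
    the parent-link graph restricted to the survivors, mirroring what a
    ground-truth annotation confined to the box would contain.  Synapses
    whose centroid leaves the box, or whose anchor segments do not survive,
    are dropped.
    """
    lo_arr = np.asarray(lo, dtype=float)
    hi_arr = np.asarray(hi, dtype=float)
    if (lo_arr > hi_arr).any():
        raise ValueError("box lower corner must not exceed upper corner")

    survivors: dict[str, Segment] = {}
    clipped: dict[str, tuple[tuple, tuple]] = {}
    for seg in morph.segments:
        res = clip_segment_to_box(np.array(seg.start), np.array(seg.end), lo_arr, hi_arr)
        if res is None:
            continue
        survivors[seg.segment_id] = seg
        clipped[seg.segment_id] = (tuple(res[0]), tuple(res[1]))

    # connected components over surviving parent links
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            lo_, hi_ = sorted((ra, rb))
            parent[hi_] = lo_

    for seg in survivors.values():
        if seg.parent is not None and seg.parent in survivors:
            union(seg.segment_id, seg.parent)

    frag_label: dict[str, str] = {}
    counters: dict[str, int] = {}
    for seg_id in sorted(survivors):
        root = find(seg_id)
        if root not in frag_label:
            neuron = survivors[root].neuron
            k = counters.get(neuron, 0)
            counters[neuron] = k + 1
            frag_label[root] = f"{neuron}#{k}"

    new_segments = []
    for seg_id in sorted(survivors):
        seg = survivors[seg_id]
        start, end = clipped[seg_id]
        keep_parent = seg.parent if seg.parent in survivors else None
        new_segments.append(
            replace(
                seg,
                neuron=frag_label[find(seg_id)],
                parent=keep_parent,
                start=start,
                end=end,
            )
        )

    new_synapses = []
    new_anchors = {}
    for r in morph.synapses:
        xyz = np.asarray(r.centroid)
        if (xyz < lo_arr).any() or (xyz > hi_arr).any():
            continue
        pre_seg, post_seg = morph.anchors[r.synapse_id]
        if pre_seg not in survivors or post_seg not in survivors:
            continue
        new_synapses.append(
            replace(
                r,
                pre_neuron=frag_label[find(pre_seg)],
                post_neuron=frag_label[find(post_seg)],
            )
        )
        new_anchors[r.synapse_id] = (pre_seg, post_seg)
    return NetworkMorphology(new_segments, new_synapses, new_anchors)
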