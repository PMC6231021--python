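"""Synthetic cortical networks: probabilistically grown neurons plus
proximity-placed synapses.

Each neuron is grown as a soma with one axonal tree and several dendritic
trees made of short cylindrical segments; growth is a random walk with
per-segment turning noise and branching, and diameters taper from the soma
outward.  Synapses are then placed by Peter's rule: every axon-dendrite
segment pair from different neurons forms a synapse with a probability that
is maximal below an inner distance ``d1``, zero beyond an outer distance
``d2``, and linearly decreasing in between; a minimum-spacing rejection step
prevents synapse clustering.

The goal is statistical plausibility as a test substrate for the error
models, not morphometric realism: all cell types share the growth model, and
only the default small network (tens of neurons, on the order of a hundred
terminals each) is exercised by the test suite.  All coordinates are
nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import linear_kernel, segment_closest_points
from .graph_model import GROUND_TRUTH, NetworkMorphology, Segment, SynapseRecord, SynapseTable

__all__ = [
    "SynapseRule",
    "GrowthConfig",
    "default_config",
    "paper_scale_config",
    "generate_morphology",
    "place_synapses",
    "derive_graph",
    "generate_network",
]


@dataclass(frozen=True)
class SynapseRule:
    """Peter's-rule placement parameters (distances in nm).

    ``p_max`` applies below ``d1`` (surface-to-surface distance), the
    probability falls linearly to 0 at ``d2``; ``min_spacing`` suppresses a
    candidate closer than this to an already-placed synapse.
    """

    p_max: float = 0.6
    d1: float = 500.0
    d2: float = 2000.0
    min_spacing: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        if not 0.0 < self.d1 < self.d2:
            raise ValueError("need 0 < d1 < d2")


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the growth model (distances nm, angles radians)."""

    neuron_counts: dict[str, int] = field(default_factory=lambda: {"pyr": 50})
    volume_um: tuple[float, float, float] = (25.0, 25.0, 25.0)
    segment_length: float = 2000.0
    branch_prob: float = 0.08
    turn_angle_sd: float = 0.35
    n_dendrites: int = 4
    axon_depth: int = 40
    dendrite_depth: int = 15
    max_segments_per_neuron: int = 180
    soma_diameter: float = 8000.0
    axon_diameter: float = 600.0
    dendrite_diameter: float = 1600.0
    taper: float = 0.96
    min_diameter: float = 200.0
    synapse_rule: SynapseRule = field(default_factory=SynapseRule)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.neuron_counts.values()):
            raise ValueError("neuron counts must be >= 0")
        total = sum(self.neuron_counts.values())
        if total > 0 and any(v <= 0 for v in self.volume_um):
            raise ValueError("non-empty network requires a positive volume")


def default_config(n_neurons: int = 50, seed: int = 0, **overrides) -> GrowthConfig:
    """The small test-scale network: ``n_neurons`` of one generic type."""
    return GrowthConfig(neuron_counts={"pyr": n_neurons}, seed=seed, **overrides)


def paper_scale_config(seed: int = 0) -> GrowthConfig:
    """A barrel-cortex-like composition: 872 neurons of five cell types in a
    79 x 79 x 1300 um volume.  Provided for completeness; far larger than
    anything the test suite runs."""
    return GrowthConfig(
        neuron_counts={
            "l23pyr": 312,
            "l4stellate": 62,
            "l4starpyr": 62,
            "l5apyr": 218,
            "l5bpyr": 218,
        },
        volume_um=(79.0, 79.0, 1300.0),
        seed=seed,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _grow_tree(
    segments: list[Segment],
    rng: np.random.Generator,
    config: GrowthConfig,
    neuron: str,
    parent_id: str,
    origin: np.ndarray,
    direction: np.ndarray,
    diameter: float,
    kind: str,
    max_depth: int,
    counter: list[int],
) -> None:
    # FIFO queue of active growth tips -> deterministic order for a fixed rng
    queue: list[tuple[str, np.ndarray, np.ndarray, float, int]] = [
        (parent_id, origin, direction, diameter, 0)
    ]
    while queue:
        parent, pos, direc, diam, depth = queue.pop(0)
        if depth >= max_depth or counter[0] >= config.max_segments_per_neuron:
            continue
        direc = _unit(direc + config.turn_angle_sd * rng.standard_normal(3))
        end = pos + direc * config.segment_length
        seg_id = f"{neuron}:{counter[0]}"
        counter[0] += 1
        segments.append(
            Segment(
                segment_id=seg_id,
                neuron=neuron,
                parent=parent,
                start=tuple(pos),
                end=tuple(end),
                diameter=diam,
                kind=kind,
            )
        )
        child_diam = max(diam * config.taper, config.min_diameter)
        queue.append((seg_id, end, direc, child_diam, depth + 1))
        if rng.random() < config.branch_prob:
            branch_dir = _unit(direc + 0.8 * rng.standard_normal(3))
            queue.append((seg_id, end, branch_dir, child_diam, depth + 1))


def generate_morphology(config: GrowthConfig) -> NetworkMorphology:
    """Grow the segment trees of every neuron (no synapses yet).

    Somata are placed uniformly in the volume; each neuron gets one axonal
    tree and ``n_dendrites`` dendritic trees.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    volume_nm = np.array(config.volume_um, dtype=float) * 1000.0
    segments: list[Segment] = []
    for cell_type in sorted(config.neuron_counts):
        count = config.neuron_counts[cell_type]
        for k in range(count):
            neuron = f"{cell_type}_{k:04d}"
            counter = [0]
            soma_pos = rng.uniform(0.0, 1.0, size=3) * volume_nm
            soma_id = f"{neuron}:soma"
            segments.append(
                Segment(
                    segment_id=soma_id,
                    neuron=neuron,
                    parent=None,
                    start=tuple(soma_pos),
                    end=tuple(soma_pos + np.array([0.0, 0.0, 500.0])),
                    diameter=config.soma_diameter,
                    kind="soma",
                )
            )
            axon_dir = _unit(rng.standard_normal(3))
            _grow_tree(
                segments, rng, config, neuron, soma_id, soma_pos, axon_dir,
                config.axon_diameter, "axon", config.axon_depth, counter,
            )
            for _ in range(config.n_dendrites):
                dend_dir = _unit(rng.standard_normal(3))
                _grow_tree(
                    segments, rng, config, neuron, soma_id, soma_pos, dend_dir,
                    config.dendrite_diameter, "dendrite", config.dendrite_depth, counter,
                )
    return NetworkMorphology(segments)


def candidate_segment_pairs(
    morph: NetworkMorphology,
    d2: float,
    cross_kind_only: bool = True,
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Cross-neuron process-segment pairs within surface distance ``d2``.

    Returns (pairs, surface_distances, contact_midpoints); ``pairs`` indexes
    into the morphology's process segments in a deterministic order.  With
    ``cross_kind_only`` the first element of each pair is an axonal segment
    and the second dendritic; otherwise all cross-neuron pairs qualify and
    the pair is ordered (axon first when kinds differ, else by segment id).
    """
    procs = [s for s in morph.segments if s.kind in ("axon", "dendrite")]
    procs.sort(key=lambda s: s.segment_id)
    if not procs:
        return [], np.empty(0), np.empty((0, 3))
    starts = np.array([s.start for s in procs])
    ends = np.array([s.end for s in procs])
    mids = (starts + ends) / 2.0
    radii = np.array([s.diameter for s in procs]) / 2.0
    lengths = np.linalg.norm(ends - starts, axis=1)
    reach = d2 + float(lengths.max()) + 2.0 * float(radii.max())
    tree = cKDTree(mids)
    raw = sorted(tree.query_pairs(r=reach))
    keep: list[tuple[int, int]] = []
    for a, b in raw:
        sa, sb = procs[a], procs[b]
        if sa.neuron == sb.neuron:
            continue
        if cross_kind_only:
            if sa.kind == "axon" and sb.kind == "dendrite":
                keep.append((a, b))
            elif sa.kind == "dendrite" and sb.kind == "axon":
                keep.append((b, a))
        else:
            if sa.kind == "dendrite" and sb.kind == "axon":
                keep.append((b, a))
            else:
                keep.append((a, b))
    if not keep:
        return [], np.empty(0), np.empty((0, 3))
    ia = np.array([p[0] for p in keep])
    ib = np.array([p[1] for p in keep])
    c1, c2, dist = segment_closest_points(starts[ia], ends[ia], starts[ib], ends[ib])
    surface = np.maximum(dist - radii[ia] - radii[ib], 0.0)
    within = surface <= d2
    pairs = [keep[i] for i in np.nonzero(within)[0]]
    return pairs, surface[within], ((c1 + c2) / 2.0)[within]


def _process_segments(morph: NetworkMorphology) -> list[Segment]:
    return sorted(
        (s for s in morph.segments if s.kind in ("axon", "dendrite")),
        key=lambda s: s.segment_id,
    )


def place_synapses(
    morph: NetworkMorphology, rule: SynapseRule, seed: int = 0
) -> NetworkMorphology:
    """Place synapses on a grown morphology by the distance rule.

    Presynaptic terminals sit on axonal segments, postsynaptic on dendritic
    segments; the centroid is the midpoint of the closest approach between
    the two segments.  Acceptance is Bernoulli per candidate pair; accepted
    candidates closer than ``min_spacing`` to an already-placed synapse are
    rejected greedily in candidate order.
    """
    rng = np.random.default_rng(seed)
    procs = _process_segments(morph)
    pairs, surface, contacts = candidate_segment_pairs(morph, rule.d2, cross_kind_only=True)
    synapses: list[SynapseRecord] = []
    anchors: dict[str, tuple[str, str]] = {}
    if pairs:
        p = linear_kernel(surface, rule.p_max, rule.d1, rule.d2)
        accepted = np.nonzero(rng.random(len(pairs)) < p)[0]
        kept_xyz = _SpacingFilter(rule.min_spacing)
        n_placed = 0
        for idx in accepted:
            xyz = contacts[idx]
            if not kept_xyz.admit(xyz):
                continue
            a, b = pairs[idx]
            syn_id = f"syn{n_placed:06d}"
            n_placed += 1
            synapses.append(
                SynapseRecord(
                    synapse_id=syn_id,
                    pre_neuron=procs[a].neuron,
                    post_neuron=procs[b].neuron,
                    centroid=tuple(xyz),
                )
            )
            anchors[syn_id] = (procs[a].segment_id, procs[b].segment_id)
    return NetworkMorphology(list(morph.segments), synapses, anchors)


class _SpacingFilter:
    """Greedy minimum-spacing admission via a uniform spatial hash."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cell = max(spacing, 1.0)
        self.grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def admit(self, xyz: np.ndarray) -> bool:
        if self.spacing <= 0:
            return True
        key = tuple(int(np.floor(v / self.cell)) for v in xyz)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for other in self.grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.linalg.norm(other - xyz) < self.spacing:
                            return False
        self.grid.setdefault(key, []).append(np.asarray(xyz, dtype=float))
        return True


def derive_graph(morph: NetworkMorphology) -> SynapseTable:
    """Project a morphology's synapses into a ground-truth synapse table."""
    records = [
        SynapseRecord(r.synapse_id, r.pre_neuron, r.post_neuron, r.centroid)
        for r in morph.synapses
    ]
    return SynapseTable(records, role=GROUND_TRUTH)


def generate_network(config: GrowthConfig) -> NetworkMorphology:
    """Morphology plus synapses in one call; synapse placement uses a seed
    derived from ``config.seed`` so the two stages stay independent."""
    morph = generate_morphology(config)
    return place_synapses(morph, config.synapse_rule, seed=config.seed + 1)
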