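"""Domain types for point-synapse connectivity tables and neuron morphology.

The connectivity abstraction is deliberately voxel-free: a brain graph is a
set of neurons (opaque string ids) connected by directed point synapses, each
carrying a single 3-D centroid in nanometres.  Ground truth and reconstruction
are both expressed in this form; nothing in the data model assumes any
correspondence between the two id spaces.

Morphology is the substrate for the geometric error models: each neuron is a
tree of short cylindrical segments (SWC-like, but with an explicit neuron
column and a process-kind tag), and each placed synapse is anchored on one
presynaptic and one postsynaptic segment.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ConsistencyError",
    "SynapseRecord",
    "SynapseTable",
    "Terminal",
    "Segment",
    "NetworkMorphology",
    "read_synapse_table",
    "write_synapse_table",
    "terminals_of",
    "read_morphology",
    "write_morphology",
    "to_graphml",
]

GROUND_TRUTH = "ground_truth"
RECONSTRUCTION = "reconstruction"

SYNAPSE_COLUMNS = ["synapse_id", "pre_neuron", "post_neuron", "x", "y", "z"]
SEGMENT_COLUMNS = [
    "segment_id", "neuron", "parent", "kind",
    "x0", "y0", "z0", "x1", "y1", "z1", "diameter",
]


class FormatError(ValueError):
    """A file does not conform to the expected column layout."""


class ValidationError(ValueError):
    """A table or morphology violates a structural invariant."""


class ConsistencyError(ValueError):
    """Two objects that must refer to each other do not."""


@dataclass(frozen=True)
class SynapseRecord:
    """One directed synapse: ``pre_neuron -> post_neuron`` at ``centroid`` (nm).

    ``pre_neuron`` and ``post_neuron`` may be equal (autapse).  Ids are opaque
    strings; no numeric or cross-table meaning is ever attached to them.
    """

    synapse_id: str
    pre_neuron: str
    post_neuron: str
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.centroid)
        if len(c) != 3 or not all(math.isfinite(v) for v in c):
            raise ValidationError(
                f"synapse {self.synapse_id!r}: centroid must be 3 finite numbers, got {self.centroid!r}"
            )
        object.__setattr__(self, "centroid", c)


@dataclass(frozen=True)
class Terminal:
    """One half of a synapse: the pre- or postsynaptic terminal on a neuron."""

    synapse_id: str
    polarity: str  # "pre" | "post"
    neuron: str


@dataclass
class SynapseTable:
    """An ordered collection of synapses with a role flag.

    ``role`` is either ``"ground_truth"`` or ``"reconstruction"``; it only
    labels intent (which side of the comparison the table sits on).
    """

    records: list[SynapseRecord]
    role: str = GROUND_TRUTH

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen: set[str] = set()
        for r in self.records:
            if r.synapse_id in seen:
                raise ValidationError(f"duplicate synapse_id {r.synapse_id!r}")
            seen.add(r.synapse_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, SynapseRecord]:
        return {r.synapse_id: r for r in self.records}

    def centroids(self) -> np.ndarray:
        """All centroids as an (n, 3) float array, in record order."""
        if not self.records:
            return np.empty((0, 3), dtype=float)
        return np.array([r.centroid for r in self.records], dtype=float)

    def neuron_ids(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.add(r.pre_neuron)
            out.add(r.post_neuron)
        return out


def terminals_of(table: SynapseTable) -> list[Terminal]:
    """Expand a synapse table into its 2·N terminals (pre and post per synapse)."""
    out: list[Terminal] = []
    for r in table.records:
        out.append(Terminal(r.synapse_id, "pre", r.pre_neuron))
        out.append(Terminal(r.synapse_id, "post", r.post_neuron))
    return out


def read_synapse_table(path, role: str = GROUND_TRUTH) -> SynapseTable:
    """Read a synapse table from a headered CSV file.

    Required columns: synapse_id, pre_neuron, post_neuron, x, y, z.
    Coordinates are nanometres.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[SynapseRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        coords = []
        for axis in ("x", "y", "z"):
            raw = getattr(row, axis)
            try:
                coords.append(float(raw))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {idx + 2}: non-numeric {axis} coordinate {raw!r}"
                ) from exc
        records.append(
            SynapseRecord(
                synapse_id=str(row.synapse_id),
                pre_neuron=str(row.pre_neuron),
                post_neuron=str(row.post_neuron),
                centroid=(coords[0], coords[1], coords[2]),
            )
        )
    return SynapseTable(records, role=role)


def write_synapse_table(table: SynapseTable, path) -> None:
    """Write a synapse table as CSV; ``read(write(t))`` reproduces ``t``.

    Output is byte-stable: coordinates are printed with repr-roundtrip
    precision and rows keep their order.
    """
    df = pd.DataFrame(
        {
            "synapse_id": [r.synapse_id for r in table.records],
            "pre_neuron": [r.pre_neuron for r in table.records],
            "post_neuron": [r.post_neuron for r in table.records],
            "x": [repr(r.centroid[0]) for r in table.records],
            "y": [repr(r.centroid[1]) for r in table.records],
            "z": [repr(r.centroid[2]) for r in table.records],
        },
        columns=SYNAPSE_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class Segment:
    """A short cylindrical piece of a neural process.

    ``parent`` is the id of the upstream segment (None for the root/soma), so
    the segments of one neuron form a rooted tree.  ``kind`` tags the process
    type: "soma", "axon" or "dendrite" — axonal segments host presynaptic
    terminals, dendritic segments postsynaptic ones.
    """

    segment_id: str
    neuron: str
    parent: str | None
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    diameter: float
    kind: str = "dendrite"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValidationError(f"segment {self.segment_id!r}: diameter must be > 0")
        object.__setattr__(self, "start", tuple(float(v) for v in self.start))
        object.__setattr__(self, "end", tuple(float(v) for v in self.end))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.start) + np.asarray(self.end)) / 2.0


@dataclass
class NetworkMorphology:
    """Neurons as forests of cylindrical segments, plus anchored synapses.

    ``anchors`` maps synapse_id -> (pre_segment_id, post_segment_id); the
    anchoring segments must belong to the synapse's pre/post neurons.
    """

    segments: list[Segment]
    synapses: list[SynapseRecord] = field(default_factory=list)
    anchors: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = list(self.segments)
        self.synapses = list(self.synapses)
        by_id: dict[str, Segment] = {}
        for s in self.segments:
            if s.segment_id in by_id:
                raise ValidationError(f"duplicate segment_id {s.segment_id!r}")
            by_id[s.segment_id] = s
        for s in self.segments:
            if s.parent is not None:
                p = by_id.get(s.parent)
                if p is None:
                    raise ValidationError(
                        f"segment {s.segment_id!r}: parent {s.parent!r} not found"
                    )
                if p.neuron != s.neuron:
                    raise ValidationError(
                        f"segment {s.segment_id!r}: parent belongs to another neuron"
                    )
        self._assert_forest(by_id)
        for syn in self.synapses:
            anchor = self.anchors.get(syn.synapse_id)
            if anchor is None:
                raise ConsistencyError(f"synapse {syn.synapse_id!r} has no anchor")
            pre_seg, post_seg = anchor
            for seg_id, neuron, side in (
                (pre_seg, syn.pre_neuron, "pre"),
                (post_seg, syn.post_neuron, "post"),
            ):
                seg = by_id.get(seg_id)
                if seg is None:
                    raise ConsistencyError(
                        f"synapse {syn.synapse_id!r}: {side} anchor {seg_id!r} not found"
                    )
                if seg.neuron != neuron:
                    raise ConsistencyError(
                        f"synapse {syn.synapse_id!r}: {side} anchor on neuron "
                        f"{seg.neuron!r}, expected {neuron!r}"
                    )

    @staticmethod
    def _assert_forest(by_id: dict[str, Segment]) -> None:
        # parent links must be acyclic; walk each chain with memoised depth
        depth: dict[str, int] = {}

        def resolve(seg_id: str, trail: set[str]) -> int:
            if seg_id in depth:
                return depth[seg_id]
            if seg_id in trail:
                raise ValidationError(f"cycle in parent links at {seg_id!r}")
            trail.add(seg_id)
            parent = by_id[seg_id].parent
            d = 0 if parent is None else resolve(parent, trail) + 1
            depth[seg_id] = d
            return d

        for seg_id in by_id:
            resolve(seg_id, set())

    def segments_by_id(self) -> dict[str, Segment]:
        return {s.segment_id: s for s in self.segments}

    def neuron_ids(self) -> set[str]:
        return {s.neuron for s in self.segments}

    def relabel_neurons(self, mapping: dict[str, str]) -> "NetworkMorphology":
        """Return a copy with neuron ids mapped through ``mapping`` (identity
        for ids not in the mapping).  Segment tree structure is preserved."""
        segs = [replace(s, neuron=mapping.get(s.neuron, s.neuron)) for s in self.segments]
        syns = [
            replace(
                r,
                pre_neuron=mapping.get(r.pre_neuron, r.pre_neuron),
                post_neuron=mapping.get(r.post_neuron, r.post_neuron),
            )
            for r in self.synapses
        ]
        return NetworkMorphology(segs, syns, dict(self.anchors))


def write_morphology(morph: NetworkMorphology, segments_path, synapses_path) -> None:
    """Write a morphology as two CSVs: one segment per line, and the synapse
    table extended with its pre/post anchor segment ids."""
    seg_df = pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in morph.segments],
            "neuron": [s.neuron for s in morph.segments],
            "parent": [s.parent if s.parent is not None else "" for s in morph.segments],
            "kind": [s.kind for s in morph.segments],
            "x0": [repr(s.start[0]) for s in morph.segments],
            "y0": [repr(s.start[1]) for s in morph.segments],
            "z0": [repr(s.start[2]) for s in morph.segments],
            "x1": [repr(s.end[0]) for s in morph.segments],
            "y1": [repr(s.end[1]) for s in morph.segments],
            "z1": [repr(s.end[2]) for s in morph.segments],
            "diameter": [repr(s.diameter) for s in morph.segments],
        },
        columns=SEGMENT_COLUMNS,
    )
    seg_df.to_csv(segments_path, index=False, lineterminator="\n")
    syn_df = pd.DataFrame(
        {
            "synapse_id": [r.synapse_id for r in morph.synapses],
            "pre_neuron": [r.pre_neuron for r in morph.synapses],
            "post_neuron": [r.post_neuron for r in morph.synapses],
            "x": [repr(r.centroid[0]) for r in morph.synapses],
            "y": [repr(r.centroid[1]) for r in morph.synapses],
            "z": [repr(r.centroid[2]) for r in morph.synapses],
            "pre_segment": [morph.anchors[r.synapse_id][0] for r in morph.synapses],
            "post_segment": [morph.anchors[r.synapse_id][1] for r in morph.synapses],
        },
        columns=SYNAPSE_COLUMNS + ["pre_segment", "post_segment"],
    )
    syn_df.to_csv(synapses_path, index=False, lineterminator="\n")


def read_morphology(segments_path, synapses_path) -> NetworkMorphology:
    seg_df = pd.read_csv(segments_path, dtype=str, keep_default_na=False)
    missing = [c for c in SEGMENT_COLUMNS if c not in seg_df.columns]
    if missing:
        raise FormatError(f"{segments_path}: missing column(s) {', '.join(missing)}")
    segments = [
        Segment(
            segment_id=row.segment_id,
            neuron=row.neuron,
            parent=row.parent or None,
            kind=row.kind,
            start=(float(row.x0), float(row.y0), float(row.z0)),
            end=(float(row.x1), float(row.y1), float(row.z1)),
            diameter=float(row.diameter),
        )
        for row in seg_df.itertuples(index=False)
    ]
    syn_df = pd.read_csv(synapses_path, dtype=str, keep_default_na=False)
    needed = SYNAPSE_COLUMNS + ["pre_segment", "post_segment"]
    missing = [c for c in needed if c not in syn_df.columns]
    if missing:
        raise FormatError(f"{synapses_path}: missing column(s) {', '.join(missing)}")
    synapses: list[SynapseRecord] = []
    anchors: dict[str, tuple[str, str]] = {}
    for row in syn_df.itertuples(index=False):
        synapses.append(
            SynapseRecord(
                synapse_id=row.synapse_id,
                pre_neuron=row.pre_neuron,
                post_neuron=row.post_neuron,
                centroid=(float(row.x), float(row.y), float(row.z)),
            )
        )
        anchors[row.synapse_id] = (row.pre_segment, row.post_segment)
    return NetworkMorphology(segments, synapses, anchors)


def to_graphml(table: SynapseTable, path) -> None:
    """Export the implied brain graph (neurons = nodes, synapses = directed
    edges with centroid attributes) to GraphML."""
    g = nx.MultiDiGraph()
    for nid in sorted(table.neuron_ids()):
        g.add_node(nid)
    for r in table.records:
        g.add_edge(
            r.pre_neuron,
            r.post_neuron,
            key=r.synapse_id,
            x=r.centroid[0],
            y=r.centroid[1],
            z=r.centroid[2],
        )
    nx.write_graphml(g, path)


def table_digest(path) -> str:
    """SHA-256 of a written file, for byte-stability checks."""
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
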