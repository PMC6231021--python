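"""The count table: the sufficient statistic for all connectivity metrics.

Rows are ground-truth neurons, columns are reconstructed fragments; entry
c_ij counts matched synaptic terminals shared by row i and column j.  Row 0
is reserved for insertions (reconstruction synapses with no ground-truth
partner) and column 0 for deletions (ground-truth synapses with no
reconstruction partner); c_00 is always 0.

For a matched synapse pair the ground-truth presynaptic terminal is counted
with the reconstruction presynaptic terminal (likewise post), so a synapse
whose direction is flipped in the reconstruction lands in cross cells and is
penalised with both false-positive and false-negative paths downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_model import ConsistencyError, SynapseTable, ValidationError
from .matching import Matching

__all__ = ["CountTable", "build_count_table"]

INS = "ins"
DEL = "del"


@dataclass
class CountTable:
    """Integer matrix of matched-terminal counts with reserved ins/del line.

    ``counts`` has shape (I+1, J+1); index 0 on each axis is the reserved
    insertion row / deletion column.  ``row_labels``/``col_labels`` name
    indices 1..I / 1..J and are sorted for determinism.
    """

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("count table must be 2-D")
        if self.counts.shape != (len(self.row_labels) + 1, len(self.col_labels) + 1):
            raise ValidationError("count table shape does not match labels")
        if (self.counts < 0).any():
            raise ValidationError("count table entries must be non-negative")
        if self.counts[0, 0] != 0:
            raise ValidationError("c_00 must be 0")

    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    @property
    def n_cols(self) -> int:
        return len(self.col_labels)

    def row_index(self, neuron: str) -> int:
        try:
            return self.row_labels.index(neuron) + 1
        except ValueError:
            raise KeyError(f"unknown ground-truth neuron {neuron!r}") from None

    def col_index(self, fragment: str) -> int:
        try:
            return self.col_labels.index(fragment) + 1
        except ValueError:
            raise KeyError(f"unknown reconstruction fragment {fragment!r}") from None

    @property
    def interior(self) -> np.ndarray:
        """Matched-terminal block c_ij for i,j >= 1."""
        return self.counts[1:, 1:]

    def matched_terminal_total(self) -> int:
        """Sum of the interior; equals 2N for N matched synapses."""
        return int(self.interior.sum())

    def row_sum(self, neuron: str) -> int:
        """All terminals of a ground-truth neuron (deletion column included)."""
        return int(self.counts[self.row_index(neuron), :].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[INS] + list(self.row_labels),
            columns=[DEL] + list(self.col_labels),
        )

    def to_csv(self, path) -> None:
        """Write with the reserved first row "ins" and first column "del"."""
        self.to_dataframe().to_csv(path, index_label="", lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path, index_col=0)
        if list(df.index[:1]) != [INS] or list(df.columns[:1]) != [DEL]:
            raise ValidationError(
                f"{path}: first row must be {INS!r} and first column {DEL!r}"
            )
        return cls(
            df.to_numpy(dtype=np.int64),
            [str(v) for v in df.index[1:]],
            [str(v) for v in df.columns[1:]],
        )


def build_count_table(
    gt: SynapseTable,
    recon: SynapseTable,
    matching: Matching,
    segmentation_only: bool = False,
) -> CountTable:
    """Tally matched terminals into a count table.

    Each matched synapse pair contributes its pre terminals to
    c[gt_pre, recon_pre] and its post terminals to c[gt_post, recon_post].
    Unmatched ground-truth synapses put both terminals in the deletion
    column; unmatched reconstruction synapses put both in the insertion row.
    With ``segmentation_only`` unmatched synapses contribute nothing, so the
    reserved row and column stay zero and missed-synapse errors in a sparse
    gold standard do not penalise the reconstruction.
    """
    gt_by_id = gt.by_id()
    recon_by_id = recon.by_id()
    for g_id, r_id in matching.pairs:
        if g_id not in gt_by_id:
            raise ConsistencyError(f"matching references unknown gt synapse {g_id!r}")
        if r_id not in recon_by_id:
            raise ConsistencyError(f"matching references unknown recon synapse {r_id!r}")
    for g_id in matching.unmatched_gt:
        if g_id not in gt_by_id:
            raise ConsistencyError(f"matching references unknown gt synapse {g_id!r}")
    for r_id in matching.unmatched_recon:
        if r_id not in recon_by_id:
            raise ConsistencyError(f"matching references unknown recon synapse {r_id!r}")

    row_neurons: set[str] = set()
    col_fragments: set[str] = set()
    for g_id, r_id in matching.pairs:
        g, r = gt_by_id[g_id], recon_by_id[r_id]
        row_neurons.update((g.pre_neuron, g.post_neuron))
        col_fragments.update((r.pre_neuron, r.post_neuron))
    if not segmentation_only:
        for g_id in matching.unmatched_gt:
            g = gt_by_id[g_id]
            row_neurons.update((g.pre_neuron, g.post_neuron))
        for r_id in matching.unmatched_recon:
            r = recon_by_id[r_id]
            col_fragments.update((r.pre_neuron, r.post_neuron))

    row_labels = sorted(row_neurons)
    col_labels = sorted(col_fragments)
    ri = {n: i + 1 for i, n in enumerate(row_labels)}
    ci = {n: j + 1 for j, n in enumerate(col_labels)}
    counts = np.zeros((len(row_labels) + 1, len(col_labels) + 1), dtype=np.int64)

    for g_id, r_id in matching.pairs:
        g, r = gt_by_id[g_id], recon_by_id[r_id]
        counts[ri[g.pre_neuron], ci[r.pre_neuron]] += 1
        counts[ri[g.post_neuron], ci[r.post_neuron]] += 1
    if not segmentation_only:
        for g_id in sorted(matching.unmatched_gt):
            g = gt_by_id[g_id]
            counts[ri[g.pre_neuron], 0] += 1
            counts[ri[g.post_neuron], 0] += 1
        for r_id in sorted(matching.unmatched_recon):
            r = recon_by_id[r_id]
            counts[0, ci[r.pre_neuron]] += 1
            counts[0, ci[r.post_neuron]] += 1

    return CountTable(counts, row_labels, col_labels)
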