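import numpy as np
import pytest

from nri import CountTable, SynapseRecord, SynapseTable


@pytest.fixture
def toy_tables():
    """The worked split+merge toy network.

    Ground truth: blue holds the presynaptic terminals of synapses A, B, C
    (all onto green), red the presynaptic terminal of D (onto orange).
    Reconstruction: fragment 2 = blue, fragment 1 = green's main body merged
    with orange, fragment 4 = green's split-off spine head (B's postsynaptic
    terminal), fragment 3 = red.
    """
    pts = {"A": (0.0, 0.0, 0.0), "B": (1000.0, 0.0, 0.0),
           "C": (2000.0, 0.0, 0.0), "D": (3000.0, 0.0, 0.0)}
    gt = SynapseTable(
        [
            SynapseRecord("A", "blue", "green", pts["A"]),
            SynapseRecord("B", "blue", "green", pts["B"]),
            SynapseRecord("C", "blue", "green", pts["C"]),
            SynapseRecord("D", "red", "orange", pts["D"]),
        ],
        role="ground_truth",
    )
    recon = SynapseTable(
        [
            SynapseRecord("a", "2", "1", pts["A"]),
            SynapseRecord("b", "2", "4", pts["B"]),
            SynapseRecord("c", "2", "1", pts["C"]),
            SynapseRecord("d", "3", "1", pts["D"]),
        ],
        role="reconstruction",
    )
    return gt, recon


def make_count_table(counts, rows=None, cols=None) -> CountTable:
    counts = np.asarray(counts, dtype=np.int64)
    rows = rows or [f"g{i}" for i in range(1, counts.shape[0])]
    cols = cols or [f"s{j}" for j in range(1, counts.shape[1])]
    return CountTable(counts, rows, cols)


def random_count_table(rng: np.random.Generator, max_dim=6, max_entry=5) -> CountTable:
    i = int(rng.integers(1, max_dim + 1))
    j = int(rng.integers(1, max_dim + 1))
    counts = rng.integers(0, max_entry + 1, size=(i + 1, j + 1))
    counts[0, 0] = 0
    return make_count_table(counts)


def random_synapse_table(rng: np.random.Generator, n, n_neurons=5, box=5000.0, prefix="g",
                         role="ground_truth") -> SynapseTable:
    records = []
    for k in range(n):
        pre, post = rng.integers(0, n_neurons, size=2)
        records.append(
            SynapseRecord(
                f"{prefix}{k:04d}", f"n{pre}", f"n{post}",
                tuple(rng.uniform(0.0, box, size=3)),
            )
        )
    return SynapseTable(records, role=role)
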