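import numpy as np
import pytest

from nri import (
    Kernel,
    NetworkMorphology,
    PerturbConfig,
    Segment,
    SynapseRecord,
    apply_perturbation,
    build_count_table,
    crop_relabel,
    delete_synapses,
    derive_graph,
    evaluate,
    global_nri,
    insert_synapses,
    match_synapses,
    merge_neurons,
    perturbation_scores,
    split_neurons,
)
from nri.perturb import DELETED_FRACTION, FOREIGN_FRACTION, SPLIT_ENTROPY
from nri.synth_network import default_config, generate_network
from conftest import make_count_table, random_synapse_table


@pytest.fixture(scope="module")
def network():
    return generate_network(default_config(n_neurons=15, seed=101))


def spine_morph():
    """A dendritic shaft with a thin spine neck carrying one synapse, plus
    two shaft synapses — the canonical split-error illustration."""
    segs = [
        Segment("soma", "g", None, (0, 0, 0), (0, 0, 500), 8000, kind="soma"),
        Segment("shaft1", "g", "soma", (0, 0, 500), (0, 0, 3000), 1500),
        Segment("shaft2", "g", "shaft1", (0, 0, 3000), (0, 0, 6000), 1400),
        Segment("spine", "g", "shaft2", (0, 0, 6000), (300, 0, 6200), 120),
        Segment("axon1", "b", None, (500, 500, 500), (500, 500, 7000), 400, kind="axon"),
    ]
    syns = [
        SynapseRecord("sA", "b", "g", (100.0, 0.0, 2000.0)),
        SynapseRecord("sB", "b", "g", (350.0, 0.0, 6200.0)),  # on the spine head
        SynapseRecord("sC", "b", "g", (100.0, 0.0, 4000.0)),
    ]
    anchors = {"sA": ("axon1", "shaft1"), "sB": ("axon1", "spine"), "sC": ("axon1", "shaft2")}
    return NetworkMorphology(segs, syns, anchors)


class TestDelete:
    def test_zero_fraction_is_identity(self):
        rng = np.random.default_rng(0)
        table = random_synapse_table(rng, 50)
        assert delete_synapses(table, 0.0, seed=1).records == table.records

    def test_full_fraction_empties_the_table(self):
        rng = np.random.default_rng(0)
        table = random_synapse_table(rng, 50)
        assert len(delete_synapses(table, 1.0, seed=1)) == 0

    def test_exact_count_removed(self):
        rng = np.random.default_rng(0)
        table = random_synapse_table(rng, 1000)
        assert len(delete_synapses(table, 0.2, seed=7)) == 800
        # half-up rounding
        small = random_synapse_table(rng, 5, prefix="q")
        assert len(delete_synapses(small, 0.5, seed=7)) == 2  # round(2.5) -> 3 removed

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        table = random_synapse_table(rng, 100)
        a = delete_synapses(table, 0.3, seed=5)
        b = delete_synapses(table, 0.3, seed=5)
        assert a.records == b.records


class TestInsert:
    def test_zero_pmax_is_identity(self, network):
        out = insert_synapses(network, Kernel(0.0, 500.0, 1500.0), seed=1)
        assert out.synapses == network.synapses

    def test_inserted_synapses_are_flagged_and_counted(self, network):
        kernel = Kernel(0.3, 500.0, 1500.0)
        out = insert_synapses(network, kernel, seed=2)
        inserted = [r for r in out.synapses if r.synapse_id.startswith("ins:")]
        assert len(out.synapses) == len(network.synapses) + len(inserted)
        assert len(inserted) > 0
        from nri.synth_network import candidate_segment_pairs
        from nri._geometry import linear_kernel

        _, surface, _ = candidate_segment_pairs(network, kernel.d2, cross_kind_only=False)
        p = linear_kernel(surface, kernel.p_max, kernel.d1, kernel.d2)
        counts = [
            sum(r.synapse_id.startswith("ins:") for r in insert_synapses(network, kernel, seed=s).synapses)
            for s in range(6)
        ]
        sigma = max(np.sqrt((p * (1 - p)).sum()), 1.0)
        assert abs(np.mean(counts) - p.sum()) < 3 * sigma

    def test_far_processes_gain_nothing(self):
        segs = [
            Segment("a", "n1", None, (0, 0, 0), (0, 0, 1000), 300, kind="axon"),
            Segment("d", "n2", None, (50000, 0, 0), (50000, 0, 1000), 300, kind="dendrite"),
        ]
        morph = NetworkMorphology(segs)
        out = insert_synapses(morph, Kernel(1.0, 500.0, 1500.0), seed=0)
        assert out.synapses == []

    def test_insertions_only_reduce_precision(self, network):
        gt = derive_graph(network)
        out = insert_synapses(network, Kernel(0.2, 500.0, 1500.0), seed=3)
        recon = derive_graph(out)
        result = evaluate(gt, recon)
        assert result.global_result.recall == 1.0
        assert result.global_result.precision < 1.0


class TestSplit:
    def test_zero_pmax_is_identity(self, network):
        out = split_neurons(network, Kernel(0.0, 300.0, 800.0), seed=1)
        assert out.synapses == network.synapses
        assert {s.neuron for s in out.segments} == {s.neuron for s in network.segments}

    def test_thick_processes_never_split(self, network):
        # every process diameter in the generated net exceeds the kernel support
        min_diam = min(s.diameter for s in network.segments if s.kind != "soma")
        out = split_neurons(network, Kernel(1.0, min_diam / 4, min_diam / 2), seed=1)
        assert {s.neuron for s in out.segments} == {s.neuron for s in network.segments}

    def test_spine_head_split_detaches_one_postsynaptic_terminal(self):
        morph = spine_morph()
        # deterministic: only the 120 nm spine neck falls below the kernel
        out = split_neurons(morph, Kernel(1.0, 200.0, 300.0), seed=0)
        moved = {r.synapse_id: r for r in out.synapses}
        assert moved["sB"].post_neuron == "g#s0"
        assert moved["sA"].post_neuron == "g" and moved["sC"].post_neuron == "g"
        # downstream: two false-negative paths on the split neuron
        gt = derive_graph(morph)
        recon = derive_graph(out)
        m = match_synapses(gt, recon)
        table = build_count_table(gt, recon, m)
        res = global_nri(table)
        assert res.fn == 2 and res.fp == 0 and res.tp == 1 + 3  # green pairs + blue's C(3,2)

    def test_splits_compose_into_fragments_of_fragments(self):
        segs = [
            Segment("r", "n", None, (0, 0, 0), (0, 0, 1000), 100),
            Segment("m", "n", "r", (0, 0, 1000), (0, 0, 2000), 100),
            Segment("t", "n", "m", (0, 0, 2000), (0, 0, 3000), 100),
        ]
        out = split_neurons(NetworkMorphology(segs), Kernel(1.0, 200.0, 300.0), seed=0)
        # root keeps its id; both descendants split off into distinct fragments
        labels = {s.segment_id: s.neuron for s in out.segments}
        assert labels["r"] == "n"
        assert labels["m"] != "n" and labels["t"] != "n" and labels["m"] != labels["t"]

    def test_splits_only_reduce_recall(self, network):
        gt = derive_graph(network)
        out = split_neurons(network, Kernel(0.4, 300.0, 800.0), seed=5)
        result = evaluate(gt, derive_graph(out))
        assert result.global_result.precision == 1.0
        assert result.global_result.recall < 1.0


class TestMerge:
    def test_zero_pmax_is_identity(self, network):
        out = merge_neurons(network, Kernel(0.0, 200.0, 600.0), seed=1)
        assert out.synapses == network.synapses

    def test_forced_merge_creates_quadratic_false_positives(self):
        # two neurons, nA with 3 terminals and nB with 2, forcibly merged
        segs = [
            Segment("a0", "nA", None, (0, 0, 0), (0, 0, 2000), 300, kind="axon"),
            Segment("d0", "nB", None, (400, 0, 0), (400, 0, 2000), 300, kind="dendrite"),
            Segment("x0", "nC", None, (90000, 0, 0), (90000, 0, 2000), 300, kind="axon"),
        ]
        syns = [
            SynapseRecord("s0", "nA", "nB", (200.0, 0.0, 500.0)),
            SynapseRecord("s1", "nA", "nB", (200.0, 0.0, 1500.0)),
            SynapseRecord("s2", "nA", "nC", (45000.0, 0.0, 1000.0)),
        ]
        anchors = {"s0": ("a0", "d0"), "s1": ("a0", "d0"), "s2": ("a0", "x0")}
        morph = NetworkMorphology(segs, syns, anchors)
        out = merge_neurons(morph, Kernel(1.0, 500.0, 600.0), seed=0)
        merged = {r.synapse_id: r for r in out.synapses}
        assert merged["s0"].pre_neuron == merged["s0"].post_neuron == "nA"
        gt = derive_graph(morph)
        result = evaluate(gt, derive_graph(out))
        # nA holds 3 terminals, nB 2: merging makes all 3x2 cross pairs FPs
        assert result.global_result.fp == 6
        assert result.global_result.recall == 1.0

    def test_merge_chain_is_transitive(self):
        segs = [
            Segment("a", "nA", None, (0, 0, 0), (0, 0, 1000), 300, kind="axon"),
            Segment("b", "nB", None, (350, 0, 0), (350, 0, 1000), 300, kind="dendrite"),
            Segment("c", "nC", None, (700, 0, 0), (700, 0, 1000), 300, kind="axon"),
        ]
        morph = NetworkMorphology(segs)
        out = merge_neurons(morph, Kernel(1.0, 100.0, 360.0), seed=0)
        assert {s.neuron for s in out.segments} == {"nA"}


class TestPerturbationScores:
    def test_unperturbed_network_scores_zero_everywhere(self, network):
        gt = derive_graph(network)
        recon = derive_graph(network)
        m = match_synapses(gt, recon)
        table = build_count_table(gt, recon, m)
        for kind in (DELETED_FRACTION, FOREIGN_FRACTION, SPLIT_ENTROPY):
            assert all(s.value == 0.0 for s in perturbation_scores(table, kind))

    def test_merge_score_formula(self):
        # A (100 terminals) merged with B and C (50 each): foreign share 0.5
        table = make_count_table([[0, 0], [0, 100], [0, 50], [0, 50]])
        scores = {s.neuron: s.value for s in perturbation_scores(table, FOREIGN_FRACTION)}
        assert scores["g1"] == pytest.approx(100 / 200)
        assert scores["g2"] == pytest.approx(150 / 200)

    def test_deleted_fraction_from_reserved_column(self):
        table = make_count_table([[0, 0], [25, 75]])
        (score,) = perturbation_scores(table, DELETED_FRACTION)
        assert score.value == pytest.approx(0.25)

    def test_equal_two_way_split_has_unit_entropy(self):
        # two terminals on two fragments: H = log 2, normalizer log 2
        table = make_count_table([[0, 0, 0], [0, 1, 1]])
        (score,) = perturbation_scores(table, SPLIT_ENTROPY)
        assert score.value == pytest.approx(1.0)

    def test_unsplit_neuron_has_zero_entropy(self):
        table = make_count_table([[0, 0], [0, 40]])
        (score,) = perturbation_scores(table, SPLIT_ENTROPY)
        assert score.value == 0.0


class TestApplyPerturbation:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            PerturbConfig("delete")
        with pytest.raises(ValueError):
            PerturbConfig("merge")
        with pytest.raises(ValueError):
            PerturbConfig("collapse", fraction=0.1)

    def test_delete_dispatch_prunes_morphology(self, network):
        out = apply_perturbation(network, PerturbConfig("delete", fraction=0.5, seed=3))
        assert len(out.synapses) == len(network.synapses) - round(0.5 * len(network.synapses))
        assert set(out.anchors) == {r.synapse_id for r in out.synapses}


class TestCropRelabel:
    def test_whole_volume_box_is_identity_up_to_renaming(self, network):
        lo = (-1e9, -1e9, -1e9)
        hi = (1e9, 1e9, 1e9)
        out = crop_relabel(network, lo, hi)
        assert len(out.segments) == len(network.segments)
        assert len(out.synapses) == len(network.synapses)
        # each neuron stays one connected fragment
        assert len(out.neuron_ids()) == len(network.neuron_ids())

    def test_branches_without_their_junction_become_two_fragments(self):
        segs = [
            Segment("root", "n", None, (0, 5000, 0), (0, 5000, 900), 500),
            Segment("left", "n", "root", (0, 5000, 900), (0, 0, 2000), 400),
            Segment("right", "n", "root", (0, 5000, 900), (0, 10000, 2000), 400),
            Segment("lt", "n", "left", (0, 0, 2000), (0, 0, 4000), 300),
            Segment("rt", "n", "right", (0, 10000, 2000), (0, 10000, 4000), 300),
        ]
        m = NetworkMorphology(segs)
        # the box starts above the junction: root is excluded entirely
        out = crop_relabel(m, (-100, -100, 1500), (100, 20000, 5000))
        kept = {s.segment_id for s in out.segments}
        assert "root" not in kept and {"lt", "rt"} <= kept
        labels = {s.segment_id: s.neuron for s in out.segments}
        assert labels["lt"] != labels["rt"]

    def test_box_outside_volume_empties_everything(self, network):
        out = crop_relabel(network, (1e9, 1e9, 1e9), (2e9, 2e9, 2e9))
        assert out.segments == [] and out.synapses == []

    def test_matched_cropping_restores_perfect_score(self, network):
        # crop both sides identically: a perfect reconstruction must score 1
        lo, hi = (3000.0, 3000.0, 3000.0), (18000.0, 18000.0, 18000.0)
        gt_crop = crop_relabel(network, lo, hi)
        recon_crop = crop_relabel(network, lo, hi)
        gt = derive_graph(gt_crop)
        recon = derive_graph(recon_crop)
        if len(gt) == 0:
            pytest.skip("crop window empty for this seed")
        result = evaluate(gt, recon)
        assert result.global_result.score == 1.0
        assert result.nvi == pytest.approx(0.0)
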