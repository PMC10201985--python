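"""Generators: planted geometry, planted alignments, graphs, table fixtures."""

import hashlib
from importlib import resources

import numpy as np
import pytest

from conftest import betweenness_oracle
from ribonet.structure import min_residue_distance
from ribonet.synthetic import (
    GenerationError,
    PlantedAlignmentSpec,
    ToyDimerSpec,
    make_graph_fixture,
    make_lineage_alignment,
    make_toy_dimer,
    table1_fixture,
    table3_fixture,
)

FIXTURE_SHA256 = {
    "table1.tsv": "f8a69e349e6022d6084ca58d07a20961b932c0343a9e2b2412a8756d6777b17a",
    "table3_bca.tsv": "8e9f9a6ab0066801fce1108b6c2aa9e69fc04c5333de5cf0e82bd7201198693d",
    "table3_cca.tsv": "9e917193a749d6b1885a71632c8282aa7d3677872b359e9508021f83bf182f78",
}


class TestToyDimer:
    def test_single_planted_contact(self):
        s, edges = make_toy_dimer(ToyDimerSpec(contact_plan=((1, 1, 3.47),), seed=0))
        assert edges == [(("A", 1, ""), ("B", 1, ""), 3.47)]
        d = min_residue_distance(s.chain("A").get(1), s.chain("B").get(1))
        assert d == pytest.approx(3.47, abs=1e-6)

    def test_empty_plan_no_interchain_contacts(self):
        s, edges = make_toy_dimer(ToyDimerSpec(contact_plan=(), seed=1))
        assert edges == []
        for ra in s.chain("A").residues:
            for rb in s.chain("B").residues:
                assert min_residue_distance(ra, rb) >= 6.0

    def test_random_plans_hit_targets(self):
        """Planted minimal distances are exact; unplanned pairs stay >= 6 Å."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            n_contacts = int(rng.integers(0, min(4, n) + 1))
            pairs = set()
            plan = []
            while len(plan) < n_contacts:
                i, j = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
                if (i, j) in pairs:
                    continue
                pairs.add((i, j))
                plan.append((i, j, float(rng.uniform(2.0, 7.0))))
            s, edges = make_toy_dimer(
                ToyDimerSpec(n_residues_per_chain=n, contact_plan=tuple(plan),
                             seed=int(rng.integers(2**31)))
            )
            planned = {(i, j): d for i, j, d in plan}
            for ra in s.chain("A").residues:
                for rb in s.chain("B").residues:
                    d = min_residue_distance(ra, rb)
                    if (ra.number, rb.number) in planned:
                        assert d == pytest.approx(planned[(ra.number, rb.number)], abs=0.01)
                    else:
                        assert d >= 6.0
            assert edges == [
                (("A", i, ""), ("B", j, ""), d) for i, j, d in plan if 2.5 <= d <= 5.0
            ]

    def test_determinism(self):
        spec = ToyDimerSpec(contact_plan=((1, 2, 3.0),), seed=9)
        s1, e1 = make_toy_dimer(spec)
        s2, e2 = make_toy_dimer(spec)
        assert e1 == e2
        c1 = np.concatenate([r.coords() for r in s1.residues()])
        c2 = np.concatenate([r.coords() for r in s2.residues()])
        assert np.array_equal(c1, c2)

    @pytest.mark.parametrize(
        "plan, message",
        [
            (((1, 1, 3.0), (1, 1, 4.0)), "conflicting"),
            (((9, 1, 3.0),), "outside"),
            (((1, 1, -1.0),), "must be > 0"),
        ],
    )
    def test_infeasible_plans(self, plan, message):
        with pytest.raises(GenerationError, match=message):
            ToyDimerSpec(n_residues_per_chain=3, contact_plan=plan)


class TestPlantedAlignment:
    def test_planted_fixed_difference(self):
        spec = PlantedAlignmentSpec(
            length=30, planted=((27, {"E1": "E", "W1": "D", "W2": "D", "W3": "D"}),), seed=3
        )
        aln, truth = make_lineage_alignment(spec)
        assert truth == {27: {"E1": "E", "W1": "D", "W2": "D", "W3": "D"}}
        for lin, aa in truth[27].items():
            assert {s[26] for s in aln.sequences[lin]} == {aa}

    def test_no_plant_empty_truth(self):
        aln, truth = make_lineage_alignment(PlantedAlignmentSpec(length=20, seed=4))
        assert truth == {}
        all_seqs = [s for group in aln.sequences.values() for s in group]
        assert len(set(all_seqs)) == 1  # every sequence identical

    def test_missing_lineage_rejected(self):
        with pytest.raises(GenerationError, match="missing"):
            PlantedAlignmentSpec(length=10, planted=((5, {"E1": "E"}),))

    def test_determinism(self):
        spec = PlantedAlignmentSpec(length=25, n_polymorphic=2, n_gap_columns=1, seed=8)
        a1, t1 = make_lineage_alignment(spec)
        a2, t2 = make_lineage_alignment(spec)
        assert a1.sequences == a2.sequences and a1.reference == a2.reference and t1 == t2


class TestTableFixtures:
    def test_fixture_files_unchanged(self):
        for name, digest in FIXTURE_SHA256.items():
            blob = resources.files("ribonet.data").joinpath(name).read_bytes()
            assert hashlib.sha256(blob).hexdigest() == digest, name

    def test_interaction_records(self):
        records = table1_fixture()
        assert len(records) == 28
        key = [r for r in records
               if r.plastid_residue == "Lys135" and r.nuclear_residue == "Glu127"]
        assert len(key) == 1
        rec = key[0]
        assert rec.distance == pytest.approx(3.12)
        assert rec.before == "salt_bridge" and rec.after == "salt_bridge"
        assert rec.nuclear_aa == {"E1": "-", "W1": "D", "W2": "D", "W3": "D"}
        for r in records:
            assert 2.5 <= r.distance <= 5.0  # all inside the interaction window

    @pytest.mark.parametrize("measure", ["BCA", "CCA"])
    def test_centrality_matrix_complete(self, measure):
        table = table3_fixture(measure)
        assert table.shape == (16, 17)
        assert not table.data.isna().any().any()
        assert list(table.data.index[:2]) == ["E1_E1", "E1_W1"]
        assert table.data.columns[0] == "98.k" and table.data.columns[-1] == "127.u"

    def test_spot_values(self):
        assert table3_fixture("BCA").data.loc["E1_E1", "98.k"] == pytest.approx(0.52)
        assert table3_fixture("CCA").data.loc["W3_W3", "127.u"] == pytest.approx(-1.57)

    def test_unknown_measure(self):
        with pytest.raises(ValueError):
            table3_fixture("DCA")


class TestGraphFixtures:
    def test_complete(self):
        g = make_graph_fixture("complete", 4)
        assert g.number_of_edges() == 6

    def test_path_end_degrees(self):
        g = make_graph_fixture("path", 5)
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1, 1, 2, 2, 2]

    def test_bridge_has_max_betweenness(self):
        g = make_graph_fixture("two_cliques_bridge", 4)
        oracle = betweenness_oracle(g)
        # the bridge is the unique degree-2 node joining the cliques
        bridge = [n for n, d in g.degree() if d == 2]
        assert len(bridge) == 1
        assert oracle[bridge[0]] == max(oracle.values())

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_graph_fixture("wheel", 5)
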