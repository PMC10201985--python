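"""Side-chain rebuilding, rotamer choice, clash relief, combination models."""

import numpy as np
import pytest

from conftest import CHAIN_MAP
from ribonet.mutagenesis import (
    CLASH_CUTOFF,
    build_combination_model,
    canonical_sidechain_atoms,
    choose_rotamer,
    clash_score,
    enumerate_combinations,
    measure_chis,
    relax_side_chain,
    rotamer_candidates,
    substitute_residue,
)
from ribonet.structure import Atom
from ribonet.synthetic import ToyDimerSpec, make_toy_dimer
from ribonet.variants import SubstitutionSet

BACKBONE = ("N", "CA", "C", "O")


def backbone_coords(structure):
    out = []
    for res in structure.residues():
        for name in BACKBONE:
            if res.has_atom(name):
                out.append(res.atom(name).position)
    return np.array(out)


@pytest.fixture
def toy():
    s, _ = make_toy_dimer(ToyDimerSpec(n_residues_per_chain=4, seed=21))
    return s


@pytest.mark.parametrize("aa", ["S", "K", "F", "W", "R", "D", "T", "P"])
def test_substitution_builds_canonical_atom_set(toy, aa):
    """The rebuilt side chain carries exactly the canonical heavy atoms."""
    mutated = substitute_residue(toy, "A", 2, aa)
    res = mutated.chain("A").get(2)
    sidechain = {a.name for a in res.atoms if a.name not in BACKBONE}
    assert sidechain == set(canonical_sidechain_atoms(res.aa3))


def test_gly_target_removes_side_chain(toy):
    with_cb = substitute_residue(toy, "A", 1, "A")
    assert with_cb.chain("A").get(1).has_atom("CB")
    back = substitute_residue(with_cb, "A", 1, "G")
    res = back.chain("A").get(1)
    assert {a.name for a in res.atoms} <= set(BACKBONE)
    assert np.array_equal(backbone_coords(back), backbone_coords(with_cb))


def test_backbone_bit_identical(toy):
    mutated = substitute_residue(toy, "B", 3, "E")
    assert np.array_equal(backbone_coords(mutated), backbone_coords(toy))


def test_pro_to_ser_atom_set(toy):
    as_pro = substitute_residue(toy, "A", 3, "P")
    as_ser = substitute_residue(as_pro, "A", 3, "S")
    res = as_ser.chain("A").get(3)
    assert {a.name for a in res.atoms} == {"N", "CA", "C", "O", "CB", "OG"}


def test_absent_residue_and_bad_target(toy):
    with pytest.raises(KeyError):
        substitute_residue(toy, "A", 99, "S")
    with pytest.raises(ValueError, match="unsupported"):
        substitute_residue(toy, "A", 1, "X")


class TestChooseRotamer:
    def test_empty_space_picks_highest_prior(self, toy):
        chis, clashes = choose_rotamer(toy, "A", 2, "SER")
        assert clashes == 0
        best_prior = max(rotamer_candidates("SER"), key=lambda c: c[1])
        assert chis == best_prior[0]

    def test_returned_candidate_is_optimal(self, toy):
        """Exhaustive check: no candidate beats the returned one."""
        from ribonet.mutagenesis import _build_sidechain, _environment_tree

        s = substitute_residue(toy, "A", 2, "K")
        res = s.chain("A").get(2)
        n, ca, c = (res.atom(x).position for x in ("N", "CA", "C"))
        env = _environment_tree(s, res.key)
        chis, best = choose_rotamer(s, "A", 2, "LYS")
        for cand, _prior in rotamer_candidates("LYS"):
            atoms = _build_sidechain("LYS", n, ca, c, cand)
            sc = clash_score(np.array([p for _, _, p in atoms]), env)
            assert best <= sc

    def test_engineered_pocket_selects_clash_free_candidate(self, toy):
        """Blocking atoms near two of three OG positions force the third."""
        from ribonet.mutagenesis import _build_sidechain

        res = toy.chain("A").get(2)
        n, ca, c = (res.atom(x).position for x in ("N", "CA", "C"))
        cands = rotamer_candidates("SER")
        keep = cands[-1][0]  # lowest-prior candidate must win on clashes

        def og_of(chis):
            atoms = {nm: p for nm, _, p in _build_sidechain("SER", n, ca, c, chis)}
            return atoms["OG"], atoms["CB"]

        blockers = []
        for chis, _ in cands:
            if chis == keep:
                continue
            og, cb = og_of(chis)
            # radially outward from CB: 1.2 Å from the bad OG, 2.6 Å from CB,
            # and > 2.5 Å from every atom of the kept candidate
            blockers.append(cb + 2.6 * (og - cb) / np.linalg.norm(og - cb))
        blocked = toy.copy()
        far = blocked.chain("B").get(4)
        for k, pos in enumerate(blockers):
            far.atoms.append(Atom(name=f"Z{k}", element="C", position=pos))
        chis, clashes = choose_rotamer(blocked, "A", 2, "SER")
        assert chis == keep and clashes == 0


class TestRelax:
    def test_clash_free_side_chain_unchanged(self, toy):
        s = substitute_residue(toy, "A", 2, "S")
        relaxed = relax_side_chain(s, "A", 2)
        before = s.chain("A").get(2).coords()
        after = relaxed.chain("A").get(2).coords()
        assert np.allclose(before, after)

    def test_engineered_clash_resolved_by_chi1(self, toy):
        s = substitute_residue(toy, "A", 2, "S")
        res = s.chain("A").get(2)
        og, cb = res.atom("OG").position, res.atom("CB").position
        clashy = s.copy()
        # 1.2 Å beyond OG along the CB->OG direction: clashes with OG but not
        # CB, and a chi1 rotation can move OG out of range
        blocker = cb + 2.6 * (og - cb) / np.linalg.norm(og - cb)
        clashy.chain("B").get(4).atoms.append(
            Atom(name="Z1", element="C", position=blocker)
        )
        from ribonet.mutagenesis import _environment_tree

        env = _environment_tree(clashy, res.key)
        sc_before = clash_score(res.coords()[4:], env)  # side-chain atoms only
        assert sc_before > 0
        relaxed = relax_side_chain(clashy, "A", 2)
        new = relaxed.chain("A").get(2)
        sidechain = np.array([a.position for a in new.atoms if a.name not in BACKBONE])
        assert clash_score(sidechain, _environment_tree(relaxed, new.key)) == 0

    def test_relaxation_never_increases_clashes(self, toy):
        from ribonet.mutagenesis import _environment_tree

        rng = np.random.default_rng(31)
        for aa in ("K", "R", "M"):
            s = substitute_residue(toy, "A", 2, aa)
            clashy = s.copy()
            res = clashy.chain("A").get(2)
            side = [a for a in res.atoms if a.name not in BACKBONE]
            target = side[int(rng.integers(len(side)))].position
            clashy.chain("B").get(1).atoms.append(
                Atom(name="Z9", element="C",
                     position=target + rng.uniform(-1, 1, size=3))
            )
            env = _environment_tree(clashy, res.key)
            before = clash_score(np.array([a.position for a in side]), env)
            relaxed = relax_side_chain(clashy, "A", 2)
            new = relaxed.chain("A").get(2)
            after = clash_score(
                np.array([a.position for a in new.atoms if a.name not in BACKBONE]),
                _environment_tree(relaxed, new.key),
            )
            assert after <= before


class TestCombinations:
    def lineage_sets(self):
        return {
            "E1": SubstitutionSet("E1", [("rps11", 2, "S")]),
            "W1": SubstitutionSet("W1", [("rps21", 3, "D"), ("rps11", 1, "K")]),
        }

    def test_enumeration(self):
        ids = enumerate_combinations(["E1", "W1", "W2", "W3"])
        assert len(ids) == 16
        assert ids[0].label == "E1_E1" and ids[-1].label == "W3_W3"
        assert len({c.label for c in ids}) == 16

    def test_empty_sets_give_template(self, toy):
        sets = {"E1": SubstitutionSet("E1", [])}
        ids = enumerate_combinations(["E1"])
        model = build_combination_model(toy, ids[0], sets, CHAIN_MAP)
        assert model.applied == []
        assert np.array_equal(
            np.concatenate([r.coords() for r in model.structure.residues()]),
            np.concatenate([r.coords() for r in toy.residues()]),
        )

    def test_compartment_routing(self, toy):
        """Maternal substitutions land on plastid chains only, paternal on nuclear."""
        from ribonet.mutagenesis import CombinationId

        model = build_combination_model(
            toy, CombinationId("E1", "W1"), self.lineage_sets(), CHAIN_MAP
        )
        applied = {(comp, gene, num, new) for comp, gene, num, _, new in model.applied}
        assert applied == {
            ("plastid", "rps11", 2, "SER"),  # E1's plastid change
            ("nuclear", "rps21", 3, "ASP"),  # W1's nuclear change
        }
        # W1's rps11 change must NOT be applied in E1_W1
        assert model.structure.chain("A").get(1).aa3 == "GLY"

    def test_backbone_rmsd_zero_for_all_models(self, toy):
        template_bb = backbone_coords(toy)
        for cid in enumerate_combinations(["E1", "W1"]):
            model = build_combination_model(toy, cid, self.lineage_sets(), CHAIN_MAP)
            assert np.array_equal(backbone_coords(model.structure), template_bb)

    def test_idempotence(self, toy):
        """Applying a substitution set twice equals applying it once."""
        once = substitute_residue(toy, "A", 2, "S")
        twice = substitute_residue(once, "A", 2, "S")
        assert np.allclose(
            np.concatenate([r.coords() for r in once.residues()]),
            np.concatenate([r.coords() for r in twice.residues()]),
        )

    def test_unknown_gene_rejected(self, toy):
        from ribonet.mutagenesis import CombinationId
        from ribonet.structure import ChainMapError

        sets = {"E1": SubstitutionSet("E1", [("rpl99", 1, "K")])}
        with pytest.raises(ChainMapError, match="rpl99"):
            build_combination_model(toy, CombinationId("E1", "E1"), sets, CHAIN_MAP)

    def test_missing_residue_reported_unapplicable(self, toy):
        from ribonet.mutagenesis import CombinationId

        sets = {"E1": SubstitutionSet("E1", [("rps11", 99, "K")])}
        model = build_combination_model(toy, CombinationId("E1", "E1"), sets, CHAIN_MAP)
        assert model.applied == []
        assert model.unapplicable == [("plastid", "rps11", 99, "K")]


def test_measure_chis_round_trip(toy):
    """Chi angles measured from a built side chain equal the requested ones."""
    s = substitute_residue(toy, "A", 2, "K")
    chis, _ = choose_rotamer(toy, "A", 2, "LYS")
    measured = measure_chis(s.chain("A").get(2))
    assert np.allclose(np.array(measured), np.array(chis), atol=1e-4)


def test_clash_cutoff_matches_rin_lower_bound():
    assert CLASH_CUTOFF == 2.5
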