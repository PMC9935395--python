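"""Greedy assembly: ranking, gates, round-trip recovery, determinism."""

import copy

import numpy as np
import pytest

from structint import (
    Assembly,
    AssemblyParams,
    DimerRecord,
    assemble,
    assembly_rmsd,
    clash_fraction,
    rank_dimers,
    score_dimer,
    try_add_dimer,
)
from structint.assembly import PlacedChain
from structint.geometry import Transform
from structint.synthetic import SyntheticComplexSpec, make_complex, random_rigid_transform

from conftest import make_point_chain


def dimer_records(sc):
    """DimerRecords for a SyntheticComplex, scored by pDockQ."""
    records = []
    for d, (i, j) in zip(sc.dimers, sc.dimer_pairs):
        pa = sc.chain_proteins[sc.structure.chains[i].chain_id]
        pb = sc.chain_proteins[sc.structure.chains[j].chain_id]
        records.append(
            DimerRecord(d.id, d, "A", "B", pa, pb, score_dimer(d, "A", "B").pdockq)
        )
    return records


def reassembly_rmsd(sc, params=None):
    asm = assemble(dimer_records(sc), params)
    model = asm.to_structure()
    pm = {c.chain_id: c.protein_accession for c in sc.structure.chains}
    return asm, assembly_rmsd(model, sc.structure, pm)


class TestRankDimers:
    def _rec(self, did, score):
        chains = [make_point_chain("A", [[0, 0, 0], [4, 0, 0], [8, 0, 0]]),
                  make_point_chain("B", [[0, 5, 0], [4, 5, 0], [8, 5, 0]])]
        from structint.structure import Structure

        return DimerRecord(did, Structure(id=did, chains=chains), "A", "B",
                           "P1", "P2", score)

    def test_descending_by_score(self):
        order = rank_dimers([self._rec("a", 0.7), self._rec("b", 0.9), self._rec("c", 0.5)])
        assert [d.pdockq for d in order] == [0.9, 0.7, 0.5]

    def test_ties_lexicographic(self):
        order = rank_dimers([self._rec("zz", 0.6), self._rec("aa", 0.6)])
        assert [d.dimer_id for d in order] == ["aa", "zz"]

    def test_empty(self):
        assert rank_dimers([]) == []


class TestClashFraction:
    def _assembly_with(self, chain):
        asm = Assembly()
        asm.placed_chains.append(
            PlacedChain("P1", 0, chain, "seed", Transform.identity())
        )
        return asm

    def test_distant_candidate_zero(self):
        placed = make_point_chain("A", [[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        cand = make_point_chain("B", [[100, 0, 0], [104, 0, 0]])
        assert clash_fraction(cand, self._assembly_with(placed)) == 0.0

    def test_identical_candidate_one(self):
        placed = make_point_chain("A", [[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        assert clash_fraction(copy.deepcopy(placed), self._assembly_with(placed)) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        placed = make_point_chain("A", rng.uniform(-15, 15, size=(20, 3)))
        cand = make_point_chain("B", rng.uniform(-15, 15, size=(15, 3)))
        asm = self._assembly_with(placed)
        got = clash_fraction(cand, asm, clash_distance=5.0)
        placed_ca = placed.ca_coords()
        n_clash = sum(
            1
            for r in cand.residues
            if any(np.linalg.norm(r.ca.position - p) < 5.0 for p in placed_ca)
        )
        assert got == pytest.approx(n_clash / len(cand.residues))


class TestTryAddDimer:
    def test_no_shared_protein_skipped(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        other = [r for r in records
                 if {r.protein_a, r.protein_b}.isdisjoint({records[0].protein_a,
                                                           records[0].protein_b})][0]
        decision = try_add_dimer(asm, other, AssemblyParams())
        assert decision.action == "skipped_no_shared_chain"

    def test_both_present_skipped(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        decision = try_add_dimer(asm, records[0], AssemblyParams())
        assert decision.action == "skipped_both_present"

    def test_consistent_dimer_added_at_ground_truth(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        extender = [r for r in records[1:]
                    if len({r.protein_a, r.protein_b} & set(asm.proteins)) == 1][0]
        decision = try_add_dimer(asm, extender, AssemblyParams())
        assert decision.action == "added"
        # the ring was generated in the global frame and the seed keeps its own
        # frame, so compare the new chain against the seed-frame ground truth
        new = asm.placed_chains[-1]
        seed_transform = ring5.transforms[records[0].dimer_id].inverse()
        truth_chain = [
            c for c in ring5.structure.chains
            if ring5.chain_proteins[c.chain_id] == new.protein
        ][0]
        truth = seed_transform.apply(truth_chain.ca_coords())
        np.testing.assert_allclose(new.chain.ca_coords(), truth, atol=1e-6)

    def test_divergent_shared_conformation_rejected_tm(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        extender = copy.deepcopy(
            [r for r in records[1:]
             if len({r.protein_a, r.protein_b} & set(asm.proteins)) == 1][0]
        )
        shared = (extender.protein_a if extender.protein_a in asm.proteins
                  else extender.protein_b)
        _, shared_chain = extender.chain_for(shared)
        rng = np.random.default_rng(0)
        for res in shared_chain.residues:  # heavy distortion kills the TM gate
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0, 8.0, 3)
        decision = try_add_dimer(asm, extender, AssemblyParams())
        assert decision.action == "rejected_tm"
        assert decision.metrics["tm_score"] <= 0.8

    def test_overlapping_new_chain_rejected_clash(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        extender = copy.deepcopy(
            [r for r in records[1:]
             if len({r.protein_a, r.protein_b} & set(asm.proteins)) == 1][0]
        )
        shared = (extender.protein_a if extender.protein_a in asm.proteins
                  else extender.protein_b)
        new_protein = extender.other_protein(shared)
        _, shared_chain = extender.chain_for(shared)
        _, new_chain = extender.chain_for(new_protein)
        # move the new chain on top of the shared chain -> full overlap
        offset = shared_chain.ca_coords()[0] - new_chain.ca_coords()[0]
        for res in new_chain.residues:
            for atom in res.atoms:
                atom.position = atom.position + offset
        decision = try_add_dimer(asm, extender, AssemblyParams())
        assert decision.action == "rejected_clash"
        assert decision.metrics["clash_fraction"] > 0.25


class TestAssemble:
    def test_single_dimer_seeds_only(self, ring5):
        records = dimer_records(ring5)
        asm = assemble([records[0]])
        assert len(asm.placed_chains) == 2
        assert [d.action for d in asm.decision_log] == ["seed"]

    @pytest.mark.parametrize("geometry,n", [("ring", 5), ("chain", 5), ("ring", 8)])
    def test_round_trip_recovers_ground_truth(self, geometry, n):
        sc = make_complex(SyntheticComplexSpec(n_chains=n, geometry=geometry, seed=n))
        asm, result = reassembly_rmsd(sc)
        assert len(asm.placed_chains) == n
        assert result.rmsd < 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_property_over_seeds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        sc = make_complex(SyntheticComplexSpec(
            n_chains=n, geometry=rng.choice(["ring", "chain"]), seed=seed + 500))
        asm, result = reassembly_rmsd(sc)
        assert len(asm.placed_chains) == n
        assert result.rmsd < 1.0

    def test_inconsistent_dimer_rejected_but_rest_built(self):
        sc = make_complex(SyntheticComplexSpec(n_chains=5, geometry="chain", seed=9))
        records = dimer_records(sc)
        # corrupt the terminal dimer: place its second chain on top of its
        # first, so only its terminal protein becomes unplaceable
        victim = [r for r in records if r.protein_b == "P005"][0]
        _, ca = victim.chain_for(victim.protein_a)
        _, cb = victim.chain_for(victim.protein_b)
        offset = ca.ca_coords()[0] - cb.ca_coords()[0]
        for res in cb.residues:
            for atom in res.atoms:
                atom.position = atom.position + offset
        asm = assemble(records)
        actions = {d.dimer_id: d.action for d in asm.decision_log
                   if d.action.startswith("rejected")}
        assert victim.dimer_id in actions
        assert actions[victim.dimer_id] == "rejected_clash"
        assert len(asm.placed_chains) == 4

    def test_deterministic_decision_log(self, ring5):
        log1 = assemble(dimer_records(ring5)).log_json()
        log2 = assemble(dimer_records(ring5)).log_json()
        assert log1 == log2

    def test_global_clash_invariant_post_hoc(self, ring5):
        asm = assemble(dimer_records(ring5))
        for k, placed in enumerate(asm.placed_chains):
            others = Assembly(placed_chains=[p for i, p in enumerate(asm.placed_chains)
                                             if i != k])
            assert clash_fraction(placed.chain, others) <= 0.25

    def test_chains_never_removed_and_bounded(self, ring5):
        records = dimer_records(ring5)
        asm = assemble(records)
        n_added = sum(1 for d in asm.decision_log if d.action in ("seed", "added"))
        assert len(asm.placed_chains) == n_added + 1  # seed places two chains
        assert len(asm.placed_chains) <= 5

    def test_start_dimer_override(self, ring5):
        records = dimer_records(ring5)
        target = rank_dimers(records)[-1].dimer_id
        asm = assemble(records, AssemblyParams(start_dimer=target))
        assert asm.decision_log[0].dimer_id == target
        assert asm.decision_log[0].action == "seed"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            assemble([])


class TestSubdimerExtraction:
    def test_trimer_decomposes_into_three_dimers(self, ring5):
        from structint.assembly import extract_subdimers
        from structint.structure import Structure

        trimer = Structure(
            id="trimer",
            chains=[copy.deepcopy(c) for c in ring5.structure.chains[:3]],
        )
        proteins = {c.chain_id: ring5.chain_proteins[c.chain_id]
                    for c in trimer.chains}
        subs = extract_subdimers(trimer, proteins)
        assert len(subs) == 3
        assert all(len(s.structure.chains) == 2 for s in subs)
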