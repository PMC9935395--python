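"""Greedy iterative assembly of multimers from pairwise complex models.

Given a set of dimer models scored by pDockQ, the builder seeds the
growing complex with the highest-scoring dimer and then repeatedly sweeps
the ranked list.  A dimer can extend the complex when exactly one of its
proteins is already placed; its copy of the shared protein is superposed
onto the placed copy (gate: TM-score > 0.8, guarding against divergent
conformations of the shared chain), the resulting rigid motion carries
its other chain into the complex frame, and the new chain is accepted if
no more than 25% of its residues clash (Cα-Cα < 5 Å) with already placed
chains.  After every successful addition the sweep restarts from the top
of the ranking; the build terminates when a full sweep adds nothing.
Every attempt is logged, making the procedure auditable and
deterministic.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Transform, kabsch, tm_score
from .interface import ScoringParams, score_dimer
from .structure import Chain, Structure, read_structure

__all__ = [
    "DimerRecord",
    "AssemblyParams",
    "PlacedChain",
    "Decision",
    "Assembly",
    "rank_dimers",
    "clash_fraction",
    "try_add_dimer",
    "assemble",
    "read_dimer_manifest",
    "extract_subdimers",
]


@dataclass
class DimerRecord:
    """A scored two-chain model: structure, chain ids, protein accessions."""

    dimer_id: str
    structure: Structure
    chain_id_a: str
    chain_id_b: str
    protein_a: str
    protein_b: str
    pdockq: float

    def __post_init__(self) -> None:
        if len(self.structure.chains) != 2:
            raise ValueError(f"dimer {self.dimer_id}: structure must have 2 chains")
        if not 0.0 <= self.pdockq < 1.0:
            raise ValueError(f"dimer {self.dimer_id}: pdockq {self.pdockq} not in [0, 1)")

    def chain_for(self, protein: str) -> tuple[str, Chain]:
        if protein == self.protein_a:
            return self.chain_id_a, self.structure.chain(self.chain_id_a)
        if protein == self.protein_b:
            return self.chain_id_b, self.structure.chain(self.chain_id_b)
        raise KeyError(f"protein {protein} not in dimer {self.dimer_id}")

    def other_protein(self, protein: str) -> str:
        return self.protein_b if protein == self.protein_a else self.protein_a


@dataclass(frozen=True)
class AssemblyParams:
    tm_min: float = 0.8  # shared-chain similarity gate, strict >
    clash_distance: float = 5.0  # Å Cα-Cα, strict <
    clash_fraction: float = 0.25  # rejection when strictly exceeded
    start_dimer: Optional[str] = None  # dimer_id; default highest pDockQ
    max_copies: Optional[int] = None  # per-protein stoichiometry cap

    def __post_init__(self) -> None:
        if not (self.tm_min > 0 and self.clash_distance > 0):
            raise ValueError("tm_min and clash_distance must be positive")
        if not 0 < self.clash_fraction < 1:
            raise ValueError("clash_fraction must be in (0, 1)")


@dataclass
class PlacedChain:
    protein: str
    copy_index: int
    chain: Chain  # coordinates already in the assembly frame
    source_dimer_id: str
    transform: Transform  # dimer frame -> assembly frame


@dataclass
class Decision:
    dimer_id: str
    action: str  # seed | added | skipped_no_shared_chain | skipped_both_present
    #             | rejected_tm | rejected_clash
    sweep: int
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dimer_id": self.dimer_id,
            "action": self.action,
            "sweep": self.sweep,
            "metrics": {k: (round(v, 6) if isinstance(v, float) else v)
                        for k, v in self.metrics.items()},
        }


@dataclass
class Assembly:
    placed_chains: list[PlacedChain] = field(default_factory=list)
    decision_log: list[Decision] = field(default_factory=list)
    params: AssemblyParams = field(default_factory=AssemblyParams)

    @property
    def proteins(self) -> list[str]:
        return [p.protein for p in self.placed_chains]

    def copies_of(self, protein: str) -> list[PlacedChain]:
        return [p for p in self.placed_chains if p.protein == protein]

    def to_structure(self, structure_id: str = "assembly") -> Structure:
        """Assembly as a Structure; chains relabeled A, B, ... in placement order."""
        import string

        labels = string.ascii_uppercase + string.ascii_lowercase + string.digits
        chains = []
        for i, placed in enumerate(self.placed_chains):
            chain = copy.deepcopy(placed.chain)
            chain.chain_id = labels[i] if i < len(labels) else f"C{i}"
            chain.protein_accession = placed.protein
            chains.append(chain)
        return Structure(id=structure_id, chains=chains)

    def log_json(self) -> str:
        return json.dumps([d.to_dict() for d in self.decision_log], indent=2)


def rank_dimers(dimers: list[DimerRecord]) -> list[DimerRecord]:
    """Descending pDockQ; ties broken lexicographically by dimer_id (stable)."""
    return sorted(dimers, key=lambda d: (-d.pdockq, d.dimer_id))


def clash_fraction(
    candidate_chain: Chain, assembly: Assembly, clash_distance: float = 5.0
) -> float:
    """Fraction of candidate residues with Cα strictly within *clash_distance*
    of any placed Cα."""
    cand = candidate_chain.ca_coords()
    if cand.shape[0] == 0:
        raise ValueError("candidate chain has no Cα atoms")
    placed = [p.chain.ca_coords() for p in assembly.placed_chains]
    placed = [c for c in placed if c.shape[0]]
    if not placed:
        return 0.0
    tree = cKDTree(np.vstack(placed))
    d, _ = tree.query(cand, k=1)
    return float(np.mean(d < clash_distance))


def _transformed_chain(chain: Chain, transform: Transform) -> Chain:
    out = copy.deepcopy(chain)
    for res in out.residues:
        for atom in res.atoms:
            atom.position = transform.apply(atom.position)
    return out


def try_add_dimer(
    assembly: Assembly, dimer: DimerRecord, params: AssemblyParams, sweep: int = 0
) -> Decision:
    """Attempt to extend the assembly with one dimer; always returns a logged
    decision (the assembly is mutated only on success).

    Exactly one of the dimer's proteins must already be placed.  Each
    placed copy of the shared protein is tried in placement order; the
    first copy passing both the TM-score gate and the clash gate accepts
    the dimer's other chain.
    """
    present = set(assembly.proteins)
    in_a, in_b = dimer.protein_a in present, dimer.protein_b in present
    if in_a and in_b:
        decision = Decision(dimer.dimer_id, "skipped_both_present", sweep)
    elif not in_a and not in_b:
        decision = Decision(dimer.dimer_id, "skipped_no_shared_chain", sweep)
    else:
        shared = dimer.protein_a if in_a else dimer.protein_b
        new_protein = dimer.other_protein(shared)
        if params.max_copies is not None and len(assembly.copies_of(new_protein)) >= params.max_copies:
            decision = Decision(dimer.dimer_id, "skipped_both_present", sweep,
                                {"note": f"max_copies reached for {new_protein}"})
            assembly.decision_log.append(decision)
            return decision
        _, shared_chain = dimer.chain_for(shared)
        _, new_chain = dimer.chain_for(new_protein)

        best_tm = 0.0
        clash_seen: Optional[float] = None
        placed_ok = None
        for placed in assembly.copies_of(shared):
            sup = tm_score(shared_chain, placed.chain)
            best_tm = max(best_tm, sup.tm_score)
            if not sup.tm_score > params.tm_min:
                continue
            # placement transform: least-squares fit over all shared Cα
            mob, ref = _matched_shared_ca(shared_chain, placed.chain)
            transform, _ = kabsch(mob, ref)
            moved = _transformed_chain(new_chain, transform)
            frac = clash_fraction(moved, assembly, params.clash_distance)
            clash_seen = frac if clash_seen is None else min(clash_seen, frac)
            if frac > params.clash_fraction:
                continue
            placed_ok = (placed, transform, moved, sup.tm_score, frac)
            break

        if placed_ok is not None:
            placed, transform, moved, tm, frac = placed_ok
            copy_index = len(assembly.copies_of(new_protein))
            assembly.placed_chains.append(
                PlacedChain(
                    protein=new_protein,
                    copy_index=copy_index,
                    chain=moved,
                    source_dimer_id=dimer.dimer_id,
                    transform=transform,
                )
            )
            decision = Decision(
                dimer.dimer_id, "added", sweep,
                {"protein": new_protein, "shared_protein": shared,
                 "tm_score": tm, "clash_fraction": frac},
            )
        elif clash_seen is not None:
            decision = Decision(
                dimer.dimer_id, "rejected_clash", sweep,
                {"shared_protein": shared, "tm_score": best_tm,
                 "clash_fraction": clash_seen},
            )
        else:
            decision = Decision(
                dimer.dimer_id, "rejected_tm", sweep,
                {"shared_protein": shared, "tm_score": best_tm},
            )
    assembly.decision_log.append(decision)
    return decision


def _matched_shared_ca(mobile: Chain, reference: Chain) -> tuple[np.ndarray, np.ndarray]:
    ref_index = {r.key: r for r in reference.residues if r.ca is not None}
    mob, ref = [], []
    for res in mobile.residues:
        if res.ca is not None and res.key in ref_index:
            mob.append(res.ca.position)
            ref.append(ref_index[res.key].ca.position)
    if len(mob) < 3:
        raise ValueError("fewer than 3 matched Cα between shared chains")
    return np.vstack(mob), np.vstack(ref)


def assemble(dimers: list[DimerRecord], params: AssemblyParams | None = None) -> Assembly:
    """Run the greedy iterative build over a set of scored dimers.

    Seeds with the top-ranked dimer (or ``params.start_dimer``), sweeps
    the ranking attempting each remaining dimer, restarts the sweep after
    every addition, and stops when a sweep adds nothing.  Deterministic
    for identical inputs; every attempt appears in the decision log.
    """
    if not dimers:
        raise ValueError("need at least one dimer")
    params = params or AssemblyParams()
    ranked = rank_dimers(dimers)

    if params.start_dimer is not None:
        seeds = [d for d in ranked if d.dimer_id == params.start_dimer]
        if not seeds:
            raise KeyError(f"start dimer {params.start_dimer!r} not in input")
        seed = seeds[0]
    else:
        seed = ranked[0]

    assembly = Assembly(params=params)
    for protein, chain_id in (
        (seed.protein_a, seed.chain_id_a),
        (seed.protein_b, seed.chain_id_b),
    ):
        chain = copy.deepcopy(seed.structure.chain(chain_id))
        assembly.placed_chains.append(
            PlacedChain(
                protein=protein,
                copy_index=0,
                chain=chain,
                source_dimer_id=seed.dimer_id,
                transform=Transform.identity(),
            )
        )
    assembly.decision_log.append(
        Decision(seed.dimer_id, "seed", 0, {"pdockq": seed.pdockq})
    )

    used = {seed.dimer_id}
    sweep = 0
    while True:
        sweep += 1
        added_this_sweep = False
        for dimer in ranked:
            if dimer.dimer_id in used:
                continue
            decision = try_add_dimer(assembly, dimer, params, sweep=sweep)
            if decision.action == "added":
                used.add(dimer.dimer_id)
                added_this_sweep = True
                break  # restart the sweep from the top of the ranking
        if not added_this_sweep:
            break
    return assembly


def read_dimer_manifest(
    path: str | Path, scoring: ScoringParams | None = None
) -> list[DimerRecord]:
    """Load dimers from a manifest TSV.

    Columns: dimer_id, path, chain_id_a, protein_a, chain_id_b, protein_b
    and optionally pdockq (computed from the model when absent).  Relative
    model paths are resolved against the manifest location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"dimer_id", "path", "chain_id_a", "protein_a", "chain_id_b", "protein_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        model_path = Path(row.path)
        if not model_path.is_absolute():
            model_path = path.parent / model_path
        structure = read_structure(model_path)
        if "pdockq" in df.columns and not pd.isna(row.pdockq):
            score = float(row.pdockq)
        else:
            score = score_dimer(structure, row.chain_id_a, row.chain_id_b, scoring).pdockq
        records.append(
            DimerRecord(
                dimer_id=str(row.dimer_id),
                structure=structure,
                chain_id_a=str(row.chain_id_a),
                chain_id_b=str(row.chain_id_b),
                protein_a=str(row.protein_a),
                protein_b=str(row.protein_b),
                pdockq=score,
            )
        )
    return records


def extract_subdimers(
    structure: Structure,
    chain_proteins: dict[str, str],
    scoring: ScoringParams | None = None,
    id_prefix: str = "",
) -> list[DimerRecord]:
    """Decompose a k-mer model into its pairwise sub-dimers.

    Supports trimer-based building: every chain pair of the k-mer becomes
    a scored DimerRecord in the k-mer's own frame, usable directly by
    :func:`assemble`.
    """
    records = []
    ids = list(chain_proteins)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ca, cb = ids[i], ids[j]
            sub = Structure(
                id=f"{id_prefix}{chain_proteins[ca]}-{chain_proteins[cb]}",
                chains=[
                    copy.deepcopy(structure.chain(ca)),
                    copy.deepcopy(structure.chain(cb)),
                ],
            )
            score = score_dimer(sub, ca, cb, scoring).pdockq
            records.append(
                DimerRecord(
                    dimer_id=sub.id,
                    structure=sub,
                    chain_id_a=ca,
                    chain_id_b=cb,
                    protein_a=chain_proteins[ca],
                    protein_b=chain_proteins[cb],
                    pdockq=score,
                )
            )
    return records
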