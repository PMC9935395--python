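"""Interface detection and pDockQ confidence scoring for dimer models.

A residue is interfacial when any of its heavy atoms lies within a cutoff
(10 Å by default) of any heavy atom of the partner chain.  The pDockQ
score combines the mean plDDT over interface residues with the log of the
interface size through a fitted sigmoid,

    pDockQ = 0.707 / (1 + exp(-0.03148 (x - 388.06))) + 0.03138,
    x = <interface plDDT> * ln(n_interface_residues),

and estimates the DockQ quality a model would achieve against the true
complex.  Conventional confidence cut-offs: > 0.23 acceptable, > 0.5 high.

A separate, stricter geometric criterion distinguishes *direct* physical
interactions from co-complex neighbours: more than 20 Cα-Cα contacts
closer than 8 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, Structure

__all__ = [
    "ScoringParams",
    "DirectnessParams",
    "InterfaceResult",
    "DirectnessResult",
    "find_interface",
    "pdockq",
    "score_dimer",
    "classify_direct",
    "confidence_bin",
]


@dataclass(frozen=True)
class ScoringParams:
    """Sigmoid constants and the interface distance cutoff.

    The four constants were fitted against DockQ on a benchmark of
    experimentally solved dimers; the score range is
    (baseline, baseline + height) = (0.03138, 0.73838).
    """

    height: float = 0.707
    slope: float = 0.03148
    midpoint: float = 388.06
    baseline: float = 0.03138
    interface_cutoff: float = 10.0  # Å, heavy-atom

    def __post_init__(self) -> None:
        if self.height <= 0 or self.slope <= 0 or self.interface_cutoff <= 0:
            raise ValueError("height, slope and interface_cutoff must be positive")


@dataclass(frozen=True)
class DirectnessParams:
    """Direct-interaction rule: more than `min_contacts` Cα pairs under `ca_cutoff`."""

    ca_cutoff: float = 8.0  # Å, strict <
    min_contacts: int = 20  # strict >

    def __post_init__(self) -> None:
        if self.ca_cutoff <= 0:
            raise ValueError("ca_cutoff must be positive")


@dataclass
class InterfaceResult:
    """Interface geometry and (optionally) the pDockQ score of a chain pair.

    ``n_contacts`` counts interface *residues* summed over both chains, the
    quantity entering x = plDDT * ln(n_contacts).
    """

    chain_id_a: str
    chain_id_b: str
    residues_a: frozenset[tuple[int, str]]  # (seq_id, insertion_code)
    residues_b: frozenset[tuple[int, str]]
    mean_if_plddt: float = float("nan")
    x: float = float("nan")
    pdockq: float = float("nan")
    params: ScoringParams = field(default_factory=ScoringParams)

    @property
    def n_contacts(self) -> int:
        return len(self.residues_a) + len(self.residues_b)


@dataclass
class DirectnessResult:
    direct: bool
    n_ca_contacts: int
    params: DirectnessParams = field(default_factory=DirectnessParams)


def _chain_atom_table(chain: Chain) -> tuple[np.ndarray, list[int]]:
    """Heavy-atom coordinates plus, per atom, the index of its residue."""
    coords, owner = [], []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.position)
            owner.append(i)
    if not coords:
        raise ValueError(f"chain {chain.chain_id}: no heavy atoms")
    return np.vstack(coords), owner


def find_interface(
    chain_a: Chain,
    chain_b: Chain,
    cutoff: float = 10.0,
    params: ScoringParams | None = None,
) -> InterfaceResult:
    """Interface residue sets of a chain pair at a heavy-atom distance cutoff.

    A residue of one chain is interfacial iff any of its heavy atoms is
    within *cutoff* (inclusive) of any heavy atom of the other chain.
    ``mean_if_plddt`` pools interface residues of both chains with equal
    weight.  KD-trees accelerate the scan; results are identical to the
    all-pairs computation.
    """
    params = replace(params or ScoringParams(), interface_cutoff=cutoff)
    xyz_a, owner_a = _chain_atom_table(chain_a)
    xyz_b, owner_b = _chain_atom_table(chain_b)

    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=cutoff)
    idx_a: set[int] = set()
    idx_b: set[int] = set()
    for ia, neighbours in enumerate(pairs):
        if neighbours:
            idx_a.add(owner_a[ia])
            for ib in neighbours:
                idx_b.add(owner_b[ib])

    res_a = frozenset(chain_a.residues[i].key for i in idx_a)
    res_b = frozenset(chain_b.residues[i].key for i in idx_b)
    plddts = [chain_a.residues[i].plddt for i in idx_a]
    plddts += [chain_b.residues[i].plddt for i in idx_b]
    mean_plddt = float(np.mean(plddts)) if plddts else float("nan")
    return InterfaceResult(
        chain_id_a=chain_a.chain_id,
        chain_id_b=chain_b.chain_id,
        residues_a=res_a,
        residues_b=res_b,
        mean_if_plddt=mean_plddt,
        params=params,
    )


def pdockq(
    mean_if_plddt: float, n_contacts: int, params: ScoringParams | None = None
) -> float:
    """Evaluate the pDockQ sigmoid.

    ``n_contacts`` is the number of interface residues over both chains.
    Zero contacts means no interface: the score is defined as 0.0 rather
    than the sigmoid baseline.
    """
    params = params or ScoringParams()
    if n_contacts < 0:
        raise ValueError("n_contacts must be non-negative")
    if n_contacts == 0:
        return 0.0
    if not 0.0 <= mean_if_plddt <= 100.0:
        raise ValueError(f"mean interface plDDT {mean_if_plddt} outside [0, 100]")
    x = mean_if_plddt * math.log(n_contacts)
    return params.height / (1.0 + math.exp(-params.slope * (x - params.midpoint))) + params.baseline


def score_dimer(
    structure: Structure,
    chain_id_a: str,
    chain_id_b: str,
    params: ScoringParams | None = None,
) -> InterfaceResult:
    """Full interface + pDockQ evaluation of a two-chain model."""
    params = params or ScoringParams()
    result = find_interface(
        structure.chain(chain_id_a),
        structure.chain(chain_id_b),
        cutoff=params.interface_cutoff,
        params=params,
    )
    n = result.n_contacts
    if n > 0:
        result.x = result.mean_if_plddt * math.log(n)
        result.pdockq = pdockq(result.mean_if_plddt, n, params)
    else:
        result.pdockq = 0.0
    return result


def classify_direct(
    chain_a: Chain, chain_b: Chain, params: DirectnessParams | None = None
) -> DirectnessResult:
    """Direct vs indirect interaction by the Cα contact-count rule.

    Counts Cα-Cα pairs strictly closer than ``ca_cutoff``; the pair
    interacts directly iff the count strictly exceeds ``min_contacts``.
    """
    params = params or DirectnessParams()
    ca_a = chain_a.ca_coords()
    ca_b = chain_b.ca_coords()
    if ca_a.shape[0] == 0 or ca_b.shape[0] == 0:
        raise ValueError("both chains must contain Cα atoms")
    pairs = cKDTree(ca_a).query_ball_tree(cKDTree(ca_b), r=params.ca_cutoff)
    n = 0
    for ia, neighbours in enumerate(pairs):
        for ib in neighbours:
            # query_ball_tree is inclusive; the rule is strict <
            if np.linalg.norm(ca_a[ia] - ca_b[ib]) < params.ca_cutoff:
                n += 1
    return DirectnessResult(direct=n > params.min_contacts, n_ca_contacts=n, params=params)


def confidence_bin(
    score: float, cutoffs: tuple[float, float] = (0.23, 0.5)
) -> Literal["low", "acceptable", "high"]:
    """Bin a pDockQ score: > 0.5 high, > 0.23 acceptable, else low (strict)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"pDockQ {score} outside [0, 1]")
    lo, hi = cutoffs
    if score > hi:
        return "high"
    if score > lo:
        return "acceptable"
    return "low"
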