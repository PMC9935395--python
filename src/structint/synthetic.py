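"""Synthetic complexes, crosslinks and fold-change matrices with known truth.

Idealized generators replace downloaded model archives in tests and
examples: every fixture carries its exact ground truth (chain placements,
rigid motions relating each dimer's private frame to the complex frame,
planted crosslink statuses, planted co-regulation labels), so geometric
and statistical pipelines can be verified to numerical precision.

Chains are idealized poly-lysine α-helices (Cα/CB/NZ per residue, 1.5 Å
rise, 100° turn) laid out with parallel axes on a line, a ring, or a
packed grid.  The default 9 Å axis spacing makes adjacent chains share a
genuine interface (well over 20 Cα pairs under 8 Å) while non-adjacent
chains stay beyond contact range; generation asserts this post hoc.
plDDT profiles are written into the residues so confidence-dependent
code paths are exercised.  All randomness flows through
``numpy.random.default_rng(seed)``, making every fixture reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Transform
from .interface import DirectnessParams, classify_direct
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "SyntheticComplexSpec",
    "SyntheticComplex",
    "make_complex",
    "make_crosslinks",
    "make_fc_matrix",
    "random_rigid_transform",
]

_HELIX_RISE = 1.5  # Å per residue along the chain axis
_HELIX_RADIUS = 2.3  # Å, Cα radius about the axis
_HELIX_TURN = np.deg2rad(100.0)


@dataclass(frozen=True)
class SyntheticComplexSpec:
    n_chains: int = 5
    residues_per_chain: int = 30
    geometry: str = "ring"  # ring | chain | packed
    spacing: float = 9.0  # Å between adjacent chain axes
    plddt_profile: str = "constant"  # constant | gradient | noisy
    plddt_value: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if self.residues_per_chain < 10:
            raise ValueError("need at least 10 residues per chain")
        if self.geometry not in ("ring", "chain", "packed"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class SyntheticComplex:
    """A generated complex with its dimer decomposition and exact transforms."""

    spec: SyntheticComplexSpec
    structure: Structure  # ground-truth complex, chains A, B, ...
    dimers: list[Structure]  # each in its own (perturbed) frame, chains A/B
    dimer_pairs: list[tuple[int, int]]  # chain indices each dimer covers
    transforms: dict[str, Transform] = field(default_factory=dict)
    # transforms[dimer_id] maps the dimer's frame back onto the complex frame
    chain_proteins: dict[str, str] = field(default_factory=dict)


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 50.0) -> Transform:
    """A uniformly random proper rotation plus a bounded random translation."""
    # rotation from a random unit quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, size=3)
    return Transform(R, t)


def _axis_positions(spec: SyntheticComplexSpec) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Chain-axis xy positions and the adjacency (pairs at ~spacing)."""
    n, s = spec.n_chains, spec.spacing
    if spec.geometry == "chain":
        pos = np.array([[i * s, 0.0] for i in range(n)])
    elif spec.geometry == "ring":
        radius = s / (2.0 * np.sin(np.pi / n))
        angles = 2.0 * np.pi * np.arange(n) / n
        pos = np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])
    else:  # packed: snake-ordered grid so consecutive chains are neighbours
        ncol = int(np.ceil(np.sqrt(n)))
        pos = []
        for i in range(n):
            row, col = divmod(i, ncol)
            if row % 2 == 1:
                col = ncol - 1 - col
            pos.append([col * s, row * s])
        pos = np.array(pos)
    adjacency = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.linalg.norm(pos[i] - pos[j]) <= s * 1.01
    ]
    return pos, adjacency


def _plddt_values(spec: SyntheticComplexSpec, rng: np.random.Generator) -> np.ndarray:
    m = spec.residues_per_chain
    if spec.plddt_profile == "constant":
        return np.full(m, spec.plddt_value)
    if spec.plddt_profile == "gradient":
        return np.linspace(50.0, 95.0, m)
    if spec.plddt_profile == "noisy":
        return np.clip(rng.normal(85.0, 10.0, size=m), 0.0, 100.0)
    raise ValueError(f"unknown plddt profile {spec.plddt_profile!r}")


def _build_chain(
    chain_id: str,
    protein: str,
    axis_xy: np.ndarray,
    plddts: np.ndarray,
    phase: float,
) -> Chain:
    residues = []
    for k in range(len(plddts)):
        theta = phase + k * _HELIX_TURN
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = np.array([axis_xy[0], axis_xy[1], 0.0]) + _HELIX_RADIUS * radial
        ca[2] = k * _HELIX_RISE
        cb = ca + 1.5 * radial
        nz = ca + 4.0 * radial
        residues.append(
            Residue(
                seq_id=k + 1,
                aa_code="LYS",
                atoms=[
                    Atom("CA", "C", ca),
                    Atom("CB", "C", cb),
                    Atom("NZ", "N", nz),
                ],
                plddt=float(plddts[k]),
            )
        )
    return Chain(chain_id=chain_id, residues=residues, protein_accession=protein)


def make_complex(spec: SyntheticComplexSpec) -> SyntheticComplex:
    """Generate a ground-truth complex plus its adjacent-pair dimer models.

    Each dimer contains copies of its two chains moved into a private
    frame by a recorded random rigid motion; the recorded transform maps
    that frame back onto the complex, so assembly output can be compared
    with exact ground truth.  Generation verifies the adjacency contract
    (adjacent chains are direct interactions; non-adjacent chains share
    no Cα contacts) and raises if the spacing violates it.
    """
    rng = np.random.default_rng(spec.seed)
    axes, adjacency = _axis_positions(spec)
    import string

    labels = string.ascii_uppercase
    chains = []
    chain_proteins: dict[str, str] = {}
    for i in range(spec.n_chains):
        cid = labels[i] if i < 26 else f"C{i}"
        protein = f"P{i + 1:03d}"
        chains.append(
            _build_chain(cid, protein, axes[i], _plddt_values(spec, rng), phase=0.0)
        )
        chain_proteins[cid] = protein
    structure = Structure(id=f"synthetic_{spec.geometry}_{spec.n_chains}", chains=chains)

    # adjacency contract: direct where adjacent, no Cα contacts elsewhere
    direct_params = DirectnessParams()
    adj_set = set(adjacency)
    for i in range(spec.n_chains):
        for j in range(i + 1, spec.n_chains):
            res = classify_direct(chains[i], chains[j], direct_params)
            if (i, j) in adj_set and not res.direct:
                raise ValueError(
                    f"spacing {spec.spacing} Å leaves adjacent chains {i},{j} "
                    f"with only {res.n_ca_contacts} Cα contacts"
                )
            if (i, j) not in adj_set and res.n_ca_contacts > 0:
                raise ValueError(
                    f"spacing {spec.spacing} Å gives non-adjacent chains {i},{j} "
                    f"{res.n_ca_contacts} Cα contacts"
                )

    dimers: list[Structure] = []
    transforms: dict[str, Transform] = {}
    import copy as _copy

    for i, j in adjacency:
        dimer_id = f"{chain_proteins[chains[i].chain_id]}-{chain_proteins[chains[j].chain_id]}"
        to_dimer = random_rigid_transform(rng)
        pair = []
        for idx, new_id in ((i, "A"), (j, "B")):
            chain = _copy.deepcopy(chains[idx])
            chain.chain_id = new_id
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = to_dimer.apply(atom.position)
            pair.append(chain)
        dimers.append(Structure(id=dimer_id, chains=pair))
        transforms[dimer_id] = to_dimer.inverse()

    return SyntheticComplex(
        spec=spec,
        structure=structure,
        dimers=dimers,
        dimer_pairs=adjacency,
        transforms=transforms,
        chain_proteins=chain_proteins,
    )


def make_crosslinks(
    complex_structure: Structure,
    n_links: int,
    satisfied_fraction: float,
    seed: int = 0,
    max_distance: float = 32.0,
) -> pd.DataFrame:
    """Sample inter-chain lysine NZ pairs with planted satisfaction statuses.

    Approximately *satisfied_fraction* of the links are drawn from pairs
    within *max_distance* (rounded to the nearest count), the rest from
    pairs beyond it.  The returned table carries the expected status for
    assertion against :func:`structint.crosslinks.validate_crosslinks`.
    """
    if not 0.0 <= satisfied_fraction <= 1.0:
        raise ValueError("satisfied_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lysines = []  # (protein, seq_id, nz_position)
    for chain in complex_structure.chains:
        protein = chain.protein_accession or chain.chain_id
        for res in chain.residues:
            nz = res.atom("NZ")
            if res.aa_code == "LYS" and nz is not None:
                lysines.append((protein, res.seq_id, nz.position, chain.chain_id))
    if len(lysines) < 2:
        raise ValueError("complex has insufficient lysine NZ atoms")

    near, far = [], []
    for ia in range(len(lysines)):
        for ib in range(ia + 1, len(lysines)):
            if lysines[ia][3] == lysines[ib][3]:
                continue  # only inter-chain links
            d = float(np.linalg.norm(lysines[ia][2] - lysines[ib][2]))
            (near if d <= max_distance else far).append((ia, ib, d))

    n_sat = int(round(n_links * satisfied_fraction))
    n_vio = n_links - n_sat
    if n_sat > len(near) or n_vio > len(far):
        raise ValueError(
            f"cannot plant {n_sat} satisfied / {n_vio} violated links "
            f"(available: {len(near)} / {len(far)})"
        )
    chosen = [(near[k], "satisfied") for k in rng.choice(len(near), n_sat, replace=False)] if n_sat else []
    chosen += [(far[k], "violated") for k in rng.choice(len(far), n_vio, replace=False)] if n_vio else []

    rows = []
    for (ia, ib, d), status in chosen:
        pa, ra, _, _ = lysines[ia]
        pb, rb, _, _ = lysines[ib]
        rows.append(
            {
                "protein_a": pa,
                "residue_a": ra,
                "protein_b": pb,
                "residue_b": rb,
                "true_distance": round(d, 3),
                "expected_status": status,
            }
        )
    return pd.DataFrame(rows)


def make_fc_matrix(
    n_sites: int = 60,
    n_conditions: int = 40,
    n_clusters: int = 3,
    signal_sd: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted co-regulation: cluster latent signal plus independent noise.

    Each cluster draws one latent log2 fold change per condition from
    N(0, signal_sd²); each member site observes it plus N(0, noise_sd²)
    noise.  Defaults give a 10:1 signal-to-noise ratio, a regime where
    within-cluster correlations approach 1 and the clustering pipeline
    should recover the labels essentially perfectly.  Returns the matrix
    (rows indexed by (protein, position)) and the true labels.
    """
    if not n_sites >= n_clusters >= 1:
        raise ValueError("need n_sites >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, signal_sd, size=(n_clusters, n_conditions))
    labels = np.arange(n_sites) % n_clusters + 1
    values = latent[labels - 1] + rng.normal(0.0, noise_sd, size=(n_sites, n_conditions))
    index = pd.MultiIndex.from_tuples(
        [(f"P{i // 5 + 1:03d}", 10 * (i % 5) + 3) for i in range(n_sites)],
        names=["protein", "position"],
    )
    matrix = pd.DataFrame(
        values, index=index, columns=[f"cond_{j + 1}" for j in range(n_conditions)]
    )
    return matrix, pd.Series(labels, index=index, name="true_cluster")
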