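"""Rigid-body superposition primitives: Kabsch, RMSD and TM-score.

These are the geometric workhorses of multimer assembly: the Kabsch
algorithm gives the closed-form least-squares proper rotation between two
matched point sets; TM-score gives a length-normalised similarity in
(0, 1] that is robust to locally divergent regions, using the standard
scale factor

    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8,   floored at 0.5 Å,

with L the reference length.  TM-score maximisation follows the classic
fragment-seeded scheme: superpose on windows of decreasing length, then
iteratively re-superpose on the residues currently within d0 until the
included set stops changing, keeping the best score over all seeds.
Correspondence between chains is by residue number (or an explicit map);
sequence-independent alignment is out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structure import Chain, Structure

__all__ = [
    "Transform",
    "SuperpositionResult",
    "kabsch",
    "tm_d0",
    "tm_score",
    "assembly_rmsd",
]


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply *other* first, then *self*."""
        return Transform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: Transform
    rmsd: float
    n_matched: int
    tm_score: float = float("nan")


def kabsch(points_p: np.ndarray, points_q: np.ndarray) -> tuple[Transform, float]:
    """Least-squares proper rotation + translation mapping P onto Q.

    Reflections are suppressed (det = +1), so mirror-image inputs keep a
    positive residual instead of being flipped.  Requires n >= 3
    non-collinear points.
    """
    P = np.asarray(points_p, dtype=float)
    Q = np.asarray(points_q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def tm_d0(length: int) -> float:
    """TM-score distance scale for a reference of *length* residues."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _matched_ca(
    mobile: Chain, reference: Chain, correspondence: dict | None
) -> tuple[np.ndarray, np.ndarray]:
    """Matched Cα coordinate arrays (mobile, reference).

    Default correspondence pairs residues sharing (seq_id, insertion_code);
    an explicit map {mobile_key: reference_key} overrides it (int keys are
    shorthand for (seq_id, "")).
    """

    def norm(k):
        return (k, "") if isinstance(k, int) else tuple(k)

    ref_index = {r.key: r for r in reference.residues if r.ca is not None}
    pairs = []
    if correspondence is None:
        for res in mobile.residues:
            if res.ca is not None and res.key in ref_index:
                pairs.append((res.ca.position, ref_index[res.key].ca.position))
    else:
        mob_index = {r.key: r for r in mobile.residues if r.ca is not None}
        for mk, rk in correspondence.items():
            mk, rk = norm(mk), norm(rk)
            if mk in mob_index and rk in ref_index:
                pairs.append((mob_index[mk].ca.position, ref_index[rk].ca.position))
    if not pairs:
        raise ValueError("empty correspondence between chains")
    mob = np.vstack([p[0] for p in pairs])
    ref = np.vstack([p[1] for p in pairs])
    return mob, ref


def _tm_from_transform(
    transform: Transform, mob: np.ndarray, ref: np.ndarray, d0: float, L: int
) -> float:
    d = np.linalg.norm(transform.apply(mob) - ref, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)


def _refine(
    transform: Transform, mob: np.ndarray, ref: np.ndarray, d0: float, max_iter: int = 20
) -> Transform:
    """Iteratively re-superpose on residues within d0 until a fixed point."""
    included = None
    for _ in range(max_iter):
        d = np.linalg.norm(transform.apply(mob) - ref, axis=1)
        new = np.nonzero(d < d0)[0]
        if new.size < 3 or (included is not None and np.array_equal(new, included)):
            break
        included = new
        try:
            transform, _ = kabsch(mob[new], ref[new])
        except ValueError:
            break
    return transform


def tm_score(
    mobile: Chain,
    reference: Chain,
    correspondence: dict | None = None,
    reference_length: int | None = None,
) -> SuperpositionResult:
    """TM-score of *mobile* against *reference* over matched Cα positions.

    Normalised by the reference chain length (overridable).  The reported
    transform is the one achieving the best score; rmsd is over all
    matched pairs under that transform.
    """
    mob, ref = _matched_ca(mobile, reference, correspondence)
    n = mob.shape[0]
    L = reference_length if reference_length is not None else sum(
        1 for r in reference.residues if r.ca is not None
    )
    if L < 3:
        raise ValueError("reference too short (need >= 3 residues)")
    d0 = tm_d0(L)

    best_tm = -1.0
    best_transform = Transform.identity()
    seed_len = n
    seed_lens = []
    while seed_len >= 4:
        seed_lens.append(seed_len)
        seed_len //= 2
    if not seed_lens:  # tiny chains: single full-length seed
        seed_lens = [n]
    for sl in seed_lens:
        step = max(1, sl // 2)
        for start in range(0, n - sl + 1, step):
            window = slice(start, start + sl)
            try:
                transform, _ = kabsch(mob[window], ref[window])
            except ValueError:
                continue
            transform = _refine(transform, mob, ref, d0)
            tm = _tm_from_transform(transform, mob, ref, d0, L)
            if tm > best_tm:
                best_tm = tm
                best_transform = transform
    if best_tm < 0:
        raise ValueError("no non-degenerate seed window found")
    rmsd = float(
        np.sqrt(np.mean(np.sum((best_transform.apply(mob) - ref) ** 2, axis=1)))
    )
    return SuperpositionResult(
        transform=best_transform, rmsd=rmsd, n_matched=n, tm_score=best_tm
    )


def _chain_pairings(
    model_chains: list[Chain], ref_chains: list[Chain], protein_map: dict[str, str]
) -> list[list[tuple[Chain, Chain]]]:
    """Candidate model-chain -> reference-chain assignments grouped by protein.

    For proteins with multiple copies every copy permutation (<= 8 copies)
    is enumerated; the caller picks the assignment minimising RMSD.
    """
    by_protein_model: dict[str, list[Chain]] = {}
    for c in model_chains:
        if c.protein_accession:
            by_protein_model.setdefault(c.protein_accession, []).append(c)
    by_protein_ref: dict[str, list[Chain]] = {}
    for c in ref_chains:
        acc = protein_map.get(c.chain_id, c.protein_accession)
        if acc:
            by_protein_ref.setdefault(acc, []).append(c)

    per_protein: list[list[list[tuple[Chain, Chain]]]] = []
    for acc, mods in sorted(by_protein_model.items()):
        refs = by_protein_ref.get(acc)
        if not refs:
            continue
        k = min(len(mods), len(refs))
        options: list[list[tuple[Chain, Chain]]] = []
        if len(refs) <= 8:
            for perm in itertools.permutations(refs, k):
                options.append(list(zip(mods[:k], perm)))
        else:
            options.append(list(zip(mods[:k], refs[:k])))
        per_protein.append(options)
    if not per_protein:
        raise ValueError("no chains matched between model and reference")

    assignments = []
    for combo in itertools.product(*per_protein):
        assignments.append([pair for group in combo for pair in group])
    return assignments


def assembly_rmsd(
    model_assembly: Structure,
    reference_structure: Structure,
    protein_map: dict[str, str] | None = None,
) -> SuperpositionResult:
    """Global Cα RMSD and TM-score of an assembled model against a reference.

    Chains are matched by protein accession (*protein_map* translates
    reference chain ids to accessions); with multiple copies of a protein,
    the copy assignment minimising RMSD is used.  A single rigid
    superposition over all matched Cα gives both RMSD and TM-score, the
    latter normalised by the reference's total Cα count.
    """
    protein_map = protein_map or {}
    L_ref = sum(
        1 for c in reference_structure.chains for r in c.residues if r.ca is not None
    )
    d0 = tm_d0(L_ref)

    best: SuperpositionResult | None = None
    for assignment in _chain_pairings(
        model_assembly.chains, reference_structure.chains, protein_map
    ):
        mob_parts, ref_parts = [], []
        for mod_chain, ref_chain in assignment:
            try:
                m, r = _matched_ca(mod_chain, ref_chain, None)
            except ValueError:
                continue
            mob_parts.append(m)
            ref_parts.append(r)
        if not mob_parts:
            continue
        mob = np.vstack(mob_parts)
        ref = np.vstack(ref_parts)
        if mob.shape[0] < 3:
            continue
        transform, rmsd = kabsch(mob, ref)
        if best is None or rmsd < best.rmsd:
            tm = _tm_from_transform(transform, mob, ref, d0, L_ref)
            best = SuperpositionResult(
                transform=transform, rmsd=rmsd, n_matched=mob.shape[0], tm_score=tm
            )
    if best is None:
        raise ValueError("no chains matched between model and reference")
    return best
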