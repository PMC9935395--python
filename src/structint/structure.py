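"""Macromolecular structure I/O with per-residue model confidence.

Reads and writes PDB / mmCIF coordinate files and exposes a small
hierarchical model (Structure > Chain > Residue > Atom).  Structure
prediction pipelines in the AlphaFold tradition store the per-residue
plDDT confidence (0-100) in the B-factor column; this module surfaces it
as ``Residue.plddt`` so every downstream distance rule can weight or
filter residues by confidence.

Parsing is delegated to gemmi; only heavy atoms are retained by default
and multi-model files contribute their first model only.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "disorder_fraction",
]

# chain labels usable in single-character PDB chain id field
_PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed into a usable model."""


@dataclass
class Atom:
    """A heavy atom: label (CA, CB, NZ, ...), element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One residue with author numbering and the plDDT carried by its atoms."""

    seq_id: int
    aa_code: str
    atoms: list[Atom] = field(default_factory=list)
    plddt: float = 0.0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"plddt {self.plddt} outside [0, 100]")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    protein_accession: Optional[str] = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.chain_id}: duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, seq_id: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        return None

    def heavy_atom_coords(self) -> np.ndarray:
        """All heavy-atom positions, shape (n_atoms, 3)."""
        coords = [a.position for r in self.residues for a in r.atoms]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)

    def ca_coords(self) -> np.ndarray:
        """Cα positions in residue order; residues lacking Cα are skipped."""
        coords = [r.ca.position for r in self.residues if r.ca is not None]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: Optional[str] = None
    format: Optional[str] = None  # "pdb" | "mmcif"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in structure")

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not in structure {self.id!r}; "
            f"available: {', '.join(self.chain_ids)}"
        )


def _detect_format(path: Path, hint: Optional[str]) -> str:
    if hint is not None:
        h = hint.lower()
        if h in ("pdb", "mmcif", "cif"):
            return "mmcif" if h == "cif" else h
        raise ValueError(f"unknown format hint {hint!r}")
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # content sniff: mmCIF files start with a data block
    with open(path) as fh:
        head = fh.read(4096)
    return "mmcif" if head.lstrip().startswith(("data_", "#")) else "pdb"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins, ties broken by altloc label order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(
    path: str | Path,
    format_hint: Optional[str] = None,
    keep_hydrogens: bool = False,
    include_ligands: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Heavy atoms only unless *keep_hydrogens*; waters are always dropped and
    other heteroatoms unless *include_ligands*.  Multi-model files use the
    first model.  Per-residue plDDT is taken from the B-factor column (the
    Cα value when atoms of a residue disagree).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no atoms parsed")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            if gres.het_flag == "H" and not include_ligands:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for gatom in gres:
                if gatom.is_hydrogen() and not keep_hydrogens:
                    continue
                by_name.setdefault(gatom.name, []).append(gatom)
            atoms = []
            bfactors = {}
            for name, alts in sorted(by_name.items()):
                ga = _pick_altloc(alts)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    )
                )
                bfactors[name] = ga.b_iso
            if not atoms:
                continue
            plddt = bfactors.get("CA", next(iter(bfactors.values())))
            residues.append(
                Residue(
                    seq_id=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    aa_code=gres.name,
                    atoms=atoms,
                    plddt=float(np.clip(plddt, 0.0, 100.0)),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureParseError(f"{path}: no atoms parsed")
    return Structure(
        id=st.name or path.stem, chains=chains, source_path=str(path), format=fmt
    )


def _to_gemmi(structure: Structure, chain_ids: dict[str, str]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain_ids[chain.chain_id])
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa_code
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.b_iso = res.plddt
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    structure: Structure, path: str | Path, format: Optional[str] = None
) -> dict[str, str]:
    """Write *structure* to *path* as PDB or mmCIF (inferred from extension).

    Chain ids illegal for single-character PDB fields are deterministically
    relabeled A, B, C, ...; the returned mapping records original -> written
    id.  More than 62 chains cannot be expressed in PDB format.
    """
    path = Path(path)
    fmt = _detect_format(path, format) if format or path.suffix else "pdb"

    ids = structure.chain_ids
    if fmt == "pdb":
        if len(ids) > len(_PDB_CHAIN_IDS):
            raise ValueError(
                f"{len(ids)} chains exceed PDB's {len(_PDB_CHAIN_IDS)} chain ids; "
                "write mmCIF instead"
            )
        if all(len(i) == 1 for i in ids) and len(set(ids)) == len(ids):
            mapping = {i: i for i in ids}
        else:
            mapping = {i: _PDB_CHAIN_IDS[k] for k, i in enumerate(ids)}
    else:
        mapping = {i: i for i in ids}

    st = _to_gemmi(structure, mapping)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return mapping


def disorder_fraction(chain: Chain, plddt_threshold: float = 50.0) -> float:
    """Fraction of residues predicted disordered: plDDT strictly below threshold.

    plDDT is on the 0-100 scale, so the conventional disorder cut is 50.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id}: empty chain")
    n_dis = sum(1 for r in chain.residues if r.plddt < plddt_threshold)
    return n_dis / len(chain.residues)
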