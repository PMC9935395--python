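"""Crosslink distance validation against complex models.

Lysine-reactive crosslinkers covalently bridge ε-amino groups whose
spatial separation fits the linker geometry; an identified crosslink
between two proteins therefore constrains the modelled complex.  A link
is *satisfied* when the Euclidean NZ-NZ distance between the two lysines
is within a maximal span (32 Å by default, covering common Lys-Lys
linkers), *violated* when it exceeds it, and *unevaluable* when either
residue is missing, not a lysine, or lacks its NZ atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .structure import Structure

__all__ = [
    "CrosslinkRecord",
    "validate_crosslinks",
    "crosslink_support_by_bin",
    "read_links_table",
    "read_chain_map",
]

LINK_COLUMNS = ["protein_a", "residue_a", "protein_b", "residue_b"]


@dataclass
class CrosslinkRecord:
    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    measured_distance: Optional[float]  # Å, NZ-NZ; None when unevaluable
    status: str  # satisfied | violated | unevaluable
    max_distance: float = 32.0
    reason: Optional[str] = None  # set when unevaluable


def read_links_table(path: str | Path) -> pd.DataFrame:
    """Read a crosslink TSV with columns protein_a, residue_a, protein_b, residue_b."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"links table missing columns: {missing}")
    return df


def read_chain_map(path: str | Path) -> dict[str, str]:
    """Read a protein-accession -> chain-id TSV (columns protein, chain_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"protein", "chain_id"}.issubset(df.columns):
        raise ValueError("chain map needs columns: protein, chain_id")
    return dict(zip(df["protein"].astype(str), df["chain_id"].astype(str)))


def _nz_position(structure: Structure, chain_id: str, seq_id: int):
    """NZ coordinates of a lysine, or (None, reason) when unevaluable."""
    chain = structure.chain(chain_id)
    res = chain.residue(int(seq_id))
    if res is None:
        return None, f"residue {seq_id} absent from chain {chain_id}"
    if res.aa_code != "LYS":
        return None, f"residue {chain_id}/{seq_id} is {res.aa_code}, not LYS"
    nz = res.atom("NZ")
    if nz is None:
        return None, f"residue {chain_id}/{seq_id} lacks NZ atom"
    return nz.position, None


def validate_crosslinks(
    structure: Structure,
    links_table: pd.DataFrame,
    chain_map: dict[str, str],
    max_distance: float = 32.0,
) -> tuple[list[CrosslinkRecord], dict]:
    """Evaluate each crosslink against the model's NZ-NZ distances.

    *chain_map* resolves protein accessions to chain ids; an accession
    missing from it is an error (the table cannot be interpreted), while a
    missing residue or atom merely marks that link unevaluable.  Returns
    the per-link records and a summary with counts per status and the
    satisfied fraction among evaluable links.
    """
    records: list[CrosslinkRecord] = []
    for row in links_table.itertuples(index=False):
        pa, pb = str(row.protein_a), str(row.protein_b)
        for p in (pa, pb):
            if p not in chain_map:
                raise KeyError(
                    f"protein {p!r} not in chain map (known: {sorted(chain_map)})"
                )
        pos_a, why_a = _nz_position(structure, chain_map[pa], row.residue_a)
        pos_b, why_b = _nz_position(structure, chain_map[pb], row.residue_b)
        if pos_a is None or pos_b is None:
            records.append(
                CrosslinkRecord(
                    pa, int(row.residue_a), pb, int(row.residue_b),
                    measured_distance=None, status="unevaluable",
                    max_distance=max_distance, reason=why_a or why_b,
                )
            )
            continue
        dist = float(np.linalg.norm(pos_a - pos_b))
        status = "satisfied" if dist <= max_distance else "violated"
        records.append(
            CrosslinkRecord(
                pa, int(row.residue_a), pb, int(row.residue_b),
                measured_distance=dist, status=status, max_distance=max_distance,
            )
        )

    counts = {s: sum(1 for r in records if r.status == s)
              for s in ("satisfied", "violated", "unevaluable")}
    n_eval = counts["satisfied"] + counts["violated"]
    summary = {
        "counts": counts,
        "n_links": len(records),
        "n_evaluable": n_eval,
        "fraction_satisfied": counts["satisfied"] / n_eval if n_eval else float("nan"),
        "any_satisfied": counts["satisfied"] > 0,
    }
    return records, summary


def crosslink_support_by_bin(
    model_records: dict[str, list[CrosslinkRecord]],
    pdockq_scores: dict[str, float],
    cutoffs: tuple[float, float] = (0.23, 0.5),
) -> pd.DataFrame:
    """Fraction of models with >= 1 satisfied link, per pDockQ confidence bin.

    Models whose links are all unevaluable are excluded from denominators.
    """
    from .interface import confidence_bin

    rows = []
    for model_id, records in model_records.items():
        evaluable = [r for r in records if r.status != "unevaluable"]
        if not evaluable or model_id not in pdockq_scores:
            continue
        rows.append(
            {
                "model_id": model_id,
                "bin": confidence_bin(pdockq_scores[model_id], cutoffs),
                "supported": any(r.status == "satisfied" for r in evaluable),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["bin", "n_models", "fraction_supported"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("bin", sort=False)
        .agg(n_models=("supported", "size"), fraction_supported=("supported", "mean"))
        .reset_index()
    )
    order = {"low": 0, "acceptable": 1, "high": 2}
    return out.sort_values("bin", key=lambda s: s.map(order)).reset_index(drop=True)
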