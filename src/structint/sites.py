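"""Mapping mutations and phosphosites onto predicted interfaces.

Given the interface residue sets of confidently modelled dimers, a site
table (protein, 1-based position, class) is annotated with whether each
site falls on an interface and with which partner.  Two interface-level
statistics follow: enrichment of one site class over another at interface
versus non-interface modelled positions (Fisher's exact test on the 2x2
table), and a recurrence ranking of interfaces by mutations per interface
position, flagging the top quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interface import InterfaceResult
from .structure import Structure

__all__ = [
    "DimerInterface",
    "EnrichmentResult",
    "dimer_interface",
    "map_sites",
    "interface_enrichment",
    "recurrence_rank",
]


@dataclass(frozen=True)
class DimerInterface:
    """Interface of one scored dimer expressed in protein coordinates."""

    dimer_id: str
    protein_a: str
    protein_b: str
    interface_a: frozenset[int]  # seq_ids of interface residues of protein_a
    interface_b: frozenset[int]
    modeled_a: frozenset[int]  # all modelled seq_ids (the enrichment denominator)
    modeled_b: frozenset[int]

    @property
    def n_interface_positions(self) -> int:
        return len(self.interface_a) + len(self.interface_b)


@dataclass
class EnrichmentResult:
    """2x2 interface enrichment of site class 1 versus class 2.

    a/b: class-1 sites at / away from interfaces; c/d: same for class 2.
    fold = (a/(a+b)) / (c/(c+d)); p from Fisher's exact test.
    """

    a: int
    b: int
    c: int
    d: int
    fold_enrichment: float
    p_value: float
    test_name: str = "fisher_exact_two_sided"


def dimer_interface(
    structure: Structure,
    result: InterfaceResult,
    protein_a: str,
    protein_b: str,
    dimer_id: str | None = None,
) -> DimerInterface:
    """Express an :class:`InterfaceResult` in protein (UniProt-style) positions."""
    chain_a = structure.chain(result.chain_id_a)
    chain_b = structure.chain(result.chain_id_b)
    return DimerInterface(
        dimer_id=dimer_id or f"{protein_a}-{protein_b}",
        protein_a=protein_a,
        protein_b=protein_b,
        interface_a=frozenset(seq for seq, _ in result.residues_a),
        interface_b=frozenset(seq for seq, _ in result.residues_b),
        modeled_a=frozenset(r.seq_id for r in chain_a.residues),
        modeled_b=frozenset(r.seq_id for r in chain_b.residues),
    )


def map_sites(
    interfaces: list[DimerInterface], sites_table: pd.DataFrame
) -> pd.DataFrame:
    """Annotate sites with interface membership, one row per site x interface.

    A site is at an interface iff its (protein, position) matches an
    interface residue of a dimer involving that protein.  Sites on
    proteins absent from every dimer, or at positions outside the modelled
    range, keep ``at_interface = NA``.
    """
    required = {"protein", "position", "site_class"}
    if not required.issubset(sites_table.columns):
        raise ValueError(f"sites table needs columns {sorted(required)}")

    rows = []
    for site in sites_table.itertuples(index=False):
        protein, pos = str(site.protein), int(site.position)
        matched_any = False
        for iface in interfaces:
            for own, iface_set, modeled, partner in (
                ("a", iface.interface_a, iface.modeled_a, iface.protein_b),
                ("b", iface.interface_b, iface.modeled_b, iface.protein_a),
            ):
                this = iface.protein_a if own == "a" else iface.protein_b
                if this != protein:
                    continue
                matched_any = True
                if pos not in modeled:
                    warnings.warn(
                        f"site {protein}/{pos} outside modelled residues of "
                        f"{iface.dimer_id}",
                        stacklevel=2,
                    )
                    at_if = pd.NA
                else:
                    at_if = pos in iface_set
                rows.append(
                    {
                        "protein": protein,
                        "position": pos,
                        "site_class": site.site_class,
                        "dimer_id": iface.dimer_id,
                        "at_interface": at_if,
                        "partner_protein": partner if at_if is True else pd.NA,
                    }
                )
        if not matched_any:
            rows.append(
                {
                    "protein": protein,
                    "position": pos,
                    "site_class": site.site_class,
                    "dimer_id": pd.NA,
                    "at_interface": pd.NA,
                    "partner_protein": pd.NA,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "position", "site_class",
            "dimer_id", "at_interface", "partner_protein",
        ],
    )


def interface_enrichment(
    annotated_sites: pd.DataFrame,
    class1: str = "pathogenic",
    class2: str = "benign",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fold enrichment of *class1* over *class2* at interface residues.

    Each (protein, position) counts once even when the protein occurs in
    several dimers; a position is interfacial if any dimer marks it so.
    """
    df = annotated_sites.dropna(subset=["at_interface"])
    per_site = (
        df.groupby(["protein", "position", "site_class"], sort=False)["at_interface"]
        .any()
        .reset_index()
    )
    sub1 = per_site[per_site["site_class"] == class1]
    sub2 = per_site[per_site["site_class"] == class2]
    a = int(sub1["at_interface"].sum())
    b = len(sub1) - a
    c = int(sub2["at_interface"].sum())
    d = len(sub2) - c
    if len(sub1) == 0 or len(sub2) == 0 or c == 0:
        raise ValueError(
            "fold enrichment undefined (empty class or zero interface count in "
            f"{class2}); consider a pseudocount"
        )
    fold = (a / (a + b)) / (c / (c + d))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(a=a, b=b, c=c, d=d, fold_enrichment=fold, p_value=float(p),
                            test_name=f"fisher_exact_{alternative.replace('-', '_')}")


def recurrence_rank(
    cancer_sites: pd.DataFrame,
    interfaces: list[DimerInterface],
    top_fraction: float = 0.25,
) -> pd.DataFrame:
    """Rank interfaces by mutation density and flag the top quantile.

    Density is mutations per interface position (site rows are counted
    with multiplicity, so recurrent mutations appear as repeated rows).
    Interfaces at or above the (1 - top_fraction) density percentile are
    flagged; empty interfaces are excluded and a zero-density interface is
    never flagged.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    rows = []
    for iface in interfaces:
        n_pos = iface.n_interface_positions
        if n_pos == 0:
            continue
        n_mut = 0
        for site in cancer_sites.itertuples(index=False):
            protein, pos = str(site.protein), int(site.position)
            if protein == iface.protein_a and pos in iface.interface_a:
                n_mut += 1
            if protein == iface.protein_b and pos in iface.interface_b:
                n_mut += 1
        rows.append(
            {
                "dimer_id": iface.dimer_id,
                "n_interface_positions": n_pos,
                "n_mutations": n_mut,
                "density": n_mut / n_pos,
            }
        )
    df = pd.DataFrame(
        rows, columns=["dimer_id", "n_interface_positions", "n_mutations", "density"]
    )
    if df.empty:
        df["top_flag"] = pd.Series(dtype=bool)
        return df
    threshold = float(np.percentile(df["density"], 100 * (1 - top_fraction)))
    df["top_flag"] = (df["density"] >= threshold) & (df["density"] > 0)
    return df.sort_values("density", ascending=False).reset_index(drop=True)
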