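"""Calling QTL, grouping them into cross-trait QTL regions, interval overlap.

A QTL is a greedy peak: the most significant variant plus every significant
variant within 1 Mb, repeated until no significant variant remains. QTL from
different traits whose lead positions lie within 1 Mb (single-linkage, so
chains can extend further) form one QTL region (QTLR); within a QTLR any
trait whose best p-value is below the suggestive level (1e-7) but not
genome-wide significant is recorded as suggestive. Regulatory-catalogue
overlap is a plain interval test converting BED's 0-based half-open
intervals to the 1-based variant coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CredibleSet, GwasResult


@dataclass
class Qtl:
    """A single-trait association peak."""

    trait: str
    chrom: str
    lead: str
    lead_pos: int
    lead_p: float
    members: list[str] = field(default_factory=list)


@dataclass
class QtlRegion:
    """A cluster of QTL (possibly for several traits) within 1 Mb."""

    region_id: str
    chrom: str
    span: tuple[int, int]
    lead_by_trait: dict[str, tuple[str, int, float]]  # trait -> (id, pos, p)
    significant_traits: list[str]
    suggestive_traits: list[str]

    @property
    def best_lead(self) -> tuple[str, int, float]:
        return min(self.lead_by_trait.values(), key=lambda t: t[2])


def call_qtl(gwas: GwasResult, threshold: float, merge_distance: int = 1_000_000) -> list[Qtl]:
    """Greedy peak-picking of significant variants into per-trait QTL.

    Ties on p are broken by the lower position.
    """
    sig = gwas.significant(threshold).sort_values(["p", "pos"], kind="mergesort")
    out: list[Qtl] = []
    remaining = sig.copy()
    while len(remaining):
        top = remaining.iloc[0]
        same = remaining[
            (remaining["chrom"] == top["chrom"])
            & (np.abs(remaining["pos"] - top["pos"]) <= merge_distance)
        ]
        out.append(
            Qtl(
                trait=gwas.trait,
                chrom=str(top["chrom"]),
                lead=str(top["variant_id"]),
                lead_pos=int(top["pos"]),
                lead_p=float(top["p"]),
                members=[str(v) for v in same["variant_id"]],
            )
        )
        remaining = remaining.drop(same.index)
    return out


def build_qtlr(
    qtl_lists: dict[str, list[Qtl]],
    gwas_all: dict[str, GwasResult],
    merge_distance: int = 1_000_000,
    suggestive: float = 1e-7,
) -> list[QtlRegion]:
    """Single-linkage merge of per-trait QTL into QTL regions.

    Lead-to-lead distance <= ``merge_distance`` on the same chromosome links
    two QTL; transitive chaining is allowed. Suggestive traits are those
    whose best p within 1 Mb of any lead is below ``suggestive`` without
    reaching genome-wide significance anywhere in the region.
    """
    qtls = [q for trait in sorted(qtl_lists) for q in qtl_lists[trait]]
    if not qtls:
        return []
    # union-find over QTL
    parent = list(range(len(qtls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(qtls)):
        for j in range(i + 1, len(qtls)):
            if qtls[i].chrom == qtls[j].chrom and abs(
                qtls[i].lead_pos - qtls[j].lead_pos
            ) <= merge_distance:
                parent[find(i)] = find(j)

    groups: dict[int, list[Qtl]] = {}
    for i, q in enumerate(qtls):
        groups.setdefault(find(i), []).append(q)

    regions: list[QtlRegion] = []
    for members in groups.values():
        chrom = members[0].chrom
        lead_by_trait: dict[str, tuple[str, int, float]] = {}
        for q in members:
            cur = lead_by_trait.get(q.trait)
            if cur is None or q.lead_p < cur[2]:
                lead_by_trait[q.trait] = (q.lead, q.lead_pos, q.lead_p)
        significant = sorted(lead_by_trait)
        positions = [q.lead_pos for q in members]
        window = (min(positions) - merge_distance, max(positions) + merge_distance)
        suggestive_traits = []
        for trait, gw in gwas_all.items():
            if trait in lead_by_trait:
                continue
            t = gw.table
            inw = (
                (t["chrom"] == chrom)
                & (t["pos"] >= window[0])
                & (t["pos"] <= window[1])
                & t["p"].notna()
            )
            if inw.any() and t.loc[inw, "p"].min() < suggestive:
                suggestive_traits.append(trait)
        best = min(lead_by_trait.values(), key=lambda t: t[2])
        regions.append(
            QtlRegion(
                region_id=f"{chrom}:{best[1] // 1_000_000} Mb",
                chrom=chrom,
                span=(min(positions), max(positions)),
                lead_by_trait=lead_by_trait,
                significant_traits=significant,
                suggestive_traits=sorted(suggestive_traits),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.span[0]))
    return regions


def flag_overlap(
    targets: pd.DataFrame | CredibleSet,
    intervals: pd.DataFrame,
    variant_positions: pd.DataFrame | None = None,
) -> pd.Series:
    """True where a variant's 1-based position falls in a BED interval.

    BED interval [start, end) in 0-based coordinates covers 1-based bases
    start+1 .. end. ``targets`` is a DataFrame with chrom/pos columns, or a
    CredibleSet together with a chrom/pos lookup in ``variant_positions``.
    """
    if isinstance(targets, CredibleSet):
        if variant_positions is None:
            raise ValueError("variant_positions required for CredibleSet input")
        lookup = variant_positions.set_index("variant_id")
        targets = lookup.loc[targets.members, ["chrom", "pos"]].reset_index()
    flags = np.zeros(len(targets), dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        sel = targets["chrom"] == chrom
        if not sel.any():
            continue
        pos = targets.loc[sel, "pos"].to_numpy()
        hit = np.zeros(pos.shape, dtype=bool)
        for start, end in zip(sub["start"], sub["end"]):
            hit |= (pos >= start + 1) & (pos <= end)
        flags[np.flatnonzero(sel)] = hit
    index = (
        targets["variant_id"]
        if "variant_id" in targets.columns
        else targets.index
    )
    return pd.Series(flags, index=index, name="in_interval")
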