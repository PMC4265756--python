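"""Phylostratigraphy and network-shell analytics.

Given a family-by-species presence matrix and the panel's stratification,
each family's *first appearance* is the oldest stratum containing any
species where the family was detected (a Dollo-style reading: losses in
intermediate lineages never rejuvenate the origin).  From the assignment
follow the per-stratum counts of novel families, the fraction of the
network predating any chosen boundary, paralog-expansion curves, and the
shell structure of the interaction network around its cadherin-catenin
core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import InteractionEdgeList, SpeciesPanel

__all__ = [
    "StratumAssignment",
    "StratumCounts",
    "first_appearance",
    "novel_counts",
    "fraction_predating",
    "paralog_counts",
    "assign_shells",
]


@dataclass(frozen=True)
class StratumAssignment:
    """First-appearance stratum per family; all-absent families separately."""

    assigned: dict[str, str]
    unassigned: tuple[str, ...]


@dataclass(frozen=True)
class StratumCounts:
    """Novel families per stratum, ordered oldest to youngest."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, stratum: str) -> int:
        return self.counts[stratum]


def first_appearance(matrix: pd.DataFrame, panel: SpeciesPanel) -> StratumAssignment:
    """Oldest stratum with at least one present species, per family.

    ``matrix`` is boolean, families by species; its species must all be in
    the panel.  Families absent everywhere are reported as unassigned, not
    dropped.
    """
    unknown = sorted(set(matrix.columns) - set(panel.species_ids()))
    if unknown:
        raise ValueError(f"presence matrix species not in panel: {unknown}")
    stratum_of = {sp: panel.stratum_of(sp) for sp in matrix.columns}
    assigned: dict[str, str] = {}
    unassigned: list[str] = []
    for family, row in matrix.iterrows():
        present = [sp for sp, flag in row.items() if flag]
        if not present:
            unassigned.append(str(family))
            continue
        assigned[str(family)] = max(
            (stratum_of[sp] for sp in present), key=panel.stratum_age
        )
    return StratumAssignment(assigned=assigned, unassigned=tuple(unassigned))


def novel_counts(assignment: StratumAssignment, panel: SpeciesPanel) -> StratumCounts:
    """Histogram of first appearances over strata (oldest to youngest)."""
    counts = {stratum: 0 for stratum in reversed(panel.strata)}
    for stratum in assignment.assigned.values():
        counts[stratum] += 1
    return StratumCounts(counts=counts)


def fraction_predating(counts: StratumCounts, boundary: str, panel: SpeciesPanel) -> float:
    """Percentage of assigned families strictly older than ``boundary``.

    With the boundary at the oldest metazoan stratum this is the fraction
    of the network predating metazoans; with the boundary one stratum
    younger it becomes the fraction already present in basal metazoans.
    """
    boundary_age = panel.stratum_age(boundary)
    total = counts.total
    if total == 0:
        raise ValueError("no assigned families; fraction undefined")
    older = sum(
        n for stratum, n in counts.counts.items()
        if panel.stratum_age(stratum) > boundary_age
    )
    return 100.0 * older / total


def paralog_counts(
    analog_table: pd.DataFrame,
    component_families: Mapping[str, str],
    panel: SpeciesPanel,
    category_map: Mapping[str, str],
    focal_members: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Family-member counts per category over evolutionary time.

    ``analog_table`` lists accepted analogs (component, species, analog);
    ``component_families`` maps components to family ids and
    ``category_map`` maps family ids to a category (e.g. cadherins,
    cadherin-binding adaptors, actin-binding adaptors, adaptors).
    ``focal_members`` optionally supplies member counts per category in the
    focal species itself (the survey table carries no focal rows).

    Returns (per-stratum, per-species) tables.  The per-stratum value is
    the *maximum* member count over that stratum's species -- one value per
    stratum on the expansion curve; the per-species table is emitted
    alongside for transparency.
    """
    missing = sorted(
        set(analog_table["species_id"]) - set(panel.species_ids())
    )
    if missing:
        raise ValueError(f"analog table species not in panel: {missing}")
    categories = sorted(set(category_map.values()))
    species_ids = panel.species_ids()
    per_species = pd.DataFrame(0, index=categories, columns=species_ids)
    seen: set[tuple[str, str]] = set()
    for row in analog_table.itertuples():
        family = component_families.get(row.component_id)
        if family is None or family not in category_map:
            continue
        key = (row.analog_id, row.species_id)
        if key in seen:  # one member may be analogous to several components
            continue
        seen.add(key)
        per_species.loc[category_map[family], row.species_id] += 1
    if focal_members:
        for category, n in focal_members.items():
            per_species.loc[category, panel.focal_species_id] = n
    strata = list(reversed(panel.strata))  # oldest -> youngest
    per_stratum = pd.DataFrame(0, index=categories, columns=strata)
    for stratum in strata:
        cols = panel.species_in_stratum(stratum)
        if cols:
            per_stratum[stratum] = per_species[cols].max(axis=1)
    return per_stratum, per_species


def assign_shells(edges: InteractionEdgeList) -> dict[str, str]:
    """Classify components by graph distance to the network core.

    Distance 0 is ``core``, 1 is shell ``1`` (direct binders of the
    cadherin tail or a catenin), 2 is shell ``2`` (indirect), anything
    further -- or disconnected -- is ``outside``.
    """
    graph = nx.Graph()
    graph.add_nodes_from(edges.components)
    graph.add_edges_from(tuple(sorted(e)) for e in edges.edges)
    labels = {comp: "outside" for comp in edges.components}
    if edges.core:
        distances = nx.multi_source_dijkstra_path_length(
            graph, set(edges.core), weight=None
        )
        for comp, dist in distances.items():
            if dist == 0:
                labels[comp] = "core"
            elif dist == 1:
                labels[comp] = "1"
            elif dist == 2:
                labels[comp] = "2"
    return labels
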