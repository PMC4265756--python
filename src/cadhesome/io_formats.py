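"""Readers and writers for every on-disk artifact of the pipeline.

Conventions
-----------
* Coordinates in files are 1-based inclusive; in memory everything is
  0-based half-open.  Conversion happens here and only here.
* Sequences are uppercased on read and must use the 20 amino-acid letters
  plus ``X``; anything else is rejected rather than silently mapped.
* Tabular outputs begin with a ``#`` comment line naming the producing
  pipeline version and seed; readers skip ``#`` lines.  FASTA output stays
  comment-free because the format has no comment syntax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from . import __version__
from .architecture import DomainAnnotation

__all__ = [
    "FormatError",
    "ProteinRecord",
    "SpeciesProteome",
    "SpeciesInfo",
    "SpeciesPanel",
    "InteractionEdgeList",
    "read_fasta",
    "write_fasta",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_species_panel",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_edge_list",
    "VALID_RESIDUES",
]

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """An on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier and owning species."""

    protein_id: str
    species_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("empty protein id")
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.protein_id!r} has invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SpeciesProteome:
    """Ordered collection of unique-id protein records for one species."""

    def __init__(self, species_id: str, records: Iterable[ProteinRecord] = ()) -> None:
        self.species_id = species_id
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.protein_id in self._records:
            raise FormatError(
                f"duplicate protein id {record.protein_id!r} in proteome "
                f"{self.species_id!r}"
            )
        self._records[record.protein_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._records[protein_id]

    def ids(self) -> list[str]:
        return list(self._records)

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self._records.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpeciesProteome)
            and self.species_id == other.species_id
            and self._records == other._records
        )


@dataclass(frozen=True)
class SpeciesInfo:
    species_id: str
    display_name: str
    stratum_id: str


@dataclass
class SpeciesPanel:
    """The species set, its stratification and the focal species.

    ``strata`` is ordered youngest (the focal lineage's own stratum) to
    oldest.  The stratification is read along the focal lineage, so a
    *larger* stratum age means an *earlier* divergence from that lineage.
    """

    species: list[SpeciesInfo]
    strata: list[str]
    focal_species_id: str
    tree: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"species assigned more than once: {dups}")
        if len(set(self.strata)) != len(self.strata):
            raise FormatError("strata order contains duplicates")
        known = set(self.strata)
        for sp in self.species:
            if sp.stratum_id not in known:
                raise FormatError(
                    f"species {sp.species_id!r} maps to undeclared stratum "
                    f"{sp.stratum_id!r}"
                )
        by_id = {s.species_id: s for s in self.species}
        if self.focal_species_id not in by_id:
            raise FormatError(f"focal species {self.focal_species_id!r} not in panel")
        if by_id[self.focal_species_id].stratum_id != self.strata[0]:
            raise FormatError(
                f"focal species {self.focal_species_id!r} must sit in the "
                f"youngest stratum {self.strata[0]!r}"
            )

    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def stratum_of(self, species_id: str) -> str:
        for sp in self.species:
            if sp.species_id == species_id:
                return sp.stratum_id
        raise KeyError(species_id)

    def stratum_age(self, stratum_id: str) -> int:
        """Rank of a stratum: 0 = youngest, larger = older."""
        try:
            return self.strata.index(stratum_id)
        except ValueError:
            raise KeyError(f"unknown stratum {stratum_id!r}") from None

    def species_in_stratum(self, stratum_id: str) -> list[str]:
        return [s.species_id for s in self.species if s.stratum_id == stratum_id]


@dataclass
class InteractionEdgeList:
    """Undirected interaction edges plus the designated network core."""

    components: frozenset[str]
    edges: frozenset[frozenset[str]]
    core: frozenset[str]

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise FormatError(f"self-loop or malformed edge: {sorted(edge)}")
            stray = edge - self.components
            if stray:
                raise FormatError(f"edge endpoint not a declared component: {sorted(stray)}")
        stray = self.core - self.components
        if stray:
            raise FormatError(f"core id not a declared component: {sorted(stray)}")


def _output_header(seed: int | None) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# cadhesome v{__version__}{seed_part}\n"


def read_fasta(path: str | Path, species_id: str | None = None) -> SpeciesProteome:
    """Read one species' protein FASTA.

    The first whitespace-delimited token of each header is the protein id;
    the remainder is kept as the description.  ``species_id`` defaults to
    the file stem.  Duplicate ids, empty sequences and residues outside the
    20-letter alphabet plus ``X`` are format errors naming the record.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    proteome = SpeciesProteome(species_id)
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: malformed FASTA header")
            try:
                proteome.add(
                    ProteinRecord(
                        protein_id=rec.id,
                        species_id=species_id,
                        sequence=seq,
                        description=rec.description[len(rec.id) :].strip(),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: {exc}") from None
    return proteome


def write_fasta(proteome: SpeciesProteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in proteome:
            desc = f" {rec.description}" if rec.description else ""
            out.write(f">{rec.protein_id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


_ANNOTATION_COLUMNS = ["protein_id", "domain_name", "start", "end", "e_value", "source"]


def read_domain_annotations(
    path: str | Path, known_ids: Iterable[str] | None = None
) -> list[DomainAnnotation]:
    """Read a tab-separated domain-call table (SMART/CDD-style, parsed).

    Columns: protein_id, domain_name, start, end, e_value, source with
    1-based inclusive coordinates.  ``start > end`` or ``start < 1`` is a
    coordinate error.  Overlapping calls are returned untouched (overlap
    resolution belongs to :mod:`cadhesome.architecture`).  Ids absent from
    ``known_ids`` (when given) are allowed but logged as warnings, since
    annotation tables may be loaded before their proteome.
    """
    path = Path(path)
    known = set(known_ids) if known_ids is not None else None
    annotations: list[DomainAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[: len(_ANNOTATION_COLUMNS)] == _ANNOTATION_COLUMNS:
                continue  # header row
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 tab-separated columns")
            pid, name = fields[0], fields[1]
            try:
                start, end = int(fields[2]), int(fields[3])
                e_value = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start < 1:
                raise FormatError(
                    f"{path}:{lineno}: start {start} violates the 1-based convention"
                )
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            source = fields[5] if len(fields) > 5 else ""
            try:
                ann = DomainAnnotation(
                    protein_id=pid,
                    domain_name=name,
                    start=start - 1,
                    end=end,
                    e_value=e_value,
                    source=source,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if known is not None and pid not in known:
                logger.warning("%s:%d: annotation for unknown protein %r", path, lineno, pid)
            annotations.append(ann)
    return annotations


def write_domain_annotations(
    annotations: Sequence[DomainAnnotation], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as out:
        out.write(_output_header(seed))
        out.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            out.write(
                f"{a.protein_id}\t{a.domain_name}\t{a.start + 1}\t{a.end}\t"
                f"{a.e_value:g}\t{a.source}\n"
            )


def read_species_panel(
    newick_path: str | Path, strata_table_path: str | Path
) -> SpeciesPanel:
    """Read the species tree plus its stratum table.

    The strata table is tab-separated with columns species_id,
    display_name, stratum_id, stratum_rank, focal -- rank 0 is the youngest
    stratum (the focal lineage), larger ranks are older; exactly one
    species carries focal=1.  Newick leaf names must match the table.
    """
    tree = dendropy.Tree.get(
        path=str(newick_path), schema="newick", preserve_underscores=True
    )
    rows = pd.read_csv(strata_table_path, sep="\t", comment="#", dtype=str)
    required = {"species_id", "stratum_id", "stratum_rank", "focal"}
    missing = required - set(rows.columns)
    if missing:
        raise FormatError(f"{strata_table_path}: missing columns {sorted(missing)}")
    if rows["species_id"].duplicated().any():
        dups = sorted(rows.loc[rows["species_id"].duplicated(), "species_id"])
        raise FormatError(f"{strata_table_path}: species listed twice: {dups}")

    rank_of: dict[str, int] = {}
    for _, row in rows.iterrows():
        rank = int(row["stratum_rank"])
        stratum = row["stratum_id"]
        if stratum in rank_of and rank_of[stratum] != rank:
            raise FormatError(
                f"{strata_table_path}: stratum {stratum!r} given two ranks"
            )
        rank_of[stratum] = rank
    ranks = sorted(rank_of.values())
    if len(set(ranks)) != len(ranks):
        clashes = sorted({s for s, r in rank_of.items() if ranks.count(r) > 1})
        raise FormatError(f"{strata_table_path}: strata share a rank: {clashes}")
    strata = [s for s, _ in sorted(rank_of.items(), key=lambda kv: kv[1])]

    table_species = set(rows["species_id"])
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for leaf in sorted(leaves - table_species):
        raise FormatError(f"tree leaf {leaf!r} absent from the strata table")
    for sp in sorted(table_species - leaves):
        raise FormatError(f"table species {sp!r} absent from the tree")

    focal_rows = rows[rows["focal"].astype(int) == 1]
    if len(focal_rows) != 1:
        raise FormatError(
            f"{strata_table_path}: exactly one focal species required, "
            f"found {len(focal_rows)}"
        )
    species = [
        SpeciesInfo(
            species_id=row["species_id"],
            display_name=row.get("display_name", row["species_id"]) or row["species_id"],
            stratum_id=row["stratum_id"],
        )
        for _, row in rows.iterrows()
    ]
    return SpeciesPanel(
        species=species,
        strata=strata,
        focal_species_id=focal_rows.iloc[0]["species_id"],
        tree=tree,
    )


def write_presence_matrix(
    matrix: pd.DataFrame, path: str | Path, seed: int | None = None
) -> None:
    """Write a boolean family-by-species presence matrix as 0/1 TSV."""
    with open(path, "w") as out:
        out.write(_output_header(seed))
        out.write("family_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for family, row in matrix.iterrows():
            out.write(str(family) + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")


def read_presence_matrix(
    path: str | Path, panel: SpeciesPanel | None = None
) -> pd.DataFrame:
    path = Path(path)
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty presence matrix")
    header = lines[0].split("\t")
    if header[0] != "family_id":
        raise FormatError(f"{path}: first column must be family_id")
    species = header[1:]
    data: dict[str, list[bool]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})"
            )
        if fields[0] in data:
            raise FormatError(f"{path}:{lineno}: duplicate family {fields[0]!r}")
        for v in fields[1:]:
            if v not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: presence values must be 0/1, got {v!r}")
        data[fields[0]] = [v == "1" for v in fields[1:]]
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=species)
    matrix.index.name = "family_id"
    if panel is not None:
        unknown = sorted(set(species) - set(panel.species_ids()))
        if unknown:
            raise FormatError(f"{path}: species not in panel: {unknown}")
    return matrix.astype(bool)


def read_edge_list(
    edges_path: str | Path,
    core_path: str | Path,
    components_path: str | Path | None = None,
) -> InteractionEdgeList:
    """Read interaction edges (two tab-separated ids per line) and the core.

    ``components_path`` optionally declares the full component universe
    (one id per line), allowing isolated components; by default the
    universe is the union of edge endpoints and the core.
    """

    def _read_ids(p: str | Path) -> list[str]:
        with open(p) as handle:
            return [ln.strip() for ln in handle if ln.strip() and not ln.startswith("#")]

    edges: set[frozenset[str]] = set()
    endpoints: set[str] = set()
    with open(edges_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{edges_path}:{lineno}: expected two ids per line")
            a, b = fields[0], fields[1]
            if a == b:
                raise FormatError(f"{edges_path}:{lineno}: self-loop on {a!r}")
            edges.add(frozenset((a, b)))
            endpoints.update((a, b))
    core = set(_read_ids(core_path))
    if components_path is not None:
        components = set(_read_ids(components_path))
    else:
        components = endpoints | core
    return InteractionEdgeList(
        components=frozenset(components),
        edges=frozenset(edges),
        core=frozenset(core),
    )
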