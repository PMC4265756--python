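"""Reciprocal best-hit orthology gated by domain architecture.

The survey's unit of inference: a focal component's best hit in a target
proteome is *analogous* when (i) the hit's own best hit back in the focal
proteome is the original component or another member of its family, and
(ii) query and hit are built from the same major domains.  "Member of the
same family" operationalizes "a highly related component": families are
the pipeline's own notion of relatedness.  On rejection there is no
fall-back to the second-best forward hit -- only the lowest-E-value
sequence is ever retrieved.

Two extensions of the basic survey are provided: *iterative expansion*,
which re-seeds the search with analogs found in intermediate lineages
(e.g. sponge and Trichoplax) while always re-BLASTing back to the focal
proteome, and an all-against-all *characterization loop* that propagates
family labels to unknown sequences until a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._sw_kernel import sw_score_many
from .architecture import Architecture, Family, architectures_match
from .io_formats import ProteinRecord, SpeciesPanel, SpeciesProteome
from .sequence_search import ScoringScheme, SearchHit, best_hit, encode, local_align, score_statistics

__all__ = [
    "RBHResult",
    "REJECT_NO_FORWARD",
    "REJECT_RECIPROCAL",
    "REJECT_ARCHITECTURE",
    "reciprocal_best_hit",
    "run_survey",
    "iterative_expansion",
    "classify_iteratively",
]

REJECT_NO_FORWARD = "no-forward-hit"
REJECT_RECIPROCAL = "reciprocal-failure"
REJECT_ARCHITECTURE = "architecture-mismatch"

ANALOG_COLUMNS = ["component_id", "species_id", "analog_id", "provenance"]


@dataclass(frozen=True)
class RBHResult:
    """Verdict of one reciprocal best-hit test."""

    component_id: str
    species_id: str
    forward: SearchHit | None
    reciprocal: SearchHit | None
    architecture_match: bool | None
    verdict: str  # "accepted" | "rejected"
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.verdict == "accepted":
            assert self.forward is not None and self.reciprocal is not None
            assert self.architecture_match

    @property
    def analog_id(self) -> str | None:
        if self.verdict == "accepted" and self.forward is not None:
            return self.forward.subject_id
        return None


def _family_map(families: Sequence[Family]) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for fam in families:
        members = frozenset(fam.members)
        for member in fam.members:
            if member in out:
                raise ValueError(f"component {member!r} appears in two families")
            out[member] = members
    return out


def _architecture_of(architectures: Mapping[str, Architecture], protein_id: str) -> Architecture:
    try:
        return architectures[protein_id]
    except KeyError:
        raise ValueError(
            f"no architecture available for {protein_id!r}; resolve domain "
            "annotations for every protein entering the pipeline"
        ) from None


def reciprocal_best_hit(
    component_id: str,
    target_proteome: SpeciesProteome,
    focal_proteome: SpeciesProteome,
    families: Sequence[Family],
    architectures: Mapping[str, Architecture],
    scheme: ScoringScheme | None = None,
    max_e: float = 10.0,
) -> RBHResult:
    """Run the full reciprocal best-hit test for one component/species pair.

    The forward search retrieves the lowest-E-value target sequence (if any
    reaches ``max_e``); its own best hit back in the focal proteome must
    fall inside the component's family, and the architectures must match
    exactly.  The reciprocal condition is checked before the architecture
    gate, so each rejection names the first failing condition.
    """
    scheme = scheme or ScoringScheme()
    family_of = _family_map(families)
    if component_id not in focal_proteome:
        raise ValueError(f"component {component_id!r} not in the focal proteome")
    query = focal_proteome[component_id]
    comp_arch = _architecture_of(architectures, component_id)

    forward = best_hit(query, target_proteome, scheme, max_e)
    if forward is None:
        return RBHResult(
            component_id, target_proteome.species_id, None, None, None,
            "rejected", REJECT_NO_FORWARD,
        )
    subject = target_proteome[forward.subject_id]
    reciprocal = best_hit(subject, focal_proteome, scheme, max_e)
    members = family_of.get(component_id, frozenset({component_id}))
    if reciprocal is None or reciprocal.subject_id not in members:
        return RBHResult(
            component_id, target_proteome.species_id, forward, reciprocal, None,
            "rejected", REJECT_RECIPROCAL,
        )
    arch_ok = architectures_match(
        comp_arch, _architecture_of(architectures, forward.subject_id), "exact"
    )
    if not arch_ok:
        return RBHResult(
            component_id, target_proteome.species_id, forward, reciprocal, False,
            "rejected", REJECT_ARCHITECTURE,
        )
    return RBHResult(
        component_id, target_proteome.species_id, forward, reciprocal, True, "accepted"
    )


def _score_matrix(
    focal_records: Sequence[ProteinRecord],
    target_records: Sequence[ProteinRecord],
    scheme: ScoringScheme,
) -> np.ndarray:
    """Exact local-alignment scores, focal x target."""
    db = np.concatenate([encode(r.sequence) for r in target_records])
    offsets = np.zeros(len(target_records) + 1, dtype=np.int64)
    np.cumsum([len(r.sequence) for r in target_records], out=offsets[1:])
    go = np.int32(scheme.gap_open + scheme.gap_extend)
    ge = np.int32(scheme.gap_extend)
    matrix = np.zeros((len(focal_records), len(target_records)), dtype=np.int32)
    for i, rec in enumerate(focal_records):
        sw_score_many(scheme.profile(rec.sequence), db, offsets, go, ge, matrix[i])
    return matrix


def _survey_one_species(
    components: Sequence[str],
    focal_proteome: SpeciesProteome,
    target_proteome: SpeciesProteome,
    family_of: Mapping[str, frozenset[str]],
    architectures: Mapping[str, Architecture],
    scheme: ScoringScheme,
    max_e: float,
) -> list[RBHResult]:
    """All components against one species, via one shared score matrix.

    Because the substitution matrix is symmetric, the focal-by-target score
    matrix serves both search directions; forward and reciprocal best hits
    are read off rows and columns with the same (score desc, id asc)
    ordering that :func:`cadhesome.sequence_search.search` uses.
    """
    focal_records = sorted(focal_proteome, key=lambda r: r.protein_id)
    target_records = sorted(target_proteome, key=lambda r: r.protein_id)
    species = target_proteome.species_id
    results: list[RBHResult] = []
    if not target_records:
        return [
            RBHResult(c, species, None, None, None, "rejected", REJECT_NO_FORWARD)
            for c in components
        ]
    matrix = _score_matrix(focal_records, target_records, scheme)
    row_of = {r.protein_id: i for i, r in enumerate(focal_records)}
    n_target = target_proteome.total_residues
    n_focal = focal_proteome.total_residues

    def _hit(query: ProteinRecord, subject: ProteinRecord, raw: int, n: int, spans: bool) -> SearchHit:
        bit, e_value = score_statistics(raw, len(query.sequence), n, scheme)
        if spans:
            aln = local_align(query.sequence, subject.sequence, scheme)
            qspan, sspan = aln.query_span, aln.subject_span
        else:
            qspan = sspan = (0, 0)
        return SearchHit(
            query_id=query.protein_id,
            subject_id=subject.protein_id,
            raw_score=raw,
            bit_score=bit,
            e_value=e_value,
            query_span=qspan,
            subject_span=sspan,
            query_coverage=(qspan[1] - qspan[0]) / len(query.sequence),
        )

    for component_id in components:
        query = focal_records[row_of[component_id]]
        comp_arch = _architecture_of(architectures, component_id)
        row = matrix[row_of[component_id]]
        j = int(np.argmax(row))  # first max = smallest subject id
        raw_fwd = int(row[j])
        if raw_fwd > 0:
            _, e_fwd = score_statistics(raw_fwd, len(query.sequence), n_target, scheme)
        else:
            e_fwd = float("inf")  # score 0 means nothing aligned
        if e_fwd > max_e:
            results.append(
                RBHResult(component_id, species, None, None, None, "rejected", REJECT_NO_FORWARD)
            )
            continue
        subject = target_records[j]
        col = matrix[:, j]
        i_rec = int(np.argmax(col))
        raw_rec = int(col[i_rec])
        if raw_rec > 0:
            _, e_rec = score_statistics(raw_rec, len(subject.sequence), n_focal, scheme)
        else:
            e_rec = float("inf")
        if e_rec > max_e:
            results.append(
                RBHResult(
                    component_id, species, _hit(query, subject, raw_fwd, n_target, False),
                    None, None, "rejected", REJECT_RECIPROCAL,
                )
            )
            continue
        reciprocal_rec = focal_records[i_rec]
        members = family_of.get(component_id, frozenset({component_id}))
        forward_hit = _hit(query, subject, raw_fwd, n_target, False)
        reciprocal_hit = _hit(subject, reciprocal_rec, raw_rec, n_focal, False)
        if reciprocal_rec.protein_id not in members:
            results.append(
                RBHResult(
                    component_id, species, forward_hit, reciprocal_hit, None,
                    "rejected", REJECT_RECIPROCAL,
                )
            )
            continue
        if not architectures_match(
            comp_arch, _architecture_of(architectures, subject.protein_id), "exact"
        ):
            results.append(
                RBHResult(
                    component_id, species, forward_hit, reciprocal_hit, False,
                    "rejected", REJECT_ARCHITECTURE,
                )
            )
            continue
        forward_hit = _hit(query, subject, raw_fwd, n_target, True)
        results.append(
            RBHResult(component_id, species, forward_hit, reciprocal_hit, True, "accepted")
        )
    return results


def run_survey(
    components: Sequence[str],
    panel: SpeciesPanel,
    proteomes: Mapping[str, SpeciesProteome],
    architectures: Mapping[str, Architecture],
    families: Sequence[Family],
    scheme: ScoringScheme | None = None,
    max_e: float = 10.0,
    species_subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal best-hit survey of every component against every species.

    Returns the analog table (component, species, analog, provenance) and
    the family-by-species presence matrix; a family is present in a species
    when at least one of its components found an accepted analog there.
    The focal species column marks families that have components at all.
    """
    scheme = scheme or ScoringScheme()
    focal_id = panel.focal_species_id
    wanted = list(species_subset) if species_subset is not None else panel.species_ids()
    missing = sorted(sp for sp in set(wanted) | {focal_id} if sp not in proteomes)
    if missing:
        raise ValueError(f"panel species without a proteome: {missing}")
    focal_proteome = proteomes[focal_id]
    for comp in components:
        if comp not in focal_proteome:
            raise ValueError(f"component {comp!r} not in the focal proteome")
        _architecture_of(architectures, comp)
    family_of = _family_map(families)
    components = sorted(components)

    rows: list[tuple[str, str, str, str]] = []
    family_ids = sorted({min(family_of.get(c, frozenset({c}))) for c in components})
    presence = pd.DataFrame(
        False, index=family_ids, columns=[sp for sp in panel.species_ids()]
    )
    presence.index.name = "family_id"
    comp_family = {c: min(family_of.get(c, frozenset({c}))) for c in components}
    presence.loc[sorted(set(comp_family.values())), focal_id] = True

    for species in wanted:
        if species == focal_id:
            continue
        for res in _survey_one_species(
            components, focal_proteome, proteomes[species], family_of,
            architectures, scheme, max_e,
        ):
            if res.verdict == "accepted":
                rows.append((res.component_id, species, res.analog_id, "direct"))
                presence.loc[comp_family[res.component_id], species] = True

    analog_table = pd.DataFrame(rows, columns=ANALOG_COLUMNS)
    return analog_table, presence


def iterative_expansion(
    components: Sequence[str],
    intermediates: Sequence[str],
    targets: Sequence[str],
    panel: SpeciesPanel,
    proteomes: Mapping[str, SpeciesProteome],
    architectures: Mapping[str, Architecture],
    families: Sequence[Family],
    scheme: ScoringScheme | None = None,
    max_e: float = 10.0,
    max_rounds: int = 3,
) -> pd.DataFrame:
    """Expand the survey through intermediate-lineage queries.

    Round 0 is the direct survey from the focal species against
    intermediates and targets.  Each later round uses the analogs accepted
    in intermediate species during the previous round as fresh queries
    against the target species; the re-search is always against the FOCAL
    proteome and must land in the original component's family, and the
    architecture gate compares the new hit with the original component.
    Newly accepted analogs are recorded with ``expansion-round-k``
    provenance.  Iteration stops when a round adds nothing.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    scheme = scheme or ScoringScheme()
    panel_species = set(panel.species_ids())
    stray = sorted(set(intermediates) - panel_species)
    if stray:
        raise ValueError(f"intermediate species not in panel: {stray}")
    focal_id = panel.focal_species_id
    focal_proteome = proteomes[focal_id]
    family_of = _family_map(families)

    round0_species = list(dict.fromkeys([*intermediates, *targets]))
    table, _ = run_survey(
        components, panel, proteomes, architectures, families, scheme, max_e,
        species_subset=round0_species,
    )
    known: set[tuple[str, str, str]] = {
        (r.component_id, r.species_id, r.analog_id) for r in table.itertuples()
    }
    rows = table.values.tolist()
    new_queries: list[tuple[str, str, str]] = [
        (r.component_id, r.species_id, r.analog_id)
        for r in table.itertuples()
        if r.species_id in set(intermediates)
    ]

    for round_k in range(1, max_rounds + 1):
        if not new_queries:
            break
        added: list[tuple[str, str, str]] = []
        for component_id, q_species, q_protein in sorted(new_queries):
            query = proteomes[q_species][q_protein]
            comp_arch = _architecture_of(architectures, component_id)
            members = family_of.get(component_id, frozenset({component_id}))
            for target in targets:
                if target == q_species:
                    continue
                forward = best_hit(query, proteomes[target], scheme, max_e)
                if forward is None:
                    continue
                key = (component_id, target, forward.subject_id)
                if key in known:
                    continue
                subject = proteomes[target][forward.subject_id]
                reciprocal = best_hit(subject, focal_proteome, scheme, max_e)
                if reciprocal is None or reciprocal.subject_id not in members:
                    continue
                if not architectures_match(
                    comp_arch, _architecture_of(architectures, forward.subject_id), "exact"
                ):
                    continue
                known.add(key)
                rows.append([component_id, target, forward.subject_id, f"expansion-round-{round_k}"])
                added.append(key)
        new_queries = [
            (c, sp, pid) for c, sp, pid in added if sp in set(intermediates)
        ]
        if not added:
            break

    return pd.DataFrame(rows, columns=ANALOG_COLUMNS)


def classify_iteratively(
    queries: Sequence[ProteinRecord],
    reference_proteomes: Iterable[SpeciesProteome],
    labels: Mapping[str, str] | Iterable[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    max_e: float = 10.0,
    max_rounds: int = 10,
) -> dict[str, str]:
    """All-against-all label propagation for uncharacterized sequences.

    Each round, every unlabeled query takes the family label of its best
    reciprocal partner in the labeled pool: the query's best hit among
    labeled references must itself pick that query as its best hit among
    the remaining unlabeled queries.  Newly labeled queries join the pool,
    and iteration continues until labels stabilize (a fixed point -- the
    label set grows monotonically).  Queries never labeled are "unrelated".
    """
    scheme = scheme or ScoringScheme()
    if isinstance(labels, Mapping):
        label_of = dict(labels)
    else:
        label_of = {}
        for pid, lab in labels:
            if pid in label_of and label_of[pid] != lab:
                raise ValueError(f"conflicting labels for reference protein {pid!r}")
            label_of[pid] = lab

    records: dict[str, ProteinRecord] = {}
    for proteome in reference_proteomes:
        for rec in proteome:
            if rec.protein_id in records:
                raise ValueError(f"duplicate protein id across references: {rec.protein_id!r}")
            records[rec.protein_id] = rec
    unknown = sorted(set(label_of) - set(records))
    if unknown:
        raise ValueError(f"labels given for proteins absent from references: {unknown}")

    query_ids = [q.protein_id for q in queries]
    if len(set(query_ids)) != len(query_ids):
        raise ValueError("duplicate query ids")

    pool = SpeciesProteome("labeled_pool")
    for pid in sorted(label_of):
        pool.add(records[pid])

    assigned: dict[str, str] = {}
    unlabeled = {q.protein_id: q for q in queries}
    for _ in range(max_rounds):
        if not unlabeled:
            break
        unlabeled_db = SpeciesProteome("unlabeled_queries")
        for pid in sorted(unlabeled):
            unlabeled_db.add(unlabeled[pid])
        newly: dict[str, str] = {}
        for pid in sorted(unlabeled):
            forward = best_hit(unlabeled[pid], pool, scheme, max_e)
            if forward is None:
                continue
            partner = pool[forward.subject_id]
            reciprocal = best_hit(partner, unlabeled_db, scheme, max_e)
            if reciprocal is not None and reciprocal.subject_id == pid:
                newly[pid] = label_of[forward.subject_id]
        if not newly:
            break
        for pid, lab in newly.items():
            assigned[pid] = lab
            label_of[pid] = lab
            pool.add(unlabeled.pop(pid))
    return {pid: assigned.get(pid, "unrelated") for pid in query_ids}
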