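"""Domain architectures: resolution, comparison and family clustering.

A protein's *architecture* is the N-to-C ordered list of its major domain
names, derived from raw domain calls (SMART/CDD-style tables) by discarding
weak or short calls and resolving overlaps.  Architectures drive two things
downstream: the architecture-agreement gate of the reciprocal best-hit test,
and the clustering of network components into protein families (the
"simplified" adhesome).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DomainAnnotation",
    "Architecture",
    "Family",
    "resolve_major_domains",
    "architectures_match",
    "architectures_from_annotations",
    "cluster_families",
    "DEFAULT_MAX_E",
    "DEFAULT_MIN_LEN",
]

# Defaults for what counts as a "major" domain.  Domain databases report
# marginal calls freely; these cutoffs keep confident, full-size domains.
DEFAULT_MAX_E = 1e-4
DEFAULT_MIN_LEN = 20


@dataclass(frozen=True)
class DomainAnnotation:
    """One located domain call on one protein.

    Coordinates are 0-based half-open (converted from 1-based inclusive at
    the file boundary by :mod:`cadhesome.io_formats`).
    """

    protein_id: str
    domain_name: str
    start: int
    end: int
    e_value: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid domain interval [{self.start},{self.end}) "
                f"for {self.domain_name} on {self.protein_id}"
            )
        if self.e_value < 0:
            raise ValueError(
                f"negative e-value {self.e_value} for {self.domain_name} "
                f"on {self.protein_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Architecture:
    """Ordered (N->C) major-domain signature of a protein; may be empty."""

    domains: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __bool__(self) -> bool:
        return bool(self.domains)

    def __str__(self) -> str:
        return "-".join(self.domains) if self.domains else "(none)"


@dataclass(frozen=True)
class Family:
    """A cluster of components sharing an architecture signature."""

    family_id: str
    members: tuple[str, ...]
    signature: Architecture
    mode: str = "exact"


def resolve_major_domains(
    annotations: Iterable[DomainAnnotation],
    max_e: float = DEFAULT_MAX_E,
    min_len: int = DEFAULT_MIN_LEN,
) -> Architecture:
    """Collapse raw domain calls for one protein into its architecture.

    Calls with ``e_value > max_e`` or shorter than ``min_len`` residues are
    discarded.  Remaining overlaps are resolved greedily by ascending
    e-value (ties: longer interval, then name); the losing annotation is
    dropped entirely rather than trimmed, because overlapping calls from
    SMART and CDD usually name the same region twice.
    """
    annotations = list(annotations)
    proteins = {a.protein_id for a in annotations}
    if len(proteins) > 1:
        raise ValueError(
            f"annotations span multiple proteins: {sorted(proteins)}"
        )
    kept: list[DomainAnnotation] = []
    candidates = [a for a in annotations if a.e_value <= max_e and a.length >= min_len]
    candidates.sort(key=lambda a: (a.e_value, -a.length, a.domain_name, a.start))
    for cand in candidates:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda a: a.start)
    return Architecture(tuple(a.domain_name for a in kept))


def architectures_from_annotations(
    annotations: Iterable[DomainAnnotation],
    protein_ids: Iterable[str] | None = None,
    max_e: float = DEFAULT_MAX_E,
    min_len: int = DEFAULT_MIN_LEN,
) -> dict[str, Architecture]:
    """Resolve architectures for every protein mentioned in a call table.

    ``protein_ids`` optionally adds proteins with no calls at all, which
    then receive an empty architecture (e.g. short unstructured proteins).
    """
    per_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        per_protein.setdefault(ann.protein_id, []).append(ann)
    if protein_ids is not None:
        for pid in protein_ids:
            per_protein.setdefault(pid, [])
    return {
        pid: resolve_major_domains(anns, max_e=max_e, min_len=min_len)
        for pid, anns in per_protein.items()
    }


def _multiset_jaccard(a: Architecture, b: Architecture) -> float:
    ca, cb = Counter(a.domains), Counter(b.domains)
    if not ca and not cb:
        return 1.0
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    return inter / union


def architectures_match(
    a: Architecture,
    b: Architecture,
    mode: str = "exact",
    broad_threshold: float = 0.5,
) -> bool:
    """Compare two architectures.

    ``exact``: same number and order of domains.  ``broad``: the multiset
    Jaccard similarity of the domain-name composition reaches
    ``broad_threshold`` (order-insensitive); this is the relaxed notion used
    for grouping e.g. the MAGUK scaffolds or the actinin/spectrin pair when
    counting paralog expansion.  Both modes are reflexive and symmetric.
    """
    if mode == "exact":
        return a.domains == b.domains
    if mode == "broad":
        return _multiset_jaccard(a, b) >= broad_threshold
    raise ValueError(f"unknown architecture comparison mode: {mode!r}")


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {i: i for i in items}

    def find(self, x: str) -> str:
        p = self._parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


def cluster_families(
    components: Mapping[str, Architecture] | Sequence[tuple[str, Architecture]],
    mode: str = "exact",
    broad_threshold: float = 0.5,
    merges: Sequence[Iterable[str]] = (),
) -> list[Family]:
    """Partition components into families by architecture agreement.

    ``exact`` mode partitions by signature equality; ``broad`` mode takes
    connected components of the broad match relation (single linkage).
    ``merges`` lists groups of component ids to force into one family
    regardless of signature -- the hook for curated exceptions (e.g. keeping
    distinct MAGUK architectures in one expansion group).

    The partition is invariant to input order; ``family_id`` is the
    lexicographically smallest member id.
    """
    if isinstance(components, Mapping):
        items = list(components.items())
    else:
        items = list(components)
    ids = [cid for cid, _ in items]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate component ids: {dups}")
    archs = dict(items)

    uf = _UnionFind(ids)
    if mode == "exact":
        by_sig: dict[tuple[str, ...], list[str]] = {}
        for cid in sorted(ids):
            by_sig.setdefault(archs[cid].domains, []).append(cid)
        for group in by_sig.values():
            for other in group[1:]:
                uf.union(group[0], other)
    elif mode == "broad":
        ordered = sorted(ids)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if architectures_match(archs[a], archs[b], "broad", broad_threshold):
                    uf.union(a, b)
    else:
        raise ValueError(f"unknown clustering mode: {mode!r}")

    for group in merges:
        group = sorted(group)
        unknown = [g for g in group if g not in archs]
        if unknown:
            raise ValueError(f"merge list names unknown components: {unknown}")
        for other in group[1:]:
            uf.union(group[0], other)

    clusters: dict[str, list[str]] = {}
    for cid in ids:
        clusters.setdefault(uf.find(cid), []).append(cid)
    families = []
    for members in clusters.values():
        members = tuple(sorted(members))
        families.append(
            Family(
                family_id=members[0],
                members=members,
                signature=archs[members[0]],
                mode=mode,
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families
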