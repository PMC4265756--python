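"""Independent oracles and small builders shared across the test suite."""

from __future__ import annotations

from collections import deque
from itertools import combinations

from cadhesome.io_formats import ProteinRecord, SpeciesProteome


def make_proteome(species_id: str, seqs: dict[str, str]) -> SpeciesProteome:
    return SpeciesProteome(
        species_id,
        [ProteinRecord(pid, species_id, seq) for pid, seq in seqs.items()],
    )


def brute_force_local_score(
    a: str, b: str, substitution, gap_open: int, gap_extend: int
) -> int:
    """Exhaustive optimal local alignment score with affine gaps.

    Enumerates every monotone set of aligned column pairs between the two
    sequences.  Unaligned residues between consecutive aligned columns form
    one deletion run and one insertion run, each costing
    gap_open + g * gap_extend; splitting a run could only cost more, so the
    maximum over all matchings is the Smith-Waterman optimum.  Completely
    independent of the dynamic-programming recurrences under test.
    """

    def gap(g: int) -> int:
        return gap_open + g * gap_extend if g > 0 else 0

    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for qi in combinations(range(len(a)), k):
            for sj in combinations(range(len(b)), k):
                score = substitution(a[qi[0]], b[sj[0]])
                for t in range(1, k):
                    score += substitution(a[qi[t]], b[sj[t]])
                    score -= gap(qi[t] - qi[t - 1] - 1)
                    score -= gap(sj[t] - sj[t - 1] - 1)
                best = max(best, score)
    return best


def naive_motif_hits(sequence: str, motif) -> list[int]:
    """Per-offset set-membership motif scan, independent of the scanner."""
    plen = len(motif.positions)
    starts = []
    offsets = (
        [len(sequence) - plen]
        if motif.anchoring == "c-terminal"
        else range(len(sequence) - plen + 1)
    )
    for start in offsets:
        if start < 0:
            continue
        ok = True
        for k, allowed in enumerate(motif.positions):
            if allowed is not None and sequence[start + k] not in allowed:
                ok = False
                break
        if ok:
            starts.append(start)
    return starts


def bfs_shells(nodes, edges, core) -> dict[str, str]:
    """Plain breadth-first-search shell labels, independent of networkx."""
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    dist = {n: None for n in nodes}
    queue = deque()
    for c in core:
        dist[c] = 0
        queue.append(c)
    while queue:
        node = queue.popleft()
        for neighbor in adjacency[node]:
            if dist[neighbor] is None:
                dist[neighbor] = dist[node] + 1
                queue.append(neighbor)
    labels = {}
    for n in nodes:
        d = dist[n]
        labels[n] = {0: "core", 1: "1", 2: "2"}.get(d, "outside")
    return labels
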