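"""Sequence motifs of the cadherin cytoplasmic tail and its partners.

The cadherin tail is natively unstructured; its function rests on short
linear motifs.  Two ~10-residue groove-binding motifs (GBMs) anchor the
tail in the armadillo-repeat grooves of its catenin partners: the
juxtamembrane-domain (JMD) GBM ``xx[ED]GGGExx`` bound by P120, and the
catenin-binding-domain (CBD) GBM bound by beta-catenin, in which an
aromatic anchor sits in a hydrophobic pocket flanked by acidic contacts
(default reconstruction ``[ED]xx[FWY]xx[ED]``; configurable because only
its structural description, not a consensus string, is published).
Regulatory sites scanned alongside: a CASP3 apoptotic cleavage site
``[DSTE]xxD[GSAN]``, a NUMB PTB-binding site ``NVYY`` and the ``YYY``
motif bound by the ubiquitin ligase Hakai.

C-terminal PDZ-binding motifs are classified from the last four residues:
class I has S/T at position -2, class II a hydrophobic residue there; both
require a hydrophobic C-terminal residue.  A cadherin carrying both
extracellular cadherin (EC) repeats and a CBD is called "classical"-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .architecture import Architecture, DomainAnnotation
from .io_formats import ProteinRecord

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "CadherinCall",
    "compile_motif",
    "scan",
    "scan_c_terminal_pdz",
    "extract_cytoplasmic_tail",
    "classify_cadherin",
    "column_conservation",
    "default_motif_set",
    "realize_pattern",
    "JMD_GBM_PATTERN",
    "CBD_GBM_PATTERN",
    "CASP3_PATTERN",
    "NUMB_PTB_PATTERN",
    "HAKAI_PATTERN",
]

JMD_GBM_PATTERN = "xx[ED]GGGExx"
CBD_GBM_PATTERN = "[ED]xx[FWY]xx[ED]"  # reconstruction; see module docstring
CASP3_PATTERN = "[DSTE]xxD[GSAN]"
NUMB_PTB_PATTERN = "NVYY"
HAKAI_PATTERN = "YYY"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Standard PDZ-binding residue classes; configurable per call.
PDZ_CLASS1_MINUS2 = frozenset("ST")
PDZ_HYDROPHOBIC = frozenset("VILFA")


@dataclass(frozen=True)
class MotifDefinition:
    """A position-restricted amino-acid class pattern.

    ``positions`` holds one allowed-residue frozenset per position; None
    means "any residue".  ``anchoring`` is ``internal`` (match anywhere) or
    ``c-terminal`` (match only flush with the sequence end).
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    anchoring: str = "internal"
    pattern: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"motif {self.name!r} has an empty pattern")
        if self.anchoring not in ("internal", "c-terminal"):
            raise ValueError(f"unknown anchoring {self.anchoring!r}")
        for i, pos in enumerate(self.positions):
            if pos is not None and not pos:
                raise ValueError(f"motif {self.name!r} position {i} allows no residue")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_name: str
    start: int  # 0-based
    matched: str


def compile_motif(
    pattern: str, name: str | None = None, anchoring: str = "internal"
) -> MotifDefinition:
    """Compile bracket notation into a motif definition.

    Grammar: an uppercase letter is a literal, ``x`` matches any residue,
    ``[...]`` encloses an allowed-residue class.  E.g. ``xx[ED]GGGExx``
    compiles to nine positions with {E,D} at position 3 (1-based).
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            close = pattern.find("]", i)
            if close == -1:
                raise ValueError(f"unbalanced bracket in motif pattern {pattern!r}")
            members = pattern[i + 1 : close]
            if not members:
                raise ValueError(f"empty residue class in motif pattern {pattern!r}")
            bad = set(members) - AMINO_ACIDS
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in {pattern!r}")
            positions.append(frozenset(members))
            i = close + 1
        elif ch == "]":
            raise ValueError(f"unbalanced bracket in motif pattern {pattern!r}")
        elif ch == "x":
            positions.append(None)
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"invalid character {ch!r} in motif pattern {pattern!r}")
    if not positions:
        raise ValueError("empty motif pattern")
    return MotifDefinition(
        name=name or pattern, positions=tuple(positions), anchoring=anchoring, pattern=pattern
    )


def default_motif_set(cbd_pattern: str = CBD_GBM_PATTERN) -> dict[str, MotifDefinition]:
    """The built-in cadherin-tail motif set, keyed by motif name."""
    return {
        "JMD_GBM": compile_motif(JMD_GBM_PATTERN, "JMD_GBM"),
        "CBD_GBM": compile_motif(cbd_pattern, "CBD_GBM"),
        "CASP3": compile_motif(CASP3_PATTERN, "CASP3"),
        "NUMB_PTB": compile_motif(NUMB_PTB_PATTERN, "NUMB_PTB"),
        "HAKAI": compile_motif(HAKAI_PATTERN, "HAKAI"),
    }


def realize_pattern(pattern: str, any_residue: str = "A") -> str:
    """One concrete sequence matching a pattern (first residue of each class).

    Used by the synthetic-data generator to plant scanner-detectable motifs.
    """
    motif = compile_motif(pattern)
    out = []
    for pos in motif.positions:
        out.append(any_residue if pos is None else min(pos))
    return "".join(out)


def scan(sequence: str | ProteinRecord, motif: MotifDefinition) -> list[MotifHit]:
    """All occurrences of a motif; overlapping hits are all reported.

    C-terminally anchored motifs are tested only flush with the end.
    """
    protein_id = sequence.protein_id if isinstance(sequence, ProteinRecord) else ""
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    plen = len(motif)
    if plen > len(seq):
        return []
    if motif.anchoring == "c-terminal":
        starts: Iterable[int] = (len(seq) - plen,)
    else:
        starts = range(len(seq) - plen + 1)
    hits = []
    for start in starts:
        window = seq[start : start + plen]
        if all(pos is None or window[k] in pos for k, pos in enumerate(motif.positions)):
            hits.append(MotifHit(protein_id, motif.name, start, window))
    return hits


def scan_c_terminal_pdz(
    sequence: str | ProteinRecord,
    class1_minus2: frozenset[str] = PDZ_CLASS1_MINUS2,
    hydrophobic: frozenset[str] = PDZ_HYDROPHOBIC,
) -> str:
    """Classify the C-terminal PDZ-binding motif: 'I', 'II' or 'none'.

    Only the last four residues are inspected.  Class I: S/T at -2 and a
    hydrophobic terminal residue; class II: hydrophobic at both -2 and 0.
    Class I takes precedence when -2 is ambiguous under custom classes.
    """
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    if len(seq) < 4:
        warnings.warn(
            f"sequence of length {len(seq)} too short for PDZ-binding "
            "classification (need >= 4 residues)",
            stacklevel=2,
        )
        return "none"
    minus2, terminal = seq[-3], seq[-1]
    if terminal not in hydrophobic:
        return "none"
    if minus2 in class1_minus2:
        return "I"
    if minus2 in hydrophobic:
        return "II"
    return "none"


def extract_cytoplasmic_tail(
    protein: str | ProteinRecord, tm_annotations: Sequence[DomainAnnotation]
) -> str:
    """Residues strictly C-terminal to the last transmembrane segment.

    Assumes single-pass type-I topology (the cadherin case), so the region
    after the last TM helix is cytoplasmic.  Raises when no TM annotation
    is supplied: use the full sequence instead for TM-less proteins.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not tm_annotations:
        raise ValueError(
            "no transmembrane annotation supplied; for proteins without a "
            "predicted TM segment use the full sequence"
        )
    last_end = max(a.end for a in tm_annotations)
    return seq[last_end:]


@dataclass(frozen=True)
class CadherinCall:
    """Motif/domain summary of one cadherin candidate.

    ``classification`` is ``classical-like`` exactly when the protein has
    both EC repeats and a CBD groove-binding motif in its tail.
    """

    protein_id: str
    has_ec_domains: bool
    has_jmd_gbm: bool
    has_cbd_gbm: bool
    pdz_binding_class: str
    classification: str


def classify_cadherin(
    architecture: Architecture,
    tail: str,
    protein_id: str = "",
    motif_set: Mapping[str, MotifDefinition] | None = None,
    ec_domain_name: str = "CA",
) -> CadherinCall:
    """Classify a cadherin candidate from its architecture and tail.

    EC repeats are recognized as ``ec_domain_name`` entries ("CA" in
    SMART nomenclature).  ``classical-like`` requires EC repeats plus a CBD
    GBM; cadherin-flavored proteins missing either (choanoflagellate-style
    EC-only cadherins, or EC-less tails that still carry GBMs) come out
    ``cadherin-nonclassical``; proteins with neither EC domains nor any GBM
    are ``not-cadherin``.
    """
    motifs = motif_set or default_motif_set()
    has_ec = ec_domain_name in architecture.domains
    has_jmd = bool(scan(tail, motifs["JMD_GBM"]))
    has_cbd = bool(scan(tail, motifs["CBD_GBM"]))
    if has_ec and has_cbd:
        classification = "classical-like"
    elif has_ec or has_jmd or has_cbd:
        classification = "cadherin-nonclassical"
    else:
        classification = "not-cadherin"
    return CadherinCall(
        protein_id=protein_id,
        has_ec_domains=has_ec,
        has_jmd_gbm=has_jmd,
        has_cbd_gbm=has_cbd,
        pdz_binding_class=scan_c_terminal_pdz(tail) if len(tail) >= 4 else "none",
        classification=classification,
    )


def column_conservation(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    reference_id: str,
    position: int,
    conservation_set: Iterable[str],
) -> float:
    """Fraction of aligned sequences conserving a reference residue.

    ``position`` is the 1-based residue index in the *ungapped* reference
    (e.g. Ser844 of human E-cadherin); it is mapped through the reference's
    gaps to its alignment column.  The fraction is taken over all rows;
    rows with a gap in that column count as non-conserved.
    """
    rows = list(alignment.items()) if isinstance(alignment, Mapping) else list(alignment)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have the same length")
    ref = dict(rows).get(reference_id)
    if ref is None:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    if position < 1:
        raise ValueError("position is 1-based; must be >= 1")
    count = 0
    column = None
    for col, ch in enumerate(ref):
        if ch != "-":
            count += 1
            if count == position:
                column = col
                break
    if column is None:
        raise ValueError(
            f"position {position} beyond the ungapped length of {reference_id!r}"
        )
    allowed = set(conservation_set)
    conserved = sum(1 for _, seq in rows if seq[column] in allowed)
    return conserved / len(rows)
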