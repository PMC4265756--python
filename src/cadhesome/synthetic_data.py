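"""Benchmark proteomes with known ground truth.

Gene families evolve along a species tree by a linear birth-death process
(duplication rate delta, loss rate mu per copy per unit branch length);
sequences diverge by a Poisson substitution model (each site substitutes
with probability 1 - e^-t along a branch of length t, replacements drawn
from the stationary residue frequencies); domain architectures are
inherited verbatim apart from configured gain/loss events; and short
linear motifs are planted on designated lineages at a fixed offset from
the C-terminus of a designated tail region.

The model is deliberately simple -- no rate heterogeneity, no indels, no
selection -- so that closed-form oracles exist for every stochastic
component: a pure-birth family has e^(delta*t) expected copies, and the
probability that a site matches its ancestor after time t is
e^-t + (1 - e^-t) * sum(pi_i^2).

Everything is reproducible: a fixed seed yields a byte-identical benchmark
bundle on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .architecture import Architecture, DomainAnnotation, Family
from .io_formats import (
    ProteinRecord,
    SpeciesInfo,
    SpeciesPanel,
    SpeciesProteome,
    write_domain_annotations,
    write_fasta,
    write_presence_matrix,
)
from .motif_scan import compile_motif, realize_pattern

__all__ = [
    "SimulationConfig",
    "MotifGainEvent",
    "DomainEvent",
    "GeneContent",
    "FamilyContent",
    "TruthTables",
    "BenchmarkBundle",
    "simulate_gene_content",
    "evolve_sequences",
    "generate_benchmark",
    "evaluate_survey",
    "SurveyScore",
    "recovery_benchmark_config",
    "adhesome_panel_config",
    "RECOVERY_TREE_NEWICK",
    "ADHESOME_TREE_NEWICK",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_DOMAIN_POOL = (
    "CA", "PDZ", "SH3", "GuKc", "ARM", "LIM",
    "EGF", "LamG", "FN3", "WW", "PH", "RhoGEF",
)


@dataclass(frozen=True)
class MotifGainEvent:
    """Plant a motif in one family on the lineage rooted at ``node``.

    The realized motif string overwrites tail residues at a fixed offset
    from the C-terminus in every descendant copy, so sequence lengths and
    truth-table coordinates stay constant.
    """

    node: str
    motif_name: str
    pattern: str
    family: str
    offset_from_cterm: int = 16


@dataclass(frozen=True)
class DomainEvent:
    """Gain or lose a domain annotation in one family below ``node``.

    A loss stops annotating the domain (the underlying residues remain,
    mimicking domain degeneration); a gain annotates a reserved C-terminal
    slot allocated for this event, keeping coordinates stable.
    """

    node: str
    family: str
    action: str  # "gain" | "loss"
    domain_name: str

    def __post_init__(self) -> None:
        if self.action not in ("gain", "loss"):
            raise ValueError(f"unknown domain event action {self.action!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one benchmark simulation.

    ``newick`` carries branch lengths in expected substitutions per site;
    ``strata_order`` runs youngest (focal) to oldest.  ``origin_nodes``
    optionally places each family's birth at a labeled tree node (default:
    the root), which is what phylostratigraphy later tries to recover.
    """

    newick: str
    species_strata: Mapping[str, str]
    strata_order: tuple[str, ...]
    focal_species: str
    n_families: int
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    root_architectures: tuple[tuple[str, ...], ...] | None = None
    origin_nodes: tuple[str | None, ...] | None = None
    motif_events: tuple[MotifGainEvent, ...] = ()
    domain_events: tuple[DomainEvent, ...] = ()
    stationary_freqs: tuple[float, ...] | None = None
    seed: int = 0
    domain_length: int = 24
    linker_length: int = 6
    pad_length: int = 6
    tail_length: int = 24
    domain_pool: tuple[str, ...] = DEFAULT_DOMAIN_POOL

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication and loss rates must be >= 0")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.pad_length + self.tail_length < 1:
            raise ValueError("pad_length + tail_length must be >= 1")
        if self.stationary_freqs is not None:
            freqs = np.asarray(self.stationary_freqs, dtype=float)
            if len(freqs) != 20 or freqs.min() < 0 or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("stationary_freqs must be 20 non-negative values summing to 1")
        if self.root_architectures is not None and len(self.root_architectures) != self.n_families:
            raise ValueError("root_architectures must list one architecture per family")
        if self.origin_nodes is not None and len(self.origin_nodes) != self.n_families:
            raise ValueError("origin_nodes must list one node (or None) per family")
        for ev in self.motif_events:
            pattern_len = len(compile_motif(ev.pattern))
            if pattern_len > ev.offset_from_cterm or ev.offset_from_cterm > self.tail_length:
                raise ValueError(
                    f"motif {ev.motif_name!r} (length {pattern_len}, offset "
                    f"{ev.offset_from_cterm}) does not fit in the {self.tail_length}"
                    "-residue tail region"
                )

    @property
    def freqs(self) -> np.ndarray:
        if self.stationary_freqs is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.stationary_freqs, dtype=float)

    def family_ids(self) -> list[str]:
        width = max(4, len(str(max(self.n_families - 1, 0))))
        return [f"F{i:0{width}d}" for i in range(self.n_families)]


# ---------------------------------------------------------------------------
# tree plumbing

def _prepare_tree(config: SimulationConfig) -> tuple[dendropy.Tree, dict]:
    tree = dendropy.Tree.get(
        data=config.newick, schema="newick", preserve_underscores=True
    )
    keys: dict[int, str] = {}
    seen: set[str] = set()
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            key = node.taxon.label
        else:
            key = node.label if node.label else f"node{idx}"
        if key in seen:
            raise ValueError(f"duplicate node label {key!r} in tree")
        seen.add(key)
        keys[id(node)] = key
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = leaves - set(config.species_strata)
    if missing:
        raise ValueError(f"tree leaves without a stratum: {sorted(missing)}")
    return tree, keys


def _find_node(tree: dendropy.Tree, keys: dict, label: str | None):
    if label is None:
        return tree.seed_node
    for node in tree.preorder_node_iter():
        if keys[id(node)] == label:
            return node
    raise ValueError(f"no tree node labeled {label!r}")


def _leaves_under(node) -> list[str]:
    return sorted(leaf.taxon.label for leaf in node.leaf_iter())


# ---------------------------------------------------------------------------
# gene content (birth-death embedding)

@dataclass
class FamilyContent:
    """One family's gene-tree embedding in the species tree."""

    family_id: str
    origin_node: str
    copies_at: dict[str, tuple[str, ...]]
    ancestor_of: dict[tuple[str, str], str]  # (node_key, copy) -> copy at parent
    births: dict[str, int]  # per edge, keyed by child node
    deaths: dict[str, int]


@dataclass
class GeneContent:
    species: list[str]
    families: list[FamilyContent]

    def counts_table(self) -> pd.DataFrame:
        data = {
            fam.family_id: [len(fam.copies_at.get(sp, ())) for sp in self.species]
            for fam in self.families
        }
        table = pd.DataFrame.from_dict(data, orient="index", columns=self.species)
        table.index.name = "family_id"
        return table


def _evolve_copies_along_branch(
    copies: Sequence[str],
    length: float,
    delta: float,
    mu: float,
    rng: np.random.Generator,
    counter: list[int],
) -> tuple[list[str], dict[str, str], int, int]:
    """Gillespie birth-death along one branch.

    Returns surviving copy labels, their branch-start ancestors, and the
    number of births and deaths on the branch.
    """
    alive = list(copies)
    ancestor = {c: c for c in alive}
    births = deaths = 0
    if delta + mu <= 0 or length <= 0:
        return alive, ancestor, births, deaths
    t = 0.0
    while alive:
        total_rate = len(alive) * (delta + mu)
        t += rng.exponential(1.0 / total_rate)
        if t > length:
            break
        idx = int(rng.integers(len(alive)))
        if rng.random() < delta / (delta + mu):
            counter[0] += 1
            child = str(counter[0])
            ancestor[child] = ancestor[alive[idx]]
            alive.append(child)
            births += 1
        else:
            ancestor.pop(alive[idx], None)
            alive.pop(idx)
            deaths += 1
    return alive, {c: ancestor[c] for c in alive}, births, deaths


def simulate_gene_content(config: SimulationConfig) -> GeneContent:
    """Embed each family's gene tree in the species tree.

    Each family starts as a single copy at its origin node and evolves by
    duplication/loss down every descending branch.  With both rates zero
    every species under the origin carries exactly one copy.
    """
    tree, keys = _prepare_tree(config)
    rng = np.random.default_rng([config.seed, 1])
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    delta, mu = config.duplication_rate, config.loss_rate

    families: list[FamilyContent] = []
    for fidx, family_id in enumerate(config.family_ids()):
        origin_label = None
        if config.origin_nodes is not None:
            origin_label = config.origin_nodes[fidx]
        origin = _find_node(tree, keys, origin_label)
        origin_key = keys[id(origin)]

        copies_at: dict[str, tuple[str, ...]] = {origin_key: ("1",)}
        ancestor_of: dict[tuple[str, str], str] = {}
        births: dict[str, int] = {}
        deaths: dict[str, int] = {}
        counter = [1]

        def _descend(node) -> None:
            parent_key = keys[id(node)]
            for child in node.child_nodes():
                child_key = keys[id(child)]
                alive, anc, nb, nd = _evolve_copies_along_branch(
                    copies_at[parent_key],
                    child.edge.length or 0.0,
                    delta,
                    mu,
                    rng,
                    counter,
                )
                copies_at[child_key] = tuple(alive)
                for copy, parent_copy in anc.items():
                    ancestor_of[(child_key, copy)] = parent_copy
                births[child_key] = nb
                deaths[child_key] = nd
                _descend(child)

        _descend(origin)
        families.append(
            FamilyContent(
                family_id=family_id,
                origin_node=origin_key,
                copies_at=copies_at,
                ancestor_of=ancestor_of,
                births=births,
                deaths=deaths,
            )
        )
    return GeneContent(species=species, families=families)


# ---------------------------------------------------------------------------
# sequences, architectures, motifs

@dataclass
class TruthTables:
    """Ground truth emitted alongside a benchmark bundle."""

    ortholog_pairs: pd.DataFrame  # component_id, species_id, protein_id, family_id
    presence: pd.DataFrame  # families x species, bool
    counts: pd.DataFrame  # families x species, int
    origins: pd.Series  # family_id -> stratum_id
    motif_placements: pd.DataFrame  # protein_id, motif_name, start


def _auto_root_architectures(config: SimulationConfig) -> list[tuple[str, ...]]:
    """Distinct 1-3 domain architectures, one per family.

    Signatures are unique across families so that exact-mode clustering of
    the focal components reproduces the true families, keeping benchmark
    truth unambiguous.
    """
    rng = np.random.default_rng([config.seed, 2])
    pool = list(config.domain_pool)
    combos: list[tuple[str, ...]] = []
    length = 1
    # shuffle within each architecture-size block so that small panels are
    # dominated by compact one/two-domain proteins
    while len(combos) < config.n_families:
        block = list(product(pool, repeat=length))
        order = rng.permutation(len(block))
        combos.extend(block[i] for i in order)
        length += 1
        if length > 6:
            raise ValueError("domain pool too small for the requested family count")
    return combos[: config.n_families]


def _protein_id(species: str, family_id: str, copy: str) -> str:
    return f"{species}|{family_id}.{copy}"


def family_of_protein(protein_id: str) -> str:
    """Parse the true family id out of a simulated protein id."""
    return protein_id.split("|", 1)[1].rsplit(".", 1)[0]


def _mutate(seq: np.ndarray, t: float, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if t <= 0:
        return seq.copy()
    child = seq.copy()
    mask = rng.random(len(seq)) < (1.0 - math.exp(-t))
    n_sub = int(mask.sum())
    if n_sub:
        child[mask] = rng.choice(20, size=n_sub, p=freqs)
    return child


def evolve_sequences(
    config: SimulationConfig, content: GeneContent
) -> tuple[dict[str, SpeciesProteome], list[DomainAnnotation], TruthTables]:
    """Evolve sequences, architectures and motifs over the gene content.

    Returns one proteome per species, a flat domain-annotation table, and
    the truth tables.  Deterministic given ``config.seed``.
    """
    tree, keys = _prepare_tree(config)
    rng = np.random.default_rng([config.seed, 3])
    freqs = config.freqs
    archs = (
        [tuple(a) for a in config.root_architectures]
        if config.root_architectures is not None
        else _auto_root_architectures(config)
    )
    fam_ids = config.family_ids()
    fam_index = {fid: i for i, fid in enumerate(fam_ids)}

    # Slot layout per family: root domains first, then one reserved slot per
    # gain event, then the tail.  Lengths are constant across the tree.
    gain_slots: dict[str, list[DomainEvent]] = {fid: [] for fid in fam_ids}
    for ev in config.domain_events:
        if ev.family not in fam_index:
            raise ValueError(f"domain event names unknown family {ev.family!r}")
        if ev.action == "gain":
            gain_slots[ev.family].append(ev)
    motif_realizations = {
        ev: realize_pattern(ev.pattern) for ev in config.motif_events
    }
    for ev in config.motif_events:
        if ev.family not in fam_index:
            raise ValueError(f"motif event names unknown family {ev.family!r}")

    dl, lk, pad, tail = (
        config.domain_length,
        config.linker_length,
        config.pad_length,
        config.tail_length,
    )

    proteomes = {sp: SpeciesProteome(sp) for sp in content.species}
    annotations: list[DomainAnnotation] = []
    ortho_rows: list[tuple[str, str, str, str]] = []
    motif_rows: list[tuple[str, str, int]] = []
    origins: dict[str, str] = {}

    node_by_key = {keys[id(n)]: n for n in tree.preorder_node_iter()}
    descendants_of = {
        key: set(_leaves_under(node)) for key, node in node_by_key.items()
    }
    age = {s: i for i, s in enumerate(config.strata_order)}

    for fam in content.families:
        fidx = fam_index[fam.family_id]
        root_arch = archs[fidx]
        n_slots = len(root_arch) + len(gain_slots[fam.family_id])
        length = pad + n_slots * (dl + lk) + tail

        # active domain slots per node: list of (slot, name, active)
        slots0 = [(i, name, True) for i, name in enumerate(root_arch)]
        slots0 += [
            (len(root_arch) + j, ev.domain_name, False)
            for j, ev in enumerate(gain_slots[fam.family_id])
        ]

        origin_node = node_by_key[fam.origin_node]
        origin_species = descendants_of[fam.origin_node]
        origins[fam.family_id] = max(
            (config.species_strata[sp] for sp in origin_species),
            key=lambda s: age[s],
        )

        root_seq = rng.choice(20, size=length, p=freqs).astype(np.int8)
        seqs_at: dict[str, dict[str, np.ndarray]] = {
            fam.origin_node: {"1": root_seq}
        }
        slots_at: dict[str, list[tuple[int, str, bool]]] = {fam.origin_node: slots0}

        def _apply_domain_events(node_key: str, slots):
            out = list(slots)
            for ev in config.domain_events:
                if ev.family != fam.family_id or ev.node != node_key:
                    continue
                if ev.action == "loss":
                    for i, (slot, name, active) in enumerate(out):
                        if name == ev.domain_name and active:
                            out[i] = (slot, name, False)
                            break
                else:  # gain: activate this event's reserved slot
                    slot_idx = len(root_arch) + gain_slots[fam.family_id].index(ev)
                    for i, (slot, name, active) in enumerate(out):
                        if slot == slot_idx:
                            out[i] = (slot, name, True)
                            break
            return out

        def _descend(node) -> None:
            parent_key = keys[id(node)]
            for child in node.child_nodes():
                child_key = keys[id(child)]
                t = child.edge.length or 0.0
                child_seqs: dict[str, np.ndarray] = {}
                for copy in sorted(fam.copies_at.get(child_key, ()), key=lambda c: int(c)):
                    parent_copy = fam.ancestor_of[(child_key, copy)]
                    child_seqs[copy] = _mutate(
                        seqs_at[parent_key][parent_copy], t, freqs, rng
                    )
                seqs_at[child_key] = child_seqs
                slots_at[child_key] = _apply_domain_events(
                    child_key, slots_at[parent_key]
                )
                _descend(child)

        _descend(origin_node)

        # plant motifs at the leaves of each gaining lineage
        planted: dict[str, list[tuple[str, int, str]]] = {}
        for ev in config.motif_events:
            if ev.family != fam.family_id:
                continue
            realization = motif_realizations[ev]
            start = length - ev.offset_from_cterm
            for sp in descendants_of[ev.node]:
                planted.setdefault(sp, []).append((ev.motif_name, start, realization))

        for sp in content.species:
            for copy in sorted(fam.copies_at.get(sp, ()), key=lambda c: int(c)):
                seq_arr = seqs_at[sp][copy]
                for motif_name, start, realization in planted.get(sp, []):
                    for k, ch in enumerate(realization):
                        seq_arr[start + k] = AA20.index(ch)
                pid = _protein_id(sp, fam.family_id, copy)
                sequence = "".join(AA20[i] for i in seq_arr)
                proteomes[sp].add(
                    ProteinRecord(
                        protein_id=pid,
                        species_id=sp,
                        sequence=sequence,
                        description=f"family={fam.family_id} copy={copy}",
                    )
                )
                for slot, name, active in slots_at[sp]:
                    if not active:
                        continue
                    start = pad + slot * (dl + lk)
                    annotations.append(
                        DomainAnnotation(
                            protein_id=pid,
                            domain_name=name,
                            start=start,
                            end=start + dl,
                            e_value=1e-20,
                            source="SIM",
                        )
                    )
                for motif_name, start, _ in planted.get(sp, []):
                    motif_rows.append((pid, motif_name, start))

    # true ortholog pairs: focal copies vs same-family copies elsewhere
    focal = config.focal_species
    for fam in content.families:
        for fcopy in sorted(fam.copies_at.get(focal, ()), key=lambda c: int(c)):
            comp = _protein_id(focal, fam.family_id, fcopy)
            for sp in content.species:
                if sp == focal:
                    continue
                for copy in sorted(fam.copies_at.get(sp, ()), key=lambda c: int(c)):
                    ortho_rows.append(
                        (comp, sp, _protein_id(sp, fam.family_id, copy), fam.family_id)
                    )

    counts = content.counts_table()
    truth = TruthTables(
        ortholog_pairs=pd.DataFrame(
            ortho_rows, columns=["component_id", "species_id", "protein_id", "family_id"]
        ),
        presence=counts > 0,
        counts=counts,
        origins=pd.Series(origins, name="stratum_id"),
        motif_placements=pd.DataFrame(
            motif_rows, columns=["protein_id", "motif_name", "start"]
        ),
    )
    return proteomes, annotations, truth


# ---------------------------------------------------------------------------
# on-disk bundles

@dataclass
class BenchmarkBundle:
    root: Path
    config: SimulationConfig
    panel: SpeciesPanel
    proteomes: dict[str, SpeciesProteome]
    annotations: list[DomainAnnotation]
    truth: TruthTables
    fasta_paths: dict[str, Path]
    annotations_path: Path
    tree_path: Path
    panel_path: Path


def _build_panel(config: SimulationConfig, tree: dendropy.Tree) -> SpeciesPanel:
    species = [
        SpeciesInfo(sp, sp, config.species_strata[sp])
        for sp in sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ]
    return SpeciesPanel(
        species=species,
        strata=list(config.strata_order),
        focal_species_id=config.focal_species,
        tree=tree,
    )


def generate_benchmark(config: SimulationConfig, out_dir: str | Path) -> BenchmarkBundle:
    """Simulate and write a complete, self-consistent benchmark bundle.

    Outputs: one FASTA per species, the domain-annotation TSV, the species
    tree and strata table, and the truth tables (presence/counts matrices,
    ortholog pairs, family origin strata, motif placements).  Running twice
    with the same config yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree, keys = _prepare_tree(config)
    content = simulate_gene_content(config)
    proteomes, annotations, truth = evolve_sequences(config, content)
    panel = _build_panel(config, tree)
    seed = config.seed

    fasta_paths: dict[str, Path] = {}
    for sp in sorted(proteomes):
        path = out_dir / f"{sp}.fasta"
        write_fasta(proteomes[sp], path)
        fasta_paths[sp] = path

    annotations_path = out_dir / "annotations.tsv"
    write_domain_annotations(annotations, annotations_path, seed=seed)

    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(config.newick.strip() + "\n")

    panel_path = out_dir / "panel.tsv"
    with open(panel_path, "w") as out:
        out.write(f"# cadhesome v{__version__} seed={seed}\n")
        out.write("species_id\tdisplay_name\tstratum_id\tstratum_rank\tfocal\n")
        for info in panel.species:
            rank = panel.stratum_age(info.stratum_id)
            focal = 1 if info.species_id == config.focal_species else 0
            out.write(
                f"{info.species_id}\t{info.display_name}\t{info.stratum_id}\t{rank}\t{focal}\n"
            )

    write_presence_matrix(truth.presence, out_dir / "truth_presence.tsv", seed=seed)
    header = f"# cadhesome v{__version__} seed={seed}\n"
    with open(out_dir / "truth_counts.tsv", "w") as out:
        out.write(header)
        truth.counts.to_csv(out, sep="\t")
    with open(out_dir / "truth_orthologs.tsv", "w") as out:
        out.write(header)
        truth.ortholog_pairs.to_csv(out, sep="\t", index=False)
    with open(out_dir / "truth_origins.tsv", "w") as out:
        out.write(header)
        truth.origins.rename_axis("family_id").to_csv(out, sep="\t")
    with open(out_dir / "truth_motifs.tsv", "w") as out:
        out.write(header)
        truth.motif_placements.to_csv(out, sep="\t", index=False)

    return BenchmarkBundle(
        root=out_dir,
        config=config,
        panel=panel,
        proteomes=proteomes,
        annotations=annotations,
        truth=truth,
        fasta_paths=fasta_paths,
        annotations_path=annotations_path,
        tree_path=tree_path,
        panel_path=panel_path,
    )


# ---------------------------------------------------------------------------
# survey scoring against truth

@dataclass(frozen=True)
class SurveyScore:
    sensitivity: float
    false_presence_rate: float
    n_present_cells: int
    n_absent_cells: int


def evaluate_survey(
    presence: pd.DataFrame,
    truth: TruthTables,
    families: Sequence[Family],
    focal_species: str,
) -> SurveyScore:
    """Compare a survey presence matrix with the generator's truth.

    Evaluated over every true family with at least one focal component and
    every non-focal species: sensitivity is the fraction of truly present
    cells called present, the false-presence rate the fraction of truly
    absent cells called present.
    """
    surveyed: dict[str, str] = {}
    for fam in families:
        for member in fam.members:
            surveyed.setdefault(family_of_protein(member), fam.family_id)
    species = [sp for sp in truth.presence.columns if sp != focal_species]
    tp = fn = fp = tn = 0
    for true_family, survey_family in sorted(surveyed.items()):
        for sp in species:
            truly_present = bool(truth.presence.loc[true_family, sp])
            called = bool(presence.loc[survey_family, sp]) if survey_family in presence.index else False
            if truly_present:
                tp += called
                fn += not called
            else:
                fp += called
                tn += not called
    n_present = tp + fn
    n_absent = fp + tn
    return SurveyScore(
        sensitivity=tp / n_present if n_present else 1.0,
        false_presence_rate=fp / n_absent if n_absent else 0.0,
        n_present_cells=n_present,
        n_absent_cells=n_absent,
    )


# ---------------------------------------------------------------------------
# canned study configurations

# Ten-species panel for parameter-recovery runs: a 0.12-high ultrametric
# tree (max pairwise divergence 0.24 substitutions/site) with five strata
# along the focal lineage.
RECOVERY_TREE_NEWICK = (
    "((((sp01:0.03,sp02:0.03)n1:0.03,sp03:0.06)n2:0.03,"
    "(sp04:0.045,sp05:0.045)n3:0.045)n4:0.03,"
    "(sp06:0.06,(sp07:0.04,(sp08:0.03,(sp09:0.02,sp10:0.02)n5:0.01)n6:0.01)n7:0.02)n8:0.06)root;"
)

RECOVERY_STRATA = {
    "sp01": "s1", "sp02": "s2", "sp03": "s2",
    "sp04": "s3", "sp05": "s3",
    "sp06": "s4", "sp07": "s4",
    "sp08": "s5", "sp09": "s5", "sp10": "s5",
}


def scaled_newick(newick: str, factor: float) -> str:
    """Multiply every branch length in a newick string by ``factor``."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def recovery_benchmark_config(
    n_families: int = 200,
    seed: int = 1,
    duplication_rate: float = 0.1,
    loss_rate: float = 0.1,
    origin_nodes: tuple[str | None, ...] | None = None,
    branch_scale: float = 1.0,
) -> SimulationConfig:
    """Study conditions for reciprocal best-hit parameter recovery.

    Ten species, divergence <= 0.3 substitutions/site between any pair
    (scale with ``branch_scale`` for lower-divergence conditions), families
    duplicated and lost at 0.1 events per copy per unit branch length.
    """
    newick = RECOVERY_TREE_NEWICK
    if branch_scale != 1.0:
        newick = scaled_newick(newick, branch_scale)
    return SimulationConfig(
        newick=newick,
        species_strata=RECOVERY_STRATA,
        strata_order=("s1", "s2", "s3", "s4", "s5"),
        focal_species="sp01",
        n_families=n_families,
        duplication_rate=duplication_rate,
        loss_rate=loss_rate,
        origin_nodes=origin_nodes,
        seed=seed,
    )


# 26-species panel mirroring the adhesome survey's taxon sampling:
# vertebrates through basal metazoans, unicellular holozoans, fungi and
# amoebozoa/apusozoa.  Branch lengths are illustrative (height 1.0).
ADHESOME_TREE_NEWICK = (
    "((((((((((((((Hs:0.10,Mm:0.10)hsmm:0.10,Gg:0.20)amniota:0.05,Xt:0.25)tetrapoda:0.05,"
    "Dr:0.30)vertebrata_n:0.10,(Ci:0.30,Bf:0.30)invchordata:0.10)chordata:0.05,"
    "(Sp:0.40,(Dm:0.30,Ce:0.30)ecdysozoa:0.10)nonchordate:0.05)bilateria_n:0.05,"
    "(Hv:0.35,Nv:0.35)cnidaria_n:0.15)eumetazoa:0.05,Ta:0.55)parahoxozoa:0.05,"
    "(Aq:0.35,Oc:0.35)porifera_n:0.25)metazoa:0.10,"
    "(Mb:0.45,Sr:0.45)choanoflagellata_n:0.25)choanozoa:0.05,Co:0.75)filozoa:0.05,"
    "Sa:0.80)holozoa:0.10,((Am:0.45,(Mv:0.35,Spu:0.35)mucoromycota:0.10)chytrid_n:0.10,"
    "(Sc:0.45,Spo:0.45)dikarya:0.10)fungi_n:0.35)opisthokonta:0.10,"
    "(Dd:0.70,Tt:0.70)amoebozoa_n:0.30)root;"
)

ADHESOME_STRATA_ORDER = (
    "vertebrata",
    "chordata_invert",
    "bilateria_nonchordate",
    "cnidaria",
    "placozoa",
    "porifera",
    "choanoflagellata",
    "filasterea",
    "ichthyosporea",
    "fungi",
    "amoebozoa_apusozoa",
)

ADHESOME_SPECIES_STRATA = {
    "Hs": "vertebrata", "Mm": "vertebrata", "Gg": "vertebrata",
    "Xt": "vertebrata", "Dr": "vertebrata",
    "Ci": "chordata_invert", "Bf": "chordata_invert",
    "Sp": "bilateria_nonchordate", "Dm": "bilateria_nonchordate",
    "Ce": "bilateria_nonchordate",
    "Hv": "cnidaria", "Nv": "cnidaria",
    "Ta": "placozoa",
    "Aq": "porifera", "Oc": "porifera",
    "Mb": "choanoflagellata", "Sr": "choanoflagellata",
    "Co": "filasterea",
    "Sa": "ichthyosporea",
    "Am": "fungi", "Mv": "fungi", "Spu": "fungi", "Sc": "fungi", "Spo": "fungi",
    "Dd": "amoebozoa_apusozoa", "Tt": "amoebozoa_apusozoa",
}


def adhesome_panel_config(
    n_families: int = 200,
    seed: int = 1,
    duplication_rate: float = 0.05,
    loss_rate: float = 0.05,
    origin_nodes: tuple[str | None, ...] | None = None,
) -> SimulationConfig:
    """A 26-species benchmark mirroring the adhesome survey's panel."""
    return SimulationConfig(
        newick=ADHESOME_TREE_NEWICK,
        species_strata=ADHESOME_SPECIES_STRATA,
        strata_order=ADHESOME_STRATA_ORDER,
        focal_species="Hs",
        n_families=n_families,
        duplication_rate=duplication_rate,
        loss_rate=loss_rate,
        origin_nodes=origin_nodes,
        seed=seed,
    )
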