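# Methods

## The inference problem

Given per-species protein sets, per-protein domain calls, a species
phylogeny stratified along a focal lineage, and a list of focal network
components, the pipeline decides for every (component, species) pair
whether the species carries an *analogous* protein, and summarizes the
resulting presence matrix phylostratigraphically. "Analogous" is
deliberately weaker than phylogenetic orthology: it is a reciprocal
best-hit (RBH) criterion reinforced by domain-architecture agreement,
chosen because the downstream questions (When did a family first appear?
How did it expand?) need detectable family membership, not resolved gene
trees. Probabilistic orthology (tree reconciliation) and profile/HMM
searches are out of scope by design.

## Search model

Alignment is exact Smith–Waterman with affine gaps: a gap of length g
costs `gap_open + g·gap_extend` (BLAST convention; defaults BLOSUM62,
11/1). There is no word seeding or banding, so scores are exactly
reproducible; the scoring kernel is compiled with numba (~5 ns/cell) and
is cross-checked in-process against Biopython's `PairwiseAligner` (used
for traceback spans) and, in the test suite, against a brute-force
enumerator over all monotone column matchings. The residue alphabet is
the 20 amino acids plus `X`, which scores 0 against everything (neutral
ambiguity); anything else is rejected at I/O.

Significance uses fixed Karlin–Altschul parameters per (matrix, gap)
preset (BLOSUM62 11/1: λ = 0.267, K = 0.041, the NCBI gapped values) —
no on-the-fly estimation, so E-values are deterministic:
`bit = (λS − ln K)/ln 2`, `E = m·n·2^(−bit)` with m the query length and
n the total residues of the searched proteome (a `fixed_n` mode pins n
for monotonicity testing). The acceptance threshold is E < 10,
calibrated so that bit ≈ 30 qualifies at typical query/database sizes.
Score-0 "hits" are never reported. Ranking is by (E asc, bit desc,
subject id asc) — total determinism. Query coverage is recorded on every
hit but never filtered on, because genuinely analogous proteins do not
always align full-length.

## The RBH verdict

For component c and target species s: take c's best hit h in s (none ⇒
reject, `no-forward-hit`); take h's best hit back in the **focal**
proteome; if it is not c or another member of c's family ⇒ reject,
`reciprocal-failure`; if c's and h's major-domain architectures differ ⇒
reject, `architecture-mismatch`; otherwise accept. "Member of the same
family" operationalizes "highly related": families are the pipeline's own
architecture clusters. The reciprocal condition is tested before the
architecture gate so each rejection names the first failing condition.
There is no fall-back to the second-best forward hit.

`run_survey` evaluates all components against all species. Because the
substitution matrix is symmetric, one exact focal×target score matrix per
species serves both search directions; forward and reciprocal best hits
are read off rows and columns with the same ordering `search()` uses, and
the equivalence of the two routes is asserted in the tests.

*Iterative expansion* reruns the search using analogs accepted in
designated intermediate species (sponge/Trichoplax-style lineages) as
queries against the targets, with the re-search always against the focal
proteome and the architecture gate always against the original component.
Provenance (`direct` / `expansion-round-k`) records which query seeded
each analog; output grows monotonically over rounds and iteration stops
at the first round that adds nothing.

*Characterization loop*: an unlabeled query adopts the family label of
its best hit among labeled references iff that reference's best hit among
the remaining unlabeled queries is the query itself; newly labeled
sequences join the reference pool. The label set grows monotonically and
reaches a fixed point; never-labeled queries are "unrelated". This is our
operationalization of iterating "until each sequence could be confidently
defined" — the original procedure gives no quantitative criterion.

## Architectures and families

Domain calls (SMART- and CDD-style sources pooled; tags kept for audit)
become an ordered major-domain signature: keep calls with E ≤ 1e-4 and
length ≥ 20 residues (the notion of "major" is not quantified upstream;
both are configurable), resolve overlaps greedily by ascending e-value
(ties: longer, then name), *dropping* the loser rather than trimming —
overlapping calls usually name the same region twice, and trimming would
invent boundaries. Exact clustering partitions by signature equality;
broad clustering takes single-linkage components of "multiset Jaccard of
domain names ≥ 0.5" (the broad mode is defined upstream only by example,
so the threshold is a package choice) and supports configured merge lists
for curated exceptions (MAGUK scaffolds, actinin/spectrin).

## Motifs

Patterns are ordered allowed-residue sets compiled from bracket notation
(`x` = any). The CBD GBM default `[ED]xx[FWY]xx[ED]` is a reconstruction
from the structural description of the β-catenin groove interaction (an
aromatic anchor flanked by acidic contacts); the published source renders
the pattern only graphically, so it is a config entry, never hard-coded.
PDZ-binding classes follow the standard convention — P0 is the C-terminal
residue and must be hydrophobic {V,I,L,F,A}; class I has S/T at P−2 (the
third-from-last residue, as in the canonical ...ETDV tail), class II a
hydrophobic P−2; class I takes precedence. Tail extraction takes
everything C-terminal to the last annotated TM segment (single-pass
type-I topology, the cadherin case). A cadherin is "classical"-like iff
it has EC repeats and a CBD GBM, by definition. Column conservation maps
a 1-based ungapped reference position through the reference's gaps and
counts gap rows as non-conserved in the denominator.

## Synthetic benchmarks

The generator emulates exactly the structure the analysis assumes, with
closed-form oracles:

* **Gene content**: each family starts as one copy at its origin node
  (default: the root; configurable per family, which is what
  phylostratigraphy later recovers) and evolves down each branch by a
  linear birth–death process (Gillespie; duplication δ and loss μ per
  copy per unit branch length). Pure birth gives E[N(t)] = e^(δt);
  per-branch copy counts obey parent + births − deaths. With δ = μ = 0,
  exactly one copy per species under the origin.
* **Sequences**: root sequences are drawn from stationary frequencies
  (default uniform); along a branch of length t each site substitutes
  with probability 1 − e^(−t), the replacement drawn from the stationary
  frequencies (so P(site matches ancestor) = e^(−t) + (1 − e^(−t))Σπ²).
  No rate heterogeneity, no indels, no selection — simple enough to
  stress the RBH logic while keeping oracles exact. Copies born
  mid-branch inherit the branch-start sequence and mutate over the full
  branch.
* **Architectures**: inherited verbatim except for configured gain/loss
  events; a loss stops annotating a domain (the residues stay —
  degeneration), a gain activates a reserved C-terminal slot, so lengths
  and coordinates are constant across the tree. Auto-generated root
  architectures are *unique per family* (shuffled enumeration of 1–3
  domain combinations) so that exact clustering of the focal proteome
  reproduces the true families and truth comparisons are unambiguous.
* **Motifs**: a gain event overwrites tail residues at a fixed offset
  from the C-terminus in every descendant leaf *after* substitution —
  i.e. the motif is held fixed on gaining lineages, a stand-in for
  purifying selection — so "all and only descendants carry a
  scanner-detectable motif" holds exactly and truth coordinates are
  stable.

Proteins are 60–120 aa mini-proteins (domain 24 aa, linker 6, pad 6,
tail 24): long enough that true homologs are separated from noise by
tens of bits at the divergences studied, small enough that the full
recovery suite (20 replicates × 200 families × 10 species ≈ 15M exact
alignments) runs in minutes. Protein ids are `species|family.copy`
(copy indices mark duplicates), keeping truth tables unambiguous. All
randomness flows from one config seed through per-stage child seeds, so
each stage is independently deterministic and bundles are byte-identical.

What the benchmarks do **not** emulate: real proteome size and
composition bias, domain shuffling, indels, alignment ambiguity from
repeats, annotation noise. Passing recovery tests therefore demonstrates
the correctness and determinism of the inference chain under its own
model assumptions, not expected accuracy on real proteomes.

## Study conditions used by the test suite

* Recovery: a 10-species ultrametric tree of height 0.12 (max pairwise
  divergence 0.24 subs/site), 200 families, δ = μ = 0.1, seeds 1–20,
  pooled; and a clean condition at branch scale 0.2 (divergence ≤ 0.048)
  with δ = μ = 0 where recovery must be exact.
* Expansion demonstration: a three-species tree with a long focal branch
  (focal–target 2.25 subs/site, sponge–target 0.95, focal–sponge 1.4)
  and 300 target-only decoy families, so the target analog is invisible
  to the direct survey but found from the sponge-level query and
  confirmed by the reciprocal search back to the focal proteome.
* The packaged 26-species presence fixture realizes the published
  112-family group totals; the 8 pre-metazoan families whose stratum is
  not printed as text are carried in the fungi stratum (all reported
  group totals are invariant to this placement), and within-group splits
  are arbitrary realizations, documented in `cadhesome.fixtures`.

## Numerical and degenerate-input choices

File coordinates are 1-based inclusive, internal coordinates 0-based
half-open; conversion happens only at the I/O boundary. Empty sequences
are I/O errors, but empty *alignments* (score 0) are valid results with
empty spans. Empty databases yield empty hit lists, not errors. Families
absent from every species are reported as unassigned, never dropped. The
per-stratum paralog value is the maximum over that stratum's species
(one value per stratum on the expansion curve; the per-species table is
emitted alongside). Tabular outputs carry a `# cadhesome v… seed=…`
header line; FASTA output is exempt because the format has no comment
syntax. Multi-isoform proteomes are a documented preprocessing
expectation: supply one sequence per gene, or accept that isoforms
appear as extra family members.

## Known limitations

The linear stratification reads first appearances along the focal
lineage only (a full tree is carried, but there is no ancestral-state
reconstruction over arbitrary topologies). Karlin–Altschul presets are
calibrated for natural protein composition, so E-values on uniform-
composition synthetic sequences are conservative. The broad-clustering
threshold and the CBD GBM pattern are package reconstructions and should
be configured explicitly when reproducing any specific published
grouping; the exact 173-component → 112-family clustering additionally
requires the curated merge list that accompanied the original survey.
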