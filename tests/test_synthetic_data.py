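from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pytest

from cadhesome.motif_scan import JMD_GBM_PATTERN, compile_motif, scan
from cadhesome.synthetic_data import (
    MotifGainEvent,
    SimulationConfig,
    evolve_sequences,
    generate_benchmark,
    recovery_benchmark_config,
    scaled_newick,
    simulate_gene_content,
    _prepare_tree,
)

TWO_SPECIES = dict(
    newick="(p:1.0,q:0.001)root;",
    species_strata={"p": "old", "q": "young"},
    strata_order=("young", "old"),
    focal_species="q",
)


def two_species_config(**kw):
    return SimulationConfig(**{**TWO_SPECIES, **kw})


class TestGeneContent:
    def test_no_events_means_single_copy_everywhere(self):
        config = SimulationConfig(
            newick="((a:0.1,b:0.1)n1:0.1,c:0.2)root;",
            species_strata={"a": "s1", "b": "s2", "c": "s3"},
            strata_order=("s1", "s2", "s3"),
            focal_species="a",
            n_families=5,
        )
        counts = simulate_gene_content(config).counts_table()
        assert counts.shape == (5, 3)
        assert (counts == 1).all().all()

    def test_heavy_loss_on_one_branch_empties_that_species(self):
        config = SimulationConfig(
            newick="(far:8.0,(a:0.01,b:0.01)n1:0.01)root;",
            species_strata={"far": "s2", "a": "s1", "b": "s1"},
            strata_order=("s1", "s2"),
            focal_species="a",
            n_families=30,
            loss_rate=2.0,
            seed=4,
        )
        counts = simulate_gene_content(config).counts_table()
        # survival probability over the long branch is ~e^-16; the short
        # branches lose only the occasional family (~2% per branch)
        assert (counts["far"] == 0).all()
        assert (counts[["a", "b"]].to_numpy() > 0).mean() > 0.9

    def test_pure_birth_mean_matches_closed_form(self):
        # E[N(t)] = e^(delta * t) for a Yule process; delta=0.2, t=1
        totals = []
        for seed in range(1, 21):
            config = two_species_config(n_families=500, duplication_rate=0.2, seed=seed)
            counts = simulate_gene_content(config).counts_table()
            totals.extend(counts["p"].tolist())
        assert np.mean(totals) == pytest.approx(math.exp(0.2), abs=0.02)

    def test_copy_conservation_along_every_branch(self):
        config = two_species_config(
            n_families=40, duplication_rate=0.5, loss_rate=0.5, seed=9
        )
        content = simulate_gene_content(config)
        tree, keys = _prepare_tree(config)
        for fam in content.families:
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    parent_key, child_key = keys[id(node)], keys[id(child)]
                    if parent_key not in fam.copies_at:
                        continue
                    n_parent = len(fam.copies_at[parent_key])
                    n_child = len(fam.copies_at[child_key])
                    assert n_child == n_parent + fam.births[child_key] - fam.deaths[child_key]

    def test_origin_node_restricts_family_to_subtree(self):
        config = SimulationConfig(
            newick="((a:0.1,b:0.1)n1:0.1,c:0.2)root;",
            species_strata={"a": "s1", "b": "s2", "c": "s3"},
            strata_order=("s1", "s2", "s3"),
            focal_species="a",
            n_families=2,
            origin_nodes=(None, "n1"),
        )
        counts = simulate_gene_content(config).counts_table()
        assert counts.loc["F0000"].tolist() == [1, 1, 1]
        assert counts.loc["F0001", "c"] == 0
        assert counts.loc["F0001", ["a", "b"]].tolist() == [1, 1]


class TestSequenceEvolution:
    def test_zero_branch_preserves_sequence(self):
        config = SimulationConfig(
            newick="(p:0.0,q:0.0)root;",
            species_strata={"p": "old", "q": "young"},
            strata_order=("young", "old"),
            focal_species="q",
            n_families=5,
            seed=2,
        )
        proteomes, _, _ = evolve_sequences(config, simulate_gene_content(config))
        for fam in ("F0000", "F0001"):
            assert (
                proteomes["p"][f"p|{fam}.1"].sequence
                == proteomes["q"][f"q|{fam}.1"].sequence
            )

    @pytest.mark.parametrize("t,n_seeds", [(10.0, 10), (0.5, 10)])
    def test_site_identity_matches_poisson_model(self, t, n_seeds):
        # P(site matches ancestor) = e^-t + (1 - e^-t) * sum(pi^2)
        expected = math.exp(-t) + (1 - math.exp(-t)) * 20 * (1 / 20) ** 2
        matches = total = 0
        for seed in range(1, n_seeds + 1):
            config = SimulationConfig(
                newick=f"(p:{t},q:0.0)root;",
                species_strata={"p": "old", "q": "young"},
                strata_order=("young", "old"),
                focal_species="q",
                n_families=20,
                seed=seed,
            )
            proteomes, _, _ = evolve_sequences(config, simulate_gene_content(config))
            for rec in proteomes["p"]:
                ancestor = proteomes["q"][rec.protein_id.replace("p|", "q|")]
                matches += sum(x == y for x, y in zip(rec.sequence, ancestor.sequence))
                total += len(rec.sequence)
        sd = math.sqrt(expected * (1 - expected) / total)
        assert matches / total == pytest.approx(expected, abs=max(5 * sd, 0.01))

    def test_motif_gained_on_lineage_detectable_in_all_and_only_descendants(self):
        config = SimulationConfig(
            newick="((a:0.05,b:0.05)meta:0.05,c:0.1)root;",
            species_strata={"a": "s1", "b": "s2", "c": "s3"},
            strata_order=("s1", "s2", "s3"),
            focal_species="a",
            n_families=3,
            motif_events=(
                MotifGainEvent("meta", "JMD_GBM", JMD_GBM_PATTERN, "F0001", 16),
            ),
            seed=6,
        )
        proteomes, _, truth = evolve_sequences(config, simulate_gene_content(config))
        motif = compile_motif(JMD_GBM_PATTERN, "JMD_GBM")
        detected = {
            rec.protein_id
            for sp in proteomes.values()
            for rec in sp
            if scan(rec.sequence, motif)
        }
        assert detected == set(truth.motif_placements["protein_id"])
        assert detected == {"a|F0001.1", "b|F0001.1"}
        # planted exactly where the truth table says
        (start,) = set(truth.motif_placements["start"])
        for pid in detected:
            sp = pid.split("|")[0]
            hits = scan(proteomes[sp][pid].sequence, motif)
            assert start in {h.start for h in hits}

    def test_motif_longer_than_tail_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            two_species_config(
                n_families=1,
                tail_length=6,
                motif_events=(
                    MotifGainEvent("root", "JMD_GBM", JMD_GBM_PATTERN, "F0000", 6),
                ),
            )


class TestBenchmarkBundle:
    @staticmethod
    def _bundle_bytes(root: Path) -> dict[str, bytes]:
        return {p.name: p.read_bytes() for p in sorted(root.iterdir())}

    def test_fixed_seed_gives_byte_identical_bundles(self, tmp_path):
        config = recovery_benchmark_config(n_families=8, seed=1)
        b1 = generate_benchmark(config, tmp_path / "one")
        b2 = generate_benchmark(config, tmp_path / "two")
        assert self._bundle_bytes(b1.root) == self._bundle_bytes(b2.root)
        b3 = generate_benchmark(
            recovery_benchmark_config(n_families=8, seed=2), tmp_path / "three"
        )
        assert self._bundle_bytes(b1.root) != self._bundle_bytes(b3.root)

    def test_bundle_is_self_consistent(self, low_divergence_bundle):
        bundle = low_divergence_bundle
        all_ids = {r.protein_id for p in bundle.proteomes.values() for r in p}
        assert {a.protein_id for a in bundle.annotations} <= all_ids
        assert set(bundle.truth.ortholog_pairs["protein_id"]) <= all_ids
        # counts agree with the proteomes
        for sp, proteome in bundle.proteomes.items():
            assert bundle.truth.counts[sp].sum() == len(proteome)

    def test_empty_bundle_is_valid(self, tmp_path):
        config = recovery_benchmark_config(n_families=0, seed=1)
        bundle = generate_benchmark(config, tmp_path / "empty")
        assert all(len(p) == 0 for p in bundle.proteomes.values())
        assert bundle.truth.presence.empty

    def test_full_panel_bundle_generates_quickly(self, tmp_path):
        import time

        from cadhesome.synthetic_data import adhesome_panel_config

        start = time.perf_counter()
        bundle = generate_benchmark(
            adhesome_panel_config(n_families=200, seed=3), tmp_path / "panel"
        )
        assert time.perf_counter() - start < 60
        assert len(bundle.proteomes) == 26
        assert bundle.truth.counts.shape[0] == 200


class TestScaledNewick:
    def test_scaling_preserves_topology_and_scales_lengths(self):
        config = recovery_benchmark_config(n_families=1, branch_scale=0.2)
        tree, _ = _prepare_tree(config)
        depth = max(
            leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        )
        assert depth == pytest.approx(0.12 * 0.2)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {
            f"sp{i:02d}" for i in range(1, 11)
        }
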