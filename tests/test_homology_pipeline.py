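from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from helpers import make_proteome
from conftest import make_bundle_parts
from cadhesome.architecture import (
    Architecture,
    architectures_from_annotations,
    cluster_families,
)
from cadhesome.homology_pipeline import (
    REJECT_ARCHITECTURE,
    REJECT_NO_FORWARD,
    REJECT_RECIPROCAL,
    classify_iteratively,
    iterative_expansion,
    reciprocal_best_hit,
    run_survey,
)
from cadhesome.io_formats import ProteinRecord
from cadhesome.sequence_search import ScoringScheme
from cadhesome.synthetic_data import evaluate_survey, recovery_benchmark_config

SEQ_A = "MKVLGWYENDAHRPQSTCIFDEKRHWNQSTAGVLIM"
SEQ_B = "PPGGSSTTAAWWHHKKRRNNQQEEDDFFYYCCMMLL"


def _families(archs):
    return cluster_families(archs)


class TestReciprocalBestHit:
    def test_exact_copy_accepted(self, scheme):
        focal = make_proteome("hs", {"hs|comp": SEQ_A, "hs|other": SEQ_B})
        target = make_proteome("sp", {"sp|copy": SEQ_A})
        archs = {
            "hs|comp": Architecture(("CA",)),
            "hs|other": Architecture(("WW",)),
            "sp|copy": Architecture(("CA",)),
        }
        res = reciprocal_best_hit(
            "hs|comp", target, focal, _families({k: archs[k] for k in ("hs|comp", "hs|other")}),
            archs, scheme,
        )
        assert res.verdict == "accepted"
        assert res.analog_id == "sp|copy"
        # acceptance invariant triple
        assert res.forward and res.reciprocal and res.architecture_match

    def test_reciprocal_to_unrelated_component_rejected(self, scheme):
        # target's only protein is a copy of a different focal protein
        focal = make_proteome("hs", {"hs|comp": SEQ_A, "hs|other": SEQ_B})
        target = make_proteome("sp", {"sp|bcopy": SEQ_B})
        archs = {
            "hs|comp": Architecture(("CA",)),
            "hs|other": Architecture(("WW",)),
            "sp|bcopy": Architecture(("WW",)),
        }
        res = reciprocal_best_hit(
            "hs|comp", target, focal,
            _families({k: archs[k] for k in ("hs|comp", "hs|other")}),
            archs, scheme, max_e=1e9,
        )
        assert res.verdict == "rejected"
        assert res.reason == REJECT_RECIPROCAL

    def test_architecture_mismatch_rejected(self, scheme):
        focal = make_proteome("hs", {"hs|comp": SEQ_A})
        target = make_proteome("sp", {"sp|copy": SEQ_A})
        archs = {
            "hs|comp": Architecture(("CA", "CA")),
            "sp|copy": Architecture(("CA",)),  # degenerate second repeat
        }
        res = reciprocal_best_hit(
            "hs|comp", target, focal, _families({"hs|comp": archs["hs|comp"]}),
            archs, scheme,
        )
        assert res.verdict == "rejected"
        assert res.reason == REJECT_ARCHITECTURE

    def test_no_forward_hit_reported(self, scheme):
        focal = make_proteome("hs", {"hs|comp": SEQ_A})
        target = make_proteome("sp", {"sp|far": SEQ_B})
        archs = {"hs|comp": Architecture(("CA",)), "sp|far": Architecture(("WW",))}
        res = reciprocal_best_hit(
            "hs|comp", target, focal, _families({"hs|comp": archs["hs|comp"]}),
            archs, scheme, max_e=1e-6,
        )
        assert res.verdict == "rejected" and res.reason == REJECT_NO_FORWARD

    def test_missing_architecture_is_configuration_error(self, scheme):
        focal = make_proteome("hs", {"hs|comp": SEQ_A})
        target = make_proteome("sp", {"sp|copy": SEQ_A})
        with pytest.raises(ValueError, match="architecture"):
            reciprocal_best_hit(
                "hs|comp", target, focal, _families({"hs|comp": Architecture(("CA",))}),
                {"hs|comp": Architecture(("CA",))}, scheme,
            )

    def test_synthetic_ortholog_accepted_per_truth(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        comp = components[0]
        res = reciprocal_best_hit(
            comp, bundle.proteomes["sp10"], bundle.proteomes["sp01"],
            families, archs, scheme,
        )
        assert res.verdict == "accepted"
        truth_pairs = bundle.truth.ortholog_pairs
        truthy = set(
            truth_pairs[
                (truth_pairs.component_id == comp) & (truth_pairs.species_id == "sp10")
            ]["protein_id"]
        )
        assert res.analog_id in truthy


class TestRunSurvey:
    def test_clean_bundle_recovered_perfectly(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        _, presence = run_survey(
            components, bundle.panel, bundle.proteomes, archs, families, scheme
        )
        score = evaluate_survey(presence, bundle.truth, families, "sp01")
        assert score.sensitivity == 1.0
        assert score.false_presence_rate == 0.0

    def test_lost_families_absent_from_matrix(self, scheme):
        config = recovery_benchmark_config(
            n_families=25, seed=13, duplication_rate=0.0, loss_rate=6.0,
            branch_scale=0.2,
        )
        panel, proteomes, annotations, truth = make_bundle_parts(config)
        archs = architectures_from_annotations(annotations)
        components = sorted(proteomes["sp01"].ids())
        families = cluster_families({c: archs[c] for c in components})
        _, presence = run_survey(components, panel, proteomes, archs, families, scheme)
        score = evaluate_survey(presence, truth, families, "sp01")
        assert score.n_absent_cells > 0  # losses actually happened
        assert score.false_presence_rate == 0.0
        assert score.sensitivity == 1.0

    def test_fast_path_agrees_with_single_pair_calls(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        table, _ = run_survey(
            components, bundle.panel, bundle.proteomes, archs, families, scheme
        )
        for comp in components[:6]:
            for sp in ("sp02", "sp07"):
                res = reciprocal_best_hit(
                    comp, bundle.proteomes[sp], bundle.proteomes["sp01"],
                    families, archs, scheme,
                )
                fast = table[
                    (table.component_id == comp) & (table.species_id == sp)
                ]["analog_id"].tolist()
                slow = [res.analog_id] if res.verdict == "accepted" else []
                assert fast == slow

    def test_empty_component_set(self, surveyed_bundle, scheme):
        bundle, archs, _, _ = surveyed_bundle
        table, presence = run_survey(
            [], bundle.panel, bundle.proteomes, archs, [], scheme
        )
        assert table.empty and presence.empty

    def test_missing_proteome_listed(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        proteomes = {k: v for k, v in bundle.proteomes.items() if k != "sp05"}
        with pytest.raises(ValueError, match="sp05"):
            run_survey(components, bundle.panel, proteomes, archs, families, scheme)

    def test_survey_deterministic(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        t1, p1 = run_survey(
            components, bundle.panel, bundle.proteomes, archs, families, scheme
        )
        t2, p2 = run_survey(
            components, bundle.panel, bundle.proteomes, archs, families, scheme
        )
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(p1, p2)


class TestIterativeExpansion:
    def test_no_intermediates_equals_direct_survey(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        targets = [sp for sp in bundle.panel.species_ids() if sp != "sp01"]
        expanded = iterative_expansion(
            components, [], targets, bundle.panel, bundle.proteomes, archs,
            families, scheme,
        )
        direct, _ = run_survey(
            components, bundle.panel, bundle.proteomes, archs, families, scheme
        )
        assert set(map(tuple, expanded.values.tolist())) == set(
            map(tuple, direct.values.tolist())
        )

    def test_output_contains_direct_survey(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        targets = [sp for sp in bundle.panel.species_ids() if sp != "sp01"]
        expanded = iterative_expansion(
            components[:5], ["sp06"], targets, bundle.panel, bundle.proteomes,
            archs, families, scheme,
        )
        direct, _ = run_survey(
            components[:5], bundle.panel, bundle.proteomes, archs, families, scheme
        )
        direct_keys = {
            (r.component_id, r.species_id, r.analog_id) for r in direct.itertuples()
        }
        expanded_keys = {
            (r.component_id, r.species_id, r.analog_id) for r in expanded.itertuples()
        }
        assert direct_keys <= expanded_keys

    def test_invalid_round_count_rejected(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        with pytest.raises(ValueError, match="max_rounds"):
            iterative_expansion(
                components, [], ["sp02"], bundle.panel, bundle.proteomes, archs,
                families, scheme, max_rounds=0,
            )

    def test_unknown_intermediate_rejected(self, surveyed_bundle, scheme):
        bundle, archs, components, families = surveyed_bundle
        with pytest.raises(ValueError, match="atlantis"):
            iterative_expansion(
                components, ["atlantis"], ["sp02"], bundle.panel,
                bundle.proteomes, archs, families, scheme,
            )


class TestClassifyIteratively:
    @staticmethod
    def _mutate(seq: str, positions, rng) -> str:
        residues = "ACDEFGHIKLMNPQRSTVWY"
        out = list(seq)
        for pos in positions:
            out[pos] = residues[int(rng.integers(20))]
        return "".join(out)

    def test_identical_query_labeled_first_round(self, scheme):
        ref = make_proteome("ref", {"catenin1": SEQ_A})
        query = ProteinRecord("q1", "x", SEQ_A)
        labels = classify_iteratively([query], [ref], {"catenin1": "catenin"}, scheme)
        assert labels == {"q1": "catenin"}

    def test_chain_propagates_in_two_rounds(self, scheme):
        # A (labeled) -> B -> C, where C is detectable only from B
        rng = np.random.default_rng(5)
        base = "".join(
            np.random.default_rng(1).choice(list("ACDEFGHIKLMNPQRSTVWY"), 80)
        )
        pos = rng.permutation(80)
        seq_b = self._mutate(base, pos[:30], rng)
        seq_c = self._mutate(seq_b, pos[30:60], rng)
        ref = make_proteome("ref", {"A": base})
        queries = [ProteinRecord("B", "x", seq_b), ProteinRecord("C", "x", seq_c)]
        strict = 1e-10
        labels = classify_iteratively(
            queries, [ref], {"A": "aardvark"}, scheme, max_e=strict
        )
        assert labels == {"B": "aardvark", "C": "aardvark"}
        # with a single round, the chain cannot reach C
        one_round = classify_iteratively(
            queries, [ref], {"A": "aardvark"}, scheme, max_e=strict, max_rounds=1
        )
        assert one_round == {"B": "aardvark", "C": "unrelated"}

    def test_unmatched_query_is_unrelated(self, scheme):
        ref = make_proteome("ref", {"A": SEQ_A})
        query = ProteinRecord("q", "x", SEQ_B)
        labels = classify_iteratively([query], [ref], {"A": "fam"}, scheme, max_e=1e-6)
        assert labels == {"q": "unrelated"}

    def test_conflicting_reference_labels_rejected(self, scheme):
        ref = make_proteome("ref", {"A": SEQ_A})
        with pytest.raises(ValueError, match="conflicting"):
            classify_iteratively(
                [], [ref], [("A", "fam1"), ("A", "fam2")], scheme
            )
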