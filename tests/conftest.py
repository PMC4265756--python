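from __future__ import annotations

import pytest

from cadhesome.architecture import architectures_from_annotations, cluster_families
from cadhesome.sequence_search import ScoringScheme
from cadhesome.synthetic_data import (
    generate_benchmark,
    recovery_benchmark_config,
    simulate_gene_content,
    evolve_sequences,
    _build_panel,
    _prepare_tree,
)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def low_divergence_bundle(tmp_path_factory):
    """A clean benchmark: 20 families, no duplication/loss, divergence <= 0.05."""
    config = recovery_benchmark_config(
        n_families=20, seed=11, duplication_rate=0.0, loss_rate=0.0, branch_scale=0.2
    )
    return generate_benchmark(config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def surveyed_bundle(low_divergence_bundle):
    """The clean bundle plus everything a survey needs, precomputed."""
    bundle = low_divergence_bundle
    archs = architectures_from_annotations(bundle.annotations)
    components = sorted(bundle.proteomes["sp01"].ids())
    families = cluster_families({c: archs[c] for c in components})
    return bundle, archs, components, families


def make_bundle_parts(config):
    """Run a simulation without touching disk; returns panel/proteomes/etc."""
    tree, _ = _prepare_tree(config)
    content = simulate_gene_content(config)
    proteomes, annotations, truth = evolve_sequences(config, content)
    return _build_panel(config, tree), proteomes, annotations, truth
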