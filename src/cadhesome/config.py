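"""Declarative pipeline configuration.

One YAML file drives a reproducible run; command-line flags override
individual keys.  Documented keys::

    matrix: BLOSUM62        # substitution matrix name
    gap_open: 11            # positive integers; a gap of length g costs
    gap_extend: 1           #   gap_open + g * gap_extend
    max_e: 10.0             # E-value acceptance threshold of the survey
    clustering_mode: exact  # exact | broad
    broad_threshold: 0.5    # multiset-Jaccard cutoff for broad matching
    domain_max_e: 1.0e-4    # "major domain" e-value cutoff
    domain_min_len: 20      # "major domain" minimum length (residues)
    cbd_gbm: "[ED]xx[FWY]xx[ED]"   # CBD groove-binding motif pattern
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .motif_scan import CBD_GBM_PATTERN
from .sequence_search import ScoringScheme

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    max_e: float = 10.0
    clustering_mode: str = "exact"
    broad_threshold: float = 0.5
    domain_max_e: float = 1e-4
    domain_min_len: int = 20
    cbd_gbm: str = CBD_GBM_PATTERN
    seed: int = 0

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix, gap_open=self.gap_open, gap_extend=self.gap_extend
        )


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword arguments (CLI flags) take precedence."""
    values: dict = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = sorted(set(loaded) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
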