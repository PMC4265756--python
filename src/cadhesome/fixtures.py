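"""Packaged reference fixtures for the adhesome survey.

The package ships a 26-species panel (vertebrates through basal metazoans,
unicellular holozoans, fungi and amoebozoa/apusozoa), the published
per-group totals of the "simplified" cadherin adhesome (112 protein
families), and a presence matrix *realizing* those totals.

The stratified counts are transcribed group totals: 45 families first
appearing at the amoebozoa/apusozoa stratum or earlier, 27 across the
unicellular-holozoan strata (ichthyosporea, filasterea, choanoflagellata),
17 at porifera and 15 in younger metazoan strata; the remaining 8
pre-metazoan families, whose exact stratum is reported only graphically,
are carried in the fungi stratum so that every group total is preserved.
The presence matrix is a synthetic realization: per-family species
occupancy (beyond a guaranteed witness in the origin stratum plus the
focal species) is arbitrary, as are family placements within a
multi-stratum group and the identities of unnamed families.  First
appearances computed from the matrix reproduce the group totals exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io_formats import SpeciesPanel, read_presence_matrix, read_species_panel

__all__ = [
    "fixture_path",
    "load_adhesome_panel",
    "load_stratum_counts",
    "load_presence_fixture",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("cadhesome").joinpath("data", name))


def load_adhesome_panel() -> SpeciesPanel:
    """The 26-species panel with its stratification (focal: Hs)."""
    return read_species_panel(
        fixture_path("adhesome_tree.nwk"), fixture_path("adhesome_panel.tsv")
    )


def load_stratum_counts() -> dict[str, int]:
    """Published novel-family totals per stratum (112 families in all)."""
    table = pd.read_csv(fixture_path("adhesome_stratum_counts.tsv"), sep="\t")
    return dict(zip(table["stratum_id"], table["n_families"].astype(int)))


def load_presence_fixture() -> pd.DataFrame:
    """The packaged 112-family presence matrix (see module docstring)."""
    return read_presence_matrix(
        fixture_path("adhesome_presence_fixture.tsv"), panel=load_adhesome_panel()
    )
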