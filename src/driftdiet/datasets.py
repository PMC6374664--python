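"""Packaged published reference tables.

Three small tables transcribed from the published study this pipeline
operationalizes, shipped so the deterministic stages can be exercised
mid-pipeline without any external data:

* the mock-homogenate mean biomass / sequence percentages with the
  published relative correction factors,
* the nightly drift-net catch biomass per family with individual dry
  masses and ESU groupings,
* the pairwise Schoener overlap values for both sampling periods.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_mock_homogenate",
    "load_drift_biomass",
    "load_overlap_pairs",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("driftdiet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mock_homogenate() -> pd.DataFrame:
    """Mock-homogenate table: family, biomass_pct, sequence_pct, rcf_published.

    Eleven rows; families indistinguishable at 18S V9 are already
    merged (three mayfly families into one row, two caddisfly families
    into another).
    """
    return _read("mock_homogenate.tsv")


def load_drift_biomass() -> pd.DataFrame:
    """Tidy nightly drift catch biomass (grams).

    Columns: night, period (drift/postdrift), family, esu,
    individual_dry_mass_mg, biomass_g. Five drift nights and two
    postdrift nights over eleven families in six ESUs.
    """
    return _read("drift_nightly_biomass.tsv")


def load_overlap_pairs() -> pd.DataFrame:
    """Pairwise Schoener overlap for 13 predator species, both periods.

    Columns: species_a, species_b (three-letter codes), alpha_drift,
    alpha_postdrift; 78 unordered pairs.
    """
    return _read("dietary_overlap_pairs.tsv")
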