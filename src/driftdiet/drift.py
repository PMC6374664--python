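"""Drift-net survey processing: counts to biomass to availability.

Nightly drift-net catches are counted from 5% subsamples of the cod-end
contents (larval sturgeon are counted whole on site), identified to
family, and converted to dry-weight biomass with per-family individual
dry masses. Families sharing an ecologically significant unit (ESU) are
summed, nights are averaged within each sampling period, and the
per-night ESU biomass vector — after flooring zero entries so Manly's
selection index stays finite — becomes the availability vector n used
by the selectivity indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "estimate_catch_biomass",
    "aggregate_biomass_to_esu",
    "period_average_biomass",
    "availability_proportions",
]


def estimate_catch_biomass(count, dry_mass_mg, subsample_fraction=0.05):
    """Nightly catch biomass in grams from a subsample count.

    ``grams = count * dry_mass_mg / subsample_fraction / 1000``.
    Taxa counted in full (no subsampling) use ``subsample_fraction=1``.
    Inputs may be scalars or aligned arrays/Series.
    """
    count_arr = np.asarray(count, dtype=float)
    mass = np.asarray(dry_mass_mg, dtype=float)
    frac = np.asarray(subsample_fraction, dtype=float)
    if (frac <= 0).any() if frac.ndim else frac <= 0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if (count_arr < 0).any() if count_arr.ndim else count_arr < 0:
        raise ValueError("counts must be nonnegative")
    if (mass < 0).any() if mass.ndim else mass < 0:
        raise ValueError("dry masses must be nonnegative")
    grams = count_arr * mass / frac / 1000.0
    if np.ndim(grams) == 0:
        return float(grams)
    if isinstance(count, pd.Series):
        return pd.Series(grams, index=count.index)
    return grams


def aggregate_biomass_to_esu(survey: pd.DataFrame,
                             family_to_esu: dict[str, str] | None = None,
                             night_col: str = "night", family_col: str = "family",
                             esu_col: str = "esu",
                             biomass_col: str = "biomass_g") -> pd.DataFrame:
    """Sum per-family nightly biomass into nights x ESUs.

    The ESU of each family is taken from ``family_to_esu`` when given,
    otherwise from the survey's own ``esu`` column. Total biomass is
    conserved: row sums equal the per-night family sums.
    """
    t = survey.copy()
    if family_to_esu is not None:
        unmapped = sorted(set(t[family_col]) - set(family_to_esu))
        if unmapped:
            raise KeyError(f"families with no ESU mapping: {unmapped}")
        t[esu_col] = t[family_col].map(family_to_esu)
    elif esu_col not in t.columns:
        raise KeyError("survey has no 'esu' column and no family_to_esu map")
    if t[esu_col].isna().any():
        bad = sorted(set(t.loc[t[esu_col].isna(), family_col]))
        raise KeyError(f"families with no ESU mapping: {bad}")
    wide = t.pivot_table(index=night_col, columns=esu_col, values=biomass_col,
                         aggfunc="sum", fill_value=0.0)
    wide.columns.name = None
    return wide.sort_index()


def period_average_biomass(nightly: pd.DataFrame,
                           night_periods: pd.Series) -> pd.DataFrame:
    """Arithmetic mean biomass per ESU across each period's nights.

    ``night_periods`` maps each night (index of ``nightly``) to its
    period label. Every period must have at least one night.
    """
    periods = night_periods.reindex(nightly.index)
    if periods.isna().any():
        bad = list(nightly.index[periods.isna()])
        raise KeyError(f"nights with no period label: {bad}")
    out = nightly.groupby(periods).mean()
    out.index.name = "period"
    if (out.index.value_counts() < 1).any():  # pragma: no cover - defensive
        raise ValueError("empty period")
    return out


def availability_proportions(esu_biomass, zero_floor: float = 0.001):
    """Biomass vector -> availability proportions n on the simplex.

    Zero biomasses among in-scope ESUs are replaced by
    ``zero_floor * total`` before normalizing, so prey observed in
    diets but absent from a night's nets keep a small positive
    availability and Manly's index stays finite. The floored entries
    are reported via the result's ``attrs['floored']``.
    """
    v = pd.Series(esu_biomass, dtype=float) if not isinstance(esu_biomass, pd.Series) \
        else esu_biomass.astype(float)
    if (v < 0).any():
        raise ValueError("biomass must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero biomass vector: availability undefined")
    if zero_floor <= 0:
        raise ValueError("zero_floor must be positive")
    floored_mask = v == 0
    floored = v.where(~floored_mask, zero_floor * total)
    n = floored / floored.sum()
    n.attrs["floored"] = list(v.index[floored_mask])
    n.attrs["m"] = int(len(v))
    return n
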