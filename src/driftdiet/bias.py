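"""Amplification-bias assessment from mock-community homogenates.

Universal 18S primers amplify taxa unevenly (rRNA copy number, primer
mismatches), so sequence proportions are a biased estimate of biomass
proportions. A homogenate of known biomass composition calibrates this:
for each family t with sequence proportion S_t and biomass proportion
B_t (and complements S_m = 1 - S_t, B_m = 1 - B_t over the other
families), the relative correction factor is the odds ratio

    RCF_t = (S_t / S_m) * (B_m / B_t)

RCF > 1 means the family is over-represented by sequence abundance,
RCF < 1 under-represented. Diet proportions can optionally be divided
by the RCFs and renormalized to undo the bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_rcf",
    "rcf_from_replicates",
    "biomass_sequence_correlation",
    "apply_rcf",
    "merge_families",
]


def _to_proportions(values: pd.Series, name: str) -> pd.Series:
    """Accept either percentages (summing to ~100) or proportions."""
    v = values.astype(float)
    total = v.sum()
    if v.min() < 0:
        raise ValueError(f"{name} has negative entries")
    if total > 1.5:  # percentages
        v = v / 100.0
    return v


def compute_rcf(mixture: pd.DataFrame, biomass_col: str = "biomass_pct",
                sequence_col: str = "sequence_pct") -> pd.DataFrame:
    """Relative correction factor per family from one mock mixture.

    Parameters
    ----------
    mixture : DataFrame
        One row per family with biomass and sequence columns, given
        either as percentages or proportions (detected by their sum).

    Returns
    -------
    DataFrame with columns ``family`` (copied through if present),
    ``rcf`` and ``overrepresented`` (RCF > 1, i.e. S_t > B_t). A family
    with zero biomass but nonzero sequences has no defined odds ratio:
    its ``rcf`` is NaN and ``undefined`` is flagged True.
    """
    B = _to_proportions(mixture[biomass_col], biomass_col)
    S = _to_proportions(mixture[sequence_col], sequence_col)
    out = mixture.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rcf = (S / (1.0 - S)) * ((1.0 - B) / B)
    undefined = (B <= 0) & (S > 0)
    rcf[undefined] = np.nan
    rcf[(B <= 0) & (S <= 0)] = np.nan
    out["rcf"] = rcf
    out["overrepresented"] = S > B
    out["undefined"] = undefined
    return out


def rcf_from_replicates(replicates: list[pd.DataFrame],
                        biomass_col: str = "biomass_pct",
                        sequence_col: str = "sequence_pct",
                        family_col: str = "family",
                        mean: str = "arithmetic") -> pd.DataFrame:
    """Average per-replicate RCFs across mock subsamples.

    ``mean='arithmetic'`` (default) or ``'geometric'``; families are
    aligned by name across replicates.
    """
    per_rep = []
    for rep in replicates:
        r = compute_rcf(rep, biomass_col, sequence_col)
        per_rep.append(r.set_index(family_col)["rcf"])
    stacked = pd.concat(per_rep, axis=1)
    if mean == "arithmetic":
        combined = stacked.mean(axis=1)
    elif mean == "geometric":
        combined = np.exp(np.log(stacked).mean(axis=1))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    return combined.rename("rcf").reset_index()


def merge_families(table: pd.DataFrame, merge_map: dict[str, str],
                   family_col: str = "family",
                   value_cols: tuple[str, ...] = ("biomass_pct", "sequence_pct"),
                   ) -> pd.DataFrame:
    """Merge families indistinguishable at the locus before RCF computation.

    ``merge_map`` sends each original family to its merged label;
    unmapped families keep their own name. Value columns are summed.
    """
    t = table.copy()
    t[family_col] = t[family_col].map(lambda f: merge_map.get(f, f))
    grouped = t.groupby(family_col, sort=False)[list(value_cols)].sum()
    return grouped.reset_index()


def biomass_sequence_correlation(pairs: pd.DataFrame,
                                 biomass_col: str = "biomass_pct",
                                 sequence_col: str = "sequence_pct") -> dict:
    """Pearson correlation of paired (biomass, sequence) percentages.

    Pairs are (family, replicate) observations pooled across mixtures.
    Returns ``{"r", "r_squared", "p_value", "n"}``; with fewer than
    3 pairs or zero variance the correlation is undefined and the dict
    carries NaNs with ``"undefined": True``.
    """
    b = pairs[biomass_col].astype(float).to_numpy()
    s = pairs[sequence_col].astype(float).to_numpy()
    n = len(b)
    if n < 3 or np.ptp(b) == 0 or np.ptp(s) == 0:
        return {"r": float("nan"), "r_squared": float("nan"),
                "p_value": float("nan"), "n": n, "undefined": True}
    res = stats.pearsonr(b, s)
    return {"r": float(res.statistic), "r_squared": float(res.statistic ** 2),
            "p_value": float(res.pvalue), "n": n, "undefined": False}


def apply_rcf(proportions, rcf, default: float = 1.0):
    """Correct diet proportions for amplification bias.

    Each proportion is divided by its taxon's RCF and the vector is
    renormalized: ``corrected_i ∝ p_i / RCF_i``. Taxa missing from the
    RCF table fall back to ``default`` (no correction).

    ``proportions`` may be a Series (one sample) or a DataFrame
    (samples x taxa); ``rcf`` a Series/dict indexed by taxon.
    """
    if isinstance(rcf, dict):
        rcf = pd.Series(rcf, dtype=float)
    if isinstance(proportions, pd.DataFrame):
        factors = rcf.reindex(proportions.columns).fillna(default)
        if (factors <= 0).any():
            bad = list(factors.index[factors <= 0])
            raise ValueError(f"RCF must be positive; offending taxa: {bad}")
        corrected = proportions.div(factors, axis=1)
        return corrected.div(corrected.sum(axis=1), axis=0)
    props = proportions.astype(float)
    factors = rcf.reindex(props.index).fillna(default)
    if (factors <= 0).any():
        bad = list(factors.index[factors <= 0])
        raise ValueError(f"RCF must be positive; offending taxa: {bad}")
    corrected = props / factors
    return corrected / corrected.sum()
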