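"""Dietary overlap, permutation inference, and prey selectivity.

The statistics operate on proportional resource-use vectors:

* Schoener's overlap  ``alpha = 1 - 0.5 * sum_i |p_xi - p_yi|``,
  with 0 = disjoint diets, 1 = identical diets, and values above 0.6
  conventionally read as substantial overlap.
* Bray-Curtis distance, which on the simplex is exactly
  ``1 - alpha``.
* A paired sign-flip permutation test for the change in overlap
  between two sampling periods: each species pair's (drift, postdrift)
  overlap values are randomly swapped, which flips the sign of the
  pair's difference, and the mean paired difference is recomputed per
  iteration.
* Manly's selection index  ``alpha_i = (r_i/n_i) / sum_j (r_j/n_j)``
  comparing diet proportions r to environmental availability n, and
  Chesson's electivity  ``eps_i = (m*alpha_i - 1) / ((m-2)*alpha_i + 1)``
  which rescales it to [-1, 1] with 0 = neutral selection for m prey
  types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "schoener_alpha",
    "bray_curtis",
    "PooledDiet",
    "pool_diets",
    "OverlapResult",
    "overlap_matrices",
    "paired_sign_flip_test",
    "SignFlipResult",
    "manly_alpha",
    "chesson_epsilon",
    "selectivity_by_day",
]

#: conventional threshold for "substantial" dietary overlap
SUBSTANTIAL_OVERLAP = 0.6


def _as_aligned_arrays(p_x, p_y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p_x, pd.Series) and isinstance(p_y, pd.Series):
        if not p_x.index.equals(p_y.index):
            if set(p_x.index) != set(p_y.index):
                raise ValueError("diet vectors are indexed over different ESUs")
            p_y = p_y.loc[p_x.index]
        return p_x.to_numpy(float), p_y.to_numpy(float)
    x = np.asarray(p_x, dtype=float)
    y = np.asarray(p_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("diet vectors have mismatched lengths")
    return x, y


def _check_simplex(v: np.ndarray, name: str, atol: float = 1e-6) -> None:
    if (v < -atol).any():
        raise ValueError(f"{name} has negative entries")
    if not np.isclose(v.sum(), 1.0, atol=atol):
        raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.6f})")


def schoener_alpha(p_x, p_y) -> float:
    """Schoener's index of overlap between two proportion vectors."""
    x, y = _as_aligned_arrays(p_x, p_y)
    _check_simplex(x, "p_x")
    _check_simplex(y, "p_y")
    return float(1.0 - 0.5 * np.abs(x - y).sum())


def bray_curtis(p_x, p_y) -> float:
    """Bray-Curtis distance between two proportion vectors.

    For vectors on the simplex this equals ``0.5 * sum |x - y|``, i.e.
    the complement of Schoener's alpha.
    """
    x, y = _as_aligned_arrays(p_x, p_y)
    _check_simplex(x, "p_x")
    _check_simplex(y, "p_y")
    return float(0.5 * np.abs(x - y).sum())


@dataclass
class PooledDiet:
    """Prey proportions pooled over all fish of one species and period."""

    species: str
    period: str
    proportions: pd.Series
    n_fish: int

    def __post_init__(self) -> None:
        _check_simplex(self.proportions.to_numpy(float), "pooled proportions")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")


def pool_diets(diet_matrix, species: str, period: str,
               method: str = "sum_counts") -> PooledDiet:
    """Pool the diets of one predator species within one period.

    With ``method='sum_counts'`` (default) prey read counts are summed
    across the qualifying samples before normalizing — because every
    sample was rarefied to the same depth, fish are near-equally
    weighted. ``method='mean_proportions'`` averages the per-fish
    proportion vectors instead (exposed for sensitivity analysis).

    Raises ``LookupError`` if no sample matches, so callers can flag
    the empty species x period cell.
    """
    meta = diet_matrix.metadata
    mask = (meta["predator_species"] == species) & (meta["period"] == period)
    if not mask.any():
        raise LookupError(f"no samples for {species!r} in period {period!r}")
    props = diet_matrix.proportions.loc[mask]
    if method == "sum_counts":
        weights = diet_matrix.prey_reads.loc[mask].astype(float)
        pooled = props.mul(weights, axis=0).sum(axis=0)
    elif method == "mean_proportions":
        pooled = props.mean(axis=0)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    pooled = pooled / pooled.sum()
    return PooledDiet(species=species, period=period, proportions=pooled,
                      n_fish=int(mask.sum()))


@dataclass
class OverlapResult:
    """Per-period Schoener overlap matrices with the paired-change summary.

    ``alpha`` maps period -> symmetric species x species DataFrame with
    unit diagonal. ``paired_delta`` holds postdrift - drift per species
    pair present in both periods; the permutation summary fields are
    filled by :func:`paired_sign_flip_test` when requested.
    """

    alpha: dict[str, pd.DataFrame]
    paired_delta: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mean_delta: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    dropped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def substantial_pairs(self, period: str,
                          threshold: float = SUBSTANTIAL_OVERLAP) -> list[tuple[str, str, float]]:
        """Species pairs whose overlap exceeds the threshold in a period."""
        mat = self.alpha[period]
        out = []
        for i, a in enumerate(mat.index):
            for b in mat.columns[i + 1:]:
                val = mat.loc[a, b]
                if pd.notna(val) and val > threshold:
                    out.append((a, b, float(val)))
        return out


def overlap_matrices(diet_matrix, periods: tuple[str, str] = ("drift", "postdrift"),
                     pooling: str = "sum_counts") -> OverlapResult:
    """Schoener overlap between every species pair, per period.

    Diets are pooled per species within each period; pairs involving a
    species absent from a period are left as NaN in that period's
    matrix. ``paired_delta`` is filled for pairs present in both
    periods (complete-pairs analysis); incomplete pairs are listed in
    ``dropped_pairs``.
    """
    meta = diet_matrix.metadata
    species = sorted(meta["predator_species"].unique())
    pooled: dict[str, dict[str, PooledDiet]] = {p: {} for p in periods}
    for period in periods:
        for sp in species:
            try:
                pooled[period][sp] = pool_diets(diet_matrix, sp, period,
                                                method=pooling)
            except LookupError:
                continue
    alpha: dict[str, pd.DataFrame] = {}
    for period in periods:
        mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
        for i, a in enumerate(species):
            if a in pooled[period]:
                mat.loc[a, a] = 1.0
            for b in species[i + 1:]:
                if a in pooled[period] and b in pooled[period]:
                    val = schoener_alpha(pooled[period][a].proportions,
                                         pooled[period][b].proportions)
                    mat.loc[a, b] = mat.loc[b, a] = val
        alpha[period] = mat
    first, second = periods
    deltas: dict[tuple[str, str], float] = {}
    dropped: list[tuple[str, str]] = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            v1 = alpha[first].loc[a, b]
            v2 = alpha[second].loc[a, b]
            if pd.notna(v1) and pd.notna(v2):
                deltas[(a, b)] = float(v2 - v1)
            else:
                dropped.append((a, b))
    delta = pd.Series(deltas, dtype=float)
    return OverlapResult(alpha=alpha, paired_delta=delta,
                         mean_delta=float(delta.mean()) if len(delta) else None,
                         dropped_pairs=dropped)


@dataclass
class SignFlipResult:
    """Outcome of the paired sign-flip permutation test."""

    mean_delta: float
    p_value: float
    n_permutations: int
    alternative: str
    n_pairs: int


def paired_sign_flip_test(alpha_first, alpha_second, n_perm: int = 99_999,
                          seed: int | np.random.Generator = 0,
                          alternative: str = "two-sided") -> SignFlipResult:
    """Permutation test for a change in paired overlap values.

    The observed statistic is the mean over species pairs of
    ``second - first``. Under the null the period labels within each
    pair are exchangeable, so each pair's difference flips sign
    independently with probability 1/2 per iteration. The p-value uses
    the add-one convention ``(1 + #extreme) / (n_perm + 1)``.

    Parameters
    ----------
    alpha_first, alpha_second : array-like or pandas.Series
        Overlap values aligned by species pair (first period and second
        period respectively).
    n_perm : int
        Number of sign-flip iterations.
    seed : int or numpy Generator
        Randomness source.
    alternative : {"two-sided", "less", "greater"}
        Sidedness of the test on the mean difference.
    """
    x, y = _as_aligned_arrays(alpha_first, alpha_second)
    if len(x) < 2:
        raise ValueError("need at least 2 pairs for the paired test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    delta = y - x
    observed = float(delta.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, delta.size)) * 2 - 1
    perm_means = (signs * delta).mean(axis=1)
    if alternative == "two-sided":
        extreme = np.abs(perm_means) >= abs(observed)
    elif alternative == "less":
        extreme = perm_means <= observed
    elif alternative == "greater":
        extreme = perm_means >= observed
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return SignFlipResult(mean_delta=observed, p_value=float(p),
                          n_permutations=n_perm, alternative=alternative,
                          n_pairs=int(delta.size))


def manly_alpha(r, n) -> np.ndarray | pd.Series:
    """Manly's selection index comparing diet r to availability n.

    ``alpha_i = (r_i / n_i) / sum_j (r_j / n_j)``; the result sums to 1
    and exceeds 1/m where a prey type is over-represented in the diet
    relative to its environmental availability. Availability must be
    strictly positive — zero-biomass prey types are floored upstream
    (see :func:`driftdiet.drift.availability_proportions`).
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if r_arr.shape != n_arr.shape:
        raise ValueError("r and n have mismatched lengths")
    if (n_arr <= 0).any():
        raise ValueError("availability n must be strictly positive; apply the "
                         "zero floor before computing selectivity")
    _check_simplex(r_arr, "diet proportions r")
    ratios = r_arr / n_arr
    alpha = ratios / ratios.sum()
    if isinstance(r, pd.Series):
        return pd.Series(alpha, index=r.index)
    return alpha


def chesson_epsilon(alpha_i, m: int):
    """Chesson's electivity: rescale Manly's alpha to [-1, 1].

    ``eps_i = (m * alpha_i - 1) / ((m - 2) * alpha_i + 1)`` with m the
    number of prey types; eps = 0 at neutral selection (alpha = 1/m),
    1 at exclusive use, -1 at complete avoidance. Strictly increasing
    in alpha for fixed m.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    a = np.asarray(alpha_i, dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise ValueError("alpha_i must lie in [0, 1]")
    eps = (m * a - 1.0) / ((m - 2) * a + 1.0)
    if isinstance(alpha_i, pd.Series):
        return pd.Series(eps, index=alpha_i.index)
    if np.isscalar(alpha_i):
        return float(eps)
    return eps


def selectivity_by_day(diet_matrix, availability_by_night: pd.DataFrame,
                       surveyed_esus: list[str],
                       date_to_night: dict | None = None) -> pd.DataFrame:
    """Per species x sampling-day Manly/Chesson selectivity table.

    For each (species, date) group, the diet vector r is the mean of
    that day's per-sample proportion vectors restricted to the surveyed
    ESUs and renormalized; availability n is the floored biomass
    proportion vector for the associated night (fish are sampled the
    day after the drift nets, so ``date_to_night`` maps sampling dates
    to survey nights; by default the date indexes availability
    directly). Groups with no surveyed-ESU reads are skipped and
    reported via the ``skipped`` attribute on the returned frame.

    Returns a tidy DataFrame with one row per (species, date, esu):
    columns r_i, n_i, manly_alpha, chesson_epsilon, m.
    """
    meta = diet_matrix.metadata
    if "date" not in meta.columns:
        raise ValueError("diet metadata must carry a 'date' column")
    missing = [e for e in surveyed_esus if e not in availability_by_night.columns]
    if missing:
        raise ValueError(f"availability table lacks surveyed ESUs: {missing}")
    m = len(surveyed_esus)
    rows = []
    skipped: list[tuple[str, object]] = []
    for (species, date), idx in meta.groupby(
            ["predator_species", "date"], sort=True).groups.items():
        props = diet_matrix.proportions.loc[idx]
        r_full = props.mean(axis=0)
        r = r_full.reindex(surveyed_esus).fillna(0.0)
        if r.sum() <= 0:
            skipped.append((species, date))
            continue
        r = r / r.sum()
        night = date_to_night[date] if date_to_night else date
        if night not in availability_by_night.index:
            raise KeyError(f"no availability vector for night {night!r}")
        n = availability_by_night.loc[night, surveyed_esus].astype(float)
        # Manly's alpha is invariant to rescaling n, but report n_i as a
        # proportion over the surveyed ESUs
        n = n / n.sum()
        alpha = manly_alpha(r, n)
        eps = chesson_epsilon(alpha, m)
        for esu in surveyed_esus:
            rows.append({
                "predator_species": species, "date": date, "esu": esu,
                "r_i": r[esu], "n_i": float(n[esu]),
                "manly_alpha": float(alpha[esu]),
                "chesson_epsilon": float(eps[esu]), "m": m,
            })
    out = pd.DataFrame(rows, columns=["predator_species", "date", "esu", "r_i",
                                      "n_i", "manly_alpha", "chesson_epsilon",
                                      "m"])
    out.attrs["skipped"] = skipped
    return out
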