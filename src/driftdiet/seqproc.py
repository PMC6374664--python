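"""Sequence screening, OTU clustering, ESU assignment, rarefaction.

The processing order is fixed and mirrors standard amplicon practice
for gut-content metabarcoding:

1. quality screening of unique primer-trimmed sequences (over-length,
   dataset-wide singletons, long homopolymer runs);
2. greedy abundance-ordered clustering into OTUs at <=2 bp difference;
3. OTU assignment to ecologically significant units (ESUs) by best
   identity against a reference database (>=95% identity over the full
   OTU length);
4. rarefaction of every sample to a common depth (samples below the
   depth are discarded);
5. removal of predator self-reads and non-bilaterian taxa, exclusion
   of samples left with fewer than ``min_prey_reads`` prey sequences
   (near-empty stomachs), and conversion to per-sample prey
   proportions.

Edit distances use the edlib bindings; "identity" is 1 - distance over
the OTU length, with end-gaps free on the reference side so the OTU is
always fully covered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

from driftdiet.containers import DietMatrix, SampleTable
from driftdiet.taxonomy import EsuTaxonomy

__all__ = [
    "filter_sequences",
    "FilterReport",
    "cluster_otus",
    "OtuClustering",
    "assign_esu",
    "rarefy",
    "rarefy_table",
    "rarefaction_curve",
    "expected_richness",
    "make_diet_matrix",
    "aggregate_to_esu",
    "process_pipeline",
]

# exclusion reason codes
LOW_DEPTH = "LOW_DEPTH"
LOW_PREY = "LOW_PREY"
ALL_SELF = "ALL_SELF"

UNASSIGNED = "__unassigned__"


@dataclass
class FilterReport:
    """Unique sequences rejected per screening rule (and reads for info)."""

    too_long: int = 0
    homopolymer: int = 0
    singleton: int = 0

    @property
    def total(self) -> int:
        return self.too_long + self.homopolymer + self.singleton


def _as_abundance_map(sequences) -> dict[str, int]:
    if isinstance(sequences, Mapping):
        return {str(s): int(c) for s, c in sequences.items()}
    counts: dict[str, int] = {}
    for s in sequences:
        counts[str(s)] = counts.get(str(s), 0) + 1
    return counts


def filter_sequences(sequences, max_trimmed_length: int = 175,
                     homopolymer_min: int = 8, drop_singletons: bool = True,
                     ) -> tuple[dict[str, int], FilterReport]:
    """Screen unique primer-trimmed sequences for quality.

    Removes sequences longer than ``max_trimmed_length``, sequences
    containing any single-base run of ``homopolymer_min`` or more, and
    (optionally) unique sequences whose dataset-wide abundance is 1.

    Parameters
    ----------
    sequences : mapping str -> int, or iterable of str
        Unique sequences with dataset-wide abundances; a plain iterable
        is tallied first.

    Returns
    -------
    (retained, report) : the surviving ``{sequence: abundance}`` map
    and the per-rule rejection counts. A sequence violating several
    rules is counted once, under the first rule in the order
    length -> homopolymer -> singleton.
    """
    abundance = _as_abundance_map(sequences)
    homopoly = re.compile(r"(.)\1{%d,}" % (homopolymer_min - 1))
    retained: dict[str, int] = {}
    report = FilterReport()
    for seq, count in abundance.items():
        if len(seq) > max_trimmed_length:
            report.too_long += 1
        elif homopoly.search(seq):
            report.homopolymer += 1
        elif drop_singletons and count == 1:
            report.singleton += 1
        else:
            retained[seq] = count
    return retained, report


@dataclass
class OtuClustering:
    """Sequence -> OTU assignment from greedy centroid clustering."""

    assignment: dict[str, str]
    centroids: dict[str, str]  # otu_id -> centroid sequence
    abundance: dict[str, int] = field(default_factory=dict)  # otu_id -> reads

    @property
    def n_otus(self) -> int:
        return len(self.centroids)


def _edit_distance(a: str, b: str, k: int = -1) -> int:
    res = edlib.align(a, b, task="distance", k=k)
    return res["editDistance"]


def cluster_otus(sequences, max_diff: int = 2) -> OtuClustering:
    """Greedy abundance-ordered centroid clustering at <= ``max_diff`` edits.

    Sequences are visited by descending abundance (ties broken
    lexicographically); each joins the first existing centroid within
    ``max_diff`` edit operations, else founds a new OTU whose centroid
    it becomes. The procedure is deterministic.
    """
    abundance = _as_abundance_map(sequences)
    order = sorted(abundance, key=lambda s: (-abundance[s], s))
    centroids: dict[str, str] = {}
    assignment: dict[str, str] = {}
    otu_abundance: dict[str, int] = {}
    for seq in order:
        hit = None
        for otu_id, centroid in centroids.items():
            d = _edit_distance(seq, centroid, k=max_diff)
            if 0 <= d <= max_diff:
                hit = otu_id
                break
        if hit is None:
            hit = f"OTU_{len(centroids) + 1:04d}"
            centroids[hit] = seq
        assignment[seq] = hit
        otu_abundance[hit] = otu_abundance.get(hit, 0) + abundance[seq]
    return OtuClustering(assignment=assignment, centroids=centroids,
                         abundance=otu_abundance)


def assign_esu(otu_representatives: Mapping[str, str], reference_db: pd.DataFrame,
               min_identity: float = 0.95, require_full_coverage: bool = True,
               ) -> tuple[pd.DataFrame, list[str]]:
    """Assign OTU representative sequences to ESUs by best identity.

    Parameters
    ----------
    otu_representatives : mapping otu_id -> sequence
    reference_db : DataFrame
        Columns ``ref_id``, ``sequence``, ``esu`` and optionally
        ``abundance`` (used for tie-breaking).
    min_identity : float
        Minimum identity (1 - edits/OTU length) for an assignment.
    require_full_coverage : bool
        If True the OTU must align over its entire length (end-gaps are
        free only on the reference side); otherwise a global alignment
        is used.

    Returns
    -------
    (assignments, unassigned) : a DataFrame indexed by otu_id with
    columns ``esu``, ``identity``, ``ref_id``; and the list of OTU ids
    below the identity threshold. Ties on identity go to the
    most-abundant reference's ESU, then lexicographically by ESU.
    """
    if reference_db.empty:
        raise ValueError("reference database is empty")
    refs = reference_db.reset_index(drop=True)
    ref_abund = refs["abundance"] if "abundance" in refs.columns else \
        pd.Series(1, index=refs.index)
    mode = "HW" if require_full_coverage else "NW"
    rows = []
    unassigned: list[str] = []
    for otu_id, seq in otu_representatives.items():
        best = None  # (identity, abundance, esu, ref_id)
        for idx, ref in refs.iterrows():
            res = edlib.align(seq, ref["sequence"], mode=mode, task="distance")
            d = res["editDistance"]
            if d < 0:
                continue
            identity = 1.0 - d / len(seq)
            cand = (identity, int(ref_abund[idx]), ref["esu"], ref["ref_id"])
            if best is None:
                best = cand
            elif cand[0] > best[0]:
                best = cand
            elif cand[0] == best[0]:
                # tie: most-abundant reference, then lexicographic ESU
                if (cand[1], ) > (best[1], ) or \
                        (cand[1] == best[1] and cand[2] < best[2]):
                    best = cand
        if best is None or best[0] < min_identity:
            unassigned.append(otu_id)
        else:
            rows.append({"otu_id": otu_id, "esu": best[2],
                         "identity": best[0], "ref_id": best[3]})
    frame = pd.DataFrame(rows, columns=["otu_id", "esu", "identity", "ref_id"])
    return frame.set_index("otu_id"), unassigned


def rarefy(sample_counts, depth: int = 1950,
           seed: int | np.random.Generator = 0):
    """Subsample one sample's counts to exactly ``depth`` reads.

    Draws without replacement (multivariate hypergeometric), so every
    rarefied count is bounded by the original. Returns ``None`` when
    the sample total is below ``depth`` — such samples are discarded,
    not padded.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = pd.Series(sample_counts).astype(np.int64) \
        if not isinstance(sample_counts, pd.Series) else sample_counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(counts.sum())
    if total < depth:
        return None
    if total == depth:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts.to_numpy(), depth)
    return pd.Series(drawn, index=counts.index)


def rarefy_table(table: SampleTable, depth: int = 1950,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[SampleTable, pd.DataFrame]:
    """Rarefy every sample; discard and log those below ``depth``.

    Returns the rarefied table (all rows summing to exactly ``depth``)
    and an exclusion log with columns sample_id, reason, detail.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept_rows = {}
    excluded = []
    for sample_id, row in table.counts.iterrows():
        out = rarefy(row, depth=depth, seed=rng)
        if out is None:
            excluded.append({"sample_id": sample_id, "reason": LOW_DEPTH,
                             "detail": f"total {int(row.sum())} < depth {depth}"})
        else:
            kept_rows[sample_id] = out
    log = pd.DataFrame(excluded, columns=["sample_id", "reason", "detail"])
    if not kept_rows:
        empty = table.counts.iloc[0:0]
        return SampleTable(empty, table.metadata.loc[empty.index]), log
    counts = pd.DataFrame(kept_rows).T
    counts = counts.loc[[s for s in table.samples if s in counts.index]]
    counts.index.name = table.counts.index.name
    return SampleTable(counts, table.metadata.loc[counts.index]), log


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected number of features observed at a depth.

    For counts n_i summing to N, hypergeometric expectation
    ``sum_i 1 - C(N - n_i, d) / C(N, d)``.
    """
    from scipy.special import gammaln

    n = np.asarray(counts, dtype=np.int64)
    n = n[n > 0]
    N = int(n.sum())
    if depth > N:
        raise ValueError("depth exceeds sample total")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        log_miss = log_comb(N - n, depth) - log_comb(N, depth)
    miss = np.where(N - n >= depth, np.exp(log_miss), 0.0)
    return float(np.sum(1.0 - miss))


def rarefaction_curve(sample_counts, depth_grid: Iterable[int], reps: int = 10,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Monte-Carlo mean observed richness at each depth.

    Depths must be ascending and no larger than the sample total; the
    mean over ``reps`` independent rarefactions is returned per depth.
    """
    depths = list(depth_grid)
    if depths != sorted(depths):
        raise ValueError("depth grid must be ascending")
    counts = pd.Series(sample_counts).astype(np.int64)
    total = int(counts.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = []
    for d in depths:
        if d > total:
            raise ValueError(f"depth {d} exceeds sample total {total}")
        richness = [
            int((rarefy(counts, depth=d, seed=rng) > 0).sum()) for _ in range(reps)
        ]
        means.append(float(np.mean(richness)))
    return pd.DataFrame({"depth": depths, "mean_richness": means})


def aggregate_to_esu(table: SampleTable, otu_to_esu: Mapping[str, str],
                     ) -> SampleTable:
    """Sum OTU columns sharing an ESU; unmapped OTUs pool as unassigned.

    Reads from OTUs without an ESU assignment are kept (they still
    occupy rarefaction depth) under the ``__unassigned__`` column,
    which is never treated as prey downstream.
    """
    mapping = {otu: otu_to_esu.get(otu, UNASSIGNED) for otu in table.features}
    counts = table.counts.T.groupby(table.features.map(mapping.get)).sum().T
    counts.columns.name = None
    return SampleTable(counts, table.metadata)


def make_diet_matrix(esu_table: SampleTable, taxonomy: EsuTaxonomy,
                     min_prey_reads: int = 20,
                     ) -> tuple[DietMatrix, pd.DataFrame]:
    """Strip self and non-prey reads; exclude near-empty stomachs.

    Per sample: the predator's own self ESUs and all non-bilaterian
    (or unassigned) features are removed; if the remaining prey reads
    number fewer than ``min_prey_reads`` the sample is excluded — with
    reason ``ALL_SELF`` when no prey reads remain at all, else
    ``LOW_PREY`` — since such fish likely had empty or near-empty
    stomachs. Surviving rows are normalized to prey proportions.

    Raises ``KeyError`` naming any predator species with no self-ESU
    declaration in the taxonomy.
    """
    prey_rows = {}
    prey_totals = {}
    excluded = []
    features = list(esu_table.features)
    for sample_id, row in esu_table.counts.iterrows():
        species = esu_table.metadata.loc[sample_id, "predator_species"]
        self_esus = taxonomy.self_esus_of(species)  # raises for unknown species
        prey_cols = [f for f in features
                     if f not in self_esus and f != UNASSIGNED
                     and taxonomy.is_prey(f, species)]
        prey = row[prey_cols]
        prey_total = int(prey.sum())
        if prey_total == 0:
            reason = ALL_SELF if int(row[list(self_esus & set(features))].sum()) > 0 \
                else LOW_PREY
            excluded.append({"sample_id": sample_id, "reason": reason,
                             "detail": "no prey reads"})
        elif prey_total < min_prey_reads:
            excluded.append({"sample_id": sample_id, "reason": LOW_PREY,
                             "detail": f"{prey_total} prey reads < {min_prey_reads}"})
        else:
            prey_rows[sample_id] = prey / prey_total
            prey_totals[sample_id] = prey_total
    log = pd.DataFrame(excluded, columns=["sample_id", "reason", "detail"])
    if not prey_rows:
        empty = pd.DataFrame(columns=pd.Index([], dtype=object))
        return DietMatrix(empty, pd.Series(dtype=int),
                          esu_table.metadata.iloc[0:0]), log
    # prey column sets differ across predators (self ESUs drop out per
    # species); absent columns mean zero use, and every column is kept
    # so matrices align on one ESU index
    props = pd.DataFrame(prey_rows).T.fillna(0.0)
    props.index.name = esu_table.counts.index.name
    reads = pd.Series(prey_totals, name="prey_reads")
    return DietMatrix(props, reads, esu_table.metadata.loc[props.index]), log


def process_pipeline(otu_table: SampleTable, otu_sequences: Mapping[str, str],
                     reference_db: pd.DataFrame, taxonomy: EsuTaxonomy,
                     depth: int = 1950, min_prey_reads: int = 20,
                     max_trimmed_length: int = 175, homopolymer_min: int = 8,
                     max_diff: int = 2, min_identity: float = 0.95,
                     seed: int | np.random.Generator = 0) -> dict:
    """Full fixed-order pipeline from a raw OTU table to a DietMatrix.

    filter -> cluster -> assign -> rarefy -> self/prey filtering ->
    proportions. ``otu_sequences`` maps the raw table's feature ids to
    their representative sequences; raw features whose sequences fail
    screening are dropped, surviving features re-cluster at
    ``max_diff`` edits and aggregate by assigned ESU.

    Returns a dict with the DietMatrix, exclusion log, filter report,
    clustering, ESU assignments and unassigned OTU ids.
    """
    missing = [f for f in otu_table.features if f not in otu_sequences]
    if missing:
        raise KeyError(f"features with no sequence: {missing[:5]}")
    col_sums = otu_table.counts.sum(axis=0)
    seq_abundance: dict[str, int] = {}
    for feat in otu_table.features:
        seq = otu_sequences[feat]
        seq_abundance[seq] = seq_abundance.get(seq, 0) + int(col_sums[feat])
    retained, filter_report = filter_sequences(
        seq_abundance, max_trimmed_length=max_trimmed_length,
        homopolymer_min=homopolymer_min)
    clustering = cluster_otus(retained, max_diff=max_diff)
    # map raw features -> new OTUs (dropping screened-out sequences)
    feat_to_otu = {
        feat: clustering.assignment.get(otu_sequences[feat])
        for feat in otu_table.features
    }
    keep = [f for f, o in feat_to_otu.items() if o is not None]
    pruned = SampleTable(otu_table.counts[keep], otu_table.metadata)
    otu_counts = pruned.counts.T.groupby(
        pruned.features.map(feat_to_otu.get)).sum().T
    otu_counts.columns.name = None
    otu_st = SampleTable(otu_counts, otu_table.metadata)
    assignments, unassigned = assign_esu(
        clustering.centroids, reference_db, min_identity=min_identity)
    rarefied, depth_log = rarefy_table(otu_st, depth=depth, seed=seed)
    esu_st = aggregate_to_esu(rarefied, assignments["esu"].to_dict())
    diet, prey_log = make_diet_matrix(esu_st, taxonomy,
                                      min_prey_reads=min_prey_reads)
    exclusions = pd.concat([depth_log, prey_log], ignore_index=True)
    return {
        "diet_matrix": diet,
        "exclusion_log": exclusions,
        "filter_report": filter_report,
        "clustering": clustering,
        "assignments": assignments,
        "unassigned": unassigned,
        "esu_table": esu_st,
    }
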