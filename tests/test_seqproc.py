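"""Screening, clustering, assignment, rarefaction and diet-matrix rules."""

import numpy as np
import pandas as pd
import pytest

import edlib
from driftdiet.containers import SampleTable
from driftdiet.seqproc import (
    aggregate_to_esu,
    assign_esu,
    cluster_otus,
    expected_richness,
    filter_sequences,
    make_diet_matrix,
    process_pipeline,
    rarefaction_curve,
    rarefy,
    rarefy_table,
)
from driftdiet.synthetic import generate_reference_db, simulate_diet_samples, \
    CommunityConfig


def seq(n, base="ACGT"):
    return (base * (n // len(base) + 1))[:n]


class TestFilterSequences:
    def test_length_boundary(self):
        ok, bad = seq(175), seq(176)
        retained, report = filter_sequences({ok: 5, bad: 5})
        assert ok in retained and bad not in retained
        assert report.too_long == 1

    def test_homopolymer_boundary(self):
        with_run = "ACGT" + "A" * 8 + "CGTA"
        just_under = "ACGT" + "A" * 7 + "CGTA"
        retained, report = filter_sequences({with_run: 9, just_under: 9})
        assert with_run not in retained and just_under in retained
        assert report.homopolymer == 1

    def test_singleton_boundary(self):
        retained, report = filter_sequences({"ACGTACGT": 1, "TTGGCCAA": 2})
        assert "TTGGCCAA" in retained and "ACGTACGT" not in retained
        assert report.singleton == 1

    def test_iterable_input_is_tallied(self):
        retained, _ = filter_sequences(["ACGTAC", "ACGTAC", "GGGTCA"])
        assert retained == {"ACGTAC": 2}

    def test_empty_input(self):
        retained, report = filter_sequences({})
        assert retained == {} and report.total == 0


def single_linkage_oracle(seqs, max_diff=2):
    """Connected components of the <=max_diff edit-distance graph."""
    items = list(seqs)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            d = edlib.align(items[i], items[j], task="distance")["editDistance"]
            if d <= max_diff:
                parent[find(i)] = find(j)
    groups = {}
    for i, s in enumerate(items):
        groups.setdefault(find(i), set()).add(s)
    return sorted(frozenset(g) for g in groups.values())


class TestClusterOtus:
    def test_identical_sequences_one_otu(self):
        res = cluster_otus({"ACGTACGTAA": 7})
        assert res.n_otus == 1

    def test_two_and_three_difference_boundary(self):
        a = "ACGTACGTACGTACGTACGT"
        two_off = "TTGTACGTACGTACGTACGT"   # 2 substitutions
        three_off = "TTTTACGTACGTACGTACGT"  # 3 substitutions
        res = cluster_otus({a: 10, two_off: 5, three_off: 5})
        assert res.assignment[a] == res.assignment[two_off]
        assert res.assignment[a] != res.assignment[three_off]

    def test_deterministic_under_ties(self):
        seqs = {"AAAATTTTCCCC": 3, "GGGGTTTTCCCC": 3}
        r1 = cluster_otus(seqs)
        r2 = cluster_otus(dict(reversed(list(seqs.items()))))
        assert r1.assignment == r2.assignment

    def test_recovers_planted_groups_vs_single_linkage(self, rng):
        """Well-separated centroids with <=2 bp variants cluster exactly."""
        bases = np.array(list("ACGT"))
        abundance = {}
        truth = []
        for g in range(8):
            centroid = "".join(rng.choice(bases, size=60))
            members = {centroid}
            abundance[centroid] = 50 - g
            for v in range(4):
                pos = rng.choice(60, size=int(rng.integers(1, 3)), replace=False)
                chars = list(centroid)
                for p in pos:
                    chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
                var = "".join(chars)
                members.add(var)
                abundance[var] = max(2, 10 - v)
            truth.append(members)
        # keep only sets whose centroids stayed >5 edits apart
        res = cluster_otus(abundance, max_diff=2)
        oracle = single_linkage_oracle(abundance, max_diff=2)
        got = {}
        for s, otu in res.assignment.items():
            got.setdefault(otu, set()).add(s)
        assert sorted(frozenset(g) for g in got.values()) == oracle
        assert res.n_otus == len(oracle) == 8


class TestAssignEsu:
    @pytest.fixture
    def refs(self):
        return pd.DataFrame({
            "ref_id": ["r1", "r2"],
            "sequence": ["A" * 30 + "C" * 30 + "G" * 30 + "T" * 10,
                         "TGCA" * 25],
            "esu": ["EsuA", "EsuB"],
            "abundance": [10, 5],
        })

    def test_identical_hits_with_unit_identity(self, refs):
        assigned, unassigned = assign_esu({"o1": refs["sequence"][1]}, refs)
        assert unassigned == []
        assert assigned.loc["o1", "esu"] == "EsuB"
        assert assigned.loc["o1", "identity"] == 1.0

    def test_below_threshold_unassigned(self, refs):
        # 6 substitutions in 100 bp: identity 0.94 < 0.95
        query = list(refs["sequence"][1])
        for p in (0, 17, 34, 51, 68, 85):
            query[p] = {"T": "A", "G": "T", "C": "G", "A": "C"}[query[p]]
        assigned, unassigned = assign_esu({"o1": "".join(query)}, refs)
        assert unassigned == ["o1"]

    def test_at_threshold_assigned(self, refs):
        query = list(refs["sequence"][1])
        for p in (0, 17, 34, 51, 68):  # 5 subs -> identity 0.95
            query[p] = {"T": "A", "G": "T", "C": "G", "A": "C"}[query[p]]
        assigned, unassigned = assign_esu({"o1": "".join(query)}, refs)
        assert assigned.loc["o1", "esu"] == "EsuB"

    def test_empty_reference_db_rejected(self):
        with pytest.raises(ValueError):
            assign_esu({"o1": "ACGT"}, pd.DataFrame())


class TestRarefy:
    def test_below_depth_discarded(self):
        assert rarefy(pd.Series({"a": 1000, "b": 949}), depth=1950) is None

    def test_exact_depth_passthrough(self):
        counts = pd.Series({"a": 1000, "b": 950})
        out = rarefy(counts, depth=1950)
        pd.testing.assert_series_equal(out, counts)

    def test_single_feature(self):
        out = rarefy(pd.Series({"a": 5000}), depth=1950, seed=1)
        assert out["a"] == 1950

    def test_sums_exactly_and_bounded(self, rng):
        counts = pd.Series(rng.integers(0, 500, size=30))
        out = rarefy(counts, depth=1950, seed=7)
        assert out.sum() == 1950
        assert (out <= counts).all()

    def test_seeded_reproducibility(self):
        counts = pd.Series(np.arange(1, 40) * 17)
        a = rarefy(counts, depth=1950, seed=42)
        b = rarefy(counts, depth=1950, seed=42)
        pd.testing.assert_series_equal(a, b)

    def test_mean_proportions_unbiased(self):
        """Across seeds, rarefied proportions match input proportions."""
        counts = pd.Series({"a": 6000, "b": 3000, "c": 1000})
        draws = [rarefy(counts, depth=1950, seed=s) / 1950 for s in range(200)]
        mean = pd.concat(draws, axis=1).mean(axis=1)
        # binomial-style CI: 3 * sqrt(p(1-p)/(200*1950))
        for feat, p in (counts / counts.sum()).items():
            assert abs(mean[feat] - p) < 3 * np.sqrt(p * (1 - p) / (200 * 1950))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rarefy(pd.Series({"a": -1, "b": 10}), depth=5)

    def test_table_rarefaction_logs_discards(self, esu_sample_table):
        rarefied, log = rarefy_table(esu_sample_table, depth=1950, seed=0)
        assert set(log["sample_id"]) == {"b1"}  # 1950 total for a1/a2/a3
        assert (log["reason"] == "LOW_DEPTH").all()
        assert (rarefied.counts.sum(axis=1) == 1950).all()


class TestRarefactionCurve:
    def test_depth_one_richness_one(self):
        curve = rarefaction_curve(pd.Series({"a": 5, "b": 5}), [1], reps=20,
                                  seed=0)
        assert curve["mean_richness"].iloc[0] == 1.0

    def test_full_depth_equals_observed_richness(self):
        counts = pd.Series({"a": 5, "b": 3, "c": 0})
        curve = rarefaction_curve(counts, [8], reps=5, seed=0)
        assert curve["mean_richness"].iloc[0] == 2.0

    def test_matches_hypergeometric_closed_form(self):
        counts = pd.Series(np.full(100, 1))  # uniform 100 features
        exact = expected_richness(counts, 50)
        curve = rarefaction_curve(counts, [50], reps=400, seed=3)
        mc = curve["mean_richness"].iloc[0]
        assert exact == pytest.approx(50.0)  # sampling w/o replacement
        assert mc == pytest.approx(exact, abs=0.5)

    def test_nondecreasing_in_depth(self):
        counts = pd.Series(np.arange(1, 21))
        curve = rarefaction_curve(counts, [10, 50, 100, 210], reps=50, seed=5)
        diffs = np.diff(curve["mean_richness"])
        assert (diffs >= -0.2).all()  # Monte-Carlo tolerance

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(pd.Series({"a": 10}), [5, 2], reps=2)


def test_expected_richness_brute_force_tiny():
    """Closed form vs exhaustive enumeration of all subsets (N=4, d=2)."""
    from itertools import combinations

    counts = {"a": 2, "b": 1, "c": 1}
    reads = ["a", "a", "b", "c"]
    richness = [len(set(sub)) for sub in combinations(reads, 2)]
    brute = np.mean(richness)
    assert expected_richness(list(counts.values()), 2) == pytest.approx(brute)


class TestMakeDietMatrix:
    def test_low_prey_excluded(self, esu_sample_table, toy_taxonomy):
        diet, log = make_diet_matrix(esu_sample_table, toy_taxonomy,
                                     min_prey_reads=20)
        reasons = log.set_index("sample_id")["reason"]
        assert reasons["a3"] == "LOW_PREY"  # 19 prey reads
        assert reasons["a2"] == "ALL_SELF"  # all reads in self ESU
        assert "a1" in diet.samples and "b1" in diet.samples

    def test_proportions(self, esu_sample_table, toy_taxonomy):
        diet, _ = make_diet_matrix(esu_sample_table, toy_taxonomy)
        row = diet.proportions.loc["a1"]
        assert row["Mayfly"] == pytest.approx(0.75)
        assert row["Caddisfly"] == pytest.approx(0.25)
        assert diet.prey_reads["a1"] == 40

    def test_self_reads_kept_for_other_predators(self, esu_sample_table,
                                                 toy_taxonomy):
        """PredB's sample counts PredA's taxon as prey."""
        counts = esu_sample_table.counts.copy()
        counts.loc["b1", "PredA_self"] = 100
        table = SampleTable(counts, esu_sample_table.metadata)
        diet, _ = make_diet_matrix(table, toy_taxonomy)
        assert diet.proportions.loc["b1", "PredA_self"] > 0
        assert "PredB_self" not in diet.proportions.columns or \
            diet.proportions.loc["b1", "PredB_self"] == 0

    def test_decoy_never_prey(self, esu_sample_table, toy_taxonomy):
        diet, _ = make_diet_matrix(esu_sample_table, toy_taxonomy)
        assert "Decoy" not in diet.proportions.columns

    def test_unknown_species_named_in_error(self, esu_sample_table,
                                            toy_taxonomy):
        meta = esu_sample_table.metadata.copy()
        meta.loc["a1", "predator_species"] = "Mystery"
        table = SampleTable(esu_sample_table.counts, meta)
        with pytest.raises(KeyError, match="Mystery"):
            make_diet_matrix(table, toy_taxonomy)


class TestEndToEnd:
    def test_pipeline_recovers_biased_truth(self):
        """Mean L1 distance to normalize(truth x bias) shrinks with depth."""
        errors = {}
        for depth in (200, 2000):
            cfg = CommunityConfig(n_predator_species=2, n_esus=10,
                                  n_samples_per_species_period=3,
                                  rarefaction_depth=depth,
                                  n_shallow_samples=0,
                                  n_empty_stomach_samples=0, seed=31)
            refs, taxonomy = generate_reference_db(cfg)
            sim = simulate_diet_samples(cfg, taxonomy, refs)
            result = process_pipeline(sim.table, sim.otu_sequences, refs,
                                      taxonomy, depth=depth, seed=1)
            diet = result["diet_matrix"]
            errs = []
            for sid in diet.samples:
                truth = sim.truth.loc[sid]
                expected = truth * sim.bias[truth.index]
                expected = expected / expected.sum()
                got = diet.proportions.loc[sid].reindex(expected.index).fillna(0)
                errs.append(np.abs(got - expected).sum())
            errors[depth] = np.mean(errs)
        assert errors[2000] < errors[200]
        assert errors[2000] < 0.15

    def test_exclusions_logged_once_with_reason(self, simulated,
                                                small_community):
        cfg, refs, taxonomy = small_community
        result = process_pipeline(simulated.table, simulated.otu_sequences,
                                  refs, taxonomy, depth=cfg.rarefaction_depth,
                                  seed=2)
        log = result["exclusion_log"]
        assert log["sample_id"].is_unique
        assert set(log["reason"]) <= {"LOW_DEPTH", "LOW_PREY", "ALL_SELF"}
        retained = set(result["diet_matrix"].samples)
        assert retained.isdisjoint(set(log["sample_id"]))
        assert retained | set(log["sample_id"]) == set(simulated.table.samples)

    def test_screening_targets_removed(self, simulated, small_community):
        cfg, refs, taxonomy = small_community
        result = process_pipeline(simulated.table, simulated.otu_sequences,
                                  refs, taxonomy, depth=cfg.rarefaction_depth,
                                  seed=2)
        fr = result["filter_report"]
        assert fr.too_long >= 1
        assert fr.homopolymer >= 1
        assert fr.singleton >= 1


def test_aggregate_to_esu_conserves_reads(esu_sample_table):
    mapping = {"PredA_self": "Fish", "PredB_self": "Fish",
               "Mayfly": "Insect", "Caddisfly": "Insect"}
    out = aggregate_to_esu(esu_sample_table, mapping)
    assert set(out.features) == {"Fish", "Insect", "__unassigned__"}
    assert (out.totals() == esu_sample_table.totals()).all()
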