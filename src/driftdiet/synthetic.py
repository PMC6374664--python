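"""Synthetic fixtures: reference sequences, gut samples, mocks, drift nets.

The generator emulates the data structures of an 18S V9 gut-content
metabarcoding study of a riverine predator community: a reference
database of ESU marker sequences, predator GI-tract OTU tables whose
reads mix predator self-DNA (defaulting to the ~43% share typical of
such samples), amplification-biased prey reads and junk OTUs, mock
homogenates of known biomass composition, and nightly drift-net counts
with a seasonal pulse of larval-fish prey during the drift period.

Every quantity is drawn from a single seeded random stream split into
named substreams (reference / diets / mock / drift), so regenerating
one stage never perturbs the others and seeded reruns are
bit-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from driftdiet.containers import SampleTable
from driftdiet.taxonomy import EsuTaxonomy

__all__ = [
    "CommunityConfig",
    "generate_reference_db",
    "simulate_diet_samples",
    "SimulatedDiet",
    "simulate_mock_homogenate",
    "simulate_drift_survey",
    "write_fixtures",
]

BASES = np.array(list("ACGT"))


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the run seed (stable across stages)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class CommunityConfig:
    """Parameters of the simulated predator-prey community.

    Defaults mirror the study design the generator emulates: 33 ESUs,
    rarefaction depth 1950 reads, ~160 bp trimmed amplicons, predator
    self-reads at 43% of a sample, and a 5-night drift / 2-night
    postdrift survey counted from 5% cod-end subsamples.
    """

    n_predator_species: int = 4
    n_esus: int = 33
    n_samples_per_species_period: int = 6
    rarefaction_depth: int = 1950
    read_length: int = 160
    bias_factors: np.ndarray | None = None  # per prey ESU; default lognormal
    bias_sigma: float = 0.5
    self_read_fraction: float = 0.43
    junk_otu_rate: float = 0.05
    dirichlet_concentration: float = 5.0
    n_decoy_esus: int = 2
    n_variants_per_esu: int = 2
    n_shallow_samples: int = 1
    n_empty_stomach_samples: int = 1
    n_drift_nights: int = 5
    n_postdrift_nights: int = 2
    subsample_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_predator_species", "n_esus",
                     "n_samples_per_species_period", "rarefaction_depth",
                     "read_length", "n_variants_per_esu", "n_drift_nights",
                     "n_postdrift_nights"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_esus < 2:
            raise ValueError("n_esus must be >= 2")
        for name in ("self_read_fraction", "junk_otu_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.self_read_fraction + self.junk_otu_rate >= 1:
            raise ValueError("self and junk fractions must leave room for prey")
        if self.bias_factors is not None:
            arr = np.asarray(self.bias_factors, dtype=float)
            if (arr <= 0).any():
                raise ValueError("bias_factors must be positive")
            self.bias_factors = arr
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")

    @property
    def esu_labels(self) -> list[str]:
        return [f"ESU_{i + 1:02d}" for i in range(self.n_esus)]

    @property
    def species_labels(self) -> list[str]:
        return [f"Predator_{i + 1:02d}" for i in range(self.n_predator_species)]

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("bias_factors"), np.ndarray):
            d["bias_factors"] = d["bias_factors"].tolist()
        return d


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


def _identity(a: str, b: str) -> float:
    import edlib

    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def generate_reference_db(config: CommunityConfig,
                          ) -> tuple[pd.DataFrame, EsuTaxonomy]:
    """Reference marker sequences and the ESU taxonomy.

    Each ESU gets one centroid sequence plus variants at most 2 bp
    away; centroids are redrawn until every cross-ESU identity is
    below 95%, so assignment is unambiguous. The first
    ``n_predator_species`` bilaterian ESUs double as the predators'
    self ESUs (self reads are removed only from samples of that
    predator, and count as prey for the others); the last
    ``n_decoy_esus`` ESUs are non-bilaterian decoys.
    """
    if config.n_esus < 2:
        raise ValueError("n_esus must be >= 2")
    n_bilaterian = config.n_esus - config.n_decoy_esus
    if config.n_predator_species > n_bilaterian:
        raise ValueError("need one bilaterian self ESU per predator species; "
                         "increase n_esus or reduce n_decoy_esus")
    rng = _substream(config.seed, "reference")
    esus = config.esu_labels
    centroids: list[str] = []
    for _ in esus:
        for _attempt in range(100):
            cand = _random_sequence(rng, config.read_length)
            if all(_identity(cand, c) < 0.95 for c in centroids):
                centroids.append(cand)
                break
        else:  # pragma: no cover - vanishingly unlikely for random DNA
            raise RuntimeError("could not draw sufficiently distinct references")
    rows = []
    for esu, centroid in zip(esus, centroids):
        for v in range(config.n_variants_per_esu):
            seq = centroid if v == 0 else _mutate(rng, centroid,
                                                  int(rng.integers(1, 3)))
            rows.append({"ref_id": f"{esu}_v{v + 1}", "sequence": seq,
                         "esu": esu, "abundance": config.n_variants_per_esu - v})
    references = pd.DataFrame(rows)
    decoys = set(esus[-config.n_decoy_esus:]) if config.n_decoy_esus else set()
    esu_table = pd.DataFrame({
        "esu": esus,
        "is_bilaterian": [e not in decoys for e in esus],
    })
    self_esus = {sp: {esus[i]} for i, sp in enumerate(config.species_labels)}
    taxonomy = EsuTaxonomy(esu_table=esu_table, self_esus=self_esus)
    return references, taxonomy


@dataclass
class SimulatedDiet:
    """Bundle from :func:`simulate_diet_samples`.

    ``table`` holds raw OTU counts with sample metadata;
    ``truth`` the per-sample true diet proportions over prey ESUs;
    ``otu_sequences`` maps every feature id to its sequence so the
    table can be pushed through the full processing pipeline.
    """

    table: SampleTable
    truth: pd.DataFrame
    truth_meta: pd.DataFrame
    otu_sequences: dict[str, str]
    bias: pd.Series
    profiles: dict[tuple[str, str], pd.Series] = field(default_factory=dict)


def _prey_esus(config: CommunityConfig, taxonomy: EsuTaxonomy,
               species: str) -> list[str]:
    self_set = taxonomy.self_esus_of(species)
    return [e for e in taxonomy.esus
            if e in taxonomy.bilaterian_esus and e not in self_set]


def simulate_diet_samples(config: CommunityConfig, taxonomy: EsuTaxonomy,
                          references: pd.DataFrame) -> SimulatedDiet:
    """Simulate raw predator GI-tract OTU tables with known truth.

    Per sample: the true diet is drawn from its species x period
    Dirichlet profile; reads are multinomial over the predator's self
    ESUs (``self_read_fraction``), prey ESUs (proportional to
    truth x bias), and non-bilaterian decoy ESUs (``junk_otu_rate``).
    Reads landing on an ESU are split across its reference variants.
    Three screening-target sequences (over-length, dataset singleton,
    8-bp homopolymer) are injected into the first sample, the first
    ``n_shallow_samples`` per species x period are generated below the
    rarefaction depth, and the next ``n_empty_stomach_samples`` carry
    almost only self reads so the prey-read threshold fires.
    """
    if config.n_esus < config.n_predator_species + config.n_decoy_esus + 2:
        raise ValueError("n_esus too small: each predator needs at least two "
                         "shared prey ESUs besides self and decoy ESUs")
    rng = _substream(config.seed, "diets")
    esus = config.esu_labels
    decoys = [e for e in esus if e not in taxonomy.bilaterian_esus]
    if config.bias_factors is not None:
        if len(config.bias_factors) != len(esus):
            raise ValueError("bias_factors must have one entry per ESU")
        bias = pd.Series(config.bias_factors, index=esus, dtype=float)
    else:
        bias = pd.Series(
            np.exp(rng.normal(0.0, config.bias_sigma, size=len(esus))),
            index=esus)
    ref_by_esu = {esu: grp for esu, grp in references.groupby("esu")}
    variant_cols = list(references["ref_id"])
    col_index = {c: i for i, c in enumerate(variant_cols)}
    otu_sequences = dict(zip(references["ref_id"], references["sequence"]))

    counts = []
    meta_rows = []
    truth_rows = []
    sample_ids = []
    for species in config.species_labels:
        prey = _prey_esus(config, taxonomy, species)
        self_set = sorted(taxonomy.self_esus_of(species))
        for period in ("drift", "postdrift"):
            profile = rng.dirichlet(np.ones(len(prey)))
            for k in range(config.n_samples_per_species_period):
                sid = f"{species}_{period}_{k + 1:02d}"
                truth = rng.dirichlet(config.dirichlet_concentration * profile)
                if truth.sum() <= 0 or np.isnan(truth).any():
                    raise ValueError("invalid simplex profile")
                shallow = k < config.n_shallow_samples
                empty = (not shallow and
                         k < config.n_shallow_samples + config.n_empty_stomach_samples)
                if shallow:
                    depth = int(rng.integers(config.rarefaction_depth // 4,
                                             config.rarefaction_depth))
                else:
                    depth = int(rng.integers(int(1.2 * config.rarefaction_depth),
                                             3 * config.rarefaction_depth))
                self_frac = 0.998 if empty else config.self_read_fraction
                junk_frac = 0.001 if empty else config.junk_otu_rate
                prey_frac = 1.0 - self_frac - junk_frac
                probs = np.zeros(len(esus))
                esu_idx = {e: i for i, e in enumerate(esus)}
                biased = truth * bias[prey].to_numpy()
                biased = biased / biased.sum()
                for e, p in zip(prey, biased):
                    probs[esu_idx[e]] = prey_frac * p
                for e in self_set:
                    probs[esu_idx[e]] = self_frac / len(self_set)
                if decoys and junk_frac > 0:
                    for e in decoys:
                        probs[esu_idx[e]] = junk_frac / len(decoys)
                probs = probs / probs.sum()
                esu_reads = rng.multinomial(depth, probs)
                row = np.zeros(len(variant_cols), dtype=np.int64)
                for e, n_reads in zip(esus, esu_reads):
                    if n_reads == 0:
                        continue
                    variants = ref_by_esu[e]
                    share = np.arange(len(variants), 0, -1, dtype=float)
                    vreads = rng.multinomial(n_reads, share / share.sum())
                    for ref_id, nv in zip(variants["ref_id"], vreads):
                        row[col_index[ref_id]] = nv
                counts.append(row)
                sample_ids.append(sid)
                date_pool = range(config.n_drift_nights) if period == "drift" \
                    else range(config.n_postdrift_nights)
                day = int(rng.choice(list(date_pool)))
                meta_rows.append({
                    "predator_species": species, "period": period,
                    "date": f"{period}_day_{day + 1}",
                    "substrate": str(rng.choice(["sand", "gravel"])),
                    "site": str(rng.choice(["PD1", "PD3", "PD4", "PD5"])),
                })
                truth_rows.append(pd.Series(truth, index=prey, name=sid))

    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                             columns=variant_cols)
    # screening-target junk OTUs, injected into the deepest sample so
    # the extra reads never tip a sample below the rarefaction depth
    target = counts_df.sum(axis=1).idxmax()
    junk_seqs = {
        "JUNK_overlong": _random_sequence(rng, 176 + int(rng.integers(0, 25))),
        "JUNK_homopolymer": (lambda s: s[:60] + "A" * 8 + s[68:])(
            _random_sequence(rng, config.read_length)),
        "JUNK_singleton": _random_sequence(rng, config.read_length),
    }
    for name, seq in junk_seqs.items():
        otu_sequences[name] = seq
        counts_df[name] = 0
        counts_df.loc[target, name] = 1 if name == "JUNK_singleton" else 5
    meta = pd.DataFrame(meta_rows, index=counts_df.index)
    truth_df = pd.DataFrame(truth_rows).fillna(0.0)
    truth_meta = meta.loc[truth_df.index, ["predator_species", "period"]]
    table = SampleTable(counts_df, meta)
    return SimulatedDiet(table=table, truth=truth_df, truth_meta=truth_meta,
                         otu_sequences=otu_sequences, bias=bias)


def simulate_mock_homogenate(biomass_proportions, bias_factors, depth: int,
                             seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """One sequenced mock mixture of known biomass composition.

    Sequence counts are multinomial over
    ``normalize(biomass x bias)`` at the given rarefied depth.
    Returns a DataFrame with family, biomass_pct, sequence_count and
    sequence_pct columns.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    biomass = pd.Series(biomass_proportions, dtype=float)
    bias = pd.Series(bias_factors, dtype=float).reindex(biomass.index)
    if bias.isna().any():
        raise ValueError("bias_factors missing for some families")
    if (bias <= 0).any():
        raise ValueError("bias_factors must be positive")
    if (biomass < 0).any() or not np.isclose(biomass.sum(), 1.0, atol=1e-6):
        raise ValueError("biomass proportions must lie on the simplex")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = (biomass * bias) / (biomass * bias).sum()
    reads = rng.multinomial(int(depth), probs.to_numpy())
    return pd.DataFrame({
        "family": biomass.index,
        "biomass_pct": 100.0 * biomass.to_numpy(),
        "sequence_count": reads,
        "sequence_pct": 100.0 * reads / reads.sum(),
    })


def simulate_drift_survey(config: CommunityConfig,
                          family_dry_mass_mg: pd.Series | None = None,
                          pulse_esus: list[str] | None = None) -> pd.DataFrame:
    """Nightly drift-net counts with a period-dependent prey pulse.

    One family per prey ESU; "pulse" families (by default the first
    third of the bilaterian ESUs, emulating larval fish and early
    mayflies) have drift-period mean counts at least as large as their
    postdrift means, which may be zero. Counts are Poisson around the
    period mean; the recorded ``count`` is the subsample count at
    ``subsample_fraction`` of the cod end.

    Returns a tidy frame: night, period, family, esu,
    individual_dry_mass_mg, subsample_fraction, count.
    """
    rng = _substream(config.seed, "drift")
    esus = [e for e in config.esu_labels][:config.n_esus - config.n_decoy_esus]
    if family_dry_mass_mg is None:
        family_dry_mass_mg = pd.Series(
            np.round(np.exp(rng.normal(0.5, 0.8, size=len(esus))), 3),
            index=esus)
    if pulse_esus is None:
        pulse_esus = esus[:max(1, len(esus) // 3)]
    base_mean = np.exp(rng.normal(3.0, 1.0, size=len(esus)))
    nights = ([(f"drift_night_{i + 1}", "drift")
               for i in range(config.n_drift_nights)] +
              [(f"postdrift_night_{i + 1}", "postdrift")
               for i in range(config.n_postdrift_nights)])
    rows = []
    for night, period in nights:
        for esu, mean in zip(esus, base_mean):
            if esu in pulse_esus:
                mu = mean if period == "drift" else mean * float(rng.uniform(0, 0.15))
            else:
                mu = mean * float(rng.uniform(0.5, 1.5))
            rows.append({
                "night": night, "period": period, "family": f"Fam_{esu}",
                "esu": esu,
                "individual_dry_mass_mg": float(family_dry_mass_mg[esu]),
                "subsample_fraction": config.subsample_fraction,
                "count": int(rng.poisson(mu)),
            })
    return pd.DataFrame(rows)


def write_fixtures(config: CommunityConfig, outdir: str | Path) -> dict:
    """Generate and write the full fixture set under ``outdir``.

    FASTA for references, TSVs for OTU counts / metadata / truth /
    taxonomy / drift survey, and a manifest JSON recording config and
    seed. Returns the manifest dict.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    references, taxonomy = generate_reference_db(config)
    sim = simulate_diet_samples(config, taxonomy, references)
    survey = simulate_drift_survey(config)

    records = [SeqRecord(Seq(row["sequence"]), id=row["ref_id"],
                         description=row["esu"])
               for _, row in references.iterrows()]
    SeqIO.write(records, out / "references.fasta", "fasta")
    sim.table.counts.to_csv(out / "otu_counts.tsv", sep="\t")
    sim.table.metadata.to_csv(out / "sample_metadata.tsv", sep="\t")
    sim.truth.to_csv(out / "truth_proportions.tsv", sep="\t")
    taxonomy.to_frame().to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    survey.to_csv(out / "drift_survey.tsv", sep="\t", index=False)
    pd.DataFrame({"otu_id": list(sim.otu_sequences),
                  "sequence": list(sim.otu_sequences.values())}
                 ).to_csv(out / "otu_sequences.tsv", sep="\t", index=False)
    manifest = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "files": ["references.fasta", "otu_counts.tsv", "sample_metadata.tsv",
                  "truth_proportions.tsv", "taxonomy.tsv", "drift_survey.tsv",
                  "otu_sequences.tsv"],
        "n_samples": int(len(sim.table.samples)),
        "n_features": int(len(sim.table.features)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
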